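"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lncstpred import DEFAULT_MODEL, DotBracketStructure, RnaSequence, score_structure


def enumerate_nested_structures(res: str, model=DEFAULT_MODEL):
    """Yield every legal pseudoknot-free dot-bracket for a short sequence.

    Independent enumeration oracle: picks the leftmost pair of a structure
    and recurses on the enclosed and following positions; deduplicates by
    pair set. Only practical for sequences up to ~12 nt.
    """
    n = len(res)

    def rec(positions):
        yield []
        for ai, i in enumerate(positions):
            for j in positions[ai + 1 :]:
                if j - i - 1 >= model.min_hairpin and model.pair_allowed(res[i], res[j]):
                    inside = [p for p in positions if i < p < j]
                    outside = [p for p in positions if p > j]
                    for s1 in rec(inside):
                        for s2 in rec(outside):
                            yield [(i, j)] + s1 + s2

    seen = set()
    for pairing in rec(list(range(n))):
        key = frozenset(pairing)
        if key in seen:
            continue
        seen.add(key)
        s = ["."] * n
        for i, j in pairing:
            s[i], s[j] = "(", ")"
        yield "".join(s)


def brute_force_mfe(seq: RnaSequence, model=DEFAULT_MODEL) -> float:
    """Exhaustive minimum of score_structure over all nested structures."""
    best = 0.0
    for s in enumerate_nested_structures(seq.residues, model):
        e = score_structure(seq, DotBracketStructure(s), model)
        if e < best:
            best = e
    return best


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
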