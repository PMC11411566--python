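"""Sequence feature extraction: overlapping k-mer and reading-frame triplet
frequencies, plus a minimum-free-energy scalar.

The full composition is 257 numbers per sequence: 64 overlapping 3-mer
frequencies, three blocks of 64 non-overlapping triplet frequencies (one per
reading frame), and one MFE value in kcal/mol. Triplets are ordered
lexicographically with A < C < G < U, the same order in every block.
"""

from __future__ import annotations

from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import LabelledSequenceSet, RnaSequence

BASES = "ACGU"
#: All 64 triplets in lexicographic order; fixed feature order everywhere.
TRIPLETS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))
_TRIPLET_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRIPLETS)}

FEATURE_GROUPS = ("3mer", "3rf", "mfe")


def kmer_frequencies(seq: RnaSequence, k: int = 3) -> np.ndarray:
    """Overlapping k-mer frequencies in lexicographic order.

    Counts over all M-k+1 windows, divided by M-k+1, so the vector sums
    to 1 for any sequence with at least one window.
    """
    m = len(seq)
    if m < k:
        raise ValueError(f"sequence {seq.id!r}: length {m} < k = {k}")
    if k == 3:
        index = _TRIPLET_INDEX
        size = 64
    else:
        words = ["".join(p) for p in product(BASES, repeat=k)]
        index = {w: i for i, w in enumerate(words)}
        size = 4**k
    counts = np.zeros(size)
    res = seq.residues
    for i in range(m - k + 1):
        counts[index[res[i : i + k]]] += 1
    return counts / (m - k + 1)


def rf_frequencies(seq: RnaSequence) -> np.ndarray:
    """Non-overlapping triplet frequencies for the three reading frames.

    Frame x (x = 1, 2, 3) reads triplets starting at position x (1-based)
    and advancing in steps of 3; a trailing partial triplet is dropped.
    Each frame's 64-vector is normalized by its own triplet count, so the
    result is a (3, 64) array whose rows each sum to 1. Requires M >= 5 so
    every frame holds at least one full triplet.
    """
    m = len(seq)
    if m < 5:
        raise ValueError(f"sequence {seq.id!r}: length {m} < 5, frame 3 empty")
    out = np.zeros((3, 64))
    res = seq.residues
    for frame in range(3):
        n = (m - frame) // 3
        for j in range(n):
            start = frame + 3 * j
            out[frame, _TRIPLET_INDEX[res[start : start + 3]]] += 1
        out[frame] /= n
    return out


def feature_manifest(groups: Sequence[str] = FEATURE_GROUPS) -> list[str]:
    """Ordered feature names for the selected groups.

    Names are ``3mer:AAA`` ... ``3mer:UUU``, ``RF1:AAA`` ... ``RF3:UUU``,
    and ``MFE``.
    """
    names: list[str] = []
    for g in groups:
        if g == "3mer":
            names.extend(f"3mer:{t}" for t in TRIPLETS)
        elif g == "3rf":
            for frame in (1, 2, 3):
                names.extend(f"RF{frame}:{t}" for t in TRIPLETS)
        elif g == "mfe":
            names.append("MFE")
        else:
            raise ValueError(f"unknown feature group {g!r}")
    return names


MfeProvider = Callable[[RnaSequence], float]


def assemble_features(
    dataset: LabelledSequenceSet,
    mfe_provider: MfeProvider | Mapping[str, float] | None = None,
    groups: Sequence[str] = FEATURE_GROUPS,
    mfe_per_nt: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Build the feature matrix for a labelled dataset.

    Parameters
    ----------
    dataset:
        Sequences plus labels; row order matches ``dataset.sequences``.
    mfe_provider:
        Either a callable mapping a sequence to its MFE (kcal/mol), or a
        precomputed ``{id: mfe}`` mapping (e.g. imported RNAfold energies).
        Required iff ``"mfe"`` is among ``groups``.
    groups:
        Feature groups to include, any subset of ``("3mer", "3rf", "mfe")``;
        subsets support feature-combination ablations.
    mfe_per_nt:
        If true, divide the MFE by sequence length (kcal/mol/nt); by default
        the raw MFE is used.

    Returns
    -------
    (frame, manifest)
        A DataFrame indexed by sequence id with one column per feature plus
        a final ``label`` column, and the feature-name manifest.
    """
    for g in groups:
        if g not in FEATURE_GROUPS:
            raise ValueError(f"unknown feature group {g!r}")
    if "mfe" in groups and mfe_provider is None:
        raise ValueError("mfe group requested but no mfe_provider given")

    manifest = feature_manifest(groups)
    rows = np.empty((len(dataset.sequences), len(manifest)))
    for r, seq in enumerate(dataset.sequences):
        parts: list[np.ndarray] = []
        for g in groups:
            if g == "3mer":
                parts.append(kmer_frequencies(seq))
            elif g == "3rf":
                parts.append(rf_frequencies(seq).ravel())
            else:
                if callable(mfe_provider):
                    mfe = mfe_provider(seq)
                else:
                    try:
                        mfe = mfe_provider[seq.id]  # type: ignore[index]
                    except KeyError:
                        raise ValueError(
                            f"no imported MFE for sequence {seq.id!r}"
                        ) from None
                if mfe_per_nt:
                    mfe = mfe / len(seq)
                parts.append(np.array([mfe]))
        rows[r] = np.concatenate(parts)

    frame = pd.DataFrame(rows, columns=manifest, index=[s.id for s in dataset.sequences])
    frame["label"] = [dataset.labels[s.id] for s in dataset.sequences]
    return frame, manifest


def matrix_from_frame(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a featurize-style DataFrame into (X, y, feature names)."""
    names = [c for c in frame.columns if c != "label"]
    return frame[names].to_numpy(dtype=float), frame["label"].to_numpy(), names


def subset_columns(manifest: Iterable[str], groups: Sequence[str]) -> list[str]:
    """Manifest names belonging to the requested feature groups."""
    wanted = feature_manifest(groups)
    have = set(manifest)
    missing = [n for n in wanted if n not in have]
    if missing:
        raise ValueError(f"features missing from manifest: {missing[:5]}")
    return wanted
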