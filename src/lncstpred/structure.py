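"""RNA secondary structure: simplified minimum-free-energy folding,
dot-bracket window classification, and triplex-by-substructure tables.

Two folding backends are supported. The built-in backend is an
interval dynamic program over the classic loop decomposition (hairpin,
stack, bulge, interior, multibranch) with a small integer-valued energy
model; it is self-contained and exactly minimizes the energy it defines,
but its parameters are deliberately simple and are NOT the Turner rules.
For biological fidelity the external RNAfold program (ViennaRNA) is the
recommended backend; its text output can be imported directly.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import TRIPLETS
from .sequence_io import (
    LabelledSequenceSet,
    RnaSequence,
    brackets_balanced,
    read_rnafold_output,
)

INF = float("inf")

#: Watson-Crick plus wobble pairs.
ALLOWED_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})
_WC = frozenset({"CG", "GC"})
_WOBBLE = frozenset({"GU", "UG"})


@dataclass(frozen=True)
class EnergyModel:
    """Simplified nearest-neighbour energy model (kcal/mol).

    Stacking rewards depend only on which pair families stack: two
    Watson-Crick G:C-type pairs stack best, a stack involving an A:U-type
    pair is intermediate, and any stack involving a wobble pair is weakest.
    Loop penalties grow mildly with loop size. Integer-friendly values keep
    exhaustive enumeration oracles exact.
    """

    stack_gc_gc: float = -3.0
    stack_mixed: float = -2.0
    stack_wobble: float = -1.0
    hairpin_base: float = 3.0
    bulge_base: float = 2.0
    bulge_per_nt: float = 0.5
    interior_base: float = 2.0
    interior_per_nt: float = 0.5
    multiloop_base: float = 4.0
    multiloop_per_branch: float = 1.0
    min_hairpin: int = 3
    #: Two-sided interior/bulge loops larger than this are not searched.
    max_internal: int = 30
    allowed_pairs: frozenset[str] = field(default=ALLOWED_PAIRS)

    def pair_allowed(self, a: str, b: str) -> bool:
        return a + b in self.allowed_pairs

    def stack_energy(self, outer: str, inner: str) -> float:
        """Stacking energy of pair ``inner`` directly inside pair ``outer``."""
        if outer in _WOBBLE or inner in _WOBBLE:
            return self.stack_wobble
        if outer in _WC and inner in _WC:
            return self.stack_gc_gc
        return self.stack_mixed

    def hairpin(self, size: int) -> float:
        if size < self.min_hairpin:
            return INF
        return self.hairpin_base

    def two_loop(self, outer: str, inner: str, s5: int, s3: int) -> float:
        """Energy of the loop between two pairs: stack, bulge, or interior."""
        if s5 == 0 and s3 == 0:
            return self.stack_energy(outer, inner)
        size = s5 + s3
        if s5 == 0 or s3 == 0:
            return self.bulge_base + self.bulge_per_nt * size
        return self.interior_base + self.interior_per_nt * size

    def multiloop(self, branches: int) -> float:
        """Closing penalty of a multibranch loop with ``branches`` inner helices."""
        return self.multiloop_base + self.multiloop_per_branch * branches


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class DotBracketStructure:
    """A balanced dot-bracket string aligned to a sequence."""

    structure: str
    source: str = "builtin"  # builtin | imported

    def __post_init__(self) -> None:
        if not brackets_balanced(self.structure):
            raise ValueError("unbalanced or invalid dot-bracket string")

    def __len__(self) -> int:
        return len(self.structure)

    def pairs(self) -> list[tuple[int, int]]:
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for i, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                out.append((stack.pop(), i))
        return sorted(out)


def score_structure(
    seq: RnaSequence, structure: DotBracketStructure, model: EnergyModel = DEFAULT_MODEL
) -> float:
    """Energy of a given nested structure under the loop decomposition.

    Every base pair closes exactly one loop (hairpin, two-loop, or
    multibranch); external unpaired bases are free. This scorer is the
    single definition of energy shared by the dynamic program and any
    enumeration oracle.
    """
    s = structure.structure
    if len(s) != len(seq):
        raise ValueError("structure length != sequence length")
    pairs = structure.pairs()
    partner = {i: j for i, j in pairs} | {j: i for i, j in pairs}
    res = seq.residues
    total = 0.0
    for i, j in pairs:
        outer = res[i] + res[j]
        if outer not in model.allowed_pairs:
            return INF
        # directly accessible interior pairs and unpaired count
        inner_pairs: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner:
                inner_pairs.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not inner_pairs:
            total += model.hairpin(j - i - 1)
        elif len(inner_pairs) == 1:
            p, q = inner_pairs[0]
            total += model.two_loop(outer, res[p] + res[q], p - i - 1, j - q - 1)
        else:
            total += model.multiloop(len(inner_pairs))
    return total


def _legal(res: str, i: int, j: int, model: EnergyModel) -> bool:
    return j - i - 1 >= model.min_hairpin and model.pair_allowed(res[i], res[j])


def fold_mfe(
    seq: RnaSequence, model: EnergyModel = DEFAULT_MODEL
) -> tuple[float, DotBracketStructure]:
    """Minimum-free-energy fold by interval dynamic programming.

    Minimizes :func:`score_structure` over all pseudoknot-free structures
    whose pairs are in ``model.allowed_pairs``, separated by at least
    ``model.min_hairpin`` unpaired bases, and whose bulge/interior loops are
    at most ``model.max_internal`` nt. The empty structure scores 0, so the
    returned MFE is always <= 0. Traceback reconstructs one optimal
    dot-bracket, which rescoring reproduces exactly.

    Intended for short-to-moderate sequences; the external RNAfold backend
    is preferred for bulk folding.
    """
    n = len(seq)
    res = seq.residues
    if n < model.min_hairpin + 2:
        return 0.0, DotBracketStructure("." * n)

    V = np.full((n, n), INF)   # best energy with (i, j) paired
    M = np.full((n, n), INF)   # >= 1 multiloop branch packed in [i, j]
    M2 = np.full((n, n), INF)  # >= 2 branches
    per_branch = model.multiloop_per_branch

    for span in range(model.min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V ---
            if _legal(res, i, j, model):
                outer = res[i] + res[j]
                best = model.hairpin(j - i - 1)
                for p in range(i + 1, j):
                    if p - i - 1 > model.max_internal:
                        break
                    qmin = max(p + model.min_hairpin + 1,
                               j - 1 - (model.max_internal - (p - i - 1)))
                    for q in range(j - 1, qmin - 1, -1):
                        if V[p, q] < INF:
                            cand = V[p, q] + model.two_loop(
                                outer, res[p] + res[q], p - i - 1, j - q - 1
                            )
                            if cand < best:
                                best = cand
                if j - i >= 2 and M2[i + 1, j - 1] < INF:
                    cand = model.multiloop_base + M2[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            # --- M / M2: pack branches, unpaired bases free ---
            m_best = M[i + 1, j] if i + 1 <= j else INF
            m2_best = M2[i + 1, j] if i + 1 <= j else INF
            for q in range(i + model.min_hairpin + 1, j + 1):
                if V[i, q] < INF:
                    branch = V[i, q] + per_branch
                    rest = M[q + 1, j] if q + 1 <= j else INF
                    # remainder may be all-unpaired (0) or hold more branches
                    m_best = min(m_best, branch + min(rest, 0.0))
                    if rest < INF:
                        m2_best = min(m2_best, branch + rest)
            M[i, j] = m_best
            M2[i, j] = m2_best

    # external level
    W = np.zeros(n + 1)  # W[j+1] = best energy of prefix 0..j
    for j in range(n):
        best = W[j]
        for i in range(0, j - model.min_hairpin):
            if V[i, j] < INF:
                best = min(best, W[i] + V[i, j])
        W[j + 1] = best

    structure = ["."] * n

    def trace_V(i: int, j: int) -> None:
        structure[i], structure[j] = "(", ")"
        target = V[i, j]
        outer = res[i] + res[j]
        if target == model.hairpin(j - i - 1):
            return
        for p in range(i + 1, j):
            if p - i - 1 > model.max_internal:
                break
            for q in range(j - 1, p + model.min_hairpin, -1):
                if j - 1 - q + p - i - 1 > model.max_internal:
                    continue
                if V[p, q] < INF and np.isclose(
                    V[p, q] + model.two_loop(outer, res[p] + res[q], p - i - 1, j - q - 1),
                    target,
                ):
                    trace_V(p, q)
                    return
        trace_M2(i + 1, j - 1, target - model.multiloop_base)

    def trace_M(i: int, j: int, target: float) -> None:
        while True:
            if i > j:
                raise AssertionError("traceback fell off M interval")
            if i + 1 <= j and np.isclose(M[i + 1, j], target):
                i += 1
                continue
            for q in range(i + model.min_hairpin + 1, j + 1):
                if V[i, q] >= INF:
                    continue
                branch = V[i, q] + per_branch
                if np.isclose(branch, target):
                    trace_V(i, q)
                    return
                rest = M[q + 1, j] if q + 1 <= j else INF
                if rest < INF and np.isclose(branch + rest, target):
                    trace_V(i, q)
                    trace_M(q + 1, j, rest)
                    return
            raise AssertionError("traceback failed in M")

    def trace_M2(i: int, j: int, target: float) -> None:
        while True:
            if i + 1 <= j and np.isclose(M2[i + 1, j], target):
                i += 1
                continue
            for q in range(i + model.min_hairpin + 1, j + 1):
                if V[i, q] >= INF:
                    continue
                branch = V[i, q] + per_branch
                rest = M[q + 1, j] if q + 1 <= j else INF
                if rest < INF and np.isclose(branch + rest, target):
                    trace_V(i, q)
                    trace_M(q + 1, j, rest)
                    return
            raise AssertionError("traceback failed in M2")

    j = n - 1
    while j >= 0:
        if np.isclose(W[j + 1], W[j]):
            j -= 1
            continue
        for i in range(0, j - model.min_hairpin):
            if V[i, j] < INF and np.isclose(W[i] + V[i, j], W[j + 1]):
                trace_V(i, j)
                j = i - 1
                break
        else:
            raise AssertionError("traceback failed at external level")

    db = DotBracketStructure("".join(structure), source="builtin")
    return float(W[n]), db


# ---------------------------------------------------------------------------
# MFE providers


def rnafold_available() -> bool:
    return shutil.which("RNAfold") is not None


def rnafold_fold(
    sequences: Sequence[RnaSequence],
) -> dict[str, tuple[str, float]]:
    """Fold sequences with the external RNAfold program.

    Returns ``{id: (dot_bracket, mfe)}``. Requires the ``RNAfold``
    executable on PATH.
    """
    if not rnafold_available():
        raise RuntimeError("RNAfold executable not found on PATH")
    fasta = "".join(f">{s.id}\n{s.residues}\n" for s in sequences)
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input=fasta,
        capture_output=True,
        text=True,
        check=True,
    )
    out: dict[str, tuple[str, float]] = {}
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    for k in range(0, len(lines), 3):
        rec_id = lines[k][1:].split()[0]
        struct_line = lines[k + 2]
        lpar = struct_line.rfind("(")
        structure = struct_line[:lpar].strip()
        mfe = float(struct_line[lpar + 1 :].rstrip(")").strip())
        out[rec_id] = (structure, mfe)
    return out


def mfe_provider_builtin(model: EnergyModel = DEFAULT_MODEL):
    """Per-sequence MFE callable backed by the built-in folder."""

    def provider(seq: RnaSequence) -> float:
        return fold_mfe(seq, model)[0]

    return provider


def mfe_map_from_rnafold_file(path) -> dict[str, float]:
    """Imported energies from an RNAfold output file, keyed by id."""
    return {seq.id: mfe for seq, _, mfe in read_rnafold_output(path)}


# ---------------------------------------------------------------------------
# Substructure classification and triplex tables

CATEGORIES = ("junction", "loop", "stem")

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGU"):
    _BASE_CODE[ord(_b)] = _i


def _triplet_indices(residues: str) -> np.ndarray:
    """Lexicographic triplet index of every overlapping window."""
    codes = _BASE_CODE[np.frombuffer(residues.encode(), dtype=np.uint8)]
    return 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]


def _window_categories(s: str) -> np.ndarray:
    """Vectorized per-window category codes: 0 junction, 1 loop, 2 stem."""
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    dot = arr == ord(".")
    opn = arr == ord("(")
    cls = arr == ord(")")
    loop = dot[:-2] & dot[1:-1] & dot[2:]
    stem = (opn[:-2] & opn[1:-1] & opn[2:]) | (cls[:-2] & cls[1:-1] & cls[2:])
    codes = np.zeros(len(s) - 2, dtype=np.int8)
    codes[loop] = 1
    codes[stem] = 2
    return codes


def classify_windows(structure: DotBracketStructure | str) -> list[str]:
    """Classify each 3-character structure window as stem, loop, or junction.

    A window is a loop if all three characters are ``.``, a stem if all
    three are ``(`` or all three are ``)``, and a junction otherwise.
    Returns M-2 categories for a structure of length M.
    """
    if isinstance(structure, str):
        structure = DotBracketStructure(structure)
    names = np.array(["junction", "loop", "stem"])
    return names[_window_categories(structure.structure)].tolist()


def triplex_substructure_frequencies(
    pairs: Iterable[tuple[RnaSequence, DotBracketStructure | str]],
) -> tuple[pd.DataFrame, list[str]]:
    """Triplet frequency per substructure category, in percent.

    For each category c and triplet t, ``freq(t | c)`` is the fraction of
    windows of category c whose sequence triplet is t, times 100, so each
    category column is a distribution over the 64 triplets summing to 100%.
    The ``baseline`` column is the uniform expectation 100/64 = 1.5625%.

    Returns the table plus a list of categories that had zero windows
    (reported as all-zero columns).
    """
    counts = {c: np.zeros(64) for c in CATEGORIES}
    n_pairs = 0
    for seq, structure in pairs:
        if isinstance(structure, str):
            structure = DotBracketStructure(structure, source="imported")
        if len(structure) != len(seq):
            raise ValueError(f"sequence {seq.id!r}: structure length mismatch")
        codes = _window_categories(structure.structure)
        trip = _triplet_indices(seq.residues)
        for code, cat in enumerate(("junction", "loop", "stem")):
            sel = trip[codes == code]
            if len(sel):
                counts[cat] += np.bincount(sel, minlength=64)
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("empty input: no (sequence, structure) pairs")

    table = pd.DataFrame(index=list(TRIPLETS))
    empty: list[str] = []
    for c in CATEGORIES:
        total = counts[c].sum()
        if total == 0:
            empty.append(c)
            table[c] = 0.0
        else:
            table[c] = 100.0 * counts[c] / total
    table["baseline"] = 100.0 / 64
    return table, empty


def sequence_triplex_frequencies(dataset: LabelledSequenceSet) -> dict[str, float]:
    """Pooled overlapping-triplet frequencies over all sequences, in percent."""
    if not dataset.sequences:
        raise ValueError("empty dataset")
    counts = np.zeros(64)
    for seq in dataset.sequences:
        counts += np.bincount(_triplet_indices(seq.residues), minlength=64)
    freqs = 100.0 * counts / counts.sum()
    return {t: float(freqs[i]) for i, t in enumerate(TRIPLETS)}
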