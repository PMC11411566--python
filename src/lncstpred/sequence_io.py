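"""Sequence and label input, dataset-construction filters, and RNAfold interop.

Sequences are held as RNA (``T`` is normalized to ``U`` on input, case is
folded to upper). Records containing ambiguity codes are rejected rather than
window-skipped so that every downstream triplet count is well defined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

ALPHABET = frozenset("ACGU")
#: Hard floor on sequence length: each of the three reading frames must
#: contain at least one full triplet, which requires M >= 5.
MIN_LENGTH = 5


class SequenceIOError(ValueError):
    """Raised for malformed FASTA/label/fold inputs."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence: identifier plus residues over {A,C,G,U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("sequence id must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceIOError(
                f"sequence {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabelledSequenceSet:
    """Sequences plus a single localization label per sequence.

    ``class_set`` is the sorted list of distinct class names; its order is
    fixed and used for all downstream tie-breaking.
    """

    sequences: list[RnaSequence]
    labels: dict[str, str]
    class_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            raise SequenceIOError("duplicate sequence ids in dataset")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise SequenceIOError(f"sequences without labels: {missing[:5]}")
        if not self.class_set:
            self.class_set = sorted(set(self.labels.values()))
        for sid, lab in self.labels.items():
            if lab not in self.class_set:
                raise SequenceIOError(f"label {lab!r} of {sid!r} not in class_set")

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.class_set}
        for seq in self.sequences:
            counts[self.labels[seq.id]] += 1
        return counts

    def __len__(self) -> int:
        return len(self.sequences)


def normalize_residues(raw: str) -> str:
    """Uppercase and convert DNA T to RNA U. Does not validate."""
    return raw.upper().replace("T", "U")


def _iter_fasta_records(text: str) -> Iterable[tuple[str, str]]:
    header = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif header is not None:
            chunks.append(line)
        else:
            raise SequenceIOError("FASTA file does not start with a '>' header")
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(
    path: str | Path, min_length: int = MIN_LENGTH
) -> tuple[list[RnaSequence], list[tuple[str, str]]]:
    """Read a FASTA file, normalize to RNA, and filter invalid records.

    Records shorter than ``min_length`` or containing characters outside
    A/C/G/U/T (either case) are rejected and reported, not raised.

    Returns
    -------
    (sequences, rejected)
        ``sequences`` are the accepted records in file order; ``rejected``
        is a list of (id, reason) pairs.

    Raises
    ------
    SequenceIOError
        On unreadable files, duplicate ids among accepted records, or when
        no record survives filtering.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise SequenceIOError(f"cannot read FASTA file {path}: {exc}") from exc

    accepted: list[RnaSequence] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec_id, raw in _iter_fasta_records(text):
        if not rec_id:
            rejected.append(("", "empty record id"))
            continue
        residues = normalize_residues(raw)
        bad = set(residues) - ALPHABET
        if bad:
            rejected.append((rec_id, f"invalid characters {sorted(bad)}"))
            continue
        if len(residues) < min_length:
            rejected.append(
                (rec_id, f"length {len(residues)} < min_length {min_length}")
            )
            continue
        if rec_id in seen:
            raise SequenceIOError(f"duplicate sequence id {rec_id!r}")
        seen.add(rec_id)
        accepted.append(RnaSequence(rec_id, residues))
    if not accepted:
        raise SequenceIOError(
            f"no sequences remain after filtering {path} "
            f"({len(rejected)} rejected)"
        )
    return accepted, rejected


def write_fasta(sequences: Sequence[RnaSequence], path: str | Path, width: int = 70) -> None:
    lines: list[str] = []
    for seq in sequences:
        lines.append(f">{seq.id}")
        for i in range(0, len(seq.residues), width):
            lines.append(seq.residues[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(
    path: str | Path, sequences: Sequence[RnaSequence]
) -> tuple[LabelledSequenceSet, list[str]]:
    """Read a two-column ``id<TAB>class`` TSV and match it to sequences.

    Sequences without a label and labels referencing unknown ids are
    excluded and returned as warnings, not errors. An id labelled twice with
    different classes is an error.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    warnings: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"\t", line)
        if len(parts) != 2:
            raise SequenceIOError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sid, cls = parts[0].strip(), parts[1].strip()
        if sid in labels and labels[sid] != cls:
            raise SequenceIOError(
                f"id {sid!r} labelled both {labels[sid]!r} and {cls!r}"
            )
        labels[sid] = cls

    known = {s.id for s in sequences}
    for sid in sorted(set(labels) - known):
        warnings.append(f"label for unknown id {sid!r} ignored")
        del labels[sid]
    kept = [s for s in sequences if s.id in labels]
    for s in sequences:
        if s.id not in labels:
            warnings.append(f"sequence {s.id!r} has no label; excluded")
    if not kept:
        raise SequenceIOError("no labelled sequences remain")
    return LabelledSequenceSet(kept, labels), warnings


def filter_min_class_size(
    dataset: LabelledSequenceSet, min_count: int = 10
) -> LabelledSequenceSet:
    """Drop classes with fewer than ``min_count`` members (and their sequences).

    The boundary is "below ``min_count``": a class with exactly ``min_count``
    members is retained.
    """
    counts = dataset.class_counts()
    keep_classes = sorted(c for c, n in counts.items() if n >= min_count)
    if not keep_classes:
        raise SequenceIOError(
            f"no classes remain with at least {min_count} members"
        )
    kept = [s for s in dataset.sequences if dataset.labels[s.id] in keep_classes]
    labels = {s.id: dataset.labels[s.id] for s in kept}
    return LabelledSequenceSet(kept, labels, keep_classes)


def _distinct_words(residues: str, word_size: int) -> frozenset[str]:
    return frozenset(
        residues[i : i + word_size] for i in range(len(residues) - word_size + 1)
    )


def word_similarity(a: RnaSequence, b: RnaSequence, word_size: int = 5) -> float:
    """Fraction of the shorter sequence's distinct words contained in the longer.

    A lightweight stand-in for alignment identity used by the greedy
    redundancy filter; 1.0 for identical sequences, 0.0 for sequences sharing
    no ``word_size``-mer.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    words_short = _distinct_words(short.residues, word_size)
    if not words_short:
        return 0.0
    words_long = _distinct_words(long_.residues, word_size)
    return len(words_short & words_long) / len(words_short)


def greedy_redundancy_filter(
    sequences: Sequence[RnaSequence],
    identity_threshold: float = 0.80,
    word_size: int = 5,
    seed: int = 0,
) -> list[RnaSequence]:
    """Greedy incremental clustering for redundancy reduction.

    Sequences are visited in order of descending length (ties broken by id so
    the result is deterministic); each joins the first existing cluster whose
    representative is at least ``identity_threshold`` similar under
    :func:`word_similarity`, else founds a new cluster. One representative
    (the longest member, i.e. the founder) is returned per cluster, in the
    order clusters were founded.

    This is a deliberately simple word-containment scheme, not a
    reimplementation of CD-HIT; it reproduces the shape of the redundancy
    step, not CD-HIT's exact clustering.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(sequences, key=lambda s: (-len(s), s.id))
    representatives: list[RnaSequence] = []
    for seq in ordered:
        for rep in representatives:
            if word_similarity(seq, rep, word_size) >= identity_threshold:
                break
        else:
            representatives.append(seq)
    return representatives


_FOLD_ENERGY_RE = re.compile(r"^(?P<struct>[().]+)\s*\(\s*(?P<mfe>-?\d+(?:\.\d+)?)\s*\)\s*$")


def brackets_balanced(structure: str) -> bool:
    depth = 0
    for ch in structure:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
        elif ch != ".":
            return False
    return depth == 0


def read_rnafold_output(
    path: str | Path,
) -> list[tuple[RnaSequence, str, float]]:
    """Parse RNAfold text output: header, sequence, then structure + energy.

    Each record is ``>id`` / sequence line / ``structure ( MFE )``. The
    structure must match the sequence length and have balanced brackets.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) % 3 != 0:
        raise SequenceIOError(
            "RNAfold output must consist of (header, sequence, structure) triples"
        )
    out: list[tuple[RnaSequence, str, float]] = []
    for i in range(0, len(lines), 3):
        header, seq_line, struct_line = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise SequenceIOError(f"expected '>' header, got {header!r}")
        rec_id = header[1:].split()[0]
        seq = RnaSequence(rec_id, normalize_residues(seq_line.strip()))
        m = _FOLD_ENERGY_RE.match(struct_line.strip())
        if m is None:
            raise SequenceIOError(f"record {rec_id!r}: unparsable structure/energy line")
        structure, mfe = m.group("struct"), float(m.group("mfe"))
        if len(structure) != len(seq):
            raise SequenceIOError(
                f"record {rec_id!r}: structure length {len(structure)} != "
                f"sequence length {len(seq)}"
            )
        if not brackets_balanced(structure):
            raise SequenceIOError(f"record {rec_id!r}: unbalanced brackets")
        out.append((seq, structure, mfe))
    return out
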