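"""Sequence-screening utilities.

Two desk-scale screens used when designing RNAi and PCR reagents against
repetitive elements: a mismatch-tolerant scan for transcript regions
complementary to an shRNA/siRNA guide (Hamming distance against the guide's
reverse complement; substitutions only, no indels or wobble), and selection
of the least variable window of a multiple alignment (entropy-based column
variability with an explicit gap penalty) for primer placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SeqHit",
    "AlignmentWindow",
    "reverse_complement",
    "find_complementary_sites",
    "least_variable_window",
    "read_fasta",
    "write_fasta",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    return [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SeqHit:
    seq_id: str
    start: int          # 0-based half-open on the subject sequence
    end: int
    mismatches: int
    strand: str = "+"   # match of the guide's reverse complement on this strand


@dataclass(frozen=True)
class AlignmentWindow:
    start: int          # 0-based half-open alignment columns
    end: int
    score: float        # mean per-column variability (lower = more conserved)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the alphabet {A, C, G, T, N}."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide: {exc.args[0]!r}") from None


_ENCODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENCODE[ord(b)] = i
_ENCODE[ord("N")] = 4  # N in the subject counts as a mismatch to any base


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if np.any(arr < 0):
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"invalid nucleotide: {bad!r}")
    return arr


def find_complementary_sites(
    guide: str, sequences, max_mismatch: int = 0, min_guide_len: int = 15
) -> list[SeqHit]:
    """All windows whose sequence matches the reverse complement of the
    guide with at most ``max_mismatch`` substitutions.

    ``sequences`` is an iterable of (seq_id, sequence) pairs (e.g. from
    ``Bio.SeqIO`` records via ``(r.id, str(r.seq))``).  ``N`` in the subject
    counts as a mismatch.  Hits are sorted by (seq_id, start).
    """
    g = guide.upper()
    if len(g) < min_guide_len:
        raise ValueError(f"guide shorter than {min_guide_len} nt")
    if any(b not in "ACGT" for b in g):
        raise ValueError("guide must be over {A,C,G,T}")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    site = _encode(reverse_complement(g))
    L = len(site)
    hits: list[SeqHit] = []
    for seq_id, seq in sequences:
        s = _encode(str(seq))
        n = s.size
        if n < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(s, L)
        mismatches = (windows != site).sum(axis=1)
        for start in np.flatnonzero(mismatches <= max_mismatch):
            hits.append(
                SeqHit(
                    seq_id=str(seq_id),
                    start=int(start),
                    end=int(start) + L,
                    mismatches=int(mismatches[start]),
                )
            )
    hits.sort(key=lambda h: (h.seq_id, h.start))
    return hits


def _column_variability(column: list[str], gap_penalty: float) -> float:
    """Shannon entropy (nats) of non-gap residue frequencies plus
    gap_penalty * gap fraction."""
    n = len(column)
    gaps = sum(1 for b in column if b == "-")
    residues = [b for b in column if b != "-"]
    if not residues:
        return gap_penalty
    counts: dict[str, int] = {}
    for b in residues:
        counts[b] = counts.get(b, 0) + 1
    total = len(residues)
    entropy = -sum((c / total) * math.log(c / total) for c in counts.values())
    return entropy + gap_penalty * (gaps / n)


def least_variable_window(
    alignment, window_len: int, gap_penalty: float | None = None
) -> AlignmentWindow:
    """Most conserved window of an equal-length gapped alignment.

    Per-column variability = entropy of non-gap residues (natural units)
    plus ``gap_penalty`` times the gap fraction (default penalty: the
    maximum attainable nucleotide entropy, ln 4); the window minimizing the
    sliding mean is returned, leftmost on ties.

    ``alignment`` is an iterable of aligned sequence strings (or objects
    with ``str()`` giving the sequence, e.g. Bio.Align records).
    """
    seqs = [str(getattr(s, "seq", s)).upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need >= 2 aligned sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    (length,) = lengths
    if not (0 < window_len <= length):
        raise ValueError("window_len must be in [1, alignment length]")
    if gap_penalty is None:
        gap_penalty = math.log(4.0)

    col_scores = np.array(
        [
            _column_variability([s[i] for s in seqs], gap_penalty)
            for i in range(length)
        ]
    )
    window_means = np.convolve(col_scores, np.ones(window_len), mode="valid") / window_len
    start = int(np.argmin(window_means))  # argmin returns leftmost minimum
    return AlignmentWindow(
        start=start, end=start + window_len, score=float(window_means[start])
    )
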