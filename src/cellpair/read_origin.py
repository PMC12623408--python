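"""Alignment-free two-reference read-origin classification and rRNA fraction.

A quality-control check for cell-line identity: reads are assigned to one of
two references (e.g. human vs rat), to both, to neither, or left ambiguous,
purely by exact canonical k-mer membership.  A high "both" fraction is the
signature of highly conserved sequence — in practice ribosomal RNA, which
can dominate libraries when rRNA depletion fails — so a companion estimator
reports the fraction of reads matching an rRNA reference.

Membership is an exact hash-set lookup over canonical (strand-collapsed)
k-mers; the per-read decision uses hit-count thresholds (``min_hits``) and a
between-reference margin, with reads failing both kept as ``ambiguous``.
"""

from __future__ import annotations

import dataclasses
import gzip
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "KmerIndex",
    "ReadOriginSummary",
    "build_kmer_index",
    "classify_reads",
    "estimate_rrna_fraction",
    "read_fastq",
]

CATEGORIES = ("A_only", "B_only", "both", "neither", "ambiguous")

_COMP = str.maketrans("ACGTN", "TGCAN")

A_FLAG, B_FLAG, BOTH_FLAG = 1, 2, 3


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def _kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "A" in km or "C" in km or "G" in km or "T" in km:
            if all(c in "ACGT" for c in km):
                yield _canonical(km)


@dataclasses.dataclass
class KmerIndex:
    """Canonical k-mer -> membership flag over two reference sets."""

    k: int
    table: dict[str, int]  # flag: 1 = A only, 2 = B only, 3 = both
    ref_a_names: list[str]
    ref_b_names: list[str]


@dataclasses.dataclass
class ReadOriginSummary:
    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts must partition the read set")

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: 100.0 * self.counts.get(c, 0) / self.total for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "count": [self.counts.get(c, 0) for c in CATEGORIES],
                "percent": [pct[c] for c in CATEGORIES],
            }
        )


def build_kmer_index(
    ref_a: Mapping[str, str], ref_b: Mapping[str, str], k: int = 25
) -> KmerIndex:
    """Index every canonical k-mer of two reference sets with its membership.

    k must be odd (no self-reverse-complement palindromes) and >= 11 (below
    that, random matches drown specificity).  k-mers containing non-ACGT
    symbols are skipped.
    """
    if k % 2 == 0 or k < 11:
        raise ValueError("k must be odd and >= 11")
    if not ref_a or not ref_b:
        raise ValueError("both references must be non-empty")
    for name, seq in {**ref_a, **ref_b}.items():
        if len(seq) < k:
            raise ValueError(f"reference record {name!r} shorter than k={k}")
    table: dict[str, int] = {}
    for seq in ref_a.values():
        for km in _kmers(seq, k):
            table[km] = A_FLAG
    for seq in ref_b.values():
        for km in _kmers(seq, k):
            table[km] = BOTH_FLAG if table.get(km) == A_FLAG else table.get(km, B_FLAG)
    return KmerIndex(k, table, list(ref_a), list(ref_b))


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, sequence) pairs from a plain or gzipped 4-line FASTQ."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(str(path), "rt") as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append((rec.description, str(rec.seq).upper()))
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ near record {len(reads) + 1} in {path}: {exc}"
            ) from exc
    return reads


def _as_reads(reads) -> list[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        return read_fastq(reads)
    return [(name, seq.upper()) for name, seq in reads]


def classify_reads(
    reads,
    index: KmerIndex,
    min_hits: int = 4,
    margin: int = 2,
) -> tuple[pd.DataFrame, ReadOriginSummary]:
    """Assign each read to A_only / B_only / both / neither / ambiguous.

    Per read, its canonical k-mers are tallied into a (A-only hits), b
    (B-only hits) and c (shared hits).  A read is ``A_only`` when a >=
    min_hits and a - b >= margin (symmetrically ``B_only``); ``both`` when
    the shared count dominates (c >= min_hits with neither unique count
    reaching min_hits); ``neither`` when a + b + c < min_hits; anything else
    is ``ambiguous``.  Reads shorter than k are ``neither``.
    """
    rows = []
    counts = {c: 0 for c in CATEGORIES}
    k = index.k
    table = index.table
    items = _as_reads(reads)
    for name, seq in items:
        a = b = c = 0
        if len(seq) >= k:
            for km in _kmers(seq, k):
                flag = table.get(km)
                if flag == A_FLAG:
                    a += 1
                elif flag == B_FLAG:
                    b += 1
                elif flag == BOTH_FLAG:
                    c += 1
        if a >= min_hits and a - b >= margin:
            cat = "A_only"
        elif b >= min_hits and b - a >= margin:
            cat = "B_only"
        elif c >= min_hits and a < min_hits and b < min_hits:
            cat = "both"
        elif a + b + c < min_hits:
            cat = "neither"
        else:
            cat = "ambiguous"
        counts[cat] += 1
        rows.append({"read": name, "a_hits": a, "b_hits": b, "both_hits": c, "category": cat})
    summary = ReadOriginSummary(counts, len(items))
    return pd.DataFrame(rows), summary


def estimate_rrna_fraction(
    reads,
    rrna_reference: Mapping[str, str],
    k: int = 25,
    min_hit_fraction: float = 0.5,
) -> float:
    """Fraction of reads matching an rRNA reference by k-mer content.

    A read counts as rRNA when at least ``min_hit_fraction`` of its k-mers
    occur in the reference's canonical k-mer set.
    """
    if not rrna_reference:
        raise ValueError("rRNA reference must be non-empty")
    if not 0 < min_hit_fraction <= 1:
        raise ValueError("min_hit_fraction must be in (0, 1]")
    ref_kmers: set[str] = set()
    for seq in rrna_reference.values():
        ref_kmers.update(_kmers(seq, k))
    items = _as_reads(reads)
    if not items:
        raise ValueError("no reads supplied")
    n_rrna = 0
    for _, seq in items:
        kms = list(_kmers(seq, k))
        if kms and sum(km in ref_kmers for km in kms) / len(kms) >= min_hit_fraction:
            n_rrna += 1
    return n_rrna / len(items)
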