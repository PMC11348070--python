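"""Sequencing-library analysis: insert extraction, ranking, k-mer enrichment.

Each selection round yields millions of reads of the 66-nt construct
(forward primer + random 30-nt insert + reverse region).  This module
extracts the insert, counts unique sequences, ranks them by frequency and
computes per-round k-mer profiles over the most abundant sequences — the
round-over-round enrichment picture that reveals which base compositions
survive selection.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .sequences import (
    ALPHABET,
    FORWARD_PRIMER,
    REVERSE_REGION,
    SequenceError,
    SequenceRecord,
    library_space_size,  # re-exported: the library-space calculator lives here too
    reverse_complement,
)

__all__ = [
    "read_library",
    "extract_insert",
    "extract_inserts",
    "rank_unique",
    "top_n",
    "kmer_profile",
    "enrichment_table",
    "library_space_size",
    "KmerProfile",
    "EnrichmentTable",
]

DEFAULT_TOP_N = 20000


class ParseError(ValueError):
    pass


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_library(
    path: str | Path, format: str = "fasta", aggregate: bool = False
) -> list[SequenceRecord]:
    """Read a FASTA/FASTQ file (gzip-transparent) into sequence records.

    One record per read with count 1; *aggregate* collapses identical
    sequences and sums counts.  Qualities are ignored.
    """
    path = Path(path)
    if format not in ("fasta", "fastq"):
        raise ParseError(f"unsupported format {format!r}")
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        try:
            for rec in SeqIO.parse(fh, format):
                records.append(SequenceRecord(str(rec.seq).upper(), 1))
        except ValueError as exc:  # malformed record (e.g. truncated FASTQ)
            raise ParseError(f"malformed {format} in {path}: {exc}") from exc
    if not records:
        raise ParseError(f"empty or unparseable {format} file: {path}")
    if aggregate:
        agg: dict[str, int] = {}
        for r in records:
            agg[r.sequence] = agg.get(r.sequence, 0) + r.count
        records = [SequenceRecord(s, c) for s, c in agg.items()]
    return records


def _find_with_mismatches(read: str, probe: str, max_mismatch: int) -> int:
    """Leftmost start of *probe* in *read* allowing Hamming mismatches; -1."""
    L = len(probe)
    for start in range(len(read) - L + 1):
        mism = 0
        for a, b in zip(read[start : start + L], probe):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return start
    return -1


def extract_insert(
    read: str,
    fwd: str = FORWARD_PRIMER,
    rev: str = REVERSE_REGION,
    max_mismatch: int = 1,
    try_reverse_complement: bool = True,
) -> tuple[str | None, str]:
    """Locate the primer-flanked insert in a read.

    Returns ``(insert, "ok")`` on success or ``(None, reason)`` with reason
    in {not_found, bad_length, ambiguous_base}.  The read is searched in the
    given orientation first, then reverse-complemented (paired-end reads may
    arrive in either orientation).
    """
    read = read.upper()
    bad = set(read) - set(ALPHABET + "N")
    if bad:
        raise SequenceError(f"invalid characters in read: {sorted(bad)}")
    for oriented in (read, reverse_complement(read)) if try_reverse_complement else (read,):
        f = _find_with_mismatches(oriented, fwd, max_mismatch)
        if f < 0:
            continue
        insert_start = f + len(fwd)
        r = _find_with_mismatches(oriented[insert_start:], rev, max_mismatch)
        if r < 0:
            continue
        insert = oriented[insert_start : insert_start + r]
        if len(insert) != 30:
            return None, "bad_length"
        if "N" in insert:
            return None, "ambiguous_base"
        return insert, "ok"
    return None, "not_found"


def extract_inserts(
    records: Iterable[SequenceRecord], **kwargs
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Batch insert extraction with aggregation and a rejection tally."""
    agg: dict[str, int] = {}
    rejects = {"not_found": 0, "bad_length": 0, "ambiguous_base": 0}
    for rec in records:
        insert, reason = extract_insert(rec.sequence, **kwargs)
        if insert is None:
            rejects[reason] += rec.count
        else:
            agg[insert] = agg.get(insert, 0) + rec.count
    return [SequenceRecord(s, c) for s, c in agg.items()], rejects


def _as_pairs(records: Iterable) -> list[tuple[str, int]]:
    out = []
    for r in records:
        if isinstance(r, SequenceRecord):
            out.append((r.sequence, r.count))
        else:
            s, c = r
            out.append((str(s), int(c)))
    return out


def rank_unique(records: Iterable) -> list[tuple[str, int]]:
    """Unique sequences sorted by descending count, ties lexicographic.

    The deterministic tie-break matters because top-N boundaries feed the
    enrichment profiles and the ML positives.
    """
    pairs = _as_pairs(records)
    if not pairs:
        raise ValueError("no records to rank")
    agg: dict[str, int] = {}
    for s, c in pairs:
        agg[s] = agg.get(s, 0) + c
    return sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))


def top_n(ranked: Sequence, n: int) -> list:
    if n < 1:
        raise ValueError("n must be >= 1")
    return list(ranked[: min(n, len(ranked))])


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


@dataclass
class KmerProfile:
    """Normalized k-mer frequencies over a sequence set (all 4^k keys)."""

    k: int
    frequencies: dict
    n_sequences: int
    weighting: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies)


def kmer_profile(records: Iterable, k: int, weighting: str = "by_unique") -> KmerProfile:
    """Overlapping k-mer frequency profile of a sequence set.

    ``by_unique`` weights each sequence once (matching profiles computed
    over "the top N sequences"); ``by_count`` weights by abundance.
    """
    if not 1 <= k <= 5:
        raise ValueError("k must be in 1..5")
    if weighting not in ("by_unique", "by_count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    pairs = _as_pairs(records)
    if not pairs:
        raise ValueError("no sequences")
    counts = {m: 0.0 for m in all_kmers(k)}
    for seq, c in pairs:
        if len(seq) < k:
            raise ValueError(f"sequence shorter than k={k}: {seq!r}")
        w = float(c) if weighting == "by_count" else 1.0
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += w
    total = sum(counts.values())
    freqs = {m: v / total for m, v in counts.items()}
    return KmerProfile(k=k, frequencies=freqs, n_sequences=len(pairs), weighting=weighting)


@dataclass
class EnrichmentTable:
    """Per-round k-mer frequency matrix (rows: rounds, columns: k-mers)."""

    k: int
    table: pd.DataFrame  # index round_index, columns k-mers, rows sum to 1
    n_top: int

    def to_tidy_tsv(self, path: str | Path) -> None:
        tidy = self.table.reset_index(names="round").melt(
            id_vars="round", var_name="kmer", value_name="frequency"
        )
        tidy.insert(1, "k", self.k)
        tidy.to_csv(path, sep="\t", index=False)

    def frequency(self, round_index: int, kmers: Iterable[str]) -> float:
        return float(self.table.loc[round_index, list(kmers)].sum())


def enrichment_table(
    rounds: Iterable,
    k: int,
    n_top: int = DEFAULT_TOP_N,
    weighting: str = "by_unique",
) -> EnrichmentTable:
    """k-mer profile of the top-*n_top* ranked sequences of each round.

    *rounds* is an iterable of LibraryRound objects or of
    (round_index, records) pairs.
    """
    rows = {}
    for rnd in rounds:
        if hasattr(rnd, "round_index"):
            idx, records = rnd.round_index, rnd.records
        else:
            idx, records = rnd
        ranked = top_n(rank_unique(records), n_top)
        prof = kmer_profile(ranked, k, weighting=weighting)
        rows[idx] = prof.frequencies
    if not rows:
        raise ValueError("no rounds supplied")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table = table[all_kmers(k)]
    return EnrichmentTable(k=k, table=table, n_top=n_top)
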