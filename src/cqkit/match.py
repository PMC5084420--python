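"""Exact whole-read matching against an assembly.

The sex-chromosome classifier counts, per contig, the reads that align
under a deliberately stringent criterion: the entire read must occur in the
contig (either strand) with zero mismatches and no indels. This module
implements that criterion with a sorted k-mer seed index — every k-mer of
every contig is stored with its position; a read's first k-mer (and the
first k-mer of its reverse complement) retrieves candidate sites which are
then verified by direct string comparison, so counts are exact.

A read occurring at several positions of one contig counts once for that
contig but may count once in each of several contigs. Reads containing N
never match (N matches nothing, not even N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cqkit.dna import encode, revcomp

logger = logging.getLogger(__name__)

DEFAULT_SEED_K = 31


@dataclass
class AlignmentCounts:
    """Per-contig tallies of zero-mismatch whole-read matches."""

    counts: dict[str, int]
    total_reads: int

    def __getitem__(self, contig_id: str) -> int:
        return self.counts[contig_id]

    @property
    def mapped_reads(self) -> int:
        """Number of reads matching at least one contig (tracked at query time)."""
        return self._mapped

    _mapped: int = field(default=0, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": list(self.counts),
                "n_reads_matched": list(self.counts.values()),
                "total_reads": self.total_reads,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AlignmentCounts":
        df = pd.read_csv(path, sep="\t")
        total = int(df["total_reads"].iloc[0]) if len(df) else 0
        return cls(dict(zip(df["contig_id"], df["n_reads_matched"].astype(int))), total)


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every k-mer of a code array into uint64; returns (codes, validity).

    Horner evaluation over k shifted views: O(n*k) work, O(n) memory.
    K-mers containing a non-ACGT base are flagged invalid.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    packed = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        valid &= window < 4
        packed = packed * np.uint64(4) + window.astype(np.uint64)
    return packed, valid


class SequenceIndex:
    """Sorted seed-k-mer index over a contig set (forward strand).

    Reverse-strand hits are found by querying the reverse complement of the
    read, so the index itself stores each contig once. Queries shorter than
    the seed length fall back to a direct per-contig scan.
    """

    def __init__(self, contigs: dict[str, str] | Iterable[tuple[str, str]], seed_k: int = DEFAULT_SEED_K):
        if not isinstance(contigs, dict):
            pairs = list(contigs)
            contigs = dict(pairs)
            if len(contigs) != len(pairs):
                raise ValueError("duplicate contig ids in input")
        if len(contigs) == 0:
            raise ValueError("cannot index an empty contig set")
        if seed_k < 1 or seed_k > 31:
            raise ValueError("seed_k must be in [1, 31]")
        self.seed_k = seed_k
        self.contig_ids: list[str] = list(contigs)
        self.contig_seqs: list[str] = [contigs[c].upper() for c in self.contig_ids]
        kcodes: list[np.ndarray] = []
        cidx: list[np.ndarray] = []
        pos: list[np.ndarray] = []
        for i, seq in enumerate(self.contig_seqs):
            packed, valid = _kmer_codes(encode(seq), seed_k)
            where = np.flatnonzero(valid)
            kcodes.append(packed[where])
            cidx.append(np.full(where.size, i, dtype=np.uint32))
            pos.append(where.astype(np.uint32))
        allk = np.concatenate(kcodes) if kcodes else np.empty(0, dtype=np.uint64)
        order = np.argsort(allk, kind="stable")
        self._kmers = allk[order]
        self._contig_of = np.concatenate(cidx)[order] if cidx else np.empty(0, np.uint32)
        self._pos_of = np.concatenate(pos)[order] if pos else np.empty(0, np.uint32)

    @classmethod
    def from_fasta(cls, path: str | Path, seed_k: int = DEFAULT_SEED_K) -> "SequenceIndex":
        from cqkit.seqio import read_fasta_dict

        return cls(read_fasta_dict(path), seed_k=seed_k)

    # --- queries -------------------------------------------------------------

    def _candidates(self, packed: np.uint64) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._kmers, packed, side="left")
        hi = np.searchsorted(self._kmers, packed, side="right")
        return self._contig_of[lo:hi], self._pos_of[lo:hi]

    def _verify(self, read: str, hits: set[int], cidx: np.ndarray, pos: np.ndarray) -> None:
        L = len(read)
        for ci, p in zip(cidx.tolist(), pos.tolist()):
            if ci in hits:
                continue
            if self.contig_seqs[ci][p : p + L] == read:
                hits.add(ci)

    def _query_scan(self, read: str) -> set[int]:
        rc = revcomp(read)
        hits: set[int] = set()
        for i, seq in enumerate(self.contig_seqs):
            if read in seq or rc in seq:
                hits.add(i)
        return hits

    def query(self, read: str) -> set[str]:
        """Contig ids in which the read occurs exactly, on either strand."""
        read = read.upper()
        if not read or "N" in read or (encode(read) > 3).any():
            return set()
        if len(read) < self.seed_k:
            hits = self._query_scan(read)
        else:
            k = self.seed_k
            hits = set()
            fwd, fwd_ok = _kmer_codes(encode(read[:k]), k)
            if fwd_ok[0]:
                self._verify(read, hits, *self._candidates(fwd[0]))
            rc = revcomp(read)
            rcp, rc_ok = _kmer_codes(encode(rc[:k]), k)
            if rc_ok[0]:
                rc_hits: set[int] = set()
                self._verify(rc, rc_hits, *self._candidates(rcp[0]))
                hits |= rc_hits
        return {self.contig_ids[i] for i in hits}

    def _bulk_seed_codes(self, seqs: Sequence[str], length: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized forward and reverse-complement seed codes for
        equal-length reads; also returns a clean-read mask (no non-ACGT)."""
        k = self.seed_k
        flat = encode("".join(seqs)).reshape(len(seqs), length)
        clean = (flat < 4).all(axis=1)
        pow4 = np.uint64(4)
        fwd = np.zeros(len(seqs), dtype=np.uint64)
        rc = np.zeros(len(seqs), dtype=np.uint64)
        for j in range(k):
            fwd = fwd * pow4 + flat[:, j].astype(np.uint64)
            # first k-mer of the reverse complement = complement of the
            # read's last k bases, reversed
            rc = rc * pow4 + (3 - flat[:, length - 1 - j]).astype(np.uint64)
        return fwd, rc, clean

    def count_matches(self, reads: Iterable[str]) -> AlignmentCounts:
        """Count, per contig, reads matching exactly at least once.

        Reads are grouped by length so seed extraction vectorizes; empty
        reads are skipped with a warning.
        """
        by_length: dict[int, list[str]] = {}
        total = 0
        n_empty = 0
        for read in reads:
            read = read.upper()
            if not read:
                n_empty += 1
                continue
            total += 1
            by_length.setdefault(len(read), []).append(read)
        if n_empty:
            logger.warning("skipped %d empty read(s)", n_empty)

        tallies = np.zeros(len(self.contig_ids), dtype=np.int64)
        mapped = 0
        k = self.seed_k
        for length, seqs in by_length.items():
            if length < k:
                for read in seqs:
                    hits = self._query_scan(read)
                    for ci in hits:
                        tallies[ci] += 1
                    mapped += bool(hits)
                continue
            fwd, rcseed, clean = self._bulk_seed_codes(seqs, length)
            lo_f = np.searchsorted(self._kmers, fwd, side="left")
            hi_f = np.searchsorted(self._kmers, fwd, side="right")
            lo_r = np.searchsorted(self._kmers, rcseed, side="left")
            hi_r = np.searchsorted(self._kmers, rcseed, side="right")
            has_hit = clean & ((lo_f < hi_f) | (lo_r < hi_r))
            for i in np.flatnonzero(has_hit):
                read = seqs[i]
                hits: set[int] = set()
                if lo_f[i] < hi_f[i]:
                    sl = slice(lo_f[i], hi_f[i])
                    self._verify(read, hits, self._contig_of[sl], self._pos_of[sl])
                if lo_r[i] < hi_r[i]:
                    rc = revcomp(read)
                    rc_hits: set[int] = set()
                    sl = slice(lo_r[i], hi_r[i])
                    self._verify(rc, rc_hits, self._contig_of[sl], self._pos_of[sl])
                    hits |= rc_hits
                for ci in hits:
                    tallies[ci] += 1
                mapped += bool(hits)
        counts = AlignmentCounts(
            {cid: int(tallies[i]) for i, cid in enumerate(self.contig_ids)}, total
        )
        counts._mapped = mapped
        return counts


def build_index(contigs: dict[str, str], seed_k: int = DEFAULT_SEED_K) -> SequenceIndex:
    """Build the exact-substring query structure over a contig set."""
    return SequenceIndex(contigs, seed_k=seed_k)


def count_exact_matches(index: SequenceIndex, reads) -> AlignmentCounts:
    """Count zero-mismatch whole-read matches for a read set.

    ``reads`` may be a :class:`~cqkit.simulate.SexReadSet` or any iterable
    of read sequence strings.
    """
    seqs = getattr(reads, "sequences", reads)
    return index.count_matches(seqs)


def naive_match_counts(contigs: dict[str, str], reads: Iterable[str]) -> AlignmentCounts:
    """Reference O(n*m) scan used as an independent oracle in tests.

    Checks every read (and its reverse complement) against every contig
    with Python substring search. Quadratic; suitable only for small
    instances.
    """
    names = list(contigs)
    seqs = [contigs[c].upper() for c in names]
    tallies = {c: 0 for c in names}
    total = 0
    mapped = 0
    for read in reads:
        read = read.upper()
        if not read:
            continue
        total += 1
        if "N" in read:
            continue
        rc = revcomp(read)
        hit_any = False
        for name, seq in zip(names, seqs):
            if read in seq or rc in seq:
                tallies[name] += 1
                hit_any = True
        mapped += hit_any
    counts = AlignmentCounts(tallies, total)
    counts._mapped = mapped
    return counts
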