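"""Kimura 2-parameter repeat divergence and accumulation landscapes.

Each transposable-element insertion is compared with its family consensus
(the assumed ancestral state). From the pairwise alignment we take the
fraction of aligned columns showing a transition (P: A<->G, C<->T) and a
transversion (Q: all other mismatches) and estimate the substitutions per
site as

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

which corrects the raw mismatch fraction upward for multiple hits. Binning
the aligned bp of every insertion by its divergence yields the accumulation
landscape: recently active families pile up at low divergence, ancient ones
at high divergence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "RC", "simple", "low-complexity", "other")

#: Returned when the K2P logarithm is undefined (P, Q too close to saturation).
SATURATED = float("nan")


def k2p_distance(p: float, q: float) -> float:
    """Kimura 2-parameter distance from transition/transversion fractions.

    Parameters are fractions of aligned, non-gap columns. Returns ``nan``
    (saturated) when ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0``, where the
    estimator's logarithm is undefined; such alignments are kept out of the
    landscape and tallied separately.
    """
    if p < 0 or q < 0 or p + q > 1:
        raise ValueError(f"invalid substitution fractions P={p}, Q={q}")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0.0 or b <= 0.0:
        return SATURATED
    return -0.5 * math.log(a * math.sqrt(b))


_PURINE = {"A", "G"}
_STANDARD = {"A", "C", "G", "T"}


def count_substitutions(
    insertion_aligned: str, consensus_aligned: str
) -> tuple[int, float, float]:
    """Classify substitutions in an explicit gapped pairwise alignment.

    Only columns carrying a standard base on both rows enter the counts;
    gap and ambiguous columns are excluded from the denominator. Returns
    ``(aligned_columns, P, Q)`` with P, Q as fractions of the countable
    columns (``nan`` fractions if no column is countable).
    """
    if len(insertion_aligned) != len(consensus_aligned):
        raise ValueError("aligned rows differ in length")
    n = 0
    ts = 0
    tv = 0
    for x, y in zip(insertion_aligned.upper(), consensus_aligned.upper()):
        if x not in _STANDARD or y not in _STANDARD:
            continue
        n += 1
        if x != y:
            if (x in _PURINE) == (y in _PURINE):
                ts += 1
            else:
                tv += 1
    if n == 0:
        return 0, float("nan"), float("nan")
    return n, ts / n, tv / n


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -2.0
    # a gap of length g costs 5 + g
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_copy_to_consensus(
    copy_seq: str, consensus_seq: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[str, str]:
    """Global affine-gap alignment of an insertion copy against its consensus.

    Scores: match +2, mismatch -2, gap open -5, gap extend -1 (a length-g
    gap costs 5+g). The first optimal alignment in Biopython's deterministic
    enumeration order is returned as ``(copy_row, consensus_row)`` gapped
    strings.
    """
    if not copy_seq or not consensus_seq:
        raise ValueError("cannot align empty sequences")
    aligner = aligner or _default_aligner()
    alignment = aligner.align(copy_seq.upper(), consensus_seq.upper())[0]
    return str(alignment[0]), str(alignment[1])


@dataclass(frozen=True)
class RepeatAlignment:
    """One TE insertion scored against its consensus."""

    contig_id: str
    start: int  # 1-based, inclusive
    end: int
    te_name: str
    te_class: str
    aligned_columns: int
    p_transitions: float
    q_transversions: float
    k2p: float  # nan when saturated

    @property
    def saturated(self) -> bool:
        return math.isnan(self.k2p)

    @classmethod
    def from_gapped(
        cls,
        contig_id: str,
        start: int,
        end: int,
        te_name: str,
        te_class: str,
        insertion_aligned: str,
        consensus_aligned: str,
    ) -> "RepeatAlignment":
        if end < start:
            raise ValueError(f"end < start for {contig_id}:{start}-{end}")
        n, p, q = count_substitutions(insertion_aligned, consensus_aligned)
        k = k2p_distance(p, q) if n > 0 else SATURATED
        return cls(contig_id, start, end, te_name, te_class, n, p, q, k)


@dataclass
class LandscapeTable:
    """Aligned repeat bp binned by divergence (percent) and TE class.

    ``table`` is indexed by bin start (percent divergence, width
    ``bin_width``); the final row, labelled by ``cap``, is open-ended so
    that every non-saturated alignment is counted and bin totals conserve
    the input aligned bp. Saturated alignments are tallied in
    ``saturated_bp`` only.
    """

    table: pd.DataFrame
    bin_width: float
    cap: float
    saturated_bp: int

    @property
    def total_bp(self) -> int:
        return int(self.table.to_numpy().sum())

    def class_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "divergence_bin_start_pct"
        out.to_csv(path, sep="\t")


def build_landscape(
    alignments: Iterable[RepeatAlignment],
    bin_width: float = 1.0,
    cap: float = 55.0,
) -> LandscapeTable:
    """Accumulate aligned bp per (TE class, divergence bin).

    Each alignment contributes its aligned column count (not its genomic
    span) to the bin containing ``100 * k2p``; divergences at or beyond
    ``cap`` land in a single open-ended top bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if cap <= 0:
        raise ValueError("cap must be positive")
    edges = np.arange(0.0, cap + bin_width / 2, bin_width)
    index = pd.Index(edges, name="divergence_bin_start_pct")
    classes: dict[str, np.ndarray] = {}
    saturated_bp = 0
    for aln in alignments:
        if aln.saturated:
            saturated_bp += aln.aligned_columns
            continue
        pct = 100.0 * aln.k2p
        if pct >= cap:
            b = len(edges) - 1
        else:
            b = int(pct // bin_width)
        col = classes.setdefault(aln.te_class, np.zeros(len(edges), dtype=np.int64))
        col[b] += aln.aligned_columns
    table = pd.DataFrame(classes, index=index).sort_index(axis=1)
    if table.empty:
        table = pd.DataFrame(index=index)
    return LandscapeTable(table=table, bin_width=bin_width, cap=cap, saturated_bp=saturated_bp)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping 1-based inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def repeat_fraction(
    annotations: Iterable[tuple[str, int, int]],
    sequence_lengths: dict[str, int],
) -> tuple[int, float]:
    """Fraction of a sequence set covered by repeat annotations.

    ``annotations`` are ``(sequence_id, start, end)`` with 1-based inclusive
    coordinates; overlapping intervals on a sequence are merged before
    summing so double-annotated bases count once. Returns
    ``(merged_repeat_bp, fraction_of_total_bp)``.
    """
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, start, end in annotations:
        if seq_id not in sequence_lengths:
            raise ValueError(f"annotation on unknown sequence {seq_id!r}")
        if start < 1 or end < start or end > sequence_lengths[seq_id]:
            raise ValueError(
                f"annotation {seq_id}:{start}-{end} outside sequence bounds "
                f"(length {sequence_lengths[seq_id]})"
            )
        per_seq.setdefault(seq_id, []).append((start, end))
    repeat_bp = 0
    for seq_id, ivals in per_seq.items():
        for start, end in merge_intervals(ivals):
            repeat_bp += end - start + 1
    total = sum(sequence_lengths.values())
    if total == 0:
        raise ValueError("empty sequence set")
    return repeat_bp, repeat_bp / total


# --- input parsers -----------------------------------------------------------

ALIGN_TSV_COLUMNS = [
    "contig_id",
    "start",
    "end",
    "te_name",
    "te_class",
    "aligned_insertion",
    "aligned_consensus",
]


def parse_align_tsv(path: str | Path) -> list[RepeatAlignment]:
    """Parse the canonical TSV alignment dialect.

    Columns: ``contig_id start end te_name te_class aligned_insertion
    aligned_consensus`` with ``-`` as the gap character and 1-based
    inclusive coordinates.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGN_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV {path} lacks columns {sorted(missing)}")
    return [
        RepeatAlignment.from_gapped(
            str(r.contig_id),
            int(r.start),
            int(r.end),
            str(r.te_name),
            str(r.te_class),
            str(r.aligned_insertion),
            str(r.aligned_consensus),
        )
        for r in df.itertuples()
    ]


def write_align_tsv(path: str | Path, rows: Iterable[dict]) -> None:
    pd.DataFrame(list(rows), columns=ALIGN_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


_ALIGN_HEADER = re.compile(
    r"^\s*\d+\s+[\d.]+\s+[\d.]+\s+[\d.]+\s+(\S+)\s+(\d+)\s+(\d+)\s+\(\d+\)"
)
_ALIGN_SEQLINE = re.compile(r"^(C?)\s*(\S+)\s+(\d+)\s+([A-Za-z\-]+)\s+(\d+)\s*$")


def parse_crossmatch_align(path: str | Path) -> list[RepeatAlignment]:
    """Best-effort parser for cross_match / RepeatMasker ``.align`` blocks.

    Each block starts with a score line (score, divergence, del, ins, query
    name and coordinates, then the matching repeat); the block body holds
    interleaved gapped query and repeat sequence lines. Annotation footer
    lines (Matrix, Transitions, Gap_init ...) are ignored. Repeat names of
    the form ``family#Class/Subfamily`` yield ``te_class = Class``.
    """
    out: list[RepeatAlignment] = []
    block: dict | None = None

    def flush(b: dict | None) -> None:
        if not b or not b["q"]:
            return
        te_class = b["te_name"].split("#", 1)[1].split("/", 1)[0] if "#" in b["te_name"] else "other"
        out.append(
            RepeatAlignment.from_gapped(
                b["contig"], b["start"], b["end"],
                b["te_name"].split("#", 1)[0], te_class,
                "".join(b["q"]), "".join(b["s"]),
            )
        )

    with open(path) as fh:
        for line in fh:
            header = _ALIGN_HEADER.match(line)
            if header:
                flush(block)
                fields = line.split()
                te_name = fields[9] if len(fields) > 9 and fields[8] == "C" else fields[8]
                block = {
                    "contig": header.group(1),
                    "start": int(header.group(2)),
                    "end": int(header.group(3)),
                    "te_name": te_name,
                    "q": [],
                    "s": [],
                }
                continue
            if block is None:
                continue
            if line.startswith(("Matrix", "Transitions", "Gap_init", "Kimura")):
                continue
            m = _ALIGN_SEQLINE.match(line)
            if not m:
                continue
            name = m.group(2)
            if name == block["contig"]:
                block["q"].append(m.group(4))
            else:
                block["s"].append(m.group(4))
    flush(block)
    return out
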