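"""Chromosome-quotient computation and sex-linkage classification.

The chromosome quotient (CQ) of a contig is the female-to-male ratio of
stringent (zero-mismatch, whole-read) alignment counts. Because a female
(XX) carries two doses of X and none of Y while a male (XY) carries one of
each, X-linked contigs sit near CQ = 2, Y-linked contigs near CQ = 0 and
autosomes near CQ = 1. Contigs with CQ below 0.05 are called putative Y;
contigs with CQ between 1.9 and 2.5 (inclusive) putative X.

Library-size normalization (dividing each count by its library total) is on
by default: it is a no-op when both sexes were sequenced to equal totals
and makes the statistic portable when they were not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from cqkit.match import AlignmentCounts

LABEL_X = "X"
LABEL_Y = "Y"
LABEL_UNASSIGNED = "unassigned"
LABEL_LOW_EVIDENCE = "low-evidence"


@dataclass(frozen=True)
class CQThresholds:
    """Decision bands of the CQ classifier.

    Y is called on the half-open band ``[0, y_max)`` ("less than"), X on
    the closed band ``[x_min, x_max]``. ``min_male_hits`` guards the
    denominator: below it the CQ is undefined and the contig is reported as
    low-evidence rather than being flooded into the X band by a tiny,
    noisy male count.
    """

    y_max: float = 0.05
    x_min: float = 1.9
    x_max: float = 2.5
    min_male_hits: int = 20
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.y_max < self.x_min < self.x_max:
            raise ValueError(
                f"thresholds must satisfy 0 < y_max < x_min < x_max, got "
                f"{self.y_max}, {self.x_min}, {self.x_max}"
            )
        if self.min_male_hits < 0:
            raise ValueError("min_male_hits must be non-negative")


@dataclass
class CQRecord:
    contig_id: str
    length: int
    female_count: int
    male_count: int
    cq: float  # nan when undefined (low evidence)
    label: str = LABEL_UNASSIGNED

    @property
    def cq_defined(self) -> bool:
        return not math.isnan(self.cq)


def compute_cq(
    female: AlignmentCounts,
    male: AlignmentCounts,
    thresholds: CQThresholds = CQThresholds(),
    lengths: dict[str, int] | None = None,
) -> list[CQRecord]:
    """Compute the chromosome quotient for every contig.

    With normalization on, ``cq = (f / F_total) / (m / M_total)``; off,
    the raw ratio ``f / m``. Records with fewer than ``min_male_hits`` male
    matches get an undefined CQ and the low-evidence label. Both count sets
    must cover the same contig universe.
    """
    if set(female.counts) != set(male.counts):
        raise ValueError("female and male counts cover different contig sets")
    f_total = female.total_reads
    m_total = male.total_reads
    if thresholds.normalize and (f_total == 0 or m_total == 0):
        raise ValueError("cannot normalize by an empty read set")
    scale = (m_total / f_total) if thresholds.normalize else 1.0
    records = []
    for contig_id, f_count in female.counts.items():
        m_count = male.counts[contig_id]
        if m_count < thresholds.min_male_hits:
            cq = float("nan")
            label = LABEL_LOW_EVIDENCE
        else:
            cq = (f_count / m_count) * scale
            label = LABEL_UNASSIGNED
        records.append(
            CQRecord(
                contig_id=contig_id,
                length=0 if lengths is None else int(lengths[contig_id]),
                female_count=f_count,
                male_count=m_count,
                cq=cq,
                label=label,
            )
        )
    return records


def classify(record: CQRecord, thresholds: CQThresholds = CQThresholds()) -> CQRecord:
    """Assign the putative X/Y/unassigned label from the CQ bands.

    Low-evidence records pass through unchanged. Y: ``cq < y_max``;
    X: ``x_min <= cq <= x_max``; anything else is unassigned.
    """
    if record.label == LABEL_LOW_EVIDENCE or not record.cq_defined:
        record.label = LABEL_LOW_EVIDENCE
        return record
    if record.cq < thresholds.y_max:
        record.label = LABEL_Y
    elif thresholds.x_min <= record.cq <= thresholds.x_max:
        record.label = LABEL_X
    else:
        record.label = LABEL_UNASSIGNED
    return record


def classify_all(
    records: Iterable[CQRecord], thresholds: CQThresholds = CQThresholds()
) -> list[CQRecord]:
    return [classify(r, thresholds) for r in records]


@dataclass
class ChromosomeSummary:
    """Per-label contig tallies and summed sizes of the putative chromosomes."""

    contig_counts: dict[str, int]
    summed_bp: dict[str, int]

    @property
    def x_minus_y_bp(self) -> int:
        return self.summed_bp.get(LABEL_X, 0) - self.summed_bp.get(LABEL_Y, 0)

    def to_dict(self) -> dict:
        return {
            "contig_counts": self.contig_counts,
            "summed_bp": self.summed_bp,
            "x_minus_y_bp": self.x_minus_y_bp,
        }


def summarize_chromosomes(records: Sequence[CQRecord]) -> ChromosomeSummary:
    """Add up contig counts and sizes per label (the putative chromosome
    sizes are the summed lengths of X- and Y-labeled contigs)."""
    counts: dict[str, int] = {}
    bp: dict[str, int] = {}
    for label in (LABEL_X, LABEL_Y, LABEL_UNASSIGNED, LABEL_LOW_EVIDENCE):
        counts[label] = 0
        bp[label] = 0
    for r in records:
        counts[r.label] = counts.get(r.label, 0) + 1
        bp[r.label] = bp.get(r.label, 0) + r.length
    return ChromosomeSummary(contig_counts=counts, summed_bp=bp)


def records_to_frame(records: Sequence[CQRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_cq_outputs(
    records: Sequence[CQRecord],
    thresholds: CQThresholds,
    out_prefix: str | Path,
    contigs: dict[str, str] | None = None,
) -> ChromosomeSummary:
    """Write the per-contig TSV, the JSON summary and, when sequences are
    supplied, FASTA subsets of the putative X and Y contigs."""
    from cqkit import seqio

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    df = df[["contig_id", "length", "female_count", "male_count", "cq", "label"]]
    df.to_csv(f"{out_prefix}.tsv", sep="\t", index=False, float_format="%.6f")
    summary = summarize_chromosomes(records)
    payload = {"thresholds": asdict(thresholds), **summary.to_dict()}
    with open(f"{out_prefix}_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if contigs is not None:
        for label, suffix in ((LABEL_X, "putative_X"), (LABEL_Y, "putative_Y")):
            members = [(r.contig_id, contigs[r.contig_id]) for r in records if r.label == label]
            seqio.write_fasta(f"{out_prefix}.{suffix}.fasta", members)
    return summary
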