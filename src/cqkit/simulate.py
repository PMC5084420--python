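"""Synthetic sexed genomes, read pools and planted transposable elements.

The generator emulates the data layout of a short-read genome project on a
species with heteromorphic XY sex chromosomes: a fragmented contig assembly
in which each contig is purely autosomal (A), X-linked or Y-linked, plus one
read pool per sex. Copy numbers follow the XX/XY karyotype — per diploid
cell a female carries A=2, X=2, Y=0 copies and a male A=2, X=1, Y=1 — which
is the depth asymmetry the chromosome-quotient classifier exploits.

Transposable-element copies are planted by overwriting a contig window with
a consensus sequence evolved under a Kimura 2-parameter substitution process
(transition/transversion-biased, multiple hits allowed) to a target expected
number of substitutions per site, so divergence estimates can be validated
against a recorded ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cqkit import seqio
from cqkit.dna import decode, encode
from cqkit.landscape import k2p_distance

logger = logging.getLogger(__name__)

CLASS_AUTOSOMAL = "A"
CLASS_X = "X"
CLASS_Y = "Y"
VALID_CLASSES = (CLASS_AUTOSOMAL, CLASS_X, CLASS_Y)

# copies per diploid cell; the female:male ratio of these weights is what
# the CQ statistic estimates (2 on X, 1 on A, 0 on Y)
COPY_WEIGHTS = {
    "female": {CLASS_AUTOSOMAL: 2.0, CLASS_X: 2.0, CLASS_Y: 0.0},
    "male": {CLASS_AUTOSOMAL: 2.0, CLASS_X: 1.0, CLASS_Y: 1.0},
}


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of a synthetic fragmented assembly.

    ``contig_length_range`` is inclusive on both ends (bp). ``gc_content``
    defaults to 0.28, typical of the AT-rich calliphorid genomes this
    pipeline targets (72% AT).
    """

    n_autosomal_contigs: int = 140
    n_x_contigs: int = 30
    n_y_contigs: int = 30
    contig_length_range: tuple[int, int] = (5_000, 50_000)
    gc_content: float = 0.28
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_autosomal_contigs, self.n_x_contigs, self.n_y_contigs)
        if any(c < 0 for c in counts):
            raise ValueError("contig counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("at least one contig is required")
        lo, hi = self.contig_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid contig_length_range {self.contig_length_range}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly between 0 and 1")


@dataclass(frozen=True)
class ReadSimSpec:
    """Parameters of one sex-pooled read library.

    ``depth`` is fold-coverage relative to the copy-weighted haploid-
    equivalent genome length of the same sex, so an autosomal contig sees
    about ``depth``-fold coverage in both libraries while the male X and Y
    see half of it. ``substitution_error_rate`` is the per-base sequencing
    error probability (substitutions only).
    """

    sex: str
    depth: float = 20.0
    read_length: int = 100
    substitution_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class TEPlantSpec:
    """One family of planted TE copies.

    ``target_divergence`` is the expected number of substitutions per site
    (multiple hits allowed), i.e. the quantity a Kimura 2-parameter estimate
    should recover. ``ts_tv_ratio`` is transitions per transversion in the
    substitution process.
    """

    consensus_id: str
    n_copies: int = 20
    target_divergence: float = 0.15
    ts_tv_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 0:
            raise ValueError("n_copies must be non-negative")
        if not 0.0 <= self.target_divergence < 0.75:
            raise ValueError("target_divergence must be in [0, 0.75)")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be positive")


@dataclass(frozen=True)
class PlantedInsertion:
    contig_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    consensus_id: str
    divergence: float  # realized K2P divergence vs consensus


@dataclass
class TruthTable:
    """Ground truth of a simulated genome: contig classes and planted TEs."""

    classes: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)
    insertions: list[PlantedInsertion] = field(default_factory=list)

    def contigs_of_class(self, label: str) -> list[str]:
        return [c for c, k in self.classes.items() if k == label]

    def total_bp(self, label: str) -> int:
        return sum(self.lengths[c] for c in self.contigs_of_class(label))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": list(self.classes),
                "class": [self.classes[c] for c in self.classes],
                "length": [self.lengths[c] for c in self.classes],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_insertions_tsv(self, path: str | Path) -> None:
        rows = [
            (i.contig_id, i.start, i.end, i.consensus_id, f"{i.divergence:.6f}")
            for i in self.insertions
        ]
        pd.DataFrame(
            rows, columns=["contig_id", "start", "end", "consensus_id", "divergence"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, insertions_path: str | Path | None = None) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        truth = cls(
            classes=dict(zip(df["contig_id"], df["class"])),
            lengths=dict(zip(df["contig_id"], df["length"].astype(int))),
        )
        if insertions_path is not None:
            ins = pd.read_csv(insertions_path, sep="\t")
            truth.insertions = [
                PlantedInsertion(
                    r.contig_id, int(r.start), int(r.end), r.consensus_id, float(r.divergence)
                )
                for r in ins.itertuples()
            ]
        return truth


@dataclass
class SexReadSet:
    """A pool of reads from one sex, with optional simulation provenance."""

    sex: str
    ids: list[str]
    sequences: list[str]
    origin: pd.DataFrame | None = None  # contig_id, start (1-based), strand

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_fastx(cls, path: str | Path, sex: str) -> "SexReadSet":
        ids, seqs = [], []
        for name, seq in seqio.read_sequences(path):
            ids.append(name)
            seqs.append(seq)
        return cls(sex=sex, ids=ids, sequences=seqs)

    def write_fastq(self, path: str | Path) -> None:
        seqio.write_fastq(path, zip(self.ids, self.sequences))


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    # base order A,C,G,T with P(C)=P(G)=gc/2
    cum = np.array([(1 - gc) / 2, (1 - gc) / 2 + gc / 2, 1 - (1 - gc) / 2])
    return np.searchsorted(cum, rng.random(n)).astype(np.uint8)


def simulate_genome(spec: GenomeSpec) -> tuple[dict[str, str], TruthTable]:
    """Generate random contigs with A/X/Y truth labels.

    Contigs are generated independently (the fragmented-assembly premise:
    the classifier works per contig and needs no linkage) with i.i.d. bases
    at the requested GC content. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.contig_length_range
    labels = (
        [CLASS_AUTOSOMAL] * spec.n_autosomal_contigs
        + [CLASS_X] * spec.n_x_contigs
        + [CLASS_Y] * spec.n_y_contigs
    )
    contigs: dict[str, str] = {}
    truth = TruthTable()
    for i, label in enumerate(labels):
        name = f"ctg{i + 1:06d}"
        length = int(rng.integers(lo, hi + 1))
        contigs[name] = decode(_random_codes(rng, length, spec.gc_content))
        truth.classes[name] = label
        truth.lengths[name] = length
    return contigs, truth


def _k2p_column_probabilities(divergence: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Expected per-site transition (p_ts) and total transversion (p_tv)
    difference probabilities after evolving for ``divergence`` expected
    substitutions per site under a K2P process with the given ts/tv bias."""
    r = ts_tv_ratio
    alpha = divergence * r / (r + 1.0)  # transition rate x time
    beta = divergence / (2.0 * (r + 1.0))  # rate to each transversion partner
    e4b = math.exp(-4.0 * beta)
    e2ab = math.exp(-2.0 * (alpha + beta))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.5 - 0.5 * e4b
    return p_ts, p_tv


def mutate_k2p(
    codes: np.ndarray, divergence: float, ts_tv_ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve encoded bases under a K2P substitution process.

    Multiple hits are modelled through the matrix exponential of the K2P
    rate matrix, so ``divergence`` is the expected number of substitution
    events per site, not the expected fraction of differing sites.
    """
    p_ts, p_tv = _k2p_column_probabilities(divergence, ts_tv_ratio)
    u = rng.random(codes.size)
    out = codes.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv / 2)
    tv2_mask = (u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)
    out[ts_mask] ^= 2  # transition partner
    out[tv1_mask] ^= 1
    out[tv2_mask] ^= 3
    return out


def _realized_divergence(planted: np.ndarray, consensus: np.ndarray) -> float:
    diff = planted ^ consensus
    n = planted.size
    p = float((diff == 2).sum()) / n
    q = float(((diff == 1) | (diff == 3)).sum()) / n
    return k2p_distance(p, q)


def plant_te_copies(
    contigs: dict[str, str],
    library: dict[str, str],
    spec: TEPlantSpec,
    truth: TruthTable | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Overwrite random contig windows with mutated consensus copies.

    Each copy is the consensus evolved under :func:`mutate_k2p` to the
    spec's target divergence; copies never overlap one another. Returns new
    contig dict and the truth table extended with the realized insertions.
    """
    if spec.consensus_id not in library:
        raise ValueError(f"consensus {spec.consensus_id!r} not in library")
    consensus = library[spec.consensus_id].upper()
    cons_codes = encode(consensus)
    if (cons_codes > 3).any():
        raise ValueError("consensus sequence must be unambiguous A/C/G/T")
    copy_len = len(consensus)

    rng = np.random.default_rng(spec.seed)
    out = dict(contigs)
    truth = truth if truth is not None else TruthTable(
        classes={c: CLASS_AUTOSOMAL for c in contigs},
        lengths={c: len(s) for c, s in contigs.items()},
    )
    occupied: dict[str, list[tuple[int, int]]] = {}
    for ins in truth.insertions:
        occupied.setdefault(ins.contig_id, []).append((ins.start - 1, ins.end))

    eligible = [c for c in out if len(out[c]) >= copy_len]
    if not eligible:
        raise ValueError(
            f"no contig can host a {copy_len} bp copy of {spec.consensus_id!r}"
        )

    for _ in range(spec.n_copies):
        placed = False
        for _attempt in range(200):
            cid = eligible[int(rng.integers(len(eligible)))]
            start = int(rng.integers(0, len(out[cid]) - copy_len + 1))
            window = (start, start + copy_len)
            if any(window[0] < e and s < window[1] for s, e in occupied.get(cid, [])):
                continue
            mutated = mutate_k2p(cons_codes, spec.target_divergence, spec.ts_tv_ratio, rng)
            seq = out[cid]
            out[cid] = seq[: window[0]] + decode(mutated) + seq[window[1] :]
            occupied.setdefault(cid, []).append(window)
            truth.insertions.append(
                PlantedInsertion(
                    contig_id=cid,
                    start=window[0] + 1,
                    end=window[1],
                    consensus_id=spec.consensus_id,
                    divergence=_realized_divergence(mutated, cons_codes),
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a non-overlapping copy of {spec.consensus_id!r}; "
                "the genome is saturated with insertions"
            )
    return out, truth


def random_te_library(
    families: Sequence[tuple[str, int]], gc: float = 0.35, seed: int = 0
) -> dict[str, str]:
    """Generate random consensus sequences for the named TE families."""
    rng = np.random.default_rng(seed)
    return {name: decode(_random_codes(rng, length, gc)) for name, length in families}


def simulate_reads(
    contigs: dict[str, str], truth: TruthTable, spec: ReadSimSpec
) -> SexReadSet:
    """Sample error-bearing reads from a copy-number-weighted template.

    Read origins are drawn with probability proportional to
    ``copy_weight(class) x available start positions``; starts are uniform
    within a contig and both strands are sampled equally. The read count is
    ``round(depth x H / read_length)`` where H is the copy-weighted
    haploid-equivalent genome length ``sum(w_c * len_c) / 2``, so summed
    read bases match ``depth x H`` to within one read.

    Three independent RNG streams (positions, error positions, error bases)
    are derived from the seed so that raising only the error rate perturbs
    reads at a superset of the lower rate's error sites.
    """
    weights = COPY_WEIGHTS[spec.sex]
    names = list(contigs)
    unknown = [c for c in names if truth.classes.get(c) not in VALID_CLASSES]
    if unknown:
        raise ValueError(f"contigs without a valid A/X/Y truth class: {unknown[:5]}")
    L = spec.read_length
    lengths = np.array([len(contigs[c]) for c in names], dtype=np.int64)
    if L > lengths.max():
        raise ValueError("read_length exceeds every contig length")
    w = np.array([weights[truth.classes[c]] for c in names])
    n_positions = np.maximum(lengths - L + 1, 0)
    sampling_weight = w * n_positions
    if sampling_weight.sum() == 0:
        raise ValueError("no contig is sampleable at this read length for this sex")

    haploid_equiv = float((w * lengths).sum()) / 2.0
    n_reads = int(round(spec.depth * haploid_equiv / L))

    pos_ss, err_pos_ss, err_base_ss = np.random.SeedSequence(spec.seed).spawn(3)
    pos_rng = np.random.default_rng(pos_ss)
    err_pos_rng = np.random.default_rng(err_pos_ss)
    err_base_rng = np.random.default_rng(err_base_ss)

    # concatenated code array for vectorized substring extraction
    big = np.concatenate([encode(contigs[c]) for c in names])
    offsets = np.concatenate([[0], np.cumsum(lengths)])[:-1]

    probs = sampling_weight / sampling_weight.sum()
    contig_idx = pos_rng.choice(len(names), size=n_reads, p=probs)
    starts = (pos_rng.random(n_reads) * n_positions[contig_idx]).astype(np.int64)
    strands = pos_rng.integers(0, 2, size=n_reads)

    ids: list[str] = []
    seqs: list[str] = []
    prefix = spec.sex[0]
    chunk = 200_000
    col = np.arange(L)
    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        codes = big[(offsets[contig_idx[lo:hi]] + starts[lo:hi])[:, None] + col]
        rc_rows = strands[lo:hi] == 1
        codes[rc_rows] = 3 - codes[rc_rows][:, ::-1]
        u = err_pos_rng.random(codes.shape)
        if spec.substitution_error_rate > 0:
            mask = u < spec.substitution_error_rate
            shift = err_base_rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            codes[mask] = (codes[mask] + shift) % 4
        text = decode(codes.ravel())
        for j in range(hi - lo):
            seqs.append(text[j * L : (j + 1) * L])
        ids.extend(f"{prefix}read{k:08d}" for k in range(lo, hi))

    origin = pd.DataFrame(
        {
            "read_id": ids,
            "contig_id": [names[i] for i in contig_idx],
            "start": starts + 1,
            "strand": np.where(strands == 1, "-", "+"),
        }
    )
    return SexReadSet(sex=spec.sex, ids=ids, sequences=seqs, origin=origin)
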