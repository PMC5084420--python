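"""Assembly summary statistics (contig counts, N50, AT content, N density).

Definitions are pinned for bit-reproducibility:

* N50 — sort contig lengths descending; the N50 is the length of the
  contig at which the running total first reaches half the assembly size
  (ties resolve to the contig crossing the boundary, the QUAST convention).
* %AT — computed over A/C/G/T calls only; N and ambiguity codes are
  excluded from the denominator.
* N's per 100 kb — ``100000 * n_count / total_bp`` with total_bp counting
  every base including N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from cqkit.dna import encode


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50: int
    mean_contig: float
    max_contig: int
    at_percent: float
    n_contigs_ge_1kb: int
    total_bp_ge_1kb: int
    ns_per_100kb: float

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path: str | Path) -> None:
        """Assembly-report-shaped two-column table."""
        rows = [
            ("No. of contigs", self.n_contigs),
            ("N50 (bp)", self.n50),
            ("Avg. contig (bp)", f"{self.mean_contig:.1f}"),
            ("Max. contig (bp)", self.max_contig),
            ("% AT", f"{self.at_percent:.2f}"),
            ("Genome size (bp)", self.total_bp),
            ("No. of contigs (>= 1000 bp)", self.n_contigs_ge_1kb),
            ("Total length (>= 1000 bp)", self.total_bp_ge_1kb),
            ("No. of N's per 100 kb", f"{self.ns_per_100kb:.2f}"),
        ]
        with open(path, "w") as fh:
            fh.write("parameter\tvalue\n")
            for key, value in rows:
                fh.write(f"{key}\t{value}\n")


def n50(lengths: Iterable[int]) -> int:
    """N50 of a length multiset (descending cumulative-sum convention)."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("empty length set")
    half = arr.sum() / 2.0
    cumulative = np.cumsum(arr)
    return int(arr[np.searchsorted(cumulative, half, side="left")])


def compute_stats(
    contigs: dict[str, str] | Iterable[tuple[str, str]], length_floor: int = 0
) -> AssemblyStats:
    """Compute assembly statistics over contigs of length >= ``length_floor``."""
    items = contigs.items() if isinstance(contigs, dict) else contigs
    lengths: list[int] = []
    at = gc = n_count = 0
    n_ge_1kb = 0
    bp_ge_1kb = 0
    for _name, seq in items:
        if len(seq) < length_floor:
            continue
        lengths.append(len(seq))
        codes = encode(seq)
        at += int(((codes == 0) | (codes == 3)).sum())
        gc += int(((codes == 1) | (codes == 2)).sum())
        n_count += int((codes > 3).sum())
        if len(seq) >= 1000:
            n_ge_1kb += 1
            bp_ge_1kb += len(seq)
    if not lengths:
        raise ValueError("no contigs at or above the length floor")
    total = int(sum(lengths))
    called = at + gc
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bp=total,
        n50=n50(lengths),
        mean_contig=total / len(lengths),
        max_contig=int(max(lengths)),
        at_percent=100.0 * at / called if called else float("nan"),
        n_contigs_ge_1kb=n_ge_1kb,
        total_bp_ge_1kb=bp_ge_1kb,
        ns_per_100kb=100_000.0 * n_count / total,
    )
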