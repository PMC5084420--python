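"""Shared fixtures: small simulated genomes and one full-scale study run."""

from __future__ import annotations

import pandas as pd
import pytest

from cqkit import GenomeSpec, simulate_genome
from cqkit.config import RunConfig
from cqkit.pipeline import run_pipeline

#: Canonical seed of the full-scale validation study run.
STUDY_SEED = 42


@pytest.fixture(scope="session")
def small_genome():
    """A 12-contig genome (6 A / 3 X / 3 Y, 3-8 kb) used across tests."""
    return simulate_genome(
        GenomeSpec(
            n_autosomal_contigs=6,
            n_x_contigs=3,
            n_y_contigs=3,
            contig_length_range=(3_000, 8_000),
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full pipeline at the study conditions: 200 contigs (140 A / 30 X /
    30 Y, 5-50 kb), both sexes at 20x, 100 bp reads, 0.5% error.

    Session-scoped because the run takes a minute; several tests read the
    same outputs.
    """
    outdir = tmp_path_factory.mktemp("study")
    config = RunConfig.from_dict({"seed": STUDY_SEED, "outdir": str(outdir)})
    report = run_pipeline(config)
    cq = pd.read_csv(outdir / "cq.tsv", sep="\t")
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t")
    merged = cq.merge(truth, on="contig_id", suffixes=("", "_truth"))
    return report, merged
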