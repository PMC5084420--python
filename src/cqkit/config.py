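"""Run configuration: one YAML document drives every pipeline stage.

Schema (all sections optional unless a stage needs them)::

    seed: 42
    outdir: runs/demo
    mode: simulate          # "simulate" or "user"
    simulate:
      genome:
        n_autosomal_contigs: 140
        n_x_contigs: 30
        n_y_contigs: 30
        contig_length_range: [5000, 50000]
        gc_content: 0.28
      reads:
        depth: 20.0
        read_length: 100
        substitution_error_rate: 0.005
      te_families:          # planted repeat families
        - {consensus_id: LINE-1, length: 3000, te_class: LINE,
           n_copies: 20, target_divergence: 0.15, ts_tv_ratio: 2.0}
    inputs:                 # user mode
      assembly: contigs.fasta
      female_reads: female.fastq.gz
      male_reads: male.fastq.gz
      repeat_alignments: repeats.tsv      # TSV dialect or .align
    thresholds: {y_max: 0.05, x_min: 1.9, x_max: 2.5,
                 min_male_hits: 20, normalize: true}
    landscape: {bin_width: 1.0, cap: 55.0}
    stats: {min_length: 0}
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cqkit.cq import CQThresholds

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "cqkit_run",
    "mode": "simulate",
    "simulate": {
        "genome": {
            "n_autosomal_contigs": 140,
            "n_x_contigs": 30,
            "n_y_contigs": 30,
            "contig_length_range": [5000, 50000],
            "gc_content": 0.28,
        },
        "reads": {
            "depth": 20.0,
            "read_length": 100,
            "substitution_error_rate": 0.005,
        },
        "te_families": [],
    },
    "inputs": {},
    "thresholds": {
        "y_max": 0.05,
        "x_min": 1.9,
        "x_max": 2.5,
        "min_male_hits": 20,
        "normalize": True,
    },
    "landscape": {"bin_width": 1.0, "cap": 55.0},
    "stats": {"min_length": 0},
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class RunConfig:
    """Validated, default-filled pipeline configuration."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, overrides: dict) -> "RunConfig":
        unknown = set(overrides) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(_deep_update(DEFAULTS, overrides))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        return cls.from_dict(loaded)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    # -- convenience accessors ------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def mode(self) -> str:
        return self.data["mode"]

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    def thresholds(self) -> CQThresholds:
        t = self.data["thresholds"]
        return CQThresholds(
            y_max=float(t["y_max"]),
            x_min=float(t["x_min"]),
            x_max=float(t["x_max"]),
            min_male_hits=int(t["min_male_hits"]),
            normalize=bool(t["normalize"]),
        )

    def validate(self) -> None:
        """Check mode, referenced paths and numeric sections before any compute."""
        if self.mode not in ("simulate", "user"):
            raise ValueError(f"mode must be 'simulate' or 'user', got {self.mode!r}")
        self.thresholds()  # raises on bad bands
        if float(self.data["landscape"]["bin_width"]) <= 0:
            raise ValueError("landscape.bin_width must be positive")
        if self.mode == "user":
            inputs = self.data["inputs"]
            for key in ("assembly", "female_reads", "male_reads"):
                if not inputs.get(key):
                    raise ValueError(f"user mode requires inputs.{key}")
                if not Path(inputs[key]).exists():
                    raise FileNotFoundError(f"inputs.{key}: no such file {inputs[key]!r}")
            extra = inputs.get("repeat_alignments")
            if extra and not Path(extra).exists():
                raise FileNotFoundError(f"inputs.repeat_alignments: no such file {extra!r}")
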