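"""Run configuration: one flat namespace of every tunable parameter.

Unknown keys are rejected so that typos never silently fall back to
defaults; every run can log the resolved configuration and its digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All decision parameters of the pipeline with their defaults."""

    # preprocessing
    rr_max_ms: float = 2000.0
    rr_min_ms: float = 350.0
    irregular_tol: float = 0.20
    keep_wake_epochs: int = 10
    min_hours: float = 5.0
    max_ahi: float = 5.0
    min_efficiency: float = 0.75
    max_leading_wake_min: float = 45.0
    max_trailing_wake_min: float = 30.0
    max_noise_fraction: float = 0.25
    # features
    resample_hz: float = 4.0
    strf_subwindows: int = 5
    strf_subwindow_s: float = 90.0
    dfa_scale_min: int = 4
    dfa_scale_max: int = 64
    dfa_dual_exponent: bool = False
    # staging
    small_frame: int = 11
    large_frame: int = 121
    sg_order: int = 2
    k_grid_lo: float = -2.0
    k_grid_hi: float = 2.0
    k_grid_n: int = 41
    c_h: float = 0.25
    c_w: float = 0.5
    n_context: int = 8
    svc_max_samples: int = 4000
    # quality
    transition_labeling: str = "printed"
    quality_cv_folds: int = 5
    # reproducibility
    seed: int = 0

    def digest(self) -> str:
        """Short stable digest of the resolved configuration."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def k_grid(self):
        import numpy as np

        return np.linspace(self.k_grid_lo, self.k_grid_hi, self.k_grid_n)
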