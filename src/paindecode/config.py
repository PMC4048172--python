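"""Pipeline configuration: a strict, fully serializable parameter set.

Every run's outputs embed the configuration (and its hash) so results are
traceable; unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .cohort import BlockDesign
from .slr import SLRHyper

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the simulate/decode pipeline in one place."""

    # paths
    cohort_dir: str = "cohort"
    output_dir: str = "results"
    # synthetic cohort
    n_per_group: int = 13
    effect_size: float = 2.0
    noise_sd: float = 1.0
    smooth_fwhm: float = 8.0
    seed: int = 0
    simulate_bold: bool = False
    # block design
    tr: float = 3.67
    n_scans_per_run: int = 86
    n_runs: int = 2
    block_s: float = 14.0
    n_cycles: int = 5
    highpass_cutoff_s: float = 128.0
    ar_coef: float = 0.3
    # decoder
    alpha_init: float = 1.0
    prune_threshold: float = 1e8
    max_iter: int = 500
    tol: float = 1e-6
    standardize: bool = True
    # inference
    permutations: int = 1000
    fdr_q: float = 0.05

    def design(self) -> BlockDesign:
        return BlockDesign(tr=self.tr, n_scans_per_run=self.n_scans_per_run,
                           n_runs=self.n_runs, block_s=self.block_s,
                           n_cycles=self.n_cycles)

    def slr_hyper(self) -> SLRHyper:
        return SLRHyper(alpha_init=self.alpha_init,
                        prune_threshold=self.prune_threshold,
                        max_iter=self.max_iter, tol=self.tol,
                        standardize=self.standardize)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kw) -> "PipelineConfig":
        d = self.to_dict()
        d.update(kw)
        return PipelineConfig(**d)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config file, applying keyword overrides.

    Unknown keys raise immediately -- a misspelled parameter must never
    silently fall back to its default.
    """
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**data)
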