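"""Run configuration for the simulate → screen → report pipeline.

The defaults encode the emulated study design: 72 plexes of 7 study
samples (+1 pooled QC each) subsampled to 500 analytic samples, a
catalogue of 4705 proteins with 589 ± 65 detected per plex, log2
abundance SD of 1, and five carotenoid analytes whose overall mean
concentrations equal the study's printed medians, with plex SD 0.4,
residual SD 0.5 and detection limits that left-censor at roughly the
observed rates (β-carotene <1%, xanthophylls ~0, α-carotene ~4%,
lycopene ~2/3 of samples).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Per-analyte (b0_true = log2 of the typical concentration in μmol/L,
#: detection_limit in μmol/L).
ANALYTE_DEFAULTS: dict[str, tuple[float, float]] = {
    "beta_carotene": (math.log2(0.10), 0.0164),
    "lutein_zeaxanthin": (math.log2(0.34), 0.020),
    "beta_cryptoxanthin": (math.log2(0.06), 0.005),
    "alpha_carotene": (math.log2(0.01), 0.0028),
    "lycopene": (math.log2(0.02), 0.0244),
}


@dataclass
class RunConfig:
    # randomness
    seed: int = 20260927
    # design
    n_plexes: int = 72
    samples_per_plex: int = 7
    n_analytic: int | None = 500
    # proteome
    n_catalogue: int = 4705
    mean_detected_per_plex: float = 589.0
    sd_detected_per_plex: float = 65.0
    abundance_sd: float = 1.0
    prevalence_sd: float = 2.0
    # carotenoid truth
    analytes: list[str] = field(default_factory=lambda: list(ANALYTE_DEFAULTS))
    sigma_B: float = 0.4
    sigma_e: float = 0.5
    slopes_pos: list[float] = field(default_factory=lambda: [0.5, 0.3])
    slopes_neg: list[float] = field(default_factory=lambda: [-0.5, -0.3])
    # thresholds & floors
    min_fraction: float = 0.10
    q_threshold: float = 0.10
    q_cut_matrix: float = 0.05
    min_obs: int = 10
    min_groups: int = 2
    pi0_method: str = "smoother"
    include_qc_in_median: bool = False
    # paths
    data_dir: str = "results/sim"
    screen_dir: str = "results/screen"

    def __post_init__(self) -> None:
        for name in ("min_fraction", "q_threshold", "q_cut_matrix"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        unknown = [a for a in self.analytes if a not in ANALYTE_DEFAULTS]
        if unknown:
            raise ConfigError(f"analytes without default calibration: {unknown}")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys take the defaults above."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of key: value pairs")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
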