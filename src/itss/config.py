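"""Run configuration: every tunable of the pipeline with its default.

The defaults are the analysis parameters of the published workflow this
package implements: 50-nt Gaussian smoothing at 99.5% kernel mass, 150-nt
windows stepped by 5 nt, the 50th/95th-percentile coverage-sum band, the
90th-percentile contig-scan threshold, 1-kb / 3-fold merging, a 4-kb contig
cap, ≥2-sample support, the 75-nt internality margin, the rank-800 cutoff,
300-nt upstream motif windows and the 0.85 relative PWM score threshold.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # shape signal
    sigma: float = 50.0
    kernel_mass: float = 0.995
    window: int = 150
    step: int = 5
    # peak filtering / contig scan (percentiles)
    rmsd_floor_percentile: float = 50.0
    coverage_sum_band: tuple[float, float] = (50.0, 95.0)
    contig_scan_percentile: float = 90.0
    tes_flank: int = 150
    # merging / consensus
    merge_proximity: int = 1000
    merge_fold: float = 3.0
    max_contig: int = 4000
    min_support: int = 2
    match_proximity: int = 150
    # internal classification
    internal_margin: int = 75
    rank_cutoff: float = 800.0
    # motifs
    upstream_window: int = 300
    motif_threshold: float = 0.85
    pwm_pseudocount: float = 0.25
    # inputs / outputs
    genome: str | None = None
    annotation: str | None = None
    exclusions: str | None = None
    control: str | None = None
    tests: list[str] = field(default_factory=list)
    mse_pwm: str | None = None
    urs1_pwm: str | None = None
    outdir: str = "itss_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.coverage_sum_band, list):
            self.coverage_sum_band = tuple(self.coverage_sum_band)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["coverage_sum_band"] = list(self.coverage_sum_band)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    def resolve(self, base: Path | None = None) -> "RunConfig":
        """Make all input paths absolute relative to ``base``."""
        if base is None:
            return self
        out = RunConfig(**asdict(self))
        for attr in ("genome", "annotation", "exclusions", "control",
                     "mse_pwm", "urs1_pwm"):
            v = getattr(out, attr)
            if v is not None and not Path(v).is_absolute():
                setattr(out, attr, str(base / v))
        out.tests = [
            str(base / t) if not Path(t).is_absolute() else t for t in out.tests
        ]
        if not Path(out.outdir).is_absolute():
            out.outdir = str(base / out.outdir)
        return out


__all__ = ["RunConfig"]
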