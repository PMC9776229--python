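"""Run configuration: depth grids, QC thresholds, drop-scan parameters.

Depth grids follow the panel's run types: DNA diagnostics (SNV and CNV)
are evaluated at 50-500X, RNA at 5-50X; the raw covdata carries the full
5X-500X grid.  All decision thresholds are inclusive (a value exactly at
the bound passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["DEPTH_GRIDS", "RunConfig", "load_config"]

#: depth thresholds (X-fold) per run type
DEPTH_GRIDS: dict[str, tuple[int, ...]] = {
    "DNA": (50, 100, 250, 500),
    "DNA_SNV": (50, 100, 250, 500),
    "DNA_CNV": (50, 100, 250, 500),
    "RNA": (5, 10, 50),
    "FULL": (5, 10, 50, 100, 250, 500),
}


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the coverage diagnostics.

    Attributes
    ----------
    run_type
        ``"DNA"`` or ``"RNA"``; selects the default depth grid.
    mpc_rule
        Run-level rule: a depth passes when the run-summary MPC (median
        over regions of the per-region MPC) is >= this percent.
    q1_rule
        Sample-level rule: a sample is flagged at a depth when the first
        quartile of its per-exon percent coverage is < this percent.
    blacklist_threshold
        A region is blacklisted at a depth when its MPC < this percent.
    mad_threshold
        Coverage-MAD compliance bound (median absolute deviation of
        median-normalized per-region CNV coverage), unitless.
    insert_size_min
        Median insert size compliance bound (bp).
    drop_min_width / drop_ratio / drop_eligibility_depth
        Base-level drop scan: a drop is a run of >= ``drop_min_width``
        bases each below ``drop_ratio`` x the exon median depth, scanned
        only in exons whose median depth >= ``drop_eligibility_depth``.
    mpc_summary
        How the run-level MPC is aggregated over regions: ``"median"``
        (default), ``"mean"``, or ``"fraction"`` (percent of regions with
        MPC >= mpc_rule).
    """

    run_type: str = "DNA"
    depths: tuple[int, ...] = ()
    mpc_rule: float = 75.0
    q1_rule: float = 75.0
    blacklist_threshold: float = 75.0
    mad_threshold: float = 0.21
    insert_size_min: float = 70.0
    drop_min_width: int = 10
    drop_ratio: float = 0.5
    drop_eligibility_depth: float = 100.0
    mpc_summary: str = "median"
    gene_separator: str = "_"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.run_type not in DEPTH_GRIDS:
            raise ValueError(f"unknown run_type {self.run_type!r}")
        if not self.depths:
            object.__setattr__(self, "depths", DEPTH_GRIDS[self.run_type])
        if not (0 <= self.mpc_rule <= 100 and 0 <= self.q1_rule <= 100
                and 0 <= self.blacklist_threshold <= 100):
            raise ValueError("percent thresholds must lie in [0, 100]")
        if not 0 < self.drop_ratio < 1:
            raise ValueError("drop_ratio must lie in (0, 1)")
        if self.drop_min_width < 1:
            raise ValueError("drop_min_width must be >= 1")
        if self.mad_threshold < 0:
            raise ValueError("mad_threshold must be >= 0")
        if self.mpc_summary not in ("median", "mean", "fraction"):
            raise ValueError(f"unknown mpc_summary {self.mpc_summary!r}")

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides.

    Precedence: explicit overrides > file values > defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        if "depths" in data:
            data["depths"] = tuple(int(d) for d in data["depths"])
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValueError(f"bad config key: {exc}") from exc
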