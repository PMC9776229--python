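"""Percent coverage, MPC, sample diagnostics and quality rules.

The central statistic is the *percent coverage* ``p`` of a region at a
depth threshold D: the percentage of the region's bases covered by at
least D reads, ``p = 100 * count / length``.  The *median percent
coverage* (MPC) of a region at D is the median of ``p`` across samples.

Two inclusive quality rules operate on these quantities, both with a 75%
default bound:

* **run rule** — at each depth of the run-type grid the run-level summary
  MPC (median over regions) should be >= 75%; a good run maximizes the
  number of passing depths;
* **sample rule** — for each sample and depth, the first quartile (Q1) of
  the per-exon ``p`` distribution should be >= 75%, i.e. at least 75% of
  exons covered at >= 75%.

A separate uniformity metric for the CNV region set is the coverage MAD:
the median absolute deviation of per-region mean depths after dividing by
their median, compliant when <= 0.21.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CovDataTable, GenomicRegion

__all__ = [
    "PercentCoverageMatrix",
    "MPCProfile",
    "SampleDiagnostics",
    "RunQualityReport",
    "CovMadResult",
    "percent_coverage",
    "mpc",
    "sample_quartiles",
    "sample_diagnostics_table",
    "run_quality",
    "flag_depleted_samples",
    "coverage_mad",
]


@dataclass
class PercentCoverageMatrix:
    """Percent of region bases covered at >= each depth, per sample.

    ``values[i, j, k]`` is on the 0-100 scale for region ``i``, sample
    ``j``, depth ``depths[k]``.
    """

    regions: list[GenomicRegion]
    samples: list[str]
    depths: tuple[int, ...]
    values: np.ndarray  # (n_regions, n_samples, n_depths), float64
    source: CovDataTable | None = None

    def depth_index(self, depth: int) -> int:
        try:
            return self.depths.index(depth)
        except ValueError:
            raise KeyError(f"depth {depth}X not in matrix grid {self.depths}") from None


@dataclass
class MPCProfile:
    """Median percent coverage across samples, per region and depth."""

    regions: list[GenomicRegion]
    depths: tuple[int, ...]
    values: np.ndarray  # (n_regions, n_depths)
    n_samples: int

    def depth_index(self, depth: int) -> int:
        try:
            return self.depths.index(depth)
        except ValueError:
            raise KeyError(f"depth {depth}X not in profile grid {self.depths}") from None


@dataclass
class SampleDiagnostics:
    """Quartile summary of one sample's per-exon percent coverage at one depth."""

    sample: str
    depth: int
    n_regions: int
    minimum: float
    q1: float
    q2: float
    q3: float
    maximum: float
    flagged: bool
    rule_threshold: float = 75.0


@dataclass
class RunQualityReport:
    """Per-depth summary MPC with the pass/fail run rule."""

    depths: tuple[int, ...]
    summary_mpc: dict[int, float]
    passes: dict[int, bool]
    rule_threshold: float = 75.0
    summary: str = "median"

    @property
    def n_pass(self) -> int:
        return sum(self.passes.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": list(self.depths),
                "summary_mpc": [self.summary_mpc[d] for d in self.depths],
                "pass": [self.passes[d] for d in self.depths],
            }
        )


@dataclass
class CovMadResult:
    """Coverage MAD of median-normalized per-region depths, with compliance."""

    mad: float
    compliant: bool
    threshold: float = 0.21
    n_regions: int = 0


def percent_coverage(table: CovDataTable) -> PercentCoverageMatrix:
    """Convert covdata base counts into percent coverage ``p``.

    ``p = 100 * count / (end - start)`` for every (region, sample, depth).
    """
    table.validate()
    lengths = table.lengths.astype(float)
    values = 100.0 * table.counts / lengths[:, None, None]
    return PercentCoverageMatrix(
        table.regions, list(table.samples), table.depths, values, source=table
    )


def mpc(matrix: PercentCoverageMatrix) -> MPCProfile:
    """Median of percent coverage across samples, per (region, depth).

    Even sample counts use the mean of the two central order statistics.
    """
    if not matrix.samples:
        raise ValueError("MPC requires at least one sample")
    values = np.median(matrix.values, axis=1)
    return MPCProfile(matrix.regions, matrix.depths, values, len(matrix.samples))


def sample_quartiles(
    matrix: PercentCoverageMatrix,
    sample: str,
    depth: int,
    region_filter: np.ndarray | None = None,
    rule_threshold: float = 75.0,
) -> SampleDiagnostics:
    """Quartiles of one sample's per-exon ``p`` distribution at one depth.

    Quartiles interpolate linearly between order statistics (the type-7
    convention).  The sample is flagged when Q1 < ``rule_threshold``.
    """
    j = matrix.samples.index(sample)
    k = matrix.depth_index(depth)
    p = matrix.values[:, j, k]
    if region_filter is not None:
        p = p[np.asarray(region_filter)]
    if p.size == 0:
        raise ValueError(f"no regions for sample {sample!r} after filtering")
    q1, q2, q3 = np.quantile(p, [0.25, 0.5, 0.75])
    return SampleDiagnostics(
        sample=sample,
        depth=depth,
        n_regions=int(p.size),
        minimum=float(p.min()),
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        maximum=float(p.max()),
        flagged=bool(q1 < rule_threshold),
        rule_threshold=rule_threshold,
    )


def sample_diagnostics_table(
    matrix: PercentCoverageMatrix,
    depths: tuple[int, ...] | None = None,
    region_filter: np.ndarray | None = None,
    rule_threshold: float = 75.0,
) -> pd.DataFrame:
    """Per-sample diagnostic table over all samples and grid depths."""
    depths = depths or matrix.depths
    rows = []
    for s in matrix.samples:
        for d in depths:
            diag = sample_quartiles(matrix, s, d, region_filter, rule_threshold)
            rows.append(
                {
                    "sample": s,
                    "depth": d,
                    "n_regions": diag.n_regions,
                    "min": diag.minimum,
                    "q1": diag.q1,
                    "q2": diag.q2,
                    "q3": diag.q3,
                    "max": diag.maximum,
                    "flagged": diag.flagged,
                }
            )
    return pd.DataFrame(rows)


def run_quality(
    profile: MPCProfile,
    depths: tuple[int, ...] | None = None,
    threshold: float = 75.0,
    summary: str = "median",
) -> RunQualityReport:
    """Apply the run-level rule: summary MPC >= threshold per depth (inclusive).

    ``summary`` aggregates the per-region MPC over regions: ``"median"``
    (default), ``"mean"``, or ``"fraction"`` (percent of regions at or
    above the threshold, compared to the same threshold).
    """
    depths = depths or profile.depths
    missing = [d for d in depths if d not in profile.depths]
    if missing:
        raise KeyError(f"depths {missing} not present in MPC profile")
    summary_mpc: dict[int, float] = {}
    passes: dict[int, bool] = {}
    for d in depths:
        col = profile.values[:, profile.depth_index(d)]
        if summary == "median":
            val = float(np.median(col))
        elif summary == "mean":
            val = float(np.mean(col))
        elif summary == "fraction":
            val = float(100.0 * np.mean(col >= threshold))
        else:
            raise ValueError(f"unknown summary {summary!r}")
        summary_mpc[d] = val
        passes[d] = val >= threshold
    return RunQualityReport(tuple(depths), summary_mpc, passes, threshold, summary)


def flag_depleted_samples(
    matrix: PercentCoverageMatrix,
    depths: tuple[int, ...] | None = None,
    threshold: float = 75.0,
    region_filter: np.ndarray | None = None,
) -> list[tuple[str, int, bool]]:
    """Sample-level rule: flagged at depth D iff Q1 of per-exon p < threshold."""
    depths = depths or matrix.depths
    out = []
    for s in matrix.samples:
        for d in depths:
            diag = sample_quartiles(matrix, s, d, region_filter, threshold)
            out.append((s, d, diag.flagged))
    return out


def coverage_mad(region_means, threshold: float = 0.21) -> CovMadResult:
    """Coverage MAD: median absolute deviation of median-normalized depths.

    Given per-region mean depths (over the CNV region set) for one sample,
    each value is divided by the median, so the normalized median is 1; the
    MAD is the median of |x_i - 1|.  Compliant when MAD <= ``threshold``.
    The statistic is invariant under scaling all means by a positive
    constant.
    """
    x = np.asarray(region_means, dtype=float)
    if x.size < 2:
        raise ValueError("coverage MAD requires at least 2 region means")
    if (x <= 0).any():
        raise ValueError("all region mean depths must be positive")
    norm = x / np.median(x)
    mad = float(np.median(np.abs(norm - np.median(norm))))
    return CovMadResult(mad=mad, compliant=mad <= threshold,
                        threshold=threshold, n_regions=int(x.size))
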