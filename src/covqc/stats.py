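"""Wet-lab and sequencing metric statistics for panel validation runs.

Metrics arrive in long format — one row per (sample, metric) with run
(1-5) and nucleic-type (DNA/RNA) labels.  The layer provides:

* descriptive statistics per run, formatted "mean ± sd / median [min; max]";
* inclusive compliance rules (e.g. DV200 >= 20%, delta-Cq <= 5, median
  insert size >= 70 bp) with per-rule compliant fractions;
* Kruskal-Wallis across-run tests and pairwise Mann-Whitney or Brown-Mood
  median tests with Benjamini-Hochberg FDR over the pair family;
* the paired Wilcoxon signed-rank comparison of pre-capture vs enriched
  library concentrations, stratified by nucleic type;
* Kendall tau-b correlations between wet metrics and per-sample coverage
  summaries (the per-exon Q2 percent coverage), stratified by variant
  type and depth, with asymptotic 95% confidence intervals.

All tests are two-sided; p < 0.05 is the significance convention.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComplianceRule",
    "TestResult",
    "TauResult",
    "RULE_PRESETS",
    "load_metrics",
    "compliance_flags",
    "describe_by_run",
    "kruskal_wallis",
    "pairwise_tests",
    "paired_library_test",
    "wilcoxon_signed_rank",
    "kendall_tau",
    "tau_correlation",
    "heatmap_export",
]

METRICS_COLUMNS = ["sample", "run", "nucleic", "metric", "value"]


def load_metrics(path: str | Path) -> pd.DataFrame:
    """Read a long-format metrics table (TSV/CSV by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics table missing column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["sample", "metric"])
    if dup.any():
        raise ValueError("duplicate (sample, metric) rows in metrics table")
    return df


@dataclass(frozen=True)
class ComplianceRule:
    """An inclusive compliance bound on one metric.

    ``comparator`` is ``"ge"`` (value >= bound passes), ``"le"`` or
    ``"within"`` (two bounds, inclusive on both ends).
    """

    metric: str
    comparator: str
    bound: float
    high: float | None = None
    applies_to: str = "both"  # DNA | RNA | both

    def __post_init__(self) -> None:
        if self.comparator not in ("ge", "le", "within"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.comparator == "within":
            if self.high is None or not self.bound < self.high:
                raise ValueError("within-rule needs bounds low < high")

    def check(self, value: float) -> bool:
        if self.comparator == "ge":
            return value >= self.bound
        if self.comparator == "le":
            return value <= self.bound
        return self.bound <= value <= self.high  # type: ignore[operator]


# Rule presets.  "inclusion" encodes the sample-inclusion thresholds used
# before library preparation (absorbance windows, DV200, delta-Cq);
# "compliant_value" encodes the per-metric compliant-value bounds attached
# to the run QC tables (including sequencing-side insert size and coverage
# MAD).  The two sets disagree on the DNA A260/280 bound and are therefore
# never merged.
RULE_PRESETS: dict[str, list[ComplianceRule]] = {
    "inclusion": [
        ComplianceRule("a260_280", "within", 1.6, 1.8, "DNA"),
        ComplianceRule("a260_280", "within", 1.8, 2.0, "RNA"),
        ComplianceRule("a260_230", "ge", 2.0, None, "both"),
        ComplianceRule("dv200", "ge", 20.0, None, "RNA"),
        ComplianceRule("delta_cq", "le", 5.0, None, "DNA"),
    ],
    "compliant_value": [
        ComplianceRule("concentration", "ge", 3.5, None, "DNA"),
        ComplianceRule("concentration", "ge", 10.5, None, "RNA"),
        ComplianceRule("a260_280", "ge", 2.0, None, "both"),
        ComplianceRule("a260_230", "ge", 2.0, None, "both"),
        ComplianceRule("dv200", "ge", 20.0, None, "RNA"),
        ComplianceRule("delta_cq", "le", 5.0, None, "DNA"),
        ComplianceRule("pre_capture", "ge", 20.0, None, "both"),
        ComplianceRule("enriched", "ge", 3.0, None, "both"),
        ComplianceRule("fragment_size", "within", 150.0, 300.0, "DNA"),
        ComplianceRule("median_insert_size", "ge", 70.0, None, "DNA"),
        ComplianceRule("coverage_mad", "le", 0.21, None, "DNA"),
    ],
}


def compliance_flags(
    table: pd.DataFrame, rules: Sequence[ComplianceRule]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate compliance rules sample-by-sample.

    Returns ``(per_sample, summary)``: one row per (rule, sample) with the
    pass flag, and one row per rule with compliant count, evaluated count
    and percent.
    """
    known = set(table["metric"])
    rows = []
    for rule in rules:
        if rule.metric not in known:
            raise KeyError(f"compliance rule references unknown metric {rule.metric!r}")
        sub = table[table["metric"] == rule.metric]
        if rule.applies_to != "both":
            sub = sub[sub["nucleic"] == rule.applies_to]
        for _, row in sub.iterrows():
            rows.append(
                {
                    "metric": rule.metric,
                    "comparator": rule.comparator,
                    "applies_to": rule.applies_to,
                    "sample": row["sample"],
                    "value": row["value"],
                    "compliant": rule.check(float(row["value"])),
                }
            )
    per_sample = pd.DataFrame(
        rows, columns=["metric", "comparator", "applies_to", "sample", "value", "compliant"]
    )
    if len(per_sample):
        grp = per_sample.groupby(["metric", "comparator", "applies_to"], sort=False)
        summary = grp["compliant"].agg(["sum", "count"]).reset_index()
        summary = summary.rename(columns={"sum": "n_compliant", "count": "n_evaluated"})
        summary["percent"] = 100.0 * summary["n_compliant"] / summary["n_evaluated"]
    else:
        summary = pd.DataFrame(
            columns=["metric", "comparator", "applies_to", "n_compliant", "n_evaluated", "percent"]
        )
    return per_sample, summary


def describe_by_run(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-run and overall descriptives: mean, sd (n-1), median, min, max.

    A run with a single value reports sd as missing, not 0.  The
    ``formatted`` column renders "mean ± sd / median [min; max]".
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise KeyError(f"metric {metric!r} not present")
    rows = []
    groups = [("overall", sub["value"])] + [
        (run, g["value"]) for run, g in sub.groupby("run")
    ]
    for label, vals in groups:
        v = vals.to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else math.nan
        mean, med = float(np.mean(v)), float(np.median(v))
        lo, hi = float(v.min()), float(v.max())
        sd_txt = f"{sd:.3g}" if v.size > 1 else "NA"
        rows.append(
            {
                "run": label,
                "n": int(v.size),
                "mean": mean,
                "sd": sd,
                "median": med,
                "min": lo,
                "max": hi,
                "formatted": f"{mean:.4g} ± {sd_txt} / {med:.4g} [{lo:.4g}; {hi:.4g}]",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    groups: tuple = ()
    adjusted_p: float | None = None
    n: int = 0
    direction: str = ""
    degenerate: bool = False


def _groups_for(table: pd.DataFrame, metric: str, by: str = "run",
                all_levels: bool = False) -> dict:
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise KeyError(f"metric {metric!r} not present")
    groups = {k: g["value"].to_numpy(dtype=float) for k, g in sub.groupby(by)}
    if all_levels:  # group labels without observations become empty groups
        for k in table[by].unique():
            groups.setdefault(k, np.empty(0))
    return groups


def kruskal_wallis(table: pd.DataFrame, metric: str, by: str = "run") -> TestResult:
    """Kruskal-Wallis rank test across groups (tie-corrected H, chi2 p).

    Identical values in every group give H = 0, p = 1 (not an error).
    """
    groups = _groups_for(table, metric, by)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", tuple(groups), n=pooled.size)
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal_wallis", tuple(groups), n=pooled.size)


def _brown_mood(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Brown-Mood median test for two groups via the exact hypergeometric.

    Counts values strictly above the pooled grand median in each group and
    applies a two-sided Fisher exact test to the resulting 2x2 table.
    """
    grand = np.median(np.concatenate([x, y]))
    above = [int((x > grand).sum()), int((y > grand).sum())]
    below = [int((x <= grand).sum()), int((y <= grand).sum())]
    odds, p = sps.fisher_exact([above, below], alternative="two-sided")
    return float(above[0]), float(p)


def pairwise_tests(
    table: pd.DataFrame,
    metric: str,
    by: str = "run",
    method: str = "mann_whitney",
    adjust: str = "fdr_bh",
) -> list[TestResult]:
    """All pairwise two-group comparisons with FDR adjustment.

    ``method`` is ``"mann_whitney"`` (rank-sum) or ``"brown_mood"``
    (median test, exact hypergeometric).  Adjusted p-values apply
    Benjamini-Hochberg (or ``"fdr_by"``) over the family of all pairs.
    Empty groups are skipped with a warning record (p = NaN), excluded
    from the adjustment family.
    """
    groups = _groups_for(table, metric, by, all_levels=True)
    if len(groups) < 2:
        raise ValueError("pairwise tests require at least 2 groups")
    results: list[TestResult] = []
    for a, b in itertools.combinations(sorted(groups), 2):
        x, y = groups[a], groups[b]
        if x.size == 0 or y.size == 0:
            warnings.warn(f"pair ({a}, {b}) skipped: empty group")
            results.append(TestResult(math.nan, math.nan, method, (a, b), degenerate=True))
            continue
        if method == "mann_whitney":
            u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
            stat = float(u)
        elif method == "brown_mood":
            stat, p = _brown_mood(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(TestResult(stat, float(p), method, (a, b), n=x.size + y.size))
    tested = [r for r in results if not r.degenerate]
    if tested:
        _, adj, _, _ = multipletests([r.p_value for r in tested], method=adjust)
        for r, q in zip(tested, adj):
            r.adjusted_p = float(q)
    return results


def wilcoxon_signed_rank(
    before: np.ndarray, after: np.ndarray, zero_method: str = "wilcox"
) -> TestResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped before ranking (``"wilcox"``, the classic
    convention; ``"pratt"`` keeps them in the ranking).  The p-value is
    exact for n <= 25 non-zero untied differences, normal approximation
    with tie correction otherwise.  All-zero differences give the
    degenerate result p = 1.  ``direction`` reports the sign of the median
    change after - before.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = after - before
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, "wilcoxon", n=0, degenerate=True)
    med = float(np.median(diffs))
    direction = "decrease" if med < 0 else ("increase" if med > 0 else "none")
    ties = np.unique(np.abs(nz)).size < nz.size
    mode = "exact" if (nz.size <= 25 and not ties) else "approx"
    stat, p = sps.wilcoxon(before, after, zero_method=zero_method, method=mode,
                           correction=False)
    return TestResult(float(stat), float(p), "wilcoxon", n=int(nz.size),
                      direction=direction)


def paired_library_test(
    table: pd.DataFrame,
    pre_metric: str = "pre_capture",
    post_metric: str = "enriched",
    zero_method: str = "wilcox",
) -> dict[str, TestResult]:
    """Pre-capture vs enriched library comparison per nucleic type.

    Pairs samples carrying both metrics; samples missing either value are
    dropped.  Returns one :func:`wilcoxon_signed_rank` result per nucleic
    type present.
    """
    wide = table[table["metric"].isin([pre_metric, post_metric])].pivot_table(
        index=["nucleic", "sample"], columns="metric", values="value"
    )
    out: dict[str, TestResult] = {}
    for nucleic, sub in wide.groupby(level="nucleic"):
        sub = sub.dropna()
        if sub.empty:
            continue
        out[str(nucleic)] = wilcoxon_signed_rank(
            sub[pre_metric].to_numpy(), sub[post_metric].to_numpy(), zero_method
        )
    return out


@dataclass
class TauResult:
    tau: float
    p_value: float
    ci_low: float
    ci_high: float
    metric: str = ""
    coverage_var: str = ""
    n: int = 0


def kendall_tau(x, y, metric: str = "", coverage_var: str = "") -> TauResult:
    """Kendall tau-b with p-value and asymptotic 95% confidence interval.

    The CI is the normal approximation tau ± 1.96·SE with
    SE = sqrt(2(2n+5) / (9n(n-1))), clipped to [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("kendall_tau needs >= 3 paired observations")
    res = sps.kendalltau(x, y)
    tau, p = float(res.statistic), float(res.pvalue)
    if math.isnan(tau):  # constant input
        return TauResult(math.nan, math.nan, math.nan, math.nan, metric, coverage_var, x.size)
    n = x.size
    se = math.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
    lo, hi = max(-1.0, tau - 1.959963984540054 * se), min(1.0, tau + 1.959963984540054 * se)
    return TauResult(tau, p, lo, hi, metric, coverage_var, n)


def tau_correlation(
    metrics: pd.DataFrame,
    coverage: pd.DataFrame,
    run: object | None = None,
    min_pairs: int = 3,
) -> list[TauResult]:
    """Wet-metric vs coverage correlations, stratified by variant type and depth.

    ``coverage`` carries one row per (sample, variant_type, depth) with the
    sample's median per-exon percent coverage in column ``q2``.  For every
    (metric, variant_type, depth) stratum, samples present in both tables
    are paired (missing values dropped pairwise); strata with fewer than
    ``min_pairs`` pairs are skipped with a warning.  ``run`` restricts both
    tables to one sequencing run.
    """
    for col in ("sample", "variant_type", "depth", "q2"):
        if col not in coverage.columns:
            raise ValueError(f"coverage table missing column {col!r}")
    if run is not None:
        metrics = metrics[metrics["run"] == run]
        if "run" in coverage.columns:
            coverage = coverage[coverage["run"] == run]
    results: list[TauResult] = []
    for metric in sorted(metrics["metric"].unique()):
        mvals = metrics[metrics["metric"] == metric].set_index("sample")["value"]
        for (vt, depth), sub in coverage.groupby(["variant_type", "depth"]):
            cvals = sub.set_index("sample")["q2"]
            common = mvals.index.intersection(cvals.index)
            x = mvals.loc[common].to_numpy(dtype=float)
            y = cvals.loc[common].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            x, y = x[keep], y[keep]
            label = f"{vt}_{depth}X"
            if x.size < min_pairs:
                warnings.warn(f"stratum ({metric}, {label}): only {x.size} pairs, skipped")
                continue
            results.append(kendall_tau(x, y, metric, label))
    return results


def heatmap_export(
    results: Sequence[TauResult],
    out_prefix: str | Path,
    alpha: float = 0.05,
) -> tuple[Path, Path]:
    """Write the tau matrix as TSV and render it as an annotated heatmap.

    Cells with p < ``alpha`` are starred in the figure.  Returns
    ``(tsv_path, png_path)``.
    """
    if not results:
        raise ValueError("no correlation results to export")
    metrics = sorted({r.metric for r in results})
    covvars = sorted({r.coverage_var for r in results})
    tau = pd.DataFrame(np.nan, index=metrics, columns=covvars)
    pval = pd.DataFrame(np.nan, index=metrics, columns=covvars)
    for r in results:
        tau.loc[r.metric, r.coverage_var] = r.tau
        pval.loc[r.metric, r.coverage_var] = r.p_value
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    tau.rename_axis("metric").to_csv(tsv_path, sep="\t")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1.2 * len(covvars) + 3, 0.6 * len(metrics) + 2)
    )
    im = ax.imshow(tau.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(covvars)), covvars, rotation=45, ha="right")
    ax.set_yticks(range(len(metrics)), metrics)
    for i in range(len(metrics)):
        for j in range(len(covvars)):
            t, p = tau.iat[i, j], pval.iat[i, j]
            if not math.isnan(t):
                star = " *" if p < alpha else ""
                ax.text(j, i, f"{t:.2f}{star}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Kendall tau-b")
    fig.tight_layout()
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return tsv_path, png_path
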