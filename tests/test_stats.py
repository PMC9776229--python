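"""QC statistics: compliance, descriptives, rank tests, FDR, Kendall tau."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from covqc import (
    RULE_PRESETS,
    ComplianceRule,
    MetricsConfig,
    MetricSpec,
    compliance_flags,
    describe_by_run,
    heatmap_export,
    kendall_tau,
    kruskal_wallis,
    load_metrics,
    paired_library_test,
    pairwise_tests,
    simulate_metrics,
    tau_correlation,
    wilcoxon_signed_rank,
)
from covqc.stats import TauResult, _brown_mood


def _metrics(values_by_run, metric="m", nucleic="DNA"):
    rows = []
    i = 0
    for run, vals in values_by_run.items():
        for v in vals:
            rows.append((f"X{i:03d}", run, nucleic, metric, float(v)))
            i += 1
    return pd.DataFrame(rows, columns=["sample", "run", "nucleic", "metric", "value"])


class TestCompliance:
    def test_dv200_boundary_inclusive(self):
        table = _metrics({1: [20.0, 19.999]}, metric="dv200", nucleic="RNA")
        rule = ComplianceRule("dv200", "ge", 20.0, applies_to="RNA")
        per_sample, summary = compliance_flags(table, [rule])
        assert per_sample["compliant"].tolist() == [True, False]
        assert summary["n_compliant"].iloc[0] == 1

    def test_all_violating_gives_zero_fraction(self):
        table = _metrics({1: [1.0, 2.0, 3.0]}, metric="dv200", nucleic="RNA")
        _, summary = compliance_flags(
            table, [ComplianceRule("dv200", "ge", 20.0, applies_to="RNA")]
        )
        assert summary["n_compliant"].iloc[0] == 0
        assert summary["percent"].iloc[0] == 0.0

    def test_fraction_matches_brute_force_count(self, rng):
        vals = rng.uniform(0, 10, 50)
        table = _metrics({1: vals}, metric="delta_cq")
        _, summary = compliance_flags(
            table, [ComplianceRule("delta_cq", "le", 5.0, applies_to="DNA")]
        )
        assert summary["n_compliant"].iloc[0] == int((vals <= 5.0).sum())
        assert summary["n_evaluated"].iloc[0] == 50

    def test_within_rule_inclusive_on_both_ends(self):
        table = _metrics({1: [1.6, 1.8, 1.59, 1.81]}, metric="a260_280")
        rule = ComplianceRule("a260_280", "within", 1.6, 1.8, "DNA")
        per_sample, _ = compliance_flags(table, [rule])
        assert per_sample["compliant"].tolist() == [True, True, False, False]

    def test_unknown_metric_is_config_error(self):
        table = _metrics({1: [1.0]})
        with pytest.raises(KeyError, match="nope"):
            compliance_flags(table, [ComplianceRule("nope", "ge", 1.0)])

    def test_nucleic_restriction(self):
        rows = [("a", 1, "DNA", "dv200", 5.0), ("b", 1, "RNA", "dv200", 5.0)]
        table = pd.DataFrame(rows, columns=["sample", "run", "nucleic", "metric", "value"])
        per_sample, _ = compliance_flags(
            table, [ComplianceRule("dv200", "ge", 20.0, applies_to="RNA")]
        )
        assert per_sample["sample"].tolist() == ["b"]

    def test_presets_are_distinct_and_valid(self):
        incl = {(r.metric, r.applies_to, r.comparator, r.bound)
                for r in RULE_PRESETS["inclusion"]}
        cv = {(r.metric, r.applies_to, r.comparator, r.bound)
              for r in RULE_PRESETS["compliant_value"]}
        assert incl != cv  # the two rule sets are never merged


class TestDescribe:
    def test_one_two_three(self):
        d = describe_by_run(_metrics({1: [1, 2, 3]}), "m")
        overall = d[d["run"] == "overall"].iloc[0]
        assert overall["mean"] == 2.0
        assert overall["sd"] == pytest.approx(1.0)
        assert overall["median"] == 2.0
        assert (overall["min"], overall["max"]) == (1.0, 3.0)

    def test_single_value_run_has_no_sd(self):
        d = describe_by_run(_metrics({1: [5.0]}), "m")
        row = d[d["run"] == 1].iloc[0]
        assert math.isnan(row["sd"])
        assert row["median"] == row["mean"] == 5.0
        assert "NA" in row["formatted"]

    def test_matches_two_pass_reference(self, rng):
        vals = rng.normal(10, 3, size=37)
        d = describe_by_run(_metrics({1: vals}), "m")
        row = d[d["run"] == "overall"].iloc[0]
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        assert row["mean"] == pytest.approx(mean, abs=1e-12)
        assert row["sd"] == pytest.approx(sd, abs=1e-12)


class TestKruskalWallis:
    def test_identical_groups_give_p_one(self):
        res = kruskal_wallis(_metrics({1: [5, 5, 5], 2: [5, 5, 5]}), "m")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_manual_rank_oracle(self):
        # three tie-free groups; textbook H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
        groups = {1: [1, 2, 3], 2: [10, 11, 12], 3: [20, 21, 22]}
        ranks = {1: [1, 2, 3], 2: [4, 5, 6], 3: [7, 8, 9]}
        N = 9
        H = 12 / (N * (N + 1)) * sum(sum(r) ** 2 / 3 for r in ranks.values()) - 3 * (N + 1)
        res = kruskal_wallis(_metrics(groups), "m")
        assert res.statistic == pytest.approx(H, abs=1e-12)
        assert res.p_value == pytest.approx(sps.chi2.sf(H, 2), abs=1e-12)

    def test_two_groups_equals_rank_sum_z_squared(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = kruskal_wallis(_metrics({1: x, 2: y}), "m")
        u, p = sps.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_permutation_null_matches_chi2_p(self, rng):
        """Label-permutation exceedance of H approximates the chi-square p."""
        vals = rng.normal(size=18)
        labels = np.repeat([1, 2, 3], 6)
        table = _metrics({r: vals[labels == r] for r in (1, 2, 3)})
        obs = kruskal_wallis(table, "m")
        exceed = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            h, _ = sps.kruskal(*(vals[perm == r] for r in (1, 2, 3)))
            exceed += h >= obs.statistic
        mc_p = exceed / n_perm
        assert abs(mc_p - obs.p_value) < 4 * math.sqrt(0.25 / n_perm) + 0.02

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(_metrics({1: [1, 2]}), "m")


def _bh_stepup(pvals):
    """Reference Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestPairwise:
    def test_five_runs_give_ten_pairs(self, rng):
        table = _metrics({r: rng.normal(size=5) for r in range(1, 6)})
        results = pairwise_tests(table, "m")
        assert len(results) == 10
        assert {r.groups for r in results} == set(itertools.combinations(range(1, 6), 2))

    def test_single_comparison_bh_identity(self, rng):
        table = _metrics({1: rng.normal(size=6), 2: rng.normal(size=6)})
        (res,) = pairwise_tests(table, "m")
        assert res.adjusted_p == pytest.approx(res.p_value)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=25))
    def test_bh_matches_stepup_reference(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(adj, _bh_stepup(pvals), atol=1e-12)

    def test_adjusted_monotone_and_bounded(self, rng):
        table = _metrics({r: rng.normal(r * 0.3, 1, size=8) for r in range(1, 6)})
        results = pairwise_tests(table, "m")
        ordered = sorted(results, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(r.adjusted_p >= r.p_value - 1e-12 and r.adjusted_p <= 1 for r in results)

    def test_brown_mood_matches_hypergeometric_oracle(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        _, p = _brown_mood(x, y)
        grand = np.median(np.concatenate([x, y]))
        a, b = int((x > grand).sum()), int((y > grand).sum())
        n1, n2 = x.size, y.size
        K = a + b  # total above the grand median
        rv = sps.hypergeom(n1 + n2, n1, K)
        p_obs = rv.pmf(a)
        oracle = sum(rv.pmf(k) for k in range(K + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_empty_group_skipped_with_warning(self):
        table = _metrics({1: [1.0, 2.0], 2: []})
        table = pd.concat(
            [table, pd.DataFrame([["z", 2, "DNA", "other", 1.0]], columns=table.columns)]
        )  # run 2 exists but has no values for metric m
        with pytest.warns(UserWarning, match="skipped"):
            results = pairwise_tests(table, "m")
        assert results[0].degenerate


class TestWilcoxon:
    def test_no_change_is_degenerate_p_one(self):
        res = wilcoxon_signed_rank(np.arange(8.0), np.arange(8.0))
        assert res.degenerate and res.p_value == 1.0

    def test_constant_decrease_detected_with_direction(self):
        pre = np.linspace(10, 20, 12)
        res = wilcoxon_signed_rank(pre, pre - 3.0)
        assert res.direction == "decrease"
        assert res.p_value < 0.05

    def test_exact_p_matches_sign_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 13))
            before = rng.normal(size=n)
            after = before + rng.normal(size=n)
            d = after - before
            ranks = sps.rankdata(np.abs(d))
            if np.unique(ranks).size < n:
                continue  # oracle assumes tie-free ranks
            wobs = ranks[d > 0].sum()
            le = ge = 0
            for signs in itertools.product((0, 1), repeat=n):
                w = sum(r for s, r in zip(signs, ranks) if s)
                le += w <= wobs
                ge += w >= wobs
            oracle = min(1.0, 2 * min(le, ge) / 2 ** n)
            res = wilcoxon_signed_rank(before, after)
            assert res.p_value == pytest.approx(oracle, abs=1e-12)

    def test_zero_differences_dropped_before_ranking(self):
        before = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        after = np.array([1.0, 2.0, 4.0, 5.0, 6.0, 7.0])  # two zeros
        res = wilcoxon_signed_rank(before, after)
        assert res.n == 4


class TestPairedLibrary:
    def test_decrease_per_nucleic_type(self):
        table, _ = simulate_metrics(MetricsConfig(
            n_runs=2, samples_per_run=15, enriched_ratio=0.4, seed=8
        ))
        results = paired_library_test(table)
        assert results["DNA"].direction == "decrease"
        assert results["DNA"].p_value < 0.05

    def test_samples_missing_one_side_are_dropped(self):
        rows = [
            ("a", 1, "DNA", "pre_capture", 50.0),
            ("a", 1, "DNA", "enriched", 20.0),
            ("b", 1, "DNA", "pre_capture", 55.0),  # no enriched value
        ]
        table = pd.DataFrame(rows, columns=["sample", "run", "nucleic", "metric", "value"])
        res = paired_library_test(table)["DNA"]
        assert res.n == 1


def _tau_b_oracle(x, y):
    """All-pairs concordant/discordant counting with tie correction."""
    n = len(x)
    C = D = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            C += 1
        else:
            D += 1
    n0 = n * (n - 1) / 2
    return (C - D) / math.sqrt((n0 - tx) * (n0 - ty))


class TestKendall:
    def test_perfect_concordance(self):
        res = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.tau == pytest.approx(1.0)

    def test_perfect_reversal(self):
        res = kendall_tau([1, 2, 3, 4], [40, 30, 20, 10])
        assert res.tau == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 13))
            x = rng.integers(0, 6, size=n).astype(float)  # ties likely
            y = rng.integers(0, 6, size=n).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            res = kendall_tau(x, y)
            assert res.tau == pytest.approx(_tau_b_oracle(x, y), abs=1e-10)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert kendall_tau(x, -y).tau == pytest.approx(-kendall_tau(x, y).tau, abs=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        x, y = rng.uniform(1, 10, 20), rng.uniform(1, 10, 20)
        base = kendall_tau(x, y).tau
        assert kendall_tau(np.exp(x), y ** 3).tau == pytest.approx(base, abs=1e-12)

    def test_ci_brackets_tau_within_unit_interval(self, rng):
        res = kendall_tau(rng.normal(size=30), rng.normal(size=30))
        assert -1 <= res.ci_low <= res.tau <= res.ci_high <= 1


class TestTauCorrelation:
    def _coverage(self, samples, rng):
        rows = []
        for vt, depth in (("SNV", 100), ("SNV", 250)):
            for s in samples:
                rows.append((s, vt, depth, float(rng.uniform(50, 100))))
        return pd.DataFrame(rows, columns=["sample", "variant_type", "depth", "q2"])

    def test_strata_produced_per_metric_and_depth(self, rng):
        table = _metrics({1: rng.normal(10, 2, 8)})
        cov = self._coverage(table["sample"].unique(), rng)
        results = tau_correlation(table, cov)
        assert {r.coverage_var for r in results} == {"SNV_100X", "SNV_250X"}
        assert all(r.n == 8 for r in results)

    def test_small_stratum_skipped_with_warning(self, rng):
        table = _metrics({1: rng.normal(10, 2, 2)})
        cov = self._coverage(table["sample"].unique(), rng)
        with pytest.warns(UserWarning, match="pairs"):
            assert tau_correlation(table, cov) == []


class TestHeatmapExport:
    def test_single_cell_matrix(self, tmp_path):
        res = [TauResult(0.5, 0.01, 0.2, 0.8, "dv200", "SNV_100X", 10)]
        tsv, png = heatmap_export(res, tmp_path / "tau")
        df = pd.read_csv(tsv, sep="\t", index_col=0)
        assert df.shape == (1, 1)
        assert df.loc["dv200", "SNV_100X"] == pytest.approx(0.5)
        assert png.exists()

    def test_tsv_roundtrip_reproduces_matrix(self, tmp_path, rng):
        results = [
            TauResult(float(rng.uniform(-1, 1)), 0.5, -1, 1, m, cv, 10)
            for m in ("a", "b") for cv in ("SNV_100X", "RNA_5X")
        ]
        tsv, _ = heatmap_export(results, tmp_path / "tau")
        df = pd.read_csv(tsv, sep="\t", index_col=0)
        for r in results:
            assert df.loc[r.metric, r.coverage_var] == pytest.approx(r.tau)

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            heatmap_export([], tmp_path / "tau")


def test_load_metrics_rejects_duplicates(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text(
        "sample\trun\tnucleic\tmetric\tvalue\n"
        "a\t1\tDNA\tx\t1.0\na\t1\tDNA\tx\t2.0\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        load_metrics(p)
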