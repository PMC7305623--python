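"""Expression normalisation, per-CpG correlation/selection, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ncatspipe import assoc, simdata
from ncatspipe.assoc import (
    InsufficientSamplesError,
    UndefinedCorrelationError,
    aggregate_correlation,
    cluster,
    correlate_cpgs,
    load_expression_csv,
    relative_expression,
    window_columns,
)
from ncatspipe.methio import RegionWindow


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "target,ref,expected",
        [
            ([20, 20, 20], [20, 20, 20], 1.0),  # dCt = 0
            ([21, 21, 21], [20, 20, 20], 0.5),  # dCt = +1
            ([18, 18, 18], [20, 20, 20], 4.0),  # dCt = -2
        ],
    )
    def test_two_to_minus_delta_ct(self, target, ref, expected):
        assert relative_expression(target, ref).value == pytest.approx(expected)

    def test_triplicate_averaging(self):
        res = relative_expression([19, 20, 21], [20, 20, 20])
        assert res.delta_ct == pytest.approx(0.0)
        assert not res.incomplete

    def test_missing_replicate_flagged(self):
        res = relative_expression([20, np.nan, 20], [20, 20, 20])
        assert res.incomplete and res.n_target == 2
        assert res.value == pytest.approx(1.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            relative_expression([np.nan] * 3, [20, 20, 20])

    def test_csv_loader(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text(
            "sample_id,ct_target_1,ct_target_2,ct_target_3,"
            "ct_ref_1,ct_ref_2,ct_ref_3\nS1,21,21,21,20,20,20\n"
        )
        df = load_expression_csv(path)
        assert df.loc["S1", "relative_expression"] == pytest.approx(0.5)


class TestCorrelateCpgs:
    def _cohort(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        meth = pd.DataFrame(
            {"cpg001": x, "cpg002": rng.uniform(0, 1, n), "cpg003": 1 - x},
            index=[f"S{i}" for i in range(n)],
        )
        expr = pd.Series(2.0 ** (-2 * x), index=meth.index)
        return meth, expr

    def test_exact_linear_selected(self):
        meth, expr = self._cohort()
        out = correlate_cpgs(meth, expr).set_index("cpg")
        assert out.loc["cpg001", "r"] == pytest.approx(-1.0)
        assert out.loc["cpg003", "r"] == pytest.approx(1.0)
        assert bool(out.loc["cpg001", "selected"]) and bool(out.loc["cpg003", "selected"])

    def test_selection_is_strict(self):
        """No row with |r| <= threshold is ever selected (any threshold)."""
        meth, expr = self._cohort(n=20, seed=3)
        for thr in (0.0, 0.3, 0.7, 1.0):
            out = correlate_cpgs(meth, expr, threshold=thr)
            ok = out[out["usable"]]
            assert (ok["selected"] == (ok["r"].abs() > thr)).all()
        # |r| can never exceed 1, so threshold 1.0 selects nothing
        assert not correlate_cpgs(meth, expr, threshold=1.0)["selected"].any()

    def test_zero_variance_flagged_never_selected(self):
        meth, expr = self._cohort()
        meth["flat"] = 0.5
        out = correlate_cpgs(meth, expr).set_index("cpg")
        assert not out.loc["flat", "usable"]
        assert out.loc["flat", "reason"] == "zero_variance"
        assert not out.loc["flat", "selected"]

    def test_pairwise_complete_with_min_n(self):
        meth, expr = self._cohort(n=6)
        meth.loc[meth.index[:3], "cpg002"] = np.nan
        out = correlate_cpgs(meth, expr).set_index("cpg")
        assert not out.loc["cpg002", "usable"]
        assert out.loc["cpg002", "reason"] == "insufficient_samples"
        assert out.loc["cpg001", "n"] == 6

    def test_oracle_equivalence_covariance_formula(self, rng):
        """Pearson r matches the direct covariance-formula computation."""
        meth = pd.DataFrame(
            rng.uniform(0, 1, (12, 5)),
            columns=[f"c{i}" for i in range(5)],
            index=[f"S{i}" for i in range(12)],
        )
        expr = pd.Series(2.0 ** rng.normal(0, 1, 12), index=meth.index)
        out = correlate_cpgs(meth, expr).set_index("cpg")
        y = np.log2(expr.to_numpy())
        for col in meth.columns:
            x = meth[col].to_numpy()
            r_manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert out.loc[col, "r"] == pytest.approx(r_manual, rel=1e-12)


class TestAggregateCorrelation:
    def test_noiseless_planted_exon_coupling(self):
        c = simdata.generate_cohort(
            simdata.CohortSpec(n_samples=30, noise_sd=0.0, cpg_sd=0.0, seed=1)
        )
        exon_cols = window_columns(c.cpg_info, RegionWindow("DMR2", 70, 81))
        r, p, n = aggregate_correlation(c.meth, c.expression, exon_cols)
        assert r == pytest.approx(-1.0, abs=1e-9)
        assert n == 30

    def test_sign_recovery_under_noise(self):
        """Planted signs recovered in nearly all moderate-noise cohorts."""
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            c = simdata.generate_cohort(
                simdata.CohortSpec(n_samples=50, noise_sd=0.3, seed=seed)
            )
            exon_cols = window_columns(c.cpg_info, RegionWindow("exon", 70, 81))
            intron_cols = window_columns(c.cpg_info, RegionWindow("intron", 99, 132))
            r_e, _, _ = aggregate_correlation(c.meth, c.expression, exon_cols)
            r_i, _, _ = aggregate_correlation(c.meth, c.expression, intron_cols)
            hits += (r_e < 0) and (r_i > 0)
        assert hits / n_runs >= 0.95

    def test_recovered_r_strengthens_as_noise_drops(self):
        strengths = []
        for noise in (1.5, 0.5, 0.05):
            rs = []
            for seed in range(10):
                c = simdata.generate_cohort(
                    simdata.CohortSpec(n_samples=50, noise_sd=noise, seed=seed)
                )
                cols = window_columns(c.cpg_info, RegionWindow("exon", 70, 81))
                r, _, _ = aggregate_correlation(c.meth, c.expression, cols)
                rs.append(abs(r))
            strengths.append(np.mean(rs))
        assert strengths[0] < strengths[1] < strengths[2]

    def test_constant_methylation_undefined(self):
        meth = pd.DataFrame({"c1": [0.5] * 6}, index=[f"S{i}" for i in range(6)])
        expr = pd.Series(np.linspace(1, 2, 6), index=meth.index)
        with pytest.raises(UndefinedCorrelationError):
            aggregate_correlation(meth, expr, ["c1"])

    def test_too_few_samples(self):
        meth = pd.DataFrame({"c1": [0.1, 0.9, 0.5]}, index=["a", "b", "c"])
        expr = pd.Series([1.0, 2.0, 3.0], index=meth.index)
        with pytest.raises(InsufficientSamplesError):
            aggregate_correlation(meth, expr, ["c1"])

    def test_null_effects_false_positive_rate(self):
        """With no planted coupling, |r| > 0.7 selections are rare (n=50)."""
        n_sel = n_tot = 0
        for seed in range(20):
            c = simdata.generate_cohort(
                simdata.CohortSpec(
                    n_samples=50, exon_effect=0.0, intron_effect=0.0,
                    noise_sd=0.3, seed=seed,
                )
            )
            out = correlate_cpgs(c.meth, c.expression)
            n_sel += int(out["selected"].sum())
            n_tot += len(out)
        # under the null at n=50, P(|r| > 0.7) is ~1e-7; a few hundred CpGs
        # should essentially never clear the threshold
        assert n_sel == 0


class TestCluster:
    def _planted_blocks(self, n_samples=8, seed=0, jitter=0.0):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0.1, 0.9, n_samples)
        exon = np.tile(s[:, None], (1, 4))
        intron = np.tile(1 - s[:, None], (1, 5))
        if jitter:
            exon = exon + rng.normal(0, jitter, exon.shape)
            intron = intron + rng.normal(0, jitter, intron.shape)
        meth = pd.DataFrame(
            np.hstack([exon, intron]),
            index=[f"S{i}" for i in range(n_samples)],
            columns=[f"e{i}" for i in range(4)] + [f"i{i}" for i in range(5)],
        )
        truth = [0] * 4 + [1] * 5
        return meth, truth

    def test_planted_partition_recovered(self):
        meth, truth = self._planted_blocks()
        res = cluster(meth)
        assert adjusted_rand_score(truth, res.cpg_clusters.to_numpy()) == 1.0

    def test_single_and_average_linkage_agree_on_blocks(self):
        meth, truth = self._planted_blocks(seed=2)
        res_avg = cluster(meth, method="average")
        res_single = cluster(meth, method="single")
        assert adjusted_rand_score(
            res_avg.cpg_clusters.to_numpy(), res_single.cpg_clusters.to_numpy()
        ) == 1.0

    def test_duplicate_columns_merge_first(self):
        meth, _ = self._planted_blocks(seed=3, jitter=0.01)
        meth["e_dup"] = meth["e0"]
        res = cluster(meth)
        # the first merge in the CpG linkage is the zero-distance pair
        assert res.cpg_linkage[0, 2] == 0.0
        merged = {int(res.cpg_linkage[0, 0]), int(res.cpg_linkage[0, 1])}
        names = {list(meth.columns)[i] for i in merged}
        assert names == {"e0", "e_dup"}

    def test_leaf_orders_are_permutations(self):
        meth, _ = self._planted_blocks(seed=4)
        res = cluster(meth)
        assert sorted(res.cpg_order) == sorted(meth.columns)
        assert sorted(res.sample_order) == sorted(meth.index)

    def test_missing_values_pairwise_complete(self):
        meth, truth = self._planted_blocks(n_samples=10, seed=5)
        meth.iloc[0, 0] = np.nan
        res = cluster(meth)
        assert adjusted_rand_score(truth, res.cpg_clusters.to_numpy()) == 1.0

    def test_all_missing_pair_rejected(self):
        meth, _ = self._planted_blocks(n_samples=4, seed=6)
        meth.iloc[:, 0] = np.nan
        with pytest.raises(ValueError):
            cluster(meth)

    def test_too_small_rejected(self):
        meth = pd.DataFrame({"a": [0.1, 0.2]}, index=["x", "y"])
        with pytest.raises(ValueError):
            cluster(meth)
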