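"""Paired t, repeated-measures ANOVA, clustering, recovery harness.

Each statistic is checked against an independent route: the paired t
against scipy's implementation and a direct hand formula, the ANOVA
against explicit textbook sums of squares (and pingouin where available),
the clustering against a brute-force O(n^3) average-linkage oracle that
recomputes all inter-cluster means at every step.
"""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster

from ergdecomp import (
    CohortDesign,
    ComponentParams,
    InputError,
    corr_average_linkage,
    paired_t,
    paired_table,
    recovery_harness,
    rm_anova2,
)

# ---------------------------------------------------------------- oracles


def brute_force_average_linkage(X):
    """O(n^3) agglomerative average linkage on correlation distance.

    Recomputes the mean of all pairwise member distances for every
    cluster pair at every step; ties broken by the lowest involved row
    index.  Returns a list of (leaves_a, leaves_b, height) frozensets in
    merge order.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 1.0 - np.corrcoef(X[i], X[j])[0, 1]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                key = (dist, min(clusters[a] | clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, _), a, b = best
        merges.append((clusters[a], clusters[b], dist))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return merges


def _merges_from_linkage(Z, n):
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, h, _size) in enumerate(Z):
        ca, cb = members[int(a)], members[int(b)]
        out.append((ca, cb, float(h)))
        members[n + step] = ca | cb
    return out


def direct_anova_ss(df):
    """Textbook split-plot sums of squares by explicit summation."""
    y = df.pivot_table(index="subject", columns="time", values="value")
    groups = df.groupby("subject")["group"].first().loc[y.index]
    gm = y.to_numpy().mean()
    t = y.shape[1]
    ss = {}
    ss["group"] = sum(
        (groups == g).sum() * t * (y[groups == g].to_numpy().mean() - gm) ** 2
        for g in groups.unique()
    )
    ss["subj_within"] = (
        t * ((y.mean(axis=1) - gm) ** 2).sum() - ss["group"]
    )
    n = y.shape[0]
    ss["time"] = n * ((y.mean(axis=0) - gm) ** 2).sum()
    cells = 0.0
    for g in groups.unique():
        block = y[groups == g]
        cells += len(block) * ((block.mean(axis=0) - gm) ** 2).sum()
    ss["interaction"] = cells - ss["group"] - ss["time"]
    ss["total"] = ((y.to_numpy() - gm) ** 2).sum()
    ss["error"] = (ss["total"] - ss["group"] - ss["subj_within"]
                   - ss["time"] - ss["interaction"])
    return ss


def _long(values, groups, times):
    rows = []
    for s, (g, per_time) in enumerate(zip(groups, values)):
        for t, v in zip(times, per_time):
            rows.append({"subject": f"s{s}", "group": g, "time": t, "value": v})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- tests


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_hand_computed_example(self):
        # pairs (1,2), (2,3), (3,5): d = (1,1,2), mean 4/3, sd 1/sqrt(3)
        t, df, _p = paired_t([2.0, 3.0, 5.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(4.0, abs=1e-12)
        assert df == 2

    def test_sign_antisymmetry(self):
        x = np.array([3.1, 4.0, 2.2, 5.5])
        y = np.array([2.0, 4.4, 1.0, 4.0])
        t1, _, p1 = paired_t(x, y)
        t2, _, p2 = paired_t(y, x)
        assert t2 == pytest.approx(-t1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-15)

    def test_matches_direct_formula_and_scipy(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.normal(0, 3, n)
            y = x + rng.normal(0.5, 1, n)
            t, df, p = paired_t(x, y)
            d = x - y
            t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            assert t == pytest.approx(t_direct, abs=1e-12)
            ref = sps.ttest_rel(x, y)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_errors(self):
        with pytest.raises(InputError):
            paired_t([1.0], [2.0])
        with pytest.raises(InputError, match="zero variance"):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestRmAnova2:
    def test_all_equal_values(self):
        df = _long([[5.0, 5.0]] * 6, ["a"] * 3 + ["b"] * 3, [1, 2])
        out = rm_anova2(df)
        assert (out["F"] == 0.0).all()
        assert (out["p"] == 1.0).all()

    def test_additive_group_effect_matches_textbook_ss(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (8, 2))
        vals = base.copy()
        vals[4:] += 10.0  # additive group effect, no interaction noise
        df = _long(vals.tolist(), ["a"] * 4 + ["b"] * 4, ["w1", "w2"])
        out = rm_anova2(df)
        ss = direct_anova_ss(df)
        assert out.loc["group", "ss"] == pytest.approx(ss["group"], rel=1e-9)
        assert out.loc["time", "ss"] == pytest.approx(ss["time"], rel=1e-9)
        assert out.loc["interaction", "ss"] == pytest.approx(
            ss["interaction"], abs=1e-9
        )

    def test_subject_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (6, 3)).tolist()
        df = _long(vals, ["a"] * 3 + ["b"] * 3, [1, 2, 3])
        shuffled = df.copy()
        shuffled["subject"] = shuffled["subject"].map(
            {"s0": "s2", "s1": "s0", "s2": "s1", "s3": "s3", "s4": "s5", "s5": "s4"}
        )
        pd.testing.assert_frame_equal(rm_anova2(df), rm_anova2(shuffled))

    def test_ss_conservation(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            vals = rng.normal(0, 2, (8, 4)).tolist()
            df = _long(vals, ["a"] * 4 + ["b"] * 4, list(range(4)))
            out = rm_anova2(df)
            # effect SS plus both error strata must recompose the total
            explicit = (out.loc["group", "ss"] + out.loc["time", "ss"]
                        + out.loc["interaction", "ss"]
                        + out.attrs["ss_subjects_within_groups"]
                        + out.attrs["ss_error_within"])
            assert explicit == pytest.approx(out.attrs["ss_total"], rel=1e-9)

    def test_matches_pingouin_mixed_anova(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        vals = (rng.normal(0, 1, (10, 3))
                + np.array([0, 0.5, 1.0])).tolist()
        df = _long(vals, ["a"] * 5 + ["b"] * 5, [1, 2, 3])
        ours = rm_anova2(df)
        ref = pingouin.mixed_anova(
            data=df, dv="value", within="time", subject="subject", between="group"
        ).set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert ours.loc["time", "F"] == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert ours.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )
        p_col = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert ours.loc["group", "p"] == pytest.approx(
            ref.loc["group", p_col], rel=1e-6
        )

    def test_unbalanced_rejected(self):
        df = _long([[1.0, 2.0]] * 4, ["a", "a", "b", "b"], [1, 2])
        df = df.drop(index=0)
        with pytest.raises(InputError, match="nbalanced"):
            rm_anova2(df)


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (5, 6))
        X[3] = X[1]
        Z, _ = corr_average_linkage(X)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {1, 3}

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (4, 8))
        X2 = X.copy()
        X2[2] = 2.0 * X[2] + 7.0
        Z1, c1 = corr_average_linkage(X, k=2)
        Z2, c2 = corr_average_linkage(X2, k=2)
        np.testing.assert_allclose(Z1[:, 2], Z2[:, 2], atol=1e-12)
        np.testing.assert_array_equal(c1, c2)

    def test_constant_row_error_names_row(self):
        X = np.random.default_rng(0).normal(0, 1, (4, 5))
        X[2] = 3.14
        with pytest.raises(InputError, match="row 2"):
            corr_average_linkage(X)

    @pytest.mark.parametrize("trial", range(10))
    def test_merge_sequence_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 11))
        X = rng.normal(0, 1, (n, 4))
        Z, _ = corr_average_linkage(X)
        ours = _merges_from_linkage(Z, n)
        oracle = brute_force_average_linkage(X)
        for (a1, b1, h1), (a2, b2, h2) in zip(ours, oracle):
            assert {a1, b1} == {a2, b2}
            assert h1 == pytest.approx(h2, rel=1e-9, abs=1e-12)

    def test_flat_clusters_at_k(self):
        rng = np.random.default_rng(11)
        tight_a = rng.normal(0, 0.01, (3, 5)) + np.linspace(0, 1, 5)
        tight_b = rng.normal(0, 0.01, (3, 5)) + np.linspace(1, 0, 5)
        X = np.vstack([tight_a, tight_b])
        _, labels = corr_average_linkage(X, k=2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]


class TestRecoveryHarness:
    DESIGN = CohortDesign(
        n_pairs=1, base=ComponentParams(noise_sd_uv=0.0),
        inter_animal_cv=0.0, seed=0,
    )

    def test_noiseless_single_replicate_closes(self):
        report = recovery_harness(self.DESIGN, n_replicates=1, seed=1)
        assert (report["rel_rmse"] <= 0.005).all()
        assert (report["n_failures"] == 0).all()

    def test_same_seed_identical_report(self):
        a = recovery_harness(self.DESIGN, n_replicates=2, seed=3)
        b = recovery_harness(self.DESIGN, n_replicates=2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_rmse_dominates_bias(self):
        noisy = replace(self.DESIGN, base=ComponentParams(noise_sd_uv=20.0),
                        inter_animal_cv=0.2)
        report = recovery_harness(noisy, n_replicates=5, seed=4)
        assert (report["rel_rmse"] >= report["rel_bias"].abs() - 1e-12).all()

    def test_more_noise_does_not_reduce_error(self):
        quiet = replace(self.DESIGN, base=ComponentParams(noise_sd_uv=5.0))
        loud = replace(self.DESIGN, base=ComponentParams(noise_sd_uv=40.0))
        r_quiet = recovery_harness(quiet, n_replicates=15, seed=5)
        r_loud = recovery_harness(loud, n_replicates=15, seed=5)
        for param in ("rmp3_uv", "s_sens", "p2max_uv"):
            assert (r_loud.loc[param, "rel_rmse"]
                    >= r_quiet.loc[param, "rel_rmse"])


class TestPairedTable:
    def test_pivots_metrics_to_pairs(self):
        metrics = pd.DataFrame([
            {"subject_id": "s1", "treatment_group": "vehicle",
             "pressure_group": "NT", "pstr_m530_uv": 15.0},
            {"subject_id": "s1", "treatment_group": "vehicle",
             "pressure_group": "OHT", "pstr_m530_uv": 10.0},
            {"subject_id": "s2", "treatment_group": "vehicle",
             "pressure_group": "NT", "pstr_m530_uv": 14.0},
        ])
        table = paired_table(metrics, "pstr_m530_uv")
        assert len(table) == 1  # s2 lacks the OHT eye
        assert table.iloc[0]["NT"] == 15.0 and table.iloc[0]["OHT"] == 10.0
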