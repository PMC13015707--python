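"""Rank tests, effect sizes, permutation machinery, PERMANOVA, beta rescaling."""

import itertools
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from phagecodon.stats import (
    adjust_pvalues,
    backtransform_beta,
    build_beta_model_spec,
    build_lmm_spec,
    cliffs_delta,
    dispersion_test,
    dunn_posthoc,
    kruskal_wallis,
    pca_scores,
    permanova,
    permutation_wilcoxon,
    rescale_for_beta,
    spearman_with_label,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank_one_sample,
)


class TestRankSum:
    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum(x, x).p_value == pytest.approx(1.0, abs=0.05)

    def test_exact_enumeration(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.method

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(0)
        res = wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
        assert "normal-approx" in res.method

    def test_empty_arm_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [])


class TestSignedRank:
    def test_all_positive_exact(self):
        res = wilcoxon_signed_rank_one_sample([1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 64)

    def test_symmetric_sample(self):
        assert wilcoxon_signed_rank_one_sample([-3, -2, -1, 1, 2, 3]).p_value == 1.0

    def test_all_zeros_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_one_sample([0.0, 0.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.H == pytest.approx(0.0)
        assert res.eta2_H == pytest.approx(0.0)

    def test_eta_squared_formula(self):
        from phagecodon.stats import KWResult

        assert KWResult(H=10.0, p_value=0.01, N=21).eta2_H == pytest.approx(0.5)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_identical_groups_p_one(self):
        res = dunn_posthoc({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res[0].p_value == pytest.approx(1.0)

    def test_three_groups_three_rows(self):
        groups = {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
        res = dunn_posthoc(groups, adjust="bonferroni")
        assert len(res) == 3
        for r in res:
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value))

    def test_bh_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(loc=i, size=8) for i, k in enumerate("abcd")}
        bh = dunn_posthoc(groups, adjust="BH")
        bonf = dunn_posthoc(groups, adjust="bonferroni")
        for r_bh, r_bonf in zip(bh, bonf):
            assert r_bh.adjusted_p <= r_bonf.adjusted_p + 1e-12


class TestCliffsDelta:
    def test_extremes(self):
        assert cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0
        assert cliffs_delta([3, 4, 5], [1, 2, 3]) == pytest.approx(8 / 9)

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n, m = int(rng.integers(1, 11)), int(rng.integers(1, 11))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=m).astype(float)
            brute = sum(
                int(xi > yj) - int(xi < yj) for xi in x for yj in y
            ) / (n * m)
            assert cliffs_delta(x, y) == pytest.approx(brute)

    @settings(derandomize=True, max_examples=30)
    @given(
        x=st.lists(st.integers(-5, 5), min_size=1, max_size=10),
        y=st.lists(st.integers(-5, 5), min_size=1, max_size=10),
    )
    def test_antisymmetry_and_bounds(self, x, y):
        d = cliffs_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-cliffs_delta(y, x))


class TestPermutationWilcoxon:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        p1 = permutation_wilcoxon(x, y, n_perm=500, seed=42).p_value
        p2 = permutation_wilcoxon(x, y, n_perm=500, seed=42).p_value
        assert p1 == p2

    def test_identical_arms_large_p(self):
        x = list(range(10))
        assert permutation_wilcoxon(x, x, n_perm=500, seed=1).p_value > 0.5

    def test_separated_arms_small_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 20)
        y = rng.normal(8, 1, 20)  # separation of ~8 SDs
        assert permutation_wilcoxon(x, y, n_perm=10_000, seed=2).p_value <= 0.001

    def test_seed_required(self):
        with pytest.raises(ValueError):
            permutation_wilcoxon([1, 2], [3, 4], n_perm=10)

    def test_converges_to_exact(self):
        x, y = [1.0, 4.0, 6.0, 9.0, 12.0], [2.0, 3.0, 5.0, 7.0, 8.0]
        exact = wilcoxon_rank_sum(x, y).p_value  # exact path: n=m=5, no ties
        perm = permutation_wilcoxon(x, y, n_perm=20_000, seed=7).p_value
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(perm - exact) < 4 * se + 1e-4


class TestSpearman:
    def test_monotone_strong(self):
        rho, p, label = spearman_with_label([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0 and label == "strong"

    def test_labels_follow_published_bins(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 40
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            rho, _, label = spearman_with_label(x, y)
            a = abs(rho)
            expected = (
                "very weak" if a <= 0.10 else
                "weak" if a <= 0.30 else
                "moderate" if a <= 0.50 else "strong"
            )
            assert label == expected

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman_with_label([1, 1, 1], [1, 2, 3])


def oracle_single_factor_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's PERMANOVA pseudo-F from pairwise distances, computed from
    group sums of squared distances (independent of the hat-matrix route)."""
    n = len(labels)
    levels = np.unique(labels)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for lev in levels:
        idx = np.where(labels == lev)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = len(levels) - 1, n - len(levels)
    return (ss_between / df_b) / (ss_within / df_w)


class TestPermanova:
    def test_matches_enumeration_oracle_n6(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 4))
        x[:3] += 1.5
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d = squareform(pdist(x))
        f_oracle = oracle_single_factor_f(d, labels)
        # exact p by full enumeration of all 720 relabelings
        f_null = [
            oracle_single_factor_f(d, labels[list(perm)])
            for perm in itertools.permutations(range(6))
        ]
        p_exact = np.mean([f >= f_oracle - 1e-12 for f in f_null])
        res = permanova(
            pd.DataFrame(x), pd.DataFrame({"g": labels}), n_perm=9_999, seed=3,
            check_dispersion=False,
        )
        assert res.pseudo_f["g"] == pytest.approx(f_oracle)
        assert res.p_values["g"] == pytest.approx(p_exact, abs=0.02)

    def test_perfect_separation(self):
        x = np.vstack([np.tile([0.0, 0.0], (4, 1)), np.tile([5.0, 5.0], (4, 1))])
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(
            pd.DataFrame(x), pd.DataFrame({"g": labels}), n_perm=999, seed=1,
            check_dispersion=False,
        )
        assert res.r2["g"] == pytest.approx(1.0)
        # minimum attainable p given the permutation count and group sizes
        assert res.p_values["g"] <= 70 / 1000 + 0.03

    def test_null_labels_nonsignificant(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(20, 5))
        labels = rng.permutation(["a"] * 10 + ["b"] * 10)
        res = permanova(
            pd.DataFrame(x), pd.DataFrame({"g": labels}), n_perm=999, seed=4,
            check_dispersion=False,
        )
        assert res.p_values["g"] > 0.05

    def test_r2_partition(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(15, 4))
        fac = pd.DataFrame(
            {"g": rng.choice(["a", "b", "c"], 15), "l": rng.choice(["u", "v"], 15)}
        )
        res = permanova(pd.DataFrame(x), fac, n_perm=99, seed=5, check_dispersion=False)
        assert sum(res.r2.values()) + res.residual_r2 == pytest.approx(1.0)

    def test_confounded_joint_model_raises(self):
        x = np.random.default_rng(1).normal(size=(8, 3))
        fac = pd.DataFrame(
            {"lifestyle": ["T"] * 4 + ["V"] * 4, "trna": ["None"] * 4 + ["Low"] * 4}
        )
        with pytest.raises(ValueError, match="confounded"):
            permanova(pd.DataFrame(x), fac, n_perm=99, seed=1, check_dispersion=False)

    def test_sequential_ss_matches_vegan(self):
        """Multi-factor F and R2 agree with vegan::adonis2 (by='terms')."""
        rng = np.random.default_rng(42)
        n = 18
        x = rng.normal(size=(n, 6))
        f1 = rng.choice(["a", "b", "c"], n)
        f2 = rng.choice(["u", "v"], n)
        x[f1 == "a"] += 1.0
        res = permanova(
            pd.DataFrame(x), pd.DataFrame({"g": f1, "l": f2}), n_perm=99, seed=1,
            check_dispersion=False,
        )
        with tempfile.TemporaryDirectory() as d:
            pd.DataFrame(x).to_csv(f"{d}/x.csv", index=False)
            pd.DataFrame({"g": f1, "l": f2}).to_csv(f"{d}/f.csv", index=False)
            script = (
                'suppressMessages(library(vegan));'
                f'x <- read.csv("{d}/x.csv"); f <- read.csv("{d}/f.csv");'
                'a <- adonis2(dist(x) ~ g + l, data=f, permutations=49, by="terms");'
                'cat(a$F[1], a$F[2], a$R2[1], a$R2[2], "\\n")'
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
        assert out.returncode == 0, out.stderr
        f_g, f_l, r2_g, r2_l = map(float, out.stdout.split())
        assert res.pseudo_f["g"] == pytest.approx(f_g, rel=1e-4)
        assert res.pseudo_f["l"] == pytest.approx(f_l, rel=1e-4)
        assert res.r2["g"] == pytest.approx(r2_g, rel=1e-4)
        assert res.r2["l"] == pytest.approx(r2_l, rel=1e-4)

    def test_dispersion_matches_vegan_betadisper(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(16, 5))
        g = np.array(["a"] * 8 + ["b"] * 8)
        x[g == "b"] *= 2.2
        d = squareform(pdist(x))
        f_stat, p = dispersion_test(d, g, n_perm=999, seed=3)
        with tempfile.TemporaryDirectory() as td:
            pd.DataFrame(x).to_csv(f"{td}/x.csv", index=False)
            script = (
                'suppressMessages(library(vegan));'
                f'x <- read.csv("{td}/x.csv");'
                'g <- factor(c(rep("a",8), rep("b",8)));'
                'b <- betadisper(dist(x), g, type="centroid");'
                'cat(anova(b)$F[1], "\\n")'
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
        assert out.returncode == 0, out.stderr
        assert f_stat == pytest.approx(float(out.stdout), rel=1e-4)
        assert p < 0.05  # unequal spread is detected


class TestPCA:
    def test_identical_rows_zero_scores(self):
        mat = pd.DataFrame(np.ones((4, 5)))
        scores = pca_scores(mat)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_two_distinct_rows_separated_on_pc1(self):
        mat = pd.DataFrame([[0.0, 0.0, 0.0], [3.0, 3.0, 3.0]])
        scores = pca_scores(mat)
        assert scores["PC1"].iloc[0] != pytest.approx(scores["PC1"].iloc[1])

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(6, 4)))
        from sklearn.decomposition import PCA

        model = PCA(svd_solver="full")
        scores = model.fit_transform(mat.to_numpy())
        recon = model.inverse_transform(scores)
        assert np.allclose(recon, mat.to_numpy(), atol=1e-10)


class TestBetaRescale:
    def test_round_trip(self):
        rng = np.random.default_rng(10)
        x = rng.normal(scale=0.2, size=50)
        r = rescale_for_beta(x)
        back = backtransform_beta(r.rescaled, r.d_min, r.d_max, r.epsilon)
        assert np.max(np.abs(back - x)) < 1e-9

    def test_strictly_inside_unit_interval(self):
        r = rescale_for_beta([-0.3, 0.0, 0.2])
        assert np.all(r.rescaled > 0) and np.all(r.rescaled < 1)
        assert r.rescaled.min() < 1e-5  # minimum maps near 0
        assert r.rescaled.max() > 1 - 1e-5

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            rescale_for_beta([0.1, 0.1, 0.1])

    def test_backtransform_example(self):
        assert backtransform_beta(0.5, -0.3, 0.2) == pytest.approx(-0.05, abs=1e-5)

    @pytest.mark.parametrize("mu", [0.0, 1.0, -0.2, 1.4])
    def test_backtransform_domain(self, mu):
        with pytest.raises(ValueError):
            backtransform_beta(mu, -0.3, 0.2)


class TestAdjustments:
    def test_bonferroni_formula(self):
        p = np.array([0.01, 0.02, 0.5])
        adj = adjust_pvalues(p, "bonferroni")
        assert adj == pytest.approx(np.minimum(1.0, 3 * p))

    def test_bh_monotone_in_raw_order(self):
        rng = np.random.default_rng(14)
        p = np.sort(rng.uniform(size=25))
        adj = adjust_pvalues(p, "BH")
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all(adj >= p - 1e-12)


def _tai_frame(n_phages=4, genes_per=5, hosts=("h1", "h2")):
    rng = np.random.default_rng(15)
    rows = []
    for i in range(n_phages):
        for j in range(genes_per):
            rows.append(
                {
                    "phage_id": f"p{i}",
                    "delta_tai": float(rng.normal(-0.1, 0.05)),
                    "lifestyle": "Virulent" if i % 2 else "Temperate",
                    "trna_group": ["None", "Low", "High"][i % 3],
                    "host": hosts[i % len(hosts)],
                }
            )
    return pd.DataFrame(rows)


class TestModelSpecs:
    def test_beta_global_includes_host(self):
        spec = build_beta_model_spec(_tai_frame(), scope="global")
        assert any(c.startswith("host[") for c in spec.fixed.columns)
        assert len(spec.response) == len(spec.fixed) == 20
        assert np.all((spec.response > 0) & (spec.response < 1))

    def test_beta_per_genus_omits_host(self):
        spec = build_beta_model_spec(_tai_frame(), scope="per_genus")
        assert not any(c.startswith("host[") for c in spec.fixed.columns)

    def test_baselines_coded_zero(self):
        df = _tai_frame()
        spec = build_beta_model_spec(df, scope="per_genus")
        base = (df["lifestyle"] == "Temperate") & (df["trna_group"] == "None")
        cols = ["lifestyle[Virulent]", "trna_group[Low]", "trna_group[High]"]
        assert (spec.fixed.loc[base.to_numpy(), cols].to_numpy() == 0).all()

    def test_unknown_lifestyle_raises(self):
        df = _tai_frame()
        df.loc[0, "lifestyle"] = "Lytic"
        with pytest.raises(ValueError, match="lifestyle"):
            build_beta_model_spec(df, scope="per_genus")

    def test_one_random_level_per_phage(self):
        spec = build_beta_model_spec(_tai_frame(), scope="global")
        assert set(spec.groups) == {"p0", "p1", "p2", "p3"}

    def test_lmm_spec_and_fit(self):
        rng = np.random.default_rng(16)
        hosts = [f"H{i}" for i in range(7)]
        host_effect = dict(zip(hosts, rng.normal(scale=2.0, size=7)))
        lifestyle = rng.choice(["Virulent", "Temperate"], 70)
        host = np.repeat(hosts, 10)
        df = pd.DataFrame(
            {
                "delta_gc": (
                    [host_effect[h] for h in host]
                    + 1.5 * (lifestyle == "Virulent")
                    + rng.normal(size=70)
                ),
                "lifestyle": lifestyle,
                "host": host,
            }
        )
        spec = build_lmm_spec(df)
        assert len(set(spec.groups)) == 7
        fit = spec.fit()
        assert np.isfinite(fit.params).all()

    def test_lmm_single_host_warns(self):
        df = pd.DataFrame(
            {"delta_gc": [0.1, 0.2], "lifestyle": ["Virulent", "Temperate"],
             "host": ["H", "H"]}
        )
        with pytest.warns(UserWarning):
            build_lmm_spec(df)

    def test_lmm_missing_column_raises(self):
        with pytest.raises(ValueError):
            build_lmm_spec(pd.DataFrame({"delta_gc": [0.1], "host": ["H"]}))
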