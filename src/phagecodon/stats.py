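"""Rank-based tests, effect sizes, permutation tests, PERMANOVA, PCA and the
beta-model preprocessing used in the phage-host comparisons.

Scalar tests wrap SciPy (exact enumeration on small tie-free samples, midrank
normal approximation otherwise); multiple-testing adjustment wraps
statsmodels. The multi-factor PERMANOVA with sequential (Type-I) sums of
squares on a distance matrix, its companion homogeneity-of-dispersion check,
Dunn's post-hoc z-tests, Cliff's delta and the beta-regression rescaling are
implemented here. All permutation procedures take a mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .indices import EPSILON

__all__ = [
    "TestResult",
    "KWResult",
    "PermanovaResult",
    "BetaRescale",
    "BetaModelSpec",
    "LMMSpec",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank_one_sample",
    "kruskal_wallis",
    "dunn_posthoc",
    "cliffs_delta",
    "permutation_wilcoxon",
    "spearman_with_label",
    "permanova",
    "dispersion_test",
    "pca_scores",
    "rescale_for_beta",
    "backtransform_beta",
    "build_beta_model_spec",
    "build_lmm_spec",
    "adjust_pvalues",
]

AdjustMethod = Literal["bonferroni", "BH", "none"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    effect_size: float | None = None
    adjusted_p: float | None = None
    adjust_method: AdjustMethod = "none"
    label: str = ""


@dataclass(frozen=True)
class KWResult:
    H: float
    p_value: float
    N: int

    @property
    def eta2_H(self) -> float:
        """Kruskal-Wallis effect size H / (N - 1)."""
        return self.H / (self.N - 1)


@dataclass(frozen=True)
class PermanovaResult:
    factors: list[str]
    r2: dict[str, float]
    pseudo_f: dict[str, float]
    p_values: dict[str, float]
    residual_r2: float
    n_permutations: int
    dispersion_p: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class BetaRescale:
    d_min: float
    d_max: float
    epsilon: float
    rescaled: np.ndarray


def adjust_pvalues(pvalues: Sequence[float], method: AdjustMethod) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment over one test family."""
    p = np.asarray(pvalues, dtype=float)
    if method == "none":
        return p
    sm_method = {"bonferroni": "bonferroni", "BH": "fdr_bh"}[method]
    return multipletests(p, method=sm_method)[1]


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when min(n, m) <= 8 and there are no ties; otherwise
    the midrank normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = min(x.size, y.size) <= 8 and not _has_ties(np.concatenate([x, y]))
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(x.size, y.size),
        method="rank-sum/" + ("exact" if exact else "normal-approx"),
        effect_size=cliffs_delta(x, y),
    )


def wilcoxon_signed_rank_one_sample(
    x: Sequence[float], mu0: float = 0.0, alternative: str = "two-sided"
) -> TestResult:
    """One-sample Wilcoxon signed-rank test against mu0 (zeros discarded)."""
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("no nonzero deviations from mu0")
    exact = d.size <= 15 and not _has_ties(np.abs(d))
    res = sps.wilcoxon(
        d, alternative=alternative, method="exact" if exact else "approx"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(d.size,),
        method="signed-rank/" + ("exact" if exact else "normal-approx"),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Midrank tie-corrected Kruskal-Wallis H with its eta-squared effect size."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]) and all(
        np.all(g == g[0]) for g in groups
    ):
        # all observations identical: H is 0 by definition but scipy raises
        return KWResult(H=0.0, p_value=1.0, N=sum(g.size for g in groups))
    H, p = sps.kruskal(*groups)
    return KWResult(H=float(H), p_value=float(p), N=sum(g.size for g in groups))


def dunn_posthoc(
    groups: dict[str, Sequence[float]], adjust: AdjustMethod = "bonferroni"
) -> list[TestResult]:
    """Dunn's post-hoc pairwise z-tests on mean ranks with tie correction."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum over tie groups of (t^3 - t)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    mean_ranks, sizes = {}, {}
    start = 0
    for name, arr in zip(names, arrays):
        r = ranks[start : start + arr.size]
        mean_ranks[name] = float(np.mean(r))
        sizes[name] = arr.size
        start += arr.size
    results = []
    raw_p = []
    for a, b in combinations(names, 2):
        na, nb = sizes[a], sizes[b]
        se = math.sqrt(
            (N * (N + 1) / 12 - tie_sum / (12 * (N - 1))) * (1 / na + 1 / nb)
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2 * sps.norm.sf(abs(z)) if se > 0 else 1.0
        results.append(
            TestResult(
                statistic=z, p_value=p, n=(na, nb), method="dunn",
                label=f"{a}_vs_{b}",
                effect_size=cliffs_delta(arrays[names.index(a)], arrays[names.index(b)]),
            )
        )
        raw_p.append(p)
    adj = adjust_pvalues(raw_p, adjust)
    return [
        TestResult(
            statistic=r.statistic, p_value=r.p_value, n=r.n, method=r.method,
            label=r.label, effect_size=r.effect_size,
            adjusted_p=float(a), adjust_method=adjust,
        )
        for r, a in zip(results, adj)
    ]


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross-pairs, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    # rank-based O((n+m) log(n+m)) evaluation of the pair counts
    greater = 0
    less = 0
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    less = (y.size - np.searchsorted(ys, x, side="right")).sum()
    return float((greater - less) / (x.size * y.size))


def permutation_wilcoxon(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Label-permutation test on the centered rank-sum statistic.

    T is the rank-sum of the first sample minus its null expectation
    n(N+1)/2; p = (#{|T*| >= |T|} + 1) / (n_perm + 1).
    """
    if seed is None:
        raise ValueError("a seed is required")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, N = x.size, pooled.size
    expect = n * (N + 1) / 2
    t_obs = abs(ranks[:n].sum() - expect)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(ranks)
        if abs(ranks[:n].sum() - expect) >= t_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult(
        statistic=float(t_obs), p_value=float(p), n=(n, y.size),
        method=f"permutation-rank-sum/{n_perm}",
        effect_size=cliffs_delta(x, y),
    )


_STRENGTH_BINS = ((0.10, "very weak"), (0.30, "weak"), (0.50, "moderate"))


def spearman_with_label(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, str]:
    """Midrank Spearman correlation with a categorical strength label.

    |rho| < 0.10 very weak, 0.10-0.30 weak, 0.30-0.50 moderate, > 0.50
    strong; boundary values go to the lower bin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input has undefined rank correlation")
    rho, p = sps.spearmanr(x, y)
    a = abs(rho)
    label = "strong"
    for bound, name in _STRENGTH_BINS:
        if a <= bound:
            label = name
            break
    return float(rho), float(p), label


# ---------------------------------------------------------------------------
# PERMANOVA with sequential (Type-I) sums of squares


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse hat matrix, robust to rank deficiency
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _design(levels: pd.Series) -> np.ndarray:
    return pd.get_dummies(levels.astype(str), drop_first=False).to_numpy(float)


def _sequential_ss(
    g: np.ndarray, factor_designs: list[np.ndarray]
) -> tuple[list[float], list[int], float, int]:
    n = g.shape[0]
    total_ss = float(np.trace(g))
    hats = []
    x = np.ones((n, 1))
    prev_hat = _hat(x)
    prev_rank = 1
    ss, dfs = [], []
    for xd in factor_designs:
        x = np.hstack([x, xd])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        ss.append(float(np.trace(h @ g @ h) - np.trace(prev_hat @ g @ prev_hat)))
        dfs.append(rank - prev_rank)
        prev_hat, prev_rank = h, rank
    resid_df = n - prev_rank
    resid_ss = total_ss - float(np.trace(prev_hat @ g @ prev_hat))
    return ss, dfs, resid_ss, resid_df


def permanova(
    delta_matrix: pd.DataFrame,
    factors: pd.DataFrame,
    n_perm: int = 9_999,
    seed: int | None = None,
    distance: str = "euclidean",
    check_dispersion: bool = True,
) -> PermanovaResult:
    """Multi-factor PERMANOVA with sequential (Type-I) sums of squares.

    `delta_matrix` is samples x variables (e.g. phages x codons of ΔRSCU);
    `factors` holds one categorical column per tested factor, tested in column
    order. Pseudo-F per factor uses the residual of the full model; p-values
    come from `n_perm` row permutations of the distance matrix. A companion
    permutation dispersion test (distance-to-centroid ANOVA) runs per factor.

    Raises if two factors are perfectly confounded in a joint model (zero
    residual degrees of freedom for the added factor) with instructions to
    test each factor alone.
    """
    if seed is None:
        raise ValueError("a seed is required")
    x = np.asarray(delta_matrix, dtype=float)
    if x.shape[0] != len(factors):
        raise ValueError("factor table and matrix row counts differ")
    names = list(factors.columns)
    for name in names:
        if factors[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")
    d = squareform(pdist(x, metric=distance))
    g = _gower_center(d)
    designs = [_design(factors[name]) for name in names]
    ss, dfs, resid_ss, resid_df = _sequential_ss(g, designs)
    if any(df == 0 for df in dfs):
        bad = names[dfs.index(0)]
        raise ValueError(
            f"factor {bad!r} adds no degrees of freedom after the preceding "
            "factors (perfectly confounded design); run single-factor models "
            "for each factor instead"
        )
    if resid_df == 0:
        raise ValueError("saturated design: no residual degrees of freedom")
    total_ss = float(np.trace(g))

    def _f(ss_i: list[float], dfs_i: list[int], rss: float, rdf: int) -> np.ndarray:
        # perfect within-group fit (rss == 0) gives an infinite pseudo-F
        denom = rss / rdf
        with np.errstate(divide="ignore"):
            return np.where(
                denom > 1e-12,
                np.array(ss_i) / np.array(dfs_i) / max(denom, 1e-300),
                np.where(np.array(ss_i) > 1e-12, np.inf, 0.0),
            )

    f_obs = _f(ss, dfs, resid_ss, resid_df)
    f_report = {k: float(v) for k, v in zip(names, f_obs)}
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(names))
    n = x.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, dfs_p, resid_ss_p, resid_df_p = _sequential_ss(gp, designs)
        hits += _f(ss_p, dfs_p, resid_ss_p, resid_df_p) >= f_obs - 1e-12
    pvals = (hits + 1) / (n_perm + 1)
    disp = {}
    if check_dispersion:
        for i, name in enumerate(names):
            disp[name] = dispersion_test(
                d, factors[name], n_perm=n_perm, seed=seed + 1 + i
            )[1]
    return PermanovaResult(
        factors=names,
        r2={k: s / total_ss for k, s in zip(names, ss)},
        pseudo_f=f_report,
        p_values=dict(zip(names, pvals)),
        residual_r2=resid_ss / total_ss,
        n_permutations=n_perm,
        dispersion_p=disp,
    )


def dispersion_test(
    distances: np.ndarray,
    grouping: Sequence,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation homogeneity-of-dispersion check (distance-to-centroid ANOVA).

    Samples are embedded by principal-coordinates analysis of the distance
    matrix; the ANOVA F of each sample's distance to its group centroid is
    compared against group-label permutations. Returns (F, p).
    """
    if seed is None:
        raise ValueError("a seed is required")
    d = np.asarray(distances, dtype=float)
    groups = np.asarray([str(v) for v in grouping])
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh(g)
    keep = vals > 1e-10
    coords = vecs[:, keep] * np.sqrt(vals[keep])

    def f_stat(labels: np.ndarray) -> float:
        dists = np.empty(len(labels))
        for lev in np.unique(labels):
            idx = labels == lev
            centroid = coords[idx].mean(axis=0)
            dists[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
        grand = dists.mean()
        levels = np.unique(labels)
        ss_between = sum(
            (labels == lev).sum() * (dists[labels == lev].mean() - grand) ** 2
            for lev in levels
        )
        ss_within = sum(
            ((dists[labels == lev] - dists[labels == lev].mean()) ** 2).sum()
            for lev in levels
        )
        df_b = len(levels) - 1
        df_w = len(labels) - len(levels)
        if df_w == 0 or ss_within == 0:
            return math.inf if ss_between > 0 else 0.0
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = f_stat(groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(groups)) >= f_obs - 1e-12:
            hits += 1
    return float(f_obs), (hits + 1) / (n_perm + 1)


def pca_scores(
    delta_matrix: pd.DataFrame, n_components: int = 2
) -> pd.DataFrame:
    """Centered (not scaled) principal-component scores per sample."""
    if len(delta_matrix) < 2:
        raise ValueError("need >= 2 samples")
    n_components = min(n_components, len(delta_matrix) - 1, delta_matrix.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(np.asarray(delta_matrix, dtype=float))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    out = pd.DataFrame(scores, columns=cols, index=delta_matrix.index)
    out.attrs["explained_variance_ratio"] = model.explained_variance_ratio_
    return out


# ---------------------------------------------------------------------------
# Beta-regression preprocessing for per-gene ΔtAI


def rescale_for_beta(x: Sequence[float], epsilon: float = EPSILON) -> BetaRescale:
    """Min-max rescale ΔtAI into the open interval (0, 1) for beta models.

    rescaled = (x - d_min + eps) / (d_max - d_min + 2 eps); any value at or
    outside the boundaries is clamped to eps / 1 - eps as a guard.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values")
    d_min, d_max = float(arr.min()), float(arr.max())
    if d_max <= d_min:
        raise ValueError("constant vector cannot be rescaled to (0, 1)")
    rescaled = (arr - d_min + epsilon) / (d_max - d_min + 2 * epsilon)
    rescaled = np.clip(rescaled, epsilon, 1 - epsilon)
    return BetaRescale(d_min=d_min, d_max=d_max, epsilon=epsilon, rescaled=rescaled)


def backtransform_beta(
    mu_rescaled: float | np.ndarray, d_min: float, d_max: float,
    epsilon: float = EPSILON,
) -> float | np.ndarray:
    """Inverse of `rescale_for_beta`: mu * (d_max - d_min + 2 eps) - eps + d_min."""
    mu = np.asarray(mu_rescaled, dtype=float)
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu_rescaled must lie strictly inside (0, 1)")
    out = mu * (d_max - d_min + 2 * epsilon) - epsilon + d_min
    return float(out) if np.isscalar(mu_rescaled) else out


@dataclass(frozen=True)
class BetaModelSpec:
    """Design matrices for the beta mixed model on rescaled per-gene ΔtAI.

    logit(mu_ij) = alpha + beta1 * Lifestyle_i + beta2 * tRNAGroup_i
    (+ host fixed effects at global scope) with a random intercept per phage
    genome. Baselines: Temperate lifestyle and the None tRNA group. Fitting
    is delegated: feed (response, fixed, groups) to any established beta-GLMM
    routine; back-transform fitted group means with `backtransform_beta`
    using the within-group extrema recorded in `rescale`.
    """

    response: np.ndarray
    fixed: pd.DataFrame
    groups: np.ndarray
    rescale: BetaRescale
    scope: str


@dataclass(frozen=True)
class LMMSpec:
    """Design for the linear mixed model  ΔGC ~ lifestyle + (1 | host)."""

    response: np.ndarray
    fixed: pd.DataFrame
    groups: np.ndarray

    def fit(self):
        """Convenience REML fit via statsmodels MixedLM."""
        import statsmodels.api as sm

        model = sm.MixedLM(self.response, self.fixed.to_numpy(float), groups=self.groups)
        return model.fit()


_LIFESTYLES = ("Temperate", "Virulent")
_TRNA_GROUPS = ("None", "Low", "High")


def build_beta_model_spec(
    per_gene: pd.DataFrame,
    scope: Literal["global", "per_genus"] = "global",
    epsilon: float = EPSILON,
) -> BetaModelSpec:
    """Design matrices for the ΔtAI beta mixed model.

    `per_gene` needs columns delta_tai, lifestyle, trna_group, phage_id and
    (at global scope) host. One row per gene; the random-intercept grouping
    is the phage genome. The host fixed effect enters only at global scope.
    """
    required = {"delta_tai", "lifestyle", "trna_group", "phage_id"}
    missing = required - set(per_gene.columns)
    if missing:
        raise ValueError(f"per-gene table missing column(s): {sorted(missing)}")
    bad_ls = set(per_gene["lifestyle"]) - set(_LIFESTYLES)
    if bad_ls:
        raise ValueError(f"unknown lifestyle level(s): {sorted(bad_ls)}")
    bad_tg = set(per_gene["trna_group"]) - set(_TRNA_GROUPS)
    if bad_tg:
        raise ValueError(f"unknown tRNA group level(s): {sorted(bad_tg)}")
    resc = rescale_for_beta(per_gene["delta_tai"].to_numpy(float), epsilon)
    fixed = pd.DataFrame({"intercept": np.ones(len(per_gene))}, index=per_gene.index)
    fixed["lifestyle[Virulent]"] = (per_gene["lifestyle"] == "Virulent").astype(float)
    for level in ("Low", "High"):
        fixed[f"trna_group[{level}]"] = (per_gene["trna_group"] == level).astype(float)
    if scope == "global":
        if "host" not in per_gene.columns:
            raise ValueError("global scope requires a 'host' column")
        hosts = sorted(per_gene["host"].unique())
        for h in hosts[1:]:  # first host is the baseline
            fixed[f"host[{h}]"] = (per_gene["host"] == h).astype(float)
    return BetaModelSpec(
        response=resc.rescaled,
        fixed=fixed,
        groups=per_gene["phage_id"].to_numpy(),
        rescale=resc,
        scope=scope,
    )


def build_lmm_spec(delta_gc_records: pd.DataFrame) -> LMMSpec:
    """Design for ΔGC ~ lifestyle + (1 | host): one row per phage per GC type."""
    required = {"delta_gc", "lifestyle", "host"}
    missing = required - set(delta_gc_records.columns)
    if missing:
        raise ValueError(f"delta-GC table missing column(s): {sorted(missing)}")
    bad = set(delta_gc_records["lifestyle"]) - set(_LIFESTYLES)
    if bad:
        raise ValueError(f"unknown lifestyle level(s): {sorted(bad)}")
    if delta_gc_records["host"].nunique() < 2:
        import warnings

        warnings.warn("single host level: random intercept is degenerate")
    fixed = pd.DataFrame(
        {
            "intercept": np.ones(len(delta_gc_records)),
            "lifestyle[Virulent]": (delta_gc_records["lifestyle"] == "Virulent").astype(
                float
            ),
        },
        index=delta_gc_records.index,
    )
    return LMMSpec(
        response=delta_gc_records["delta_gc"].to_numpy(float),
        fixed=fixed,
        groups=delta_gc_records["host"].to_numpy(),
    )
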