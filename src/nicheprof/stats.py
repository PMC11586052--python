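"""Statistical battery for carbon-use profiles.

Covers the comparison/inference layer of the pipeline: a Yates-corrected
2-sample test of equal proportions, a Shapiro-Wilk-routed two-sample test
(Welch's t when both samples look Gaussian, Wilcoxon rank-sum otherwise),
Benjamini-Hochberg FDR adjustment, Bray-Curtis dissimilarity of profiles,
two-factor sequential-SS PERMANOVA, PERMDISP with Tukey HSD, the Mantel
test, OLS of phenotypic dissimilarity on phylogenetic distance, and
kingdom x treatment models of the per-isolate metrics with a leaf-level
cluster adjustment.

Permutation p-values use the (b + 1)/(B + 1) convention, where b counts
permuted statistics at least as extreme as the observed one; every
permutation routine takes an explicit seed and is reproducible under it.
PERMANOVA and Mantel also accept ``permutations="all"`` for exhaustive
enumeration on small instances (p is then the exact proportion over all n!
relabelings, the identity included).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "equal_proportions_test",
    "two_sample_auto",
    "bh_adjust",
    "bray_curtis",
    "permanova",
    "permdisp",
    "PermdispResult",
    "mantel",
    "dissimilarity_phylo_regression",
    "metric_model",
    "MetricModelResult",
    "write_phylip_square",
    "read_phylip_square",
]


# --------------------------------------------------------------------------
# elementary tests
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    """One hypothesis test, with the routing decision kept for audit."""

    name: str
    statistic: float
    p_value: float
    test_used: str
    n1: int
    n2: int
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)


def equal_proportions_test(x1: int, n1: int, x2: int, n2: int, name: str = "equal_proportions") -> TestResult:
    """2-sample test of equal proportions (Yates-corrected chi-squared, df=1)."""
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError("each group needs at least one trial")
        if not 0 <= x <= n:
            raise ValueError(f"successes {x} outside [0, {n}]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if table.sum(axis=0).min() == 0:
        # degenerate margin (all successes or all failures): no difference testable
        return TestResult(name, 0.0, 1.0, "equal_proportions", n1, n2)
    res = scipy.stats.chi2_contingency(table, correction=True)
    return TestResult(name, float(res.statistic), float(res.pvalue), "equal_proportions", n1, n2)


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:  # constant sample: treat as maximally non-Gaussian
        return 0.0
    return float(scipy.stats.shapiro(x).pvalue)


def two_sample_auto(
    a: Sequence[float], b: Sequence[float], alpha_normality: float = 0.05, name: str = "two_sample"
) -> TestResult:
    """Normality-routed two-sample comparison (two-sided).

    Shapiro-Wilk is run on each sample; if both p >= ``alpha_normality`` a
    Welch t-test is used, otherwise a Wilcoxon rank-sum (exact enumeration
    below n=10 per group when untied, normal approximation with continuity
    and tie correction otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs >= 3 observations for the Shapiro-Wilk gate")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa >= alpha_normality and pb >= alpha_normality:
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        return TestResult(
            name, float(res.statistic), float(res.pvalue), "welch_t", a.size, b.size,
            extra={"shapiro_p": (pa, pb)},
        )
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) < 10 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    pval = float(res.pvalue)
    if math.isnan(pval):  # fully tied samples: no evidence of a difference
        pval = 1.0
    return TestResult(
        name, float(res.statistic), pval, "wilcoxon", a.size, b.size,
        extra={"shapiro_p": (pa, pb), "method": method},
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: Sequence[TestResult]) -> list[TestResult]:
    """Fill ``p_adjusted`` across one explicit BH family of results."""
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return list(results)


# --------------------------------------------------------------------------
# dissimilarity
# --------------------------------------------------------------------------

def bray_curtis(profiles, clipped: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity of carbon-use profiles over all 95 substrates.

    Corrected ODs are clipped at zero (Bray-Curtis is undefined for negative
    abundances); pass ``clipped=False`` to use raw corrected values for
    sensitivity checks. Pairs of all-zero profiles, where the index is 0/0,
    are assigned distance 1.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    x = np.vstack([
        p.corrected_od_nonneg if clipped else p.corrected_od for p in profiles
    ])
    with np.errstate(invalid="ignore"):
        condensed = pdist(x, metric="braycurtis")
    condensed = np.where(np.isnan(condensed), 1.0, condensed)
    return DistanceMatrix(squareform(condensed), ids=[p.isolate_id for p in profiles])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _dummy_columns(data: pd.DataFrame, factor: str) -> np.ndarray:
    levels = pd.unique(data[factor])
    if len(levels) < 2:
        raise ValueError(f"factor '{factor}' has a single level in this subset")
    counts = data[factor].value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"factor '{factor}' has levels with < 2 samples: {bad}")
    return np.column_stack([(data[factor] == lv).to_numpy(float) for lv in levels[1:]])


def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    blocks = [_dummy_columns(data, p) for p in parts]
    cols = blocks[0]
    for blk in blocks[1:]:
        cols = np.concatenate(
            [cols[:, [i]] * blk for i in range(cols.shape[1])], axis=1
        )
    return cols


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def permanova(
    dm: DistanceMatrix,
    data: pd.DataFrame,
    terms: Sequence[str] = ("kingdom", "treatment", "kingdom:treatment"),
    permutations: int | str = 999,
    seed=None,
) -> pd.DataFrame:
    """Sequential (Type-I) permutational multivariate ANOVA on a distance matrix.

    Terms enter in the given order (interactions written ``a:b``); sums of
    squares come from traces of hat-matrix products with the Gower-centered
    matrix, pseudo-F per term uses the full-model residual, and p-values come
    from free row/column permutations of the distance matrix. R^2 values per
    term plus the residual sum to 1. ``permutations="all"`` enumerates every
    relabeling (guarded at n <= 8).

    Returns a table with rows per term plus Residual and Total.
    """
    d = dm.data
    n = d.shape[0]
    data = data.loc[list(dm.ids)]
    g = _gower_center(d)
    ss_total = float(np.trace(g))

    designs = [np.ones((n, 1))]
    for t in terms:
        designs.append(np.hstack([designs[-1], _term_columns(data, t)]))
    hats = [_hat(x) for x in designs]
    ranks = [np.linalg.matrix_rank(x) for x in designs]
    dfs = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    df_res = n - ranks[-1]

    def term_stats(gmat: np.ndarray):
        model_ss = [float(np.sum(h * gmat)) for h in hats]  # trace(H G), H symmetric
        ss = [model_ss[k + 1] - model_ss[k] for k in range(len(terms))]
        ss_res = float(np.trace(gmat)) - model_ss[-1]
        f = [
            (ss[k] / dfs[k]) / (ss_res / df_res) if dfs[k] > 0 and df_res > 0 else np.nan
            for k in range(len(terms))
        ]
        return np.array(ss), ss_res, np.array(f)

    ss_obs, ss_res, f_obs = term_stats(g)

    if permutations == "all":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        count = np.zeros(len(terms))
        total = 0
        for idx in itertools.permutations(range(n)):
            gp = g[np.ix_(idx, idx)]
            _, _, f_perm = term_stats(gp)
            count += f_perm >= f_obs - 1e-12
            total += 1
        pvals = count / total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(int(permutations)):
            idx = rng.permutation(n)
            gp = g[np.ix_(idx, idx)]
            _, _, f_perm = term_stats(gp)
            count += f_perm >= f_obs - 1e-12
        pvals = (count + 1) / (int(permutations) + 1)

    rows = []
    for k, t in enumerate(terms):
        rows.append(
            {"term": t, "df": dfs[k], "SumOfSqs": ss_obs[k], "R2": ss_obs[k] / ss_total,
             "F": f_obs[k], "p": pvals[k]}
        )
    rows.append({"term": "Residual", "df": df_res, "SumOfSqs": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# PERMDISP
# --------------------------------------------------------------------------

def _pcoa_axes(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes; negative-eigenvalue axes kept as 'imaginary'."""
    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    tol = max(np.abs(eigval).max(), 1.0) * 1e-10
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def _geometric_median(points: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the spatial (geometric) median."""
    if points.shape[1] == 0:
        return np.zeros(0)
    y = points.mean(axis=0)
    for _ in range(max_iter):
        diff = points - y
        dist = np.linalg.norm(diff, axis=1)
        at_point = dist < 1e-12
        if at_point.any():
            # Weiszfeld stalls on a data point; it is the optimum iff the
            # resultant pull of the others has norm <= multiplicity
            others = ~at_point
            if not others.any():
                return y
            pull = np.sum((points[others] - y) / dist[others, None], axis=0)
            if np.linalg.norm(pull) <= at_point.sum():
                return y
            w = 1.0 / dist[others]
            y_new = (points[others] * w[:, None]).sum(axis=0) / w.sum()
        else:
            w = 1.0 / dist
            y_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for gidx in range(k):
        v = values[codes == gidx]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


@dataclass
class PermdispResult:
    distances: pd.Series  # per-sample distance to its group center
    group_means: pd.Series
    statistic: float  # ANOVA F on the distances
    p_value: float
    tukey: pd.DataFrame
    center: str
    permutations: int


def permdisp(
    dm: DistanceMatrix,
    grouping: Mapping[str, str] | pd.Series,
    permutations: int = 9999,
    seed=None,
    center: str = "median",
) -> PermdispResult:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Samples are embedded by principal coordinates with negative-eigenvalue
    axes retained as an imaginary part; each sample's squared distance to
    its group's center (spatial median by default, centroid optional) is the
    real-part contribution minus the imaginary-part contribution, floored at
    zero before taking the root. The F statistic of a one-way ANOVA on those
    distances is compared against group-label permutations, and Tukey HSD
    (Tukey-Kramer for unequal n) compares group means.
    """
    if center not in ("median", "centroid"):
        raise ValueError("center must be 'median' or 'centroid'")
    grouping = pd.Series(grouping).loc[list(dm.ids)]
    levels = pd.unique(grouping)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    codes = grouping.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    real, imag = _pcoa_axes(dm.data)

    dists = np.empty(len(grouping))
    for gidx in range(len(levels)):
        mask = codes == gidx
        if center == "median":
            c_real = _geometric_median(real[mask])
            c_imag = _geometric_median(imag[mask])
        else:
            c_real = real[mask].mean(axis=0)
            c_imag = imag[mask].mean(axis=0)
        sq = ((real[mask] - c_real) ** 2).sum(axis=1) - ((imag[mask] - c_imag) ** 2).sum(axis=1)
        dists[mask] = np.sqrt(np.maximum(sq, 0.0))

    k = len(levels)
    f_obs = _anova_f(dists, codes, k)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(int(permutations)):
        f_perm = _anova_f(dists, rng.permutation(codes), k)
        if f_perm >= f_obs - 1e-12:
            b += 1
    pval = (b + 1) / (int(permutations) + 1)

    groups_arr = grouping.to_numpy()
    if np.ptp(dists) == 0:
        tukey_df = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"])
    else:
        tk = pairwise_tukeyhsd(dists, groups_arr, alpha=0.05)
        tukey_df = pd.DataFrame(
            tk.summary().data[1:], columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"]
        )
    means = pd.Series(dists, index=grouping.index).groupby(grouping).mean()
    return PermdispResult(
        distances=pd.Series(dists, index=grouping.index),
        group_means=means,
        statistic=float(f_obs),
        p_value=float(pval),
        tukey=tukey_df,
        center=center,
        permutations=int(permutations),
    )


# --------------------------------------------------------------------------
# Mantel & dissimilarity regression
# --------------------------------------------------------------------------

def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int | str = 999,
    seed=None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices.

    ``d2`` is label-aligned to ``d1``; p comes from simultaneous row/column
    permutations of ``d2`` (one-sided 'greater' by default, matching common
    ecology usage; 'two-sided' compares |r|).
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share their label sets")
    d2 = d2.filter(d1.ids)
    x = _upper(d1.data)
    m2 = d2.data
    y = _upper(m2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "less":
            return r_perm <= r_obs + 1e-12
        return abs(r_perm) >= abs(r_obs) - 1e-12

    n = m2.shape[0]
    if permutations == "all":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        b = 0
        total = 0
        for idx in itertools.permutations(range(n)):
            yp = _upper(m2[np.ix_(idx, idx)])
            b += extreme(float(np.corrcoef(x, yp)[0, 1]))
            total += 1
        return r_obs, b / total
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(int(permutations)):
        idx = rng.permutation(n)
        yp = _upper(m2[np.ix_(idx, idx)])
        b += extreme(float(np.corrcoef(x, yp)[0, 1]))
    return r_obs, (b + 1) / (int(permutations) + 1)


def dissimilarity_phylo_regression(
    d_pheno: DistanceMatrix,
    d_phylo: DistanceMatrix,
    meta: pd.DataFrame,
    strata: Sequence[str] = ("kingdom", "treatment"),
) -> pd.DataFrame:
    """Per-stratum OLS of carbon-use dissimilarity on phylogenetic distance.

    Within each stratum cell (e.g. kingdom x treatment), all isolate pairs
    present in both matrices are regressed. The pairwise observations are
    not independent, so the reported p-values are nominal — use the Mantel
    test for inference; the R^2 values quantify variance explained.
    """
    shared = [i for i in d_pheno.ids if i in set(d_phylo.ids)]
    meta = meta.loc[[i for i in shared if i in meta.index]]
    rows = []
    for key, sub in meta.groupby(list(strata), observed=True, sort=False):
        ids = [i for i in shared if i in set(sub.index)]
        if len(ids) < 3:
            continue
        dp = d_pheno.filter(ids).data
        dg = d_phylo.filter(ids).data
        y = _upper(dp)
        x = _upper(dg)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(strata, key))
            | {
                "n_isolates": len(ids),
                "n_pairs": y.size,
                "slope": float(model.params[1]),
                "intercept": float(model.params[0]),
                "R2": float(model.rsquared),
                "p_nominal": float(model.f_pvalue),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# kingdom x treatment models of the metrics
# --------------------------------------------------------------------------

@dataclass
class MetricModelResult:
    response: str
    model_used: str  # poisson_gee | lognormal_mixed | lognormal_ols
    params: pd.DataFrame
    emmeans: pd.DataFrame  # estimated marginal means per kingdom x treatment cell
    contrasts: pd.DataFrame
    warnings: list[str]


_CELLS = [("Bacteria", "control"), ("Bacteria", "NPKμ"), ("Fungi", "control"), ("Fungi", "NPKμ")]


def _fixed_design(kingdom: pd.Series, treatment: pd.Series) -> pd.DataFrame:
    kf = (kingdom == "Fungi").astype(float)
    tn = (treatment == "NPKμ").astype(float)
    return pd.DataFrame(
        {"Intercept": 1.0, "kingdom[Fungi]": kf, "treatment[NPKμ]": tn, "kingdom:treatment": kf * tn}
    )


def _cell_row(kingdom: str, treatment: str) -> np.ndarray:
    kf = float(kingdom == "Fungi")
    tn = float(treatment == "NPKμ")
    return np.array([1.0, kf, tn, kf * tn])


def metric_model(metrics: pd.DataFrame, response: str) -> MetricModelResult:
    """Model a per-isolate metric on kingdom x treatment with leaf clustering.

    NW is modelled as Poisson with a log link via GEE with an exchangeable
    working correlation clustered on leaf (a population-averaged account of
    the leaf random effect); TG and GE are modelled on the natural-log scale
    with a linear mixed model carrying a random leaf intercept. Estimated
    marginal means per cell and all pairwise contrasts (Wald z) are returned
    on the model's link scale. A singular/non-converging mixed fit falls
    back to fixed-effects-only OLS, recorded in ``warnings``.
    """
    if response not in ("NW", "TG", "GE"):
        raise ValueError("response must be one of NW, TG, GE")
    df = metrics.copy()
    warnings_: list[str] = []
    for trt, sub in df.groupby("treatment", observed=True):
        if sub["leaf_id"].nunique() < 2:
            raise ValueError(f"treatment '{trt}' has fewer than 2 leaves")

    if response == "NW":
        y = df["NW"].astype(float)
        link_scale = "log-count"
    else:
        keep = df[response].notna() & (df[response] > 0)
        dropped = int((~keep).sum())
        if dropped:
            warnings_.append(f"dropped {dropped} rows with undefined/non-positive {response}")
        df = df.loc[keep]
        y = np.log(df[response].astype(float))
        link_scale = f"ln({response})"

    x = _fixed_design(df["kingdom"], df["treatment"])
    groups = df["leaf_id"].to_numpy()

    if response == "NW":
        model = sm.GEE(
            y, x, groups=groups, family=sm.families.Poisson(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        fit = model.fit()
        model_used = "poisson_gee"
        beta = fit.params.to_numpy()
        cov = fit.cov_params().to_numpy()
    else:
        model_used = "lognormal_mixed"
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fit = sm.MixedLM(y, x, groups=groups).fit(reml=True)
            if not np.isfinite(fit.cov_re.iloc[0, 0]) or fit.cov_re.iloc[0, 0] < 1e-10:
                warnings_.append("leaf variance component at boundary (~0); estimates equal fixed-effects fit")
            beta = fit.fe_params.to_numpy()
            cov = fit.cov_params().to_numpy()[: len(beta), : len(beta)]
        except Exception as exc:  # singular fit
            warnings_.append(f"mixed model failed ({exc}); falling back to fixed-effects OLS")
            fit = sm.OLS(y, x).fit()
            model_used = "lognormal_ols"
            beta = fit.params.to_numpy()
            cov = fit.cov_params().to_numpy()

    params = pd.DataFrame(
        {
            "term": x.columns,
            "estimate": beta,
            "se": np.sqrt(np.diag(cov)),
        }
    )

    em_rows = []
    for kd, trt in _CELLS:
        l = _cell_row(kd, trt)
        est = float(l @ beta)
        se = float(np.sqrt(l @ cov @ l))
        em_rows.append({"kingdom": kd, "treatment": trt, "emmean": est, "se": se, "scale": link_scale})
    emmeans = pd.DataFrame(em_rows)

    ct_rows = []
    for i in range(len(_CELLS)):
        for j in range(i + 1, len(_CELLS)):
            l = _cell_row(*_CELLS[i]) - _cell_row(*_CELLS[j])
            est = float(l @ beta)
            se = float(np.sqrt(l @ cov @ l))
            z = est / se if se > 0 else np.nan
            p = 2 * scipy.stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            ct_rows.append(
                {
                    "contrast": f"{_CELLS[i][0]}.{_CELLS[i][1]} - {_CELLS[j][0]}.{_CELLS[j][1]}",
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": p,
                    "significant": bool(p < 0.05) if np.isfinite(z) else False,
                }
            )
    contrasts = pd.DataFrame(ct_rows)
    return MetricModelResult(response, model_used, params, emmeans, contrasts, warnings_)


# --------------------------------------------------------------------------
# distance-matrix text IO (labelled square PHYLIP)
# --------------------------------------------------------------------------

def write_phylip_square(dm: DistanceMatrix, path, relaxed: bool = True) -> None:
    """Write a labelled square distance matrix in PHYLIP format.

    Relaxed mode (default) writes full names followed by whitespace; strict
    mode truncates/pads names to the classic 10 characters.
    """
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label, row in zip(dm.ids, dm.data):
            name = label if relaxed else f"{label[:10]:<10}"
            fh.write(name + " " + " ".join(repr(float(v)) for v in row) + "\n")


def read_phylip_square(path) -> DistanceMatrix:
    """Read a labelled square PHYLIP distance matrix."""
    with open(path) as fh:
        tokens = fh.readline().split()
        n = int(tokens[0])
        ids, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1 : n + 1]])
    if len(ids) != n:
        raise ValueError(f"expected {n} rows, found {len(ids)}")
    return DistanceMatrix(np.asarray(rows), ids=ids)
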