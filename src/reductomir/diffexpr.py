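"""Negative-binomial Wald differential expression for small dose designs.

The model follows the standard RNA-seq count workflow: counts K_ij are
NB(mu_ij, alpha_i) with mu_ij = s_j * q_ij, variance mu + alpha * mu^2, where
s_j are median-of-ratios size factors and q_ij is the fitted group mean on the
log scale. Gene-wise dispersions are estimated by profile maximum likelihood,
a mean-dispersion trend alpha_tr(mu) = a1 / mu + a0 is fitted by iteratively
reweighted regression, and final dispersions maximize the likelihood plus a
log-normal prior centred on the trend (empirical-Bayes shrinkage, suited to
n = 3-4 per group). Contrast log2 fold changes are tested with a Wald z
statistic; family-wise error is controlled by Bonferroni, and a separate
biological-significance filter requires |log2FC| > 1 with normalized count
sum > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, polygamma

from .core_io import CountMatrix, SampleDesign

__all__ = [
    "SizeFactors",
    "DispersionEstimates",
    "estimate_size_factors",
    "normalized_counts",
    "estimate_dispersions",
    "wald_test",
    "apply_de_filters",
    "pca_summary",
    "PCAResult",
    "ddct_fold_change",
    "resolve_contrast",
]

MIN_DISP = 1e-8
LFC_CLAMP = 10.0  # log2 units, used when one group is all zeros
_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scaling constants (all positive)."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise ValueError("size factors must be positive and finite")
        geo = float(np.exp(np.log(self.factors).mean()))
        if not (0.5 <= geo <= 2.0):
            warnings.warn(
                f"geometric mean of size factors is {geo:.3g}; libraries may "
                "be badly scaled or counts may not be raw"
            )

    @property
    def values(self) -> np.ndarray:
        return self.factors.to_numpy(dtype=float)


def estimate_size_factors(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors (ratio to the per-feature geometric mean)."""
    counts = cm.values.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; filter features "
            "or check the input"
        )
    logs = np.log(counts[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logs - log_geomean, axis=0))
    return SizeFactors(pd.Series(s, index=cm.sample_ids, name="size_factor"))


def normalized_counts(cm: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    return cm.counts / sf.factors


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized over features)
# ---------------------------------------------------------------------------


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; k, mu are (F, S), alpha is (F,) or (F, 1)."""
    alpha = np.atleast_1d(alpha).astype(float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    r = 1.0 / alpha
    mu_safe = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(k + r)
            - gammaln(r)
            - gammaln(k + 1.0)
            + r * np.log(r / (r + mu_safe))
            + k * np.log(mu_safe / (r + mu_safe))
        )
    ll = np.where((mu <= 0) & (k == 0), 0.0, ll)
    ll = np.where((mu <= 0) & (k > 0), -np.inf, ll)
    return ll.sum(axis=1)


def _fit_group_means(
    counts: np.ndarray,
    s: np.ndarray,
    alpha: np.ndarray,
    group_masks: list[np.ndarray],
    n_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """MLE of per-group means q_g (features x groups) at fixed dispersion.

    Solves the NB score equation by the fixed point
    q <- sum_j k_j w_j / sum_j s_j w_j with w_j = 1 / (1 + alpha * mu_j),
    which reduces to the weighted mean of k/s and converges quickly.
    """
    alpha = np.atleast_1d(alpha).astype(float)[:, None]
    F = counts.shape[0]
    out = np.empty((F, len(group_masks)))
    for g, mask in enumerate(group_masks):
        k = counts[:, mask]
        sj = s[mask]
        q = k.sum(axis=1) / sj.sum()
        for _ in range(n_iter):
            mu = sj[None, :] * q[:, None]
            w = 1.0 / (1.0 + alpha * mu)
            denom = (sj[None, :] * w).sum(axis=1)
            q_new = (k * w).sum(axis=1) / denom
            if np.max(np.abs(q_new - q) / np.maximum(q, 1e-8)) < tol:
                q = q_new
                break
            q = q_new
        out[:, g] = q
    return out


def _profile_loglik(
    counts: np.ndarray,
    s: np.ndarray,
    alpha: np.ndarray,
    group_masks: list[np.ndarray],
    n_iter: int = 10,
) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood at dispersion alpha.

    Group means are refitted at each alpha; the adjustment
    -0.5 * log det(X^T W X) (which factorizes over groups for a group-means
    design) corrects the downward bias of the plain MLE when the mean
    parameters are estimated from few samples.
    """
    q = _fit_group_means(counts, s, alpha, group_masks, n_iter=n_iter)
    mu = np.zeros_like(counts, dtype=float)
    alpha_col = np.atleast_1d(alpha)[:, None]
    cr = np.zeros(counts.shape[0])
    for g, mask in enumerate(group_masks):
        mu_g = s[mask][None, :] * q[:, [g]]
        mu[:, mask] = mu_g
        w_g = (mu_g / (1.0 + alpha_col * mu_g)).sum(axis=1)
        cr += 0.5 * np.log(np.maximum(w_g, 1e-300))
    return _nb_loglik(counts, mu, alpha) - cr


def _argmax_quadratic(x: np.ndarray, y: np.ndarray, best: np.ndarray) -> np.ndarray:
    """Refine a grid argmax by parabolic interpolation on (x, y) triples."""
    i = np.clip(best, 1, len(x) - 2)
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    idx = np.arange(len(best))
    y0, y1, y2 = y[i - 1, idx], y[i, idx], y[i + 1, idx]
    denom = (y0 - 2 * y1 + y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (y0 - y2) / denom
    shift = np.where(np.isfinite(shift) & (np.abs(shift) <= 1.0), shift, 0.0)
    step = x1 - x0
    return x1 + shift * step


@dataclass
class DispersionEstimates:
    """Gene-wise, trended and final (MAP) NB dispersions per feature."""

    genewise: pd.Series
    trended: pd.Series
    final: pd.Series
    outlier: pd.Series
    trend_coeffs: tuple[float, float]  # (a0, a1) in alpha = a1 / mu + a0
    prior_var: float
    base_mean: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        for series in (self.genewise, self.trended, self.final):
            if (series < MIN_DISP - 1e-12).any():
                raise ValueError("dispersions below the minimum bound")


def _fit_trend(
    alpha_hat: np.ndarray, base_mean: np.ndarray, max_iter: int = 50
) -> tuple[float, float, np.ndarray]:
    """Fit alpha_tr(mu) = a1 / mu + a0 by iteratively reweighted regression.

    Gamma-style weights 1 / fitted^2; one round of outlier exclusion drops
    features whose |log residual| exceeds 2 before the final fit. Falls back
    to the mean dispersion if the iteration fails to converge.
    """
    use = (alpha_hat > MIN_DISP * 10) & (base_mean > 0)
    if use.sum() < 2:
        mean_disp = float(np.maximum(alpha_hat.mean(), MIN_DISP))
        warnings.warn("too few features for a dispersion trend; using the mean")
        return mean_disp, 0.0, np.full_like(alpha_hat, mean_disp)

    def _irls(y: np.ndarray, mu: np.ndarray) -> tuple[float, float] | None:
        X = np.column_stack([np.ones_like(mu), 1.0 / mu])
        coef = np.array([max(np.median(y), 1e-6), 0.0])
        for _ in range(max_iter):
            fitted = np.maximum(X @ coef, 1e-10)
            w = 1.0 / fitted**2
            WX = X * w[:, None]
            try:
                new = np.linalg.solve(X.T @ WX, WX.T @ y)
            except np.linalg.LinAlgError:
                return None
            new = np.maximum(new, [1e-12, 0.0])
            if np.max(np.abs(new - coef) / np.maximum(np.abs(coef), 1e-8)) < 1e-6:
                return float(new[0]), float(new[1])
            coef = new
        return None

    y, mu = alpha_hat[use], base_mean[use]
    res = _irls(y, mu)
    if res is None:
        mean_disp = float(np.maximum(alpha_hat.mean(), MIN_DISP))
        warnings.warn("dispersion trend fit did not converge; using the mean")
        return mean_disp, 0.0, np.full_like(alpha_hat, mean_disp)
    a0, a1 = res
    fitted = a1 / mu + a0
    keep = np.abs(np.log(y / np.maximum(fitted, 1e-12))) <= 2.0
    if keep.sum() >= 2 and keep.sum() < len(y):
        res2 = _irls(y[keep], mu[keep])
        if res2 is not None:
            a0, a1 = res2
    trend = a1 / np.maximum(base_mean, 1e-8) + a0
    return a0, a1, np.maximum(trend, MIN_DISP)


def estimate_dispersions(
    cm: CountMatrix,
    sf: SizeFactors,
    design: SampleDesign | None = None,
    min_disp: float = MIN_DISP,
    max_disp: float = 50.0,
    prior_var_floor: float = 0.25,
) -> DispersionEstimates:
    """Gene-wise MLE, trend fit and empirical-Bayes (MAP) shrinkage.

    The MAP estimate maximizes the NB profile log-likelihood plus a
    Normal(log alpha_tr, sigma^2_prior) prior on log alpha, with
    sigma^2_prior = max(floor, MAD-based residual variance minus the expected
    sampling variance of a log dispersion estimate). Features whose gene-wise
    estimate exceeds the trend by more than two (scaled) MADs are flagged as
    outliers and keep their gene-wise value.
    """
    design = design or cm.design
    counts = cm.values.astype(float)
    s = sf.values
    groups = design.groups.reindex(cm.sample_ids)
    group_masks = [
        (groups == g).to_numpy() for g in pd.unique(groups)
    ]
    n_params = len(group_masks)
    n_samples = counts.shape[1]
    if n_samples - n_params < 1:
        raise ValueError("not enough residual degrees of freedom to estimate dispersion")

    nonzero = counts.sum(axis=1) > 0
    base_mean = (counts / s[None, :]).mean(axis=1)

    log_grid = np.linspace(np.log(min_disp), np.log(max_disp), 60)
    F = counts.shape[0]
    ll_grid = np.empty((len(log_grid), F))
    for i, la in enumerate(log_grid):
        ll_grid[i] = _profile_loglik(
            counts, s, np.full(F, np.exp(la)), group_masks, n_iter=8
        )
    best = ll_grid.argmax(axis=0)
    log_alpha_hat = _argmax_quadratic(log_grid, ll_grid, best)
    alpha_hat = np.clip(np.exp(log_alpha_hat), min_disp, max_disp)
    alpha_hat[~nonzero] = min_disp

    if F < 2:
        warnings.warn("single feature: no dispersion trend, final = gene-wise MLE")
        idx = pd.Index(cm.feature_ids, name="feature_id")
        series = pd.Series(alpha_hat, index=idx)
        return DispersionEstimates(
            genewise=series,
            trended=series.copy(),
            final=series.copy(),
            outlier=pd.Series(False, index=idx),
            trend_coeffs=(float(alpha_hat[0]), 0.0),
            prior_var=prior_var_floor,
            base_mean=pd.Series(base_mean, index=idx),
        )

    a0, a1, alpha_tr = _fit_trend(alpha_hat[nonzero], base_mean[nonzero])
    trend = np.full(F, max(a0, min_disp))
    trend[nonzero] = alpha_tr

    log_resid = np.log(alpha_hat[nonzero]) - np.log(trend[nonzero])
    mad = np.median(np.abs(log_resid - np.median(log_resid)))
    s_lr = 1.4826 * mad
    # expected sampling variance of log alpha-hat for m residual d.o.f.
    sampling_var = float(polygamma(1, max((n_samples - n_params), 1) / 2.0))
    prior_var = max(prior_var_floor, s_lr**2 - sampling_var)

    offsets = np.linspace(-8.0, 8.0, 61)
    post_grid = np.empty((len(offsets), F))
    log_trend = np.log(trend)
    for i, g in enumerate(offsets):
        alpha_g = np.clip(np.exp(log_trend + g), min_disp, max_disp)
        post_grid[i] = _profile_loglik(counts, s, alpha_g, group_masks, n_iter=8) - (
            g**2
        ) / (2.0 * prior_var)
    best = post_grid.argmax(axis=0)
    g_map = _argmax_quadratic(offsets, post_grid, best)
    alpha_map = np.clip(np.exp(log_trend + g_map), min_disp, max_disp)

    outlier = np.zeros(F, dtype=bool)
    outlier[nonzero] = (np.log(alpha_hat[nonzero]) - log_trend[nonzero]) > 2.0 * max(
        s_lr, 1e-8
    )
    final = np.where(outlier, alpha_hat, alpha_map)
    final[~nonzero] = min_disp

    idx = pd.Index(cm.feature_ids, name="feature_id")
    return DispersionEstimates(
        genewise=pd.Series(alpha_hat, index=idx),
        trended=pd.Series(trend, index=idx),
        final=pd.Series(final, index=idx),
        outlier=pd.Series(outlier, index=idx),
        trend_coeffs=(a0, a1),
        prior_var=prior_var,
        base_mean=pd.Series(base_mean, index=idx),
    )


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------


def resolve_contrast(
    design: SampleDesign, contrast: str | tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, str]:
    """Resolve a contrast into (mask_A, mask_B, label); beta = log2(A / B).

    ``"pooled"`` pools every transgenic dose level (dose_code > 0) against the
    zero-dose group; ``"dose"`` contrasts the highest dose level against the
    next-highest; a tuple gives explicit (A, B) group labels.
    """
    groups = design.frame["group"].to_numpy()
    doses = design.frame["dose_code"].to_numpy()
    if contrast in ("pooled", "pooled_Tg_vs_NTg"):
        mask_a, mask_b = doses > 0, doses == 0
        label = "pooled_Tg_vs_NTg"
    elif contrast in ("dose", "TgH_vs_TgL"):
        levels = np.sort(np.unique(doses[doses > 0]))
        if len(levels) < 2:
            raise ValueError("dose contrast needs at least two nonzero dose levels")
        mask_a, mask_b = doses == levels[-1], doses == levels[-2]
        label = "dose_high_vs_low"
    elif isinstance(contrast, tuple) and len(contrast) == 2:
        a, b = contrast
        mask_a, mask_b = groups == a, groups == b
        label = f"{a}_vs_{b}"
    else:
        raise ValueError(f"unrecognized contrast: {contrast!r}")
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"both contrast groups need >= 2 samples for {label}")
    return mask_a, mask_b, label


def wald_test(
    cm: CountMatrix,
    sf: SizeFactors,
    dispersions: DispersionEstimates,
    design: SampleDesign | None = None,
    contrast: str | tuple[str, str] = "pooled",
) -> pd.DataFrame:
    """Per-feature NB Wald test of log2 fold change for the given contrast.

    Returns a DataFrame with one row per feature: baseMean, log2FC, lfcSE,
    stat, pvalue, Bonferroni qvalue, the normalized count sum, flags, and the
    contrast label. Features with all-zero counts in both contrast groups are
    not tested (NaN p) and are excluded from the Bonferroni family size. A
    group with all-zero counts yields a log2FC clamped to +/-10 with
    ``lfc_clamped`` set rather than an infinite estimate.
    """
    design = design or cm.design
    counts = cm.values.astype(float)
    s = sf.values
    mask_a, mask_b, label = resolve_contrast(design, contrast)
    alpha = dispersions.final.reindex(cm.feature_ids).to_numpy()

    q = _fit_group_means(counts, s, alpha, [mask_a, mask_b], n_iter=100)
    q_a, q_b = q[:, 0], q[:, 1]

    clamped = np.zeros(len(q_a), dtype=bool)
    tested = ~((q_a <= 0) & (q_b <= 0))
    zero_a = (q_a <= 0) & tested
    zero_b = (q_b <= 0) & tested
    q_a_eff = np.where(zero_a, q_b * 2.0**-LFC_CLAMP, q_a)
    q_b_eff = np.where(zero_b, q_a * 2.0**-LFC_CLAMP, q_b)
    clamped = zero_a | zero_b

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(q_a_eff / q_b_eff)
    lfc = np.clip(lfc, -LFC_CLAMP, LFC_CLAMP)

    # observed Fisher information of the two-group NB GLM with log link:
    # Var(beta_ln) = 1 / W_A + 1 / W_B with W_g = sum_j mu_j / (1 + alpha mu_j)
    def _weight(q_eff: np.ndarray, mask: np.ndarray) -> np.ndarray:
        mu = s[mask][None, :] * q_eff[:, None]
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    w_a = _weight(q_a_eff, mask_a)
    w_b = _weight(q_b_eff, mask_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(1.0 / w_a + 1.0 / w_b)
    se = se_ln / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / se, 0.0)
    pvalue = np.where(tested, 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    m = int(tested.sum())
    qvalue = np.minimum(pvalue * m, 1.0)

    norm = counts / s[None, :]
    base_mean = norm.mean(axis=1)
    count_sum = norm.sum(axis=1)

    out = pd.DataFrame(
        {
            "feature_id": cm.feature_ids,
            "baseMean": base_mean,
            "log2FC": np.where(tested, lfc, 0.0),
            "lfcSE": np.where(tested, se, np.nan),
            "stat": np.where(tested, stat, np.nan),
            "pvalue": pvalue,
            "qvalue_bonferroni": qvalue,
            "count_sum": count_sum,
            "lfc_clamped": clamped & tested,
            "contrast": label,
        }
    )
    return apply_de_filters(out, return_all=True)


def apply_de_filters(
    results: pd.DataFrame,
    q_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    count_sum_thresh: float = 1.0,
    require: str = "none",
    return_all: bool = False,
) -> pd.DataFrame:
    """Set the candidate and biological-significance flags; optionally filter.

    ``sig_candidate`` is Bonferroni Q < q_thresh; ``bio_flag`` is
    |log2FC| > lfc_thresh with normalized count sum > count_sum_thresh.
    ``require`` is one of "none", "sig", "bio", "both".
    """
    if results["contrast"].nunique() > 1:
        raise ValueError("apply_de_filters expects results from a single contrast")
    out = results.copy()
    out["sig_candidate"] = out["qvalue_bonferroni"] < q_thresh
    out["bio_flag"] = (out["log2FC"].abs() > lfc_thresh) & (
        out["count_sum"] > count_sum_thresh
    )
    if return_all or require == "none":
        return out
    if require == "sig":
        return out[out["sig_candidate"]]
    if require == "bio":
        return out[out["bio_flag"]]
    if require == "both":
        return out[out["sig_candidate"] & out["bio_flag"]]
    raise ValueError(f"unknown require mode {require!r}")


# ---------------------------------------------------------------------------
# PCA summary and qPCR helper
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    variance_fractions: np.ndarray  # one per component, sums to 1
    cumulative: np.ndarray
    scores: pd.DataFrame  # samples x components


def pca_summary(
    cm: CountMatrix, sf: SizeFactors, n_components: int = 3
) -> PCAResult:
    """Sample-space PCA of log2(normalized count + 1), feature-centred.

    log2(x + 1) stands in for a regularized-log variance stabilization; the
    contract reported here is the per-component variance fraction (summing to
    one over all components) and the sample scores.
    """
    if cm.counts.shape[1] < 3:
        raise ValueError("PCA summary needs at least 3 samples")
    x = np.log2(normalized_counts(cm, sf).to_numpy() + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # centre each feature
    if np.allclose(x, 0.0):
        raise ValueError("zero-variance matrix: PCA undefined")
    # samples in rows
    u, sv, _ = np.linalg.svd(x.T, full_matrices=False)
    var = sv**2
    fractions = var / var.sum()
    k = min(n_components, len(sv))
    scores = pd.DataFrame(
        u[:, :k] * sv[:k],
        index=cm.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(
        variance_fractions=fractions,
        cumulative=np.cumsum(fractions),
        scores=scores,
    )


def ddct_fold_change(
    ct_target: pd.Series,
    ct_reference: pd.Series,
    groups: pd.Series,
    control_group: str,
) -> pd.Series:
    """Relative qPCR quantification by the 2^-ddCt method.

    dCt_s = Ct_target,s - Ct_reference,s; ddCt_s = dCt_s - mean(dCt over the
    control group); fold = 2^-ddCt.
    """
    ct_target = pd.Series(ct_target)
    ct_reference = pd.Series(ct_reference).reindex(ct_target.index)
    groups = pd.Series(groups).reindex(ct_target.index)
    if ct_reference.isna().any():
        missing = list(ct_reference[ct_reference.isna()].index)
        raise ValueError(f"reference gene not measured in samples: {missing}")
    control = groups == control_group
    if not control.any():
        raise ValueError(f"control group {control_group!r} absent from samples")
    dct = ct_target - ct_reference
    ddct = dct - dct[control].mean()
    return (2.0 ** (-ddct)).rename("fold_change")
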