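"""Negative-binomial differential expression for count matrices.

The stage mirrors the standard bulk RNA-seq workflow: median-of-ratios
size-factor normalization, per-feature dispersion estimation with shrinkage
toward a mean-dispersion trend, a per-feature NB GLM Wald test (log link,
two-level design, IRLS), Benjamini-Hochberg FDR, and the calling rule used
throughout the pipeline: FDR < 0.05 and a mean expression change of more
than 50 percent, i.e. |log2 fold change| > log2(1.5). A sample-level QC
filter removes samples with fewer than one million assigned reads, and a
simple variance-stabilizing transform is provided for heatmap display.

Model
-----
Counts K_ij ~ NB(mu_ij, alpha_i) with Var = mu + alpha * mu^2 and
mu_ij = s_j * exp(x_j' beta_i), where s_j are size factors and x_j encodes
the two-level case-vs-control design. The Wald statistic is the case
coefficient divided by its standard error from the observed Fisher
information; two-sided p-values use the standard normal reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter_samples",
    "size_factors",
    "estimate_dispersions",
    "wald_test",
    "call_de",
    "vst",
    "DECall",
]

#: columns of a differential-expression result table
DE_COLUMNS = ["feature_id", "base_mean", "lfc", "se", "wald", "pvalue", "fdr"]

LOG2_150PCT = np.log2(1.5)


# ---------------------------------------------------------------------------
# sample QC


def qc_filter_samples(
    matrix: CountMatrix,
    sheet: SampleSheet,
    min_assigned: int = 1_000_000,
) -> tuple[CountMatrix, SampleSheet, list[str]]:
    """Drop samples with fewer than ``min_assigned`` assigned reads.

    The threshold is a strict "less than": a sample with exactly
    ``min_assigned`` reads is retained. Returns the filtered matrix and
    sheet plus the list of excluded sample ids.

    Raises
    ------
    ValueError
        If all samples are removed or fewer than two samples remain in
        either condition.
    """
    tab = sheet.table
    excluded = list(tab.loc[tab["assigned_reads"] < min_assigned, "sample_id"])
    keep = [s for s in matrix.sample_ids if s not in set(excluded)]
    if excluded:
        logger.info("qc_filter_samples: excluded %d samples: %s", len(excluded), excluded)
    if not keep:
        raise ValueError(f"all {len(excluded)} samples fall below {min_assigned} assigned reads")
    kept_sheet = sheet.subset(keep)
    counts_per_cond = kept_sheet.table["condition"].value_counts()
    if len(counts_per_cond) < 2 or (counts_per_cond < 2).any():
        raise ValueError(
            "fewer than 2 samples per condition remain after read-count QC: "
            f"{counts_per_cond.to_dict()}"
        )
    return matrix.subset_samples(keep), kept_sheet, excluded


# ---------------------------------------------------------------------------
# normalization


def size_factors(matrix: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, s_j is the median over features (restricted to
    features with a positive geometric mean across samples) of
    K_ij / geomean_i(K_i.).
    """
    counts = matrix.counts.astype(float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    # geometric mean per feature; -inf rows (any zero) are excluded
    log_geo = log_counts.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError(
            "no feature is expressed in every sample; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    log_ratios = log_counts[usable] - log_geo[usable, None]
    log_sf = np.median(log_ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return np.exp(log_sf)


def vst(matrix: CountMatrix, sf: np.ndarray) -> pd.DataFrame:
    """log2(normalized count + 4): a VST surrogate for heatmap display only."""
    q = matrix.counts / np.asarray(sf)[None, :]
    return pd.DataFrame(np.log2(q + 4.0), index=matrix.feature_ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# dispersion estimation

_ALPHA_FLOOR = 1e-8
_SHRINK_N0 = 4.0  # prior weight in the dispersion shrinkage


def estimate_dispersions(
    matrix: CountMatrix,
    sf: np.ndarray,
    conditions: np.ndarray,
) -> np.ndarray:
    """Per-feature NB dispersion with shrinkage toward a fitted trend.

    A method-of-moments estimate is formed from normalized counts within
    conditions: with v the df-pooled within-condition variance and mu the
    within-condition means, alpha_hat = max(0, (v - mu) / mu^2). A smooth
    trend alpha_tr(mu) = a1/mu + a0 is fitted by least squares to the
    positive estimates, and the final value is the geometric combination
    exp(w log alpha_hat + (1-w) log alpha_tr), floored at 1e-8.

    The weight w is set empirically (empirical Bayes): the spread of
    log alpha_hat around the trend in excess of its chi-square sampling
    variance estimates how much dispersions truly vary between features,
    and w = prior_var / (prior_var + sampling_var), capped at
    n_eff / (n_eff + n0) with n_eff the residual degrees of freedom and
    n0 = 4. When the observed spread is explained by sampling noise alone
    the estimates collapse onto the trend, which keeps the Wald test
    calibrated at small n.
    """
    conditions = np.asarray(conditions)
    levels = pd.unique(conditions)
    if len(levels) < 2:
        raise ValueError("dispersion estimation requires >= 2 conditions")
    for lev in levels:
        if (conditions == lev).sum() < 2:
            raise ValueError(f"condition {lev!r} has < 2 samples")

    q = matrix.counts / np.asarray(sf)[None, :]
    n_features = q.shape[0]
    ss = np.zeros(n_features)  # pooled within-condition sum of squares
    msq = np.zeros(n_features)  # df-weighted squared group means
    df_total = 0.0
    mu_overall = q.mean(axis=1)
    for lev in levels:
        sub = q[:, conditions == lev]
        df_g = sub.shape[1] - 1
        m_g = sub.mean(axis=1)
        ss += ((sub - m_g[:, None]) ** 2).sum(axis=1)
        msq += df_g * m_g**2
        df_total += df_g
    v_pool = ss / df_total
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (v_pool - mu_overall) / (msq / df_total)
    alpha_hat = np.where(mu_overall > 0, np.maximum(alpha_hat, 0.0), 0.0)

    alpha_trend = _fit_trend(mu_overall, alpha_hat)

    n_eff = len(conditions) - len(levels)
    w_cap = n_eff / (n_eff + _SHRINK_N0)
    sampling_var = float(polygamma(1, df_total / 2.0))
    pos = alpha_hat > 0
    if pos.sum() >= 10:
        resid = np.log(alpha_hat[pos]) - np.log(np.maximum(alpha_trend[pos], _ALPHA_FLOOR))
        mad = np.median(np.abs(resid - np.median(resid)))
        spread = (1.4826 * mad) ** 2
        prior_var = max(spread - sampling_var, 0.0)
        w = min(w_cap, prior_var / (prior_var + sampling_var))
    else:
        w = w_cap
    log_hat = np.log(np.maximum(alpha_hat, _ALPHA_FLOOR))
    log_tr = np.log(np.maximum(alpha_trend, _ALPHA_FLOOR))
    alpha = np.exp(w * log_hat + (1.0 - w) * log_tr)
    return np.maximum(alpha, _ALPHA_FLOOR)


def _fit_trend(mu: np.ndarray, alpha_hat: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha_tr(mu) = a1/mu + a0 on positive estimates."""
    ok = (alpha_hat > 0) & (mu > 0)
    if ok.sum() < 2:
        # too few informative features: flat fallback at the mean estimate
        a0 = float(alpha_hat[ok].mean()) if ok.any() else _ALPHA_FLOOR
        return np.full_like(mu, max(a0, _ALPHA_FLOOR))
    X = np.column_stack([1.0 / mu[ok], np.ones(ok.sum())])
    coef, *_ = np.linalg.lstsq(X, alpha_hat[ok], rcond=None)
    a1, a0 = max(coef[0], 0.0), max(coef[1], _ALPHA_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        trend = np.where(mu > 0, a1 / mu + a0, a0)
    return trend


# ---------------------------------------------------------------------------
# Wald test

_MAX_IRLS_ITER = 100
_IRLS_TOL = 1e-8
_BETA_BOUND = 30.0


def wald_test(
    matrix: CountMatrix,
    sheet: SampleSheet,
    control: str | None = None,
    case: str | None = None,
    sf: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
) -> pd.DataFrame:
    """NB GLM Wald test of case vs control for every feature.

    Returns a DataFrame with columns feature_id, base_mean, lfc, se, wald,
    pvalue, fdr. ``lfc`` is the log2 fold change case/control. Features with
    all-zero counts are reported with lfc undefined (NaN) and p = 1, and are
    excluded from the BH adjustment. Features whose IRLS fit does not
    converge within 100 iterations are flagged the same way and logged.
    """
    tab = sheet.table.set_index("sample_id").loc[matrix.sample_ids]
    conditions = tab["condition"].to_numpy()
    control, case = _resolve_levels(conditions, control, case)
    x = (conditions == case).astype(float)

    if sf is None:
        sf = size_factors(matrix)
    sf = np.asarray(sf, dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersions(matrix, sf, conditions)
    alpha = np.asarray(dispersions, dtype=float)

    y = matrix.counts.astype(float)
    base_mean = (y / sf[None, :]).mean(axis=1)
    tested = y.sum(axis=1) > 0

    b0, b1, se_b1, converged = _irls_two_group(y, sf, x, alpha)

    lfc = np.where(tested, b1 / np.log(2.0), np.nan)
    se = np.where(tested, se_b1 / np.log(2.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    pvalue = np.where(
        tested & converged & np.isfinite(wald),
        2.0 * stats.norm.sf(np.abs(np.nan_to_num(wald))),
        1.0,
    )
    n_flagged = int((tested & ~converged).sum())
    if n_flagged:
        logger.warning("wald_test: %d features failed to converge; p set to 1", n_flagged)

    fdr = np.ones(len(pvalue))
    test_mask = tested & converged & np.isfinite(wald)
    if test_mask.any():
        fdr[test_mask] = multipletests(pvalue[test_mask], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "base_mean": base_mean,
            "lfc": lfc,
            "se": se,
            "wald": wald,
            "pvalue": pvalue,
            "fdr": fdr,
        }
    )


def _resolve_levels(conditions, control, case) -> tuple[str, str]:
    levels = sorted(pd.unique(conditions))
    if len(levels) != 2:
        raise ValueError(f"design must have exactly two condition levels, got {levels}")
    if control is None and case is None:
        for guess in ("control", "ctrl", "healthy", "vehicle"):
            if guess in levels:
                control = guess
                break
        else:
            control = levels[0]
    if control is None:
        control = next(l for l in levels if l != case)
    if case is None:
        case = next(l for l in levels if l != control)
    if {control, case} != set(levels):
        raise ValueError(f"control={control!r}/case={case!r} do not match levels {levels}")
    return control, case


def _irls_two_group(
    y: np.ndarray, sf: np.ndarray, x: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for the NB GLM with log link and a binary covariate.

    Fits mu_ij = s_j exp(b0_i + b1_i x_j) per feature; returns coefficient
    arrays, the Wald standard error of b1 from the Fisher information, and a
    convergence flag.
    """
    n_features = y.shape[0]
    is_case = x == 1.0
    # moment initialization on normalized counts with a half-count pseudocount
    q = y / sf[None, :]
    m_ctrl = q[:, ~is_case].mean(axis=1) + 0.5
    m_case = q[:, is_case].mean(axis=1) + 0.5
    b0 = np.log(m_ctrl)
    b1 = np.log(m_case) - np.log(m_ctrl)

    converged = np.zeros(n_features, dtype=bool)
    active = np.ones(n_features, dtype=bool)
    for _ in range(_MAX_IRLS_ITER):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * x[None, :]
        mu = sf[None, :] * np.exp(np.clip(eta, -_BETA_BOUND, _BETA_BOUND))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta + (y - mu) / np.maximum(mu, 1e-300)
        sw = w.sum(axis=1)
        swx = w[:, is_case].sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w[:, is_case] * z[:, is_case]).sum(axis=1)
        det = swx * (sw - swx)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_b1 = (sw * swxz - swx * swz) / det
            new_b0 = (swz - swx * new_b1) / sw
        bad = ~np.isfinite(new_b1) | ~np.isfinite(new_b0)
        new_b1 = np.where(bad, b1, new_b1)
        new_b0 = np.where(bad, b0, new_b0)
        new_b0 = np.clip(new_b0, -_BETA_BOUND, _BETA_BOUND)
        new_b1 = np.clip(new_b1, -_BETA_BOUND, _BETA_BOUND)
        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        newly = active & (delta < _IRLS_TOL)
        converged |= newly
        active &= ~newly

    eta = b0[:, None] + b1[:, None] * x[None, :]
    mu = sf[None, :] * np.exp(np.clip(eta, -_BETA_BOUND, _BETA_BOUND))
    w = mu / (1.0 + alpha[:, None] * mu)
    sw_case = w[:, is_case].sum(axis=1)
    sw_ctrl = w[:, ~is_case].sum(axis=1)
    with np.errstate(divide="ignore"):
        var_b1 = 1.0 / sw_case + 1.0 / sw_ctrl
    se_b1 = np.sqrt(var_b1)
    return b0, b1, se_b1, converged


# ---------------------------------------------------------------------------
# calling


@dataclass
class DECall:
    """Differentially expressed feature sets split by direction."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    @property
    def all(self) -> set[str]:
        return self.up | self.down


def call_de(results: pd.DataFrame, alpha: float = 0.05, min_change: float = 0.5) -> DECall:
    """Select features with fdr < alpha and |lfc| > log2(1 + min_change).

    Both inequalities are strict: a feature at fdr exactly alpha, or at a
    fold change of exactly 1 + min_change, is not called.
    """
    bound = np.log2(1.0 + min_change)
    lfc = results["lfc"]
    sel = (results["fdr"] < alpha) & (lfc.abs() > bound) & lfc.notna()
    up = set(results.loc[sel & (lfc > 0), "feature_id"])
    down = set(results.loc[sel & (lfc < 0), "feature_id"])
    return DECall(up=up, down=down)
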