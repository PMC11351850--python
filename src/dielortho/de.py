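"""Per-species day-vs-night differential expression on NB counts.

Two method flavors are provided, mirroring the common exact-test and
GLM/Wald-test approaches to two-group count comparisons:

* ``exact`` — condition on the per-gene grand total after rescaling samples to
  a common effective library size, and sum the probabilities of all splits at
  least as extreme as the observed one under a negative-binomial model with
  equal group means;
* ``wald`` — per-gene NB log-linear model with a night indicator fitted by
  IRLS, normal-tail p-value on the coefficient.

The fold-change sign convention is night-over-day: positive log2fc means
night overexpression.  Normalization factors here are absolute per-sample
size factors (normalized counts = counts / factor); the TMM flavor builds
them from trimmed mean M-values and rescales to product 1, the median-ratio
flavor is the classic median-of-ratios-to-geometric-mean estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

LN2 = np.log(2.0)


@dataclass
class NormFactors:
    factors: np.ndarray  # per-sample, positive
    method: str  # "tmm" or "median_ratio"

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Trimmed-mean-of-M-values size factors (product rescaled to 1).

    The reference sample is the column whose 75th percentile of
    counts-per-total is closest to the mean of those percentiles.  Per sample,
    the factor is 2**(precision-weighted mean of M = log2(count/ref count)),
    after trimming ``trim_m`` of the M distribution and ``trim_a`` of the A
    (average log abundance) distribution, over genes nonzero in both.

    sklearn conventions: X is samples x genes; ``transform`` divides each
    sample by its factor.
    """

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05):
        self.trim_m = trim_m
        self.trim_a = trim_a

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("TMM requires at least 2 samples")
        if not X.any():
            raise ValueError("TMM requires some nonzero counts")
        totals = X.sum(axis=1)
        q75 = np.array(
            [np.percentile(row / tot, 75) if tot > 0 else 0.0 for row, tot in zip(X, totals)]
        )
        self.reference_ = int(np.argmin(np.abs(q75 - q75.mean())))
        ref = X[self.reference_]

        log_factors = np.zeros(X.shape[0])
        for s in range(X.shape[0]):
            if s == self.reference_:
                continue
            both = (X[s] > 0) & (ref > 0)
            if not both.any():
                warnings.warn(
                    f"sample {s} shares no nonzero gene with the reference; factor set to 1"
                )
                continue
            y_s, y_r = X[s, both], ref[both]
            m = np.log2(y_s / y_r)
            a = 0.5 * np.log2(y_s * y_r)
            keep = _double_trim(m, a, self.trim_m, self.trim_a)
            if not keep.any():
                keep = np.ones_like(m, dtype=bool)
            # delta-method precision weights on the M-values
            w = 1.0 / (1.0 / y_s[keep] + 1.0 / y_r[keep])
            log_factors[s] = np.average(m[keep], weights=w)
        log_factors -= log_factors.mean()  # product of factors = 1
        self.factors_ = 2.0**log_factors
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) / self.factors_[:, None]


def _double_trim(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Keep genes inside both the central (1-2*trim) spans of M and A."""
    n = len(m)
    keep = np.ones(n, dtype=bool)
    for vals, frac in ((m, trim_m), (a, trim_a)):
        k = int(np.floor(n * frac))
        if k > 0:
            order = np.argsort(vals, kind="stable")
            keep[order[:k]] = False
            keep[order[n - k :]] = False
    return keep


class MedianRatioNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios size factors: factor_s = median over genes of
    count[g, s] / geometric mean over samples of count[g, .], using only genes
    nonzero in every sample.  Falls back to TMM (with a warning) when no gene
    is nonzero everywhere."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        all_nonzero = (X > 0).all(axis=0)
        if not all_nonzero.any():
            warnings.warn("no gene nonzero in all samples; falling back to TMM factors")
            self.factors_ = TMMNormalizer().fit(X).factors_
            return self
        sub = X[:, all_nonzero]
        log_geomean = np.mean(np.log(sub), axis=0)
        self.factors_ = np.exp(np.median(np.log(sub) - log_geomean, axis=1))
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) / self.factors_[:, None]


def normalize_tmm(m: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    est = TMMNormalizer(trim_m=trim_m, trim_a=trim_a).fit(m.counts.T)
    return NormFactors(factors=est.factors_, method="tmm")


def normalize_median_ratio(m: CountMatrix) -> NormFactors:
    est = MedianRatioNormalizer().fit(m.counts.T)
    return NormFactors(factors=est.factors_, method="median_ratio")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    m: CountMatrix,
    factors: NormFactors,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Per-gene NB dispersion phi (variance = mu + phi * mu^2).

    Method-of-moments estimates on normalized counts, pooled within diel
    groups, shrunk toward a lowess trend of phi on log mean with weights
    df / (df + prior_df).
    """
    night = np.array([s.diel_phase == "night" for s in m.samples])
    return _dispersion_from_arrays(m.counts, factors.factors, night, prior_df)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x)


def _nb_group_logpmf(t: np.ndarray, mean: float, size: float) -> np.ndarray:
    """log P(sum of group counts = t) for an NB group sum (NB sizes add)."""
    if not np.isfinite(size):  # Poisson limit
        return t * np.log(mean) - mean - gammaln(t + 1.0)
    logp = size * np.log(size / (size + mean)) + t * np.log(mean / (size + mean))
    return gammaln(t + size) - gammaln(size) - gammaln(t + 1.0) + logp


def exact_test_log_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Natural-log two-sided conditional exact p-value for group totals
    (y_a, y_b) from n_a and n_b equal-library samples under NB with equal
    means, computed entirely in log space so extreme splits keep their
    ordering instead of underflowing to 0.

    Sums the probabilities of every split of the grand total whose probability
    does not exceed the observed split's.
    """
    total = y_a + y_b
    if total == 0:
        return 0.0
    mu = total / (n_a + n_b)
    size_a = n_a / phi if phi > 0 else np.inf
    size_b = n_b / phi if phi > 0 else np.inf
    t = np.arange(total + 1)
    logp = _nb_group_logpmf(t, n_a * mu, size_a) + _nb_group_logpmf(
        (total - t).astype(float), n_b * mu, size_b
    )
    logp -= logsumexp(logp)  # condition on the grand total
    obs = logp[y_a]
    tail = logp[logp <= obs + 1e-9]
    return float(min(0.0, logsumexp(tail)))


def exact_test_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value (see exact_test_log_pvalue)."""
    return float(np.exp(exact_test_log_pvalue(y_a, y_b, n_a, n_b, phi)))


class NBDifferentialExpression(BaseEstimator):
    """Two-group NB differential expression (scikit-learn style).

    Parameters
    ----------
    method : "exact" or "wald"
    alpha, lfc_min : significance thresholds (BH-adjusted p < alpha and
        |log2fc| >= lfc_min).
    prior_df : shrinkage strength for the dispersion trend.
    normalizer : "tmm" or "median_ratio".

    ``fit(X, y)`` takes X as samples x genes (raw integer counts) and y as the
    phase label per sample ("day"/"night" or 0/1 with 1 = night).  Fitted
    attributes: ``results_`` (per-gene DataFrame), ``factors_``,
    ``dispersion_``.
    """

    def __init__(
        self,
        method: str = "exact",
        alpha: float = 0.05,
        lfc_min: float = 2.0,
        prior_df: float = 10.0,
        normalizer: str = "tmm",
    ):
        self.method = method
        self.alpha = alpha
        self.lfc_min = lfc_min
        self.prior_df = prior_df
        self.normalizer = normalizer

    def fit(self, X, y, gene_ids=None, dispersion=None, factors=None):
        X = np.asarray(X)
        y = np.asarray(y)
        if self.method not in ("exact", "wald"):
            raise ValueError("method must be 'exact' or 'wald'")
        night = np.isin(y, ["night", 1, "1", True])
        day = ~night
        if night.sum() == 0 or day.sum() == 0:
            raise ValueError("both day and night groups must be non-empty")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[1])]

        if factors is None:
            norm_est = TMMNormalizer() if self.normalizer == "tmm" else MedianRatioNormalizer()
            factors = norm_est.fit(X).factors_
        factors = np.asarray(factors, dtype=float)
        self.factors_ = factors

        z = X / factors[:, None]  # samples x genes, normalized
        if dispersion is None:
            dispersion = _dispersion_from_arrays(X.T, factors, night, self.prior_df)
        dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float), (X.shape[1],))
        self.dispersion_ = dispersion

        mean_night = z[night].mean(axis=0)
        mean_day = z[day].mean(axis=0)
        log2fc = np.log2((mean_night + 0.5) / (mean_day + 0.5))
        mean_expr = z.mean(axis=0)

        if self.method == "exact":
            pseudo = _round_half_even(z).astype(np.int64)
            ya = pseudo[night].sum(axis=0)
            yb = pseudo[day].sum(axis=0)
            log_p = np.array(
                [
                    exact_test_log_pvalue(int(a), int(b), int(night.sum()), int(day.sum()), phi)
                    for a, b, phi in zip(ya, yb, dispersion)
                ]
            )
            flags = np.zeros(X.shape[1], dtype=bool)
        else:
            coef, se, converged = _wald_irls(X.T, factors, night, dispersion)
            with np.errstate(invalid="ignore", divide="ignore"):
                zstat = np.where(se > 0, coef / se, 0.0)
            log_p = LN2 + norm.logsf(np.abs(zstat))  # log(2 * upper tail)
            log_p = np.minimum(log_p, 0.0)
            log_p = np.where(converged, log_p, 0.0)
            all_zero = X.sum(axis=0) == 0
            log_p = np.where(all_zero, 0.0, log_p)
            log2fc = np.where(all_zero, 0.0, coef / LN2)
            flags = ~converged

        log_adj_p = adjust_bh_log(log_p)
        p = np.exp(log_p)
        adj_p = np.exp(log_adj_p)
        self.results_ = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "log2fc": log2fc,
                "mean_expr": mean_expr,
                "p": p,
                "adj_p": adj_p,
                "log10_adj_p": log_adj_p / np.log(10.0),
                "method": self.method,
                "significant": (adj_p < self.alpha) & (np.abs(log2fc) >= self.lfc_min),
                "nonconverged": flags,
            }
        )
        return self

    def predict(self, X=None):
        """Significant flags from the fitted results."""
        return self.results_["significant"].to_numpy()


def _dispersion_from_arrays(counts_gxs, factors, night, prior_df, trend_cap_q=0.99):
    """Per-group method-of-moments phi pooled across groups (df-weighted), so
    differentially expressed genes are not inflated by the between-group mean
    difference; lowess trend (non-robust, so it tracks the conditional mean of
    the skewed estimator) with df/(df + prior_df) shrinkage."""
    z = counts_gxs / factors[None, :]
    groups = [np.flatnonzero(night), np.flatnonzero(~night)]
    df = sum(max(len(g) - 1, 0) for g in groups)
    grand_mean = z.mean(axis=1)
    # trend abscissa: geometric mean of the group means — for null genes this
    # is the grand mean, while strongly DE genes are placed at their baseline
    # abundance instead of between their two group means
    gmeans = [z[:, g].mean(axis=1) for g in groups if len(g) > 0]
    abscissa = np.sqrt(np.prod(np.clip(gmeans, 1e-8, None), axis=0)) if gmeans else grand_mean
    abscissa = np.where(grand_mean > 0, abscissa, 0.0)
    if df < 1:
        warnings.warn("fewer than 2 replicates in every group; using trend-only dispersions")
        raw = np.zeros(counts_gxs.shape[0])
    else:
        # pooled within-group variance over a (debiased) mean of squared group
        # means: unbiased under group mean differences, unlike dividing by the
        # grand mean, which inflates phi for strongly DE genes
        num = np.zeros(counts_gxs.shape[0])
        den = np.zeros(counts_gxs.shape[0])
        mean_sq = np.zeros(counts_gxs.shape[0])
        for g in groups:
            if len(g) < 2:
                continue
            gmean = z[:, g].mean(axis=1)
            gvar = z[:, g].var(axis=1, ddof=1)
            num += gvar * (len(g) - 1)
            den += gmean * (len(g) - 1)
            # E[m^2] = mu^2 + var/n, so subtract the plug-in correction
            mean_sq += np.clip(gmean**2 - gvar / len(g), 0.0, None) * (len(g) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(mean_sq > 0, (num - den) / mean_sq, 0.0)
        raw = np.clip(raw, 0.0, None)
    positive = grand_mean > 0
    trend = np.full_like(grand_mean, 1e-8)
    if positive.sum() >= 10:
        # iterated capped fit: plain lowess first (non-robust, since the raw
        # estimator is right-skewed and a robust fit would chase its median,
        # not its mean), then cap raw values at a chi-square-quantile multiple
        # of the local trend and refit, so a minority of genuinely
        # hyper-variable genes cannot drag the trend for their neighbours
        x = np.log(abscissa[positive])
        vals = raw[positive]
        fitted = lowess(vals, x, frac=0.5, it=0, return_sorted=False)
        cap_factor = float(chi2.ppf(trend_cap_q, df) / df) if df > 0 else np.inf
        for _ in range(2):
            cap = np.clip(fitted, 1e-8, None) * cap_factor
            fitted = lowess(np.minimum(vals, cap), x, frac=0.5, it=0, return_sorted=False)
        trend[positive] = np.clip(fitted, 1e-8, None)
    elif positive.any():
        trend[positive] = max(float(np.mean(raw[positive])), 1e-8)
    w = df / (df + prior_df)
    return np.clip(w * raw + (1.0 - w) * trend, 1e-8, None)


def _wald_irls(
    counts_gxs: np.ndarray,
    factors: np.ndarray,
    night: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for the per-gene model log mu = offset + b0 + b1*night.

    Genes with an all-zero group use counts + 0.5 (documented separation
    fallback giving a finite estimate).  Returns (b1, se(b1), converged).
    """
    G = counts_gxs.shape[0]
    x = night.astype(float)
    offset = np.log(factors)

    y = counts_gxs.astype(float)
    night_sum = y[:, night].sum(axis=1)
    day_sum = y[:, ~night].sum(axis=1)
    nonzero = (night_sum + day_sum) > 0
    separated = nonzero & ((night_sum == 0) | (day_sum == 0))
    y = np.where(separated[:, None], y + 0.5, y)

    mu = y + 0.5
    eta = np.log(mu)
    b0 = np.zeros(G)
    b1 = np.zeros(G)
    # initialize from group means of normalized counts
    z0 = y / factors[None, :]
    m_day = z0[:, ~night].mean(axis=1)
    m_night = z0[:, night].mean(axis=1)
    b0 = np.log(np.maximum(m_day, 1e-8))
    b1 = np.log(np.maximum(m_night, 1e-8)) - b0

    converged = np.zeros(G, dtype=bool)
    active = nonzero.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)
        zwork = eta - offset[None, :] + (y - mu) / mu

        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = swx  # x is 0/1 so x^2 = x
        swz = (w * zwork).sum(axis=1)
        swxz = (w * x[None, :] * zwork).sum(axis=1)
        det = sw * swxx - swx**2
        ok = det > 1e-12
        new_b0 = np.where(ok, (swxx * swz - swx * swxz) / np.where(ok, det, 1.0), b0)
        new_b1 = np.where(ok, (sw * swxz - swx * swz) / np.where(ok, det, 1.0), b1)
        delta = np.abs(new_b0 - b0) + np.abs(new_b1 - b1)
        b0 = np.where(active, new_b0, b0)
        b1 = np.where(active, new_b1, b1)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly

    eta = offset[None, :] + b0[:, None] + b1[:, None] * x[None, :]
    eta = np.clip(eta, -50, 50)
    mu = np.exp(eta)
    w = mu / (1.0 + phi[:, None] * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    det = sw * swx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = np.where(det > 1e-12, sw / det, np.inf)
    se = np.sqrt(var_b1)
    converged = converged | ~nonzero  # all-zero genes are reported, not flagged
    return b1, se, converged


# ---------------------------------------------------------------------------
# functional wrappers (spec operation surface)
# ---------------------------------------------------------------------------

def _run_test(
    m: CountMatrix, factors: NormFactors, phi: np.ndarray, method: str, **kw
) -> pd.DataFrame:
    phases = np.array([s.diel_phase for s in m.samples])
    est = NBDifferentialExpression(method=method, **kw)
    est.fit(
        m.counts.T,
        phases,
        gene_ids=m.gene_ids,
        dispersion=phi,
        factors=factors.factors,
    )
    return est.results_


def exact_test(m: CountMatrix, factors: NormFactors, phi: np.ndarray, **kw) -> pd.DataFrame:
    return _run_test(m, factors, phi, "exact", **kw)


def wald_test(m: CountMatrix, factors: NormFactors, phi: np.ndarray, **kw) -> pd.DataFrame:
    return _run_test(m, factors, phi, "wald", **kw)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_bh_log(log_p) -> np.ndarray:
    """BH step-up on natural-log p-values, entirely in log space (order
    preserved, capped at log 1 = 0); keeps extreme p-values distinguishable."""
    log_p = np.asarray(log_p, dtype=float)
    m = log_p.size
    if m == 0:
        return log_p
    order = np.argsort(log_p, kind="stable")
    adj = log_p[order] + np.log(m) - np.log(np.arange(1, m + 1))
    adj = np.minimum.accumulate(adj[::-1])[::-1]  # min over j >= i
    adj = np.minimum(adj, 0.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_significant(
    results: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 2.0
) -> pd.DataFrame:
    """(Re)flag significance: BH-adjusted p < alpha and |log2fc| >= lfc_min."""
    out = results.copy()
    out["significant"] = (out["adj_p"] < alpha) & (out["log2fc"].abs() >= lfc_min)
    return out


def select_stratum(results: pd.DataFrame, window: str) -> pd.DataFrame:
    """One-sided fold-change strata over significant genes, e.g. "<=-5",
    ">=5", ">=2" (log2 units)."""
    sig = results[results["significant"]]
    op = window[:2]
    val = float(window[2:])
    if op == "<=":
        return sig[sig["log2fc"] <= val]
    if op == ">=":
        return sig[sig["log2fc"] >= val]
    raise ValueError(f"window must start with '<=' or '>=': {window!r}")


def method_consensus(a: pd.DataFrame, b: pd.DataFrame) -> tuple[set[str], dict[str, int]]:
    """Genes significant under both methods, with the set sizes report."""
    sa = set(a.loc[a["significant"], "gene_id"])
    sb = set(b.loc[b["significant"], "gene_id"])
    shared = sa & sb
    return shared, {"n_a": len(sa), "n_b": len(sb), "n_shared": len(shared)}
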