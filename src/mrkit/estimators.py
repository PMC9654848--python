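"""Causal-effect estimators for two-sample Mendelian randomization.

Given k harmonized instruments with SNP-exposure effects ``beta_exp_j``
(SE ``se_exp_j``) and SNP-outcome effects ``beta_out_j`` (SE ``se_out_j``),
the estimators implemented here are:

* **Wald ratio** — the per-SNP estimate ``beta_out_j / beta_exp_j`` with
  first-order SE ``se_out_j / |beta_exp_j|``.
* **IVW** (inverse-variance weighted) — the weighted average of Wald
  ratios, equivalently weighted least squares of ``beta_out`` on
  ``beta_exp`` through the origin with weights ``1/se_out²``.  SEs use a
  multiplicative random-effects model: the residual scale
  ``sigma = sqrt(Q / (k - 1))`` is floored at 1, so the fixed-effect SE
  is inflated only when Cochran's Q exceeds its sampling expectation.
* **MR-Egger** — the same weighted regression with an unconstrained
  intercept, after orienting every instrument to ``beta_exp >= 0``.  A
  nonzero intercept indicates directional horizontal pleiotropy; the
  slope is a pleiotropy-robust causal estimate under the InSIDE
  assumption.  Inference uses t(k - 2) with the residual scale floored
  at 1.
* **Weighted median** — the inverse-variance-weighted median of Wald
  ratios, consistent when instruments carrying at least half the weight
  are valid; its SE comes from a parametric bootstrap.

Estimators are scikit-learn style: construct with hyper-parameters, call
``fit(instruments)``, read fitted attributes (``estimate_``, ``se_``,
``ci_low_``, ``ci_high_``, ``pval_`` ...).  Thin module-level functions
(:func:`ivw`, :func:`egger`, :func:`weighted_median`) wrap them for
one-shot use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import InsufficientInstrumentsError

#: Two-sided 95% normal quantile used for every confidence interval.
Z975 = 1.959964


@dataclass
class MrEstimate:
    """One method's causal-effect estimate with normal/t-based 95% CI."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    residual_scale: float = 1.0


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test across per-SNP causal estimates."""

    q_stat: float
    df: int
    pval: float


def _validate_instruments(X, min_snps: int, who: str):
    """Extract (ids, beta_exp, se_exp, beta_out, se_out) float arrays from a
    harmonized-instrument frame (or any mapping of array-likes)."""
    if isinstance(X, pd.DataFrame):
        frame = X
    else:
        frame = pd.DataFrame(X)
    required = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"instrument table lacks column(s) {missing}")
    k = len(frame)
    if k < min_snps:
        raise InsufficientInstrumentsError(f"{who} needs at least {min_snps} instruments; got {k}")
    ids = frame["snp_id"].to_numpy(dtype=object)
    arrs = [np.asarray(frame[c], dtype=float) for c in required[1:]]
    for name, arr in zip(required[1:], arrs):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    if np.any(arrs[1] <= 0) or np.any(arrs[3] <= 0):
        raise ValueError("standard errors must be positive")
    return (ids, *arrs)


def wald_ratios(instruments: pd.DataFrame, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP ratio estimates ``beta_out/beta_exp``.

    SEs are first-order (``se_out/|beta_exp|``) by default; the
    second-order delta-method correction adds the exposure uncertainty
    term ``beta_out² se_exp² / beta_exp⁴``.  SNPs with ``beta_exp == 0``
    are skipped.
    """
    ids, bx, sx, by, sy = _validate_instruments(instruments, 1, "wald_ratios")
    keep = bx != 0
    ids, bx, sx, by, sy = ids[keep], bx[keep], sx[keep], by[keep], sy[keep]
    est = by / bx
    var = sy**2 / bx**2
    if second_order:
        var = var + by**2 * sx**2 / bx**4
    return pd.DataFrame({"snp_id": ids, "estimate": est, "se": np.sqrt(var)})


def cochran_q(instruments: pd.DataFrame, estimate: float) -> HeterogeneityResult:
    """Cochran's Q about a given causal estimate:
    ``Q = sum((beta_out_j - estimate * beta_exp_j)² / se_out_j²)``,
    referred to chi-square with k - 1 degrees of freedom."""
    _, bx, _, by, sy = _validate_instruments(instruments, 2, "cochran_q")
    q = float(np.sum((by - estimate * bx) ** 2 / sy**2))
    df = len(bx) - 1
    return HeterogeneityResult(q_stat=q, df=df, pval=float(stats.chi2.sf(q, df)))


class IVW(BaseEstimator):
    """Inverse-variance-weighted estimator with multiplicative random effects.

    Parameters
    ----------
    random_effects : bool, default True
        Inflate the SE by ``max(1, sqrt(Q/(k-1)))``.  With False the
        fixed-effect SE is reported regardless of heterogeneity.

    Attributes
    ----------
    estimate_, se_, ci_low_, ci_high_, pval_ : float
    n_snps_ : int
    residual_scale_ : float
        The applied scale (1 when heterogeneity is at or below expectation).
    q_stat_, q_df_, q_pval_ : Cochran's Q about the IVW estimate.
    """

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y=None) -> "IVW":
        ids, bx, sx, by, sy = _validate_instruments(X, 2, "IVW")
        w = 1.0 / sy**2
        s_xy = float(np.sum(w * bx * by))
        s_xx = float(np.sum(w * bx**2))
        est = s_xy / s_xx
        k = len(bx)
        q = float(np.sum(w * (by - est * bx) ** 2))
        sigma = max(1.0, np.sqrt(q / (k - 1))) if self.random_effects else 1.0
        se = sigma / np.sqrt(s_xx)
        self.estimate_ = est
        self.se_ = float(se)
        self.ci_low_ = est - Z975 * self.se_
        self.ci_high_ = est + Z975 * self.se_
        self.pval_ = float(2.0 * stats.norm.sf(abs(est) / self.se_))
        self.n_snps_ = k
        self.residual_scale_ = float(sigma)
        self.q_stat_ = q
        self.q_df_ = k - 1
        self.q_pval_ = float(stats.chi2.sf(q, k - 1))
        self.snp_ids_ = list(ids)
        return self

    def to_result(self) -> MrEstimate:
        return MrEstimate("ivw", self.estimate_, self.se_, self.ci_low_, self.ci_high_,
                          self.pval_, self.n_snps_, self.residual_scale_)

    def heterogeneity(self) -> HeterogeneityResult:
        return HeterogeneityResult(self.q_stat_, self.q_df_, self.q_pval_)


class MREgger(BaseEstimator):
    """MR-Egger weighted regression with an unconstrained intercept.

    Instruments are first oriented so every ``beta_exp`` is nonnegative
    (the estimate is otherwise coding-dependent).  SEs use the residual
    scale ``sqrt(RSS/(k-2))`` floored at 1; p-values come from t(k - 2).

    Attributes
    ----------
    estimate_, se_, ci_low_, ci_high_, pval_ : slope (causal effect)
    intercept_, intercept_se_, intercept_ci_low_, intercept_ci_high_,
    intercept_pval_ : directional-pleiotropy test
    residual_scale_, n_snps_, q_stat_, q_df_, q_pval_
    """

    def fit(self, X, y=None) -> "MREgger":
        ids, bx, sx, by, sy = _validate_instruments(X, 3, "MR-Egger")
        flip = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * flip, by * flip
        w = 1.0 / sy**2
        design = np.column_stack([np.ones_like(bx), bx])
        xtwx = design.T @ (w[:, None] * design)
        xtwy = design.T @ (w * by)
        coef = np.linalg.solve(xtwx, xtwy)
        k = len(bx)
        resid = by - design @ coef
        rss = float(np.sum(w * resid**2))
        sigma2 = max(1.0, rss / (k - 2))
        cov = sigma2 * np.linalg.inv(xtwx)
        se = np.sqrt(np.diag(cov))
        tq = float(stats.t.ppf(0.975, k - 2))
        pvals = 2.0 * stats.t.sf(np.abs(coef) / se, k - 2)
        self.intercept_, self.estimate_ = map(float, coef)
        self.intercept_se_, self.se_ = map(float, se)
        self.ci_low_ = self.estimate_ - tq * self.se_
        self.ci_high_ = self.estimate_ + tq * self.se_
        self.intercept_ci_low_ = self.intercept_ - tq * self.intercept_se_
        self.intercept_ci_high_ = self.intercept_ + tq * self.intercept_se_
        self.intercept_pval_, self.pval_ = float(pvals[0]), float(pvals[1])
        self.n_snps_ = k
        self.residual_scale_ = float(np.sqrt(sigma2))
        self.q_stat_ = rss
        self.q_df_ = k - 2
        self.q_pval_ = float(stats.chi2.sf(rss, k - 2))
        self.snp_ids_ = list(ids)
        return self

    def to_results(self) -> tuple[MrEstimate, MrEstimate]:
        slope = MrEstimate("egger_slope", self.estimate_, self.se_, self.ci_low_,
                           self.ci_high_, self.pval_, self.n_snps_, self.residual_scale_)
        intercept = MrEstimate("egger_intercept", self.intercept_, self.intercept_se_,
                               self.intercept_ci_low_, self.intercept_ci_high_,
                               self.intercept_pval_, self.n_snps_, self.residual_scale_)
        return slope, intercept


class WeightedMedian(BaseEstimator):
    """Weighted median of Wald ratios with parametric-bootstrap SE.

    The point estimate sorts the per-SNP ratios ascending (ties broken by
    SNP id for determinism), forms standardized mid-cumulative weights
    ``s_j = (cum_j - w_j/2) / sum(w)`` with inverse-variance weights
    ``w_j = 1/se_ratio_j²``, and linearly interpolates the ratio at
    ``s = 0.5``.  The SE is the standard deviation of the estimate over
    ``n_boot`` parametric resamples of (beta_exp, beta_out) from normal
    distributions centred on the observations with their reported SEs;
    instruments are processed in sorted-SNP-id order so the bootstrap is
    invariant to input ordering.

    Parameters
    ----------
    n_boot : int, default 1000
    seed : int, default 42
    second_order : bool, default False
        Use second-order Wald-ratio SEs for the weights.
    """

    def __init__(self, n_boot: int = 1000, seed: int = 42, second_order: bool = False):
        self.n_boot = n_boot
        self.seed = seed
        self.second_order = second_order

    @staticmethod
    def _weighted_median(ratios: np.ndarray, weights: np.ndarray,
                         ids: np.ndarray | None = None) -> float:
        order = (np.lexsort((ids, ratios)) if ids is not None
                 else np.argsort(ratios, kind="stable"))
        r = ratios[order]
        w = weights[order]
        cum = np.cumsum(w)
        s = (cum - 0.5 * w) / cum[-1]
        return float(np.interp(0.5, s, r))

    def fit(self, X, y=None) -> "WeightedMedian":
        ids, bx, sx, by, sy = _validate_instruments(X, 3, "weighted median")
        order = np.argsort(ids.astype(str), kind="stable")
        ids, bx, sx, by, sy = ids[order], bx[order], sx[order], by[order], sy[order]
        if np.any(bx == 0):
            raise ValueError("beta_exp of 0 makes a Wald ratio undefined")

        def point(bx_, by_):
            est_ = by_ / bx_
            var = sy**2 / bx_**2
            if self.second_order:
                var = var + by_**2 * sx**2 / bx_**4
            return self._weighted_median(est_, 1.0 / var, ids.astype(str))

        est = point(bx, by)
        rng = np.random.default_rng(self.seed)
        k = len(bx)
        boot = np.empty(self.n_boot)
        for b in range(self.n_boot):
            boot[b] = point(bx + sx * rng.standard_normal(k),
                            by + sy * rng.standard_normal(k))
        se = float(np.std(boot, ddof=1))
        self.estimate_ = est
        self.se_ = se
        self.ci_low_ = est - Z975 * se
        self.ci_high_ = est + Z975 * se
        self.pval_ = float(2.0 * stats.norm.sf(abs(est) / se))
        self.n_snps_ = k
        self.residual_scale_ = 1.0
        self.snp_ids_ = list(ids)
        return self

    def to_result(self) -> MrEstimate:
        return MrEstimate("weighted_median", self.estimate_, self.se_, self.ci_low_,
                          self.ci_high_, self.pval_, self.n_snps_)


def ivw(instruments: pd.DataFrame, random_effects: bool = True
        ) -> tuple[MrEstimate, HeterogeneityResult]:
    """One-shot IVW fit returning (estimate, heterogeneity)."""
    model = IVW(random_effects=random_effects).fit(instruments)
    return model.to_result(), model.heterogeneity()


def egger(instruments: pd.DataFrame) -> tuple[MrEstimate, MrEstimate]:
    """One-shot MR-Egger fit returning (slope, intercept) estimates."""
    return MREgger().fit(instruments).to_results()


def weighted_median(instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 42,
                    second_order: bool = False) -> MrEstimate:
    """One-shot weighted-median fit."""
    return WeightedMedian(n_boot=n_boot, seed=seed,
                          second_order=second_order).fit(instruments).to_result()
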