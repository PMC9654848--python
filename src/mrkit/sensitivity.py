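"""Outlier and influence diagnostics for MR instrument sets.

Two complementary checks of the no-horizontal-pleiotropy assumption:

* **Leave-one-out (LOO)** refits IVW k times, each time dropping one
  instrument.  An instrument is flagged influential when its removal
  flips the sign of the causal estimate or moves its p-value across the
  significance level — i.e. when the overall conclusion hinges on that
  single SNP.
* **MR-PRESSO** (pleiotropy residual sum and outlier test) compares the
  observed weighted residual sum of squares about leave-one-out IVW
  predictions with its parametric-simulation null.  A significant global
  test indicates horizontal pleiotropy somewhere in the set; per-SNP
  residual p-values (Bonferroni-corrected) localize the outliers, and a
  distortion test asks whether removing them shifts the estimate more
  than removing a random subset of the same size would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .estimators import IVW, _validate_instruments

LOO_COLUMNS = ["snp_id", "estimate", "se", "ci_low", "ci_high", "pval", "flagged"]


@dataclass
class LooResult:
    """Leave-one-out table (one row per left-out SNP) plus the flag set."""

    table: pd.DataFrame
    flags: list[str]
    full_estimate: float
    full_pval: float
    alpha: float


@dataclass
class PressoResult:
    """MR-PRESSO global, per-SNP outlier and distortion test results."""

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    distortion_pval: float | None
    n_sim: int
    seed: int


def leave_one_out(instruments: pd.DataFrame, alpha: float = 0.05,
                  random_effects: bool = True) -> LooResult:
    """IVW on every size-(k-1) subset.

    The influence rule is a convention, documented rather than derived:
    flag SNP j when the estimate without it changes sign relative to the
    full-set estimate, or when significance at ``alpha`` differs between
    the full-set and reduced-set fits.
    """
    _validate_instruments(instruments, 3, "leave-one-out")
    full = IVW(random_effects=random_effects).fit(instruments)
    rows = []
    flags = []
    for j in range(len(instruments)):
        reduced = instruments.drop(instruments.index[j])
        m = IVW(random_effects=random_effects).fit(reduced)
        snp = instruments.iloc[j]["snp_id"]
        sign_flip = np.sign(m.estimate_) != np.sign(full.estimate_)
        sig_cross = (m.pval_ < alpha) != (full.pval_ < alpha)
        flagged = bool(sign_flip or sig_cross)
        if flagged:
            flags.append(snp)
        rows.append({"snp_id": snp, "estimate": m.estimate_, "se": m.se_,
                     "ci_low": m.ci_low_, "ci_high": m.ci_high_,
                     "pval": m.pval_, "flagged": flagged})
    return LooResult(table=pd.DataFrame(rows, columns=LOO_COLUMNS), flags=flags,
                     full_estimate=full.estimate_, full_pval=full.pval_, alpha=alpha)


def _loo_estimates(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vector of leave-one-out IVW estimates, one per left-out index."""
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


class MRPresso(BaseEstimator):
    """MR-PRESSO residual-sum-of-squares pleiotropy test.

    Parameters
    ----------
    n_sim : int, default 1000
        Parametric simulations for the null RSS distribution.
    seed : int, default 42
    outlier_alpha : float, default 0.05
        Family-wise level for per-SNP outlier calls (Bonferroni over k).
    global_alpha : float, default 0.05
        Outliers are only called when the global test rejects at this
        level; with no evidence of pleiotropy anywhere in the set,
        per-SNP flags would be multiplicity artefacts.

    Notes
    -----
    Instruments are sorted by SNP id before any random draw, so results
    are invariant to input ordering for a given seed.  Empirical
    p-values use the ``(1 + count) / (n_sim + 1)`` estimator and
    therefore never reach zero.

    Attributes
    ----------
    rss_obs_, global_pval_ : float
    outlier_pvals_ : dict of snp_id -> empirical p
    outliers_ : list of snp_id
    distortion_pval_ : float or None (None when no outliers were called)
    """

    def __init__(self, n_sim: int = 1000, seed: int = 42, outlier_alpha: float = 0.05,
                 global_alpha: float = 0.05):
        self.n_sim = n_sim
        self.seed = seed
        self.outlier_alpha = outlier_alpha
        self.global_alpha = global_alpha

    def fit(self, X, y=None) -> "MRPresso":
        ids, bx, sx, by, sy = _validate_instruments(X, 4, "MR-PRESSO")
        if self.n_sim < 100:
            raise ValueError("n_sim must be at least 100 for stable empirical p-values")
        order = np.argsort(ids.astype(str), kind="stable")
        ids, bx, sx, by, sy = (a[order] for a in (ids, bx, sx, by, sy))
        k = len(bx)
        w = 1.0 / sy**2

        b_loo = _loo_estimates(bx, by, w)
        resid2_obs = w * (by - b_loo * bx) ** 2
        rss_obs = float(np.sum(resid2_obs))

        rng = np.random.default_rng(self.seed)
        bx_sim = bx + sx * rng.standard_normal((self.n_sim, k))
        by_sim = b_loo * bx + sy * rng.standard_normal((self.n_sim, k))
        b_loo_sim = _loo_estimates(bx_sim, by_sim, w)
        resid2_sim = w * (by_sim - b_loo_sim * bx_sim) ** 2
        rss_sim = np.sum(resid2_sim, axis=1)

        self.rss_obs_ = rss_obs
        self.global_pval_ = float((1 + np.sum(rss_sim >= rss_obs)) / (self.n_sim + 1))
        per_snp = (1 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (self.n_sim + 1)
        self.outlier_pvals_ = {str(i): float(p) for i, p in zip(ids, per_snp)}
        cutoff = self.outlier_alpha / k
        if self.global_pval_ < self.global_alpha:
            self.outliers_ = [str(i) for i, p in zip(ids, per_snp) if p < cutoff]
        else:
            self.outliers_ = []

        self.distortion_pval_ = None
        if self.outliers_:
            self.distortion_pval_ = self._distortion(ids, bx, by, w, rng)
        self.snp_ids_ = [str(i) for i in ids]
        self.n_snps_ = k
        return self

    def _distortion(self, ids, bx, by, w, rng) -> float | None:
        """Shift in IVW after removing the called outliers, referred to the
        null of removing equally many randomly chosen instruments."""
        k = len(bx)
        out_mask = np.isin(ids.astype(str), self.outliers_)
        m = int(out_mask.sum())
        if k - m < 2:
            return None
        est_all = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        keep = ~out_mask
        est_clean = float(np.sum(w[keep] * bx[keep] * by[keep])
                          / np.sum(w[keep] * bx[keep] ** 2))
        d_obs = abs(est_clean - est_all)
        d_null = np.empty(self.n_sim)
        for b in range(self.n_sim):
            drop = rng.choice(k, size=m, replace=False)
            mask = np.ones(k, dtype=bool)
            mask[drop] = False
            est_b = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
            d_null[b] = abs(est_b - est_all)
        return float((1 + np.sum(d_null >= d_obs)) / (self.n_sim + 1))

    def to_result(self) -> PressoResult:
        return PressoResult(self.rss_obs_, self.global_pval_, self.outlier_pvals_,
                            list(self.outliers_), self.distortion_pval_,
                            self.n_sim, self.seed)


def presso(instruments: pd.DataFrame, n_sim: int = 1000, seed: int = 42,
           outlier_alpha: float = 0.05, global_alpha: float = 0.05) -> PressoResult:
    """One-shot MR-PRESSO fit."""
    return MRPresso(n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha,
                    global_alpha=global_alpha).fit(instruments).to_result()
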