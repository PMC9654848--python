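"""Instrument-strength quality control.

For a standardized exposure, a biallelic SNP with effect-allele frequency
``p`` and per-allele effect ``beta`` explains ``R² = 2 p (1 - p) beta²``
of the trait variance.  The corresponding single-instrument F-statistic
against a null of no association is ``F = R² (N - 2) / (1 - R²)`` with
``N`` the exposure GWAS sample size; F < 10 is the conventional
weak-instrument flag, below which weak-instrument bias in two-sample
Mendelian randomization is considered material.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .exceptions import (
    DegenerateFrequencyError,
    InsufficientSampleError,
    InvalidStandardizationError,
)

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0

QC_COLUMNS = ["snp_id", "eaf", "beta_exp", "se_exp", "z", "r2", "f_stat", "weak"]


def r2_for_snp(eaf: float, beta_exp: float) -> float:
    """Proportion of exposure variance explained: ``2 p (1-p) beta²``.

    Valid for a standardized exposure (unit variance); values >= 1 signal
    betas that are not on a standardized scale.
    """
    if not (0.0 < eaf < 1.0):
        raise DegenerateFrequencyError(f"eaf must lie strictly in (0, 1); got {eaf}")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta_exp**2
    if r2 >= 1.0:
        raise InvalidStandardizationError(
            f"explained variance {r2:.3f} >= 1; exposure beta not standardized"
        )
    return r2


def f_statistic(r2: float, n: float, k: int = 1) -> float:
    """Instrument F-statistic from explained variance.

    The default single-regressor form is ``R² (N - 2) / (1 - R²)``; for
    ``k`` joint regressors the general form
    ``(R² / (1 - R²)) ((N - k - 1) / k)`` is used.
    """
    if n <= 2:
        raise InsufficientSampleError(f"need n > 2 for an F-statistic; got {n}")
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0, 1); got {r2}")
    if k == 1:
        return r2 * (n - 2) / (1.0 - r2)
    return (r2 / (1.0 - r2)) * ((n - k - 1) / k)


def compute_qc(instruments: pd.DataFrame, n_exposure: float, f_min: float = WEAK_F_THRESHOLD) -> pd.DataFrame:
    """Per-instrument QC table mirroring the exposure block of a typical
    instrument-variable listing: Z-score, explained variance, F, weak flag.

    Parameters
    ----------
    instruments
        Harmonized-instrument frame (needs snp_id, eaf, beta_exp, se_exp).
    n_exposure
        Exposure GWAS sample size feeding the F-statistic.
    """
    rows = []
    for rec in instruments.itertuples(index=False):
        r2 = r2_for_snp(rec.eaf, rec.beta_exp)
        f = f_statistic(r2, n_exposure)
        rows.append(
            {
                "snp_id": rec.snp_id,
                "eaf": rec.eaf,
                "beta_exp": rec.beta_exp,
                "se_exp": rec.se_exp,
                "z": rec.beta_exp / rec.se_exp,
                "r2": r2,
                "f_stat": f,
                "weak": f < f_min,
            }
        )
    return pd.DataFrame(rows, columns=QC_COLUMNS)


def filter_weak(
    instruments: pd.DataFrame, qc: pd.DataFrame, f_min: float = WEAK_F_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split instruments into (kept, dropped) by the weak-instrument rule
    ``F >= f_min`` (default 10)."""
    if instruments.empty:
        return instruments.copy(), instruments.copy()
    strong = set(qc.loc[qc["f_stat"] >= f_min, "snp_id"])
    mask = instruments["snp_id"].isin(strong)
    dropped = instruments[~mask].reset_index(drop=True)
    for snp in dropped["snp_id"]:
        logger.info("dropping weak instrument %s (F < %g)", snp, f_min)
    return instruments[mask].reset_index(drop=True), dropped


def write_qc_report(qc: pd.DataFrame, path: str | Path) -> None:
    qc.to_csv(path, sep="\t", index=False)
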