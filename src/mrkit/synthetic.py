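"""Synthetic two-sample MR studies with known ground truth, and the
packaged selenium instrument fixture.

The generator draws, for each of k instruments, a true SNP-exposure
effect ``gamma_j``, a pleiotropic direct effect ``alpha_j`` on the
outcome, and observed summary statistics

    beta_exp_j ~ Normal(gamma_j, se_exp_j²)
    beta_out_j ~ Normal(beta_true * gamma_j + alpha_j, se_out_j²)

with per-SNP standard errors drawn uniformly from configurable ranges
(heteroscedastic, as in real GWAS where allele frequency and imputation
quality vary by SNP).  Pleiotropy modes:

* ``none`` — alpha_j = 0: all instruments valid.
* ``balanced`` — alpha_j ~ Normal(0, tau²): inflates heterogeneity but
  leaves IVW approximately unbiased.
* ``directional`` — alpha_j ~ Normal(mu, tau²): biases IVW; because
  alpha is drawn independently of gamma the InSIDE condition holds, so
  the MR-Egger intercept targets mu and its slope the causal effect.

Gross outliers (single SNPs with large pleiotropic offsets, in units of
their outcome SE) can be injected at chosen indices to exercise
MR-PRESSO and leave-one-out diagnostics.

The defaults mimic the scale of the selenium application: exposure
effects of a Z-score GWAS with ~10,000 samples and outcome effects from
a kidney-function GWAS of several hundred thousand samples (outcome SEs
two to three orders of magnitude below exposure SEs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .sumstats import INSTRUMENT_COLUMNS, SummaryStatRecord

logger = logging.getLogger(__name__)

#: Non-palindromic allele pairs cycled over generated SNPs.
_ALLELE_PAIRS = (("A", "G"), ("T", "C"), ("G", "A"), ("C", "T"))


@dataclass
class SimConfig:
    """Configuration of one simulated two-sample study.

    Defaults reflect a realistic instrument panel: per-SD exposure
    effects around 0.2 (as for the selenium instruments), exposure SEs
    of a ~10k-sample GWAS, outcome SEs of a ~800k-sample GWAS.
    """

    k: int = 20
    beta_true: float = 0.0
    seed: int = 0
    gamma_mean: float = 0.2
    gamma_sd: float = 0.05
    gamma_min: float = 0.05
    se_exp_range: tuple[float, float] = (0.02, 0.05)
    se_out_range: tuple[float, float] = (0.0003, 0.0013)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    pleiotropy: str = "none"
    mu_pleio: float = 0.0
    tau_pleio: float = 0.0
    outlier_spec: list[tuple[int, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.k < 2:
            raise ConfigurationError(f"need k >= 2 instruments; got {self.k}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        for name in ("se_exp_range", "se_out_range", "eaf_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} {getattr(self, name)} invalid")
        if not (0 < self.eaf_range[0] and self.eaf_range[1] < 1):
            raise ConfigurationError(f"eaf_range {self.eaf_range} outside (0, 1)")
        if self.gamma_min < 0:
            raise ConfigurationError("gamma_min must be nonnegative")
        for idx, _ in self.outlier_spec:
            if not (0 <= idx < self.k):
                raise ConfigurationError(f"outlier index {idx} outside [0, {self.k})")


@dataclass
class SimulatedStudy:
    """Generated exposure/outcome records plus the generating truth."""

    exposure: list[SummaryStatRecord]
    outcome: list[SummaryStatRecord]
    beta_true: float
    gamma: np.ndarray
    alpha: np.ndarray
    config: SimConfig

    def instruments(self) -> pd.DataFrame:
        """Harmonized-instrument frame (exposure and outcome share allele
        coding by construction, so no flips occur)."""
        rows = [
            {
                "snp_id": e.snp_id, "eaf": e.eaf,
                "beta_exp": e.beta, "se_exp": e.se, "p_exp": e.pval,
                "beta_out": o.beta, "se_out": o.se, "p_out": o.pval,
                "palindromic": False, "flipped": False,
            }
            for e, o in zip(self.exposure, self.outcome)
        ]
        return pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def generate_study(config: SimConfig) -> SimulatedStudy:
    """Draw one study; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.k

    gamma = config.gamma_mean + config.gamma_sd * rng.standard_normal(k)
    small = np.abs(gamma) < config.gamma_min
    gamma[small] = np.where(gamma[small] >= 0, config.gamma_min, -config.gamma_min)

    if config.pleiotropy == "none":
        alpha = np.zeros(k)
    else:
        mu = config.mu_pleio if config.pleiotropy == "directional" else 0.0
        alpha = mu + config.tau_pleio * rng.standard_normal(k)

    se_exp = rng.uniform(*config.se_exp_range, size=k)
    se_out = rng.uniform(*config.se_out_range, size=k)
    eaf = rng.uniform(*config.eaf_range, size=k)

    beta_exp = gamma + se_exp * rng.standard_normal(k)
    mean_out = config.beta_true * gamma + alpha
    beta_out = mean_out + se_out * rng.standard_normal(k)
    for idx, offset in config.outlier_spec:
        beta_out[idx] += offset * se_out[idx]
        alpha = alpha.copy()
        alpha[idx] += offset * se_out[idx]

    p_exp = _two_sided_p(beta_exp, se_exp)
    p_out = _two_sided_p(beta_out, se_out)

    exposure, outcome = [], []
    for j in range(k):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        common = dict(
            snp_id=f"rs{1000001 + j}", chrom="1", pos=1_000_000 * (j + 1),
            effect_allele=ea, other_allele=oa, eaf=float(eaf[j]),
        )
        exposure.append(SummaryStatRecord(
            beta=float(beta_exp[j]), se=float(se_exp[j]),
            pval=float(max(p_exp[j], 5e-324)), **common))
        outcome.append(SummaryStatRecord(
            beta=float(beta_out[j]), se=float(se_out[j]),
            pval=float(max(p_out[j], 5e-324)), **common))
    return SimulatedStudy(exposure=exposure, outcome=outcome,
                          beta_true=config.beta_true, gamma=gamma, alpha=alpha,
                          config=config)


# ---------------------------------------------------------------------------
# Packaged selenium instrument fixture
# ---------------------------------------------------------------------------

#: Exposure GWAS meta-analysis size behind the fixture's F-statistics
#: (5477 blood + 4162 toenail selenium participants).
SELENIUM_N_EXPOSURE = 9639

#: Outcome GWAS sizes for the two kidney-function traits.
SELENIUM_N_OUTCOME = {"egfr": 765_348 + 436_561, "bun": 852_678}

#: The one instrument with a genome-wide-significant eGFR association.
SELENIUM_EGFR_CONFOUNDED_SNP = "rs921943"


def selenium_table() -> pd.DataFrame:
    """The full packaged instrument table for the selenium exposure: 11
    independent, non-palindromic, genome-wide-significant SNPs with their
    exposure associations (Z-score-derived beta/SE), published F and R²
    values, and associations with both kidney-function outcomes."""
    ref = resources.files("mrkit.data").joinpath("selenium_instruments.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", float_precision="round_trip")


def selenium_fixture(outcome: str = "egfr") -> pd.DataFrame:
    """Harmonized instruments for the selenium exposure against one
    kidney-function outcome (``"egfr"`` or ``"bun"``).

    Returns all 11 instruments; the outcome-association exclusion (which
    removes rs921943 for eGFR) is a separate, explicit pipeline step.
    """
    outcome = outcome.lower()
    if outcome not in ("egfr", "bun"):
        raise ConfigurationError(f"unknown outcome {outcome!r}; expected 'egfr' or 'bun'")
    table = selenium_table()
    frame = pd.DataFrame({
        "snp_id": table["snp_id"],
        "eaf": table["eaf"],
        "beta_exp": table["beta_exp"],
        "se_exp": table["se_exp"],
        "p_exp": table["p_exp"],
        "beta_out": table[f"beta_{outcome}"],
        "se_out": table[f"se_{outcome}"],
        "p_out": table[f"p_{outcome}"],
        "palindromic": False,
        "flipped": False,
    })
    return frame[INSTRUMENT_COLUMNS]
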