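# Methods

`mrkit` implements two-sample Mendelian randomization (MR) for summary
statistics: exposure and outcome associations measured in separate GWAS,
combined per SNP without individual-level data. This note records the
statistical model, the conventions and numerical choices the library
commits to, what the synthetic generator does and does not emulate, and
known limitations.

## Model and assumptions

For instrument j, let β̂_xj (SE σ_xj) be the SNP–exposure association and
β̂_yj (SE σ_yj) the SNP–outcome association, both aligned to the same
effect allele. Under the instrumental-variable assumptions — the SNP is
(I) associated with the exposure, (II) independent of confounders, and
(III) affects the outcome only through the exposure — each Wald ratio
β̂_yj/β̂_xj estimates the same causal effect β.

Instrument selection enforces these assumptions operationally:
genome-wide significance on the exposure (p < 5×10⁻⁸, assumption I),
pairwise LD pruning (r² < 0.3 within 10 Mb, greedy by ascending
p-value, against a user-supplied LD table) so instruments contribute
quasi-independent information, a weak-instrument filter (F ≥ 10), and
exclusion of any instrument whose *outcome* association is itself
genome-wide significant (assumption III: such a SNP plausibly acts on
the outcome through a pathway other than the exposure). The
outcome-association threshold reuses 5×10⁻⁸; it is a convention, chosen
because the one exclusion it produces on the packaged selenium panel
(rs921943 against eGFR, p = 2.62×10⁻¹²) is unambiguous at any
conventional genome-wide level.

## Estimators

**IVW.** β̂ = Σw_j β̂_xj β̂_yj / Σw_j β̂_xj², w_j = 1/σ_yj² — identical to
weighted least squares of β̂_y on β̂_x through the origin. SEs use a
*multiplicative random-effects* model: the fixed-effect SE is scaled by
φ = max(1, √(Q/(k−1))), where Q = Σw_j(β̂_yj − β̂β̂_xj)² is Cochran's Q.
Flooring at 1 means heterogeneity below sampling expectation never
*shrinks* the SE; on the packaged panel this yields a fixed-effect-width
interval for eGFR (Q p = 0.43, φ ≈ 1.005) and an inflated one for BUN
(Q p = 0.043, φ ≈ 1.37) from the same code path. p-values are two-sided
normal; 95% CIs use z = 1.959964.

**MR-Egger.** The same weighted regression with a free intercept, after
orienting every instrument to β̂_x ≥ 0 (the fit is otherwise
allele-coding dependent). The intercept estimates the mean directional
pleiotropic effect; the slope is a pleiotropy-adjusted causal estimate
under InSIDE (instrument strength independent of direct effects).
Inference uses t with k−2 df and the same multiplicative scale floored
at 1. Egger's slope is consistent only when instrument-strength
variation dominates exposure-side noise; with weak, similar-strength
instruments it suffers regression dilution (see limitations).

**Weighted median.** Per-SNP ratios are sorted ascending (ties broken
by SNP id), weighted by inverse first-order ratio variance
w_j = β̂_xj²/σ_yj², and the estimate interpolates the ratio at
standardized mid-cumulative weight s_j = (cum_j − w_j/2)/Σw at s = 0.5.
Consistent when valid instruments carry ≥ 50% of the weight. The SE is
a parametric bootstrap (default 1000 draws of β̂_x, β̂_y from normals at
their SEs); instruments are processed in sorted-id order so the result
is independent of input ordering, and bit-reproducible given a seed. A
second-order ratio SE (adding β̂_y²σ_x²/β̂_x⁴) is available but off by
default; first-order weights are the common convention.

## Diagnostics

**Leave-one-out.** IVW on each size-(k−1) subset. "Influential" has no
canonical definition; the library's rule flags a SNP when its removal
flips the estimate's sign or moves its p-value across α (default 0.05)
— i.e. when the qualitative conclusion depends on one variant. On the
packaged panel this flags nothing for eGFR and {rs921943, rs10944} for
BUN (removing either moves BUN from p < 0.05 to p > 0.05).

**MR-PRESSO.** Observed residual sum of squares about leave-one-out IVW
predictions, RSS = Σ w_j(β̂_yj − β̂₍₋ⱼ₎β̂_xj)², compared with its
parametric null: simulate β̂*_xj ~ N(β̂_xj, σ_xj²),
β̂*_yj ~ N(β̂₍₋ⱼ₎β̂_xj, σ_yj²), recompute leave-one-out estimates on each
simulated study, and take the empirical upper-tail probability with the
(1 + count)/(n_sim + 1) estimator (never exactly zero). Per-SNP outlier
p-values come from each SNP's simulated weighted-residual distribution,
Bonferroni-corrected at α = 0.05; outliers are only *called* when the
global test rejects — absent global evidence of pleiotropy, per-SNP
flags would be multiplicity artefacts. When outliers are called, a
distortion test compares the estimate shift after their removal against
the null of removing equally many randomly chosen instruments. Draws
are keyed to instruments sorted by SNP id, making results independent
of input order for a given seed. Defaults: n_sim = 1000, seed 42.

## Instrument strength

For a standardized exposure, R²_j = 2p_j(1−p_j)β̂_xj² and
F_j = R²_j(N−2)/(1−R²_j) with N the exposure GWAS size (one regressor;
a general k-regressor form is available). The packaged panel's F values
reproduce at N = 9639 (5477 blood + 4162 toenail participants) to four
significant figures for 10 of 11 instruments. The exception, rs705415,
back-solves to an effective N ≈ 8054 — consistent with that variant
being unavailable in part of the meta-analysis — and is carried as
published rather than recomputed. A related wrinkle carried as-is: the
published per-SNP R² range (0.63–3.58%) does not match the source
text's "0.32–1.76%" summary; the table is authoritative here.

Z-score GWAS effects convert to beta/SE via
β = z/√(2p(1−p)(n+z²)), σ = 1/√(2p(1−p)(n+z²)), so β/σ = z exactly.

## Power

Two-sided power for a continuous outcome uses the normal approximation
power = Φ(−z₁₋α/₂ + |β|√(nR²)) + Φ(−z₁₋α/₂ − |β|√(nR²)), with n the
outcome GWAS size, R² the summed instrument explained variance, and β
in SD-outcome per SD-exposure units (the no-confounding closed form;
raw effects can be standardized with `standardize_effect`). The inverse
(`min_detectable_effect`) brackets and bisects to 10⁻¹². Note the units
trap: effects reported on a log-trait scale (SD ≈ 0.2 for log eGFR)
are ~5× larger in SD units, which is what makes effects of order 0.004
detectable with ≥ 99% power at outcome sizes near 10⁶.

## Synthetic studies

The generator draws γ_j ~ N(0.2, 0.05²) (clamped away from 0 at 0.05 so
ratios are defined), α_j per pleiotropy mode (none / balanced
N(0, τ²) / directional N(μ, τ²), drawn independently of γ so InSIDE
holds), then β̂_xj ~ N(γ_j, σ_xj²), β̂_yj ~ N(βγ_j + α_j, σ_yj²) with SEs
uniform on (0.02, 0.05) and (0.0003, 0.0013). These defaults mirror the
selenium application: a ~10⁴-sample Z-score exposure GWAS against
~10⁶-sample outcome GWAS. Outliers are injected as offsets in units of
the target SNP's outcome SE. Alleles are non-palindromic by
construction; EAFs uniform on (0.05, 0.95).

The generator does **not** emulate: LD between instruments (clumping is
tested on hand-built LD tables), winner's-curse selection of
instruments, sample overlap between exposure and outcome GWAS,
allele-frequency-dependent SEs, or InSIDE violations (correlated
pleiotropy). Recovery tests passing on this generator therefore
validate the estimators' arithmetic and their stated robustness
properties, not robustness to those real-data phenomena.

Validation experiments that probe estimator recovery or outlier
detection use a strong-instrument variant (exposure SEs 0.002–0.01,
γ spread 0.1): with the default noise level, exposure-side measurement
error produces a few-percent regression dilution in IVW and a larger
one in Egger, which is a property of the estimators, not a bug, and
would otherwise confound bias assertions. Null-calibration experiments
(type-I error, MR-PRESSO global p uniformity) use the defaults, where
dilution is irrelevant under β = 0. Experiment sizes (100–500
replicates, 200–1000 MR-PRESSO simulations, 10⁵ Monte-Carlo draws for
the power check) keep the full suite in the seconds-to-minutes range
while leaving Monte-Carlo error well inside the asserted tolerances.

## Harmonization conventions

Outcome records align to the exposure's effect allele, trying the
reported alleles and their strand complement; a match on the swapped
pair flips the outcome beta's sign and complements its EAF.
Palindromic SNPs (A/T, C/G) default to *drop*, matching the selenium
panel's construction (all 11 SNPs non-palindromic); an opt-in
`infer` policy aligns them by allele frequency and drops those with
either EAF in (0.42, 0.58). Irreconcilable allele pairs and SNPs absent
from either study are dropped with logged counts. LD pairs missing from
the user's table are treated as independent with a warning (the library
deliberately has no LD reference panel of its own). Clumping runs on
the exposure table before the outcome merge, the usual order in
summary-statistic MR, so instrument selection never depends on outcome
data.

## Degenerate inputs and tie-breaks

EAF of exactly 0/1, SE ≤ 0, k below each estimator's minimum (2 for
IVW, 3 for Egger/weighted-median/LOO, 4 for MR-PRESSO) raise typed
errors; β̂_x = 0 drops that SNP from ratio-based computation with a
diagnostic. Q = 0 (identical ratios) yields φ = 1 and heterogeneity
p = 1. Equal ratio ties in the weighted median are ordered by SNP id.
The pipeline aborts, naming the stage, if any filter leaves fewer than
3 instruments.

## Limitations

Beyond the generator gaps above: no correlated-instrument (generalized
least squares) IVW, no mode-based or robust-regression estimators, no
Steiger directionality filtering, no multivariable MR, no binary-outcome
power (the kidney outcomes are continuous), and no LD computation from
genotype panels. The leave-one-out influence rule and the
outcome-association exclusion threshold are documented conventions, not
identified quantities; sensitivity of conclusions to them can be probed
by rerunning with different `alpha` / `p_outcome_exclude`.
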