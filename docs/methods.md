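# Methods

## Scope and model

`fluxconverge` quantifies the agreement between eddy-covariance (EC) and
biometric (BM) estimates of annual forest carbon fluxes.  The analysis
object is a flat site table: one row per site with EC fluxes (NEP, Reco,
GPP), BM component fluxes, a categorical profile of the BM methodology,
environmental covariates and, optionally, repeated carbon-stock
inventories.  All fluxes are annual sums in gC m⁻² y⁻¹; the sign
convention is NEP > 0 for a carbon sink, and differences are stored as
D = BM − EC (the EC − BM orientation is the negation).

BM budgets are assembled from the identities NEP = NPP − Rh,
Reco = Ra + Rh, GPP = NPP + Ra and Rsoil = Rroot + Rh-soil.  NPP requires
at least its three major parts (aboveground wood, foliage, fine roots);
every further reported part is summed in.  Understory respiration is added
to aboveground Ra only when reported separately, since it is otherwise
typically folded into Rleaf/Rwood — this avoids double counting.  Rh-cwd
is treated as zero when absent or excluded, *in both NEP and Reco*, so
that the closure identity GPP − Reco = NEP holds exactly whenever all
three fluxes are computable; every omission is recorded in
`completeness_flags` and sites are never dropped for it.

## Uncertainty model

Half-range uncertainties are approximated as `s = p · RF / √l`:

| quantity | meaning | default |
|---|---|---|
| `p` (gC m⁻² y⁻¹) | biome-typical flux range | NEP: 350 extratropical, 700 tropical; Reco/GPP: 1000 at the equator falling linearly to 500 at ≥60° latitude |
| `RF` (–) | method reduction factor | EC 0.3; BM 0.3 (high-quality data) or 0.6 (fair) |
| `l` (years) | replicate measurement years | from the site table; method-specific values override the site value |

The √l form is standard-error scaling of replicate years; it reproduces
the reference case 350 × 0.3 = 105 → 105/√2 ≈ 74 exactly.  The latitude
ramp for Reco/GPP is a documented linear stand-in between the two known
endpoints; only the bounds are externally fixed.  Reported uncertainties
are half-ranges used symmetrically as error bars and as regression weights
(1/s); no distributional claim is attached to them.  An optional
`tropical_multiplier` inflates tropical Reco/GPP uncertainties (default
1.0), since direct estimates suggest the approximation can be too tight
in the tropics.

## Statistics

**Major-axis regression** (model II) is used for BM-vs-EC scatter because
both axes carry errors of comparable magnitude.  The slope is the first
principal axis of the sample covariance matrix; R² is the squared Pearson
correlation and the p-value the Pearson correlation test.  The slope CI is
the classical Jolicoeur F-based interval on the axis angle; when that
interval is undefined or brackets the vertical, a percentile bootstrap
(2000 resamples, fixed internal seed) is used and flagged.  Note that when
the EC and BM error variances differ appreciably the MA slope attenuates
slightly toward the lower-error axis and its nominal CI undercovers; the
recovery report quantifies this on synthetic data.

**Paired comparisons** gate on a Shapiro–Wilk test of the pair differences
at α = 0.05 (configurable): normal differences use the paired t-test,
otherwise a Wilcoxon signed-rank test (exact null for n ≤ 25 without ties,
normal approximation with continuity correction above; zeros dropped, tied
ranks averaged).  All-zero differences return the degenerate result
(mean 0, p = 1).

**Weighted screens** regress the flux difference (absolute for NEP,
relative for Reco/GPP) on one covariate at a time by weighted least
squares with weights 1/s — the literal inverse uncertainty; a
`weight_power` switch gives classical 1/s².  The combined pair uncertainty
is the root sum of squares of the EC and BM half-ranges.  Categorical
predictors are dummy-coded and tested with an overall F-test.
Breusch–Pagan (α = 0.05) on the weighted residuals gates the inference:
under heteroskedasticity the White HC0 covariance is used and R² is
reported as the squared Pearson correlation of response and fit.  No
multiple-testing correction is applied across the screen — each row is an
independent univariate question, and corrected and uncorrected readings
can be formed from the reported p-values.

**Relative difference** (BM − EC)/((BM + EC)/2) is restricted to Reco and
GPP: NEP takes both signs, which makes the normalization ill-defined.

**Two-way ANOVA** (light inhibition × Rleaf parameterization, NSF-chamber
subset) uses type-II sums of squares, which are unbalanced-safe; an empty
factor crossing makes the interaction inestimable (reported as NaN) and
main effects are then tested in the additive model.

**Outlier handling**: outliers are intentionally retained everywhere —
high-discrepancy sites are the object of study.  Leave-one-out refits of
each screen flag points whose omission moves the p-value across the 0.05
or 0.10 thresholds.

## Gap-filling

Branch-turnover NPP is added as 22% of aboveground wood NPP (falling back
to 8% of total NPP when wood NPP is unavailable) at sites that did not
measure it; mycorrhizal NPP as 14% of total NPP.  Fractions always apply
to the original, pre-fill values.  Gap-filling is a sensitivity/reporting
step only: filled NPP never feeds back into the convergence tables.  Minor
terms (root exudation, non-structural carbohydrate accumulation,
herbivory, volatile organics, ~1–4% of NPP) are not imputed.

## Topographic indices

Elevation variability is the population standard deviation (divisor n) of
the 729 pixels of a 27 × 27, 90 m DEM quadrat centred at the tower — the
pixels are the whole quadrat, not a sample (the n vs n−1 choice matters by
<0.1% at this size).  Topographical slope is 100·(z_max − z_min)/d with d
the Euclidean centre-to-centre distance between the extreme pixels; ties
break to the first occurrence in row-major order, and a flat grid returns
0.  The grid is treated as a plane with fixed spacing (appropriate for
90 m satellite-derived DEMs); no reprojection or void-filling.

## Synthetic data generator

The generator emulates the structure of the study dataset, not any real
site.  Defaults: 6 boreal / 22 temperate / 3 tropical sites; true GPP
drawn per zone (1000±200, 1800±400, 3200±300 gC m⁻² y⁻¹ — chosen inside
the observed per-zone flux ranges); NPP:GPP 0.45; NPP shares
foliage/wood/root/other 0.30/0.34/0.30/0.06 with fine roots 70% of root
NPP; Ra shares leaf/wood/root/understory 0.39/0.22/0.38/0.01; Rh:Reco
0.32 with Rh-cwd 5% of Reco.  Latent truth satisfies all budget
identities exactly.  Observation noise is multiplicative Gaussian
(CV-based, EC 5%, BM 8%) for the positive fluxes and additive
(sd = CV·GPP) for NEP, keeping Reco/GPP positive and mirroring the
magnitude-proportional uncertainty model.

Bias mechanisms, each tied to a sampled method-variant category:

* `nep_bm_offset` (default −100 gC m⁻² y⁻¹) shifts total BM NPP by exactly
  the offset (spread proportionally over the parts), emulating systematic
  NPP underestimation;
* Rleaf is inflated by 20% at sites neglecting light inhibition of leaf
  dark respiration (sampled with P(considered) = 0.28);
* NSNF (closed static) chamber sites underestimate Rsoil by 15%, applied
  equally to Rroot and Rh-soil so the soil partition identity still holds;
* sites not reporting Rh-cwd (35%) omit the component entirely.

These mechanisms interact the way compensating errors do in real
compilations: the Rsoil deficit and the unreported Rh-cwd *raise* BM NEP
and therefore cancel part of the injected NPP deficit, so the emergent
net NEP difference of a default-condition dataset is smaller in magnitude
than the injected −100.  Parameter-recovery tests that target a single
mechanism therefore switch the others off (`SimConfig.zero_bias()` plus
the one bias under study); the recovery acceptance check injects the
offset alone at 5% noise and recovers it within 3 s.e.m. in ≥95% of 200
replicates.

What the generator does **not** emulate: spatial or temporal correlation
between sites, asymmetric or heavy-tailed measurement error,
footprint mismatch between the EC tower and the BM plots, and any
correlation between environmental covariates and the biases (covariates
are drawn independently).  Passing recovery tests therefore demonstrate
the correctness of the estimators under the stated error model, not the
field accuracy of either method.

## Problem sizes and numerical choices

Simulation-based tests use 31-site datasets, 200 replicates for offset
recovery and 5,000 replicates for the type-I calibration of the gated
paired test — sizes at which the Monte-Carlo error of the checked rates is
well below the asserted bounds.  Consistency tolerances: the Rsoil
partition allows 1 gC m⁻² y⁻¹ slack; oracle comparisons (eigen
decomposition, normal equations) are asserted at 1e-10; closure is
asserted at 1e-9.  Degenerate inputs are handled explicitly: circular
scatter raises an undefined-axis error, constant predictors raise a
singular-design error, a constant ANOVA response is flagged degenerate,
zero-variance groups fall back to exact permutation tests.

## Known limitations

* The latitude dependence of the Reco/GPP base range is a linear
  interpolation between its published endpoints; the original tabulation
  is finer-grained.
* The MA slope CI undercovers under strongly unequal EC/BM error
  variances (see above).
* The screens are univariate by design; the single interaction known to
  matter (soil chamber × light inhibition) is handled by the dedicated
  NSF-subset ANOVA, but no general interaction search is performed.
* Stock-change NEP uses wood + soil stocks only and assumes constant
  lateral losses over the inventory interval.
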