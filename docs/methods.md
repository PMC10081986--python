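# Methods

## Index and calibration

H-Print is the phytoplankton-marker share of the summed intensities of
the three monitored HBIs, `100·HBI III/(IP₂₅+HBI II+HBI III)`. It is a
ratio of response-normalized SIM peak areas, so it is invariant under a
common rescaling of all three channels and needs no absolute
quantification; intensities are assumed already response-normalized and
no response-factor correction is applied. The index is undefined when all
three intensities are zero; such samples are excluded and logged — an
undefined value is never coerced to 0 or 100, and output files mark it
with an explicit `NA`.

The calibration `iPOC = 101.08 − 1.02·H-Print` (from a controlled
ice-algae feeding experiment; R² = 0.97, df = 23) is treated as injectable
data, not a code constant: `Calibration` carries intercept, slope and a
`clamp` flag. The line exceeds 100 % at H-Print 0 and falls to −0.92 % at
H-Print 100. Because iPOC is a carbon *share*, reported values are
clamped to [0, 100] by default, with the raw line value retained
alongside; setting `clamp=False` recovers the unclamped line. Whether
out-of-range calibration outputs should be clamped, truncated or reported
as-is is genuinely open — a percentage axis suggests clamping but nothing
forces it — hence the flag rather than a hard-coded rule.

Classification is by marker presence, not by an iPOC threshold:
`pelagic_only` means both sea-ice HBIs are exactly zero while HBI III is
present. No detection-limit threshold beyond exact zero is applied; LOD
behaviour belongs to upstream QC and to the synthetic generator's dropout
model, since no instrument LOD is available to the pipeline.

## Survey statistics

Box-plot summaries use linear-interpolation quartiles. The whisker
convention is configurable because the two common conventions (extreme
values vs Tukey 1.5×IQR fences with outliers beyond) are both in use in
this literature and are sometimes conflated in figure captions; the
default is Tukey, with `minmax` as an override. The 50 % exceedance uses
a strict inequality: a sample at exactly 50 % does not have a *stronger*
sea-ice than phytoplankton signature.

Regression fits are exact QR least squares with SEs from
`σ̂²(X'X)⁻¹`, t statistics `β̂/SE`, and two-sided p-values from the t
distribution with `n − k` degrees of freedom. AIC is `2k − 2ℓ` with the
full Gaussian log-likelihood (constants included) and `k` counting the
error variance, matching R's `AIC` for `lm`; statsmodels, which omits the
variance from `k`, differs by exactly 2, and the test suite asserts that
relationship explicitly. AIC ties break by parsimony, then formula
lexicographic order. Rank-deficient designs are refused with the
collinear columns named.

Habitat enters the design as a single ordered score (pelagic 0, mixed 1,
sympagic 2, benthic 3) by default. A four-level factor summarized by one
t-value implies a single-column coding, but the score assignment itself
is a modelling choice, so it is configurable and a three-dummy treatment
coding (per-level t-values) is available. Month is a numeric 1–12
covariate by default — again the single-t convention — with a sin/cos
circular option. The month-shift robustness check relabels months with
modular wraparound (January − 3 → October) and refits; a conclusion that
survives relabeling does not hinge on the alignment of the month covariate
with the seasonal cycle.

### Sensitivity analysis

For a treatment column with statistic `t` on `df` residual degrees of
freedom, the partial R² with the outcome is `t²/(t²+df)`. With partial
Cohen's `f = |t|/√df` and `f_q = q·f`, the robustness value — the minimal
partial R², with both treatment and outcome, that an unobserved
confounder needs to reduce the estimate by the fraction `q` — is

    RV_q = ½(√(f_q⁴ + 4 f_q²) − f_q²),

implemented in the algebraically equivalent form `2/(√(1+4/f_q²)+1)`,
which is stable for large `f_q` (the naive difference cancels
catastrophically above `f_q ≈ 10⁴`). At significance level α the critical
`f* = t*_{α,df−1}/√(df−1)` is subtracted from `f_q` first (one residual
degree of freedom is ceded to the hypothetical confounder), the result is
floored at 0, and the extreme case `f* > 1/f_q` switches to
`(f_q² − f*²)/(1 + f_q²)`. Both variants are verified in the tests
against an independent nested-grid search for the confounder strength
that drives the bias-adjusted statistic `(f_q − x/√(1−x))·√(df−1)` to the
critical value.

## Sediment inventory

Per layer, iPOC fraction = clamped calibration output / 100 and
`mg iPOC/g = TOC × fraction`. This is a deliberate *theoretical maximum*:
no degradation, bioturbation-mixing or burial-efficiency discount is
applied, so the per-layer value can only overstate the standing stock.
Ages are linear in depth (`age(d) = sampling year − d/rate`, default
1 mm y⁻¹) with no compaction correction. The accessible inventory over a
horizon (default 70 mm, a burrowing-depth scale for Arctic infauna)
reports the min–max of per-layer values among layers that overlap the
horizon at all; a partially overlapping layer counts in full, which is
conservative for a maximum estimate. The min–max is a per-layer range,
not an uncertainty envelope. Layers whose intensities are all zero have
undefined iPOC and are flagged rather than treated as zero.

## Synthetic data

The generator draws habitat (weights 0.45/0.25/0.20/0.10 for
benthic/pelagic/mixed/sympagic, reflecting a benthos-heavy survey), month
(uniform), latitude (uniform on 55–82° N) and year (uniform 1982–2019),
then builds the true mean iPOC from habitat base levels (benthic 70,
sympagic 65, mixed 55, pelagic 40 %), a +0.5 %/degree latitude gradient
centred on the sampled midpoint (68.5° N, so the configured habitat
levels are the marginal group means), and a post-bloom suppression of
pelagic iPOC: an amplitude of 20 % at the May and September bloom months
decaying with a 3-week e-folding time — the turnover scale of HBI lipids
in consumer tissue — applied in full to pelagic and at half weight to
mixed-habitat consumers.

Noise is added on the logit of iPOC/100 (SD 0.35 by default), which keeps
simulated values strictly inside (0, 100) without truncation artifacts. A
first-order bias correction (`z ← z − σ²(1−2p)/2`) keeps the mean of the
simulated values at the configured mean to O(σ⁴), so group-mean recovery
tests can compare against the configured levels directly.

True iPOC is inverted through the unclamped calibration line to an
H-Print (feasibility — mean iPOC inside (0, 100), implied H-Print inside
[0, 100] — is validated and violations raise errors); a lognormal total
intensity is partitioned into HBI III = (H-Print/100)·total and the
remainder is split IP₂₅:HBI II by a lognormal ratio (mean 1, CV 0.3).
Measurement therefore adds no error beyond the generated noise, and a
noise-free configuration round-trips exactly through the pipeline.
Corruption is applied last: with probability 0.03 a sample loses all
three HBIs (detection-limit dropout, producing the excluded class) and
with probability 0.04 it loses only the sea-ice HBIs (pelagic-only). The
exported truth table records per-sample true iPOC, the corruption flags
and the generating parameters; tests state expectations from this truth,
never from field-data numbers.

For estimator-validation studies the categorical structure is replaced by
an explicit linear model (`LinearEffects`: intercept 55, habitat score
+8 %/step, latitude +0.5 %/deg, month −0.5 %/month, month×habitat
−0.4 %/(month·step)) so that "the generating coefficient" is well defined
in the fitted design. Recovery runs use 20 datasets of n = 2000 — large
enough that the interaction t-statistic is far from the selection
boundary while the whole study runs in seconds — and compare the median
estimate across datasets to the generating value.

What the generator does *not* emulate: species-level random effects and
taxon-specific lipid retention, spatial autocorrelation and uneven
station coverage, inter-annual trends, correlated month×latitude sampling
bias (covariates are drawn independently), and any mechanistic link
between ice conditions and production. Passing recovery tests therefore
show that the estimators are correct under the assumed structure, not
that the structure captures all features of real survey data.

## Degenerate inputs and edge rules

Empty sample batches, all-excluded datasets, empty groups, zero-length
horizons and rank-deficient designs raise errors rather than returning
defaults. The H-Print ratio is clipped against floating-point overshoot
(a pure-HBI III sample can evaluate to 100 + 1 ulp). Missing months are a
first-class state: excluded from monthly bins and regressions with a
logged count, never encoded as 0 or 13.

## Limitations

The calibration's feeding-experiment provenance (single prey type,
equilibrium assumption) is inherited, not re-derived; its uncertainty is
not propagated into per-sample iPOC. The ordered habitat score imposes
equal spacing between habitat levels in the default coding. The sediment
estimate is a maximum bound by construction and per-gram only (per-area
inventories would require dry bulk density profiles, which the core
tables used here do not carry).
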