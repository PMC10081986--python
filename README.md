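# ipoc — sea-ice carbon tracing from HBI lipid biomarkers

`ipoc` turns per-sample GC–MS intensities of three highly branched
isoprenoid (HBI) diatom lipids into quantitative estimates of how much of
an Arctic consumer's carbon came from sea-ice algae rather than pelagic
phytoplankton, and provides the statistical and sediment-inventory layers
needed to analyse such estimates across a large, heterogeneous survey of
consumers (benthic invertebrates, zooplankton, fish, seabirds, marine
mammals).

It is written for ecologists and biogeochemists working with
source-specific lipid tracers: IP₂₅ (*m/z* 350.3) and HBI II (*m/z* 348.3)
are synthesized by sea-ice diatoms, HBI III (*m/z* 346.3) by open-water
phytoplankton.

## The model

The three intensities are combined into the **H-Print** index,

```
H-Print (%) = 100 · HBI III / (IP₂₅ + HBI II + HBI III)
```

(0 % = fully sympagic signal, 100 % = fully pelagic), which a linear
calibration from a controlled ice-algae feeding experiment converts to
**iPOC**, the sea-ice particulate organic carbon share of marine-origin
carbon in the sample:

```
iPOC (%) = 101.08 − 1.02 · H-Print        (R² = 0.97, df = 23)
```

Reported iPOC is clamped to [0, 100] (the raw line value is retained).
Samples with no measurable HBIs at all are excluded — the index is
undefined — and samples containing only phytoplankton HBIs are classified
`pelagic_only`.

On top of this the package provides:

* **Survey summaries** — species- and month-binned box-plot statistics and
  the share of consumers whose iPOC exceeds a threshold (default 50 %: a
  stronger sea-ice than phytoplankton signature).
* **Model selection** — exact QR least-squares fits of
  `iPOC ~ month + year + latitude + habitat (+ month × habitat)` term
  sets, ranked by AIC (full Gaussian likelihood, error variance counted),
  with a modular three-month-shift robustness check.
* **Sensitivity analysis** — omitted-variable-bias statistics for a chosen
  treatment: partial R² `t²/(t²+df)` and robustness values
  `RV_q = (√(f_q⁴+4f_q²) − f_q²)/2` with `f_q = q·|t|/√df`, optionally at
  a significance level α.
* **Sediment inventory** — per-layer theoretical-maximum iPOC (TOC × ice
  fraction), a constant-rate age model (`age(d) = sampling year − d/rate`),
  and the min–max iPOC accessible to infauna within a bioturbation horizon
  (default 70 mm).
* **Synthetic data** — a generator that emulates the survey's structure
  (habitat-stratified iPOC, post-bloom pelagic dips, latitude gradient,
  lognormal intensities, detection-limit dropouts) with exported ground
  truth, so every stage is testable without field data.

## Worked example

```python
from ipoc import compute_hprint, hprint_to_ipoc
from ipoc.hprint import run_pipeline
from ipoc.foodweb_stats import (_included_frame, fit_ols,
                                proportion_above, sensitivity)
from ipoc.synthetic_data import SyntheticConfig, generate_samples

h = compute_hprint(ip25=0.8, hbi2=0.4, hbi3=1.8)
raw, ipoc = hprint_to_ipoc(h)
print(f"H-Print = {h:.2f}%  ->  iPOC = {ipoc:.2f}%")

samples, truth = generate_samples(SyntheticConfig(n_samples=500, seed=11))
results, excluded = run_pipeline(samples)
count, prop = proportion_above(results, 50.0)
print(f"{len(results)} samples, {len(excluded)} excluded (no measurable HBIs)")
print(f"{count} of {len(results) - len(excluded)} included ({prop:.1%}) above 50% iPOC")

df = _included_frame(results, samples).dropna(subset=["month"])
fit = fit_ols(df, ("month", "latitude", "habitat", "month:habitat"))
s = sensitivity(fit, "habitat", alpha=0.05)
print(f"habitat: t = {fit.t('habitat'):.2f}, partial R2 = "
      f"{s.partial_r2_outcome:.3f}, robustness value = {s.robustness_value:.3f}")
```

prints

```
H-Print = 60.00%  ->  iPOC = 39.88%
500 samples, 18 excluded (no measurable HBIs)
325 of 482 included samples (67.4%) above 50% iPOC
habitat: t = 9.71, partial R2 = 0.169, robustness value = 0.361
```

A sample whose HBI pool is 60 % phytoplankton-derived gets ~40 % of its
carbon from sea ice; in this synthetic survey two-thirds of consumers
carry a stronger sea-ice than phytoplankton signature, and an unobserved
confounder would need a partial R² of ~0.36 with both habitat and iPOC to
explain the habitat effect away entirely.

The same steps are available from a shell:

```
ipoc synth --n 500 --seed 11 --out samples.csv --truth truth.csv
ipoc compute samples.csv --out results.csv --log exclusions.txt
ipoc stats samples.csv --treatment habitat --out report/
ipoc sediment core.csv --rate 1.0 --sampling-year 2008 --horizon 70 --out core_report.csv
```

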