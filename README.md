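# evquant

Single extracellular-vesicle (EV) image quantification and dual-biomarker
analysis for antibody-capture biochip assays read out by total internal
reflection fluorescence (TIRF) microscopy.

In these assays, individual EVs captured on a functionalized surface show
up as diffraction-limited bright spots — a molecular-beacon channel
reports a target mRNA (e.g. GPC1 mRNA in the exosome-rich subpopulation)
and a labeled-antibody channel reports a membrane protein (e.g. GPC1 on
tumor-associated microvesicles). `evquant` turns stacks of such frames
into a per-well summary statistic, calibrates it against vesicle
spike-ins, and carries the downstream clinical statistics: diagnostic
cutoffs, H/L quadrant calls, ROC comparison, and survival dichotomization.
A synthetic-data module generates TIRF-like frames with exact ground truth
and diagnostic/prognostic cohorts, so the entire pipeline is testable
without microscope data.

## The statistic

Each frame is wavelet-denoised, bright spots are segmented above a local
background estimate, and every spot is measured against the trimmed mean
of a surrounding annulus. Spots are kept when their equivalent diameter
lies in the EV window (6–20 px by default; smaller objects are noise
specks, larger ones aggregates) and their net intensity clears a histogram
cutoff derived from blank controls. The per-well **total fluorescence
intensity** is

```
TFI = ( Σ_k Σ_j Σ_i [ FI_in(i,j,k) − F̄I_lbg(j,k) ] ) / l
```

with `i` over the pixels of a spot, `j` over the spots of an image, `k`
over the `l` effective images of the well (a well is a 10 × 10 image
array; frames failing saturation QC reduce `l`). `FI_in` is the pixel
intensity inside the spot and `F̄I_lbg` the local background mean around
it. A sample's marker level is the mean TFI of its replicate wells, and a
log–log calibration line against EV spike-ins translates TFI into EV
equivalents per mL with a blank-mean + 3 SD limit of detection.

Downstream, a sample is called **H** (high) on a marker when its TFI is
strictly above that marker's cutoff — derived either at 100% specificity
(maximum of the control values) or by Youden's index — giving the H/H,
H/L, L/H, L/L quadrants with L/L the negative class. The statistics module
provides Mann–Whitney U (exact for small samples), empirical ROC with
DeLong comparison of correlated AUCs, two-sample power, Kaplan–Meier
estimation with Greenwood errors, the two-group log-rank test, and
maximally selected log-rank dichotomization of a marker against overall
survival.

## Worked example

```python
import evquant as ev

# simulate one well of TIRF frames with known ground truth
cfg = ev.ImageSimConfig(spot_count=20, seed=42)
images, truth = ev.simulate_well(cfg, n_images=10, well_id="W1")
result = ev.quantify_well(images, ev.QuantConfig(), channel="mrna")
n_true = sum(sum(t.category == "signal" for t in fr) for fr in truth)
print(f"well {result.well_id}: l={result.l} images, "
      f"{len(result.retained_spots)} spots retained ({n_true} true), TFI={result.tfi:,.0f}")

# dual-biomarker discovery cohort
records = ev.simulate_cohort(ev.CohortSimConfig(n_control=20, n_case=20, seed=7))
cutoffs = ev.derive_cutoff_pair(records, method="full_specificity")
print(f"cutoffs (100% specificity): mRNA {cutoffs.cutoff_mrna:,.0f}, "
      f"mProtein {cutoffs.cutoff_mprotein:,.0f}")
labels = [0 if s.is_control else 1 for s in records]
dual = ev.roc_curve(ev.combined_score(records, ("mrna", "mprotein")), labels)
print(f"dual-marker AUC = {dual.auc:.3f} (95% CI {dual.ci95[0]:.3f}-{dual.ci95[1]:.3f})")
```

prints

```
well W1: l=10 images, 183 spots retained (192 true), TFI=214,807
cutoffs (100% specificity): mRNA 73,320, mProtein 8,397
dual-marker AUC = 0.970 (95% CI 0.915-1.000)
```

The well simulation placed 192 EV-sized spots across ten frames; the
pipeline recovered 183 of them (the rest are chance overlaps merged into
one component) and their summed background-subtracted intensity, averaged
over frames, is the well TFI. On the 20 + 20 cohort the
maximum-of-controls cutoffs make every deriving control negative by
construction, and the logistic dual-marker score separates cases from
controls with AUC 0.97.

## Command line

```
evquant simulate --preset demo --seed 7 --out demo/
evquant quant --images demo/images --channel mrna --out results/ --cutoff AUTO
evquant classify --sheet demo/samples.csv --out results/
evquant roc --sheet demo/samples.csv --marker dual --out results/
evquant survival --sheet demo/samples.csv --marker mrna --out results/
```

Every results directory receives the exact run configuration and its hash
for provenance.

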