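# glymphoquant

Quantification pipelines for three readouts used in rodent studies of
spinal glymphatic function and its gut–nervous-system context:

1. **Tracer kinetics** — influx and clearance rates of an intrathecally
   injected contrast tracer, from ROI-mean MRI signal-intensity (SI) time
   series sampled over a 5 h window;
2. **AQP4 polarization** — the degree to which aquaporin-4 immunofluorescence
   is restricted to perivascular astrocytic end-feet, from registered
   AQP4/CD31 two-channel images;
3. **Histopathology scoring** — a seven-feature ordinal rubric for colonic
   injury with a 0–22 composite score.

Each stage is paired with a seeded synthetic-data generator that produces
inputs with known ground truth, so the whole pipeline can be verified
end-to-end without animal data. A small reporting layer provides
mean ± SD group summaries and ANOVA/Tukey or Kruskal–Wallis/Dunn
comparisons.

## The statistics at the core

**Kinetics.** For one animal's SI curve with baseline `SI_0` (time 0),
maximum `SI_peak` at time `T1`, and final value `SI_end` at the window end
`W` (default 5 h):

```
V1   = (SI_peak − SI_0)   / T1          # influx (absorption) rate
V2   = (SI_peak − SI_end) / (W − T1)    # clearance rate
T2   = W − T1
SIPH = (SI_peak − SI_end) / (c − T1)    # c defaults to 6; c = W makes SIPH = V2
```

Peak ties break to the earliest timepoint. Rates stay at full precision
internally; rounding to integers happens only in formatted reports.

**Polarization.** With `M_pv` the mean background-corrected AQP4 intensity
over perivascular ring ROIs (morphological dilation of the CD31 vessel
mask, minus the vessels):

```
Polarization Index = 100 × #{pixels with AQP4 < M_pv} / #{analysed pixels}
```

The inequality is strict, the index is bounded in [0, 100], and it is
invariant under affine intensity rescaling. Higher = more polarized.

**Histology.** Composite = sum of seven ordinal subscores (inflammation
depth 0–4, infiltration 0–3, crypt damage 0–4, crypt abscess 0–2,
submucosal edema 0–3, goblet-cell loss 0–3, crypt hyperplasia 0–3);
per-animal score = mean over sections.

## Worked example

```python
import glymphoquant as gq

# a noiseless tracer curve with known rates is recovered exactly
series = gq.simulate_si_curve(gq.KineticSimParams(
    initial_si=6769, v_in=1730, t_peak=1.5, v_out=547, noise_sd=0))
res = gq.estimate_kinetics(series)
print(f"v1={res.v1:.1f} v2={res.v2:.1f} T1={res.peak_time} T2={res.t2}")
# v1=1730.0 v2=547.0 T1=1.5 T2=3.5

# a simulated two-channel image is scored against its ground truth
image, truth = gq.simulate_if_image(gq.ImageSimParams(
    perivascular_enrichment=3.0, noise_sd=0, seed=13))
out = gq.quantify_image(image)
print(f"true={truth.true_polarization_index:.4f} "
      f"est={out.polarization_index:.4f} n_vessels={out.n_vessels}")
# true=98.7915 est=98.7915 n_vessels=6
```

`v1`/`v2` are the influx and clearance slopes in SI units per hour — equal
to the generating slopes because the curve is noiseless. The polarization
index of 98.8% says that almost the whole image lies strictly below the
perivascular mean: with a 3× perivascular enrichment and no noise, every
non-ring pixel does.

The same stages are available from the shell:

```sh
glymphoquant simulate-kinetics --seed 1 --out-dir sim/
glymphoquant kinetics --input sim/si_curves.csv --round-report --output out/
glymphoquant simulate-images --n-images 2 --seed 3 --out-dir imgs/
glymphoquant polarization --aqp4 imgs/img000_aqp4.tif --cd31 imgs/img000_cd31.tif \
    --output polarization.csv
glymphoquant simulate-histology --out-dir hist/ --seed 2
glymphoquant histology --grades hist/grades.csv --out scores.csv
glymphoquant report --input metrics.csv --test anova_tukey --out report.json
```

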