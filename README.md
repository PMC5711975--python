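# ciquant

Quantification of **collective cancer-cell invasion** in breast-tumor
tissue sections, and of its association with distant metastasis-free
survival.

Breast carcinomas invade the peritumoral fat predominantly as cohesive
multicellular units — compact nests, broad strands, and thin single-file
chains — rather than as single cells. `ciquant` implements the
measurement chain for this phenotype on multiplexed fluorescence-style
images (nuclear stain, pan-cytokeratin, E-cadherin, vimentin, CD44):

* **Image cytometry** — background correction, automated thresholding of
  the junctional-marker channel, exclusion of normal ducts, nucleus
  detection, and connected-component labeling of multicellular tumor
  groups versus individualized cells.
* **CI score** — the collective-invasion score of a section,

  ```
  CI = (% of total tumor area inside adipose tissue)
       / (% of adipose tissue in the whole section)
  ```

  i.e. tumor occupancy of the fat normalized by how much fat the section
  contains. CI > 1 indicates preferential adipose invasion.
* **Per-region densitometry** — mean gray values of vimentin/cytokeratin
  in luminal epithelium, invading groups, and stromal cells.
* **Survival statistics** — median dichotomization, Kaplan–Meier curves,
  Mantel–Cox log-rank test, O/E hazard ratio with 95% CI, Mann–Whitney,
  and Kruskal–Wallis with Dunn's post test — all authored in
  `ciquant.survival` and cross-checked against independent
  implementations in the test suite.
* **Synthetic data** — a first-class generator of slides (known masks,
  per-cell ground truth) and patient cohorts (known hazard structure),
  so the whole pipeline is testable without any clinical data.

## Worked example

Simulate three slides, quantify them, and stratify a simulated cohort:

```bash
ciquant simulate-slides --outdir demo/synthetic --n-slides 3 --seed 3
ciquant quantify --indir demo/synthetic --outdir demo/quant
ciquant simulate-cohort --out demo/cohort.csv --n-patients 200 --seed 3
ciquant survival --cohort demo/cohort.csv --outdir demo/survival
```

which prints

```
wrote 3 slides to demo/synthetic
quantified 3 slides (3 scored) -> demo/quant [config ed8e963e4b866aab]
wrote cohort of 200 patients to demo/cohort.csv
log-rank chi2=35.57 p=0.0000 HR=3.74 -> demo/survival
```

`demo/quant/slide_quant.csv` then holds one row per slide, e.g.

```
slide_id,pct_adipose,pct_tumor_in_adipose,ci_score,excluded,...
slide000,35.026,36.515,1.0425,False,...
```

against generator ground truth (`demo/synthetic/ground_truth.csv`) of
1.0415 for that slide — the thresholding path recovers the true score to
better than 0.1%. In the survival output, `HR=3.74` (95% CI 2.44–5.74,
log-rank p ≈ 2·10⁻⁹) is the estimate for that particular 200-patient
draw, whose true high-vs-low hazard ratio was 2.3 — a single draw can
land this far up; the calibration run below shows the estimator is
centered. `demo/survival/km_steps.csv` carries the plot-ready
Kaplan–Meier step coordinates and `survival_summary.json` the test
statistics and secondary comparisons.

The same operations are available as a library:

```python
from ciquant import synthetic, segmentation, scoring
from ciquant.datatypes import RegionMasks

image, truth = synthetic.generate_slide(synthetic.SyntheticSlideParams(seed=1))
channel = segmentation.correct_background(image["ecadherin"], "mode_subtract")
tumor = segmentation.threshold_channel(channel, "otsu")
pct_a, pct_t = scoring.area_fractions(RegionMasks(
    tissue=truth.tissue_mask, adipose=truth.adipose_mask, tumor=tumor))
print(scoring.ci_score(pct_t, pct_a))   # 0.8375 vs truth 0.8386
```

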