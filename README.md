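# cytomorph

Quantifying the **morphological structure of bacterioplankton communities**
from flow-cytometric dot clouds.

A stained bacterioplankton sample run on a flow cytometer yields, per cell,
side scatter (SSC, internal complexity), green fluorescence (FL1, nucleic
acid content) and forward scatter (FSC, cell size). After gating and log10
transformation these events form a three-dimensional dot cloud whose shape
is a physical fingerprint of the community. `cytomorph` extracts a
12-metric fingerprint per sample, checks replicate quality, classifies
communities into categorical types, and links the fingerprints to
environmental drivers — with a synthetic-data generator so the entire
workflow is testable without instrument data.

## The model

**Geometric dimension.** The cloud is summarized by its 90% covariance
error ellipsoid. With sample mean μ and covariance Σ of the log10
(SSC, FL1, FSC) events, the ellipsoid is {x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₀.₉₀,₃},
where χ²₀.₉₀,₃ = 6.251 is the chi-square critical value at 90% confidence
with 3 degrees of freedom. Its axis lengths along the channels are

    W = 2·√(6.251·λ_SSC),  H = 2·√(6.251·λ_FL1),  L = 2·√(6.251·λ_FSC)

with λ the covariance eigenvalues attributed to channel axes by dominant
eigenvector loading. Volume is V = (4/3)·π·a·b·c with semi-axes a, b, c =
W/2, H/2, L/2, and eccentricity e = √(1 − b²/a²) is computed in the
FL1–SSC plane from W and H (0 = circular, → 1 = elongated).

**Topographic dimension.** Cloud orientation is captured by Type II
(major-axis) regression slopes — the line minimizing perpendicular
residuals, appropriate when both channels carry error — in the FL1–SSC,
FL1–FSC and SSC–FSC planes. Internal heterogeneity is the number of
*cytometric populations*: density peaks of the cloud in the FL1–SSC plane,
found by seeded k-means over-segmentation followed by density-valley
merging.

Together: three centroids, W, H, L, V, eccentricity, three slopes, and the
population count — 12 metrics per sample. Duplicate acquisitions are
compared with a two-sided F-test on the FL1 variance (pairs rejected at
α = 0.05 are discarded) and averaged. Downstream, samples are classified
(prolate H > W vs oblate W > H; volume small < 2.5 / medium 2.5–3.5 /
large > 3.5; simple = 1 population vs complex ≥ 2) and the metric block is
ordinated (Bray–Curtis PCoA, PERMANOVA) and regressed on environmental
variables (PLS2 with VIP ≥ 0.8 predictor selection).

## Worked example

```bash
cytomorph simulate --n-samples 12 --n-events 20000 --seed 7 --out demo/study
cytomorph extract  --manifest demo/study/manifest.csv --out demo/out
cytomorph stats    --metrics demo/out/metrics.csv \
                   --env demo/study/environment.csv --out demo/out
```

or equivalently from Python:

```python
from cytomorph import StudySpec, generate_study, PipelineConfig, run_all
from cytomorph.simulate import write_study

write_study(generate_study(StudySpec(n_samples=12, n_events=20_000, seed=7)),
            "demo/study")
bundle = run_all(PipelineConfig(manifest="demo/study/manifest.csv",
                                env_path="demo/study/environment.csv",
                                outdir="demo/out"))
```

The extracted fingerprints (`demo/out/metrics.csv`) begin:

```
sample_id     H     W     V  eccentricity  n_populations_int
  lake000 2.507 0.987 1.352         0.919                  2
  lake001 1.863 1.365 1.983         0.680                  1
  lake002 1.904 1.383 2.069         0.687                  1
```

`lake000` is a tall (H ≈ 2.5 log-decades), narrow, strongly elongated
(e ≈ 0.92) cloud with two density peaks — a prolate, complex community of
the kind found in productive, evaporated waters — while `lake001–002` are
single-population prolate clouds. The statistics stage reports that the
first two PCoA axes carry 92.7% of the Bray–Curtis variance among the
fingerprints, and the PLS variable-importance scores select five
environmental predictors at VIP ≥ 0.8, led by TP (total phosphorus,
VIP 1.28) — the trophic driver wired into the generator.

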