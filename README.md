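# hypercsi

Processing pipeline for hyperpolarised [1-¹³C]pyruvate chemical shift
imaging (CSI) of the mouse brain, together with a digital phantom
generator and a nocturnal locomotor-tracking module.

Hyperpolarised [1-¹³C]pyruvate MRI transiently boosts the ¹³C signal by
several orders of magnitude, making the conversion of injected pyruvate
to lactate (via LDH, a glycolytic flux surrogate) and to bicarbonate
(via PDH, an oxidative-phosphorylation surrogate) visible in vivo. A
2-D phase-encoded CSI acquisition yields a complex tensor
`(x, y, spectral)` — one free-induction decay per k-space line — from
which whole-brain metabolite ratios (Lac/Pyr, Bic/Pyr, Lac/Bic) are the
readout. The package is aimed at preclinical MR groups who want a
tested, reproducible version of this reconstruction chain, and at
methods developers who need ground-truth phantoms to validate each
stage.

## The processing chain

Starting from 16×16 centric-ordered k-space (TR 75 ms, FA 10°, 2 kHz /
128 points at 1.5 T):

1. **Reconstruction** — orthonormal inverse 2-D DFT over space, FFT over
   the spectral axis.
2. **Tensor denoising** — truncated higher-order SVD (Tucker) of the
   `(x, y, f)` tensor with core ranks (8, 8, 12): the mode-k factors are
   the leading left singular vectors of the mode-k unfoldings, and the
   tensor is projected onto those subspaces.
3. **Guided super-resolution** — each spectral bin is reconstructed onto
   the 64×64 grid of the (downsampled) T₂-weighted anatomical image by
   minimising `‖Dx − y‖² + λ Σₑ wₑ (xᵢ − xⱼ)²`, where `D` is the 4×4
   block-mean operator and the edge weights `wₑ ∈ (0, 1]` decrease with
   the anatomical gradient, so smoothing breaks at tissue boundaries.
4. **Quantification** — first-point-corrected, apodised, zero-filled
   spectra; a local complex polynomial baseline is subtracted under each
   peak window and the AUC is the magnitude of the complex window
   integral (phase-insensitive). Whole-ROI ratios are ratios of
   ROI-summed AUCs over an Otsu-derived brain mask.
5. **Group statistics** — per-animal whole-ROI ratios are compared
   against the pre-treatment group with a pooled-variance unpaired
   two-sided Student's t-test, and reported as mean ± SD with percent
   change vs baseline.

The phantom module generates all of this synthetically with known
ground truth: an elliptical brain with smoothly heterogeneous
pyruvate/lactate/bicarbonate/alanine/pyruvate-hydrate amplitude maps
(mask-mean ratios pinned exactly to requested targets), Lorentzian
lines at literature shifts, per-shot RF/T₁ polarisation consumption if
enabled, circular complex k-space noise, and a matched 128×128 T₂w
guide. The locomotion module simulates, renders and tracks 30×19 cm
home-cage sessions and reports distance per hour.

## Worked example

```python
from hypercsi.pipeline import run_pipeline

res = run_pipeline({"phantom": {"ratios": {"Lac/Pyr": 0.256,
                                           "Bic/Pyr": 0.138}},
                    "noise": {"snr": 20.0}}, seed=1)
for name, val in res.whole_roi_ratios.items():
    print(f"{name:22s} recovered {val:.4f}   truth {res.truth_ratios[name]:.4f}")
```

prints

```
lactate/pyruvate       recovered 0.2503   truth 0.2560
bicarbonate/pyruvate   recovered 0.1395   truth 0.1380
lactate/bicarbonate    recovered 1.7945   truth 1.8551
```

i.e. a single noisy acquisition at peak SNR 20 recovers the commanded
whole-brain ratios to a few percent; averaging over seeds (as the
acceptance script does) brings the recovery well under 1%. The same
pipeline is available from the shell:

```bash
hypercsi run --config pipeline.yaml --seed 1 --out results/
hypercsi simulate --seed 1 --out run.h5 --guide-out t2w.nii.gz
hypercsi denoise --in run.h5 --ranks 8 8 12 --out run_dn.h5
```

Every run writes a manifest (config hash, stage list, output digests)
sufficient for exact replay.

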