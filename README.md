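# neuropipe

A desk-scale toolkit for the bespoke computational stages of a large
multimodal brain-MRI processing and quality-control pipeline, exercised
entirely on synthetic phantoms. Every stage runs in seconds on a laptop
— no scanner data, no external atlases, no GPU.

## What it does

The package covers nine processing stages:

1. **Synthetic phantoms** (`neuropipe.phantom`) — a structural T1-like
   phantom with tissue compartments, 15 subcortical structures, a bias
   field, a nonlinear-warp magnitude map and controllable artifact
   injection (11 "unusable" problem codes and 7 milder imperfection
   codes); plus simulators for two-echo multi-coil susceptibility
   acquisitions, interspersed b=0 diffusion volumes, and group
   resting-fMRI with known network structure.
2. **Protocol conformance** (`neuropipe.conformance`) — checks acquired
   dimensions, voxel sizes, volume counts and diffusion shell structure
   against the reference protocol, and routes non-conformant data into
   `unusable/` subfolders (an unusable T1 blocks all downstream
   processing).
3. **Defacing** (`neuropipe.deface`) — rasterises face/ear box masks
   defined in standard space into native space via an affine, with an
   auditable brain-overlap report.
4. **Bias-field transfer** (`neuropipe.bias`) — applies a bias field
   estimated elsewhere and quantifies the result by the interquartile
   range of median-normalised white-matter intensity.
5. **swMRI processing** (`neuropipe.swmri`) — per-coil homodyne phase
   filtering, complex coil combination, fourth-power venogram, two-echo
   R2*/T2* relaxometry, in-plane median filtering with limited
   hole-filling, and per-structure T2* summaries.
6. **Fieldmap b=0 selection** (`neuropipe.b0select`) — picks the b=0
   volume that best correlates with the rest, with a threshold-gated
   preference for the first volume.
7. **fMRI networks** (`neuropipe.fmrinet`) — Gaussian-weighted
   straight-line highpass filtering, incremental group PCA (MIGP), dual
   regression, artefact-node cleanup, full and L2-regularised partial
   netmats with an autocorrelation-corrected r-to-z transform, netmat
   vectorisation, spatial smoothing and ROI activation summaries.
8. **T1 QC features** (`neuropipe.qcfeatures`) — a manifest of exactly
   190 named features in 16 categories (template discrepancy, SNR/CNR,
   volumes, asymmetries, mask quality, warp statistics, lesions, …)
   extracted from a phantom bundle.
9. **QC classification** (`neuropipe.qcclassify`) — Gaussian naive
   Bayes, a discrete Bayesian-network classifier and a cost-sensitive
   MetaCost wrapper, fused by the Minimum-Probability rule, evaluated
   with stratified k-fold cross-validation.

`neuropipe.benchmark` ties it together: it generates a labelled cohort
of 240 phantoms (200 clean with natural anatomical variation, 40 with
injected problems) and scores the classifier on it.

## Worked example

```python
from neuropipe.phantom import PhantomParams, generate_t1_bundle
from neuropipe.qcfeatures import default_manifest, extract_all
from neuropipe.benchmark import make_qc_benchmark
from neuropipe.qcclassify import cross_validate, confusion_metrics

vec = extract_all(generate_t1_bundle(PhantomParams(seed=11)))
print(len(vec.values))                  # 190

X, y = make_qc_benchmark(seed=0)        # ~30 s
m = confusion_metrics(cross_validate(X, y, k=10, seed=0))
print(m["sensitivity"], m["flagged_rate"])   # 0.975  0.1625
```

A `neuropipe` command-line interface exposes the same stages
(`neuropipe phantom`, `neuropipe qc`, `neuropipe swmri`, …); run
`neuropipe --help`.

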