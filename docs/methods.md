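# Methods

## The statistic

For one nucleus with locus ROI `L` and nucleus mask `N` (with `L ⊆ N`), the
enrichment score on the signal channel `g` is

```
E = max_{v∈L} g(v) / max_{v∈N} g(v)
```

`E ∈ (0, 1]` because the locus is part of the nucleus, and `E = 1` iff the
locus contains a voxel attaining the nucleus-global maximum. The whole-nucleus
maximum deliberately *includes* the locus; excluding it would remove the upper
bound and change the statistic's meaning.

Properties that matter in practice:

* **Shift sensitivity.** Adding a constant background `c` moves the score
  toward 1 monotonically (`(m+c)/(M+c)` is increasing in `c`). The default
  applies no background subtraction — the score is defined on the raw
  channel — but an in-nucleus median subtraction (clipped at zero) is
  available (`QuantifyParams.background_subtract`) for acquisitions with a
  large camera offset.
* **Noise sensitivity.** A literal maximum rides the extreme order statistic
  of Poisson noise. A robust variant replaces both maxima with the
  `q`-quantile of the respective voxel sets (`estimator="quantile"`, default
  `q = 0.999`). Because the locus voxel set is small, its high quantile is
  close to its maximum while the nucleus's is not, so the robust score is
  *not* bounded by 1; it separates enriched from unenriched conditions at
  least as well (`analysis/04_estimator_robustness.py`). `strict_max` remains
  the default because it is the assay's published definition.
* **2D vs 3D.** Maxima can be taken on a single optical section (default) or
  a full 3D stack; the choice is recorded in the run config. For a
  max-statistic a representative section exercises the same machinery at a
  fraction of the cost.

## Segmentation and detection

* **Nucleus (DAPI):** Gaussian smoothing (`smoothing_sigma` 2 px) → Otsu
  threshold → largest connected component ≥ `min_nucleus_size` (500 px) →
  hole filling. Otsu on the smoothed channel is intensity-scale invariant, so
  laser power/gain differences do not move the mask. Nuclei touching the
  image border are excluded by default (truncated nuclei bias a
  max-statistic); every exclusion is logged with its reason.
* **Locus (red):** voxels above the `threshold_quantile` (default 0.995) of
  *in-nucleus* red intensities form candidate foci; the focus with the
  highest peak intensity is kept, dilated by `dilation_radius` (default
  2 px) and re-intersected with the nucleus. The quantile adapts to focus
  brightness — the binding-site-mutant construct's dimmer focus is still
  found — and the dilation absorbs ~1 px chromatic/registration offsets
  between the red and green channels; sensitivity to this radius is part of
  the shipped robustness analysis. Multiple candidate foci are counted and
  flagged (`qc` column): the constructs are single-locus insertions, so extra
  foci indicate artefacts. How the original assay delimited its ROI is not
  public; quantile-plus-dilation is this package's own, tested, choice.

## Group statistics

Default test: two-sided Mann–Whitney U on per-nucleus scores — robust for a
bounded ratio with ties at 1. Reference implementation: a seeded permutation
test on the difference of group means (add-one Monte-Carlo p with ≥ 10,000
shuffles; exact enumeration of all label assignments whenever their number
does not exceed the shuffle budget, so groups totalling ≤ 12 are always
exact). Labels follow the assay's convention: `***` p ≤ 1e-4, `*` p ≤ 0.01,
`ns` otherwise; no intermediate tier exists. No multiplicity adjustment by
default (matching the assay's presentation); Holm-adjusted p-values can be
reported alongside.

The experimental unit is deliberately ambiguous in this kind of assay
(per-nucleus signals, p-values attributed to three biological replicates).
The package's primary analysis pools per-nucleus scores across replicates;
a replicate-level analysis (Welch's t on per-replicate means, n = number of
replicates) is always computed next to it. Neither is presented as "the"
correct unit; with three replicates the replicate-level test is low-powered
by construction.

## The synthetic scene generator

The generator emulates single polytene nuclei in 2D 256×256 sections at
0.06 µm/px (a desk-scale stand-in for full-frame acquisitions; the geometry,
not the pixel count, is what the statistic sees):

* **Nucleus:** ellipse, default semi-axes 85×105 px, random orientation.
* **DAPI texture:** sinusoidal bands (default 12) across the long axis with a
  smooth random phase wobble, contrast 0.5 — only the band/interband
  intensity statistics matter downstream, not chromosome anatomy.
* **Red locus:** one anisotropic Gaussian focus (σ default 3 px, jittered
  0.7–1.3×; position uniform within 0.6 of the nucleus radius; amplitude
  600 photons, halved for the mutant-enhancer preset). Ground-truth locus
  mask: the 2σ ellipsoid.
* **Green signal:** background level `B` (120 photons; 3× for the
  bright-dimer presets) times a texture that is a `green_band_coupling`
  (default 0.6) mixture of the DAPI-band texture and an independent smooth
  texture — the interaction signal follows chromatin only partially — times
  `1 + β·locus_profile`. The effect size `β` (`enrichment_beta`) is 0 for
  null conditions and 1.5 for enriched presets.
* **Optics/noise:** Gaussian PSF with σ 0.85 px (FWHM ≈ 0.12 µm at the
  default voxel size), then Poisson shot noise plus Gaussian read noise
  (σ 3 photons), clipped at zero. Stacks are written as 16-bit TIFF with
  round-half-even quantization and a saturation flag on clipping.

Determinism: every scene is a pure function of its spec; texture and noise
streams derive from `seed` via independent child sequences, and dataset-level
jitter derives from the dataset seed and the condition name, so whole runs
are bit-reproducible.

What the generator does **not** model: Airy/vendor PSFs and deconvolution,
spectral bleed-through, chromatic aberration beyond what the ROI dilation
absorbs, nucleus-to-nucleus depth effects, autofluorescence gradients, or
real polytene banding genomics. Passing tests therefore demonstrate that the
*pipeline* recovers known effects under realistic photon statistics and
partial DAPI/green correlation — not that real acquisitions are free of the
unmodelled artefacts above.

## Validation studies and problem sizes

* Statistic vs brute-force voxel-scan oracle: 200 randomized toy scenes
  ≤ 32×32, exact equality required.
* Recovery: 20 jittered default scenes — nucleus IoU ≥ 0.90, locus centroid
  error ≤ 2 px, mutant-preset detection ≥ 95 %.
* Power/pattern: 50 runs of the seven-condition experiment, 30 nuclei × 3
  replicates each; enriched-vs-control contrasts significant at `*` and the
  mutant `ns` against its null in ≥ 90 % of runs; enriched condition means
  exceed all unenriched means.
* Null calibration: 200 repetitions of 30-vs-30 nuclei from the identical
  null preset; rejection rate at α = 0.01 must lie in [0.002, 0.03].
* Simulator fidelity: Poisson variance/mean within 10 % at λ ≥ 50 over
  ≥ 10⁵ voxels; bit-identical regeneration; the 3× global-green construction
  between the bright-dimer and reference presets verified exactly pre-noise.
* Determinism: a full pipeline run repeated under one config/seed yields
  byte-identical score and comparison CSVs.

These sizes were chosen so the whole validation runs in minutes on a single
CPU while keeping Monte-Carlo tolerances meaningful.

## Numerical and degenerate-input choices

* Coordinates 0-based, axis order (Z,)Y,X everywhere; masks are boolean voxel
  sets; intensities float32 in memory, uint16 on disk.
* Constant or all-zero DAPI → `NoNucleusFound`; no voxel above the red
  threshold → `NoLocusFound`; zero green over the nucleus →
  `DegenerateSignal`. All three exclude the nucleus with a logged reason
  rather than aborting the run; a manifest whose every scene fails is a
  pipeline error.
* Permutation ties are compared with a 1e-12 absolute tolerance on the
  difference-of-means statistic.
* Scene specs validate geometry eagerly: the nucleus plus a 3σ PSF margin
  must fit in the frame, and the locus centre must lie inside the nucleus
  ellipsoid.

## Known limitations

* The locus ROI definition (quantile + dilation) is this package's decision;
  with strongly clustered red background it may differ from hand-drawn ROIs.
* The strict-max statistic saturates at 1: very strong enrichment compresses
  against the upper bound, so effect *sizes* near saturation are not
  comparable, only their presence.
* The replicate-level test with three replicates has little power; pooled
  per-nucleus p-values treat nuclei as exchangeable across replicates.
* 3D support is functional but second-class: defaults, presets and the
  validation studies are tuned for 2D sections.
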