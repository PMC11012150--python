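# bifor

Quantification of protein-complex enrichment at a fluorescently labelled
genomic locus in nuclear confocal images, with a fully synthetic validation
harness.

## The problem

In *Drosophila* salivary-gland nuclei, a genomic locus (an enhancer carrying
*INT* cassettes bound by ParB–mCherry) appears as a single bright red focus,
while a green channel reports a protein–protein interaction signal
(bimolecular fluorescence complementation) distributed over the polytene
chromosomes. The biological question is whether the green signal is
*specifically enriched* at the labelled enhancer — i.e. whether a given
protein complex is recruited to that locus — and whether that enrichment
differs between constructs (wild-type, binding-site mutant, consensus
enhancer; different protein pairs).

For each nucleus the package computes the enrichment ratio

```
E = max(green | locus ROI) / max(green | whole nucleus),   E ∈ (0, 1]
```

the maximum signal intensity measured on the labelled enhancer divided by the
maximum signal intensity measured in the whole nucleus. `E = 1` exactly when
the locus contains a nucleus-global maximum voxel — the signature of strong
recruitment. Conditions are compared with a two-sided Mann–Whitney U test on
per-nucleus scores (a seeded permutation test is the reference
implementation), and labelled `***` (p ≤ 1e-4), `*` (p ≤ 0.01) or `ns`.

The pipeline is: nucleus segmentation from DAPI (Gaussian smoothing + Otsu +
largest component), locus detection from the red channel (in-nucleus
intensity quantile + brightest connected focus + small dilation), then the
ratio on the green channel, then group statistics across conditions and
biological replicates.

Because no public acquisitions exist for this assay, the package ships a
synthetic scene generator with known ground truth — banded elliptical nuclei,
a red locus focus of variable size/shape/position, a green background only
partially coupled to the banding, an optional multiplicative enrichment at
the locus, Gaussian PSF blur, and Poisson + Gaussian noise — so every stage
is validated against truth masks and known effect sizes.

## Worked example

Run the seven-condition demo (10 nuclei × 3 replicates per condition):

```bash
python analysis/01_simulate_conditions.py
python analysis/02_quantify_enrichment.py
python analysis/03_compare_conditions.py
```

or equivalently `bifor run --outdir results/demo_run --seed 20240613`.
The quantification step prints:

```
scored 210/210 nuclei (0 excluded); per-condition mean enrichment:
               mean  median  count
condition
SCR_ALONE_WT  0.782   0.784     30
SCR_EXD_CONS  0.987   1.000     30
SCR_EXD_MUT   0.754   0.751     30
SCR_EXD_WT    0.970   1.000     30
UBX_ALONE_WT  0.781   0.771     30
UBX_EXD_CONS  0.939   1.000     30
UBX_EXD_WT    0.766   0.755     30
```

Enriched conditions (Scr/Exd on the wild-type enhancer, both dimers on the
consensus enhancer) sit near 1 — the locus usually *is* the brightest spot in
the nucleus — while unenriched conditions (monomers, Ubx/Exd on the wild-type
enhancer despite its 3× brighter global signal, and the binding-site mutant)
sit near 0.75. The comparison step prints the significance pattern:

```
  SCR_EXD_WT     vs SCR_ALONE_WT   p= 5.07e-09  ***
  SCR_EXD_WT     vs UBX_EXD_WT     p= 8.92e-10  ***
  SCR_EXD_WT     vs SCR_EXD_MUT    p= 3.79e-10  ***
  UBX_EXD_WT     vs UBX_ALONE_WT   p=     0.52  ns
  SCR_EXD_MUT    vs SCR_ALONE_WT   p=    0.252  ns
  SCR_EXD_CONS   vs SCR_EXD_MUT    p= 1.23e-11  ***
  UBX_EXD_CONS   vs UBX_EXD_WT     p= 1.16e-06  ***
```

i.e. specific enrichment is detected exactly where the simulated conditions
contain it, and nowhere else. `analysis/04_estimator_robustness.py` compares
the strict-maximum estimator against the robust quantile(0.999) variant and
the sensitivity to the locus-ROI dilation radius on identical scenes.

## Library and CLI surface

```python
import bifor

spec = bifor.SceneSpec(enrichment_beta=1.5, seed=1)
stack, truth = bifor.generate_scene(spec)
nucleus = bifor.segment_nucleus(stack.channels["dapi"])
locus = bifor.detect_locus(stack.channels["red"], nucleus)
score = bifor.enrichment_ratio(stack.channels["green"], locus, nucleus)
```

CLI subcommands: `bifor simulate`, `bifor quantify`, `bifor compare`,
`bifor run` (see `--help` of each).

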