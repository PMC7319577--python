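# probekit

Normalization, analysis and visualization of low-throughput RNA chemical
probing data (SHAPE, DMS, CMCT) read out by capillary electrophoresis.

Chemical probing reports, per nucleotide, how susceptible an RNA is to
modification by a reagent — high reactivity marks flexible, mostly unpaired
positions. Turning QuShape's raw per-nucleotide signal into something a
structure-prediction tool can use takes several tedious manual steps:
normalization, replicate averaging, file-format conversion, running several
predictors, and drawing the results. probekit automates that workflow as an
importable Python library with a thin command line on top. It is aimed at
bench scientists probing individual RNAs (riboswitches, aptamers, regulatory
elements) and at bioinformaticians who want the same normalization applied
identically across a series of experiments.

## What it computes

**2–8% box-plot normalization.** From the *N* measured reactivities, the top
10% most reactive positions are selected (⌈0.10 N⌉) and the top 20% of that
selection (⌈0.20 ⌈0.10 N⌉⌉) is excluded as outliers. The divisor is the mean
of the remaining ≈8% most-reactive values; every measured value is divided by
it and clamped to [0, 1]. Positions with no readout stay *missing* (written
as −999 in reactivity files, displayed as −1 in tables and B-factors). For
DMS and CMCT the divisor can be computed from the reagent-susceptible letters
only (A/C for DMS, G/U for CMCT).

**Probing-directed prediction.** Normalized reactivities are handed, in the
two-column dialect used by RNAfold's and ShapeKnots' SHAPE options, to
external engines: RNAfold (SHAPE mode) and ShapeKnots for SHAPE data,
RNAstructure Fold for DMS/CMCT, and eight sequence-only methods in prediction
mode. Reactivity-to-pseudo-energy conversion happens inside those tools;
missing executables are skipped, never fatal.

**Base-pair consensus.** Across a set of equal-length predictions, every base
pair present in at least 50% of them (configurable) is retained; conflicting
pairs are resolved by occurrence frequency, then lexicographically.
Pseudoknotted (crossing) pairs are fully supported through multi-family
dot-bracket notation.

**Visualization and 3D mapping.** Per-nucleotide heatmaps (SHAPE
yellow–orange–red, DMS yellow–green, CMCT white–red), three-bin barplots
(black < 0.3 ≤ orange < 0.7 ≤ red), VARNA color-map/invocation exports for
radiate, circular and linear layouts, and injection of reactivities into the
B-factor columns of a PDB file for any 3D viewer that colors by temperature
factor.

## Worked example

```python
from probekit import normalize_profile, parse_qushape, write_reactivity_file
from probekit.synthetic import SynthParams, hairpin_structure, synth_profile, synth_qushape

raw = synth_profile(SynthParams(structure=hairpin_structure(), seed=7))
result = normalize_profile(parse_qushape(synth_qushape(raw)))
print(f"divisor: {result.factor:.2f} "
      f"(selected top {result.n_selected}, excluded top {result.n_excluded})")
print("\n".join(write_reactivity_file(result.profile).splitlines()[:3]))
```

prints

```
divisor: 501.62 (selected top 3, excluded top 1)
1 0.269
2 0.065
3 0.154
```

The divisor is the mean of the 2 most-reactive positions that survive outlier
exclusion (30 measured values → select 3, exclude 1); each line of the
reactivity file is a 1-based position and its normalized value, with −999
marking positions without a readout. The same analysis from a shell:

```bash
probekit shape --seq-text GGCGA... --qushape replicate1.tsv --outdir results/
probekit predict --seq-text GGCGA... --outdir results/
```

`examples/` holds one short script per capability (normalization, consensus,
the full SHAPE pipeline, PDB B-factor mapping), each printing the numbers it
computes.

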