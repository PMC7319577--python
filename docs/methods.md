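# Methods

## The probing signal and its normalization

Chemical probes modify RNA nucleotides in a conformation-dependent way: SHAPE
reagents acylate the 2′-hydroxyl of flexible (mostly unpaired) nucleotides at
every base identity, DMS methylates the Watson–Crick face of unpaired A (N1)
and C (N3), and CMCT modifies unpaired U (N3) and G (N1). After capillary
electrophoresis and QuShape quantification, the per-nucleotide signal is in
arbitrary instrument units and must be normalized before structure prediction
tools can consume it.

probekit applies the box-plot ("2–8%") rule to the measured values of one
profile:

1. `n_selected = ⌈0.10 N⌉` most-reactive values are selected;
2. `n_excluded = ⌈0.20 n_selected⌉` of those, the very highest, are excluded
   as outliers;
3. the divisor is the mean of the remaining values (ranks
   `n_excluded+1 … n_selected` in descending order);
4. every measured value is divided by the divisor, then clamped to [0, 1]
   (values > 1 become 1, negative background-subtracted values become 0).

Ceiling rounding for both counts is a deliberate choice: the rule then stays
defined down to N = 11 (select 2, exclude 1, average 1), and the error raised
below that reports the minimum. Ties in the descending ranking are broken by
position order (stable sort), so the divisor is deterministic. Values already
in [0, 1] are renormalized like any others — the operation has no hidden fast
path, so repeated runs over a series of experiments are always comparable.

In nucleotide-specific mode (DMS/CMCT) the divisor is computed only from
measured values at susceptible letters, but *all* measured positions are
divided and clamped, so the full profile remains displayable; a separate
engine-input flag (`mask_unsusceptible`) writes −999 at non-susceptible
positions when the downstream folding engine should ignore them. Both
behaviors are exposed because reasonable pipelines differ here.

Missing data is a state, not a number. Internally a position is `measured` or
`missing` (NaN-backed); the sentinels −999 (reactivity files) and −1 (tables,
VARNA color maps, B-factors) exist only at serialization boundaries.
Replicates are normalized *before* averaging; the average at a position uses
whichever replicates measured it and is missing only when all replicates are.

## Inputs and coordinates

Sequences are canonicalized to uppercase A/C/G/U (T accepted and read as U;
FASTA headers stripped). All coordinates are 1-based and inclusive. QuShape
exports are tab-separated with the sequence in the `seqRNA` column; the
reactivity column defaults to `areaDiff` (QuShape's background-subtracted
signal) and is configurable since QuShape exports several candidate columns.
A region of interest trims cassette nucleotides from both ends before
analysis and renumbers from 1, recording the applied offset in the profile's
origin label. Sequence disagreements between the profile and the user
reference are reported position-by-position; `strict` mode turns a non-empty
report into an error. Input length is capped at 600 nt by default (prediction
quality and engine runtime degrade beyond that) and the cap is a visible,
overridable parameter.

## Secondary structures, pseudoknots, consensus

A structure is a set of pairs `(i, j)`, `i < j`, each position used at most
once; crossing pairs are permitted. Dot-bracket text uses one stack per
bracket family — `()`, `[]`, `{}`, `<>`, then `Aa`…`Zz` — so pseudoknots of
up to 30 layers parse and write. The writer assigns pairs (ascending `i`)
greedily to the first family where they cross nothing already placed, which
reproduces the conventional `()`‑only text for nested structures. No minimum
hairpin-loop size is enforced on parsed structures: user-supplied structures
are accepted as given, and folding engines enforce their own.

The consensus over ≥ 2 equal-length predictions keeps pairs whose occurrence
fraction is at least the threshold (default 0.5, i.e. "at least half", with
exact boundary inclusion). Candidates sharing a nucleotide are resolved by
higher frequency, then smaller `(i, j)`; this tie-break is a determinism
choice, since pure pair-set voting does not define one. Raising the threshold
can only remove pairs.

## Prediction engines

Engines are external programs behind a uniform adapter: SHAPE mode runs
ViennaRNA RNAfold (`--shape`) and RNAstructure ShapeKnots; DMS/CMCT run
RNAstructure Fold with the matching option; prediction mode runs RNAfold,
Fold, ProbKnot, CentroidFold, CONTRAfold, IPknot and LinearFold (CONTRAfold
and Vienna parameterizations). Everything runs with default settings; the
conversion of reactivities into pseudo-energies is each tool's own job and is
not reimplemented. A missing executable produces a `skipped` prediction with
a warning — a run degrades to whichever engines are installed, and a probing
run with zero engines still yields the normalized profile, plots and files.
Engine output is validated (dot-bracket or CT, correct length) before a
prediction counts as `ok`. A scripted in-process mock engine exercises the
ok/failed/skipped contract in tests without any installation.

## Visualization and 3D mapping

Heatmap ramps per probe: SHAPE `YlOrRd`, DMS `YlGn`, CMCT `Reds`; missing
positions are neutral grey, which no ramp contains. The barplot bins values
black/orange/red at 0.3 and 0.7; bins are left-closed/right-open except the
last, so 0.3 is orange and 0.7 is red (the boundary ownership is a
convention fixed here for determinism). Plots are written as both PNG and
SVG. VARNA is treated as an optional Java renderer: the module always writes
a per-nucleotide color-map file (missing as −1) and a complete invocation
descriptor for the radiate/circular/linear layouts, and runs Java only when
a jar is configured; with `grey_out`, non-susceptible positions of DMS/CMCT
profiles are listed for grey rendering.

PDB mapping is textual surgery on fixed columns: the k-th residue of the
chosen chain (author order, model 1) is matched to profile position
`k + offset`, letter mismatches are reported (> 10% disagreement aborts with
a position list, which usually means the offset is wrong), and matched
residues receive their value in columns 61–66 (`%6.2f`) of every atom
record. Missing and unmatched residues get −1.00. Bytes outside those
columns are preserved exactly, so nonstandard records survive the round
trip. mmCIF and multi-model ensembles are out of scope; model 1 is used when
MODEL records exist.

## Synthetic data

The generator draws position `i` from
`scale · max(0, Normal(mean_i, noise_sd))` where `mean_i` is the paired or
unpaired mean under a ground-truth structure, and drops each position with
the missing rate. Defaults — paired mean 1, unpaired mean 5, noise sd 0.5,
5% missing, scale 100 — emulate a clean low-throughput experiment with a 5×
paired/unpaired contrast and an arbitrary instrument gain. Truncation at
zero keeps raw values physically nonnegative (the negative-clamp path is
exercised by explicit fixtures instead). The generator does not model signal
decay along the read, sequence-dependent reactivity, primer shadows or
band-compression artifacts, so passing recovery tests shows the pipeline
preserves a pairedness contrast, not that it corrects real CE artifacts.
Versioned ground-truth topologies: a 30-nt hairpin, a 40-nt H-type
pseudoknot, and a 60-nt three-helix junction.

## Numerical notes

* The divisor equals a full-sort/slice/mean computation bit-for-bit; tests
  compare against an independent brute-force oracle.
* Normalization is scale-invariant: mathematically `normalize(c·x) =
  normalize(x)` for any `c > 0`. In IEEE-754 arithmetic the identity is
  bitwise only when `c` is a power of two; otherwise `c·x` itself rounds
  per-element and outputs may differ by a few ulp (relative ~1e-15), which is
  how the property is asserted.
* Averaging replicates is order-invariant up to the same few-ulp float
  summation effects.
* B-factor injection is exact to the `%6.2f` format, i.e. within 0.005 of
  the stored value on reparse.
* Problem sizes in the test-suite (profiles ≤ 500 nt, ensembles ≤ 8
  structures of length ≤ 40, 100-seed recovery simulations on the 30-nt
  hairpin) are chosen so the whole suite runs in seconds while still covering
  the small-N edge cases the ceiling rule creates.

## Known limitations

* No chromatogram processing: QuShape's signal alignment and quantification
  are upstream.
* No folding algorithms of its own and no pseudo-energy conversion; absent
  engines mean absent predictions.
* Single-probe analyses only; combining SHAPE+DMS+CMCT evidence in one
  prediction is not attempted.
* The QuShape reactivity column name varies across exports; `areaDiff` is a
  default, not a guarantee — pass `reactivity_column` explicitly when in
  doubt.
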