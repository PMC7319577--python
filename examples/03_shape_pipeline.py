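"""A complete SHAPE-mode analysis run.

Generates a synthetic QuShape replicate for a hairpin RNA, then runs the full
pipeline: normalization, SHAPE-directed prediction (ViennaRNA RNAfold if
installed; RNAstructure ShapeKnots is skipped when absent), heatmap, barplot,
VARNA export files and the results table.  Artifacts land in
``example_output/``.
"""

from probekit.pipeline import RunConfig, run
from probekit.synthetic import SynthParams, hairpin_structure, synth_profile, synth_qushape

raw = synth_profile(SynthParams(structure=hairpin_structure(), seed=7))
config = RunConfig(
    mode="shape",
    sequence=raw.sequence.residues,
    qushape_texts=[synth_qushape(raw)],
    qushape_origins=["replicate1.tsv"],
    outdir="example_output",
    layouts=("radiate",),
)
bundle = run(config)

entry = bundle.run_log["normalization"][0]
print(f"normalization divisor: {entry['factor']:.2f} ({entry['subset']})")
for e in bundle.run_log["engines"]:
    print(f"engine {e['engine']}: {e['status']}")
for pred in bundle.ok_predictions():
    print(f"  {pred.engine} found {len(pred.structure.pairs)} base pairs")
print("\nartifacts written:")
for path in bundle.manifest:
    print(f"  {path}")
print("\nThe heatmap/barplot show the normalized profile; reactivities.txt "
      "is ready for RNAfold/ShapeKnots-style tools.")
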