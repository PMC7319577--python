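"""Normalize a QuShape export with the 2-8% rule.

Builds a synthetic QuShape TSV for a 30-nt hairpin (unpaired positions ~5x
more reactive than paired ones), parses it, applies the box-plot
normalization and prints the divisor plus the resulting reactivity file.
"""

from probekit import normalize_profile, parse_qushape, write_reactivity_file
from probekit.synthetic import SynthParams, hairpin_structure, synth_profile, synth_qushape

raw = synth_profile(SynthParams(structure=hairpin_structure(), seed=7))
qushape_text = synth_qushape(raw)
print("QuShape input (first 4 lines):")
print("\n".join(qushape_text.splitlines()[:4]), "\n")

profile = parse_qushape(qushape_text)
result = normalize_profile(profile)
print(f"divisor: {result.factor:.2f}  "
      f"(selected top {result.n_selected}, excluded top {result.n_excluded}; "
      f"{result.subset})")
print("\nreactivity file (first 6 positions):")
print("\n".join(write_reactivity_file(result.profile).splitlines()[:6]))
print("\nEvery measured value now lies in [0, 1]; values near 1 mark the "
      "most chemically reactive (typically unpaired) nucleotides.")
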