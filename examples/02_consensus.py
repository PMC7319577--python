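"""Base-pair consensus over several secondary-structure predictions.

Three predictions of a 12-nt hairpin disagree about the outermost pair of the
stem; the consensus keeps every pair present in at least half of them and
reports each pair's occurrence frequency.
"""

from probekit import consensus, parse_dotbracket, write_dotbracket

predictions = [
    parse_dotbracket("((((....))))", label="method-1"),
    parse_dotbracket("((((....))))", label="method-2"),
    parse_dotbracket("(((......)))", label="method-3"),
]
result = consensus(predictions)

print("input predictions:")
for s in predictions:
    print(f"  {write_dotbracket(s)}  ({s.label})")
print(f"\nconsensus ({result.n_inputs} inputs, threshold 50%):")
print(f"  {write_dotbracket(result.structure)}")
for pair, freq in sorted(result.frequency.items()):
    print(f"  pair {pair}: in {freq:.0%} of predictions")
print("\nPair (4,9) survives at 67% occurrence; a pair seen in only one "
      "prediction (<50%) would be dropped.")
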