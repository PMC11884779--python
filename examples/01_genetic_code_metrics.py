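"""Mutational covariates from the standard genetic code.

For every unordered amino-acid pair, three quantities describe how hard it
is for mutation alone to interchange them: the minimum number of nucleotide
changes between any two of their codons, the difference in mean codon GC
fraction, and the difference in mean codon pyrimidine fraction (a proxy for
whether the exchange tends to require transversions).
"""

from aasub import gc_content, min_mutational_steps, pair_metric_table, pyrimidine_proportion

table = pair_metric_table()
print(f"pair metric table: {len(table)} unordered pairs\n")
print(table.head(8).to_string(index=False))

print("\nexamples:")
print(f"  Phe -> Leu needs {min_mutational_steps('F', 'L')} nucleotide change(s); "
      f"Met -> Tyr needs {min_mutational_steps('M', 'Y')}.")
print(f"  GC fraction of Gly codons: {gc_content('G'):.3f} "
      f"(vs {gc_content('F'):.3f} for Phe)")
print(f"  Phe codons are all-pyrimidine ({pyrimidine_proportion('F'):.1f}), "
      f"Lys codons contain none ({pyrimidine_proportion('K'):.1f}): an F<->K "
      "exchange maximally shifts pyrimidine content.")

steps = table["min_steps"].value_counts().sort_index()
print("\npairs per step class:", dict(steps))
print("Most pairs are 2 steps apart; only a handful need 3 — those exchanges "
      "depend entirely on multiple sequential mutations.")
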