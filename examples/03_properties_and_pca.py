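"""Physicochemical difference axes: PCA of pairwise property differences.

The embedded default set holds eight published AAIndex scales.  For each of
the 190 amino-acid pairs we take absolute property differences, then run a
standardized PCA.  One leading axis collects charge/hydrophobicity-family
differences and the other size-family differences — the two covariates the
mixed models use.
"""

from aasub import builtin_properties, pairwise_differences, property_correlations, run_pca

props = builtin_properties()
print("embedded scales (name: AAIndex accession):")
for name, acc in props.attrs["provenance"].items():
    print(f"  {name}: {acc}")

corr = property_correlations(props)
print(f"\nr(molecular weight, volume)        = {corr.loc['molecular_weight', 'volume']:+.2f}")
print(f"r(contact energy, hydropathy)      = {corr.loc['contact_energy', 'hydropathy']:+.2f}")
print("Strongly related scales like these are why the differences are "
      "condensed by PCA instead of entering a regression together.")

res = run_pca(pairwise_differences(props), standardize=True)
print("\nexplained variance fractions:",
      ", ".join(f"{n}: {f:.2f}"
                for n, f in res.explained_fraction.head(4).items()))
print("\ntop contributors (percent of component):")
for pc in ("PC1", "PC2"):
    top = res.contributions[pc].nlargest(3)
    print(f"  {pc}: " + ", ".join(f"{k} ({v:.0f}%)" for k, v in top.items()))
print("\nThe two property families split across the first two axes — here the "
      "size family (ASA, weight, volume) leads PC1 and the charge/hydrophobicity "
      "family PC2; which family comes first depends on the property list. Both "
      "scores are joined onto every pair as model covariates.")
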