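"""TPM normalization and four-dataset sharing (Venn) analysis.

Counts are length-normalized to TPM (each tissue column sums to one
million); presence is strict TPM > 0; sharing is decomposed over the three
tissue datasets plus their combined union.
"""

import venomscaffold as vs

_, _, truth, counts = vs.generate(vs.SimConfig(seed=4))
table = vs.compute_tpm(counts)
print("TPM column sums:",
      {t: round(table.tpm[t].sum()) for t in table.tissues})

sets = vs.presence_sets(table)
sets["combine"] = set.union(*sets.values())
rep = vs.venn_counts(sets)
print(f"common to all four datasets: {rep.n_common}")
for (a, b), n in sorted(rep.pairwise.items()):
    print(f"  shared by {a} & {b}: {n}")

top = vs.top_n(table, "column", n=5)
print("top-5 by TPM in column:")
print(top.round(1))
# a/b DEG flag: |log2 fold change| > 2 with pseudocount 1
a, b = top.iloc[0], top.iloc[-1]
print(f"DEG flag top vs fifth: {vs.deg_flag(a, b)}")
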