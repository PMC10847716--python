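"""Simulate a biparental F2 segregating the four lint% loci.

Builds the 'T586' x 'Pima S-7' F2 (303 plants) under the default
additive-penalty effect model, then prints the fuzzless:fuzzy split with a
3:1 segregation test and the per-locus class means.
"""

import numpy as np

from lintseg import chi_square_segregation, genotype_class_summary
from lintseg.presets import design_population

pop = design_population("TP_F2", seed=11)
df = pop.to_dataframe()

n_fuzzless = int(df["fuzzless"].sum())
n_fuzzy = len(df) - n_fuzzless
seg = chi_square_segregation([n_fuzzless, n_fuzzy], [3, 1])
print(f"TP F2, n={len(df)}: {n_fuzzless} fuzzless vs {n_fuzzy} fuzzy")
print(f"  3:1 goodness of fit: chi2={seg.chi2:.3f}, p={seg.p_value:.4f}")
print("  (dominant fuzzless: one loss-of-function MYB25-like_At allele suffices)\n")

for locus in ("MYB25like_At", "HD1_At", "MYB25like_Dt", "HD1_Dt"):
    labels = df[locus].map({0: "func/func", 1: "func/lof", 2: "lof/lof"})
    summ = genotype_class_summary(labels, df["lint_pct"], marker_id=locus)
    cells = ", ".join(
        f"{c.label}: {c.mean_lint_pct:.2f}% (n={c.n}, {c.letter})" for c in summ.classes
    )
    print(f"{locus:>13}  {cells}")
print(
    "\nMeans drop with loss-of-function dosage; shared letters mark classes whose"
    "\nlint% difference is not significant (Welch t-test, alpha=0.05)."
)
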