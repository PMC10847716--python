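"""Genotype-class lint% distribution table for a single-locus F2.

Simulates the 'SL1-7-1' x 'T586' F2 (101 plants, only HD1_At segregating,
class means 20.47 / 13.75 / 5.14) and prints the binned distribution table
with group means and significance letters, in the layout used for
segregating-population tables: an exact-zero (fiberless) column followed by
(lo, hi] lint% bins.
"""

from lintseg import genotype_class_summary
from lintseg.presets import design_population, st_f2_effect_model

pop = design_population("ST_F2", seed=5, model=st_f2_effect_model())
df = pop.to_dataframe()
labels = df["HD1_At"].map({0: "HD1_At T586/T586", 1: "HD1_At SL/T586", 2: "HD1_At SL/SL"})

summ = genotype_class_summary(
    labels, df["lint_pct"], bin_edges=[5, 10, 15, 20, 25, 30], marker_id="HD1_At"
)
print(summ.to_dataframe().to_string(index=False))
print(
    "\nEach row is a genotype class at HD1_At: bin columns count plants per lint%"
    "\nrange ('0' = fiberless), 'mean_lint_pct' is the class mean and distinct"
    "\nletters mark significantly different classes (p < 0.05)."
)
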