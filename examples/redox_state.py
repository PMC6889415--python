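"""Quantify cysteine oxidation from differential isotopic alkylation.

Free thiols carry the light (12C-IPA) label; previously oxidized thiols,
labelled after reduction, carry the heavy (13C-IPA) label. The oxidized
fraction of a cysteine is the pooled heavy ion abundance over the total
across its 2-4 quantified peptides. Two insulin time bins are compared
with the two-sided exact Wilcoxon rank-sum test: a small p indicates the
oxidized fraction changed with sustained insulin exposure.
"""

from aktredox import compare_bins, redox_fraction

# (light, heavy) ion abundances per peptide, two replicates per time bin
early_bin = [
    redox_fraction([(995.0, 5.0), (498.0, 2.0)]),
    redox_fraction([(990.0, 6.0), (502.0, 3.0)]),
]
late_bin = [
    redox_fraction([(980.0, 14.0), (490.0, 8.0)]),
    redox_fraction([(975.0, 13.0), (487.0, 7.0)]),
]

print("C60 oxidized fraction, 0-5 min:  ", [f"{x:.4f}" for x in early_bin])
print("C60 oxidized fraction, 10-60 min:", [f"{x:.4f}" for x in late_bin])
u, p = compare_bins(early_bin, late_bin)
fold = (sum(late_bin) / len(late_bin)) / (sum(early_bin) / len(early_bin))
print(f"fold increase {fold:.1f}, rank-sum U = {u:g}, two-sided p = {p:.3f}")
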