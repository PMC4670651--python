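"""Antigen-specific B-cell fraction needed for one STC per cell.

For the affinity-matured association constant (Ka = 1e-3 pM^-1) and a
minimum cross-link number of 2, bisects the antigen-specific B-cell
fraction until each aggregate level reaches one signal-transducing
complex per cell.  The largest of the three thresholds is the fraction
above which every aggregate level supports potential T-cell-independent
activation.
"""

from aggimmuno import crosslink as cx

thresholds = {}
for aga0 in (0.1, 12.0, 1500.0):
    res = cx.fraction_threshold(Ka=1e-3, Aga0=aga0, n=100, s=2)
    thresholds[aga0] = res.percent
    print(f"aggregate {aga0:7.1f} pM: threshold fraction = {res.percent:.4g}%")

print(f"\nworst case over aggregate levels: {max(thresholds.values()):.4g}%")
print("-> below this percentage of antigen-specific B cells, at least one")
print("   aggregate level stays under one STC per cell.")

low = cx.fraction_threshold(Ka=1e-7, Aga0=12.0, n=100, s=2)
print(f"\nlow-affinity antibodies (Ka = 1e-7 pM^-1): attained = {low.attained}")
print("-> without affinity maturation the threshold is never reached.")
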