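"""Signal-transducing complexes per B cell across the physiological grid.

Runs the default cross-linking sweep (aggregate valency n = 100, minimum
cross-link numbers s = 2/5/10) over three association constants, three
aggregate concentrations and an antigen-specific B-cell fraction ladder,
then prints the s = 2 readout as a table.  Values above 1 mark conditions
where a B cell carries at least one aggregate cross-linking >= 2 of its
receptors -- the prerequisite for T-cell-independent activation.
"""

from aggimmuno import crosslink as cx

table = cx.sweep()
s2 = table[table.s == 2].pivot_table(
    index=["Ka_pM_inv", "Aga0_pM"], columns="specific_fraction",
    values="stc_per_cell")
print("STC per antigen-specific B cell (s = 2), columns = specific fraction")
print(s2.to_string(float_format="%.3g"))

high_s = table[table.s.isin([5, 10])].stc_per_cell.max()
print(f"\nmax STC/cell anywhere on the grid for s in {{5, 10}}: {high_s:.3g}")
print("-> activation thresholds of 5-10 cross-links are never reached;")
print("   only s = 2 with affinity-matured Ka and enough specific B cells")
print("   produces more than one complex per cell.")
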