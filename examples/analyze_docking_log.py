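"""Extract a representative binding free energy from a docking log.

Builds a synthetic clustering histogram (as an AutoDock4-style log),
parses it, applies the representative-energy rule — the mean binding
energy of the most populated cluster, averaged over clusters with
similar populations — and converts the energy to a predicted pKi.
"""

from zincbias import ThermoConstants, dg_to_pki, make_dlg, parse_dlg, representative_dg

# one dominant cluster
dlg = make_dlg([(-8.0, -8.3, 60), (-7.5, -7.9, 30), (-6.0, -6.2, 10)], seed=1)
clusters = parse_dlg(dlg)
dg = representative_dg(clusters)
print(f"dominant cluster case: representative dG = {dg:.2f} kcal/mol")
print(f"  -> predicted pKi at 310 K: {dg_to_pki(dg, ThermoConstants()):.2f}")

# two near-equal clusters: their mean energies are averaged
dlg2 = make_dlg([(-8.0, -8.4, 45), (-7.5, -7.8, 44), (-6.0, -6.1, 10)], seed=2)
dg2 = representative_dg(parse_dlg(dlg2), similar_frac=0.9)
print(f"\nsimilar-population case: representative dG = {dg2:.2f} kcal/mol")
print("  (-8.0 and -7.5 averaged because 44 poses is within 90% of 45)")
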