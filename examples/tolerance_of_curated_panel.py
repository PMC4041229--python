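"""Tolerance analytics over the curated eight-species literature panel.

Loads the packaged EC50 records for PCE, CT, CF and 1,2-DCA, asks which
species tolerate free-phase PCE, and expresses the printed panel-average
EC50s as percentages of each solvent's aqueous solubility.
"""

import solvtol as st

solvents = st.read_solvents_toml()
records = st.load_curated_results()

pce_tolerant = sorted(r.species for r in records
                      if r.solvent == "PCE" and "above_pce_solubility" in r.flags)
print(f"free-phase PCE tolerant ({len(pce_tolerant)}/8):")
for sp in pce_tolerant:
    print(f"  {sp}")

# panel-average EC50s as percent of aqueous solubility: although CF and
# 1,2-DCA EC50s are numerically larger, they are *smaller* fractions of
# what can dissolve, so free phases of polar solvents are tolerated worse
for solvent, avg_ec50 in (("CT", 1.0), ("CF", 3.5), ("1,2-DCA", 12.3)):
    pct = st.percent_of_solubility(avg_ec50, solvents[solvent])
    print(f"average {solvent} EC50 {avg_ec50} mM = {pct.rounded}% of solubility "
          f"({solvents[solvent].aqueous_solubility:g} mM)")

by = st.curated_effective_values()
rec = by["Klebsiella sp."]["PCE"]
print(f"\nmost tolerant pairing: Klebsiella sp. / PCE, EC50 {rec.value} mM "
      f"({rec.method}; nominal scale, {rec.value / 0.9:.1f}x the solubility limit)")
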