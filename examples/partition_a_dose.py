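"""Where does a microlitre of carbon tetrachloride go in a sealed tube?

Doses 1 µL of neat CT into a 25 mL anaerobic tube holding 10 mL medium
at 30 °C and partitions it between medium, headspace and (if the dose
were large enough) a free phase.
"""

import solvtol as st

solvents = st.read_solvents_toml()
ct = solvents["CT"]
vial = st.VialSetup(liquid_volume=10.0, headspace_volume=15.0, temperature=30.0)
dose = st.SolventDose("neat", volume_added=1.0)

res = st.partition_dose(ct, vial, dose)
print(f"total dose:            {res.total_amount:.2f} umol")
print(f"dissolved in medium:   {res.aqueous_concentration:.3f} mM")
print(f"in headspace gas:      {res.headspace_concentration:.3f} mM")
print(f"nominal concentration: {res.nominal_concentration:.3f} mM")
print(f"free phase present:    {res.free_phase}")

# The dissolved concentration is well below the nominal one: CT is
# volatile (Hcc ~ 1.4 at 30 C), so the 15 mL headspace holds a large
# share of the dose.  Cells only experience the dissolved 0.33 mM.
planned = st.dose_for_aqueous_concentration(ct, vial, 1.0)
print(f"\nto reach 1.0 mM dissolved, dose {planned.volume_added:.2f} uL of neat CT")
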