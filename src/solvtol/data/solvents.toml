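# Default physicochemical constants for the four chlorinated aliphatic
# hydrocarbons handled by solvtol.  These are implementer-sourced
# literature values (CRC-handbook-style molar masses and densities;
# dimensionless air/water Henry constants near 25 C from standard
# compilations, extended over 20-37 C with a van't Hoff ln(Hcc) vs 1/T
# fit); edit this file or load your own to override.  Solubilities:
# PCE 0.9 mM and CT 5 mM are the conventional maximum aqueous
# solubilities; CF and 1,2-DCA solubilities are literature values
# (7.95 g/L and 8.6 g/L at ~25 C).
#
# henry entries are [temperature_C, Hcc] with Hcc = C_gas / C_aq.

[PCE]  # perchloroethene (tetrachloroethene)
molar_mass_g_mol = 165.83
density_g_ml = 1.622
log_pow = 2.88
solubility_mM = 0.9
henry = [[20, 0.5566], [25, 0.72], [30, 0.9235], [37, 1.291]]

[CT]  # carbon tetrachloride
molar_mass_g_mol = 153.82
density_g_ml = 1.594
log_pow = 2.64
solubility_mM = 5.0
henry = [[20, 0.8887], [25, 1.13], [30, 1.426], [37, 1.949]]

[CF]  # chloroform (trichloromethane)
molar_mass_g_mol = 119.38
density_g_ml = 1.489
log_pow = 1.97
solubility_mM = 66.6
henry = [[20, 0.1153], [25, 0.15], [30, 0.1935], [37, 0.2725]]

["1,2-DCA"]  # 1,2-dichloroethane
molar_mass_g_mol = 98.96
density_g_ml = 1.253
log_pow = 1.48
solubility_mM = 86.9
henry = [[20, 0.03627], [25, 0.048], [30, 0.06295], [37, 0.09066]]
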