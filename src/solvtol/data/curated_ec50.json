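{
  "description": "Curated panel of published EC50 values (mmol/L) for eight anaerobic bacteria exposed to four chlorinated solvents in sealed-vial growth assays. Only values printed in the source study's text are transcribed; entries known only as ranges or bounds are stored as such, and nothing is read off figures. PCE values above 0.9 mM are on the nominal concentration scale (free phase present).",
  "records": [
    {"species": "Klebsiella sp.", "solvent": "PCE", "kind": "point", "value": 4.95, "method": "extrapolated", "flags": ["above_pce_solubility"], "source": "results, PCE paragraph: most PCE-tolerant species, extrapolated from 54% growth at the top nominal dose of 4.58 mM"},
    {"species": "E. coli", "solvent": "PCE", "kind": "range", "lo": 0.9, "hi": null, "flags": ["above_pce_solubility"], "source": "results, PCE paragraph: EC50 above PCE solubility of 0.9 mM"},
    {"species": "P. aeruginosa", "solvent": "PCE", "kind": "range", "lo": 0.9, "hi": null, "flags": ["above_pce_solubility"], "source": "results, PCE paragraph: EC50 above PCE solubility of 0.9 mM"},
    {"species": "Clostridium sp.", "solvent": "PCE", "kind": "range", "lo": 0.9, "hi": null, "flags": ["above_pce_solubility"], "source": "results, PCE paragraph: EC50 above PCE solubility of 0.9 mM"},
    {"species": "Paenibacillus sp.", "solvent": "PCE", "kind": "range", "lo": 0.9, "hi": null, "flags": ["above_pce_solubility"], "source": "results, PCE paragraph: EC50 above PCE solubility of 0.9 mM"},
    {"species": "S. oneidensis", "solvent": "PCE", "kind": "range", "lo": 0.3, "hi": 0.9, "flags": [], "source": "results, PCE paragraph: affected below free-phase appearance; all species grew at 50% with 0.3 mM PCE or more"},
    {"species": "G. sulfurreducens", "solvent": "PCE", "kind": "range", "lo": 0.3, "hi": 0.4, "flags": [], "source": "discussion, literature comparison: PCE EC50s of 0.3-0.4 mM for the two slow-growing respirers"},
    {"species": "D. vulgaris", "solvent": "PCE", "kind": "range", "lo": 0.3, "hi": 0.4, "flags": [], "source": "discussion, literature comparison: PCE EC50s of 0.3-0.4 mM for the two slow-growing respirers"},

    {"species": "Paenibacillus sp.", "solvent": "CT", "kind": "point", "value": 2.4, "method": "interpolated", "flags": [], "source": "results, CT paragraph: most CT-tolerant organism, EC50 2.4 mM"},
    {"species": "E. coli", "solvent": "CT", "kind": "range", "lo": 0.5, "hi": 2.4, "flags": [], "source": "results, CT paragraph: remaining species' EC50s between 0.5 and 2.4 mM"},
    {"species": "Klebsiella sp.", "solvent": "CT", "kind": "range", "lo": 0.5, "hi": 2.4, "flags": [], "source": "results, CT paragraph: remaining species' EC50s between 0.5 and 2.4 mM"},
    {"species": "Clostridium sp.", "solvent": "CT", "kind": "range", "lo": 0.5, "hi": 2.4, "flags": [], "source": "results, CT paragraph: remaining species' EC50s between 0.5 and 2.4 mM"},
    {"species": "P. aeruginosa", "solvent": "CT", "kind": "range", "lo": 0.5, "hi": 2.4, "flags": [], "source": "results, CT paragraph: remaining species' EC50s between 0.5 and 2.4 mM"},
    {"species": "S. oneidensis", "solvent": "CT", "kind": "left", "bound": 0.08, "flags": ["no_growth_at_lowest"], "source": "results, CT paragraph: no growth at the lowest level tested, 80 uM"},
    {"species": "D. vulgaris", "solvent": "CT", "kind": "left", "bound": 0.08, "flags": ["no_growth_at_lowest"], "source": "results, CT paragraph: no growth at the lowest level tested, 80 uM"},
    {"species": "G. sulfurreducens", "solvent": "CT", "kind": "left", "bound": 0.03, "flags": ["no_growth_at_lowest"], "source": "results, CT paragraph: no growth at the lowest level tested, 30 uM"},

    {"species": "G. sulfurreducens", "solvent": "CF", "kind": "point", "value": 0.2, "method": "interpolated", "flags": [], "source": "results, CF paragraph: EC50 of 0.2 mM"},
    {"species": "D. vulgaris", "solvent": "CF", "kind": "left", "bound": 0.2, "flags": ["no_growth_at_lowest"], "source": "results, CF paragraph: completely inhibited at the lowest test concentration of 0.2 mM"},
    {"species": "E. coli", "solvent": "CF", "kind": "range", "lo": 3.5, "hi": null, "flags": [], "source": "results, CF paragraph: EC50 above 3.5 mM"},
    {"species": "Klebsiella sp.", "solvent": "CF", "kind": "range", "lo": 3.5, "hi": null, "flags": [], "source": "results, CF paragraph: EC50 above 3.5 mM"},
    {"species": "Clostridium sp.", "solvent": "CF", "kind": "range", "lo": 3.5, "hi": null, "flags": [], "source": "results, CF paragraph: EC50 above 3.5 mM"},
    {"species": "Paenibacillus sp.", "solvent": "CF", "kind": "range", "lo": 3.5, "hi": null, "flags": [], "source": "results, CF paragraph: EC50 above 3.5 mM"},
    {"species": "P. aeruginosa", "solvent": "CF", "kind": "range", "lo": 3.5, "hi": null, "flags": [], "source": "results, CF paragraph: EC50 above 3.5 mM"},
    {"species": "S. oneidensis", "solvent": "CF", "kind": "range", "lo": 3.5, "hi": null, "flags": [], "source": "results, CF paragraph: EC50 above 3.5 mM"},

    {"species": "G. sulfurreducens", "solvent": "1,2-DCA", "kind": "point", "value": 6.5, "method": "extrapolated", "flags": [], "source": "results, 1,2-DCA paragraph: EC50 of 6.5 mM by extrapolation (70% growth at the top tested level of 3.72 mM)"},
    {"species": "D. vulgaris", "solvent": "1,2-DCA", "kind": "right", "bound": 6.5, "flags": [], "source": "results, 1,2-DCA paragraph: no decreasing trend up to 4.65 mM; assigned a minimum EC50 of 6.5 mM"},
    {"species": "E. coli", "solvent": "1,2-DCA", "kind": "range", "lo": 6.5, "hi": null, "flags": [], "source": "results, 1,2-DCA paragraph: EC50s consistently above 6.5 mM"},
    {"species": "Klebsiella sp.", "solvent": "1,2-DCA", "kind": "range", "lo": 6.5, "hi": null, "flags": [], "source": "results, 1,2-DCA paragraph: EC50s consistently above 6.5 mM"},
    {"species": "Clostridium sp.", "solvent": "1,2-DCA", "kind": "range", "lo": 6.5, "hi": null, "flags": [], "source": "results, 1,2-DCA paragraph: EC50s consistently above 6.5 mM"},
    {"species": "Paenibacillus sp.", "solvent": "1,2-DCA", "kind": "range", "lo": 6.5, "hi": null, "flags": [], "source": "results, 1,2-DCA paragraph: EC50s consistently above 6.5 mM"},
    {"species": "P. aeruginosa", "solvent": "1,2-DCA", "kind": "range", "lo": 6.5, "hi": null, "flags": [], "source": "results, 1,2-DCA paragraph: EC50s consistently above 6.5 mM"},
    {"species": "S. oneidensis", "solvent": "1,2-DCA", "kind": "range", "lo": 6.5, "hi": null, "flags": [], "source": "results, 1,2-DCA paragraph: EC50s consistently above 6.5 mM"}
  ]
}
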