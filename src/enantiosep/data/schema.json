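{
  "screening_csv": {
    "description": "One row per (CSP, eluent, analyte) screening measurement.",
    "columns": {
      "csp": "chiral stationary phase identifier (e.g. AD, OD, Cell2)",
      "eluent": "neat eluent name (MeOH, EtOH, 1-PrOH, 2-PrOH) or 'Solvent1:Solvent2=x:y' V/V%",
      "analyte": "omeprazole | rabeprazole | lansoprazole | other",
      "k1": "retention factor of the first-eluting enantiomer (dimensionless, >= 0)",
      "k2": "retention factor of the second-eluting enantiomer (dimensionless, >= k1)",
      "rs": "resolution 2(t2-t1)/(w1+w2); '-' marks coelution (stored as missing)",
      "eeo": "R-S (R elutes first) | S-R (S elutes first) | '-' (coelution) | '?' (unknown)"
    }
  },
  "vant_hoff_csv": {
    "description": "Temperature series for van 't Hoff analysis, one row per (system, analyte, enantiomer, T).",
    "columns": {
      "csp": "chiral stationary phase identifier",
      "eluent": "eluent name",
      "analyte": "analyte name",
      "enantiomer": "R | S (or 1 | 2 for elution-position series)",
      "T_celsius": "column temperature in degrees Celsius",
      "k": "retention factor (dimensionless, > 0)"
    }
  },
  "hysteresis_csv": {
    "description": "Hysteresis loop, one row per (composition, direction).",
    "columns": {
      "csp": "chiral stationary phase identifier",
      "analyte": "analyte name",
      "solvent_pair": "e.g. MeOH-2-PrOH (first solvent is the 100% starting eluent)",
      "pct_meoh": "V/V% MeOH in the mixture (0-100)",
      "direction": "forward (sweep starting from 100% MeOH) | reverse (starting from 0% MeOH)",
      "k_R": "retention factor of the R enantiomer",
      "k_S": "retention factor of the S enantiomer",
      "rs": "optional resolution",
      "eeo": "optional elution order (R-S | S-R | -)"
    }
  },
  "descriptor_csv": {
    "description": "Molecular descriptors, one row per analyte.",
    "columns": {
      "analyte": "analyte name",
      "...": "numeric descriptor columns (mol_weight, logp, tpsa, ...)"
    }
  }
}
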