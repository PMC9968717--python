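{
  "_comment": [
    "Population parameter estimates for the benazeprilat-RAAS QSP model.",
    "Keys are the programming-language variable names of the published parameter",
    "table, kept 1:1 for auditability. 'value' is the typical (population) value",
    "as printed; 'iiv_sd' is the SD of the inter-individual random effect on the",
    "transformed scale (0 where none was estimated); 'link' is the h() transform",
    "used to realize individual parameters (lognormal, logitnormal, or none).",
    "Amounts in the published table are on the model's internal micromolar scale",
    "(all concentration data were converted to umol/L before fitting); the",
    "engine converts to pmol via constants.AMOUNT_SCALE."
  ],
  "parameters": {
    "Frxn_0abs_pop": {"value": 0.695, "iiv_sd": 0.606, "link": "logitnormal", "unit": "-", "description": "Fraction of benazepril zero-order (delayed-path) absorbed"},
    "F_bio_pop": {"value": 0.883, "iiv_sd": 0.451, "link": "logitnormal", "unit": "-", "description": "Bioavailability of benazepril"},
    "Frxn_ACE_fr_pop": {"value": 0.035, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Fraction of ACE in free circulation compartment"},
    "delta_24hr_pop": {"value": 0.292, "iiv_sd": 0.768, "link": "lognormal", "unit": "-", "description": "Scale of renin production variance due to chronobiology"},
    "Vpl_pop": {"value": 48.5, "iiv_sd": 0.298, "link": "lognormal", "unit": "L", "description": "Volume of plasma compartment"},
    "Vts_pop": {"value": 0.965, "iiv_sd": 1.4, "link": "lognormal", "unit": "L", "description": "Volume of tissue compartment"},
    "Vns_pop": {"value": 23.6, "iiv_sd": 0.824, "link": "lognormal", "unit": "L", "description": "Volume of non-specific binding for benazepril"},
    "Vrn_pop": {"value": 4.3, "iiv_sd": 0.030, "link": "lognormal", "unit": "L", "description": "Volume of kidney compartment"},
    "Qfr_ns_pop": {"value": 85.1, "iiv_sd": 0.0, "link": "none", "unit": "L/h", "description": "Intercompartmental flow between free circulation and non-specific binding compartment"},
    "Qfr_ts_pop": {"value": 2.0, "iiv_sd": 1.4, "link": "lognormal", "unit": "L/h", "description": "Intercompartmental flow between free circulation and tissue compartment"},
    "Qrn_pop": {"value": 12.3, "iiv_sd": 0.030, "link": "lognormal", "unit": "L/h", "description": "Intercompartmental flow between plasma and kidney compartment"},
    "ACE_total_pop": {"value": 0.0002, "iiv_sd": 0.231, "link": "lognormal", "unit": "umol", "description": "Total amount of ACE (micromolar amount scale)"},
    "Shcc_pop": {"value": 93.3, "iiv_sd": 0.355, "link": "lognormal", "unit": "pmol/L", "description": "Concentration of angiotensin I (1-10) at time 0"},
    "Phcc_pop": {"value": 56.7, "iiv_sd": 0.274, "link": "lognormal", "unit": "pmol/L", "description": "Concentration of angiotensin II (1-8) at time 0"},
    "Ang17hcc_pop": {"value": 33.7, "iiv_sd": 0.332, "link": "lognormal", "unit": "pmol/L", "description": "Concentration of angiotensin (1-7) at time 0"},
    "AngIIIhcc_pop": {"value": 5.0, "iiv_sd": 0.324, "link": "lognormal", "unit": "pmol/L", "description": "Concentration of angiotensin III (2-8) at time 0"},
    "AngIVhcc_pop": {"value": 9.1, "iiv_sd": 0.287, "link": "lognormal", "unit": "pmol/L", "description": "Concentration of angiotensin IV (3-8) at time 0"},
    "ka1_pop": {"value": 0.0148, "iiv_sd": 0.030, "link": "lognormal", "unit": "1/h", "description": "First-order analog absorption rate"},
    "ka_pop": {"value": 1.5, "iiv_sd": 0.560, "link": "lognormal", "unit": "1/h", "description": "Zero-order analog absorption rate"},
    "Cl_pop": {"value": 27.3, "iiv_sd": 0.030, "link": "lognormal", "unit": "L/h", "description": "Clearance rate of benazeprilat"},
    "ClP_pop": {"value": 118.0, "iiv_sd": 0.214, "link": "lognormal", "unit": "L/h", "description": "Clearance rate of angiotensin II (1-8)"},
    "ClS_pop": {"value": 6.4, "iiv_sd": 0.030, "link": "lognormal", "unit": "L/h", "description": "Clearance rate of angiotensin I (1-10)"},
    "ClAng17_pop": {"value": 98.1, "iiv_sd": 0.030, "link": "lognormal", "unit": "L/h", "description": "Clearance rate of angiotensin (1-7)"},
    "ClAngIII_pop": {"value": 250.0, "iiv_sd": 0.0, "link": "none", "unit": "L/h", "description": "Clearance rate of angiotensin III (2-8) (fixed)"},
    "ClAngIV_pop": {"value": 165.0, "iiv_sd": 0.0, "link": "none", "unit": "L/h", "description": "Clearance rate of angiotensin IV (3-8)"},
    "kd_pop": {"value": 39.3, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Ratio of enzyme-substrate association rate to angiotensin II catalysis"},
    "k1_s_pop": {"value": 3.0, "iiv_sd": 0.0, "link": "none", "unit": "1/s", "description": "Rate of ACE-angiotensin I dissociation, scaled (fixed)"},
    "k2_s_pop": {"value": 2.9, "iiv_sd": 0.0, "link": "none", "unit": "1/s", "description": "Rate of angiotensin II catalysis from the ACE-angiotensin I complex, scaled (fixed)"},
    "k3_s_pop": {"value": 7.0, "iiv_sd": 0.0, "link": "none", "unit": "1/s", "description": "Rate of ACE-benazeprilat dissociation, scaled"},
    "kI_17_pop": {"value": 0.347, "iiv_sd": 0.254, "link": "lognormal", "unit": "1/h", "description": "Overall conversion rate of angiotensin I to angiotensin (1-7)"},
    "kII_17_pop": {"value": 0.344, "iiv_sd": 0.189, "link": "lognormal", "unit": "1/h", "description": "Overall conversion rate of angiotensin II to angiotensin (1-7)"},
    "kII_III_pop": {"value": 6.0, "iiv_sd": 0.231, "link": "lognormal", "unit": "1/h", "description": "Overall conversion rate of angiotensin II to angiotensin III"},
    "kIII_IV_pop": {"value": 5.2, "iiv_sd": 0.030, "link": "lognormal", "unit": "1/h", "description": "Overall conversion rate of angiotensin III to angiotensin IV"},
    "PRA_pop": {"value": 8.4, "iiv_sd": 1.2, "link": "lognormal", "unit": "h", "description": "Clock time of peak angiotensin I production during the 24-h cycle"},
    "r_S_pop": {"value": 0.0117, "iiv_sd": 0.335, "link": "lognormal", "unit": "umol/h", "description": "Relative rate of angiotensin I production (micromolar amount scale)"},
    "bAngI_1to10": {"value": 0.535, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Proportional measurement error SD of angiotensin I"},
    "bAngII_1to8": {"value": 0.263, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Proportional measurement error SD of angiotensin II"},
    "bAngIII_2to8": {"value": 0.454, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Proportional measurement error SD of angiotensin III"},
    "bAngIV_3to8": {"value": 0.226, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Proportional measurement error SD of angiotensin IV"},
    "bAng_1to7": {"value": 0.306, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Proportional measurement error SD of angiotensin (1-7)"},
    "bconcentration": {"value": 0.292, "iiv_sd": 0.0, "link": "none", "unit": "-", "description": "Proportional measurement error SD of benazeprilat"}
  },
  "constants": {
    "MW_BENAZEPRIL_HCL": {"value": 460.96, "unit": "g/mol", "description": "Molecular weight of benazepril hydrochloride (RDKit, PubChem CID 5362124 salt form)"},
    "MW_BENAZEPRILAT": {"value": 396.44, "unit": "g/mol", "description": "Molecular weight of benazeprilat (RDKit, PubChem CID 5463984)"},
    "AMOUNT_SCALE": {"value": 1e6, "unit": "pmol/umol", "description": "Conversion from the model's internal micromolar amount scale to picomoles"},
    "RATE_SCALE": {"value": 3600.0, "unit": "s/h", "description": "Conversion of the per-second 'scaled' enzyme rate constants to per-hour"}
  }
}
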