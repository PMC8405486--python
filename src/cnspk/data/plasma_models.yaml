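# Empirical compartmental plasma PK model fixtures.
#
# Units: clearances mL/min, volumes mL, absorption rate constant 1/min,
# inter-individual variability as %CV per parameter (exponential model),
# residual error: proportional %CV and additive SD in ng/mL.
# These parameter sets are fixed inputs (no re-estimation machinery).

rat:
  acetaminophen:
    n_compartments: 3
    cl_cen: {value: 4.70, units: mL/min}
    q_per1: {value: 11.18, units: mL/min}
    q_per2: {value: 31.35, units: mL/min}
    v_cen: {value: 50.71, units: mL}
    v_per1: {value: 27891.70, units: mL}
    v_per2: {value: 162.47, units: mL}
    iiv_cv_pct: {cl_cen: 35.5}
    prop_cv_pct: 26.7
    add_sd: 0.0
  atenolol:
    n_compartments: 2
    cl_cen: {value: 6.30, units: mL/min}
    q_per1: {value: 4.25, units: mL/min}
    q_per2: {value: 0.0, units: mL/min}
    v_cen: {value: 118.70, units: mL}
    v_per1: {value: 203.36, units: mL}
    v_per2: {value: 0.0, units: mL}
    iiv_cv_pct: {cl_cen: 8.9}
    prop_cv_pct: 14.7
    add_sd: 0.0
  methotrexate:
    n_compartments: 3
    cl_cen: {value: 8.31, units: mL/min}
    q_per1: {value: 23.33, units: mL/min}
    q_per2: {value: 0.79, units: mL/min}
    v_cen: {value: 38.16, units: mL}
    v_per1: {value: 139.95, units: mL}
    v_per2: {value: 47.99, units: mL}
    iiv_cv_pct: {cl_cen: 36.5, q_per2: 52.3, v_per2: 29.5}
    prop_cv_pct: 17.6
    add_sd: 0.0
  morphine:
    n_compartments: 3
    cl_cen: {value: 23.34, units: mL/min}
    q_per1: {value: 4.97, units: mL/min}
    q_per2: {value: 31.68, units: mL/min}
    v_cen: {value: 175.73, units: mL}
    v_per1: {value: 1636.28, units: mL}
    v_per2: {value: 475.86, units: mL}
    iiv_cv_pct: {cl_cen: 46.9, q_per1: 93.9, v_cen: 92.5, v_per2: 49.2}
    prop_cv_pct: 24.2
    add_sd: 0.0
  paliperidone:
    n_compartments: 2
    cl_cen: {value: 219.46, units: mL/min}
    q_per1: {value: 6765.63, units: mL/min}
    q_per2: {value: 0.0, units: mL/min}
    v_cen: {value: 25.00, units: mL}
    v_per1: {value: 32981.00, units: mL}
    v_per2: {value: 0.0, units: mL}
    iiv_cv_pct: {cl_cen: 44.4, v_per1: 45.5}
    prop_cv_pct: 20.0
    add_sd: 0.0
  phenytoin:
    n_compartments: 2
    cl_cen: {value: 47.72, units: mL/min}
    q_per1: {value: 415.88, units: mL/min}
    q_per2: {value: 0.0, units: mL/min}
    v_cen: {value: 453.32, units: mL}
    v_per1: {value: 2268.39, units: mL}
    v_per2: {value: 0.0, units: mL}
    iiv_cv_pct: {cl_cen: 65.8, v_cen: 122.5, v_per1: 22.0}
    prop_cv_pct: 16.3
    add_sd: 1571.0
  quinidine:
    n_compartments: 3
    cl_cen: {value: 178.28, units: mL/min}
    q_per1: {value: 238.03, units: mL/min}
    q_per2: {value: 753.99, units: mL/min}
    v_cen: {value: 183.65, units: mL}
    v_per1: {value: 7335.00, units: mL}
    v_per2: {value: 5062.54, units: mL}
    iiv_cv_pct: {cl_cen: 26.1, q_per1: 38.4}
    prop_cv_pct: 23.4
    add_sd: 20.8
  raclopride:
    n_compartments: 3
    cl_cen: {value: 45.40, units: mL/min}
    q_per1: {value: 68.04, units: mL/min}
    q_per2: {value: 15.03, units: mL/min}
    v_cen: {value: 50.44, units: mL}
    v_per1: {value: 468.42, units: mL}
    v_per2: {value: 690.00, units: mL}
    iiv_cv_pct: {cl_cen: 13.6}
    prop_cv_pct: 14.3
    add_sd: 0.0
  remoxipride:
    n_compartments: 3
    cl_cen: {value: 47.43, units: mL/min}
    q_per1: {value: 16.52, units: mL/min}
    q_per2: {value: 56.76, units: mL/min}
    v_cen: {value: 82.89, units: mL}
    v_per1: {value: 602.77, units: mL}
    v_per2: {value: 457.52, units: mL}
    iiv_cv_pct: {cl_cen: 31.0, q_per2: 29.8, v_cen: 124.4, v_per1: 36.4, v_per2: 44.7}
    prop_cv_pct: 21.3
    add_sd: 0.0
  risperidone:
    n_compartments: 1
    cl_cen: {value: 773.30, units: mL/min}
    q_per1: {value: 0.0, units: mL/min}
    q_per2: {value: 0.0, units: mL/min}
    v_cen: {value: 47936.80, units: mL}
    v_per1: {value: 0.0, units: mL}
    v_per2: {value: 0.0, units: mL}
    iiv_cv_pct: {cl_cen: 89.9, v_cen: 66.9}
    prop_cv_pct: 29.6
    add_sd: 12.9

human:
  acetaminophen:
    n_compartments: 1
    cl_cen: {value: 495.00, units: mL/min}
    q_per1: {value: 0.0, units: mL/min}
    q_per2: {value: 0.0, units: mL/min}
    v_cen: {value: 108000.00, units: mL}
    v_per1: {value: 0.0, units: mL}
    v_per2: {value: 0.0, units: mL}
    iiv_cv_pct: {}
    prop_cv_pct: 23.9
    add_sd: 0.0
  indomethacin:
    n_compartments: 2
    cl_cen: {value: 14200.00, units: mL/min}
    q_per1: {value: 54600.00, units: mL/min}
    q_per2: {value: 0.0, units: mL/min}
    v_cen: {value: 1320000.00, units: mL}
    v_per1: {value: 10300000.00, units: mL}
    v_per2: {value: 0.0, units: mL}
    # intramuscular dosing: first-order absorption, bioavailability 100%
    ka: {value: 2850000.0, units: 1/min}
    bioavailability: 1.0
    iiv_cv_pct: {q_per1: 145.9}
    prop_cv_pct: 22.3
    add_sd: 0.0
  morphine:
    n_compartments: 2
    cl_cen: {value: 3070.00, units: mL/min}
    q_per1: {value: 3030.00, units: mL/min}
    q_per2: {value: 0.0, units: mL/min}
    v_cen: {value: 16000.00, units: mL}
    v_per1: {value: 95400.00, units: mL}
    v_per2: {value: 0.0, units: mL}
    iiv_cv_pct: {cl_cen: 27.1, v_cen: 59.6}
    prop_cv_pct: 9.6
    add_sd: 0.0
  oxycodone:
    n_compartments: 3
    cl_cen: {value: 1140.00, units: mL/min}
    q_per1: {value: 11700.00, units: mL/min}
    q_per2: {value: 47.40, units: mL/min}
    v_cen: {value: 93600.00, units: mL}
    v_per1: {value: 178000.00, units: mL}
    v_per2: {value: 19400.00, units: mL}
    iiv_cv_pct: {cl_cen: 31.1, v_cen: 86.7}
    prop_cv_pct: 19.1
    add_sd: 0.0
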