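# Drug-specific parameter fixtures (12 reference compounds).
#
# MW g/mol; pKa = strongest acidic group, pKb = strongest basic group
# (null = no such group); logP = octanol-water log10 partition coefficient.
# kpuu: default unbound tissue-to-plasma steady-state targets per region
# (ecf / lv / cm); kpuu_variants hold alternative sets (dose-specific or
# species-corrected), keyed by label.
#
# af_reported entries transcribe externally reported asymmetry factors.
# The source table's AF columns are typographically ambiguous, so these are
# marked unverified; the steady-state asymmetry-factor solver is the
# authoritative path.
#
# fu_plasma values are study inputs not reproduced here; defaults of 1.0
# (i.e. simulations are driven by unbound plasma directly) should be
# overridden with measured values when available. fu_csf = 1 except
# indomethacin (0.47).

acetaminophen:
  mw: {value: 151.16, units: g/mol}
  charge_class: neutral
  pka: 9.46
  pkb: -4.4
  logp: 0.46
  kpuu: {ecf: 0.51, lv: 0.51, cm: 0.51}
  kpuu_variants:
    rat: {ecf: 0.51, lv: 0.51, cm: 0.51}
    human: {ecf: 1.0, lv: 1.0, cm: 1.0}   # assumed equilibrium, physiological knowledge
  af_reported:
    unverified: true
    rat: {af_out_ecf: 12.5, af_out_lv: 86.8, af_out_cm: 90.0}

atenolol:
  mw: {value: 266.34, units: g/mol}
  charge_class: base
  pka: 14.08
  pkb: 9.67
  logp: 0.16
  kpuu: {ecf: 0.037, lv: 0.037, cm: 0.037}
  kpuu_variants:
    rat: {ecf: 0.037, lv: 0.037, cm: 0.037}
  af_reported:
    unverified: true
    rat: {af_out_ecf: 9.9e4, af_out_lv: 8.3e5, af_out_cm: 8.3e5}

indomethacin:
  mw: {value: 357.8, units: g/mol}
  charge_class: acid
  pka: 3.79
  pkb: -2.9
  logp: 4.27
  fu_csf: 0.47
  kpuu: {ecf: 0.1, lv: 0.272, cm: 0.272}
  kpuu_variants:
    human: {ecf: 0.1, lv: 0.272, cm: 0.272}  # ecf rat-derived/8-scaled; lv, cm measured in humans
  af_reported:
    unverified: true
    human: {af_out_ecf: 5.7, af_out_lv: 47.3, af_out_cm: 48.1}

methotrexate:
  mw: {value: 454.45, units: g/mol}
  charge_class: acid
  pka: 3.41
  pkb: 2.81
  logp: -1.85
  kpuu: {ecf: 0.018, lv: 0.0066, cm: 0.0024}
  kpuu_variants:
    rat: {ecf: 0.018, lv: 0.0066, cm: 0.0024}
  af_reported:
    unverified: true
    rat: {af_out_ecf: 4.1e8, af_out_lv: 9.5e9, af_out_cm: 2.6e10}

morphine:
  mw: {value: 285.34, units: g/mol}
  charge_class: base
  pka: 10.26
  pkb: 9.12
  logp: 0.87
  kpuu: {ecf: 0.38, lv: 0.38, cm: 0.38}
  kpuu_variants:
    rat_dose_4mgkg: {ecf: 0.38, lv: 0.38, cm: 0.38}
    rat_dose_10_40mgkg: {ecf: 0.23, lv: 0.23, cm: 0.23}
    human: {ecf: 0.23, lv: 0.23, cm: 0.23}  # rat values corrected for human translation
  af_reported:
    unverified: true
    rat_dose_4mgkg: {af_out_ecf: 372.8, af_out_lv: 2999.5, af_out_cm: 3088.1}
    rat_dose_10_40mgkg: {af_out_ecf: 764.5, af_out_lv: 6248.0, af_out_cm: 6336.6}
    human: {af_out_ecf: 170.4, af_out_lv: 671.8, af_out_cm: 677.2}

oxycodone:
  mw: {value: 315.37, units: g/mol}
  charge_class: base
  pka: 13.56
  pkb: 8.21
  logp: 0.7
  kpuu: {ecf: 1.69, lv: 2.0, cm: 2.0}
  kpuu_variants:
    human: {ecf: 1.69, lv: 2.0, cm: 2.0}  # ecf rat-corrected; lv, cm measured in humans
  af_reported:
    unverified: true
    human: {af_in_ecf: 7.6, af_in_lv: 100.6, af_in_cm: 94.7}

paliperidone:
  mw: {value: 426.49, units: g/mol}
  charge_class: base
  pka: 13.74
  pkb: 8.76
  logp: 1.8
  kpuu: {ecf: 0.5, lv: 0.5, cm: 0.5}
  kpuu_variants:
    rat: {ecf: 0.5, lv: 0.5, cm: 0.5}
  af_reported:
    unverified: true
    rat: {af_out_ecf: 13.7, af_out_lv: 90.8, af_out_cm: 96.0}

phenytoin:
  mw: {value: 252.27, units: g/mol}
  charge_class: neutral
  pka: 9.47
  pkb: -9.0
  logp: 2.47
  kpuu: {ecf: 0.26, lv: 0.26, cm: 0.26}
  kpuu_variants:
    rat: {ecf: 0.26, lv: 0.26, cm: 0.26}
  af_reported:
    unverified: true
    rat: {af_out_ecf: 4.2, af_out_lv: 6.5, af_out_cm: 6.5}

quinidine:
  mw: {value: 324.42, units: g/mol}
  charge_class: base
  pka: 13.89
  pkb: 9.05
  logp: 3.44
  kpuu: {ecf: 1.5, lv: 1.5, cm: 1.5}
  kpuu_variants:
    rat: {ecf: 1.5, lv: 1.5, cm: 1.5}
  af_reported:
    unverified: true
    rat: {af_in_ecf: 1.5, af_in_lv: 3.9, af_in_cm: 3.6}

raclopride:
  mw: {value: 347.24, units: g/mol}
  charge_class: amphoteric
  pka: 5.31
  pkb: 9.32
  logp: 3.38
  kpuu: {ecf: 1.1, lv: 1.1, cm: 1.1}
  kpuu_variants:
    rat: {ecf: 1.1, lv: 1.1, cm: 1.1}
  af_reported:
    unverified: true   # AF_in columns not recoverable from the source text
    rat: {af_in_ecf: null, af_in_lv: null, af_in_cm: null}

remoxipride:
  mw: {value: 371.28, units: g/mol}
  charge_class: base
  pka: 13.06
  pkb: 8.4
  logp: 2.1
  kpuu: {ecf: 0.8, lv: 0.8, cm: 0.8}
  kpuu_variants:
    rat: {ecf: 0.8, lv: 0.8, cm: 0.8}
  af_reported:
    unverified: true
    rat: {af_out_ecf: 2.2, af_out_lv: 6.2, af_out_cm: 7.5}

risperidone:
  mw: {value: 410.49, units: g/mol}
  charge_class: base
  pka: null
  pkb: 8.76
  logp: 3.27
  kpuu: {ecf: 0.97, lv: 0.97, cm: 0.97}
  kpuu_variants:
    rat: {ecf: 0.97, lv: 0.97, cm: 0.97}
  af_reported:
    unverified: true
    rat: {af_out_ecf: 1.3, af_out_lv: 1.2, af_out_cm: 1.4}
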