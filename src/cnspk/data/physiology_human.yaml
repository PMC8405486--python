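# Human CNS physiology defaults.
#
# Best-effort literature values (flagged as such): where several literature
# values exist the mean was used. Each field carries its canonical units.
species: human
fields:
  v_mv:           {value: 30.0,    units: mL}       # cerebral microvascular blood volume
  v_ecf:          {value: 240.0,   units: mL}       # brain ECF (~17% of brain volume)
  v_icf:          {value: 960.0,   units: mL}       # brain ICF
  v_lys:          {value: 10.0,    units: mL}       # lysosomes (lumped, ~1% cell volume)
  v_lv:           {value: 22.5,    units: mL}       # lateral ventricles CSF
  v_tfv:          {value: 22.5,    units: mL}       # third + fourth ventricles CSF
  v_cm:           {value: 7.5,     units: mL}       # cisterna magna CSF
  v_sas:          {value: 90.0,    units: mL}       # subarachnoid (incl. spinal/lumbar) CSF
  v_brain:        {value: 1400.0,  units: mL}       # total brain volume
  q_cbf:          {value: 610.0,   units: mL/min}   # cerebral blood flow
  q_ecf:          {value: 0.175,   units: mL/min}   # ECF bulk flow
  q_csf:          {value: 0.35,    units: mL/min}   # CSF production/flow
  sa_bbb:         {value: 1.2e5,   units: cm^2}     # BBB endothelial surface (~12 m^2)
  sa_bcsfb_lv:    {value: 5.0e4,   units: cm^2}     # choroid plexus at lateral ventricles (microvilli-amplified epithelium)
  sa_bcsfb_tfv:   {value: 5.0e4,   units: cm^2}     # choroid plexus at third/fourth ventricles
  sa_lys:         {value: 3.0e5,   units: cm^2}     # total lysosomal membrane (lumped)
  pore_radius_nm: {value: 0.9,     units: nm}       # tight-junction pore radius
  para_path_um:   {value: 0.5,     units: um}       # effective paracellular path length
  para_fraction:  {value: 1.0e-4,  units: dimensionless}
  cell_count:     {value: 1.7e11,  units: count}    # neurons + glia
  cell_radius_um: {value: 5.0,     units: um}
  ph_plasma:      {value: 7.4,     units: pH}
  ph_ecf:         {value: 7.3,     units: pH}
  ph_icf:         {value: 7.0,     units: pH}
  ph_lys:         {value: 5.0,     units: pH}
  ph_csf:         {value: 7.3,     units: pH}
  bcm_volume_fraction: {value: 0.05, units: dimensionless}
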