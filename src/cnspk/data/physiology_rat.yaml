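# Rat CNS physiology defaults.
#
# Best-effort literature values (flagged as such): where several literature
# values exist the mean was used. Each field carries its canonical units.
# Sources are indicated per field; override any field for a specific study.
species: rat
fields:
  v_mv:           {value: 0.06,    units: mL}       # cerebral microvascular blood volume, ~3% brain
  v_ecf:          {value: 0.29,    units: mL}       # brain ECF (microdialysis/TMA+ studies)
  v_icf:          {value: 1.44,    units: mL}       # brain ICF, ~80% of parenchymal water
  v_lys:          {value: 0.014,   units: mL}       # lysosomes, ~1% of cell volume (lumped)
  v_lv:           {value: 0.05,    units: mL}       # lateral ventricles CSF
  v_tfv:          {value: 0.09,    units: mL}       # third + fourth ventricles CSF
  v_cm:           {value: 0.017,   units: mL}       # cisterna magna CSF
  v_sas:          {value: 0.18,    units: mL}       # subarachnoid space CSF
  v_brain:        {value: 1.8,     units: mL}       # total brain volume (~1.8 g, density ~1)
  q_cbf:          {value: 1.2,     units: mL/min}   # cerebral blood flow
  q_ecf:          {value: 0.0002,  units: mL/min}   # ECF bulk flow (0.2 uL/min)
  q_csf:          {value: 0.0022,  units: mL/min}   # CSF production/flow (2.2 uL/min)
  sa_bbb:         {value: 263.0,   units: cm^2}     # BBB endothelial surface
  sa_bcsfb_lv:    {value: 99.0,    units: cm^2}     # choroid plexus at lateral ventricles (microvilli-amplified epithelium)
  sa_bcsfb_tfv:   {value: 99.0,    units: cm^2}     # choroid plexus at third/fourth ventricles
  sa_lys:         {value: 700.0,   units: cm^2}     # total lysosomal membrane (lumped)
  pore_radius_nm: {value: 0.9,     units: nm}       # tight-junction pore radius
  para_path_um:   {value: 0.5,     units: um}       # effective paracellular path length
  para_fraction:  {value: 1.0e-4,  units: dimensionless}  # fraction of barrier surface that is paracellular
  cell_count:     {value: 3.3e8,   units: count}    # total brain cells (neurons + glia)
  cell_radius_um: {value: 5.0,     units: um}       # equal-sphere brain cell radius
  ph_plasma:      {value: 7.4,     units: pH}
  ph_ecf:         {value: 7.3,     units: pH}
  ph_icf:         {value: 7.0,     units: pH}
  ph_lys:         {value: 5.0,     units: pH}       # lumped lysosomal lumen
  ph_csf:         {value: 7.3,     units: pH}
  bcm_volume_fraction: {value: 0.05, units: dimensionless}  # phospholipid fraction of brain volume
# v_bcm and sa_bcm are derived: v_bcm = bcm_volume_fraction * v_brain;
# sa_bcm = cell_count * 4*pi*cell_radius^2.
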