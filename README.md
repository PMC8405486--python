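# cnspk

A physiologically-based CNS pharmacokinetic simulator: an empirical
compartmental plasma model drives a nine-compartment brain/CSF disposition
model (microvessels, brain ECF/ICF, lysosomes, brain cell membrane, lateral
ventricles, third+fourth ventricles, cisterna magna, subarachnoid space)
through cerebral blood flow.

Mechanistic features:

- **pH-gated passive transport** — compartment-specific neutral fractions
  from adapted Henderson–Hasselbalch equations; only neutral species cross
  membranes transcellularly, charged species are restricted to the
  paracellular tight-junction route (Renkin-type steric hindrance).
- **Non-specific brain binding** — diffusion clearances between brain
  ECF/ICF and the brain-cell-membrane phospholipid compartment (5% of brain
  volume) whose steady-state concentration ratio equals the octanol–water
  partition coefficient by construction.
- **Asymmetry factors** — active transport/metabolism lumped into
  multipliers on passive influx (AF_in) or efflux (AF_ef) clearance,
  calibrated by steady-state root finding so the model reproduces measured
  unbound tissue-to-plasma ratios (Kp_uu) in ECF, lateral ventricles and
  cisterna magna simultaneously (three-scenario rule: Kp_uu < 1 solves
  AF_ef, Kp_uu > 1 solves AF_in, Kp_uu = 1 leaves both at 1).
- **Evaluation machinery** — replicate simulations with exponential
  inter-individual and proportional/additive residual variability
  (visual-predictive-check bands), and RA / %AFE / %AAFE / %MARA / SMAPE
  statistics.
- **In-silico experiments** — one-at-a-time parameter sensitivity analysis
  (log2 sensitivity index at 1.1/1.5/2-fold perturbations) and the
  altered-CSF-dynamics study (2x/5x CSF volume and flow scenarios with
  ECF-to-SAS surrogacy read-outs).

The linear time-invariant ODE system is propagated exactly with piecewise
matrix exponentials (steady states by direct linear solve); a stiff ODE
solver route is kept as an independent cross-check.

Drug physicochemistry (12 reference compounds), empirical plasma model
parameter sets (rat and human) and rat/human physiology defaults ship as
YAML fixtures under `src/cnspk/data/`. Physiology values are best-effort
literature means, documented per field and fully overridable. A synthetic
observed-data generator makes the whole repository testable offline.

## CLI

```bash
# CNS trajectories for a packaged drug fixture (9 compartments, tidy CSV)
cnspk simulate --species rat --drug acetaminophen --dose-ng 1e6 --out runs/sim

# synthetic observed dataset, then model evaluation against it
cnspk fixtures --species rat --drug acetaminophen --out runs/fx
cnspk evaluate --observed runs/fx/synthetic_observed.csv \
    --species rat --drug acetaminophen --out runs/ev

# sensitivity analysis and altered-CSF-dynamics scenario (human)
cnspk sensitivity --drug acetaminophen --kpuu-variant human \
    --parameter q_csf --parameter sa_bbb --out runs/sens
cnspk scenario --drug acetaminophen --kpuu-variant human \
    --volume-fold 2 --flow-fold 2 --out runs/csf2x
```

Every run writes a `manifest.json` (config hash, seed, version); runs with
identical manifests are bit-identical.

## Package layout

| module | contents |
| --- | --- |
| `cnspk.physiology` | validated physiology parameter sets, config I/O, fold perturbations |
| `cnspk.drug_params` | drug records, ionization, partitioning, permeability building blocks |
| `cnspk.plasma_pk` | 1–3 compartment plasma models, doses, IIV/residual sampling |
| `cnspk.cns_model` | CNS system assembly, asymmetry-factor calibration, simulation, descriptors |
| `cnspk.metrics` | observed datasets, VPC bands, RA/%AFE/%AAFE/%MARA/SMAPE |
| `cnspk.scenarios` | sensitivity analysis, CSF-dynamics scenarios, physiology IIV |
| `cnspk.workbench` | CLI, synthetic fixtures, manifests |
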