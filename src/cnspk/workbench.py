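"""CLI, run configuration, file I/O and the synthetic-fixture generator.

All randomness flows through explicit integer seeds; every run writes a
manifest (config hash, seed, package version) so two runs with the same
manifest are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import click
import numpy as np
import pandas as pd

from . import __version__
from .cns_model import (
    COMPARTMENTS,
    CnsSystem,
    build_system,
    simulate_coupled,
    simulation_to_frame,
)
from .drug_params import DrugRecord, load_drugs, select_kpuu_variant
from .metrics import ObservedDataset, evaluate, vpc
from .physiology import PhysiologySet, load_physiology
from .plasma_pk import DoseEvent, PlasmaModelSpec, load_plasma_models, sample_variability
from .scenarios import run_csf_scenarios, run_sensitivity

__all__ = [
    "RunConfig",
    "SyntheticObservedSpec",
    "default_physiology",
    "generate_synthetic_observed",
    "replicate_predictor",
    "write_manifest",
    "main",
]

OBSERVED_CSV_COLUMNS = (
    "drug", "species", "individual", "compartment", "time_min", "conc", "units", "fu_applied"
)


def default_physiology(species: str) -> PhysiologySet:
    """Packaged physiology defaults for 'rat' or 'human'."""
    name = f"physiology_{species}.yaml"
    try:
        text = resources.files("cnspk.data").joinpath(name).read_text(encoding="utf-8")
    except FileNotFoundError:
        raise ValueError(f"no packaged physiology for species {species!r} (rat, human)")
    import yaml

    return load_physiology(yaml.safe_load(text), species=species)


@dataclass(frozen=True)
class RunConfig:
    """Settings of one simulation/evaluation run (recorded in the manifest)."""

    species: str
    drug: str
    dose_ng: float
    route: str = "iv-bolus"
    infusion_min: float = 0.0
    t_max_min: float = 1440.0
    dt_min: float = 2.0
    seed: int = 1
    kpuu_variant: str | None = None

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_max_min + self.dt_min / 2, self.dt_min)

    def doses(self) -> list[DoseEvent]:
        return [
            DoseEvent(
                amount=self.dose_ng, route=self.route, start=0.0,
                duration=self.infusion_min,
            )
        ]


@dataclass(frozen=True)
class SyntheticObservedSpec:
    """Recipe for a synthetic observed dataset (stands in for in-vivo
    microdialysis data, which are not distributable)."""

    drug: DrugRecord
    physiology: PhysiologySet
    plasma_spec: PlasmaModelSpec
    doses: Sequence[DoseEvent]
    times_per_compartment: Mapping[str, Sequence[float]]
    n_individuals: int = 6
    noise_cv_pct: float = 20.0
    seed: int = 1
    include_iiv: bool = True

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.noise_cv_pct < 0:
            raise ValueError("noise_cv_pct must be >= 0")


def generate_synthetic_observed(
    spec: SyntheticObservedSpec, system: CnsSystem | None = None
) -> pd.DataFrame:
    """Simulate typical + inter-individual profiles, sample them at the
    stated times and apply multiplicative log-normal noise. Deterministic
    given the spec's seed; emits the observed-data CSV dialect."""
    system = system or build_system(spec.physiology, spec.drug, af_mode="solve")
    all_times = sorted({t for ts in spec.times_per_compartment.values() for t in ts})
    grid = np.unique(np.concatenate([[0.0], np.asarray(all_times, dtype=float)]))
    sigma = float(np.sqrt(np.log1p((spec.noise_cv_pct / 100.0) ** 2)))

    draws = sample_variability(spec.plasma_spec, spec.n_individuals, spec.seed)
    rows = []
    for individual, draw in enumerate(draws, start=1):
        eta = draw.eta if spec.include_iiv else {}
        sim = simulate_coupled(system, spec.plasma_spec, spec.doses, grid, eta=eta)
        for comp, times in spec.times_per_compartment.items():
            idx = np.searchsorted(grid, np.asarray(times, dtype=float))
            conc = sim[comp][idx]
            if sigma > 0:
                conc = conc * np.exp(draw._rng.normal(0.0, sigma, size=conc.shape))
            for t, c in zip(times, conc):
                rows.append(
                    {
                        "drug": spec.drug.name,
                        "species": spec.physiology.species,
                        "individual": individual,
                        "compartment": comp,
                        "time_min": float(t),
                        "conc": float(c),
                        "units": "ng/mL",
                        "fu_applied": True,
                    }
                )
    return pd.DataFrame(rows, columns=list(OBSERVED_CSV_COLUMNS))


def replicate_predictor(
    system: CnsSystem,
    plasma_spec: PlasmaModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    compartments: Sequence[str] = COMPARTMENTS,
) -> Callable[[Mapping[str, float]], dict[str, np.ndarray]]:
    """Predict function for :func:`cnspk.metrics.vpc`: eta -> compartment
    concentration profiles on ``times``."""
    times = np.asarray(times, dtype=float)

    def predict(eta: Mapping[str, float]) -> dict[str, np.ndarray]:
        sim = simulate_coupled(system, plasma_spec, doses, times, eta=eta)
        return {comp: sim[comp] for comp in compartments}

    return predict


def write_manifest(out_dir: Path, config: Mapping, seed: int) -> Path:
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(payload),
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "cnspk_version": __version__,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def _resolve_drug(name: str, variant: str | None = None) -> DrugRecord:
    drugs = load_drugs()
    if name not in drugs:
        raise click.ClickException(
            f"unknown drug {name!r}; available fixtures: {', '.join(sorted(drugs))}"
        )
    drug = drugs[name]
    if variant:
        drug = select_kpuu_variant(drug, variant)
    return drug


def _resolve_plasma(species: str, drug: str) -> PlasmaModelSpec:
    models = load_plasma_models()
    if species not in models:
        raise click.ClickException(
            f"no plasma models for species {species!r}; available: {', '.join(models)}"
        )
    if drug not in models[species]:
        raise click.ClickException(
            f"no {species} plasma model for {drug!r}; available: "
            f"{', '.join(sorted(models[species]))}"
        )
    return models[species][drug]


@click.group()
def main() -> None:
    """CNS pharmacokinetic simulator workbench."""


@main.command()
@click.option("--species", default="rat", show_default=True)
@click.option("--drug", "drug_name", required=True)
@click.option("--dose-ng", type=float, default=1e6, show_default=True)
@click.option("--route", type=click.Choice(["iv-bolus", "iv-infusion", "first-order-absorption"]),
              default="iv-bolus", show_default=True)
@click.option("--infusion-min", type=float, default=0.0, show_default=True)
@click.option("--t-max-min", type=float, default=1440.0, show_default=True)
@click.option("--dt-min", type=float, default=2.0, show_default=True)
@click.option("--kpuu-variant", default=None)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out", "out_dir", type=click.Path(file_okay=False), required=True)
def simulate(species, drug_name, dose_ng, route, infusion_min, t_max_min, dt_min,
             kpuu_variant, seed, out_dir) -> None:
    """Simulate CNS trajectories for one packaged drug fixture."""
    config = RunConfig(
        species=species, drug=drug_name, dose_ng=dose_ng, route=route,
        infusion_min=infusion_min, t_max_min=t_max_min, dt_min=dt_min,
        seed=seed, kpuu_variant=kpuu_variant,
    )
    drug = _resolve_drug(drug_name, kpuu_variant)
    plasma_spec = _resolve_plasma(species, drug_name)
    try:
        system = build_system(default_physiology(species), drug, af_mode="solve")
        sim = simulate_coupled(system, plasma_spec, config.doses(), config.times())
    except ValueError as exc:
        raise click.ClickException(str(exc))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = simulation_to_frame(sim, drug_name)
    frame.to_csv(out / "trajectories.csv", index=False)
    write_manifest(out, config.__dict__, seed)
    click.echo(f"wrote {out / 'trajectories.csv'} ({len(frame)} rows, 9 compartments)")


@main.command()
@click.option("--observed", "observed_csv", type=click.Path(exists=True, dir_okay=False),
              required=True)
@click.option("--species", default="rat", show_default=True)
@click.option("--drug", "drug_name", required=True)
@click.option("--dose-ng", type=float, default=1e6, show_default=True)
@click.option("--route", default="iv-bolus", show_default=True)
@click.option("--infusion-min", type=float, default=0.0, show_default=True)
@click.option("--kpuu-variant", default=None)
@click.option("--n-reps", type=int, default=200, show_default=True)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out", "out_dir", type=click.Path(file_okay=False), required=True)
def evaluate_cmd(observed_csv, species, drug_name, dose_ng, route, infusion_min,
                 kpuu_variant, n_reps, seed, out_dir) -> None:
    """Evaluate model predictions against an observed concentration CSV."""
    drug = _resolve_drug(drug_name, kpuu_variant)
    plasma_spec = _resolve_plasma(species, drug_name)
    observed = ObservedDataset(pd.read_csv(observed_csv))
    doses = [DoseEvent(amount=dose_ng, route=route, start=0.0, duration=infusion_min)]

    obs_times = np.unique(observed.frame["time_min"].to_numpy(dtype=float))
    grid = np.unique(np.concatenate([[0.0], obs_times]))
    compartments = tuple(sorted(observed.frame["compartment"].unique()))
    unknown = set(compartments) - set(COMPARTMENTS)
    if unknown:
        raise click.ClickException(f"unknown compartments in observed data: {sorted(unknown)}")
    try:
        system = build_system(default_physiology(species), drug, af_mode="solve")
        predict = replicate_predictor(system, plasma_spec, doses, grid, compartments)
        bands = vpc(predict, plasma_spec, grid, n_reps=n_reps, seed=seed)
        report = evaluate(observed, bands.med_pred_frame(drug_name))
    except ValueError as exc:
        raise click.ClickException(str(exc))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "relative_accuracy.csv", out / "summary.csv")
    write_manifest(
        out,
        {"observed": str(observed_csv), "species": species, "drug": drug_name,
         "dose_ng": dose_ng, "route": route, "n_reps": n_reps},
        seed,
    )
    click.echo(report.summary.to_string(index=False))


@main.command()
@click.option("--species", default="human", show_default=True)
@click.option("--drug", "drug_names", multiple=True, required=True)
@click.option("--parameter", "parameters", multiple=True, required=True)
@click.option("--fold", "folds", multiple=True, type=float, default=(1.1, 1.5, 2.0),
              show_default=True)
@click.option("--dose-ng", type=float, default=1e9, show_default=True)
@click.option("--t-max-min", type=float, default=1440.0, show_default=True)
@click.option("--dt-min", type=float, default=2.0, show_default=True)
@click.option("--kpuu-variant", default=None)
@click.option("--plasma-species", default="human", show_default=True)
@click.option("--plasma-drug", default="acetaminophen", show_default=True)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out", "out_dir", type=click.Path(file_okay=False), required=True)
def sensitivity(species, drug_names, parameters, folds, dose_ng, t_max_min, dt_min,
                kpuu_variant, plasma_species, plasma_drug, seed, out_dir) -> None:
    """One-at-a-time physiology perturbations with log2 sensitivity indices."""
    drugs = [_resolve_drug(name, kpuu_variant) for name in drug_names]
    plasma_spec = _resolve_plasma(plasma_species, plasma_drug)
    physiology = default_physiology(species)
    times = np.arange(0.0, t_max_min + dt_min / 2, dt_min)
    doses = [DoseEvent(amount=dose_ng)]
    try:
        results = run_sensitivity(
            physiology, drugs, plasma_spec, doses, times, list(parameters), list(folds)
        )
    except ValueError as exc:
        raise click.ClickException(str(exc))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([r.__dict__ for r in results])
    frame.to_csv(out / "sensitivity.csv", index=False)
    write_manifest(
        out,
        {"species": species, "drugs": list(drug_names), "parameters": list(parameters),
         "folds": list(folds), "dose_ng": dose_ng},
        seed,
    )
    click.echo(f"wrote {out / 'sensitivity.csv'} ({len(frame)} rows)")


@main.command()
@click.option("--species", default="human", show_default=True)
@click.option("--drug", "drug_name", required=True)
@click.option("--volume-fold", type=float, default=1.0, show_default=True)
@click.option("--flow-fold", type=float, default=1.0, show_default=True)
@click.option("--dose-ng", type=float, default=1e9, show_default=True)
@click.option("--t-max-min", type=float, default=1440.0, show_default=True)
@click.option("--dt-min", type=float, default=2.0, show_default=True)
@click.option("--kpuu-variant", default=None)
@click.option("--plasma-species", default="human", show_default=True)
@click.option("--plasma-drug", default="acetaminophen", show_default=True)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out", "out_dir", type=click.Path(file_okay=False), required=True)
def scenario(species, drug_name, volume_fold, flow_fold, dose_ng, t_max_min, dt_min,
             kpuu_variant, plasma_species, plasma_drug, seed, out_dir) -> None:
    """Altered-CSF-dynamics scenario (scaled CSF volumes and/or flow)."""
    drug = _resolve_drug(drug_name, kpuu_variant)
    plasma_spec = _resolve_plasma(plasma_species, plasma_drug)
    physiology = default_physiology(species)
    times = np.arange(0.0, t_max_min + dt_min / 2, dt_min)
    try:
        result = run_csf_scenarios(
            physiology, drug, plasma_spec, [DoseEvent(amount=dose_ng)], times,
            volume_fold=volume_fold, flow_fold=flow_fold,
        )
    except ValueError as exc:
        raise click.ClickException(str(exc))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = simulation_to_frame(result.baseline, drug_name)
    base["scenario"] = "physiological"
    scen = simulation_to_frame(result.scenario, drug_name)
    scen["scenario"] = f"vol{volume_fold}x_flow{flow_fold}x"
    pd.concat([base, scen], ignore_index=True).to_csv(out / "profiles.csv", index=False)
    deltas = pd.DataFrame(
        [
            {"compartment": comp, "descriptor": desc, "ratio_vs_physiological": value}
            for comp, descs in result.descriptor_deltas.items()
            for desc, value in descs.items()
        ]
    )
    deltas.to_csv(out / "descriptor_ratios.csv", index=False)
    write_manifest(
        out,
        {"species": species, "drug": drug_name, "volume_fold": volume_fold,
         "flow_fold": flow_fold, "dose_ng": dose_ng},
        seed,
    )
    click.echo(deltas.to_string(index=False))


@main.command()
@click.option("--species", default="rat", show_default=True)
@click.option("--drug", "drug_name", default="acetaminophen", show_default=True)
@click.option("--dose-ng", type=float, default=1e6, show_default=True)
@click.option("--n-individuals", type=int, default=6, show_default=True)
@click.option("--noise-cv-pct", type=float, default=20.0, show_default=True)
@click.option("--seed", type=int, default=1, show_default=True)
@click.option("--out", "out_dir", type=click.Path(file_okay=False), required=True)
def fixtures(species, drug_name, dose_ng, n_individuals, noise_cv_pct, seed, out_dir) -> None:
    """Write a synthetic observed dataset from packaged fixtures."""
    drug = _resolve_drug(drug_name)
    plasma_spec = _resolve_plasma(species, drug_name)
    sample_times = [15.0, 30.0, 60.0, 120.0, 240.0, 480.0]
    spec = SyntheticObservedSpec(
        drug=drug,
        physiology=default_physiology(species),
        plasma_spec=plasma_spec,
        doses=[DoseEvent(amount=dose_ng)],
        times_per_compartment={"ECF": sample_times, "LV": sample_times, "CM": sample_times},
        n_individuals=n_individuals,
        noise_cv_pct=noise_cv_pct,
        seed=seed,
    )
    try:
        frame = generate_synthetic_observed(spec)
    except ValueError as exc:
        raise click.ClickException(str(exc))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out / "synthetic_observed.csv", index=False)
    write_manifest(
        out,
        {"species": species, "drug": drug_name, "dose_ng": dose_ng,
         "n_individuals": n_individuals, "noise_cv_pct": noise_cv_pct},
        seed,
    )
    click.echo(f"wrote {out / 'synthetic_observed.csv'} ({len(frame)} rows)")


main.add_command(evaluate_cmd, name="evaluate")


if __name__ == "__main__":
    sys.exit(main())
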