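"""In-silico experiments: parameter sensitivity analysis and the
altered-CSF-dynamics surrogacy study.

Both experiments perturb physiology while holding the drug's calibrated
asymmetry factors fixed (the perturbation probes the physiology's effect at
fixed drug disposition); re-solving the factors after perturbation is
available via ``resolve_af=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cns_model import (
    BARRIERS,
    COMPARTMENTS,
    CnsSimulation,
    CnsSystem,
    build_system,
    pk_descriptors,
    simulate_coupled,
)
from .drug_params import DrugRecord
from .physiology import Perturbation, PhysiologySet, apply_perturbations
from .plasma_pk import DoseEvent, PlasmaModelSpec

__all__ = [
    "DESCRIPTORS",
    "SENSITIVITY_FOLDS",
    "CSF_VOLUME_FIELDS",
    "PHYSIOLOGY_IIV_WHITELIST",
    "SensitivityResult",
    "CsfScenarioResult",
    "PhysiologyIivResult",
    "run_sensitivity",
    "run_csf_scenarios",
    "add_physiology_iiv",
    "sensitivity_index",
    "compound_growth_pct",
]

DESCRIPTORS = ("cmax", "tmax", "auc")
SENSITIVITY_FOLDS = (1.1, 1.5, 2.0)
#: the four CSF compartment volumes scaled together in the CSF scenarios
CSF_VOLUME_FIELDS = ("v_lv", "v_tfv", "v_cm", "v_sas")
#: physiology fields eligible for nominal inter-individual variability
PHYSIOLOGY_IIV_WHITELIST = (
    "q_cbf", "q_ecf", "q_csf", "pore_radius_nm", "para_path_um", "para_fraction",
    "sa_bbb", "sa_bcsfb_lv", "sa_bcsfb_tfv",
)


def sensitivity_index(y_d: float, y_o: float) -> float:
    """log2(Y_d / Y_o); 0 whenever the descriptor is unchanged."""
    if y_d == y_o:
        return 0.0
    if y_o <= 0 or y_d <= 0:
        return math.inf if y_d > y_o else -math.inf
    return math.log2(y_d / y_o)


@dataclass(frozen=True)
class SensitivityResult:
    drug: str
    parameter: str
    fold: float
    compartment: str
    descriptor: str
    y_o: float
    y_d: float
    index: float
    failed: bool = False


def _af_snapshot(system: CnsSystem) -> dict[str, tuple[float, float]]:
    return {b: (system.barriers[b].af_in, system.barriers[b].af_ef) for b in BARRIERS}


def run_sensitivity(
    physiology: PhysiologySet,
    drugs: Sequence[DrugRecord],
    plasma_spec: PlasmaModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    parameters: Sequence[str],
    folds: Sequence[float] = SENSITIVITY_FOLDS,
    compartments: Sequence[str] = ("ECF", "ICF", "SAS"),
    resolve_af: bool = False,
) -> list[SensitivityResult]:
    """One-at-a-time fold perturbations of CNS parameters.

    Emits one result per (drug x parameter x fold x compartment x
    descriptor). Asymmetry factors are calibrated on the unperturbed
    physiology and held fixed unless ``resolve_af``. A failing perturbed
    simulation is flagged, not fatal.
    """
    times = np.asarray(times, dtype=float)
    results: list[SensitivityResult] = []
    for drug in drugs:
        base_system = build_system(physiology, drug, af_mode="solve")
        af = _af_snapshot(base_system)
        base_sim = simulate_coupled(base_system, plasma_spec, doses, times)
        base_desc = {
            comp: dict(zip(DESCRIPTORS, base_sim.descriptors(comp))) for comp in compartments
        }
        for parameter in parameters:
            for fold in folds:
                try:
                    perturbed = apply_perturbations(physiology, [Perturbation(parameter, fold)])
                    system = build_system(
                        perturbed, drug,
                        af_mode="solve" if resolve_af else "use-provided",
                        af_overrides=None if resolve_af else af,
                    )
                    sim = simulate_coupled(system, plasma_spec, doses, times)
                except Exception:
                    for comp in compartments:
                        for desc in DESCRIPTORS:
                            results.append(
                                SensitivityResult(
                                    drug=drug.name, parameter=parameter, fold=fold,
                                    compartment=comp, descriptor=desc,
                                    y_o=base_desc[comp][desc], y_d=math.nan,
                                    index=math.nan, failed=True,
                                )
                            )
                    continue
                for comp in compartments:
                    values = dict(zip(DESCRIPTORS, sim.descriptors(comp)))
                    for desc in DESCRIPTORS:
                        y_o, y_d = base_desc[comp][desc], values[desc]
                        results.append(
                            SensitivityResult(
                                drug=drug.name, parameter=parameter, fold=fold,
                                compartment=comp, descriptor=desc,
                                y_o=y_o, y_d=y_d, index=sensitivity_index(y_d, y_o),
                            )
                        )
    return results


@dataclass(frozen=True)
class CsfScenarioResult:
    """Physiological vs altered-CSF simulation of one drug."""

    drug: str
    volume_fold: float
    flow_fold: float
    baseline: CnsSimulation
    scenario: CnsSimulation
    ecf_sas_ratio_baseline: np.ndarray
    ecf_sas_ratio_scenario: np.ndarray
    descriptor_deltas: Mapping[str, Mapping[str, float]]  # compartment -> descriptor -> Yd/Yo


def run_csf_scenarios(
    physiology: PhysiologySet,
    drug: DrugRecord,
    plasma_spec: PlasmaModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    volume_fold: float = 1.0,
    flow_fold: float = 1.0,
) -> CsfScenarioResult:
    """Scale the four CSF compartment volumes by ``volume_fold`` and the CSF
    flow by ``flow_fold``; simulate ECF and SAS under a shared plasma
    forcing with the drug's physiological asymmetry-factor calibration held
    fixed. Reports descriptor ratios and the ECF-to-SAS concentration ratio."""
    if volume_fold <= 0 or flow_fold <= 0:
        raise ValueError("scenario folds must be > 0")
    times = np.asarray(times, dtype=float)

    base_system = build_system(physiology, drug, af_mode="solve")
    af = _af_snapshot(base_system)
    baseline = simulate_coupled(base_system, plasma_spec, doses, times)

    perturbations = [Perturbation(name, volume_fold) for name in CSF_VOLUME_FIELDS]
    perturbations.append(Perturbation("q_csf", flow_fold))
    altered = apply_perturbations(physiology, perturbations)
    system = build_system(altered, drug, af_mode="use-provided", af_overrides=af)
    scenario = simulate_coupled(system, plasma_spec, doses, times)

    def ratio(sim: CnsSimulation) -> np.ndarray:
        sas = sim["SAS"]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sas > 0, sim["ECF"] / sas, np.nan)

    deltas: dict[str, dict[str, float]] = {}
    for comp in ("ECF", "SAS"):
        base_desc = dict(zip(DESCRIPTORS, baseline.descriptors(comp)))
        scen_desc = dict(zip(DESCRIPTORS, scenario.descriptors(comp)))
        deltas[comp] = {
            desc: (scen_desc[desc] / base_desc[desc]) if base_desc[desc] != 0 else math.nan
            for desc in DESCRIPTORS
        }
    return CsfScenarioResult(
        drug=drug.name, volume_fold=volume_fold, flow_fold=flow_fold,
        baseline=baseline, scenario=scenario,
        ecf_sas_ratio_baseline=ratio(baseline),
        ecf_sas_ratio_scenario=ratio(scenario),
        descriptor_deltas=deltas,
    )


@dataclass(frozen=True)
class PhysiologyIivResult:
    times: np.ndarray
    lower: Mapping[str, np.ndarray]
    median: Mapping[str, np.ndarray]
    upper: Mapping[str, np.ndarray]
    cv_pct: float
    n_reps: int
    seed: int


def add_physiology_iiv(
    physiology: PhysiologySet,
    drug: DrugRecord,
    plasma_spec: PlasmaModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    cv_pct: float,
    n_reps: int = 200,
    seed: int = 0,
    parameters: Sequence[str] = PHYSIOLOGY_IIV_WHITELIST,
    compartments: Sequence[str] = COMPARTMENTS,
) -> PhysiologyIivResult:
    """Nominal inter-individual variability on CNS physiology parameters.

    Per replicate, each whitelisted parameter is multiplied by an
    independent log-normal factor exp(sigma Z) with sigma = sqrt(ln(1+CV^2))
    (median 1). Plasma stays at its typical profile to isolate the CNS
    contribution. Asymmetry factors are held at physiological calibration.
    Deterministic given ``seed``; returns 2.5/50/97.5 percentile bands.
    """
    if cv_pct < 0:
        raise ValueError("cv_pct must be >= 0")
    times = np.asarray(times, dtype=float)
    base_system = build_system(physiology, drug, af_mode="solve")
    af = _af_snapshot(base_system)
    sigma = math.sqrt(math.log1p((cv_pct / 100.0) ** 2))

    # para_fraction must stay in (0, 1): clamp multiplicative excursions
    def bounded_fold(name: str, fold: float) -> float:
        if name == "para_fraction":
            current = getattr(physiology, name)
            return min(fold, 0.99 / current)
        return fold

    rng = np.random.default_rng(seed)
    stacks: dict[str, list[np.ndarray]] = {comp: [] for comp in compartments}
    for _ in range(n_reps):
        z = rng.standard_normal(len(parameters))
        folds = np.exp(sigma * z)
        perts = [
            Perturbation(name, bounded_fold(name, fold))
            for name, fold in zip(parameters, folds)
        ]
        perturbed = apply_perturbations(physiology, perts)
        system = build_system(perturbed, drug, af_mode="use-provided", af_overrides=af)
        sim = simulate_coupled(system, plasma_spec, doses, times)
        for comp in compartments:
            stacks[comp].append(sim[comp])

    lower, median, upper = {}, {}, {}
    for comp, reps in stacks.items():
        arr = np.vstack(reps)
        lower[comp] = np.percentile(arr, 2.5, axis=0)
        median[comp] = np.percentile(arr, 50.0, axis=0)
        upper[comp] = np.percentile(arr, 97.5, axis=0)
    return PhysiologyIivResult(
        times=times, lower=lower, median=median, upper=upper,
        cv_pct=cv_pct, n_reps=n_reps, seed=seed,
    )


def compound_growth_pct(annual_pct: float, years: float) -> float:
    """Relative size after compound annual growth, as a percent of baseline
    (e.g. ventricular volume expansion over two decades of aging)."""
    return 100.0 * (1.0 + annual_pct / 100.0) ** years
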