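"""Nine-compartment CNS disposition model driven by plasma.

State vector: amounts (ng) in, fixed order,
MV (brain microvessels), ECF, ICF, LYS (lysosomes), BCM (brain cell
membrane), LV (lateral ventricles), TFV (third+fourth ventricles),
CM (cisterna magna), SAS (subarachnoid space).

Transport topology:
  plasma <-> MV via cerebral blood flow (plasma is an external forcing);
  MV <-> ECF (BBB), MV <-> LV (BCSFB at LV), MV <-> TFV (BCSFB at TFV):
    paracellular + pH-gated transcellular, scaled by asymmetry factors;
  ECF <-> ICF and ICF <-> LYS: transcellular only (neutral species);
  ECF <-> BCM and ICF <-> BCM: non-specific binding diffusion clearances;
  ECF -> LV: ECF bulk flow; LV -> TFV -> CM -> SAS -> sink:
    CSF flow plus entrained ECF bulk flow. No direct ECF <-> SAS exchange.

Transcellular flux convention: J(A -> B) = P_trans * SA * PHF_A * Cu_A, so
only the neutral fraction crosses and pH gradients drive ion trapping.
Charged species use the paracellular route only, which PHF does not scale.
Asymmetry factors multiply the total passive influx (AF_in) or efflux
(AF_ef) clearance of their barrier.

The system is linear time-invariant for a fixed plasma forcing; steady
states are obtained by direct linear solve, and time courses by an exact
piecewise propagator (matrix exponential with piecewise-linear forcing).
A stiff ODE-solver route is kept as an alternative/oracle.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from .drug_params import (
    DiffusionCoefficients,
    DrugRecord,
    MembraneBinding,
    PermeabilityCoefficients,
    aqueous_diffusivity,
    build_membrane_binding,
    compute_phf,
    molecular_radius_nm,
    transmembrane_permeability,
)
from .physiology import PhysiologySet
from .plasma_pk import (
    DoseEvent,
    PlasmaModelSpec,
    PlasmaProfile,
    dose_schedule,
    plasma_matrices,
)

__all__ = [
    "COMPARTMENTS",
    "BARRIERS",
    "BarrierDisposition",
    "CnsOptions",
    "CnsSystem",
    "CnsSimulation",
    "CnsModelError",
    "CalibrationError",
    "build_system",
    "paracellular_clearance",
    "hindrance_factor",
    "solve_asymmetry_factors",
    "scale_af_interspecies",
    "steady_state_concentrations",
    "kpuu_steady_state",
    "simulate_cns",
    "simulate_coupled",
    "pk_descriptors",
    "simulation_to_frame",
]

logger = logging.getLogger(__name__)

COMPARTMENTS = ("MV", "ECF", "ICF", "LYS", "BCM", "LV", "TFV", "CM", "SAS")
_IDX = {name: i for i, name in enumerate(COMPARTMENTS)}
BARRIERS = ("BBB", "BCSFB_LV", "BCSFB_TFV")
#: barrier -> (tissue compartment, Kp_uu region used for calibration)
_BARRIER_TISSUE = {"BBB": ("ECF", "ecf"), "BCSFB_LV": ("LV", "lv"), "BCSFB_TFV": ("TFV", "cm")}

_AF_BRACKET_LOG10 = 12.0  # AF searched in [1, 10**12]


class CnsModelError(ValueError):
    """Raised on inconsistent system construction or simulation input."""


class CalibrationError(RuntimeError):
    """Raised when no asymmetry factor >= 1 can reach a Kp_uu target."""


@dataclass
class BarrierDisposition:
    """Passive clearances and asymmetry factors at one barrier.

    ``cl_trans`` is permeability * surface area before pH gating;
    ``phf_donor``/``phf_tissue`` are the neutral fractions on the
    microvessel and tissue sides. At most one of ``af_in``/``af_ef``
    exceeds 1 (three-scenario rule).
    """

    barrier: str
    cl_para: float
    cl_trans: float
    phf_donor: float
    phf_tissue: float
    kpuu_target: Optional[float] = None
    af_in: float = 1.0
    af_ef: float = 1.0

    def __post_init__(self) -> None:
        if self.af_in < 1.0 or self.af_ef < 1.0:
            raise CnsModelError(f"{self.barrier}: asymmetry factors must be >= 1")
        if self.af_in > 1.0 and self.af_ef > 1.0:
            raise CnsModelError(
                f"{self.barrier}: at most one of af_in/af_ef may exceed 1"
            )

    @property
    def cl_in(self) -> float:
        """Total influx clearance (mL/min), plasma/MV side -> tissue."""
        return self.af_in * (self.cl_trans * self.phf_donor + self.cl_para)

    @property
    def cl_out(self) -> float:
        """Total efflux clearance (mL/min), tissue -> MV."""
        return self.af_ef * (self.cl_trans * self.phf_tissue + self.cl_para)


@dataclass(frozen=True)
class CnsOptions:
    """Route toggles, used by reduced-system tests and diagnostics.

    ``icf_exchange=False`` removes every route touching ICF (ECF<->ICF,
    ICF<->LYS, ICF<->BCM); ``membrane_binding=False`` removes the BCM
    binding clearances; ``ecf_bulk_flow=False`` removes the ECF->LV bulk
    route (the CSF cascade then carries Q_CSF only).
    """

    icf_exchange: bool = True
    lysosome: bool = True
    membrane_binding: bool = True
    ecf_bulk_flow: bool = True


@dataclass
class CnsSystem:
    """Assembled CNS disposition system for one drug and one physiology."""

    physiology: PhysiologySet
    drug: DrugRecord
    barriers: dict[str, BarrierDisposition]
    membrane: MembraneBinding
    phf: dict[str, float]  # compartment -> neutral fraction
    cl_bcm_trans: float  # ECF<->ICF transcellular, before pH gating
    cl_lys_trans: float  # ICF<->LYS transcellular, before pH gating
    options: CnsOptions = field(default_factory=CnsOptions)

    @property
    def volumes(self) -> np.ndarray:
        p = self.physiology
        return np.array(
            [p.v_mv, p.v_ecf, p.v_icf, p.v_lys, p.v_bcm, p.v_lv, p.v_tfv, p.v_cm, p.v_sas]
        )

    def rate_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(M, e): dA/dt = M A + e * Cu_plasma(t), amounts in ng.

        All CNS compartments hold unbound drug (CSF binding is an
        observation-side correction, see ``DrugRecord.fu_csf``); bound
        membrane drug is explicit in the BCM compartment.
        """
        p = self.physiology
        n = len(COMPARTMENTS)
        M = np.zeros((n, n))
        V = self.volumes

        def exchange(src: str, dst: str, cl: float) -> None:
            # clearance cl (mL/min) acting on the concentration of src
            i, j = _IDX[src], _IDX[dst]
            k = cl / V[i]
            M[i, i] -= k
            M[j, i] += k

        def sink(src: str, cl: float) -> None:
            i = _IDX[src]
            M[i, i] -= cl / V[i]

        # plasma <-> MV via cerebral blood flow; efflux side here, influx in e
        sink("MV", p.q_cbf)

        # barriers
        for barrier_id, (tissue, _) in _BARRIER_TISSUE.items():
            disp = self.barriers[barrier_id]
            exchange("MV", tissue, disp.cl_in)
            exchange(tissue, "MV", disp.cl_out)

        # brain cell membrane crossing and lysosomes (transcellular, pH-gated)
        if self.options.icf_exchange:
            exchange("ECF", "ICF", self.cl_bcm_trans * self.phf["ECF"])
            exchange("ICF", "ECF", self.cl_bcm_trans * self.phf["ICF"])
            if self.options.lysosome:
                exchange("ICF", "LYS", self.cl_lys_trans * self.phf["ICF"])
                exchange("LYS", "ICF", self.cl_lys_trans * self.phf["LYS"])

        # non-specific binding to the brain cell membrane compartment
        if self.options.membrane_binding:
            exchange("ECF", "BCM", self.membrane.cl_wo)
            exchange("BCM", "ECF", self.membrane.cl_ow)
            if self.options.icf_exchange:
                exchange("ICF", "BCM", self.membrane.cl_wo)
                exchange("BCM", "ICF", self.membrane.cl_ow)

        # bulk fluid flows carry total (bound + unbound) drug
        q_chain = p.q_csf
        if self.options.ecf_bulk_flow:
            i, j = _IDX["ECF"], _IDX["LV"]
            k = p.q_ecf / V[i]
            M[i, i] -= k
            M[j, i] += k
            q_chain += p.q_ecf
        for src, dst in (("LV", "TFV"), ("TFV", "CM"), ("CM", "SAS")):
            i, j = _IDX[src], _IDX[dst]
            k = q_chain / V[i]
            M[i, i] -= k
            M[j, i] += k
        sink("SAS", q_chain)  # absorption sites: elimination

        e = np.zeros(n)
        e[_IDX["MV"]] = p.q_cbf
        return M, e

    def unbound_concentrations(self, amounts: np.ndarray) -> np.ndarray:
        """Concentrations from amounts (aqueous compartments are unbound by
        construction; BCM is reported as membrane concentration)."""
        return np.asarray(amounts) / self.volumes


@dataclass(frozen=True)
class CnsSimulation:
    """Solved unbound concentration-time trajectories for all compartments."""

    times: np.ndarray
    conc: np.ndarray  # (n_compartments, n_times), ng/mL
    plasma_unbound: np.ndarray  # driving profile, ng/mL
    compartments: tuple[str, ...] = COMPARTMENTS

    def __getitem__(self, compartment: str) -> np.ndarray:
        return self.conc[_IDX[compartment]]

    def descriptors(self, compartment: str) -> tuple[float, float, float]:
        return pk_descriptors(self.times, self[compartment])


# ---------------------------------------------------------------------------
# passive clearances


def hindrance_factor(lam: float) -> float:
    """Renkin-type steric hindrance for a sphere of relative size ``lam`` =
    molecular radius / pore radius; 1 at lam = 0, 0 for lam >= 1."""
    if lam >= 1.0:
        return 0.0
    poly = 1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5
    return max((1.0 - lam) ** 2 * poly, 0.0)


def paracellular_clearance(
    physiology: PhysiologySet,
    drug: DrugRecord,
    barrier: str,
    diffusion: DiffusionCoefficients | None = None,
) -> float:
    """Aqueous tight-junction clearance (mL/min) at one barrier; applies
    equally to neutral and charged species."""
    surface = {
        "BBB": physiology.sa_bbb,
        "BCSFB_LV": physiology.sa_bcsfb_lv,
        "BCSFB_TFV": physiology.sa_bcsfb_tfv,
    }
    if barrier not in surface:
        raise CnsModelError(f"unknown barrier {barrier!r}; expected one of {BARRIERS}")
    d_aq = aqueous_diffusivity(drug.mw, diffusion)
    lam = molecular_radius_nm(drug.mw) / physiology.pore_radius_nm
    path_cm = physiology.para_path_um * 1e-4
    area = surface[barrier] * physiology.para_fraction
    return d_aq * area * hindrance_factor(lam) / path_cm


# ---------------------------------------------------------------------------
# system assembly


def build_system(
    physiology: PhysiologySet,
    drug: DrugRecord,
    af_mode: str = "solve",
    af_overrides: Mapping[str, tuple[float, float]] | None = None,
    options: CnsOptions | None = None,
    perm_coeffs: PermeabilityCoefficients | None = None,
    diffusion: DiffusionCoefficients | None = None,
    kinetic_scale: float | None = None,
) -> CnsSystem:
    """Assemble the CNS system for one drug.

    af_mode:
      * ``"solve"`` — calibrate asymmetry factors against the drug's Kp_uu
        targets (steady-state root finding);
      * ``"use-provided"`` — take AF values from ``af_overrides``
        (barrier -> (af_in, af_ef));
      * ``"passive"`` — leave all AF at 1 (no active transport).
    """
    options = options or CnsOptions()
    phf = {
        "MV": compute_phf(drug, physiology.ph_plasma).phf,
        "ECF": compute_phf(drug, physiology.ph_ecf).phf,
        "ICF": compute_phf(drug, physiology.ph_icf).phf,
        "LYS": compute_phf(drug, physiology.ph_lys).phf,
        "LV": compute_phf(drug, physiology.ph_csf).phf,
        "TFV": compute_phf(drug, physiology.ph_csf).phf,
        "CM": compute_phf(drug, physiology.ph_csf).phf,
        "SAS": compute_phf(drug, physiology.ph_csf).phf,
    }
    p_trans = transmembrane_permeability(drug, perm_coeffs)
    tissue_side_phf = {"BBB": phf["ECF"], "BCSFB_LV": phf["LV"], "BCSFB_TFV": phf["TFV"]}

    barriers: dict[str, BarrierDisposition] = {}
    for barrier_id in BARRIERS:
        region = _BARRIER_TISSUE[barrier_id][1]
        barriers[barrier_id] = BarrierDisposition(
            barrier=barrier_id,
            cl_para=paracellular_clearance(physiology, drug, barrier_id, diffusion),
            cl_trans=p_trans * {
                "BBB": physiology.sa_bbb,
                "BCSFB_LV": physiology.sa_bcsfb_lv,
                "BCSFB_TFV": physiology.sa_bcsfb_tfv,
            }[barrier_id],
            phf_donor=phf["MV"],
            phf_tissue=tissue_side_phf[barrier_id],
            kpuu_target=drug.kpuu.get(region),
        )

    system = CnsSystem(
        physiology=physiology,
        drug=drug,
        barriers=barriers,
        membrane=build_membrane_binding(drug, physiology, kinetic_scale),
        phf=phf,
        cl_bcm_trans=p_trans * physiology.sa_bcm,
        cl_lys_trans=p_trans * physiology.sa_lys,
        options=options,
    )

    if af_mode == "solve":
        missing = [b for b in BARRIERS if system.barriers[b].kpuu_target is None]
        if missing:
            raise CnsModelError(
                f"{drug.name}: af_mode='solve' needs Kp_uu targets for all barriers; "
                f"missing {missing}"
            )
        solve_asymmetry_factors(system)
    elif af_mode == "use-provided":
        if af_overrides is None:
            raise CnsModelError("af_mode='use-provided' requires af_overrides")
        for barrier_id in BARRIERS:
            if barrier_id not in af_overrides:
                raise CnsModelError(f"af_overrides missing barrier {barrier_id!r}")
            af_in, af_ef = af_overrides[barrier_id]
            system.barriers[barrier_id].af_in = 1.0
            system.barriers[barrier_id].af_ef = 1.0
            system.barriers[barrier_id].af_in = af_in
            system.barriers[barrier_id].af_ef = af_ef
            system.barriers[barrier_id].__post_init__()
    elif af_mode != "passive":
        raise CnsModelError(f"unknown af_mode {af_mode!r}")
    return system


# ---------------------------------------------------------------------------
# steady state and asymmetry factor calibration


def steady_state_concentrations(system: CnsSystem, cu_plasma: float = 1.0) -> np.ndarray:
    """Unbound steady-state concentrations under a constant unbound plasma
    concentration (direct linear solve)."""
    M, e = system.rate_matrix()
    # compartments disconnected by route toggles have all-zero rows and stay
    # at zero; solve the active subsystem
    active = np.flatnonzero((np.abs(M).sum(axis=1) + np.abs(e)) > 0)
    amounts = np.zeros(M.shape[0])
    sub = np.ix_(active, active)
    amounts[active] = np.linalg.solve(M[sub], -e[active] * cu_plasma)
    return system.unbound_concentrations(amounts)


def kpuu_steady_state(system: CnsSystem) -> dict[str, float]:
    """Steady-state unbound tissue-to-plasma ratios for the calibrated regions."""
    conc = steady_state_concentrations(system, cu_plasma=1.0)
    return {
        "ecf": conc[_IDX["ECF"]],
        "lv": conc[_IDX["LV"]],
        "cm": conc[_IDX["CM"]],
    }


def _set_af(disp: BarrierDisposition, af: float) -> None:
    if disp.kpuu_target is None or disp.kpuu_target == 1.0:
        disp.af_in = disp.af_ef = 1.0
    elif disp.kpuu_target > 1.0:
        disp.af_ef = 1.0
        disp.af_in = af
    else:
        disp.af_in = 1.0
        disp.af_ef = af


def solve_asymmetry_factors(
    system: CnsSystem, rtol: float = 1e-10, max_sweeps: int = 200
) -> dict[str, BarrierDisposition]:
    """Calibrate asymmetry factors so the steady state under a constant unit
    unbound plasma concentration reproduces all Kp_uu targets simultaneously.

    Per barrier, the three-scenario rule fixes which factor is free:
    Kp_uu < 1 -> AF_in = 1, solve AF_ef; Kp_uu > 1 -> AF_ef = 1, solve
    AF_in; Kp_uu = 1 -> both 1. Each free factor is bracketed in
    [1, 10^12] on a log scale (scalar root find) and the barriers are swept
    Gauss-Seidel style until all targets agree to relative tolerance.
    """
    free = []
    for barrier_id in BARRIERS:
        disp = system.barriers[barrier_id]
        _set_af(disp, 1.0)
        if disp.kpuu_target is not None and disp.kpuu_target != 1.0:
            free.append(barrier_id)

    def region_value(barrier_id: str) -> float:
        return kpuu_steady_state(system)[_BARRIER_TISSUE[barrier_id][1]]

    def residual(barrier_id: str, log_af: float) -> float:
        _set_af(system.barriers[barrier_id], 10.0**log_af)
        return math.log(region_value(barrier_id) / system.barriers[barrier_id].kpuu_target)

    for sweep in range(max_sweeps):
        converged = True
        for barrier_id in free:
            disp = system.barriers[barrier_id]
            current = math.log10(disp.af_in if disp.kpuu_target > 1.0 else disp.af_ef)
            if abs(residual(barrier_id, current)) <= rtol:
                continue
            converged = False
            r_lo = residual(barrier_id, 0.0)
            r_hi = residual(barrier_id, _AF_BRACKET_LOG10)
            if r_lo == 0.0:
                _set_af(disp, 1.0)
                continue
            if r_lo * r_hi > 0:
                _set_af(disp, 10.0**current)
                raise CalibrationError(
                    f"{system.drug.name} / {barrier_id}: no asymmetry factor in "
                    f"[1, 1e{_AF_BRACKET_LOG10:.0f}] reaches Kp_uu target "
                    f"{disp.kpuu_target} (passive steady state gives "
                    f"{region_value(barrier_id):.4g})"
                )
            log_af = brentq(
                lambda x: residual(barrier_id, x), 0.0, _AF_BRACKET_LOG10,
                xtol=1e-13, rtol=8.9e-16, maxiter=300,
            )
            _set_af(disp, 10.0**log_af)
        if converged:
            break
    else:
        raise CalibrationError(
            f"{system.drug.name}: asymmetry factor sweeps did not converge"
        )

    achieved = kpuu_steady_state(system)
    for barrier_id in BARRIERS:
        disp = system.barriers[barrier_id]
        region = _BARRIER_TISSUE[barrier_id][1]
        scenario = (
            "equilibrium" if disp.kpuu_target in (None, 1.0)
            else ("active influx" if disp.kpuu_target > 1.0 else "active efflux")
        )
        logger.info(
            "%s %s: Kp_uu target=%s achieved=%.6g AF_in=%.6g AF_ef=%.6g (%s)",
            system.drug.name, barrier_id, disp.kpuu_target,
            achieved[region], disp.af_in, disp.af_ef, scenario,
        )
    return system.barriers


def scale_af_interspecies(af: float, scaling_factor: float) -> float:
    """Interspecies translation of an asymmetry factor: af / scaling_factor,
    clamped at 1 (with a warning) if the quotient falls below 1."""
    if scaling_factor <= 0:
        raise CnsModelError(f"scaling_factor must be > 0, got {scaling_factor}")
    scaled = af / scaling_factor
    if scaled < 1.0:
        warnings.warn(
            f"scaled asymmetry factor {scaled:.4g} < 1; clamping to 1", stacklevel=2
        )
        return 1.0
    return scaled


# ---------------------------------------------------------------------------
# simulation


def _propagate_linear_forcing(
    M: np.ndarray, e: np.ndarray, times: np.ndarray, forcing: np.ndarray,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Exact states for dA/dt = M A + e * u(t) with u piecewise linear
    between grid points. Augments with (u, du/dt) carrier states so one
    matrix exponential per unique step size suffices."""
    n = M.shape[0]
    N = np.zeros((n + 2, n + 2))
    N[:n, :n] = M
    N[:n, n] = e
    N[n, n + 1] = 1.0

    x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
    out = np.zeros((len(times), n))
    out[0] = x
    cache: dict[float, np.ndarray] = {}
    for k in range(1, len(times)):
        h = times[k] - times[k - 1]
        if h == 0.0:
            out[k] = x
            continue
        P = cache.get(h)
        if P is None:
            P = expm(N * h)
            cache[h] = P
        slope = (forcing[k] - forcing[k - 1]) / h
        z = np.concatenate([x, [forcing[k - 1], slope]])
        x = P[:n] @ z
        out[k] = x
    return out


def simulate_cns(
    system: CnsSystem,
    plasma: Union[PlasmaProfile, np.ndarray, float, Callable[[np.ndarray], np.ndarray]],
    times: Sequence[float],
    method: str = "expm",
    x0: np.ndarray | None = None,
) -> CnsSimulation:
    """Simulate the CNS system driven by an unbound plasma profile.

    ``plasma`` may be a :class:`PlasmaProfile` (its unbound trace is
    resampled onto ``times``, which must be covered by the profile grid),
    an array aligned with ``times``, a constant, or a callable of time.

    ``method="expm"`` (default) uses the exact piecewise propagator with
    the forcing taken piecewise-linear between grid points;
    ``method="lsoda"`` integrates with a stiff ODE solver at tolerances
    rtol=1e-8, atol=1e-10 * peak forcing amount.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) < 0):
        raise CnsModelError("times must be a sorted 1-D grid with >= 2 points")

    if isinstance(plasma, PlasmaProfile):
        if times[0] < plasma.times[0] - 1e-9 or times[-1] > plasma.times[-1] + 1e-9:
            raise CnsModelError("plasma profile does not cover the requested time grid")
        forcing = np.interp(times, plasma.times, plasma.conc_unbound)
    elif callable(plasma):
        forcing = np.asarray(plasma(times), dtype=float)
    elif np.ndim(plasma) == 0:
        forcing = np.full(times.shape, float(plasma))
    else:
        forcing = np.asarray(plasma, dtype=float)
        if forcing.shape != times.shape:
            raise CnsModelError("plasma array must align with the time grid")

    M, e = system.rate_matrix()
    if method == "expm":
        amounts = _propagate_linear_forcing(M, e, times, forcing, x0)
    elif method == "lsoda":
        from scipy.integrate import solve_ivp

        peak = max(float(np.max(forcing)) * float(np.max(system.volumes)), 1.0)

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            u = np.interp(t, times, forcing)
            return M @ y + e * u

        sol = solve_ivp(
            rhs, (times[0], times[-1]),
            np.zeros(len(COMPARTMENTS)) if x0 is None else np.asarray(x0, dtype=float),
            method="LSODA", t_eval=times, rtol=1e-8, atol=1e-10 * peak,
            jac=lambda t, y: M,
        )
        if not sol.success:
            raise CnsModelError(f"integrator failed at t={sol.t[-1] if sol.t.size else times[0]}: {sol.message}")
        amounts = sol.y.T
    else:
        raise CnsModelError(f"unknown method {method!r}")

    conc = system.unbound_concentrations(amounts).T
    return CnsSimulation(times=times, conc=conc, plasma_unbound=forcing)


def simulate_coupled(
    system: CnsSystem,
    plasma_spec: PlasmaModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    eta: Mapping[str, float] | None = None,
) -> CnsSimulation:
    """Simulate plasma and CNS jointly as one block-triangular linear system
    (plasma forces the CNS; the CNS does not feed back). Exact piecewise
    matrix-exponential propagation, including dose boundaries."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) < 0) or times[0] < 0:
        raise CnsModelError("times must be a sorted, non-negative 1-D grid with >= 2 points")

    pm = plasma_matrices(plasma_spec, eta)
    boluses, infusions = dose_schedule(plasma_spec, doses, pm)
    M_cns, e_cns = system.rate_matrix()

    n_p = pm.A.shape[0]
    n_c = M_cns.shape[0]
    n = n_p + n_c
    A = np.zeros((n, n))
    A[:n_p, :n_p] = pm.A
    A[n_p:, n_p:] = M_cns
    # CNS driven by unbound central plasma concentration
    A[n_p:, pm.cen_index] += e_cns * plasma_spec.fu_plasma / pm.params["v_cen"]

    boundaries = {t for t, _ in boluses}
    for t0, t1, _ in infusions:
        boundaries.update((t0, t1))
    grid = np.unique(np.concatenate([times, np.fromiter(boundaries, dtype=float)]))
    grid = grid[(grid >= times[0]) & (grid <= times[-1])]

    from .plasma_pk import _Propagator

    prop = _Propagator(A)
    x = np.zeros(n)
    out = np.zeros((len(times), n))
    want: dict[float, list[int]] = {}
    for i, t in enumerate(times):
        want.setdefault(float(t), []).append(i)

    prev = grid[0]
    for k, t in enumerate(grid):
        if k > 0:
            u = np.zeros(n)
            for t0, t1, rate in infusions:
                if t0 - 1e-12 <= prev and t <= t1 + 1e-12:
                    u[:n_p] = u[:n_p] + rate
            x = prop.step(x, u, t - prev)
        for t_b, jump in boluses:
            if t_b == t:
                x[:n_p] = x[:n_p] + jump
        for i in want.get(float(t), ()):
            out[i] = x
        prev = t

    plasma_unbound = np.maximum(
        out[:, pm.cen_index] / pm.params["v_cen"] * plasma_spec.fu_plasma, 0.0
    )
    conc = system.unbound_concentrations(out[:, n_p:]).T
    return CnsSimulation(times=times, conc=conc, plasma_unbound=plasma_unbound)


# ---------------------------------------------------------------------------
# descriptors and output


def pk_descriptors(times: Sequence[float], conc: Sequence[float]) -> tuple[float, float, float]:
    """(C_max, T_max, AUC): maximum concentration, time of *first* maximum,
    trapezoidal AUC over the grid."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size < 2:
        raise CnsModelError("need at least 2 time points for PK descriptors")
    i_max = int(np.argmax(conc))  # argmax returns the first maximum
    auc = float(np.trapezoid(conc, times))
    return float(conc[i_max]), float(times[i_max]), auc


def simulation_to_frame(
    simulation: CnsSimulation, drug: str, replicate: int | None = None
) -> pd.DataFrame:
    """Tidy output: columns drug, compartment, time_min, conc_ng_per_ml, replicate."""
    frames = []
    for name in simulation.compartments:
        frames.append(
            pd.DataFrame(
                {
                    "drug": drug,
                    "compartment": name,
                    "time_min": simulation.times,
                    "conc_ng_per_ml": simulation[name],
                    "replicate": -1 if replicate is None else replicate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
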