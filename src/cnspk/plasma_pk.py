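"""Empirical compartmental plasma models: the forcing function of the CNS system.

Linear mammillary systems of 1-3 compartments, with optional first-order
absorption, exponential inter-individual variability (parameter * exp(eta))
and a proportional/additive residual model. Profiles are propagated exactly
with piecewise matrix exponentials (the system is linear time-invariant
between dose boundaries); an independent ODE-solver oracle lives in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from scipy.linalg import expm

__all__ = [
    "PlasmaModelSpec",
    "DoseEvent",
    "PlasmaProfile",
    "IndividualDraw",
    "PlasmaValidationError",
    "simulate_plasma",
    "sample_variability",
    "plasma_matrices",
    "dose_schedule",
    "load_plasma_models",
]

ROUTES = ("iv-bolus", "iv-infusion", "first-order-absorption")
#: parameters that may carry inter-individual variability
IIV_PARAMETERS = ("cl_cen", "q_per1", "q_per2", "v_cen", "v_per1", "v_per2", "ka")


class PlasmaValidationError(ValueError):
    """Raised on inconsistent plasma model specs or dose events."""


@dataclass(frozen=True)
class PlasmaModelSpec:
    """An empirical plasma PK parameter set with variability terms.

    Clearances mL/min, volumes mL, ``ka`` 1/min. ``iiv_cv_pct`` maps
    parameter names to %CV interpreted under an exponential model
    (omega = CV/100 by default, see :func:`sample_variability`).
    Residual: proportional %CV and additive SD (ng/mL).
    """

    name: str
    n_compartments: int
    cl_cen: float
    v_cen: float
    q_per1: float = 0.0
    q_per2: float = 0.0
    v_per1: float = 0.0
    v_per2: float = 0.0
    ka: Optional[float] = None
    bioavailability: float = 1.0
    fu_plasma: float = 1.0
    iiv_cv_pct: Mapping[str, float] = field(default_factory=dict)
    prop_cv_pct: float = 0.0
    add_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise PlasmaValidationError(f"n_compartments must be 1-3, got {self.n_compartments}")
        if self.v_cen <= 0:
            raise PlasmaValidationError("v_cen must be > 0")
        if self.cl_cen < 0:
            raise PlasmaValidationError("cl_cen must be >= 0")
        active = [("q_per1", "v_per1"), ("q_per2", "v_per2")][: self.n_compartments - 1]
        for q_name, v_name in active:
            if getattr(self, q_name) <= 0 or getattr(self, v_name) <= 0:
                raise PlasmaValidationError(
                    f"{q_name}/{v_name} must be > 0 for an active peripheral compartment"
                )
        for q_name, v_name in [("q_per1", "v_per1"), ("q_per2", "v_per2")][self.n_compartments - 1 :]:
            if getattr(self, q_name) != 0 or getattr(self, v_name) != 0:
                raise PlasmaValidationError(
                    f"unused compartment must have zero {q_name} and {v_name}"
                )
        for key, cv in self.iiv_cv_pct.items():
            if key not in IIV_PARAMETERS:
                raise PlasmaValidationError(f"unknown IIV parameter {key!r}")
            if cv < 0:
                raise PlasmaValidationError(f"IIV %CV for {key!r} must be >= 0")
        if self.prop_cv_pct < 0 or self.add_sd < 0:
            raise PlasmaValidationError("residual terms must be >= 0")
        if not (0 < self.bioavailability <= 1):
            raise PlasmaValidationError("bioavailability must be in (0, 1]")


@dataclass(frozen=True)
class DoseEvent:
    """amount in ng; start/duration in min."""

    amount: float
    route: str = "iv-bolus"
    start: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise PlasmaValidationError(f"dose amount must be > 0, got {self.amount}")
        if self.route not in ROUTES:
            raise PlasmaValidationError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.route == "iv-infusion" and self.duration <= 0:
            raise PlasmaValidationError("infusion duration must be > 0")
        if self.start < 0:
            raise PlasmaValidationError("dose start must be >= 0")


@dataclass(frozen=True)
class PlasmaProfile:
    times: np.ndarray
    conc_total: np.ndarray  # ng/mL, central compartment
    conc_unbound: np.ndarray  # ng/mL, fu_plasma * total


@dataclass(frozen=True)
class PlasmaMatrices:
    """Rate matrix over amount states plus bookkeeping for dose routing."""

    A: np.ndarray
    state_names: tuple[str, ...]
    cen_index: int
    depot_index: Optional[int]
    params: Mapping[str, float]


def effective_parameters(spec: PlasmaModelSpec, eta: Mapping[str, float] | None) -> dict[str, float]:
    """Typical parameters scaled by exp(eta) per parameter."""
    eta = eta or {}
    params = {
        "cl_cen": spec.cl_cen,
        "q_per1": spec.q_per1,
        "q_per2": spec.q_per2,
        "v_cen": spec.v_cen,
        "v_per1": spec.v_per1,
        "v_per2": spec.v_per2,
        "ka": spec.ka if spec.ka is not None else 0.0,
    }
    for key, value in eta.items():
        if key not in params:
            raise PlasmaValidationError(f"unknown eta parameter {key!r}")
        params[key] = params[key] * math.exp(value)
    return params


def plasma_matrices(spec: PlasmaModelSpec, eta: Mapping[str, float] | None = None) -> PlasmaMatrices:
    params = effective_parameters(spec, eta)
    names: list[str] = []
    depot_index = None
    if spec.ka is not None:
        depot_index = 0
        names.append("depot")
    cen_index = len(names)
    names.append("cen")
    per_indices = []
    if spec.n_compartments >= 2:
        per_indices.append(len(names))
        names.append("per1")
    if spec.n_compartments >= 3:
        per_indices.append(len(names))
        names.append("per2")

    n = len(names)
    A = np.zeros((n, n))
    A[cen_index, cen_index] -= params["cl_cen"] / params["v_cen"]
    for per_number, idx in enumerate(per_indices, start=1):
        q = params[f"q_per{per_number}"]
        v = params[f"v_per{per_number}"]
        A[cen_index, cen_index] -= q / params["v_cen"]
        A[idx, cen_index] += q / params["v_cen"]
        A[cen_index, idx] += q / v
        A[idx, idx] -= q / v
    if depot_index is not None:
        A[depot_index, depot_index] -= params["ka"]
        A[cen_index, depot_index] += params["ka"]
    return PlasmaMatrices(
        A=A, state_names=tuple(names), cen_index=cen_index,
        depot_index=depot_index, params=params,
    )


def dose_schedule(
    spec: PlasmaModelSpec, doses: Iterable[DoseEvent], matrices: PlasmaMatrices
) -> tuple[list[tuple[float, np.ndarray]], list[tuple[float, float, np.ndarray]]]:
    """Split doses into (time, state-jump) boluses and (t0, t1, rate) infusions."""
    n = len(matrices.state_names)
    boluses: list[tuple[float, np.ndarray]] = []
    infusions: list[tuple[float, float, np.ndarray]] = []
    for dose in doses:
        if dose.route == "first-order-absorption":
            if matrices.depot_index is None:
                raise PlasmaValidationError(
                    f"{spec.name}: absorption dose given but the spec has no "
                    "absorption rate constant (ka)"
                )
            jump = np.zeros(n)
            jump[matrices.depot_index] = dose.amount * spec.bioavailability
            boluses.append((dose.start, jump))
        elif dose.route == "iv-bolus":
            jump = np.zeros(n)
            jump[matrices.cen_index] = dose.amount
            boluses.append((dose.start, jump))
        else:  # iv-infusion
            rate = np.zeros(n)
            rate[matrices.cen_index] = dose.amount / dose.duration
            infusions.append((dose.start, dose.start + dose.duration, rate))
    return boluses, infusions


class _Propagator:
    """Caches exp([[A, u], [0, 0]] * h) per (h, input vector)."""

    def __init__(self, A: np.ndarray):
        self.A = A
        self.n = A.shape[0]
        self._cache: dict[tuple, np.ndarray] = {}

    def step(self, x: np.ndarray, u: np.ndarray, h: float) -> np.ndarray:
        if h == 0.0:
            return x
        key = (round(h, 12), u.tobytes())
        P = self._cache.get(key)
        if P is None:
            M = np.zeros((self.n + 1, self.n + 1))
            M[: self.n, : self.n] = self.A
            M[: self.n, self.n] = u
            P = expm(M * h)
            self._cache[key] = P
        return P[: self.n, : self.n] @ x + P[: self.n, self.n]


def _propagate(
    A: np.ndarray,
    boluses: list[tuple[float, np.ndarray]],
    infusions: list[tuple[float, float, np.ndarray]],
    times: np.ndarray,
) -> np.ndarray:
    """Exact states at ``times`` (boluses at time t are included in the value
    reported at t, i.e. the t+ convention)."""
    n = A.shape[0]
    prop = _Propagator(A)
    boundaries = {t for t, _ in boluses}
    for t0, t1, _ in infusions:
        boundaries.update((t0, t1))
    grid = np.unique(np.concatenate([times, np.array(sorted(boundaries), dtype=float)]))
    grid = grid[grid >= 0.0]
    if grid.size == 0 or grid[0] > 0.0:
        grid = np.concatenate([[0.0], grid])

    x = np.zeros(n)
    out = np.zeros((len(times), n))
    want = {t: [] for t in times}
    for i, t in enumerate(times):
        want[t].append(i)

    prev = grid[0]
    for k, t in enumerate(grid):
        if k > 0:
            u = np.zeros(n)
            for t0, t1, rate in infusions:
                if t0 <= prev and t <= t1 + 1e-12:
                    u = u + rate
            x = prop.step(x, u, t - prev)
        for t_b, jump in boluses:
            if t_b == t:
                x = x + jump
        for i in want.get(t, ()):
            out[i] = x
        prev = t
    return out


def simulate_plasma(
    spec: PlasmaModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    eta: Mapping[str, float] | None = None,
) -> PlasmaProfile:
    """Simulate the total and unbound central concentration-time profile."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0) or np.any(times < 0):
        raise PlasmaValidationError("times must be a sorted, non-negative 1-D grid")
    matrices = plasma_matrices(spec, eta)
    boluses, infusions = dose_schedule(spec, doses, matrices)
    states = _propagate(matrices.A, boluses, infusions, times)
    conc = states[:, matrices.cen_index] / matrices.params["v_cen"]
    conc = np.maximum(conc, 0.0)
    return PlasmaProfile(times=times, conc_total=conc, conc_unbound=spec.fu_plasma * conc)


# ---------------------------------------------------------------------------
# variability


@dataclass
class IndividualDraw:
    """One individual's eta vector plus a seeded residual-draw stream.

    ``apply_residual`` maps a prediction array to the observed scale:
    pred * (1 + eps_prop) + eps_add, with fresh draws per element.
    """

    eta: dict[str, float]
    spec: PlasmaModelSpec
    _rng: np.random.Generator

    def apply_residual(self, pred: np.ndarray) -> np.ndarray:
        pred = np.asarray(pred, dtype=float)
        sigma_prop = self.spec.prop_cv_pct / 100.0
        eps_prop = self._rng.normal(0.0, sigma_prop, size=pred.shape) if sigma_prop > 0 else 0.0
        eps_add = self._rng.normal(0.0, self.spec.add_sd, size=pred.shape) if self.spec.add_sd > 0 else 0.0
        return pred * (1.0 + eps_prop) + eps_add


def sample_variability(
    spec: PlasmaModelSpec, n: int, seed: int, omega_transform: str = "cv"
) -> list[IndividualDraw]:
    """Draw ``n`` individuals deterministically from ``seed``.

    eta ~ Normal(0, omega^2) per parameter with nonzero %CV. The %CV -> omega
    transform defaults to omega = CV/100 ("cv"); "lognormal" uses
    omega^2 = ln(1 + CV^2), the exact lognormal-CV relation.
    """
    if n < 1:
        raise PlasmaValidationError(f"n must be >= 1, got {n}")
    if omega_transform not in ("cv", "lognormal"):
        raise PlasmaValidationError("omega_transform must be 'cv' or 'lognormal'")
    children = np.random.SeedSequence(seed).spawn(n)
    draws = []
    for child in children:
        rng = np.random.default_rng(child)
        eta = {}
        for key in sorted(spec.iiv_cv_pct):
            cv = spec.iiv_cv_pct[key] / 100.0
            if cv == 0:
                continue
            omega = cv if omega_transform == "cv" else math.sqrt(math.log1p(cv**2))
            eta[key] = rng.normal(0.0, omega)
        draws.append(IndividualDraw(eta=eta, spec=spec, _rng=rng))
    return draws


# ---------------------------------------------------------------------------
# fixtures


def load_plasma_models(
    source: Union[str, Path, Mapping, None] = None,
) -> dict[str, dict[str, PlasmaModelSpec]]:
    """Load plasma model specs keyed species -> drug name."""
    if source is None:
        text = resources.files("cnspk.data").joinpath("plasma_models.yaml").read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        doc = source
    else:
        with open(source, "r", encoding="utf-8") as handle:
            doc = yaml.safe_load(handle)

    out: dict[str, dict[str, PlasmaModelSpec]] = {}
    for species, drug_map in doc.items():
        out[species] = {}
        for name, entry in drug_map.items():
            out[species][name] = PlasmaModelSpec(
                name=f"{species}:{name}",
                n_compartments=int(entry["n_compartments"]),
                cl_cen=float(entry["cl_cen"]["value"]),
                q_per1=float(entry["q_per1"]["value"]),
                q_per2=float(entry["q_per2"]["value"]),
                v_cen=float(entry["v_cen"]["value"]),
                v_per1=float(entry["v_per1"]["value"]),
                v_per2=float(entry["v_per2"]["value"]),
                ka=float(entry["ka"]["value"]) if "ka" in entry else None,
                bioavailability=float(entry.get("bioavailability", 1.0)),
                iiv_cv_pct=dict(entry.get("iiv_cv_pct", {})),
                prop_cv_pct=float(entry.get("prop_cv_pct", 0.0)),
                add_sd=float(entry.get("add_sd", 0.0)),
            )
    return out
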