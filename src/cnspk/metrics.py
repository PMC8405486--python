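"""Model-evaluation statistics and replicate-simulation (VPC) machinery.

Conventions: observed data are tidy records (drug, species, individual,
compartment, time_min, conc) with strictly positive concentrations
(log-scale metrics). Median predictions are matched to observations
exactly at observed times (no interpolation). The 95% prediction interval
uses empirical 2.5/97.5 percentiles with the linear-interpolation
percentile definition.

RA_drug  = mean over a drug's observations of log10(MedP/Obs)
ARA_drug = mean of |log10(MedP/Obs)|
%AFE  = 100 * 10^(mean over drugs of RA_drug)
%AAFE = 100 * 10^(mean over drugs of |RA_drug|)
%MARA = 100 * 10^(mean over drugs of ARA_drug)
SMAPE = (100/M) * sum |2 (Obs - MedP) / (Obs + MedP)|, bounded by 200%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plasma_pk import PlasmaModelSpec, sample_variability

__all__ = [
    "OBSERVED_COLUMNS",
    "ObservedDataset",
    "EvaluationReport",
    "MetricsError",
    "VpcResult",
    "vpc",
    "relative_accuracy",
    "fold_errors",
    "smape",
    "evaluate",
]

OBSERVED_COLUMNS = ("drug", "species", "individual", "compartment", "time_min", "conc")
_MATCH_KEYS = ["drug", "compartment", "time_min"]


class MetricsError(ValueError):
    """Raised on malformed observed data or unmatched predictions."""


@dataclass(frozen=True)
class ObservedDataset:
    """Validated observed concentration records."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(OBSERVED_COLUMNS) - set(self.frame.columns)
        if missing:
            raise MetricsError(f"observed data missing columns: {sorted(missing)}")
        bad = self.frame[~(self.frame["conc"] > 0)]
        if len(bad):
            row = bad.iloc[0]
            raise MetricsError(
                "observed concentrations must be strictly positive; first offending "
                f"record: drug={row['drug']} individual={row['individual']} "
                f"compartment={row['compartment']} time={row['time_min']} conc={row['conc']}"
            )

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    @property
    def n_individuals(self) -> int:
        return self.frame.groupby(["drug", "individual"]).ngroups

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["drug"].unique()))


@dataclass(frozen=True)
class VpcResult:
    """Replicate-simulation percentile bands plus the matched-median lookup."""

    times: np.ndarray
    compartments: tuple[str, ...]
    lower: Mapping[str, np.ndarray]  # 2.5th percentile per compartment
    median: Mapping[str, np.ndarray]
    upper: Mapping[str, np.ndarray]  # 97.5th percentile
    n_reps: int
    seed: int

    def med_pred(self, compartment: str, time_min: float) -> float:
        """Time-matched median prediction; the time must be on the VPC grid."""
        matches = np.flatnonzero(np.isclose(self.times, time_min, rtol=0, atol=1e-9))
        if matches.size == 0:
            raise MetricsError(
                f"no simulation time matches observation time {time_min} "
                f"(compartment {compartment}); VPC grid must include observed times"
            )
        return float(self.median[compartment][matches[0]])

    def med_pred_frame(self, drug: str) -> pd.DataFrame:
        rows = []
        for comp in self.compartments:
            for t, v in zip(self.times, self.median[comp]):
                rows.append({"drug": drug, "compartment": comp, "time_min": t, "med_pred": v})
        return pd.DataFrame(rows)


def vpc(
    predict: Callable[[Mapping[str, float]], Mapping[str, np.ndarray]],
    plasma_spec: PlasmaModelSpec,
    times: Sequence[float],
    n_reps: int = 200,
    seed: int = 0,
    interval: float = 95.0,
) -> VpcResult:
    """Replicate simulations with sampled inter-individual (eta) and residual
    (eps) variability; returns empirical median and prediction-interval bands.

    ``predict(eta)`` must return compartment -> concentration array aligned
    with ``times``. Deterministic given ``seed``.
    """
    if n_reps < 2:
        raise MetricsError(f"n_reps must be >= 2, got {n_reps}")
    times = np.asarray(times, dtype=float)
    draws = sample_variability(plasma_spec, n_reps, seed)
    stacks: dict[str, list[np.ndarray]] = {}
    for draw in draws:
        profile = predict(draw.eta)
        for comp, conc in profile.items():
            conc = np.asarray(conc, dtype=float)
            if conc.shape != times.shape:
                raise MetricsError(f"prediction for {comp} does not align with the time grid")
            stacks.setdefault(comp, []).append(draw.apply_residual(conc))
    lo_q, hi_q = (100.0 - interval) / 2.0, 100.0 - (100.0 - interval) / 2.0
    lower, median, upper = {}, {}, {}
    for comp, reps in stacks.items():
        arr = np.vstack(reps)
        lower[comp] = np.percentile(arr, lo_q, axis=0)
        median[comp] = np.percentile(arr, 50.0, axis=0)
        upper[comp] = np.percentile(arr, hi_q, axis=0)
    return VpcResult(
        times=times, compartments=tuple(stacks), lower=lower, median=median,
        upper=upper, n_reps=n_reps, seed=seed,
    )


def _matched(observed: ObservedDataset, med_pred: pd.DataFrame) -> pd.DataFrame:
    if not set(_MATCH_KEYS + ["med_pred"]).issubset(med_pred.columns):
        raise MetricsError(f"med_pred frame needs columns {_MATCH_KEYS + ['med_pred']}")
    merged = observed.frame.merge(med_pred, on=_MATCH_KEYS, how="left", validate="m:1")
    unmatched = merged[merged["med_pred"].isna()]
    if len(unmatched):
        row = unmatched.iloc[0]
        raise MetricsError(
            "observation without a time-matched median prediction: "
            f"drug={row['drug']} compartment={row['compartment']} time={row['time_min']}"
        )
    bad = merged[~(merged["med_pred"] > 0)]
    if len(bad):
        row = bad.iloc[0]
        raise MetricsError(
            "median prediction must be strictly positive for log metrics: "
            f"drug={row['drug']} compartment={row['compartment']} time={row['time_min']} "
            f"med_pred={row['med_pred']}"
        )
    return merged


def relative_accuracy(observed: ObservedDataset, med_pred: pd.DataFrame) -> pd.DataFrame:
    """Per (drug, compartment): RA (mean log10 MedP/Obs), ARA (mean absolute
    log10 ratio), and the per-drug observation count M."""
    merged = _matched(observed, med_pred)
    merged["log_ratio"] = np.log10(merged["med_pred"] / merged["conc"])
    grouped = merged.groupby(["drug", "compartment"], sort=True)
    out = grouped["log_ratio"].agg(ra="mean", ara=lambda s: s.abs().mean(), m="size")
    return out.reset_index()


def fold_errors(ra_table: pd.DataFrame) -> pd.DataFrame:
    """Per compartment across drugs: %AFE, %AAFE, %MARA (drugs weighted
    equally), plus the drug count D."""
    if len(ra_table) == 0:
        raise MetricsError("fold_errors requires at least one drug")
    grouped = ra_table.groupby("compartment", sort=True)
    rows = []
    for comp, sub in grouped:
        afe = sub["ra"].mean()
        aafe = sub["ra"].abs().mean()
        mara = sub["ara"].mean()
        rows.append(
            {
                "compartment": comp,
                "pct_afe": 100.0 * 10.0**afe,
                "pct_aafe": 100.0 * 10.0**aafe,
                "pct_mara": 100.0 * 10.0**mara,
                "n_drugs": len(sub),
            }
        )
    return pd.DataFrame(rows)


def smape(observed: ObservedDataset, med_pred: pd.DataFrame) -> pd.DataFrame:
    """Symmetric mean absolute percentage error per compartment (pooled over
    drugs); each record contributes |2 (Obs - MedP) / (Obs + MedP)|."""
    merged = _matched(observed, med_pred)
    merged["sape"] = np.abs(
        2.0 * (merged["conc"] - merged["med_pred"]) / (merged["conc"] + merged["med_pred"])
    )
    out = merged.groupby("compartment", sort=True)["sape"].agg(["mean", "size"]).reset_index()
    out["smape_pct"] = 100.0 * out["mean"]
    return out[["compartment", "smape_pct", "size"]].rename(columns={"size": "n_obs"})


@dataclass(frozen=True)
class EvaluationReport:
    """Per-drug relative accuracies and per-compartment summary statistics."""

    ra_table: pd.DataFrame  # drug, compartment, ra, ara, m
    summary: pd.DataFrame  # compartment, pct_afe, pct_aafe, pct_mara, smape_pct

    def to_csv(self, ra_path, summary_path) -> None:
        self.ra_table.to_csv(ra_path, index=False)
        self.summary.to_csv(summary_path, index=False)


def evaluate(observed: ObservedDataset, med_pred: pd.DataFrame) -> EvaluationReport:
    """Full evaluation: RA/ARA per drug and %AFE/%AAFE/%MARA/SMAPE per
    compartment."""
    ra_table = relative_accuracy(observed, med_pred)
    summary = fold_errors(ra_table).merge(smape(observed, med_pred), on="compartment")
    return EvaluationReport(ra_table=ra_table, summary=summary)
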