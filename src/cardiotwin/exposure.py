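"""Translation of plasma / heart-tissue concentrations into free cardiac
concentrations, the driving force of the electrophysiology stage.

Two routes are provided and agree at distribution equilibrium:

* observed plasma  -> C_free = C_plasma x Kp_ht x fu_ht  (partition rule);
* simulated heart  -> C_free = C_heart,total x fu_ht     (tissue binding on
  the simulated tissue total — more faithful during non-equilibrium
  overdose kinetics).

Three overdose-case methodologies are implemented: observed-plasma (with
metabolite imputation at half the parent level when unmeasured), simulation
selected at the parent plasma maximum within the reported ECG window, and
simulation from the estimated dose alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .params import CaseRecord, CompoundParams, DoseEvent, IndividualParams
from .pbpk import ConcentrationSeries, PbpkModel

Provenance = Literal["from_plasma_eq5", "from_simulated_heart"]


@dataclass
class CardiacExposure:
    """Free cardiac concentrations per analyte, ng/mL (uM derived via MW)."""

    times: np.ndarray
    free_ngml: dict[str, np.ndarray]
    mw: dict[str, float]
    provenance: Provenance
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        for k, v in self.free_ngml.items():
            v = np.atleast_1d(np.asarray(v, dtype=float))
            if np.any(v < 0):
                raise ValueError(f"negative free concentration for {k}")
            self.free_ngml[k] = v

    @property
    def free_uM(self) -> dict[str, np.ndarray]:
        return {k: v / self.mw[k] for k, v in self.free_ngml.items()}

    def at_time(self, t: float) -> dict[str, float]:
        """Linear interpolation of free concentration (uM) at time t."""
        return {k: float(np.interp(t, self.times, v)) for k, v in self.free_uM.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for analyte, arr in self.free_ngml.items():
            rows.append(pd.DataFrame({
                "time_h": self.times,
                "analyte": analyte,
                "free_cardiac_ng_per_mL": arr,
                "free_cardiac_uM": arr / self.mw[analyte],
                "provenance": self.provenance,
            }))
        return pd.concat(rows, ignore_index=True)


def free_cardiac_from_plasma(c_plasma_ngml, compound: CompoundParams):
    """Partition rule: free cardiac = total plasma x Kp_ht x fu_ht."""
    c = np.asarray(c_plasma_ngml, dtype=float)
    if np.any(c < 0):
        raise ValueError("plasma concentration must be non-negative")
    out = c * compound.Kp_ht * compound.fu_ht
    return float(out) if out.ndim == 0 else out


def impute_nt_plasma(c_at_plasma_ngml: float) -> float:
    """Half-the-parent rule, used only when the metabolite level is missing."""
    if c_at_plasma_ngml < 0:
        raise ValueError("plasma concentration must be non-negative")
    return 0.5 * c_at_plasma_ngml


def free_cardiac_from_simulation(series: ConcentrationSeries,
                                 compounds: Sequence[CompoundParams]) -> CardiacExposure:
    """Free cardiac = simulated heart-tissue total x fu_ht, per analyte."""
    free, mw = {}, {}
    for c in compounds:
        if c.name not in series.data or "heart" not in series.data[c.name]:
            raise ValueError(f"series lacks a heart channel for {c.name}")
        free[c.name] = series.data[c.name]["heart"] * c.fu_ht
        mw[c.name] = c.MW
    return CardiacExposure(times=series.times, free_ngml=free, mw=mw,
                           provenance="from_simulated_heart",
                           metadata=dict(series.metadata))


CaseMode = Literal["observed_plasma", "simulated_full", "simulated_dose_only"]


def _simulated_case_exposure(case: CaseRecord, model: PbpkModel,
                             twin: Optional[IndividualParams],
                             t_end_h: float) -> tuple[ConcentrationSeries, CardiacExposure]:
    if case.estimated_dose_mg is None:
        raise ValueError("case lacks an estimated dose; fields missing: [estimated_dose_mg]")
    t_grid = np.linspace(0.05, t_end_h, 400)
    regimen = [DoseEvent(time=0.0, dose_po=case.estimated_dose_mg)]
    x0 = None
    if case.prior_AT_treatment:
        # prior chronic therapy: toxic ingestion starts from steady state of a
        # standard 75 mg q.d. maintenance regimen
        maint = [DoseEvent(time=0.0, dose_po=75.0)]
        x0, _ = model.simulate_to_steady_state(maint, 24.0, individual=twin)
    series = model.simulate(regimen, t_grid, individual=twin, method="expm", x0=x0,
                            metadata={"case_id": case.id})
    exposure = free_cardiac_from_simulation(series, [model.parent, model.metabolite])
    return series, exposure


def exposure_for_case_group(case: CaseRecord,
                            mode: CaseMode,
                            model: Optional[PbpkModel] = None,
                            twin: Optional[IndividualParams] = None,
                            t_end_h: float = 24.0) -> CardiacExposure:
    """Dispatch the three overdose-case methodologies.

    * ``observed_plasma``: partition rule on the reported plasma levels, with
      the metabolite imputed at half the parent level when unmeasured;
    * ``simulated_full``: PBPK run from the estimated dose; exposure taken at
      the simulated parent plasma maximum within the reported ECG window;
    * ``simulated_dose_only``: PBPK run from the estimated dose; exposure at
      the parent plasma maximum (ECG window if reported, else global).
    """
    if mode == "observed_plasma":
        if case.at_plasma_ngml is None:
            raise ValueError("mode observed_plasma: fields missing: [at_plasma_ngml]")
        if model is None:
            from .pbpk import PbpkModel as _M
            model = _M.default()
        at, nt = model.parent, model.metabolite
        c_at = case.at_plasma_ngml
        c_nt = case.nt_plasma_ngml if case.nt_plasma_ngml is not None else impute_nt_plasma(c_at)
        t = case.measurement_window_h[0] if case.measurement_window_h else 0.0
        return CardiacExposure(
            times=np.array([t]),
            free_ngml={at.name: np.array([free_cardiac_from_plasma(c_at, at)]),
                       nt.name: np.array([free_cardiac_from_plasma(c_nt, nt)])},
            mw={at.name: at.MW, nt.name: nt.MW},
            provenance="from_plasma_eq5",
            metadata={"case_id": case.id, "nt_imputed": case.nt_plasma_ngml is None},
        )

    if mode not in ("simulated_full", "simulated_dose_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if model is None:
        raise ValueError(f"mode {mode}: a PBPK model is required")
    if mode == "simulated_full" and case.at_plasma_ngml is None:
        raise ValueError("mode simulated_full: fields missing: [at_plasma_ngml]")
    series, exposure = _simulated_case_exposure(case, model, twin, t_end_h)

    window = case.ecg_window_h
    at_plasma = series[model.parent.name, "plasma"]
    if window is not None:
        sel = (series.times >= window[0]) & (series.times <= window[1])
        if not np.any(sel):
            raise ValueError(f"ECG window {window} outside simulated grid")
        k = np.flatnonzero(sel)[int(np.argmax(at_plasma[sel]))]
    else:
        k = int(np.argmax(at_plasma))
    t_sel = float(series.times[k])
    return CardiacExposure(
        times=np.array([t_sel]),
        free_ngml={a: np.array([exposure.free_ngml[a][k]]) for a in exposure.free_ngml},
        mw=exposure.mw,
        provenance="from_simulated_heart",
        metadata={"case_id": case.id, "mode": mode, "selection_time_h": t_sel},
    )
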