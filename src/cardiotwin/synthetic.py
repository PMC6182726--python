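"""Synthetic inputs for every pipeline stage.

No clinical dataset ships with this package (the concentration-time and
RR-concentration data the original analysis used were digitized from
published plots and are not redistributable), so each consumer is exercised
on generated data with the statistical structure the analysis assumes:

* virtual clinical trials: population-mean plasma profiles of parent and
  metabolite after oral dosing, with proportional + additive measurement
  noise (defaults: 10% CV, 0.5 ng/mL floor);
* Emax datasets: log-spaced concentrations with RR values from the
  decreasing sigmoid plus Gaussian noise;
* overdose case records for the three case-group methodologies.

Every generator returns a "truth sidecar" so recovery experiments are
self-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .emax import FITTED_EMAX, rr_from_concentration
from .params import AbsorptionParams, CaseRecord, DoseEvent, EmaxParams
from .pbpk import PbpkModel


class TrialSpec(BaseModel):
    """One simulated clinical trial arm."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    dose_mg: float = Field(gt=0)
    n_doses: int = Field(default=1, ge=1)
    dose_interval_h: float = Field(default=24.0, gt=0)
    sampling_times_h: tuple[float, ...] = (1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10, 12, 16, 24, 36, 48)
    noise_cv: float = Field(default=0.10, ge=0)
    noise_floor_ngml: float = Field(default=0.5, ge=0)
    seed: int = 0

    @property
    def regimen(self) -> list[DoseEvent]:
        return [DoseEvent(time=i * self.dose_interval_h, dose_po=self.dose_mg)
                for i in range(self.n_doses)]

    def model_post_init(self, __context) -> None:
        t = np.asarray(self.sampling_times_h)
        if np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("sampling times must be positive and increasing")


def generate_trial(spec: TrialSpec, model: PbpkModel,
                   truth: Optional[AbsorptionParams] = None) -> tuple[pd.DataFrame, dict]:
    """Simulate the population-mean profiles at the truth absorption
    parameters and apply the measurement-noise model.

    Returns (observations, truth sidecar); observation columns follow the
    fitting dialect: study_id, time_h, analyte, concentration_ng_per_mL.
    """
    ab = truth or model.absorption
    times = np.asarray(spec.sampling_times_h, dtype=float)
    system = model.system(ab)
    from .pbpk import simulate
    series = simulate(system, spec.regimen, times, method="expm", keep_states=False)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for analyte in (model.parent.name, model.metabolite.name):
        clean = series[analyte, "plasma"]
        noisy = clean * (1.0 + spec.noise_cv * rng.standard_normal(clean.size))
        if spec.noise_floor_ngml > 0:
            noisy = noisy + spec.noise_floor_ngml * rng.standard_normal(clean.size)
        rows.append(pd.DataFrame({
            "study_id": spec.study_id, "time_h": times, "analyte": analyte,
            "concentration_ng_per_mL": np.maximum(noisy, 0.0),
        }))
    obs = pd.concat(rows, ignore_index=True)
    truth_sidecar = {
        "ka": ab.ka, "t_lag": ab.t_lag, "F": ab.F, "fa_Fg": ab.fa_Fg,
        "study_id": spec.study_id, "dose_mg": spec.dose_mg, "seed": spec.seed,
        "noise_cv": spec.noise_cv, "noise_floor_ngml": spec.noise_floor_ngml,
    }
    return obs, truth_sidecar


def generate_fitting_dataset(model: PbpkModel,
                             doses_mg: Sequence[float] = (25.0, 50.0, 75.0),
                             truth: Optional[AbsorptionParams] = None,
                             noise_cv: float = 0.10,
                             noise_floor_ngml: float = 0.5,
                             seed: int = 0) -> tuple[pd.DataFrame, dict, dict]:
    """Three-trial fitting problem: one single-dose arm per dose level.

    Returns (observations, regimens, truth sidecar).
    """
    frames, regimens = [], {}
    sidecar = {}
    for i, dose in enumerate(doses_mg):
        spec = TrialSpec(study_id=f"trial{i + 1}", dose_mg=dose,
                         noise_cv=noise_cv, noise_floor_ngml=noise_floor_ngml,
                         seed=seed * 1000 + i)
        obs, sc = generate_trial(spec, model, truth)
        frames.append(obs)
        regimens[spec.study_id] = spec.regimen
        sidecar = sc
    sidecar.pop("study_id", None)
    sidecar.pop("dose_mg", None)
    sidecar["doses_mg"] = list(doses_mg)
    return pd.concat(frames, ignore_index=True), regimens, sidecar


def generate_emax_dataset(truth: EmaxParams = FITTED_EMAX,
                          n_points: int = 40,
                          conc_range_uM: tuple[float, float] = (0.01, 10.0),
                          noise_sd_ms: float = 120.98,
                          seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Log-spaced concentrations, corrected-form RR plus Gaussian noise."""
    if n_points < 8:
        raise ValueError("need at least 8 points")
    rng = np.random.default_rng(seed)
    conc = np.logspace(np.log10(conc_range_uM[0]), np.log10(conc_range_uM[1]), n_points)
    rr = rr_from_concentration(conc, truth) + noise_sd_ms * rng.standard_normal(n_points)
    df = pd.DataFrame({"conc_uM": conc, "rr_ms": rr})
    sidecar = {**truth.model_dump(), "noise_sd_ms": noise_sd_ms, "seed": seed,
               "n_points": n_points}
    return df, sidecar


CaseGroup = Literal["group1", "group2", "group3"]

# synthetic overdose concentration range straddles the Emax EC50
# (~30 ng/mL = 0.11 uM up to ~1000 ng/mL = 3.6 uM)
_CASE_PLASMA_RANGE_NGML = (30.0, 1000.0)
_CASE_DOSE_RANGE_MG = (500.0, 3000.0)


def generate_case(template: CaseGroup, seed: int = 0) -> CaseRecord:
    """A record with exactly the fields each case-group methodology needs.

    group1: plasma levels only (no dose); group2: dose + plasma + ECG
    window; group3: dose only.
    """
    rng = np.random.default_rng(seed)
    age = float(rng.uniform(18, 80))
    sex = "F" if rng.random() < 0.5 else "M"
    rr = float(rng.uniform(350, 900))  # overdose tachycardia range
    plasma = float(np.exp(rng.uniform(*np.log(_CASE_PLASMA_RANGE_NGML))))
    dose = float(rng.uniform(*_CASE_DOSE_RANGE_MG))
    common = dict(age=age, sex=sex, RR_ms=rr,
                  prior_AT_treatment=bool(rng.random() < 0.3))
    if template == "group1":
        with_nt = rng.random() < 0.5
        return CaseRecord(id=f"g1-{seed}",
                          at_plasma_ngml=plasma,
                          nt_plasma_ngml=0.6 * plasma if with_nt else None,
                          measurement_window_h=(2.0, 4.0), **common)
    if template == "group2":
        return CaseRecord(id=f"g2-{seed}", estimated_dose_mg=dose,
                          at_plasma_ngml=plasma,
                          measurement_window_h=(2.0, 4.0),
                          ecg_window_h=(2.0, 6.0), **common)
    if template == "group3":
        # no plasma level and no recorded RR: the heart rate must come from
        # the Emax stage downstream
        return CaseRecord(id=f"g3-{seed}", estimated_dose_mg=dose, age=age,
                          sex=sex, prior_AT_treatment=common["prior_AT_treatment"])
    raise ValueError(f"unknown template {template!r}")
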