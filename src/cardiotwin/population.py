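"""Virtual individuals and virtual twins.

Absorption-parameter variability:

* F ~ Normal(0.459, 0.093) truncated to [0.33, 0.62] (rejection sampling);
* fa*Fg ~ lognormal with arithmetic mean 0.832 and arithmetic CV 0.131,
  untruncated (values > 1 are allowed — enterohepatic recirculation);
* t_lag ~ lognormal with arithmetic mean t_lag_mean and CV 0.30, drawn once
  per individual and reused across all of that individual's doses.

Pairs with F > fa*Fg (hepatic escape fraction above 1) are jointly rejected
and resampled; the resample count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .params import AbsorptionParams, CaseRecord, IndividualParams

F_MEAN, F_SD, F_LO, F_HI = 0.459, 0.093, 0.33, 0.62
FAFG_MEAN, FAFG_CV = 0.832, 0.131
TLAG_MEAN_DEFAULT, TLAG_CV = 1.33, 0.30
KA_DEFAULT = 0.24

# normal-physiology ion defaults used when a record does not report them
# (extracellular set of the cardiomyocyte model)
NORMAL_IONS_MM = {"K": 4.2, "Na": 140.0, "Ca": 2.4}

_REJECTION_CAP = 10**6


def _lognormal_from_mean_cv(mean: float, cv: float, rng: np.random.Generator,
                            size=None) -> np.ndarray | float:
    """Draw lognormal variates moment-matched to an arithmetic mean and CV."""
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = np.log(mean) - 0.5 * sigma * sigma
    return rng.lognormal(mu, sigma, size)


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for given arithmetic mean/CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.log(mean) - 0.5 * sigma * sigma, sigma


def sample_F(rng: np.random.Generator, size=None,
             mean: float = F_MEAN, sd: float = F_SD,
             lo: float = F_LO, hi: float = F_HI) -> np.ndarray | float:
    """Truncated-normal bioavailability by rejection."""
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    out = np.empty(n)
    filled = 0
    draws = 0
    cap = max(_REJECTION_CAP, 20 * n)
    while filled < n:
        m = max(n - filled, 16)
        x = rng.normal(mean, sd, m)
        x = x[(x >= lo) & (x <= hi)]
        take = min(x.size, n - filled)
        out[filled:filled + take] = x[:take]
        filled += take
        draws += m
        if draws > cap:
            raise RuntimeError("rejection sampling failed to terminate")
    return float(out[0]) if scalar else out.reshape(size)


def sample_faFg(rng: np.random.Generator, size=None,
                mean: float = FAFG_MEAN, cv: float = FAFG_CV,
                interpret: Literal["arithmetic_cv", "log_sigma"] = "arithmetic_cv"
                ) -> np.ndarray | float:
    """Untruncated lognormal gut availability.

    ``interpret`` selects how the stated CV is read: as the arithmetic CV of
    the variate (default, moment-matched) or directly as the sigma of the
    underlying log-scale normal.
    """
    if interpret == "arithmetic_cv":
        x = _lognormal_from_mean_cv(mean, cv, rng, size)
    elif interpret == "log_sigma":
        x = mean if cv == 0 else rng.lognormal(np.log(mean) - 0.5 * cv * cv, cv, size)
    else:
        raise ValueError(f"unknown interpretation {interpret!r}")
    return float(x) if size is None else x


def sample_tlag(mean_tlag: float, rng: np.random.Generator, size=None,
                cv: float = TLAG_CV,
                family: Literal["lognormal", "truncnormal"] = "lognormal") -> np.ndarray | float:
    """One lag-time draw per individual (constant across that subject's doses)."""
    if mean_tlag <= 0:
        raise ValueError("mean_tlag must be positive")
    if family == "lognormal":
        x = _lognormal_from_mean_cv(mean_tlag, cv, rng, size)
        return float(x) if size is None else x
    # truncated-normal alternative (positivity enforced by rejection)
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    out = np.empty(n)
    filled = 0
    while filled < n:
        x = rng.normal(mean_tlag, cv * mean_tlag, max(n - filled, 16))
        x = x[x > 0]
        take = min(x.size, n - filled)
        out[filled:filled + take] = x[:take]
        filled += take
    return float(out[0]) if scalar else out.reshape(size)


@dataclass
class Population:
    individuals: list[IndividualParams]
    resample_count: int = 0
    seed: Optional[int] = None
    summary: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            rows.append({
                "id": ind.id, "age": ind.age, "sex": ind.sex,
                "body_weight": ind.body_weight,
                "ka": ind.absorption.ka, "t_lag": ind.absorption.t_lag,
                "F": ind.absorption.F, "fa_Fg": ind.absorption.fa_Fg,
                "Fh": ind.absorption.Fh,
                "RR_baseline_ms": ind.RR_baseline_ms,
                "K_mM": ind.K_mM, "Na_mM": ind.Na_mM, "Ca_mM": ind.Ca_mM,
                "prior_AT_treatment": ind.prior_AT_treatment,
            })
        return pd.DataFrame(rows)


def _sample_absorption(rng: np.random.Generator, ka: float, mean_tlag: float,
                       sd_F: float = F_SD,
                       cv_faFg: float = FAFG_CV,
                       cv_tlag: float = TLAG_CV) -> tuple[AbsorptionParams, int]:
    """Jointly valid (F, fa_Fg, t_lag) draw; returns (params, rejections)."""
    rejections = 0
    for _ in range(10000):
        F = F_MEAN if sd_F == 0 else sample_F(rng, sd=sd_F)
        faFg = FAFG_MEAN if cv_faFg == 0 else sample_faFg(rng, cv=cv_faFg)
        if F <= faFg:
            tlag = sample_tlag(mean_tlag, rng, cv=cv_tlag) if cv_tlag > 0 else mean_tlag
            return AbsorptionParams(ka=ka, t_lag=tlag, F=F, fa_Fg=faFg), rejections
        rejections += 1
    raise RuntimeError("could not draw a pair with F <= fa*Fg")


def make_population(n: int, rng_seed: int = 1111,
                    ka: float = KA_DEFAULT, mean_tlag: float = TLAG_MEAN_DEFAULT,
                    sd_F: float = F_SD, cv_faFg: float = FAFG_CV,
                    cv_tlag: float = TLAG_CV,
                    age_range: tuple[float, float] = (18.0, 65.0),
                    weight_range: tuple[float, float] = (55.0, 95.0)) -> Population:
    """Sample ``n`` virtual individuals, deterministic for a given seed.

    ``sd_F=0`` / ``cv_faFg=0`` / ``cv_tlag=0`` collapse the respective
    distribution to its mean (the "mean individual" configuration).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if age_range[0] >= age_range[1] or weight_range[0] >= weight_range[1]:
        raise ValueError("invalid demographics config")
    rng = np.random.default_rng(rng_seed)
    individuals, total_rej = [], 0
    for i in range(n):
        absorption, rej = _sample_absorption(rng, ka, mean_tlag, sd_F, cv_faFg, cv_tlag)
        total_rej += rej
        individuals.append(IndividualParams(
            id=f"virt{i:04d}",
            age=float(rng.uniform(*age_range)),
            sex="F" if rng.random() < 0.5 else "M",
            body_weight=float(rng.uniform(*weight_range)),
            absorption=absorption,
        ))
    pop = Population(individuals=individuals, resample_count=total_rej, seed=rng_seed)
    df = pop.to_frame()
    pop.summary = {c: (float(df[c].mean()), float(df[c].std()))
                   for c in ("F", "fa_Fg", "t_lag")}
    return pop


def make_virtual_twin(case: CaseRecord, rng: np.random.Generator,
                      ka: float = KA_DEFAULT,
                      mean_tlag: float = TLAG_MEAN_DEFAULT) -> IndividualParams:
    """Fix the twin's known covariates to the case record; sample the rest.

    Ions missing from the record default to normal physiology.
    """
    absorption, _ = _sample_absorption(rng, ka, mean_tlag)
    return IndividualParams(
        id=f"twin-{case.id}",
        age=case.age,
        sex=case.sex,
        absorption=absorption,
        RR_baseline_ms=case.RR_ms,
        K_mM=case.K_mM if case.K_mM is not None else NORMAL_IONS_MM["K"],
        Na_mM=case.Na_mM if case.Na_mM is not None else NORMAL_IONS_MM["Na"],
        Ca_mM=case.Ca_mM if case.Ca_mM is not None else NORMAL_IONS_MM["Ca"],
        prior_AT_treatment=case.prior_AT_treatment,
    )
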