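"""Domain parameter types shared across the pipeline.

All models are pydantic models so that YAML/JSON configs are validated on
load.  Unit conventions used throughout the package:

* amounts in mg, volumes in L, flows and clearances in L/h, time in hours
  (PBPK side); membrane-model time in ms (cardiomyocyte side);
* concentrations at the I/O boundary in ng/mL (== ug/L); molar
  concentrations in uM, with uM = (ng/mL) / MW[g/mol].
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


def ngml_to_uM(c_ngml: float, mw: float) -> float:
    """Convert ng/mL (== ug/L) to uM using the compound's molecular weight."""
    return c_ngml / mw


def uM_to_ngml(c_uM: float, mw: float) -> float:
    return c_uM * mw


class CompoundParams(BaseModel):
    """Physicochemical and disposition constants for one analyte.

    The parent drug carries a full tissue ``Kp_map``; the metabolite carries
    the minimal-PBPK leg instead (``Kp_re`` plus central volume ``V_central``,
    rest volume ``V_re`` and distribution flow ``Q_re``).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    MW: float = Field(gt=0, description="molecular weight, g/mol")
    Kp_ht: float = Field(gt=0, description="heart tissue:plasma partition coefficient")
    fu_ht: float = Field(gt=0, le=1, description="unbound fraction in heart tissue")
    BP: float = Field(default=1.0, gt=0, description="blood:plasma ratio")
    CL_int_h: float = Field(default=0.0, ge=0, description="hepatic intrinsic clearance, L/h")
    CL_other: float = Field(default=0.0, ge=0, description="additional systemic clearance, L/h")
    fm_metabolite: float = Field(
        default=0.0, ge=0, le=1,
        description="fraction of hepatic clearance converted to the metabolite (parent only)",
    )
    Kp_map: Optional[dict[str, float]] = Field(
        default=None, description="tissue -> Kp table for the full-PBPK leg (parent)")
    Kp_re: Optional[float] = Field(
        default=None, gt=0, description='single "rest"-compartment Kp (metabolite leg)')
    V_central: Optional[float] = Field(
        default=None, gt=0, description="metabolite central volume, L")
    V_re: Optional[float] = Field(
        default=None, gt=0, description='metabolite "rest" volume, L')
    Q_re: Optional[float] = Field(
        default=None, gt=0, description="metabolite central<->rest distribution flow, L/h")

    @model_validator(mode="after")
    def _positive_kps(self) -> "CompoundParams":
        if self.Kp_map is not None:
            bad = {k: v for k, v in self.Kp_map.items() if v <= 0}
            if bad:
                raise ValueError(f"non-positive Kp values: {bad}")
        return self


class AbsorptionParams(BaseModel):
    """First-order oral absorption with lag: ka, t_lag, F and fa*Fg.

    ``fa_Fg`` may exceed 1 (enterohepatic recirculation); the hepatic escape
    fraction Fh = F / fa_Fg must lie in (0, 1] so that first-pass metabolite
    formation is non-negative.
    """

    model_config = ConfigDict(frozen=True)

    ka: float = Field(gt=0, description="first-order absorption rate, 1/h")
    t_lag: float = Field(ge=0, description="absorption lag time, h")
    F: float = Field(gt=0, le=1, description="oral bioavailability")
    fa_Fg: float = Field(gt=0, description="fraction absorbed x gut escape fraction")

    @property
    def Fh(self) -> float:
        """Hepatic escape fraction, F / (fa*Fg)."""
        return self.F / self.fa_Fg

    @model_validator(mode="after")
    def _fh_in_unit_interval(self) -> "AbsorptionParams":
        if self.F > self.fa_Fg:
            raise ValueError(
                f"F={self.F} > fa_Fg={self.fa_Fg} implies Fh > 1 "
                "(negative first-pass metabolite formation)")
        return self


class DoseEvent(BaseModel):
    model_config = ConfigDict(frozen=True)

    time: float = Field(ge=0, description="administration time, h")
    dose_po: float = Field(gt=0, description="oral dose as free base, mg")


class Tissue(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    volume: float = Field(gt=0, description="L")
    flow: float = Field(gt=0, description="blood flow, L/h")


class PhysiologySpec(BaseModel):
    """Compound-independent anatomy/physiology scaffold.

    ``lumped=True`` collapses the parent disposition to a single well-mixed
    central compartment of volume ``V_venous`` (used for closed-form checks
    and minimal configurations); otherwise tissues are perfusion-limited with
    the lung in series between the venous and arterial pools.
    """

    lumped: bool = False
    V_venous: float = Field(gt=0, description="venous blood volume (or lumped central volume), L")
    V_arterial: float = Field(default=1.85, gt=0, description="arterial blood volume, L")
    cardiac_output: float = Field(default=390.0, gt=0, description="L/h")
    tissues: list[Tissue] = Field(default_factory=list)
    age: float = Field(default=35.0, gt=0)
    sex: Literal["M", "F"] = "M"
    body_weight: float = Field(default=70.0, gt=0, description="kg")

    @model_validator(mode="after")
    def _flows_within_cardiac_output(self) -> "PhysiologySpec":
        if not self.lumped:
            names = [t.name for t in self.tissues]
            if len(set(names)) != len(names):
                raise ValueError("duplicate tissue names")
            if "lung" not in names:
                raise ValueError("non-lumped physiology requires a 'lung' tissue")
            q = sum(t.flow for t in self.tissues if t.name != "lung")
            if q > self.cardiac_output * (1 + 1e-9):
                raise ValueError(
                    f"sum of tissue flows {q:.1f} L/h exceeds cardiac output "
                    f"{self.cardiac_output:.1f} L/h")
        return self


class IndividualParams(BaseModel):
    """One virtual subject: demographics plus sampled absorption parameters."""

    id: str = "subject"
    age: float = Field(default=35.0, gt=0)
    sex: Literal["M", "F"] = "M"
    body_weight: float = Field(default=70.0, gt=0)
    absorption: AbsorptionParams
    RR_baseline_ms: Optional[float] = Field(default=None, gt=0)
    K_mM: Optional[float] = Field(default=None, gt=0)
    Na_mM: Optional[float] = Field(default=None, gt=0)
    Ca_mM: Optional[float] = Field(default=None, gt=0)
    prior_AT_treatment: bool = False


class EmaxParams(BaseModel):
    """Concentration--RR sigmoid: baseline RR0, asymptote RRmax, EC50, Hill n.

    RR0 > RRmax encodes tachycardia at high drug concentration.
    """

    model_config = ConfigDict(frozen=True)

    RR0: float = Field(gt=0, description="baseline RR, ms")
    RRmax: float = Field(gt=0, description="maximum-effect RR, ms")
    EC50: float = Field(gt=0, description="uM")
    n: float = Field(gt=0, description="sigmoidicity")

    @model_validator(mode="after")
    def _ordering(self) -> "EmaxParams":
        if not self.RR0 > self.RRmax:
            raise ValueError("RR0 must exceed RRmax (RR shortens with concentration)")
        return self


class CaseRecord(BaseModel):
    """An overdose case: demographics, estimated dose, single-window plasma
    levels, heart rate and ion concentrations — any of which may be missing.
    """

    id: str = "case"
    age: float = Field(gt=0)
    sex: Literal["M", "F"]
    estimated_dose_mg: Optional[float] = Field(default=None, gt=0)
    at_plasma_ngml: Optional[float] = Field(default=None, ge=0)
    nt_plasma_ngml: Optional[float] = Field(default=None, ge=0)
    measurement_window_h: Optional[tuple[float, float]] = None
    ecg_window_h: Optional[tuple[float, float]] = None
    RR_ms: Optional[float] = Field(default=None, gt=0)
    K_mM: Optional[float] = Field(default=None, gt=0)
    Na_mM: Optional[float] = Field(default=None, gt=0)
    Ca_mM: Optional[float] = Field(default=None, gt=0)
    prior_AT_treatment: bool = False

    @model_validator(mode="after")
    def _windows_ordered(self) -> "CaseRecord":
        for w in (self.measurement_window_h, self.ecg_window_h):
            if w is not None and not w[0] < w[1]:
                raise ValueError(f"window {w} must be increasing")
        if self.estimated_dose_mg is None and self.at_plasma_ngml is None:
            raise ValueError("case needs at least an estimated dose or an AT plasma level")
        return self
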