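"""Config loading/validation and the package's file dialects.

CSV dialect: comma-separated, dot decimal, UTF-8, mandatory header row,
units encoded in column names.  Configs are YAML or JSON with a ``schema``
tag; validation errors name the file and field.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import ValidationError

from .myocyte import ChannelBlockSpec
from .params import AbsorptionParams, CaseRecord, CompoundParams, PhysiologySpec

PathLike = Union[str, Path]

OBS_COLUMNS = ("study_id", "time_h", "analyte", "concentration_ng_per_mL")
SERIES_COLUMNS = ("individual_id", "time_h", "analyte", "matrix", "conc_ng_per_mL")


def _data_path(name: str):
    return resources.files("cardiotwin.data").joinpath(name)


def load_yaml_or_json(path: PathLike) -> dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    text = p.read_text()
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _validated(cls, payload: dict, source: str):
    try:
        return cls(**payload)
    except ValidationError as exc:
        errs = "; ".join(f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}"
                         for e in exc.errors())
        raise ValueError(f"{source}: {errs}") from exc


def load_physiology(path: Optional[PathLike] = None) -> PhysiologySpec:
    if path is None:
        payload = yaml.safe_load(_data_path("physiology_default.yaml").read_text())
        source = "physiology_default.yaml"
    else:
        payload = load_yaml_or_json(path)
        source = str(path)
    payload.pop("schema", None)
    return _validated(PhysiologySpec, payload, source)


def load_compounds(path: Optional[PathLike] = None
                   ) -> tuple[CompoundParams, CompoundParams, AbsorptionParams]:
    if path is None:
        payload = yaml.safe_load(_data_path("compounds_default.yaml").read_text())
        source = "compounds_default.yaml"
    else:
        payload = load_yaml_or_json(path)
        source = str(path)
    parent = _validated(CompoundParams, payload["parent"], f"{source}:parent")
    met = _validated(CompoundParams, payload["metabolite"], f"{source}:metabolite")
    absorption = _validated(AbsorptionParams, payload["absorption"], f"{source}:absorption")
    return parent, met, absorption


def load_default_model_configs():
    phys = load_physiology()
    parent, met, absorption = load_compounds()
    return phys, parent, met, absorption


def load_blocks(path: Optional[PathLike] = None) -> ChannelBlockSpec:
    if path is None:
        payload = yaml.safe_load(_data_path("blocks_example.yaml").read_text())
    else:
        payload = load_yaml_or_json(path)
    return ChannelBlockSpec.from_dict(payload)


def load_case(path: PathLike) -> CaseRecord:
    payload = load_yaml_or_json(path)
    payload.pop("schema", None)
    return _validated(CaseRecord, payload, str(path))


def read_observations(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: malformed header, missing columns {sorted(missing)}; "
            f"expected {list(OBS_COLUMNS)}")
    if df.empty:
        raise ValueError(f"{path}: no observation rows")
    if not pd.api.types.is_numeric_dtype(df["time_h"]) or \
       not pd.api.types.is_numeric_dtype(df["concentration_ng_per_mL"]):
        raise ValueError(f"{path}: time_h and concentration_ng_per_mL must be numeric")
    return df


def config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def write_manifest(outdir: PathLike, payload: dict) -> Path:
    """Run manifest: seeds, version, config hash — enough to reproduce."""
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"cardiotwin_version": __version__,
                "config_hash": config_hash(payload), **payload}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
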