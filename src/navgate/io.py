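"""Configuration files, shipped fixtures and result serialization.

Channel and drug parameters live in flat key-value YAML files; results
are written as tidy CSV plus a JSON sidecar carrying the run metadata
(config hash, solver settings, seed) so every output is traceable to the
exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DrugSpec, GateSpec, RateLaw
from .msa import MSAParams
from .protocols import SweepResult

__all__ = [
    "gates_from_dict", "gates_to_dict", "load_channel_params",
    "save_channel_params", "default_channel_params", "load_drug", "save_drug",
    "prototype_drugs", "drug_grid", "default_msa_params",
    "sweep_to_frame", "write_results", "config_hash",
]

_GATE_KEYS = {"act": "activation", "fast": "fast_inactivation",
              "slow": "slow_inactivation"}
# opening of the activation gate saturates on depolarization; recovery
# (opening) of the inactivation gates saturates on hyperpolarization
_SENSES = {
    ("act", "open"): "depolarized", ("act", "close"): "hyperpolarized",
    ("fast", "open"): "hyperpolarized", ("fast", "close"): "depolarized",
    ("slow", "open"): "hyperpolarized", ("slow", "close"): "depolarized",
}


def gates_from_dict(params: dict) -> dict[str, GateSpec]:
    """Build the three gate specs from the 18 flat parameters
    (``A_act_open``, ``Vhalf_act_open``, ``r_act_open``, ...)."""
    gates = {}
    for short, name in _GATE_KEYS.items():
        laws = {}
        for direction in ("open", "close"):
            laws[direction] = RateLaw(
                A=float(params[f"A_{short}_{direction}"]),
                Vhalf=float(params[f"Vhalf_{short}_{direction}"]),
                r=float(params[f"r_{short}_{direction}"]),
                sense=_SENSES[(short, direction)])
        gates[name] = GateSpec(name=name, opening=laws["open"],
                               closing=laws["close"])
    return gates


def gates_to_dict(gates: dict[str, GateSpec]) -> dict:
    out = {}
    for short, name in _GATE_KEYS.items():
        g = gates[name]
        for direction, law in (("open", g.opening), ("close", g.closing)):
            out[f"A_{short}_{direction}"] = float(law.A)
            out[f"Vhalf_{short}_{direction}"] = float(law.Vhalf)
            out[f"r_{short}_{direction}"] = float(law.r)
    return out


def load_channel_params(path: str | Path) -> dict[str, GateSpec]:
    with open(path) as fh:
        return gates_from_dict(yaml.safe_load(fh))


def save_channel_params(gates: dict[str, GateSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(gates_to_dict(gates), fh, sort_keys=True)


def default_channel_params() -> dict[str, GateSpec]:
    """The shipped calibrated 18-parameter set for the gating cube."""
    text = resources.files("navgate.data").joinpath(
        "tetracube_calibrated.yaml").read_text()
    return gates_from_dict(yaml.safe_load(text))


def load_drug(path: str | Path) -> DrugSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return DrugSpec(
        name=d.get("name", Path(path).stem),
        ka=float(d["ka"]), kd=float(d["kd"]),
        CA=float(d.get("CA", 1.0)), CF=float(d.get("CF", 1.0)),
        CS=float(d.get("CS", 1.0)),
        concentration=float(d.get("concentration_uM", 0.0)))


def save_drug(drug: DrugSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({
            "name": drug.name, "ka": drug.ka, "kd": drug.kd,
            "CA": drug.CA, "CF": drug.CF, "CS": drug.CS,
            "concentration_uM": drug.concentration,
        }, fh, sort_keys=False)


# prototypical mechanisms: fast binding ka = 0.5 /s/uM, kd = 100 /s;
# slow binding ka = 0.005 /s/uM, kd = 1 /s; the preferred state's factor
# is 10; applied at 30 uM.  Resting Kd is 200 uM for all four.
_PROTOTYPES = {
    "FI_fb": dict(ka=0.5, kd=100.0, CF=10.0, CS=1.0),
    "FI_sb": dict(ka=0.005, kd=1.0, CF=10.0, CS=1.0),
    "SI_fb": dict(ka=0.5, kd=100.0, CF=1.0, CS=10.0),
    "SI_sb": dict(ka=0.005, kd=1.0, CF=1.0, CS=10.0),
}


def prototype_drugs(concentration: float = 30.0) -> dict[str, DrugSpec]:
    """The four prototypical inhibitor mechanisms."""
    return {name: DrugSpec(name=name, concentration=concentration, **kw)
            for name, kw in _PROTOTYPES.items()}


def drug_grid() -> list[DrugSpec]:
    """The 100-drug parameter grid: 10 kinetics pairs spanning
    ka = 5e-4 .. 15 /s/uM (kd = 0.1 .. 3000 /s, fixed ka/kd = 5e-3 so the
    resting affinity is constant) crossed with factor values 2, 5, 10, 20,
    50 applied as either CF or CS."""
    kas = np.geomspace(5e-4, 15.0, 10)
    drugs = []
    for factor in (2.0, 5.0, 10.0, 20.0, 50.0):
        for which in ("CF", "CS"):
            for ka in kas:
                kd = ka / 5e-3
                kw = {"CF": factor} if which == "CF" else {"CS": factor}
                drugs.append(DrugSpec(
                    name=f"{'FI' if which == 'CF' else 'SI'}_x{factor:g}_ka{ka:.2e}",
                    ka=float(ka), kd=float(kd), **kw))
    return drugs


def default_msa_params() -> MSAParams:
    text = resources.files("navgate.data").joinpath("msa_default.yaml").read_text()
    d = yaml.safe_load(text)
    return MSAParams(
        sensor_fwd=RateLaw(d["A_sensor_fwd"], d["Vhalf_sensor_fwd"],
                           d["r_sensor_fwd"], sense="depolarized"),
        sensor_bwd=RateLaw(d["A_sensor_bwd"], d["Vhalf_sensor_bwd"],
                           d["r_sensor_bwd"], sense="hyperpolarized"),
        open_rate=d["open_rate"], close_rate=d["close_rate"],
        kon_fast=d["kon_fast"], koff_fast=d["koff_fast"], a_fast=d["a_fast"],
        kon_slow=d["kon_slow"], koff_slow=d["koff_slow"], a_slow=d["a_slow"])


def sweep_to_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Tidy frame: one row per (sweep_value, condition)."""
    rows = []
    for r in results:
        for x, y in zip(r.x, r.current):
            rows.append({"protocol": r.protocol, "condition": r.condition,
                         "sweep_value": float(x), "relative_current": float(y)})
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_results(frame: pd.DataFrame, out: str | Path, metadata: dict) -> None:
    """CSV plus JSON sidecar; the sidecar embeds the config hash."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)
    meta = dict(metadata)
    meta["config_hash"] = config_hash(metadata)
    out.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
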