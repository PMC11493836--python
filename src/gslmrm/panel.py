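"""Scheduled polarity-switching MRM panel construction.

Builds the transition list (precursor/product m/z, charge, polarity,
scheduled retention-time window) for the multiplexed glycosphingolipid
assay from a declarative panel configuration, predicts retention times
from a simple class-base + chain-length model, and reads/writes
transition lists as CSV (native and Skyline-style small-molecule
dialects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List

import pandas as pd
import yaml

from . import chem
from .chem import LipidSpecies, make_species

__all__ = [
    "Transition",
    "RTModel",
    "PanelConfig",
    "load_panel_config",
    "default_panel_config",
    "predict_rt",
    "build_panel",
    "write_transition_list",
    "read_transition_list",
    "write_skyline_transition_list",
]


@dataclass(frozen=True)
class Transition:
    """One scheduled MRM transition."""

    transition_id: str
    species_id: str
    class_name: str
    ceramide: str
    polarity: str  # "positive" | "negative"
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    rt_min: float
    rt_window_min: float = 1.0
    role: str = "analyte"

    @property
    def window(self) -> tuple:
        half = self.rt_window_min / 2.0
        return (self.rt_min - half, self.rt_min + half)


@dataclass(frozen=True)
class RTModel:
    """Retention-time prediction: class base RT (at d36:1) plus a chain
    term.  More sialic acids -> earlier elution (encoded in the bases);
    longer acyl chains -> later; double bonds -> slightly earlier."""

    class_base_rt: Dict[str, float]
    chain_slope_per_carbon: float = 0.05
    unsat_slope: float = 0.05


@dataclass
class PanelConfig:
    """Declarative panel: per-class ceramide rosters, IS definitions,
    IS-to-class assignment, RT model and acquisition window settings."""

    classes: Dict[str, List[str]]  # class -> ceramide shorthands
    internal_standards: List[LipidSpecies]
    is_map: Dict[str, str]  # analyte class -> IS species_id
    rt_model: RTModel
    gradient_min: float = 15.0
    rt_window_min: float = 1.0
    charge_overrides: Dict[str, int] = field(default_factory=dict)
    rt_overrides: Dict[str, float] = field(default_factory=dict)


def load_panel_config(path) -> PanelConfig:
    """Load a panel configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _config_from_dict(raw)


def default_panel_config() -> PanelConfig:
    """The shipped default configuration (84 analytes, 4 IS)."""
    with resources.files("gslmrm.data").joinpath("default_panel.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> PanelConfig:
    classes = {}
    charge_overrides = {}
    rt_overrides = {}
    for cname, cdef in raw["classes"].items():
        if cname not in chem.LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {cname!r} in panel config")
        species = list(cdef["species"])
        if len(set(species)) != len(species):
            raise ValueError(f"duplicate ceramide species in class {cname}")
        classes[cname] = species
        for key in ("charge", "rt"):
            for sid, val in (cdef.get(f"{key}_overrides") or {}).items():
                full_id = f"{cname} {sid}"
                (charge_overrides if key == "charge" else rt_overrides)[full_id] = val
    standards = [
        make_species(d["class"], d["ceramide"], role="internal_standard")
        for d in raw["internal_standards"]
    ]
    rt_raw = raw["rt_model"]
    rt_model = RTModel(
        class_base_rt=dict(rt_raw["class_base_rt"]),
        chain_slope_per_carbon=float(rt_raw.get("chain_slope_per_carbon", 0.05)),
        unsat_slope=float(rt_raw.get("unsat_slope", 0.05)),
    )
    return PanelConfig(
        classes=classes,
        internal_standards=standards,
        is_map=dict(raw["is_map"]),
        rt_model=rt_model,
        gradient_min=float(raw.get("gradient_min", 15.0)),
        rt_window_min=float(raw.get("rt_window_min", 1.0)),
        charge_overrides=charge_overrides,
        rt_overrides=rt_overrides,
    )


def predict_rt(species: LipidSpecies, model: RTModel, gradient_min: float = 15.0) -> float:
    """Predicted retention time in minutes.

    RT = class base + chain_slope * (total ceramide carbons - 36)
       - unsat_slope * (total double bonds - 1), referenced to d36:1.
    """
    cname = species.lipid_class.name
    if cname not in model.class_base_rt:
        raise ValueError(f"no base RT configured for class {cname}")
    cer = species.ceramide
    rt = (
        model.class_base_rt[cname]
        + model.chain_slope_per_carbon * (cer.total_carbons - 36)
        - model.unsat_slope * (cer.total_double_bonds - 1)
    )
    if not (1.0 < rt < gradient_min):
        raise ValueError(
            f"predicted RT {rt:.2f} min for {species.species_id} falls outside "
            f"(1, {gradient_min}) — adjust the RT model"
        )
    return rt


def build_panel(cfg: PanelConfig) -> List[Transition]:
    """Build the full transition list: one transition per analyte species
    plus one per internal standard, scheduled windows centred on the
    predicted RT."""
    transitions: List[Transition] = []
    seen = set()

    def add(species: LipidSpecies):
        sid = species.species_id
        cer = species.ceramide
        # key on the resolved molecule: "d36:1" and "d18:1/18:0" collide
        key = (
            species.lipid_class.name,
            cer.base_carbons,
            cer.base_double_bonds,
            cer.acyl_carbons,
            cer.acyl_double_bonds,
            cer.label,
        )
        if key in seen:
            raise ValueError(f"duplicate species in panel: {sid}")
        seen.add(key)
        charge = cfg.charge_overrides.get(sid, chem.default_charge(species.lipid_class.name))
        rt = cfg.rt_overrides.get(sid)
        if rt is None:
            rt = predict_rt(species, cfg.rt_model, cfg.gradient_min)
        transitions.append(
            Transition(
                transition_id=f"T{len(transitions) + 1:03d}",
                species_id=sid,
                class_name=species.lipid_class.name,
                ceramide=species.ceramide.shorthand,
                polarity=species.lipid_class.polarity,
                precursor_mz=round(chem.precursor_mz(species, charge), 4),
                precursor_charge=charge,
                product_mz=round(chem.quantifier_fragment_mz(species), 4),
                rt_min=round(rt, 3),
                rt_window_min=cfg.rt_window_min,
                role=species.role,
            )
        )

    for cname, ceramides in cfg.classes.items():
        if cname not in cfg.is_map:
            raise ValueError(f"no internal standard assigned to class {cname}")
        for cer in ceramides:
            add(make_species(cname, cer))
    is_ids = {s.species_id for s in cfg.internal_standards}
    missing = set(cfg.is_map.values()) - is_ids
    if missing:
        raise ValueError(f"is_map references undefined internal standards: {sorted(missing)}")
    for std in cfg.internal_standards:
        add(std)
    return transitions


_COLUMNS = [
    "transition_id",
    "species_id",
    "class",
    "ceramide",
    "polarity",
    "precursor_mz",
    "precursor_charge",
    "product_mz",
    "rt_min",
    "rt_window_min",
    "role",
]


def panel_to_frame(panel: List[Transition]) -> pd.DataFrame:
    rows = [
        {
            "transition_id": t.transition_id,
            "species_id": t.species_id,
            "class": t.class_name,
            "ceramide": t.ceramide,
            "polarity": t.polarity,
            "precursor_mz": t.precursor_mz,
            "precursor_charge": t.precursor_charge,
            "product_mz": t.product_mz,
            "rt_min": t.rt_min,
            "rt_window_min": t.rt_window_min,
            "role": t.role,
        }
        for t in panel
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_transition_list(panel: List[Transition], path) -> None:
    """Write the native transition-list CSV (lossless round-trip)."""
    panel_to_frame(panel).to_csv(path, index=False)


def read_transition_list(path) -> List[Transition]:
    """Read a native transition-list CSV with validation."""
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(_COLUMNS)
    if unknown:
        raise ValueError(f"unknown columns in transition list: {sorted(unknown)}")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in transition list: {sorted(missing)}")
    panel = []
    seen = set()
    for i, row in df.iterrows():
        for col in ("precursor_mz", "product_mz", "rt_min", "rt_window_min"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {i + 1}: non-numeric value {row[col]!r} in column {col}"
                ) from None
        tid = str(row["transition_id"])
        if tid in seen:
            raise ValueError(f"row {i + 1}: duplicated transition id {tid!r}")
        seen.add(tid)
        panel.append(
            Transition(
                transition_id=tid,
                species_id=str(row["species_id"]),
                class_name=str(row["class"]),
                ceramide=str(row["ceramide"]),
                polarity=str(row["polarity"]),
                precursor_mz=float(row["precursor_mz"]),
                precursor_charge=int(row["precursor_charge"]),
                product_mz=float(row["product_mz"]),
                rt_min=float(row["rt_min"]),
                rt_window_min=float(row["rt_window_min"]),
                role=str(row["role"]),
            )
        )
    return panel


def write_skyline_transition_list(panel: List[Transition], path) -> None:
    """Export in a Skyline-style small-molecule column layout."""
    rows = []
    for t in panel:
        z = t.precursor_charge
        adduct = f"[M+{z}H]" if z > 0 else f"[M-{abs(z)}H]"
        rows.append(
            {
                "Molecule List Name": t.class_name,
                "Precursor Name": t.species_id,
                "Precursor Adduct": adduct,
                "Precursor m/z": t.precursor_mz,
                "Precursor Charge": z,
                "Product m/z": t.product_mz,
                "Explicit Retention Time": t.rt_min,
                "Explicit Retention Time Window": t.rt_window_min,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
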