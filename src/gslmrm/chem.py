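"""Compositional chemistry for glycosphingolipids.

Gangliosides and neutral glycosphingolipids are built from a ceramide
(a sphingoid base N-acylated with a fatty acid) carrying a glycan head
group assembled from hexose (Hex), N-acetylhexosamine (HexNAc) and
N-acetylneuraminic acid (NeuAc, sialic acid) residues.  This module
parses ceramide shorthand (``d18:1/18:0``), builds elemental formulas
for whole species, and computes monoisotopic precursor and quantifier
fragment m/z values for MRM transitions.

Conventions
-----------
* The sphingoid base is always dihydroxy ("d"); summed shorthand such as
  ``d36:1`` is resolved assuming a fixed d18:1 base, which every
  commercial standard used here carries.
* Charge adjustment uses the proton mass (1.00727646 Da), not the H atom
  mass: ``[M-H]- = M - 1.00727646``.
* Sialylated classes fragment to the dehydrated sialic acid anion
  ([NeuAc - H2O - H]-, m/z 290.1); neutral classes to the dehydrated
  sphingosine cation ([d18:1 base + H - 2 H2O]+, m/z 264.3).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "CeramideSpec",
    "GlycanComposition",
    "LipidClassDef",
    "LipidSpecies",
    "LIPID_CLASSES",
    "parse_ceramide",
    "ceramide_formula",
    "species_formula",
    "precursor_mz",
    "quantifier_fragment_mz",
    "default_charge",
]


def _load_masses() -> Dict[str, float]:
    with resources.files("gslmrm.data").joinpath("atomic_masses.json").open() as fh:
        raw = json.load(fh)
    return {k: v for k, v in raw.items() if not k.startswith("_")}


_MASSES = _load_masses()
PROTON_MASS: float = _MASSES.pop("proton")
#: Monoisotopic atomic masses (Da); "D" = deuterium.
ATOMIC_MASS: Mapping[str, float] = dict(_MASSES)


class LipidParseError(ValueError):
    """Raised when lipid shorthand cannot be parsed."""


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition with non-negative integer counts.

    Supports element-wise addition/subtraction and integer scaling;
    subtraction that would yield a negative count raises ``ValueError``.
    Deuterium is tracked under the element symbol ``D``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element {el!r}")
            if not isinstance(n, int) or isinstance(n, bool):
                raise ValueError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self.counts)
        for el, n in other.counts.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self.counts)
        for el, n in other.counts.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({out[el]})"
                )
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula scaling requires a non-negative integer")
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    @property
    def monoisotopic_mass(self) -> float:
        return sum(ATOMIC_MASS[el] * n for el, n in self.counts.items())

    def hill_formula(self) -> str:
        """Hill-order string, deuterium rendered as D after H."""
        order = ["C", "H", "D"] + sorted(
            el for el in self.counts if el not in ("C", "H", "D")
        )
        parts = []
        for el in order:
            n = self.counts.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __bool__(self) -> bool:
        return bool(self.counts)


# -- building blocks ---------------------------------------------------------

WATER = ElementalFormula({"H": 2, "O": 1})
#: Dehydrated glycosyl residues (each glycosidic bond loses one water).
HEX_RESIDUE = ElementalFormula({"C": 6, "H": 10, "O": 5})
HEXNAC_RESIDUE = ElementalFormula({"C": 8, "H": 13, "N": 1, "O": 5})
NEUAC_RESIDUE = ElementalFormula({"C": 11, "H": 17, "N": 1, "O": 8})
#: Intact d18:1 sphingoid base (sphingosine), C18H37NO2.
SPHINGOSINE_D18_1 = ElementalFormula({"C": 18, "H": 37, "N": 1, "O": 2})


_CERAMIDE_RE = re.compile(
    r"^d(?P<c1>\d+):(?P<db1>\d+)"
    r"(?:/(?P<c2>\d+):(?P<db2>\d+))?"
    r"(?:-d(?P<label>[35]))?$"
)


@dataclass(frozen=True)
class CeramideSpec:
    """A ceramide: d-type sphingoid base plus N-acyl chain.

    ``label`` deuteriums sit on the acyl chain (0, 3 or 5), replacing
    that many hydrogens.  ``summed`` records whether the spec came from
    summed shorthand (``d36:1``) rather than the full base/acyl form.
    """

    base_carbons: int
    base_double_bonds: int
    acyl_carbons: int
    acyl_double_bonds: int
    label: int = 0
    summed: bool = False

    def __post_init__(self):
        if self.base_carbons < 12 or self.acyl_carbons < 12:
            raise ValueError(
                f"chain too short: base {self.base_carbons}, acyl {self.acyl_carbons} "
                "(need >= 12 carbons each)"
            )
        if self.base_double_bonds < 0 or self.acyl_double_bonds < 0:
            raise ValueError("double bond counts must be >= 0")
        if self.label not in (0, 3, 5):
            raise ValueError(f"deuterium label must be 0, 3 or 5, got {self.label}")

    @property
    def total_carbons(self) -> int:
        return self.base_carbons + self.acyl_carbons

    @property
    def total_double_bonds(self) -> int:
        return self.base_double_bonds + self.acyl_double_bonds

    @property
    def shorthand(self) -> str:
        """Round-trip rendering: summed specs render summed."""
        suffix = f"-d{self.label}" if self.label else ""
        if self.summed:
            return f"d{self.total_carbons}:{self.total_double_bonds}{suffix}"
        return (
            f"d{self.base_carbons}:{self.base_double_bonds}"
            f"/{self.acyl_carbons}:{self.acyl_double_bonds}{suffix}"
        )


def parse_ceramide(shorthand: str) -> CeramideSpec:
    """Parse ceramide shorthand.

    Accepts the full form ``d18:1/18:0`` (optionally ``-d3``/``-d5``)
    and the summed form ``d36:1``, which is resolved assuming a fixed
    d18:1 sphingoid base (acyl = total-18 carbons, total-1 double bonds).
    """
    text = shorthand.strip()
    m = _CERAMIDE_RE.match(text)
    if m is None:
        raise LipidParseError(f"cannot parse ceramide shorthand {text!r}")
    c1, db1 = int(m["c1"]), int(m["db1"])
    label = int(m["label"]) if m["label"] else 0
    if m["c2"] is not None:
        return CeramideSpec(c1, db1, int(m["c2"]), int(m["db2"]), label)
    # summed form: fixed d18:1 base
    if c1 < 30:
        raise LipidParseError(
            f"summed shorthand {text!r}: total carbons {c1} < 30 cannot hold "
            "a d18:1 base plus a >=12-carbon acyl chain"
        )
    if db1 < 1:
        raise LipidParseError(
            f"summed shorthand {text!r}: needs >= 1 double bond for the d18:1 base"
        )
    return CeramideSpec(18, 1, c1 - 18, db1 - 1, label, summed=True)


def ceramide_formula(c: CeramideSpec) -> ElementalFormula:
    """Elemental formula of the intact ceramide.

    Ceramide = sphingoid base + fatty acid - H2O (amide bond).  A d-type
    base with B carbons and k double bonds is C_B H_(2B-2k+3) N O2; a
    fatty acid with n carbons and j double bonds is C_n H_(2n-2j) O2.
    The deuterium label replaces ``label`` hydrogens on the acyl chain.
    """
    base = ElementalFormula(
        {
            "C": c.base_carbons,
            "H": 2 * c.base_carbons - 2 * c.base_double_bonds + 3,
            "N": 1,
            "O": 2,
        }
    )
    acyl = ElementalFormula(
        {
            "C": c.acyl_carbons,
            "H": 2 * c.acyl_carbons - 2 * c.acyl_double_bonds,
            "O": 2,
        }
    )
    formula = base + acyl - WATER
    if c.label:
        formula = formula - ElementalFormula({"H": c.label}) + ElementalFormula(
            {"D": c.label}
        )
    return formula


@dataclass(frozen=True)
class GlycanComposition:
    """Glycan head group as residue counts (dehydrated residues)."""

    n_hex: int = 0
    n_hexnac: int = 0
    n_neuac: int = 0

    def __post_init__(self):
        if min(self.n_hex, self.n_hexnac, self.n_neuac) < 0:
            raise ValueError("residue counts must be >= 0")
        if self.n_neuac > 4:
            raise ValueError(f"n_neuac {self.n_neuac} > 4")
        if self.n_hex + self.n_hexnac + self.n_neuac > 8:
            raise ValueError("total residues > 8")

    def formula(self) -> ElementalFormula:
        return (
            self.n_hex * HEX_RESIDUE
            + self.n_hexnac * HEXNAC_RESIDUE
            + self.n_neuac * NEUAC_RESIDUE
        )


@dataclass(frozen=True)
class LipidClassDef:
    """A glycosphingolipid class: name, glycan composition, detection mode.

    Sialylated classes (n_neuac >= 1) are detected in negative mode with
    the sialic-acid quantifier; neutral classes in positive mode with
    the sphingosine quantifier.
    """

    name: str
    glycan: GlycanComposition

    @property
    def polarity(self) -> str:
        return "negative" if self.glycan.n_neuac >= 1 else "positive"

    @property
    def quantifier(self) -> str:
        return "neuac" if self.glycan.n_neuac >= 1 else "sphingosine"


def _g(h, hn, s):
    return GlycanComposition(n_hex=h, n_hexnac=hn, n_neuac=s)


#: The 14 targeted classes along the ganglioside biosynthetic pathway
#: (Svennerholm nomenclature: M/D/T/Q = 1/2/3/4 sialic acids; the trailing
#: digit encodes the neutral sugar series).
LIPID_CLASSES: Dict[str, LipidClassDef] = {
    name: LipidClassDef(name, glycan)
    for name, glycan in {
        "GlcCer": _g(1, 0, 0),
        "LacCer": _g(2, 0, 0),
        "Gb3": _g(3, 0, 0),
        "GA2": _g(2, 1, 0),
        "GM3": _g(2, 0, 1),
        "GM2": _g(2, 1, 1),
        "GM1": _g(3, 1, 1),
        "GD3": _g(2, 0, 2),
        "GD2": _g(2, 1, 2),
        "GD1": _g(3, 1, 2),
        "GT3": _g(2, 0, 3),
        "GT2": _g(2, 1, 3),
        "GT1": _g(3, 1, 3),
        "GQ1": _g(3, 1, 4),
    }.items()
}


@dataclass(frozen=True)
class LipidSpecies:
    """One panel entry: a class plus a specific ceramide."""

    lipid_class: LipidClassDef
    ceramide: CeramideSpec
    role: str = "analyte"  # analyte | internal_standard

    def __post_init__(self):
        if self.role not in ("analyte", "internal_standard"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "internal_standard":
            if self.ceramide.label == 0 and self.ceramide.acyl_carbons % 2 == 0:
                raise ValueError(
                    "internal standards must carry a deuterium label or an "
                    f"odd-carbon acyl chain, got {self.ceramide.shorthand}"
                )

    @property
    def species_id(self) -> str:
        return f"{self.lipid_class.name} {self.ceramide.shorthand}"


def make_species(class_name: str, ceramide: str, role: str = "analyte") -> LipidSpecies:
    """Convenience constructor from class name + ceramide shorthand."""
    if class_name not in LIPID_CLASSES:
        raise KeyError(
            f"unknown lipid class {class_name!r}; known: {sorted(LIPID_CLASSES)}"
        )
    return LipidSpecies(LIPID_CLASSES[class_name], parse_ceramide(ceramide), role)


def species_formula(s: LipidSpecies) -> ElementalFormula:
    """Elemental formula of the whole species (ceramide + glycan residues)."""
    return ceramide_formula(s.ceramide) + s.lipid_class.glycan.formula()


def precursor_mz(s: LipidSpecies, charge: int) -> float:
    """Monoisotopic precursor m/z at a signed charge state.

    Positive z: (M + z*mp)/z.  Negative z: (M - |z|*mp)/|z|, with mp the
    proton mass.  The charge sign must match the class polarity.
    """
    if charge == 0:
        raise ValueError("charge must be non-zero")
    pol = s.lipid_class.polarity
    if pol == "positive" and charge != 1:
        raise ValueError(
            f"{s.species_id} is detected in positive mode; charge must be +1, got {charge}"
        )
    if pol == "negative" and charge not in (-1, -2, -3):
        raise ValueError(
            f"{s.species_id} is a ganglioside (negative mode); charge must be "
            f"-1, -2 or -3, got {charge}"
        )
    m = species_formula(s).monoisotopic_mass
    z = abs(charge)
    if charge > 0:
        return (m + z * PROTON_MASS) / z
    return (m - z * PROTON_MASS) / z


def default_charge(class_name: str) -> int:
    """Default precursor charge: [M-H]- for mono-sialo, [M-2H]2- for
    >= 2 NeuAc, [M+H]+ for neutral classes."""
    n = LIPID_CLASSES[class_name].glycan.n_neuac
    if n == 0:
        return 1
    return -1 if n == 1 else -2


def quantifier_fragment_mz(s: LipidSpecies) -> float:
    """Quantifier product-ion m/z for a species.

    Sialylated classes: dehydrated sialic acid anion [NeuAc - H2O - H]-,
    i.e. the NeuAc residue C11H17NO8 minus a proton (~290.1).  Neutral
    classes: dehydrated sphingosine cation [d18:1 base + H - 2 H2O]+
    from C18H37NO2 (~264.3).  The acyl deuterium label of internal
    standards does not shift either fragment.
    """
    if s.lipid_class.quantifier == "neuac":
        return NEUAC_RESIDUE.monoisotopic_mass - PROTON_MASS
    return SPHINGOSINE_D18_1.monoisotopic_mass + PROTON_MASS - 2 * WATER.monoisotopic_mass
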