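"""SMIRKS-keyed DE parameter libraries and direct chemical perception.

Parameters are assigned to atoms straight from substructure chemistry: each
library record pairs a SMIRKS pattern carrying exactly one tagged atom
(``[...:1]``) with (epsilon, r_m).  Record order is significant — when several
patterns match the same atom the *last* record in the library wins, so later
records refine earlier, more generic ones.

Libraries live in a single-file XML dialect::

    <DEForceField>
      <GlobalShape alpha="16.766" beta="4.427"/>
      <DoubleExponential>
        <Atom smirks="[#1:1]" epsilon="0.01" r_m="2.9" label="H-generic"/>
        ...
      </DoubleExponential>
      <Electrostatics scale14="0.8333333" scale14_vdw="0.5"/>
      <VirtualSites>
        <BisectorSite parent="O" distance="0.105" charge="-1.054"/>
      </VirtualSites>
    </DEForceField>

Attribute units are fixed (kcal/mol, Angstrom, elementary charge); there are
no per-attribute unit strings.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .potentials import GlobalShape, PairParams

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "SmirksRecord",
    "VirtualSiteDef",
    "ParameterLibrary",
    "MolecularGraph",
    "load_library",
    "save_library",
    "assign_parameters",
    "validate_library",
    "LibraryParseError",
    "AssignmentError",
]


class LibraryParseError(ValueError):
    """Malformed library file (bad XML, missing elements, duplicate labels)."""


class AssignmentError(ValueError):
    """A molecule contains atoms not covered by any library record."""


@dataclass(frozen=True)
class SmirksRecord:
    """One typed vdW parameter: a SMIRKS pattern with a single tagged atom.

    The tagged atom (map index 1) is the atom that receives ``params`` when
    the pattern matches; the rest of the pattern is chemical context.
    """

    smirks: str
    params: PairParams
    label: str

    def __post_init__(self) -> None:
        query = Chem.MolFromSmarts(self.smirks)
        if query is None:
            raise LibraryParseError(f"record {self.label!r}: unparseable SMIRKS {self.smirks!r}")
        tagged = [a.GetIdx() for a in query.GetAtoms() if a.GetAtomMapNum() == 1]
        if len(tagged) != 1:
            raise LibraryParseError(
                f"record {self.label!r}: SMIRKS must tag exactly one atom with :1, "
                f"got {len(tagged)} in {self.smirks!r}"
            )


@dataclass(frozen=True)
class VirtualSiteDef:
    """A bisector-type massless site (the M-site of 4-point water models).

    parent   -- element symbol of the anchoring atom (e.g. "O")
    distance -- displacement from the parent along the H-parent-H bisector, A
    charge   -- site charge, e (the parent's own charge is taken from input)
    """

    parent: str
    distance: float
    charge: float


@dataclass
class ParameterLibrary:
    records: list[SmirksRecord]
    shape: GlobalShape
    scale14_vdw: float = 0.5
    scale14_elec: float = 0.8333333
    vsites: list[VirtualSiteDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.records]
        dups = {l for l in labels if labels.count(l) > 1}
        if dups:
            raise LibraryParseError(f"duplicate record labels: {sorted(dups)}")


# ---------------------------------------------------------------------------
# Molecular graphs
# ---------------------------------------------------------------------------

_BOND_ORDERS = {
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


@dataclass
class MolecularGraph:
    """A molecule as element/charge-decorated graph plus optional geometry.

    elements       -- element symbols, one per atom
    formal_charges -- integer formal charges
    partial_charges -- per-atom partial charges, e (input data, never derived)
    bonds          -- (i, j, order) tuples; order in {1, 1.5, 2, 3}
    coordinates    -- optional (n_atoms, 3) Cartesian Angstrom
    """

    elements: list[str]
    formal_charges: list[int]
    partial_charges: np.ndarray
    bonds: list[tuple[int, int, float]]
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.partial_charges = np.asarray(self.partial_charges, dtype=float)
        if len(self.partial_charges) != len(self.elements):
            raise ValueError("one partial charge per atom required")
        total = float(np.sum(self.partial_charges))
        if abs(total - sum(self.formal_charges)) > 1e-6:
            raise ValueError(
                f"partial charges sum to {total:.8f}, expected net formal "
                f"charge {sum(self.formal_charges)}"
            )
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (len(self.elements), 3):
                raise ValueError("coordinates must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def to_rdkit(self) -> Chem.Mol:
        """Build a sanitised RDKit molecule with explicit hydrogens."""
        mol = Chem.RWMol()
        for sym, fc in zip(self.elements, self.formal_charges):
            atom = Chem.Atom(sym)
            atom.SetFormalCharge(fc)
            atom.SetNoImplicit(True)
            mol.AddAtom(atom)
        for i, j, order in self.bonds:
            mol.AddBond(int(i), int(j), _BOND_ORDERS[float(order)])
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return out

    @classmethod
    def from_smiles(
        cls,
        smiles: str,
        partial_charges=None,
        coordinates=None,
    ) -> "MolecularGraph":
        """Build a graph (explicit hydrogens) from SMILES.

        Partial charges default to zero on every atom; real charges are the
        caller's responsibility (charge generation is out of scope).
        """
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {smiles!r}")
        mol = Chem.AddHs(mol)
        return cls._from_rdkit(mol, partial_charges, coordinates)

    @classmethod
    def from_sdf(cls, path) -> "MolecularGraph":
        """Read the first molecule of a V2000 SDF, with partial charges.

        Charges are read from per-atom double properties named
        ``PartialCharge`` (the ``atom.dprop.PartialCharge`` block) or from a
        whitespace-separated molecule-level ``PartialCharges`` field.
        """
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None:
            raise ValueError(f"no readable molecule in {path}")
        charges = None
        if all(a.HasProp("PartialCharge") for a in mol.GetAtoms()):
            charges = [a.GetDoubleProp("PartialCharge") for a in mol.GetAtoms()]
        elif mol.HasProp("PartialCharges"):
            charges = [float(x) for x in mol.GetProp("PartialCharges").split()]
        coords = None
        if mol.GetNumConformers():
            coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
        return cls._from_rdkit(mol, charges, coords)

    @classmethod
    def _from_rdkit(cls, mol: Chem.Mol, partial_charges, coordinates) -> "MolecularGraph":
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        formal = [a.GetFormalCharge() for a in mol.GetAtoms()]
        if partial_charges is None:
            partial_charges = np.zeros(len(elements))
            if sum(formal) != 0:
                # keep the charge-sum invariant for ions: spread the net charge
                partial_charges += sum(formal) / len(elements)
        rev = {v: k for k, v in _BOND_ORDERS.items()}
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), rev[b.GetBondType()])
            for b in mol.GetBonds()
        ]
        return cls(elements, formal, np.asarray(partial_charges, float), bonds, coordinates)


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------


def save_library(lib: ParameterLibrary, path) -> None:
    root = ET.Element("DEForceField")
    ET.SubElement(root, "GlobalShape", alpha=repr(lib.shape.alpha), beta=repr(lib.shape.beta))
    de = ET.SubElement(root, "DoubleExponential")
    for rec in lib.records:
        ET.SubElement(
            de,
            "Atom",
            smirks=rec.smirks,
            epsilon=repr(rec.params.epsilon),
            r_m=repr(rec.params.r_m),
            label=rec.label,
        )
    ET.SubElement(
        root,
        "Electrostatics",
        scale14=repr(lib.scale14_elec),
        scale14_vdw=repr(lib.scale14_vdw),
    )
    vs = ET.SubElement(root, "VirtualSites")
    for v in lib.vsites:
        ET.SubElement(
            vs,
            "BisectorSite",
            parent=v.parent,
            distance=repr(v.distance),
            charge=repr(v.charge),
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="unicode")


def _require(elem: ET.Element | None, name: str) -> ET.Element:
    if elem is None:
        raise LibraryParseError(f"missing required element <{name}>")
    return elem


def load_library(path) -> ParameterLibrary:
    path = Path(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise LibraryParseError(f"{path}: not well-formed XML ({exc})") from exc
    if root.tag != "DEForceField":
        raise LibraryParseError(f"{path}: root element is <{root.tag}>, expected <DEForceField>")
    shape_el = _require(root.find("GlobalShape"), "GlobalShape")
    try:
        shape = GlobalShape(float(shape_el.get("alpha")), float(shape_el.get("beta")))
    except (TypeError, ValueError) as exc:
        raise LibraryParseError(f"<GlobalShape>: {exc}") from exc
    de = _require(root.find("DoubleExponential"), "DoubleExponential")
    records = []
    for atom in de.findall("Atom"):
        try:
            records.append(
                SmirksRecord(
                    smirks=atom.get("smirks"),
                    params=PairParams(float(atom.get("epsilon")), float(atom.get("r_m"))),
                    label=atom.get("label"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise LibraryParseError(f"<Atom label={atom.get('label')!r}>: {exc}") from exc
    elec = root.find("Electrostatics")
    scale14_elec = float(elec.get("scale14", "0.8333333")) if elec is not None else 0.8333333
    scale14_vdw = float(elec.get("scale14_vdw", "0.5")) if elec is not None else 0.5
    vsites = []
    vs = root.find("VirtualSites")
    if vs is not None:
        for v in vs.findall("BisectorSite"):
            vsites.append(
                VirtualSiteDef(
                    parent=v.get("parent"),
                    distance=float(v.get("distance")),
                    charge=float(v.get("charge")),
                )
            )
    return ParameterLibrary(records, shape, scale14_vdw, scale14_elec, vsites)


# ---------------------------------------------------------------------------
# Assignment by direct chemical perception
# ---------------------------------------------------------------------------


def assign_parameters(
    mol: MolecularGraph, lib: ParameterLibrary
) -> tuple[list[PairParams], list[str]]:
    """Assign per-atom DE parameters by SMIRKS substructure matching.

    Every record is matched against the molecule in library order; each match
    stamps its parameters onto the atom under the tagged position, so the last
    matching record wins.  The result is a pure function of (graph, library):
    permuting atom indices permutes the output identically.

    Raises :class:`AssignmentError` if any atom is left unmatched — elements
    outside the parameterised chemistry are rejected, never silently defaulted.
    """
    rdmol = mol.to_rdkit()
    assigned: list[PairParams | None] = [None] * mol.n_atoms
    labels: list[str | None] = [None] * mol.n_atoms
    for rec in lib.records:
        query = Chem.MolFromSmarts(rec.smirks)
        tagged_pos = next(
            a.GetIdx() for a in query.GetAtoms() if a.GetAtomMapNum() == 1
        )
        matches = rdmol.GetSubstructMatches(query, uniquify=False, maxMatches=100000)
        for match in matches:
            idx = match[tagged_pos]
            assigned[idx] = rec.params
            labels[idx] = rec.label
    missing = [i for i, p in enumerate(assigned) if p is None]
    if missing:
        desc = ", ".join(f"{i} ({mol.elements[i]})" for i in missing)
        raise AssignmentError(f"no library record matches atom(s): {desc}")
    return list(assigned), list(labels)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_library(lib: ParameterLibrary) -> list[dict]:
    """Collect machine-readable issues without raising.

    Each issue is ``{"code": ..., "where": ..., "message": ...}``.  Because
    the dataclass constructors already reject hard errors, this is mainly
    useful for libraries built field-by-field or edited on disk.
    """
    issues: list[dict] = []
    if not lib.shape.alpha > lib.shape.beta:
        issues.append(
            {
                "code": "invalid_shape",
                "where": "GlobalShape",
                "message": f"alpha ({lib.shape.alpha}) must exceed beta ({lib.shape.beta})",
            }
        )
    for rec in lib.records:
        if rec.params.epsilon < 0:
            issues.append(
                {
                    "code": "negative_epsilon",
                    "where": rec.label,
                    "message": f"epsilon = {rec.params.epsilon}",
                }
            )
        if rec.params.r_m <= 0:
            issues.append(
                {
                    "code": "nonpositive_r_m",
                    "where": rec.label,
                    "message": f"r_m = {rec.params.r_m}",
                }
            )
        if Chem.MolFromSmarts(rec.smirks) is None:
            issues.append(
                {
                    "code": "unparseable_smirks",
                    "where": rec.label,
                    "message": rec.smirks,
                }
            )
    return issues


def _unsafe_library(records, shape_alpha, shape_beta, **kw) -> ParameterLibrary:
    """Build a library bypassing constructor validation (for validate tests)."""
    lib = ParameterLibrary.__new__(ParameterLibrary)
    lib.records = records
    shape = GlobalShape.__new__(GlobalShape)
    object.__setattr__(shape, "alpha", shape_alpha)
    object.__setattr__(shape, "beta", shape_beta)
    lib.shape = shape
    lib.scale14_vdw = kw.get("scale14_vdw", 0.5)
    lib.scale14_elec = kw.get("scale14_elec", 0.8333333)
    lib.vsites = kw.get("vsites", [])
    return lib


def _unsafe_record(smirks: str, epsilon: float, r_m: float, label: str) -> SmirksRecord:
    rec = SmirksRecord.__new__(SmirksRecord)
    object.__setattr__(rec, "smirks", smirks)
    params = PairParams.__new__(PairParams)
    object.__setattr__(params, "epsilon", epsilon)
    object.__setattr__(params, "r_m", r_m)
    object.__setattr__(rec, "params", params)
    object.__setattr__(rec, "label", label)
    return rec
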