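"""Fixtures and system assembly: water boxes, toy solutes, and the packaged
parameter library.

The packaged library carries the trained global DE shape (alpha = 16.766,
beta = 4.427) but *synthetic stand-in* per-type (epsilon, r_m) values chosen
to be physically plausible for C/H/O/N/Br chemistry — they are placeholders
for exercising the machinery, not a trained parameter set.  The 4-point
water entry mimics a re-optimised bisector-site model: vdW on oxygen only,
hydrogen charges balanced by a negative M-site on the HOH bisector, with
polar hydrogens carrying no vdW term at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .params import (
    MolecularGraph,
    ParameterLibrary,
    SmirksRecord,
    VirtualSiteDef,
    assign_parameters,
)
from .potentials import GlobalShape, PairParams
from .system import (
    Configuration,
    InteractingSystem,
    VirtualSite,
    build_exclusions,
    place_virtual_sites,
)
from .units import WATER_MOLAR_MASS, AMU_PER_A3_TO_G_PER_ML

__all__ = [
    "fixture_library",
    "water_molecule",
    "build_system",
    "make_water_box",
    "make_toy_solute",
    "make_de_fluid",
    "FixtureSpec",
    "ELEMENT_MASSES",
]

ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "P": 30.974,
    "S": 32.06,
    "Br": 79.904,
}

#: Rigid water geometry: O-H bond length (A) and H-O-H angle (degrees).
WATER_OH = 0.9572
WATER_HOH_DEG = 104.52


def fixture_library() -> ParameterLibrary:
    """The packaged stand-in library: ~10 SMIRKS types plus 4-point water.

    Record order is significant (last match wins), so generic types come
    first and chemically specific refinements after.  Polar hydrogens carry
    epsilon = 0: their vdW term is removed and excluded-volume protection
    comes from the heavy atom they ride on.
    """
    rec = [
        ("[#1:1]", 0.0157, 2.97, "H-generic"),
        ("[#1:1]-[#6X4]", 0.0157, 2.94, "H-aliphatic"),
        ("[#1:1]-[#8]", 0.0, 1.0, "H-polar-O"),
        ("[#1:1]-[#7]", 0.0, 1.2, "H-polar-N"),
        ("[#6:1]", 0.09, 3.85, "C-generic"),
        ("[#6X4:1]", 0.11, 3.80, "C-sp3"),
        ("[#8:1]", 0.21, 3.40, "O-generic"),
        ("[#8X2H1:1]", 0.21, 3.42, "O-hydroxyl"),
        ("[#7:1]", 0.19, 3.65, "N-generic"),
        ("[#35:1]", 0.31, 4.05, "Br"),
        ("[#8X2H2:1]", 0.179, 3.55, "O-water"),
        ("[#1:1]-[#8X2H2]", 0.0, 1.0, "H-water"),
    ]
    return ParameterLibrary(
        records=[SmirksRecord(s, PairParams(e, r), l) for s, e, r, l in rec],
        shape=GlobalShape(16.766, 4.427),
        scale14_vdw=0.5,
        scale14_elec=0.8333333,
        vsites=[VirtualSiteDef(parent="O", distance=0.1053, charge=-1.05174)],
    )


def water_molecule() -> MolecularGraph:
    """One rigid 4-point-ready water: O-H 0.9572 A, HOH 104.52 degrees.

    Partial charges sum to zero on the atoms (O negative); attaching the
    library's M-site moves the oxygen charge onto the bisector site.
    """
    half = math.radians(WATER_HOH_DEG / 2.0)
    h = WATER_OH * np.array(
        [[math.sin(half), 0.0, math.cos(half)], [-math.sin(half), 0.0, math.cos(half)]]
    )
    coords = np.vstack([[0.0, 0.0, 0.0], h])
    return MolecularGraph(
        elements=["O", "H", "H"],
        formal_charges=[0, 0, 0],
        partial_charges=np.array([-1.05174, 0.52587, 0.52587]),
        bonds=[(0, 1, 1.0), (0, 2, 1.0)],
        coordinates=coords,
    )


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------


def _match_vsites(mol: MolecularGraph, lib: ParameterLibrary):
    """Local (parent, h1, h2, def) tuples for bisector sites in this molecule."""
    neighbours: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for i, j, _ in mol.bonds:
        neighbours[int(i)].append(int(j))
        neighbours[int(j)].append(int(i))
    out = []
    for vdef in lib.vsites:
        for idx, el in enumerate(mol.elements):
            if el != vdef.parent:
                continue
            hs = [n for n in neighbours[idx] if mol.elements[n] == "H"]
            if len(hs) == 2 and len(neighbours[idx]) == 2:
                out.append((idx, hs[0], hs[1], vdef))
    return out


def build_system(
    molecules: list[MolecularGraph],
    library: ParameterLibrary,
    *,
    box=None,
    cutoff: float | None = None,
    switch_width: float | None = None,
    params_override: list[list[PairParams] | None] | None = None,
    solute: int | None = None,
) -> tuple[InteractingSystem, Configuration]:
    """Assemble molecules + library into an interacting system.

    Every molecule must carry coordinates.  Parameters are assigned by
    SMIRKS perception unless ``params_override[m]`` supplies explicit
    per-atom values for molecule ``m``.  Virtual sites defined by the
    library are instantiated on matching parents (an O bonded to exactly two
    hydrogens, for the water M-site), taking over the parent's charge.

    ``box`` is an edge length (cubic) or three edges; the default cutoff is
    min(9 A, half the shortest edge).  ``solute`` tags one molecule index
    for alchemical work.
    """
    if params_override is None:
        params_override = [None] * len(molecules)
    eps, rm, charge, mol_id, is_vsite, masses, coords = [], [], [], [], [], [], []
    vsites: list[VirtualSite] = []
    exclusions: dict[tuple[int, int], str] = {}
    offset = 0
    for m, mol in enumerate(molecules):
        if mol.coordinates is None:
            raise ValueError(f"molecule {m} has no coordinates")
        if params_override[m] is not None:
            params = list(params_override[m])
        else:
            params, _ = assign_parameters(mol, library)
        n = mol.n_atoms
        eps += [p.epsilon for p in params]
        rm += [p.r_m for p in params]
        q = list(np.asarray(mol.partial_charges, dtype=float))
        masses += [ELEMENT_MASSES[el] for el in mol.elements]
        coords.append(np.asarray(mol.coordinates, dtype=float))
        for (i, j), kind in build_exclusions(mol).items():
            exclusions[(i + offset, j + offset)] = kind
        matched = _match_vsites(mol, library) if params_override[m] is None else []
        site_local = n
        for parent, h1, h2, vdef in matched:
            q[parent] = q[parent] - vdef.charge  # move charge onto the site
            q.append(vdef.charge)
            eps.append(0.0)
            rm.append(1.0)
            masses.append(0.0)
            coords.append(np.zeros((1, 3)))  # placed below
            vsites.append(
                VirtualSite(
                    site=offset + site_local,
                    parent=offset + parent,
                    h1=offset + h1,
                    h2=offset + h2,
                    distance=vdef.distance,
                )
            )
            # a massless site never interacts within its own molecule
            for other in range(site_local):
                exclusions[(offset + other, offset + site_local)] = "excluded"
            site_local += 1
        charge += q
        total = site_local
        mol_id += [m] * total
        is_vsite += [False] * n + [True] * (total - n)
        offset += total

    conf = Configuration(np.vstack(coords), None if box is None else np.resize(np.asarray(box, float), 3))
    if conf.box is not None:
        default_cut = min(9.0, float(conf.box.min()) / 2.0)
    else:
        default_cut = 9.0
    cut = default_cut if cutoff is None else cutoff
    sw = min(1.0, 0.25 * cut) if switch_width is None else switch_width
    system = InteractingSystem(
        eps,
        rm,
        charge,
        mol_id,
        library.shape,
        is_vsite=is_vsite,
        vsites=vsites,
        exclusions=exclusions,
        cutoff=cut,
        switch_width=sw,
        scale14_vdw=library.scale14_vdw,
        scale14_elec=library.scale14_elec,
        masses=masses,
        solute_mol=solute,
    )
    conf = place_virtual_sites(conf, system)
    return system, conf


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible generator request; the seed is mandatory."""

    kind: str  # water_box | de_fluid | toy_solute | dimer
    n: int = 0
    density: float = 0.997
    seed: int = 0


def make_water_box(
    n_molecules: int,
    library: ParameterLibrary | None = None,
    density: float = 0.997,
    seed: int = 0,
    *,
    solute: MolecularGraph | None = None,
    solute_params: list[PairParams] | None = None,
) -> tuple[InteractingSystem, Configuration]:
    """Rigid 4-point waters on a jittered cubic lattice at the target density.

    The box edge follows from n * M_water / density; molecules receive
    random orientations and small positional jitter, with a guaranteed
    minimum O-O separation of 2 A.  Deterministic per seed.  An optional
    solute replaces the molecule nearest the box centre and is tagged for
    alchemical work.
    """
    if n_molecules < 2:
        raise ValueError("need at least two molecules")
    library = library or fixture_library()
    rng = np.random.default_rng(seed)
    n_sites = n_molecules + (1 if solute is not None else 0)
    volume = n_molecules * WATER_MOLAR_MASS * AMU_PER_A3_TO_G_PER_ML / density
    edge = volume ** (1.0 / 3.0)
    cells = math.ceil(n_sites ** (1.0 / 3.0))
    spacing = edge / cells
    if spacing < 2.05:
        raise ValueError(
            f"density {density} infeasible for n={n_molecules}: lattice spacing "
            f"{spacing:.2f} A < 2.05 A cannot respect the 2 A minimum separation"
        )
    # nearest-neighbour approach is bounded by spacing - 2*jitter
    jitter = 0.4 * (spacing - 2.0)
    points = []
    for i in range(cells):
        for j in range(cells):
            for k in range(cells):
                points.append((np.array([i, j, k]) + 0.5) * spacing)
    order = rng.permutation(len(points))[:n_sites]
    centres = [points[i] + rng.uniform(-jitter, jitter, 3) for i in order]

    template = water_molecule()
    molecules: list[MolecularGraph] = []
    overrides: list[list[PairParams] | None] = []
    solute_centre = None
    if solute is not None:
        mid = np.full(3, edge / 2.0)
        nearest = int(np.argmin([np.linalg.norm(c - mid) for c in centres]))
        solute_centre = centres.pop(nearest)
    for c in centres:
        rot = Rotation.random(random_state=rng).as_matrix()
        coords = template.coordinates @ rot.T + c
        molecules.append(
            MolecularGraph(
                template.elements,
                template.formal_charges,
                template.partial_charges,
                template.bonds,
                coords,
            )
        )
        overrides.append(None)
    solute_index = None
    if solute is not None:
        centroid = np.asarray(solute.coordinates).mean(axis=0)
        coords = np.asarray(solute.coordinates) - centroid + solute_centre
        molecules.append(
            MolecularGraph(
                solute.elements,
                solute.formal_charges,
                solute.partial_charges,
                solute.bonds,
                coords,
            )
        )
        overrides.append(solute_params)
        solute_index = len(molecules) - 1

    system, conf = build_system(
        molecules, library, box=edge, params_override=overrides, solute=solute_index
    )
    _check_min_separation(system, conf, 2.0)
    return system, conf


def _check_min_separation(system: InteractingSystem, conf: Configuration, d_min: float):
    heavy = np.flatnonzero((system.masses > 2.0))
    x = conf.coordinates[heavy]
    delta = x[:, None, :] - x[None, :, :]
    if conf.box is not None:
        delta -= conf.box * np.round(delta / conf.box)
    r = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    np.fill_diagonal(r, np.inf)
    # heavy atoms within one molecule may legitimately sit closer
    same = system.mol_id[heavy][:, None] == system.mol_id[heavy][None, :]
    r = np.where(same, np.inf, r)
    if float(r.min()) < d_min:
        raise ValueError(f"generated box violates {d_min} A minimum separation")


def make_de_fluid(
    n_particles: int,
    *,
    epsilon: float = 0.2,
    r_m: float = 3.5,
    density_reduced: float = 0.05,
    shape: GlobalShape | None = None,
    seed: int = 0,
    solute_params: PairParams | None = None,
) -> tuple[InteractingSystem, Configuration]:
    """A box of single-site DE particles (a toy monatomic fluid).

    ``density_reduced`` is particles per r_m^3.  If ``solute_params`` is
    given the first particle becomes a tagged solute with those parameters.
    """
    if n_particles < 2:
        raise ValueError("need at least two particles")
    shape = shape or GlobalShape(16.766, 4.427)
    rng = np.random.default_rng(seed)
    volume = n_particles * r_m**3 / density_reduced
    edge = volume ** (1.0 / 3.0)
    cells = math.ceil(n_particles ** (1.0 / 3.0))
    spacing = edge / cells
    points = []
    for i in range(cells):
        for j in range(cells):
            for k in range(cells):
                points.append((np.array([i, j, k]) + 0.5) * spacing)
    order = rng.permutation(len(points))[:n_particles]
    coords = np.array([points[i] for i in order]) + rng.uniform(
        -0.1 * spacing, 0.1 * spacing, (n_particles, 3)
    )
    eps = np.full(n_particles, epsilon)
    rms = np.full(n_particles, r_m)
    solute = None
    if solute_params is not None:
        eps[0], rms[0] = solute_params.epsilon, solute_params.r_m
        solute = 0
    system = InteractingSystem(
        eps,
        rms,
        np.zeros(n_particles),
        np.arange(n_particles),
        shape,
        cutoff=min(9.0, edge / 2.0),
        switch_width=min(1.0, 0.25 * edge / 2.0),
        masses=np.full(n_particles, 16.04),
        solute_mol=solute,
    )
    return system, Configuration(coords, np.full(3, edge))


_TOY_SOLUTES = {
    # noble-gas-like probe: fast-relaxing single site for scaled-down
    # free-energy studies (well depth/position in the neon range)
    "neon_ua": dict(
        elements=["Ne"],
        charges=[0.0],
        bonds=[],
        coords=[[0.0, 0.0, 0.0]],
        params=[PairParams(0.069, 3.1)],
    ),
    "methane_ua": dict(
        elements=["C"],
        charges=[0.0],
        bonds=[],
        coords=[[0.0, 0.0, 0.0]],
        params=[PairParams(0.2, 4.0)],
    ),
    "ethanol3": dict(
        elements=["C", "C", "O"],
        charges=[0.0, 0.25, -0.25],
        bonds=[(0, 1, 1.0), (1, 2, 1.0)],
        coords=[[0.0, 0.0, 0.0], [1.54, 0.0, 0.0], [2.02, 1.33, 0.0]],
        params=[PairParams(0.18, 3.9), PairParams(0.12, 3.8), PairParams(0.2, 3.4)],
    ),
}


def make_toy_solute(
    spec: str,
    charges=None,
    de_params: list[PairParams] | None = None,
    library: ParameterLibrary | None = None,
) -> tuple[MolecularGraph, list[PairParams]]:
    """A rigid toy solute ready for alchemical tagging.

    ``spec`` is a packaged name ("methane_ua", "ethanol3") or a SMILES
    string.  SMILES solutes get RDKit-embedded coordinates and library-
    assigned parameters (unparameterised elements are rejected); explicit
    ``charges``/``de_params`` win over defaults.
    """
    if spec in _TOY_SOLUTES:
        d = _TOY_SOLUTES[spec]
        q = np.asarray(charges if charges is not None else d["charges"], float)
        graph = MolecularGraph(
            elements=list(d["elements"]),
            formal_charges=[0] * len(d["elements"]),
            partial_charges=q,
            bonds=list(d["bonds"]),
            coordinates=np.asarray(d["coords"], float),
        )
        return graph, list(de_params if de_params is not None else d["params"])

    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(spec)
    if mol is None:
        raise ValueError(f"unknown solute spec {spec!r}")
    mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=7)
    coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    graph = MolecularGraph.from_smiles(spec, partial_charges=charges, coordinates=coords)
    library = library or fixture_library()
    params, _ = assign_parameters(graph, library)
    if de_params is not None:
        params = list(de_params)
    return graph, params
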