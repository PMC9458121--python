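"""Synthetic test systems, file writers, and an independent energy oracle.

Every recipe produces a small, fully parameterized system whose force-field
palette is anchored on the canonical printed AMBER records (the HP
Lennard-Jones type, the CT-HC bond, the C-N-H angle, the NJ-CJ-ND-CK
cosine series and the CJ-NJ-CD-NH improper): bonds are 340 kcal/mol/A^2 at
1.09 A, angles 50 kcal/mol/rad^2 at 120.0001 deg, torsions carry a single
4.75 kcal/mol two-fold term with a 180 deg phase, impropers 1.1 kcal/mol
with period 2.  Positions are quantized to 0.001 A so the PDB, inpcrd and
in-memory representations agree exactly.

:func:`brute_force_energy` re-implements the whole Hamiltonian with naive
scalar loops, its own geometry formulas (projection-based dihedrals,
atan2-based angles) and networkx shortest paths for the 1-2/1-3/1-4
classification; it shares no evaluation code with the energy engine and
serves as the package's independent oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from .errors import GenerationError
from .params import (
    PRMTOP_CHARGE_FACTOR,
    AngleParams,
    BondParams,
    ImproperParams,
    ParameterSet,
    TorsionParams,
    AtomTypeParams,
    combine_lj,
)
from .energy import CONSTANTS, PhysicalConstants
from .topology import (
    Atom,
    ConnectivityGraph,
    MolecularSystem,
    build_system,
)

__all__ = [
    "PRINTED_PARAM_BLOCK",
    "FixtureSpec",
    "make_fixture",
    "brute_force_energy",
    "write_prmtop",
    "write_inpcrd",
    "write_pdb",
]

#: The canonical Gaussian-style parameter records used throughout the
#: test systems (one record of each kind).
PRINTED_PARAM_BLOCK = """\
VDW HP     1.1000     0.0157
HrmStr1 CT HC 340.00 1.0900
HrmBnd1    C    N    H 50.00 120.0001
AmbTrs NJ CJ ND CK    0 180 0    0 0.000    4.750    0.000    0.000 1.0
ImpTrs CJ NJ CD NH     1.1    180.0 2.0
"""

# palette constants (values of the canonical records above)
BOND_K, BOND_L0 = 340.0, 1.09
ANGLE_K, ANGLE_THETA0 = 50.0, 120.0001
TORSION_PHASES = (0.0, 180.0, 0.0, 0.0)
TORSION_MAGS = (0.0, 4.75, 0.0, 0.0)
TORSION_NPATHS = 1.0
IMP_K, IMP_PHASE, IMP_PERIOD = 1.1, 180.0, 2.0

# per-type LJ parameters anchored on the canonical HP record (1.10, 0.0157),
# with mild spread so type-mixing bugs are visible
_TYPE_CYCLE = ("CT", "HC", "C", "N")
_VDW = {
    "CT": (1.1000, 0.0157),
    "HC": (0.9000, 0.0100),
    "C": (1.2000, 0.0300),
    "N": (1.3000, 0.0500),
}
_ELEMENT = {"CT": 6, "HC": 1, "C": 6, "N": 7}
_MASS = {"CT": 12.01, "HC": 1.008, "C": 12.01, "N": 14.01}

#: improper parameters exist only for centres of this type, so
#: 3-coordinated centres of other types exercise the warning path
_IMPROPER_CENTRE_TYPE = "C"

RECIPES = ("chain", "star", "ring", "two-molecule", "random")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe name, atom count, and seed; same spec => same system."""

    recipe: str
    n_atoms: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; choose from {RECIPES}")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")


# ---------------------------------------------------------------------------
# Recipe construction
# ---------------------------------------------------------------------------

def _palette_for(
    graph: ConnectivityGraph, types: List[str]
) -> ParameterSet:
    """Generate every parameter record the enumerated terms will need."""
    params = ParameterSet()
    for t in sorted(set(types)):
        r, eps = _VDW[t]
        params.add_vdw(AtomTypeParams(t, r, eps))
    for i, j in graph.bonds():
        if params.get_bond((types[i], types[j])) is None:
            params.add_bond(BondParams((types[i], types[j]), BOND_K, BOND_L0))
    for j in range(graph.n_atoms):
        nbrs = sorted(graph.neighbors(j))
        for i, k in itertools.combinations(nbrs, 2):
            key = (types[i], types[j], types[k])
            if params.get_angle(key) is None:
                params.add_angle(AngleParams(key, ANGLE_K, ANGLE_THETA0))
        if len(nbrs) == 3 and types[j] == _IMPROPER_CENTRE_TYPE:
            a, b, d = nbrs
            key4 = (types[a], types[b], types[j], types[d])
            if params.get_improper(key4) is None:
                params.add_improper(ImproperParams(key4, IMP_K, IMP_PHASE, IMP_PERIOD))
    for j, k in graph.bonds():
        for i in graph.neighbors(j) - {k}:
            for l in graph.neighbors(k) - {j}:
                if i == l:
                    continue
                key = (types[i], types[j], types[k], types[l])
                if params.get_torsion(key) is None:
                    params.add_torsion(
                        TorsionParams(key, TORSION_PHASES, TORSION_MAGS, TORSION_NPATHS)
                    )
    return params


def _quantize(coords: np.ndarray) -> np.ndarray:
    return np.round(coords, 3)


def _chain_positions(n: int, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    pos = np.zeros((n, 3))
    for i in range(n):
        pos[i] = (1.0 * i + origin[0], 0.5 * (i % 2) + origin[1], 0.1 * (i % 3) + origin[2])
    return pos


def _assemble(
    graph: ConnectivityGraph,
    coords: np.ndarray,
    charges: List[float],
    types: Optional[List[str]] = None,
) -> MolecularSystem:
    n = graph.n_atoms
    if types is None:
        types = [_TYPE_CYCLE[i % len(_TYPE_CYCLE)] for i in range(n)]
    params = _palette_for(graph, types)
    atoms = [
        Atom(index=i, type_name=types[i], charge=charges[i],
             name=f"{types[i][0]}{i + 1}")
        for i in range(n)
    ]
    system = build_system(atoms, graph, params)
    system.set_positions(_quantize(coords))
    return system


def _alternating_charges(n: int) -> List[float]:
    return [0.1 if i % 2 == 0 else -0.1 for i in range(n)]


def make_fixture(spec: FixtureSpec) -> MolecularSystem:
    """Build the synthetic system described by ``spec``.

    Recipes: ``chain`` (path graph, the canonical 1-2/1-3/1-4 ladder),
    ``star`` (atom 0 bonded to all others), ``ring`` (cycle), ``two-molecule``
    (two disconnected chains 4 A apart), ``random`` (seeded random tree with
    1.0-1.6 A bonds and ring closures between nearby atoms, charges uniform
    in [-1, 1] e, positions inside a 20 A box with minimum pair separation
    0.8 A).
    """
    n = spec.n_atoms
    if spec.recipe == "chain":
        graph = ConnectivityGraph(n, [(i, i + 1) for i in range(n - 1)])
        return _assemble(graph, _chain_positions(n), _alternating_charges(n))

    if spec.recipe == "ring":
        if n < 3:
            raise ValueError("ring recipe needs at least 3 atoms")
        graph = ConnectivityGraph(
            n, [(i, (i + 1) % n) for i in range(n)]
        )
        radius = 1.4 / (2.0 * math.sin(math.pi / n))
        coords = np.array(
            [
                (
                    radius * math.cos(2 * math.pi * i / n),
                    radius * math.sin(2 * math.pi * i / n),
                    0.15 * (i % 2),
                )
                for i in range(n)
            ]
        )
        return _assemble(graph, coords, _alternating_charges(n))

    if spec.recipe == "star":
        if n < 2:
            raise ValueError("star recipe needs at least 2 atoms")
        graph = ConnectivityGraph(n, [(0, i) for i in range(1, n)])
        coords = np.zeros((n, 3))
        golden = math.pi * (3.0 - math.sqrt(5.0))
        for i in range(1, n):
            k = i - 1
            z = 1.0 - 2.0 * (k + 0.5) / (n - 1)
            rho = math.sqrt(max(0.0, 1.0 - z * z))
            coords[i] = (1.1 * rho * math.cos(golden * k), 1.1 * rho * math.sin(golden * k), 1.1 * z)
        # centre gets type C so stars with 3 arms carry a parameterized improper
        types = ["C"] + [_TYPE_CYCLE[i % len(_TYPE_CYCLE)] for i in range(1, n)]
        return _assemble(graph, coords, _alternating_charges(n), types)

    if spec.recipe == "two-molecule":
        if n < 2:
            raise ValueError("two-molecule recipe needs at least 2 atoms")
        n1 = n // 2
        n2 = n - n1
        graph = ConnectivityGraph(n)
        for i in range(n1 - 1):
            graph.add_bond(i, i + 1)
        for i in range(n2 - 1):
            graph.add_bond(n1 + i, n1 + i + 1)
        coords = np.vstack(
            [_chain_positions(n1), _chain_positions(n2, origin=(0.3, 4.0, 0.6))]
        )
        return _assemble(graph, coords, _alternating_charges(n))

    # random: a seeded random tree with chemically sensible bond lengths
    # (each atom near its parent), ring closures between nearby atoms,
    # everything inside a 20 A box with 0.8 A minimum pair separation
    rng = np.random.default_rng(spec.seed)
    graph = ConnectivityGraph(n)
    parents = [int(rng.integers(0, i)) for i in range(1, n)]
    for i, par in enumerate(parents, start=1):
        graph.add_bond(par, i)
    coords = np.zeros((n, 3))
    coords[0] = rng.uniform(5.0, 15.0, size=3)
    for i in range(1, n):
        par = parents[i - 1]
        for _attempt in range(10000):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = coords[par] + rng.uniform(1.0, 1.6) * direction
            if np.all((cand >= 0.0) & (cand <= 20.0)) and np.min(
                np.linalg.norm(coords[:i] - cand, axis=1)
            ) >= 0.802:
                coords[i] = cand
                break
        else:
            raise GenerationError(
                f"could not place atom {i} with 0.8 A separation in the 20 A box"
            )
    # close a few rings between atoms that happen to sit close together
    for _ in range(n // 10):
        i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
        if (
            i != j
            and j not in graph.neighbors(i)
            and np.linalg.norm(coords[i] - coords[j]) < 2.0
        ):
            graph.add_bond(i, j)
    charges = [float(q) for q in rng.uniform(-1.0, 1.0, size=n)]
    return _assemble(graph, coords, charges)


# ---------------------------------------------------------------------------
# File writers (PRMTOP / inpcrd / PDB)
# ---------------------------------------------------------------------------

def _section(name: str, fmt: str, values, render, per_line: int) -> List[str]:
    lines = [f"%FLAG {name}", f"%FORMAT({fmt})"]
    if not values:
        lines.append("")
        return lines
    for start in range(0, len(values), per_line):
        lines.append("".join(render(v) for v in values[start : start + per_line]))
    return lines


def _int_section(name: str, values) -> List[str]:
    return _section(name, "10I8", list(values), lambda v: f"{v:8d}", 10)


def _float_section(name: str, values) -> List[str]:
    return _section(name, "3E24.16", list(values), lambda v: f"{v:24.16E}", 3)


def _str_section(name: str, values) -> List[str]:
    return _section(name, "20a4", list(values), lambda v: f"{v:<4s}", 20)


def write_prmtop(system: MolecularSystem, path, title: str = "synthetic fixture") -> None:
    """Write a PARM7-style topology that round-trips through the reader."""
    n = system.n_atoms
    types = system.type_names
    labels: List[str] = []
    for t in types:
        if t not in labels:
            labels.append(t)
    ntypes = len(labels)
    type_index = [labels.index(t) + 1 for t in types]

    # packed LJ upper triangle via the combination rule
    npairs = ntypes * (ntypes + 1) // 2
    acoef = [0.0] * npairs
    bcoef = [0.0] * npairs
    nb_index = [0] * (ntypes * ntypes)

    def packed(i: int, j: int) -> int:  # 1-based i <= j
        return j * (j - 1) // 2 + i

    for i in range(1, ntypes + 1):
        for j in range(i, ntypes + 1):
            pi_ = packed(i, j)
            a = system.params.get_vdw(labels[i - 1])
            b = system.params.get_vdw(labels[j - 1])
            co = combine_lj(a, b)
            acoef[pi_ - 1] = co.a_coef
            bcoef[pi_ - 1] = co.b_coef
            nb_index[(i - 1) * ntypes + (j - 1)] = pi_
            nb_index[(j - 1) * ntypes + (i - 1)] = pi_

    # bonded parameter pools keyed by record identity
    bond_pool: Dict[Tuple[float, float], int] = {}
    bond_entries: List[int] = []
    for i, j in system.terms.bonds:
        rec = system.params.get_bond((types[i], types[j]))
        key = (rec.force_constant, rec.eq_length)
        pi_ = bond_pool.setdefault(key, len(bond_pool) + 1)
        bond_entries += [3 * i, 3 * j, pi_]

    angle_pool: Dict[Tuple[float, float], int] = {}
    angle_entries: List[int] = []
    for i, j, k in system.terms.angles:
        rec = system.params.get_angle((types[i], types[j], types[k]))
        key = (rec.force_constant, math.radians(rec.eq_angle))
        pi_ = angle_pool.setdefault(key, len(angle_pool) + 1)
        angle_entries += [3 * i, 3 * j, 3 * k, pi_]

    dihedral_pool: Dict[Tuple[float, float, float], int] = {}
    dihedral_entries: List[int] = []
    seen_14: set = set()

    def dihedral_param(kd: float, period: float, phase_deg: float) -> int:
        key = (kd, period, math.radians(phase_deg))
        return dihedral_pool.setdefault(key, len(dihedral_pool) + 1)

    for i, j, k, l in system.terms.torsions:
        rec = system.params.get_torsion((types[i], types[j], types[k], types[l]))
        slots = [
            (sl + 1, rec.magnitudes[sl], rec.phase_offsets[sl])
            for sl in range(4)
            if rec.magnitudes[sl] != 0.0
        ] or [(1, 0.0, rec.phase_offsets[0])]
        pair = (min(i, l), max(i, l))
        needs_flag = pair in seen_14
        if (needs_flag or len(slots) > 1) and k == 0:
            # a negative index cannot encode atom 0; reverse the quadruple
            i, j, k, l = l, k, j, i
        for s_i, (period, kd, phase) in enumerate(slots):
            pi_ = dihedral_param(kd / rec.n_paths, float(period), phase)
            k_enc = 3 * k
            if s_i > 0 or needs_flag:
                k_enc = -k_enc
            dihedral_entries += [3 * i, 3 * j, k_enc, 3 * l, pi_]
        seen_14.add(pair)
    for i, j, k, l in system.terms.impropers:
        rec = system.params.get_improper((types[i], types[j], types[k], types[l]))
        if l == 0:
            # the improper flag is a negative fourth index; keep atom 0 out
            i, l = l, i
        pi_ = dihedral_param(rec.magnitude, rec.period, rec.phase)
        dihedral_entries += [3 * i, 3 * j, -(3 * k), -(3 * l), pi_]

    n_dihedrals = len(dihedral_entries) // 5
    pointers = [0] * 31
    pointers[0] = n
    pointers[1] = ntypes
    pointers[3] = len(system.terms.bonds)  # MBONA (all bonds written H-free)
    pointers[5] = len(system.terms.angles)
    pointers[7] = n_dihedrals
    pointers[11] = 1  # NRES
    pointers[12] = len(system.terms.bonds)
    pointers[13] = len(system.terms.angles)
    pointers[14] = n_dihedrals
    pointers[15] = len(bond_pool)
    pointers[16] = len(angle_pool)
    pointers[17] = len(dihedral_pool)
    pointers[18] = ntypes

    def pool_values(pool, slot):
        ordered = sorted(pool.items(), key=lambda kv: kv[1])
        return [key[slot] for key, _ in ordered]

    lines: List[str] = ["%VERSION  VERSION_STAMP = V0001.000"]
    lines += ["%FLAG TITLE", "%FORMAT(20a4)", title[:80]]
    lines += _int_section("POINTERS", pointers)
    lines += _str_section("ATOM_NAME", [a.name or a.type_name for a in system.atoms])
    lines += _float_section(
        "CHARGE", [a.charge * PRMTOP_CHARGE_FACTOR for a in system.atoms]
    )
    lines += _int_section("ATOMIC_NUMBER", [_ELEMENT.get(t, 0) for t in types])
    lines += _float_section("MASS", [_MASS.get(t, 1.0) for t in types])
    lines += _int_section("ATOM_TYPE_INDEX", type_index)
    lines += _int_section("NONBONDED_PARM_INDEX", nb_index)
    lines += _str_section("RESIDUE_LABEL", ["MOL"])
    lines += _int_section("RESIDUE_POINTER", [1])
    lines += _float_section("BOND_FORCE_CONSTANT", pool_values(bond_pool, 0))
    lines += _float_section("BOND_EQUIL_VALUE", pool_values(bond_pool, 1))
    lines += _float_section("ANGLE_FORCE_CONSTANT", pool_values(angle_pool, 0))
    lines += _float_section("ANGLE_EQUIL_VALUE", pool_values(angle_pool, 1))
    lines += _float_section("DIHEDRAL_FORCE_CONSTANT", pool_values(dihedral_pool, 0))
    lines += _float_section("DIHEDRAL_PERIODICITY", pool_values(dihedral_pool, 1))
    lines += _float_section("DIHEDRAL_PHASE", pool_values(dihedral_pool, 2))
    lines += _float_section("LENNARD_JONES_ACOEF", acoef)
    lines += _float_section("LENNARD_JONES_BCOEF", bcoef)
    lines += _int_section("BONDS_INC_HYDROGEN", [])
    lines += _int_section("BONDS_WITHOUT_HYDROGEN", bond_entries)
    lines += _int_section("ANGLES_INC_HYDROGEN", [])
    lines += _int_section("ANGLES_WITHOUT_HYDROGEN", angle_entries)
    lines += _int_section("DIHEDRALS_INC_HYDROGEN", [])
    lines += _int_section("DIHEDRALS_WITHOUT_HYDROGEN", dihedral_entries)
    lines += _str_section("AMBER_ATOM_TYPE", types)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_inpcrd(system: MolecularSystem, path, title: str = "synthetic fixture") -> None:
    """AMBER ASCII restart: title, atom count, then 6F12.7 coordinates."""
    pos = system.positions
    lines = [title, f"{system.n_atoms:5d}"]
    flat = pos.reshape(-1)
    for start in range(0, len(flat), 6):
        lines.append("".join(f"{v:12.7f}" for v in flat[start : start + 6]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pdb(system: MolecularSystem, path) -> None:
    """Minimal PDB with one ATOM record per atom (coordinates to 0.001 A)."""
    pos = system.positions
    lines = []
    for atom, (x, y, z) in zip(system.atoms, pos):
        name = (atom.name or atom.type_name)[:4]
        lines.append(
            f"ATOM  {atom.index + 1:5d} {name:<4s}{atom.residue_name[:3]:<3s}  "
            f"{atom.residue_id + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Independent brute-force oracle
# ---------------------------------------------------------------------------

def _o_dist(p, q) -> float:
    return math.sqrt(
        (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2
    )


def _o_sub(p, q):
    return (p[0] - q[0], p[1] - q[1], p[2] - q[2])


def _o_dot(u, v) -> float:
    return u[0] * v[0] + u[1] * v[1] + u[2] * v[2]


def _o_cross(u, v):
    return (
        u[1] * v[2] - u[2] * v[1],
        u[2] * v[0] - u[0] * v[2],
        u[0] * v[1] - u[1] * v[0],
    )


def _o_angle(p0, p1, p2) -> float:
    u = _o_sub(p0, p1)
    v = _o_sub(p2, p1)
    cr = _o_cross(u, v)
    return math.atan2(math.sqrt(_o_dot(cr, cr)), _o_dot(u, v))


def _o_dihedral(p0, p1, p2, p3) -> float:
    # projection construction (independent of the plane-normal kernel)
    b0 = _o_sub(p0, p1)
    b1 = _o_sub(p2, p1)
    b2 = _o_sub(p3, p2)
    nb1 = math.sqrt(_o_dot(b1, b1))
    b1u = (b1[0] / nb1, b1[1] / nb1, b1[2] / nb1)
    d0 = _o_dot(b0, b1u)
    d2 = _o_dot(b2, b1u)
    v = (b0[0] - d0 * b1u[0], b0[1] - d0 * b1u[1], b0[2] - d0 * b1u[2])
    w = (b2[0] - d2 * b1u[0], b2[1] - d2 * b1u[1], b2[2] - d2 * b1u[2])
    x = _o_dot(v, w)
    y = _o_dot(_o_cross(b1u, v), w)
    return math.atan2(y, x)


def brute_force_energy(
    system: MolecularSystem, constants: PhysicalConstants = CONSTANTS
) -> Dict[str, float]:
    """Naive re-evaluation of every term; the package's independent oracle.

    Returns per-class totals under the report section names plus
    ``"total"``.  Geometry, pair classification (networkx shortest paths)
    and accumulation are all coded separately from the energy engine.
    """
    pos = [tuple(map(float, a.position)) for a in system.atoms]
    types = system.type_names
    p = system.params

    bond_terms = []
    for i, j in system.terms.bonds:
        rec = p.bond_table.get((types[i], types[j])) or p.bond_table.get(
            (types[j], types[i])
        )
        d = _o_dist(pos[i], pos[j])
        bond_terms.append(rec.force_constant * (d - rec.eq_length) ** 2)

    angle_terms = []
    for i, j, k in system.terms.angles:
        rec = p.angle_table.get((types[i], types[j], types[k])) or p.angle_table.get(
            (types[k], types[j], types[i])
        )
        th = _o_angle(pos[i], pos[j], pos[k])
        angle_terms.append(
            rec.force_constant * (th - rec.eq_angle * math.pi / 180.0) ** 2
        )

    torsion_terms = []
    for i, j, k, l in system.terms.torsions:
        quad = (types[i], types[j], types[k], types[l])
        rec = p.torsion_table.get(quad) or p.torsion_table.get(quad[::-1])
        phi = _o_dihedral(pos[i], pos[j], pos[k], pos[l])
        acc = 0.0
        for s in range(4):
            acc += rec.magnitudes[s] * (
                1.0 + math.cos((s + 1) * phi - rec.phase_offsets[s] * math.pi / 180.0)
            )
        torsion_terms.append(acc / rec.n_paths)

    improper_terms = []
    for i, j, k, l in system.terms.impropers:
        key = (tuple(sorted((types[i], types[j], types[l]))), types[k])
        rec = p.improper_table[key]
        sig = _o_dihedral(pos[i], pos[j], pos[k], pos[l])
        improper_terms.append(
            rec.magnitude * (1.0 - math.cos(rec.period * (sig - rec.phase * math.pi / 180.0)))
        )

    # nonbonded with networkx minimal bond-path classification
    g = nx.Graph()
    g.add_nodes_from(range(system.n_atoms))
    for i, nbrs in system.graph.adjacency.items():
        for j in nbrs:
            g.add_edge(i, j)
    near: Dict[Tuple[int, int], int] = {}
    for i in range(system.n_atoms):
        for j, d in nx.single_source_shortest_path_length(g, i, cutoff=3).items():
            if j > i and d >= 1:
                near[(i, j)] = d

    vdw_terms = []
    coul_terms = []
    charges = [a.charge for a in system.atoms]
    for i in range(system.n_atoms):
        for j in range(i + 1, system.n_atoms):
            depth = near.get((i, j))
            if depth in (1, 2):
                continue
            if depth == 3:
                s_lj, s_cl = constants.lj_14_scale, constants.coulomb_14_scale
            else:
                s_lj, s_cl = 1.0, 1.0
            r = _o_dist(pos[i], pos[j])
            ti, tj = p.vdw_table[types[i]], p.vdw_table[types[j]]
            eps = math.sqrt(ti.well_depth * tj.well_depth)
            dd = ti.radius + tj.radius
            a_c = eps * dd**12
            b_c = 2.0 * eps * dd**6
            vdw_terms.append(s_lj * (a_c / r**12 - b_c / r**6))
            coul_terms.append(
                s_cl * constants.coulomb_prefactor * charges[i] * charges[j] / r
            )

    # exact accumulation: the oracle should not add its own rounding noise
    out = {
        "Bonds": math.fsum(bond_terms),
        "Angles": math.fsum(angle_terms),
        "Torsions": math.fsum(torsion_terms),
        "Out-of-Plane": math.fsum(improper_terms),
        "VDW": math.fsum(vdw_terms),
        "Coulomb": math.fsum(coul_terms),
    }
    out["total"] = math.fsum(out.values())
    return out
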