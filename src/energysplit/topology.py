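"""Molecular system representation and bonded-term enumeration.

Atoms are 0-based everywhere.  All bonded-term instances (angles, proper
torsions, improper candidates) and the nonbonded 1-2/1-3/1-4 pair
classification are derived from covalent connectivity alone, so a topology
plus a parameter set is enough to evaluate the full force field.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import CoordinateFormatError, PrmtopFormatError
from .params import PRMTOP_CHARGE_FACTOR, ParameterSet, params_from_prmtop
from .prmtop import PrmtopFile

__all__ = [
    "Atom",
    "ConnectivityGraph",
    "TermTable",
    "PathScaleMap",
    "MolecularSystem",
    "build_system",
    "read_prmtop_topology",
    "read_coordinates",
    "enumerate_angles",
    "enumerate_torsions",
    "enumerate_impropers",
    "classify_pairs",
]

EXCLUDED_12 = "excluded_12"
EXCLUDED_13 = "excluded_13"
SCALED_14 = "scaled_14"
FULL = "full"


@dataclass
class Atom:
    """One atom: force-field type, charge (e), position (A)."""

    index: int
    type_name: str
    charge: float
    position: Optional[np.ndarray] = None
    residue_id: int = 0
    residue_name: str = "MOL"
    name: str = ""


class ConnectivityGraph:
    """Symmetric covalent adjacency over atom indices 0..n-1."""

    def __init__(self, n_atoms: int, bonds: Iterable[Tuple[int, int]] = ()):
        self.n_atoms = n_atoms
        self.adjacency: Dict[int, Set[int]] = {i: set() for i in range(n_atoms)}
        for i, j in bonds:
            self.add_bond(i, j)

    def add_bond(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError(f"self-bond on atom {i}")
        if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
            raise ValueError(f"bond ({i},{j}) outside 0..{self.n_atoms - 1}")
        self.adjacency[i].add(j)
        self.adjacency[j].add(i)

    def neighbors(self, i: int) -> Set[int]:
        return self.adjacency[i]

    def bonds(self) -> List[Tuple[int, int]]:
        """Each covalent bond once, as (i, j) with i < j, sorted."""
        return sorted(
            (i, j) for i, nbrs in self.adjacency.items() for j in nbrs if i < j
        )


def enumerate_angles(graph: ConnectivityGraph) -> List[Tuple[int, int, int]]:
    """All bend angles (i, j, k), j central, canonical orientation i < k."""
    out = []
    for j in range(graph.n_atoms):
        for i, k in itertools.combinations(sorted(graph.neighbors(j)), 2):
            out.append((i, j, k))
    return out


def enumerate_torsions(graph: ConnectivityGraph) -> List[Tuple[int, int, int, int]]:
    """All proper torsions: simple 4-atom paths, deduplicated under reversal."""
    out = []
    for j, k in graph.bonds():
        for i in sorted(graph.neighbors(j) - {k}):
            for l in sorted(graph.neighbors(k) - {j}):
                if i == l:
                    continue  # 3-ring: not a simple path
                t = (i, j, k, l)
                out.append(min(t, t[::-1]))
    # a 4-cycle produces each ring-closing torsion from one central bond only,
    # but sort for a stable order
    return sorted(set(out))


def enumerate_impropers(
    graph: ConnectivityGraph,
    params: ParameterSet,
    type_names: Sequence[str],
) -> Tuple[List[Tuple[int, int, int, int]], List[str]]:
    """Improper (out-of-plane) terms for every exactly-3-coordinated centre.

    For a candidate centre ``c`` with neighbours sorted by index, the
    orderings of the three non-central atoms are tried in lexicographic
    order against the improper table (the centre stays third); the first
    type match is emitted.  Centres without parameters produce a warning
    and no term — never an error.
    """
    terms: List[Tuple[int, int, int, int]] = []
    warnings: List[str] = []
    for c in range(graph.n_atoms):
        nbrs = sorted(graph.neighbors(c))
        if len(nbrs) != 3:
            continue
        match = None
        for a, b, d in itertools.permutations(nbrs):
            types = (type_names[a], type_names[b], type_names[c], type_names[d])
            if params.get_improper(types) is not None:
                match = (a, b, c, d)
                break
        if match is None:
            warnings.append(
                f"no improper parameters for centre atom {c} "
                f"(type {type_names[c]}, neighbours {nbrs}); term skipped"
            )
        else:
            terms.append(match)
    return terms, warnings


class PathScaleMap:
    """Per-pair nonbonded classification from minimal bond-path length.

    1 bond -> excluded_12, 2 -> excluded_13, 3 -> scaled_14, >= 4 bonds or
    disconnected -> full.  Only the non-full pairs are stored; lookups are
    symmetric and total.
    """

    _BY_DEPTH = {1: EXCLUDED_12, 2: EXCLUDED_13, 3: SCALED_14}

    def __init__(self, near: Dict[Tuple[int, int], int]):
        self._near = near  # (i<j) -> minimal path length in {1,2,3}

    def classification(self, i: int, j: int) -> str:
        if i == j:
            raise ValueError("pair classification needs two distinct atoms")
        key = (i, j) if i < j else (j, i)
        depth = self._near.get(key)
        return FULL if depth is None else self._BY_DEPTH[depth]

    def items(self):
        """Stored non-full pairs as ((i, j), classification)."""
        for key, depth in self._near.items():
            yield key, self._BY_DEPTH[depth]


def classify_pairs(graph: ConnectivityGraph) -> PathScaleMap:
    """Breadth-first search from every atom, truncated at depth 3.

    Ring closures take the shorter path (e.g. opposite atoms of a 4-cycle
    are 1-3, not 1-5), matching standard AMBER exclusion-list semantics.
    """
    near: Dict[Tuple[int, int], int] = {}
    for src in range(graph.n_atoms):
        depths = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            if depths[u] == 3:
                continue
            for v in graph.neighbors(u):
                if v not in depths:
                    depths[v] = depths[u] + 1
                    queue.append(v)
        for v, d in depths.items():
            if v > src and d >= 1:
                near[(src, v)] = d
    return PathScaleMap(near)


@dataclass
class TermTable:
    """Enumerated bonded-term instances (atom-index tuples)."""

    bonds: List[Tuple[int, int]] = field(default_factory=list)
    angles: List[Tuple[int, int, int]] = field(default_factory=list)
    torsions: List[Tuple[int, int, int, int]] = field(default_factory=list)
    impropers: List[Tuple[int, int, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bonds) + len(self.angles) + len(self.torsions) + len(self.impropers)


@dataclass
class MolecularSystem:
    """Atoms + connectivity + enumerated terms + parameters."""

    atoms: List[Atom]
    graph: ConnectivityGraph
    terms: TermTable
    params: ParameterSet
    improper_warnings: List[str] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def type_names(self) -> List[str]:
        return [a.type_name for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def has_positions(self) -> bool:
        return all(a.position is not None for a in self.atoms)

    @property
    def positions(self) -> np.ndarray:
        if not self.has_positions:
            raise ValueError("system has no coordinates attached")
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_positions(self, coords: np.ndarray) -> "MolecularSystem":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        for atom, row in zip(self.atoms, coords):
            atom.position = row.copy()
        return self


def build_system(
    atoms: List[Atom], graph: ConnectivityGraph, params: ParameterSet
) -> MolecularSystem:
    """Enumerate every bonded-term instance and assemble a system."""
    type_names = [a.type_name for a in atoms]
    impropers, warnings = enumerate_impropers(graph, params, type_names)
    terms = TermTable(
        bonds=graph.bonds(),
        angles=enumerate_angles(graph),
        torsions=enumerate_torsions(graph),
        impropers=impropers,
    )
    return MolecularSystem(atoms, graph, terms, params, warnings)


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def read_prmtop_topology(path) -> MolecularSystem:
    """Load atoms, charges, types, connectivity and parameters from PRMTOP.

    Positions are left unset; attach them with :func:`read_coordinates`.
    Charges are divided by 18.2223 on read to recover elementary-charge
    units.
    """
    pf = PrmtopFile.read(path)
    labels = pf.atom_type_labels
    names = pf.atom_names
    residues = _residue_assignment(pf)
    atoms = [
        Atom(
            index=i,
            type_name=labels[i],
            charge=pf.raw_charges[i] / PRMTOP_CHARGE_FACTOR,
            name=str(names[i]),
            residue_id=residues[i][0],
            residue_name=residues[i][1],
        )
        for i in range(pf.natom)
    ]
    graph = ConnectivityGraph(pf.natom)
    for i, j in pf.bonds:
        if not (0 <= i < pf.natom and 0 <= j < pf.natom):
            raise PrmtopFormatError(f"bond atom index {max(i, j)} out of range")
        graph.add_bond(i, j)
    params = params_from_prmtop(pf)
    return build_system(atoms, graph, params)


def _residue_assignment(pf: PrmtopFile) -> List[Tuple[int, str]]:
    labels = pf.sections.get("RESIDUE_LABEL")
    pointers = pf.sections.get("RESIDUE_POINTER")
    if not labels or not pointers:
        return [(0, "MOL")] * pf.natom
    out: List[Tuple[int, str]] = []
    starts = [p - 1 for p in pointers] + [pf.natom]
    for ri, lab in enumerate(labels):
        for _ in range(starts[ri], starts[ri + 1]):
            out.append((ri, str(lab)))
    if len(out) != pf.natom:
        return [(0, "MOL")] * pf.natom
    return out


def read_coordinates(
    path, fmt: str, system: MolecularSystem, frame: int = 0
) -> MolecularSystem:
    """Attach coordinates from an AMBER inpcrd/restart or a PDB file.

    The atom count must match the system; for multi-frame files the first
    frame is used unless ``frame`` selects another.
    """
    if fmt == "inpcrd":
        coords = _read_inpcrd(path, system.n_atoms, frame)
    elif fmt == "pdb":
        coords = _read_pdb(path, system.n_atoms, frame)
    else:
        raise ValueError(f"unknown coordinate format {fmt!r}")
    return system.set_positions(coords)


def _read_inpcrd(path, n_atoms: int, frame: int) -> np.ndarray:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise CoordinateFormatError(f"{path}: truncated inpcrd file")
    header = lines[1].split()
    try:
        file_natom = int(header[0])
    except (IndexError, ValueError):
        raise CoordinateFormatError(
            f"{path}: line 2: expected the atom count, got {lines[1]!r}"
        ) from None
    if file_natom != n_atoms:
        raise CoordinateFormatError(
            f"{path}: file has {file_natom} atoms, system has {n_atoms}"
        )
    values: List[float] = []
    for lineno, line in enumerate(lines[2:], start=3):
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise CoordinateFormatError(
                    f"{path}: line {lineno}: unparseable numeric field {tok!r}"
                ) from None
    per_frame = 3 * n_atoms
    n_frames = len(values) // per_frame
    if n_frames < 1:
        raise CoordinateFormatError(
            f"{path}: found {len(values)} values, need {per_frame}"
        )
    if not 0 <= frame < n_frames:
        raise CoordinateFormatError(
            f"{path}: frame {frame} requested, file holds {n_frames}"
        )
    chunk = values[frame * per_frame : (frame + 1) * per_frame]
    return np.array(chunk, dtype=float).reshape(n_atoms, 3)


def _read_pdb(path, n_atoms: int, frame: int) -> np.ndarray:
    """Coordinates from ATOM/HETATM records (fixed columns 31-54).

    Parsed in double precision so values written with three decimals are
    recovered exactly.  MODEL/ENDMDL blocks delimit frames.
    """
    frames: List[List[Tuple[float, float, float]]] = [[]]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL") and frames[-1]:
                frames.append([])
            elif line.startswith(("ATOM", "HETATM")):
                try:
                    xyz = (
                        float(line[30:38]),
                        float(line[38:46]),
                        float(line[46:54]),
                    )
                except ValueError:
                    raise CoordinateFormatError(
                        f"{path}: line {lineno}: unparseable coordinates"
                    ) from None
                frames[-1].append(xyz)
    frames = [f for f in frames if f]
    if not frames:
        raise CoordinateFormatError(f"{path}: no ATOM/HETATM records found")
    if not 0 <= frame < len(frames):
        raise CoordinateFormatError(
            f"{path}: frame {frame} requested, file holds {len(frames)}"
        )
    chosen = frames[frame]
    if len(chosen) != n_atoms:
        raise CoordinateFormatError(
            f"{path}: file has {len(chosen)} atoms, system has {n_atoms}"
        )
    return np.array(chosen, dtype=float)
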