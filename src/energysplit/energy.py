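"""Energy kernels and whole-system evaluation for the AMBER Hamiltonian.

E_system = sum_bonds kb (l - l0)^2
         + sum_angles ka (theta - theta0)^2
         + sum_dihedrals sum_{i=1..4} kd_i (1 + cos(i phi - A_i)) / N
         + sum_impropers ki (1 - cos(P (sigma - A)))
         + sum_{i<j} (A_ij / r^12 - B_ij / r^6) * S_LJ
         + sum_{i<j} (1 / 4 pi eps0) q_i q_j / r * S_Coulomb

No cutoff and no periodic boundary conditions: every atom pair enters the
nonbonded sums, scaled by its 1-2/1-3/1-4 classification.  All energies are
kcal/mol, lengths Angstrom, charges elementary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import EvaluationError, MissingParameterError
from .params import AngleParams, BondParams, ImproperParams, TorsionParams
from .topology import (
    EXCLUDED_12,
    EXCLUDED_13,
    FULL,
    SCALED_14,
    MolecularSystem,
    PathScaleMap,
    classify_pairs,
)

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "TermEnergy",
    "EnergyTotals",
    "distance",
    "bend_angle",
    "dihedral_angle",
    "bond_energy",
    "angle_energy",
    "torsion_energy",
    "improper_energy",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "scale_factors",
    "total_energy",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed constants of the Hamiltonian.

    ``coulomb_prefactor`` is 1/(4 pi eps0) in kcal mol^-1 A e^-2; the 1-4
    scales follow the Gaussian 09 convention (Coulomb 1/1.2, LJ 0.5).
    """

    coulomb_prefactor: float = 332.063712827427
    coulomb_14_scale: float = 1.0 / 1.2
    lj_14_scale: float = 0.5


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class TermEnergy:
    term_kind: str
    atom_indexes: Tuple[int, ...]
    energy: float


@dataclass
class EnergyTotals:
    """Per-class subtotals and the grand total, kcal/mol."""

    bonds: float = 0.0
    angles: float = 0.0
    torsions: float = 0.0
    out_of_plane: float = 0.0
    vdw: float = 0.0
    coulomb: float = 0.0
    warnings: List[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return (
            self.bonds + self.angles + self.torsions
            + self.out_of_plane + self.vdw + self.coulomb
        )

    def as_dict(self) -> Dict[str, float]:
        return {
            "Bonds": self.bonds,
            "Angles": self.angles,
            "Torsions": self.torsions,
            "Out-of-Plane": self.out_of_plane,
            "VDW": self.vdw,
            "Coulomb": self.coulomb,
        }


# ---------------------------------------------------------------------------
# Geometry kernels
# ---------------------------------------------------------------------------

def distance(p, q) -> float:
    """Euclidean distance in Angstrom."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return float(np.sqrt(np.dot(d, d)))


def bend_angle(pi, pj, pk, atoms: Optional[Sequence[int]] = None) -> float:
    """Angle at pj in radians, in [0, pi]; the cosine is clamped to [-1, 1]."""
    v1 = np.asarray(pi, dtype=float) - np.asarray(pj, dtype=float)
    v2 = np.asarray(pk, dtype=float) - np.asarray(pj, dtype=float)
    n1 = float(np.sqrt(np.dot(v1, v1)))
    n2 = float(np.sqrt(np.dot(v2, v2)))
    if n1 == 0.0 or n2 == 0.0:
        where = f" (atoms {tuple(atoms)})" if atoms is not None else ""
        raise EvaluationError(f"zero-length arm in angle term{where}")
    c = float(np.dot(v1, v2)) / (n1 * n2)
    return math.acos(max(-1.0, min(1.0, c)))


def dihedral_angle(pi, pj, pk, pl, atoms: Optional[Sequence[int]] = None) -> float:
    """Signed angle between the ijk and jkl planes, in (-pi, pi].

    Plane normals are cross products of the bond vectors; the sign comes
    from the j->k axis.  Invariant under rigid motion of all four points.
    """
    pi, pj, pk, pl = (np.asarray(p, dtype=float) for p in (pi, pj, pk, pl))
    b1, b2, b3 = pj - pi, pk - pj, pl - pk
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = float(np.sqrt(np.dot(n1, n1)))
    norm2 = float(np.sqrt(np.dot(n2, n2)))
    norm_b2 = float(np.sqrt(np.dot(b2, b2)))
    if norm1 == 0.0 or norm2 == 0.0 or norm_b2 == 0.0:
        where = f" (atoms {tuple(atoms)})" if atoms is not None else ""
        raise EvaluationError(f"collinear or coincident atoms in torsion term{where}")
    y = float(np.dot(np.cross(n1, n2), b2)) / norm_b2
    x = float(np.dot(n1, n2))
    phi = math.atan2(y, x)
    return math.pi if phi == -math.pi else phi


# ---------------------------------------------------------------------------
# Term energies
# ---------------------------------------------------------------------------

def bond_energy(params: BondParams, l: float) -> float:
    return params.force_constant * (l - params.eq_length) ** 2


def angle_energy(params: AngleParams, theta: float) -> float:
    theta0 = math.radians(params.eq_angle)
    return params.force_constant * (theta - theta0) ** 2


def torsion_energy(params: TorsionParams, phi: float) -> float:
    if params.n_paths <= 0:
        raise EvaluationError("torsion with non-positive number of paths N")
    total = 0.0
    for i in range(4):
        kd = params.magnitudes[i]
        if kd == 0.0:
            continue
        a_rad = math.radians(params.phase_offsets[i])
        total += kd * (1.0 + math.cos((i + 1) * phi - a_rad))
    return total / params.n_paths


def improper_energy(params: ImproperParams, sigma: float) -> float:
    a_rad = math.radians(params.phase)
    return params.magnitude * (1.0 - math.cos(params.period * (sigma - a_rad)))


def lj_pair_energy(coefs, r: float, scale: float) -> float:
    if scale == 0.0:
        return 0.0
    if r <= 0.0:
        if coefs.a_coef == 0.0 and coefs.b_coef == 0.0:
            return 0.0
        raise EvaluationError("Lennard-Jones pair at zero separation")
    r6 = r**6
    return scale * (coefs.a_coef / (r6 * r6) - coefs.b_coef / r6)


def coulomb_pair_energy(
    qi: float, qj: float, r: float, scale: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    if scale == 0.0:
        return 0.0
    if r <= 0.0:
        raise EvaluationError("Coulomb pair at zero separation")
    return scale * constants.coulomb_prefactor * qi * qj / r


def scale_factors(
    classification: str, constants: PhysicalConstants = CONSTANTS
) -> Tuple[float, float]:
    """(S_LJ, S_Coulomb) for one pair classification."""
    if classification in (EXCLUDED_12, EXCLUDED_13):
        return 0.0, 0.0
    if classification == SCALED_14:
        return constants.lj_14_scale, constants.coulomb_14_scale
    if classification == FULL:
        return 1.0, 1.0
    raise ValueError(f"unknown pair classification {classification!r}")


# ---------------------------------------------------------------------------
# Whole-system evaluation
# ---------------------------------------------------------------------------

def bonded_term_energies(system: MolecularSystem):
    """Yield (kind, atom_indexes, energy) for every bonded-term instance.

    Missing bond/angle/torsion parameters raise
    :class:`MissingParameterError` naming the type sequence; improper terms
    were already filtered at enumeration time.
    """
    pos = system.positions
    types = system.type_names
    params = system.params
    for i, j in system.terms.bonds:
        rec = params.get_bond((types[i], types[j]))
        if rec is None:
            raise MissingParameterError(
                f"no bond parameters for {types[i]}-{types[j]} (atoms {i},{j})"
            )
        yield "bond", (i, j), bond_energy(rec, distance(pos[i], pos[j]))
    for i, j, k in system.terms.angles:
        rec = params.get_angle((types[i], types[j], types[k]))
        if rec is None:
            raise MissingParameterError(
                f"no angle parameters for {types[i]}-{types[j]}-{types[k]} "
                f"(atoms {i},{j},{k})"
            )
        theta = bend_angle(pos[i], pos[j], pos[k], atoms=(i, j, k))
        yield "angle", (i, j, k), angle_energy(rec, theta)
    for i, j, k, l in system.terms.torsions:
        rec = params.get_torsion((types[i], types[j], types[k], types[l]))
        if rec is None:
            raise MissingParameterError(
                f"no torsion parameters for "
                f"{types[i]}-{types[j]}-{types[k]}-{types[l]} (atoms {i},{j},{k},{l})"
            )
        phi = dihedral_angle(pos[i], pos[j], pos[k], pos[l], atoms=(i, j, k, l))
        yield "torsion", (i, j, k, l), torsion_energy(rec, phi)
    for i, j, k, l in system.terms.impropers:
        rec = params.get_improper((types[i], types[j], types[k], types[l]))
        if rec is None:  # pragma: no cover - filtered at enumeration
            continue
        sigma = dihedral_angle(pos[i], pos[j], pos[k], pos[l], atoms=(i, j, k, l))
        yield "improper", (i, j, k, l), improper_energy(rec, sigma)


def nonbonded_pair_arrays(
    system: MolecularSystem,
    pair_map: Optional[PathScaleMap] = None,
    constants: PhysicalConstants = CONSTANTS,
):
    """Vectorized per-pair LJ and Coulomb energies over all i<j pairs.

    Returns ``(ii, jj, e_lj, e_coulomb)`` aligned numpy arrays in ascending
    (i, j) order.  Excluded pairs contribute exact zeros.
    """
    n = system.n_atoms
    if n < 2:
        empty = np.zeros(0)
        return empty.astype(int), empty.astype(int), empty, empty
    if pair_map is None:
        pair_map = classify_pairs(system.graph)
    pos = system.positions
    charges = system.charges
    types = system.type_names

    unique_types = sorted(set(types))
    for t in unique_types:
        if system.params.get_vdw(t) is None:
            raise MissingParameterError(f"no VDW parameters for atom type {t}")
    radius = {t: system.params.get_vdw(t).radius for t in unique_types}
    depth = {t: system.params.get_vdw(t).well_depth for t in unique_types}
    r_atom = np.array([radius[t] for t in types])
    e_atom = np.array([depth[t] for t in types])

    ii, jj = np.triu_indices(n, k=1)
    diff = pos[ii] - pos[jj]
    r = np.sqrt(np.einsum("ij,ij->i", diff, diff))

    s_lj = np.ones(len(ii))
    s_cl = np.ones(len(ii))
    for (i, j), cls in pair_map.items():
        flat = i * n - i * (i + 1) // 2 + (j - i - 1)  # triu flat index
        s_lj[flat], s_cl[flat] = scale_factors(cls, constants)

    eps = np.sqrt(e_atom[ii] * e_atom[jj])
    d = r_atom[ii] + r_atom[jj]
    a = eps * d**12
    b = 2.0 * eps * d**6

    active = (s_lj != 0.0) | (s_cl != 0.0)
    bad = active & (r == 0.0)
    if np.any(bad):
        k = int(np.argmax(bad))
        raise EvaluationError(
            f"nonbonded pair at zero separation (atoms {int(ii[k])},{int(jj[k])})"
        )
    safe_r = np.where(r == 0.0, 1.0, r)
    r6 = safe_r**6
    e_lj = np.where(active, s_lj * (a / (r6 * r6) - b / r6), 0.0)
    e_cl = np.where(
        active,
        s_cl * constants.coulomb_prefactor * charges[ii] * charges[jj] / safe_r,
        0.0,
    )
    return ii, jj, e_lj, e_cl


def _chunked_sum(values: np.ndarray, workers: int) -> float:
    """Deterministic reduction: per-worker partial sums combined in order."""
    workers = max(1, int(workers))
    if workers == 1 or len(values) == 0:
        return float(np.sum(values))
    chunks = np.array_split(values, workers)
    return float(sum(float(np.sum(c)) for c in chunks))


def total_energy(
    system: MolecularSystem,
    workers: int = 1,
    constants: PhysicalConstants = CONSTANTS,
) -> EnergyTotals:
    """Evaluate every term class over the whole system (no cutoff).

    Deterministic: bonded terms accumulate in enumeration order, the
    nonbonded pair loop runs in ascending (i, j) order with per-worker
    partial sums combined in worker-index order.
    """
    totals = EnergyTotals(warnings=list(system.improper_warnings))
    slot = {"bond": "bonds", "angle": "angles", "torsion": "torsions",
            "improper": "out_of_plane"}
    for kind, _, e in bonded_term_energies(system):
        setattr(totals, slot[kind], getattr(totals, slot[kind]) + e)
    _, _, e_lj, e_cl = nonbonded_pair_arrays(system, constants=constants)
    totals.vdw = _chunked_sum(e_lj, workers)
    totals.coulomb = _chunked_sum(e_cl, workers)
    return totals
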