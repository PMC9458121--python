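"""AMBER force-field parameters in the Gaussian-style MM record format.

The five record kinds are whitespace-delimited plain text, one record per
line::

    VDW     HP  1.1000  0.0157              # atom type, R (Angstrom), eps (kcal/mol)
    HrmStr1 CT HC  340.00  1.0900           # bond kb (kcal/mol/A^2), l0 (A)
    HrmBnd1 C N H  50.00  120.0001          # angle ka (kcal/mol/rad^2), theta0 (deg)
    AmbTrs  NJ CJ ND CK 0 180 0 0  0.000 4.750 0.000 0.000  1.0
                                            # phases A1..A4 (deg), kd1..kd4, N paths
    ImpTrs  CJ NJ CD NH  1.1  180.0  2.0    # improper ki, phase A (deg), period P

Angles and phases are stored in degrees, exactly as printed; conversion to
radians happens once, inside the energy kernels.  Lookup keys are
canonicalized so that a bond stored as ``CT HC`` is found when queried as
``HC CT`` (and similarly for angles and proper torsions under reversal).
Improper keys keep the central atom type fixed in the third position while
the other three may appear in any order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

from .errors import ParameterBlockError

__all__ = [
    "AtomTypeParams",
    "BondParams",
    "AngleParams",
    "TorsionParams",
    "ImproperParams",
    "LJPairCoefficients",
    "ParameterSet",
    "parse_gaussian_mm_block",
    "write_gaussian_mm_block",
    "params_from_prmtop",
    "combine_lj",
    "lookup_bonded",
]

#: PRMTOP stores charges premultiplied by this factor (sqrt of the Coulomb
#: prefactor in AMBER's internal units); divide on read to recover charges
#: in elementary-charge units.
PRMTOP_CHARGE_FACTOR = 18.2223


@dataclass(frozen=True)
class AtomTypeParams:
    """Per-type Lennard-Jones parameters: radius R (A) and well depth eps."""

    type_name: str
    radius: float
    well_depth: float

    def __post_init__(self) -> None:
        if not self.type_name:
            raise ValueError("atom type name must be non-empty")
        if self.radius < 0 or self.well_depth < 0:
            raise ValueError(
                f"negative LJ parameters for type {self.type_name!r}"
            )


@dataclass(frozen=True)
class BondParams:
    """Harmonic bond: kb in kcal/mol/A^2, l0 in A."""

    type_pair: Tuple[str, str]
    force_constant: float
    eq_length: float


@dataclass(frozen=True)
class AngleParams:
    """Harmonic angle: ka in kcal/mol/rad^2, theta0 stored in degrees."""

    type_triple: Tuple[str, str, str]
    force_constant: float
    eq_angle: float


@dataclass(frozen=True)
class TorsionParams:
    """Four-slot cosine series; slot i (1-based) has periodicity i.

    ``phase_offsets`` are in degrees, ``magnitudes`` in kcal/mol and the
    whole series is divided by ``n_paths``.
    """

    type_quad: Tuple[str, str, str, str]
    phase_offsets: Tuple[float, float, float, float]
    magnitudes: Tuple[float, float, float, float]
    n_paths: float

    def __post_init__(self) -> None:
        if len(self.phase_offsets) != 4 or len(self.magnitudes) != 4:
            raise ValueError("torsion records carry exactly 4 phase/magnitude slots")
        if self.n_paths <= 0:
            raise ValueError("number of paths N must be positive")


@dataclass(frozen=True)
class ImproperParams:
    """Out-of-plane term; the central atom type is third in ``type_quad``."""

    type_quad: Tuple[str, str, str, str]
    magnitude: float
    phase: float
    period: float

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("improper period P must be positive")


@dataclass(frozen=True)
class LJPairCoefficients:
    """Pairwise A/B coefficients: A = eps*D^12, B = 2*eps*D^6."""

    a_coef: float
    b_coef: float
    eps_pair: float
    d_pair: float


def _bond_key(pair: Sequence[str]) -> Tuple[str, str]:
    a, b = pair
    return min((a, b), (b, a))


def _angle_key(triple: Sequence[str]) -> Tuple[str, str, str]:
    t = tuple(triple)
    return min(t, t[::-1])


def _torsion_key(quad: Sequence[str]) -> Tuple[str, str, str, str]:
    t = tuple(quad)
    return min(t, t[::-1])


def _improper_key(quad: Sequence[str]) -> Tuple[Tuple[str, ...], str]:
    a, b, c, d = quad
    return (tuple(sorted((a, b, d))), c)


@dataclass
class ParameterSet:
    """Type-keyed lookup tables for one force field.

    Tables are dictionaries keyed by canonicalized type tuples; duplicate
    records (after canonicalization) keep the first occurrence and append a
    warning.  ``charge_source`` records where atomic charges come from
    (``"prmtop"`` or ``None`` when the block itself carries no charges).
    """

    vdw_table: dict = field(default_factory=dict)
    bond_table: dict = field(default_factory=dict)
    angle_table: dict = field(default_factory=dict)
    torsion_table: dict = field(default_factory=dict)
    improper_table: dict = field(default_factory=dict)
    charge_source: Optional[str] = None
    warnings: list = field(default_factory=list, compare=False)

    # -- insertion with first-wins duplicate handling ---------------------
    def add_vdw(self, rec: AtomTypeParams) -> None:
        if rec.type_name in self.vdw_table:
            self.warnings.append(f"duplicate VDW record for type {rec.type_name}; keeping first")
            return
        self.vdw_table[rec.type_name] = rec

    def add_bond(self, rec: BondParams) -> None:
        key = _bond_key(rec.type_pair)
        if key in self.bond_table:
            self.warnings.append(f"duplicate bond record {'-'.join(key)}; keeping first")
            return
        self.bond_table[key] = rec

    def add_angle(self, rec: AngleParams) -> None:
        key = _angle_key(rec.type_triple)
        if key in self.angle_table:
            self.warnings.append(f"duplicate angle record {'-'.join(key)}; keeping first")
            return
        self.angle_table[key] = rec

    def add_torsion(self, rec: TorsionParams) -> None:
        key = _torsion_key(rec.type_quad)
        if key in self.torsion_table:
            self.warnings.append(f"duplicate torsion record {'-'.join(key)}; keeping first")
            return
        self.torsion_table[key] = rec

    def add_improper(self, rec: ImproperParams) -> None:
        key = _improper_key(rec.type_quad)
        if key in self.improper_table:
            self.warnings.append(
                f"duplicate improper record {'-'.join(rec.type_quad)}; keeping first"
            )
            return
        self.improper_table[key] = rec

    # -- canonical lookups ------------------------------------------------
    def get_vdw(self, type_name: str) -> Optional[AtomTypeParams]:
        return self.vdw_table.get(type_name)

    def get_bond(self, types: Sequence[str]) -> Optional[BondParams]:
        return self.bond_table.get(_bond_key(types))

    def get_angle(self, types: Sequence[str]) -> Optional[AngleParams]:
        return self.angle_table.get(_angle_key(types))

    def get_torsion(self, types: Sequence[str]) -> Optional[TorsionParams]:
        return self.torsion_table.get(_torsion_key(types))

    def get_improper(self, types: Sequence[str]) -> Optional[ImproperParams]:
        return self.improper_table.get(_improper_key(types))


def lookup_bonded(params: ParameterSet, kind: str, types: Sequence[str]):
    """Canonical parameter lookup; returns the record or ``None`` on a miss.

    ``kind`` is one of ``bond``, ``angle``, ``torsion``, ``improper``; a
    label count that does not match the kind is a usage error.
    """
    expected = {"bond": 2, "angle": 3, "torsion": 4, "improper": 4}
    if kind not in expected:
        raise ValueError(f"unknown bonded kind {kind!r}")
    if len(types) != expected[kind]:
        raise ValueError(
            f"{kind} lookup needs {expected[kind]} type labels, got {len(types)}"
        )
    getter = {
        "bond": params.get_bond,
        "angle": params.get_angle,
        "torsion": params.get_torsion,
        "improper": params.get_improper,
    }[kind]
    return getter(types)


def combine_lj(a: AtomTypeParams, b: AtomTypeParams) -> LJPairCoefficients:
    """Lorentz-Berthelot combination: eps_ij = sqrt(eps_i eps_j), D_ij = R_i + R_j."""
    eps = math.sqrt(a.well_depth * b.well_depth)
    d = a.radius + b.radius
    return LJPairCoefficients(
        a_coef=eps * d**12, b_coef=2.0 * eps * d**6, eps_pair=eps, d_pair=d
    )


# ---------------------------------------------------------------------------
# Gaussian-style block: parse / write
# ---------------------------------------------------------------------------

_FIELD_COUNTS = {"VDW": 3, "HrmStr1": 4, "HrmBnd1": 5, "AmbTrs": 13, "ImpTrs": 7}


def _floats(tokens: Sequence[str], lineno: int) -> list:
    out = []
    for tok in tokens:
        try:
            out.append(float(tok))
        except ValueError:
            raise ParameterBlockError(
                f"line {lineno}: non-numeric field {tok!r}"
            ) from None
    return out


def parse_gaussian_mm_block(text: str) -> ParameterSet:
    """Parse a multi-line Gaussian-style MM parameter block.

    Empty input yields an empty :class:`ParameterSet`.  Unknown keywords and
    wrong field counts raise :class:`ParameterBlockError` naming the line.
    """
    params = ParameterSet()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        keyword, rest = tokens[0], tokens[1:]
        if keyword not in _FIELD_COUNTS:
            raise ParameterBlockError(f"line {lineno}: unknown record keyword {keyword!r}")
        if len(rest) != _FIELD_COUNTS[keyword]:
            raise ParameterBlockError(
                f"line {lineno}: {keyword} expects {_FIELD_COUNTS[keyword]} fields, "
                f"got {len(rest)}"
            )
        if keyword == "VDW":
            (r, eps) = _floats(rest[1:], lineno)
            params.add_vdw(AtomTypeParams(rest[0], r, eps))
        elif keyword == "HrmStr1":
            (kb, l0) = _floats(rest[2:], lineno)
            params.add_bond(BondParams((rest[0], rest[1]), kb, l0))
        elif keyword == "HrmBnd1":
            (ka, th0) = _floats(rest[3:], lineno)
            params.add_angle(AngleParams((rest[0], rest[1], rest[2]), ka, th0))
        elif keyword == "AmbTrs":
            vals = _floats(rest[4:], lineno)
            phases, mags, npaths = vals[0:4], vals[4:8], vals[8]
            if npaths <= 0:
                raise ParameterBlockError(f"line {lineno}: number of paths must be > 0")
            params.add_torsion(
                TorsionParams(tuple(rest[0:4]), tuple(phases), tuple(mags), npaths)
            )
        else:  # ImpTrs
            (ki, phase, period) = _floats(rest[4:], lineno)
            if period <= 0:
                raise ParameterBlockError(f"line {lineno}: improper period must be > 0")
            params.add_improper(ImproperParams(tuple(rest[0:4]), ki, phase, period))
    return params


def _fmt(value: float) -> str:
    # fixed-point with 4 decimals when that is exact (the printed convention);
    # otherwise enough digits for a lossless round trip
    s = f"{value:.4f}"
    if float(s) == value:
        return s
    return repr(value)


def write_gaussian_mm_block(params: ParameterSet) -> str:
    """Serialize a :class:`ParameterSet`; output re-parses to an equal set.

    Records are emitted in a fixed order (VDW, HrmStr1, HrmBnd1, AmbTrs,
    ImpTrs; each sorted by type labels) so output is deterministic.
    """
    lines = []
    for rec in sorted(params.vdw_table.values(), key=lambda r: r.type_name):
        lines.append(f"VDW {rec.type_name} {_fmt(rec.radius)} {_fmt(rec.well_depth)}")
    for key in sorted(params.bond_table):
        rec = params.bond_table[key]
        lines.append(
            f"HrmStr1 {rec.type_pair[0]} {rec.type_pair[1]} "
            f"{_fmt(rec.force_constant)} {_fmt(rec.eq_length)}"
        )
    for key in sorted(params.angle_table):
        rec = params.angle_table[key]
        lines.append(
            f"HrmBnd1 {' '.join(rec.type_triple)} "
            f"{_fmt(rec.force_constant)} {_fmt(rec.eq_angle)}"
        )
    for key in sorted(params.torsion_table):
        rec = params.torsion_table[key]
        lines.append(
            f"AmbTrs {' '.join(rec.type_quad)} "
            + " ".join(_fmt(p) for p in rec.phase_offsets)
            + " "
            + " ".join(_fmt(m) for m in rec.magnitudes)
            + f" {_fmt(rec.n_paths)}"
        )
    for key in sorted(params.improper_table):
        rec = params.improper_table[key]
        lines.append(
            f"ImpTrs {' '.join(rec.type_quad)} "
            f"{_fmt(rec.magnitude)} {_fmt(rec.phase)} {_fmt(rec.period)}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# PRMTOP -> ParameterSet
# ---------------------------------------------------------------------------

def invert_lj_diagonal(a_coef: float, b_coef: float) -> Tuple[float, float]:
    """Recover (eps, D) from diagonal A/B coefficients.

    eps = B^2 / (4 A) and D = (2 A / B)^(1/6); both zero when A = B = 0.
    """
    if a_coef == 0.0 or b_coef == 0.0:
        return 0.0, 0.0
    eps = b_coef * b_coef / (4.0 * a_coef)
    d = (2.0 * a_coef / b_coef) ** (1.0 / 6.0)
    return eps, d


def params_from_prmtop(prmtop) -> ParameterSet:
    """Build a :class:`ParameterSet` from parsed PRMTOP content.

    Per-type R and eps come from the diagonal Lennard-Jones A/B
    coefficients (degenerate rows warn and fall back to R = eps = 0);
    bonded tables are keyed by the AMBER atom-type labels of the atoms each
    instance touches.  Torsion records sharing a type quadruple are merged
    into the 4-slot cosine series; a conflicting duplicate for the same
    periodicity keeps the first value and warns.
    """
    params = ParameterSet(charge_source="prmtop")
    labels = prmtop.atom_type_labels
    type_index = prmtop.atom_type_indices  # 1-based per atom

    # first label seen for each nonbonded type index
    index_label: dict = {}
    for lab, ti in zip(labels, type_index):
        index_label.setdefault(ti, lab)

    ntypes = prmtop.ntypes
    acoef = prmtop.lj_acoef
    bcoef = prmtop.lj_bcoef
    nb_index = prmtop.nonbonded_parm_index
    for ti in sorted(index_label):
        lab = index_label[ti]
        flat = nb_index[ntypes * (ti - 1) + (ti - 1)]
        if flat <= 0:  # 10-12 hydrogen-bond slot; treat as no LJ
            params.warnings.append(f"type {lab}: no 6-12 diagonal; R=eps=0")
            params.add_vdw(AtomTypeParams(lab, 0.0, 0.0))
            continue
        a, b = acoef[flat - 1], bcoef[flat - 1]
        if (a == 0.0) != (b == 0.0):
            params.warnings.append(
                f"type {lab}: inconsistent LJ diagonal (A={a}, B={b}); R=eps=0"
            )
            params.add_vdw(AtomTypeParams(lab, 0.0, 0.0))
            continue
        if a == 0.0 and b == 0.0:
            params.warnings.append(f"type {lab}: zero LJ diagonal; R=eps=0")
            params.add_vdw(AtomTypeParams(lab, 0.0, 0.0))
            continue
        eps, d = invert_lj_diagonal(a, b)
        params.add_vdw(AtomTypeParams(lab, d / 2.0, eps))

    def atom_types(idx: Iterable[int]) -> Tuple[str, ...]:
        return tuple(labels[i] for i in idx)

    for (i, j), pi in prmtop.bond_instances:
        kb = prmtop.bond_force_constants[pi]
        l0 = prmtop.bond_eq_lengths[pi]
        key = _bond_key(atom_types((i, j)))
        if key not in params.bond_table:
            params.add_bond(BondParams(key, kb, l0))

    for (i, j, k), pi in prmtop.angle_instances:
        ka = prmtop.angle_force_constants[pi]
        th0 = math.degrees(prmtop.angle_eq_values[pi])  # PRMTOP stores radians
        key = _angle_key(atom_types((i, j, k)))
        if key not in params.angle_table:
            params.add_angle(AngleParams(key, ka, th0))

    # accumulate torsion slots, then freeze
    torsion_slots: dict = {}
    for (i, j, k, l), pi, improper in prmtop.dihedral_instances:
        kd = prmtop.dihedral_force_constants[pi]
        period = prmtop.dihedral_periodicities[pi]
        phase = math.degrees(prmtop.dihedral_phases[pi])
        types = atom_types((i, j, k, l))
        if improper:
            if params.get_improper(types) is None:
                params.add_improper(ImproperParams(types, kd, phase, abs(period)))
            continue
        n = int(round(abs(period)))
        if not 1 <= n <= 4:
            params.warnings.append(
                f"torsion {'-'.join(types)}: periodicity {period} outside slots 1-4; skipped"
            )
            continue
        key = _torsion_key(types)
        slots = torsion_slots.setdefault(key, {})
        if n in slots:
            if slots[n] != (kd, phase):
                params.warnings.append(
                    f"conflicting torsion record {'-'.join(key)} periodicity {n}; keeping first"
                )
            continue
        slots[n] = (kd, phase)
    for key, slots in torsion_slots.items():
        mags = [0.0, 0.0, 0.0, 0.0]
        phases = [0.0, 0.0, 0.0, 0.0]
        for n, (kd, phase) in slots.items():
            mags[n - 1] = kd
            phases[n - 1] = phase
        params.add_torsion(TorsionParams(key, tuple(phases), tuple(mags), 1.0))
    return params
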