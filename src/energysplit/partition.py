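"""Fragment assignment and exact energy partitioning.

Every energy term is routed into exactly one bucket, keyed by the set of
distinct fragment labels among its atoms: one label is a fragment
self-energy (E_frag), two to four labels are pair/triple/quadruple
interaction energies (E_int).  The arithmetic sum of all buckets
reconstructs the unpartitioned total:

    E_system = sum_i E_frag_i + sum_{i<j} E_int_{i-j}
             + sum E_int_{i-j-k} + sum E_int_{i-j-k-l}

Atoms not covered by any user selection fall into the reserved remainder
fragment ``"X"``; empty fragments are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .energy import (
    CONSTANTS,
    PhysicalConstants,
    bonded_term_energies,
    nonbonded_pair_arrays,
)
from .errors import FragmentError
from .topology import MolecularSystem

__all__ = [
    "REMAINDER_LABEL",
    "FragmentScheme",
    "EnergyReport",
    "assign_fragments",
    "bucket_for",
    "partitioned_energy",
    "delta_report",
]

REMAINDER_LABEL = "X"

CLASS_NAMES = ("Bonds", "Angles", "Torsions", "Out-of-Plane", "VDW", "Coulomb")


@dataclass
class FragmentScheme:
    """Total mapping atom index -> fragment label.

    ``labels`` preserves presentation order: user fragments in the order
    given, then the remainder ``"X"`` (when non-empty).
    """

    labels: List[str]
    atom_labels: List[str]

    def __post_init__(self) -> None:
        self._order = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def label_of(self, atom: int) -> str:
        return self.atom_labels[atom]

    def members(self, label: str) -> List[int]:
        return [i for i, lab in enumerate(self.atom_labels) if lab == label]

    def membership(self) -> Dict[str, List[int]]:
        return {lab: self.members(lab) for lab in self.labels}

    def sort_key(self, label: str) -> int:
        return self._order[label]


def assign_fragments(
    selections: Mapping[str, Iterable[int]], n_atoms: int
) -> FragmentScheme:
    """Build a total fragment scheme from user atom-index selections.

    Selections must be disjoint and in range; ``"X"`` is reserved for the
    automatically computed remainder.  Empty fragments (including an empty
    remainder) are dropped.
    """
    owner: Dict[int, str] = {}
    ordered_labels: List[str] = []
    for label, indexes in selections.items():
        label = str(label)
        if label == REMAINDER_LABEL:
            raise FragmentError(
                f"fragment label {REMAINDER_LABEL!r} is reserved for the remainder"
            )
        if label in ordered_labels:
            raise FragmentError(f"duplicate fragment label {label!r}")
        idx = sorted(set(int(i) for i in indexes))
        for i in idx:
            if not 0 <= i < n_atoms:
                raise FragmentError(
                    f"fragment {label!r}: atom index {i} outside 0..{n_atoms - 1}"
                )
            if i in owner:
                raise FragmentError(
                    f"atom {i} selected by both fragment {owner[i]!r} and {label!r}"
                )
            owner[i] = label
        if idx:
            ordered_labels.append(label)
    atom_labels = [owner.get(i, REMAINDER_LABEL) for i in range(n_atoms)]
    if any(lab == REMAINDER_LABEL for lab in atom_labels):
        ordered_labels.append(REMAINDER_LABEL)
    return FragmentScheme(ordered_labels, atom_labels)


def bucket_for(atom_indexes: Sequence[int], scheme: FragmentScheme) -> Tuple[str, ...]:
    """Sorted set of distinct fragment labels among the participating atoms."""
    labels: Set[str] = {scheme.label_of(i) for i in atom_indexes}
    return tuple(sorted(labels, key=scheme.sort_key))


@dataclass
class EnergyReport:
    """Per-class bucket energies plus totals, warnings and run metadata.

    ``classes`` maps a term-class name (Bonds, Angles, Torsions,
    Out-of-Plane, VDW, Coulomb) to ``{bucket key: kcal/mol}`` where a bucket
    key is a tuple of 1-4 fragment labels.  Buckets with no routed terms are
    absent.
    """

    scheme: FragmentScheme
    classes: Dict[str, Dict[Tuple[str, ...], float]]
    warnings: List[str] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def class_totals(self) -> Dict[str, float]:
        return {name: sum(b.values()) for name, b in self.classes.items()}

    @property
    def total_energy(self) -> float:
        return sum(self.class_totals.values())

    def bucket_total(self, key: Tuple[str, ...]) -> float:
        return sum(b.get(key, 0.0) for b in self.classes.values())

    def bucket_keys(self) -> List[Tuple[str, ...]]:
        keys: Set[Tuple[str, ...]] = set()
        for buckets in self.classes.values():
            keys.update(buckets)
        return sorted(keys, key=lambda k: (len(k), [self.scheme.sort_key(x) for x in k]))


def partitioned_energy(
    system: MolecularSystem,
    scheme: FragmentScheme,
    workers: int = 1,
    constants: PhysicalConstants = CONSTANTS,
) -> EnergyReport:
    """Evaluate each term once and accumulate it into its fragment bucket."""
    if scheme.n_atoms != system.n_atoms:
        raise FragmentError(
            f"scheme covers {scheme.n_atoms} atoms, system has {system.n_atoms}"
        )
    classes: Dict[str, Dict[Tuple[str, ...], float]] = {
        name: {} for name in CLASS_NAMES
    }
    routed = 0
    slot = {"bond": "Bonds", "angle": "Angles", "torsion": "Torsions",
            "improper": "Out-of-Plane"}
    for kind, atoms, e in bonded_term_energies(system):
        key = bucket_for(atoms, scheme)
        buckets = classes[slot[kind]]
        buckets[key] = buckets.get(key, 0.0) + e
        routed += 1

    # nonbonded: route pairs by the fragment ids of their two end atoms
    ii, jj, e_lj, e_cl = nonbonded_pair_arrays(system, constants=constants)
    n_pairs = len(ii)
    if n_pairs:
        frag_id = np.array([scheme.sort_key(lab) for lab in scheme.atom_labels])
        nf = len(scheme.labels)
        fi, fj = frag_id[ii], frag_id[jj]
        lo, hi = np.minimum(fi, fj), np.maximum(fi, fj)
        flat = lo * nf + hi
        workers = max(1, int(workers))
        size = nf * nf
        lj_sums = np.zeros(size)
        cl_sums = np.zeros(size)
        counts = np.zeros(size, dtype=int)
        # per-worker partial accumulation, combined in worker-index order
        for part in np.array_split(np.arange(n_pairs), workers):
            if len(part) == 0:
                continue
            lj_sums += np.bincount(flat[part], weights=e_lj[part], minlength=size)
            cl_sums += np.bincount(flat[part], weights=e_cl[part], minlength=size)
            counts += np.bincount(flat[part], minlength=size)
        for b in range(size):
            if counts[b] == 0:
                continue
            lo_i, hi_i = divmod(b, nf)
            key = (
                (scheme.labels[lo_i],)
                if lo_i == hi_i
                else (scheme.labels[lo_i], scheme.labels[hi_i])
            )
            classes["VDW"][key] = classes["VDW"].get(key, 0.0) + float(lj_sums[b])
            classes["Coulomb"][key] = classes["Coulomb"].get(key, 0.0) + float(cl_sums[b])
        routed += n_pairs

    report = EnergyReport(
        scheme=scheme,
        classes=classes,
        warnings=list(system.improper_warnings),
        metadata={
            "workers": max(1, int(workers)),
            "fragments": scheme.membership(),
            "routed_terms": routed,
        },
    )
    return report


def delta_report(a: EnergyReport, b: EnergyReport) -> EnergyReport:
    """Bucket-wise differences ``b - a`` between two conformations.

    Both reports must use the same fragment labels; buckets present in only
    one report are treated as zero in the other.
    """
    la, lb = set(a.scheme.labels), set(b.scheme.labels)
    if la != lb:
        only_a = sorted(la - lb)
        only_b = sorted(lb - la)
        raise FragmentError(
            f"fragment labels differ between reports: only in first {only_a}, "
            f"only in second {only_b}"
        )
    classes: Dict[str, Dict[Tuple[str, ...], float]] = {}
    for name in CLASS_NAMES:
        ba = a.classes.get(name, {})
        bb = b.classes.get(name, {})
        keys = set(ba) | set(bb)
        classes[name] = {k: bb.get(k, 0.0) - ba.get(k, 0.0) for k in sorted(keys)}
    return EnergyReport(
        scheme=b.scheme,
        classes=classes,
        warnings=[],
        metadata={"delta": True, "fragments": b.scheme.membership()},
    )
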