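"""Reader for AMBER PRMTOP/PARM7 sectioned ASCII topology files.

The format is a sequence of ``%FLAG <NAME>`` sections, each preceded by a
``%FORMAT(...)`` descriptor (e.g. ``10I8``, ``5E16.8``, ``20a4``) that fixes
the field width and type of the data lines that follow.  Fields are parsed
strictly by the declared width, so packed lines without separating spaces
are handled correctly.

Only the sections needed for energy evaluation are interpreted; everything
else is retained verbatim in :attr:`PrmtopFile.sections`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .errors import PrmtopFormatError

__all__ = ["PrmtopFile"]

_FORMAT_RE = re.compile(r"\(\s*(\d+)\s*([aAiIeEfFgG])\s*(\d+)(?:\.(\d+))?\s*\)")

# POINTERS slots (standard PARM7 ordering)
_NATOM, _NTYPES = 0, 1
_NBONH, _MBONA = 2, 3
_NTHETH, _MTHETA = 4, 5
_NPHIH, _MPHIA = 6, 7
_NRES = 11
_NUMBND, _NUMANG, _NPTRA = 15, 16, 17

_MANDATORY = (
    "POINTERS",
    "CHARGE",
    "ATOM_TYPE_INDEX",
    "AMBER_ATOM_TYPE",
    "NONBONDED_PARM_INDEX",
    "LENNARD_JONES_ACOEF",
    "LENNARD_JONES_BCOEF",
    "BONDS_INC_HYDROGEN",
    "BONDS_WITHOUT_HYDROGEN",
)


def _parse_section(fmt: str, lines: Sequence[str], name: str) -> list:
    m = _FORMAT_RE.search(fmt)
    if m is None:
        raise PrmtopFormatError(f"section {name}: unparseable %FORMAT {fmt!r}")
    _, code, width = m.group(1), m.group(2).lower(), int(m.group(3))
    out: list = []
    for line in lines:
        line = line.rstrip("\n")
        for start in range(0, len(line), width):
            tok = line[start : start + width].strip()
            if not tok:
                continue
            if code == "a":
                out.append(tok)
            elif code == "i":
                try:
                    out.append(int(tok))
                except ValueError:
                    raise PrmtopFormatError(
                        f"section {name}: bad integer field {tok!r}"
                    ) from None
            else:
                try:
                    out.append(float(tok))
                except ValueError:
                    raise PrmtopFormatError(
                        f"section {name}: bad numeric field {tok!r}"
                    ) from None
    return out


@dataclass
class PrmtopFile:
    """Parsed PRMTOP content with typed accessors for the energy pipeline."""

    sections: Dict[str, list] = field(default_factory=dict)

    # ------------------------------------------------------------------
    @classmethod
    def read(cls, path) -> "PrmtopFile":
        with open(path) as fh:
            text = fh.read()
        return cls.from_text(text)

    @classmethod
    def from_text(cls, text: str) -> "PrmtopFile":
        sections: Dict[str, list] = {}
        name = None
        fmt = None
        body: List[str] = []

        def flush():
            if name is not None:
                sections[name] = _parse_section(fmt or "(20a4)", body, name)

        for line in text.splitlines():
            if line.startswith("%VERSION") or line.startswith("%COMMENT"):
                continue
            if line.startswith("%FLAG"):
                flush()
                name = line[len("%FLAG") :].strip()
                fmt = None
                body = []
            elif line.startswith("%FORMAT"):
                fmt = line[len("%FORMAT") :].strip()
            elif name is not None:
                body.append(line)
        flush()

        pf = cls(sections)
        pf._validate()
        return pf

    def _validate(self) -> None:
        for sec in _MANDATORY:
            if sec not in self.sections:
                raise PrmtopFormatError(f"missing mandatory section {sec}")
        ptr = self.sections["POINTERS"]
        if len(ptr) < 20:
            raise PrmtopFormatError("POINTERS section truncated")
        natom = ptr[_NATOM]
        for sec in ("CHARGE", "ATOM_TYPE_INDEX", "AMBER_ATOM_TYPE"):
            if len(self.sections[sec]) != natom:
                raise PrmtopFormatError(
                    f"section {sec} has {len(self.sections[sec])} entries, "
                    f"POINTERS says NATOM={natom}"
                )
        if len(self.sections["BONDS_INC_HYDROGEN"]) != 3 * ptr[_NBONH]:
            raise PrmtopFormatError("BONDS_INC_HYDROGEN length inconsistent with NBONH")
        nbona = len(self.sections["BONDS_WITHOUT_HYDROGEN"]) // 3
        if len(self.sections["BONDS_WITHOUT_HYDROGEN"]) % 3 != 0:
            raise PrmtopFormatError("BONDS_WITHOUT_HYDROGEN length not a multiple of 3")
        if nbona != ptr[_MBONA]:
            raise PrmtopFormatError(
                f"BONDS_WITHOUT_HYDROGEN holds {nbona} bonds, POINTERS says {ptr[_MBONA]}"
            )

    # ------------------------------------------------------------------
    @property
    def pointers(self) -> list:
        return self.sections["POINTERS"]

    @property
    def natom(self) -> int:
        return self.pointers[_NATOM]

    @property
    def ntypes(self) -> int:
        return self.pointers[_NTYPES]

    @property
    def raw_charges(self) -> list:
        """Charges as stored (premultiplied by 18.2223)."""
        return self.sections["CHARGE"]

    @property
    def atom_type_labels(self) -> list:
        return self.sections["AMBER_ATOM_TYPE"]

    @property
    def atom_names(self) -> list:
        return self.sections.get("ATOM_NAME", [""] * self.natom)

    @property
    def atom_type_indices(self) -> list:
        return self.sections["ATOM_TYPE_INDEX"]

    @property
    def nonbonded_parm_index(self) -> list:
        return self.sections["NONBONDED_PARM_INDEX"]

    @property
    def lj_acoef(self) -> list:
        return self.sections["LENNARD_JONES_ACOEF"]

    @property
    def lj_bcoef(self) -> list:
        return self.sections["LENNARD_JONES_BCOEF"]

    @property
    def bond_force_constants(self) -> list:
        return self.sections.get("BOND_FORCE_CONSTANT", [])

    @property
    def bond_eq_lengths(self) -> list:
        return self.sections.get("BOND_EQUIL_VALUE", [])

    @property
    def angle_force_constants(self) -> list:
        return self.sections.get("ANGLE_FORCE_CONSTANT", [])

    @property
    def angle_eq_values(self) -> list:
        """Equilibrium angles in radians, as stored."""
        return self.sections.get("ANGLE_EQUIL_VALUE", [])

    @property
    def dihedral_force_constants(self) -> list:
        return self.sections.get("DIHEDRAL_FORCE_CONSTANT", [])

    @property
    def dihedral_periodicities(self) -> list:
        return self.sections.get("DIHEDRAL_PERIODICITY", [])

    @property
    def dihedral_phases(self) -> list:
        """Phases in radians, as stored."""
        return self.sections.get("DIHEDRAL_PHASE", [])

    # -- term instance lists (0-based atom indices, 0-based param index) --
    @property
    def bond_instances(self) -> List[Tuple[Tuple[int, int], int]]:
        out = []
        for sec in ("BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN"):
            data = self.sections.get(sec, [])
            for n in range(0, len(data), 3):
                i, j, pi = data[n : n + 3]
                out.append(((abs(i) // 3, abs(j) // 3), pi - 1))
        return out

    @property
    def angle_instances(self) -> List[Tuple[Tuple[int, int, int], int]]:
        out = []
        for sec in ("ANGLES_INC_HYDROGEN", "ANGLES_WITHOUT_HYDROGEN"):
            data = self.sections.get(sec, [])
            for n in range(0, len(data), 4):
                i, j, k, pi = data[n : n + 4]
                out.append(((abs(i) // 3, abs(j) // 3, abs(k) // 3), pi - 1))
        return out

    @property
    def dihedral_instances(self) -> List[Tuple[Tuple[int, int, int, int], int, bool]]:
        """Entries ``((i, j, k, l), param_index, is_improper)``.

        A negative third index (skip-1-4 marker) is taken as its absolute
        value; a negative fourth index marks an improper torsion.
        """
        out = []
        for sec in ("DIHEDRALS_INC_HYDROGEN", "DIHEDRALS_WITHOUT_HYDROGEN"):
            data = self.sections.get(sec, [])
            for n in range(0, len(data), 5):
                i, j, k, l, pi = data[n : n + 5]
                improper = l < 0
                out.append(
                    ((abs(i) // 3, abs(j) // 3, abs(k) // 3, abs(l) // 3), pi - 1, improper)
                )
        return out

    @property
    def bonds(self) -> List[Tuple[int, int]]:
        """Covalent bonds as 0-based atom index pairs (both sections)."""
        return [pair for pair, _ in self.bond_instances]
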