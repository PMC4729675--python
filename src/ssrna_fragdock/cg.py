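"""Coarse-grained bead model: domain types, bead mapping, structure I/O.

The reduced representation places one pseudo-atom ("bead") at the unweighted
center of mass of a small group of heavy atoms.  Nucleotides map to 6 beads
(pyrimidines) or 7 beads (purines): one phosphate bead, two sugar/backbone
beads and 3-4 base beads.  Amino acids map to 3 or 4 beads.  The mapping is
loaded from an editable tab-separated table shipped with the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Allowed bead roles.
ROLES = ("backbone", "sugar", "base", "phosphate", "sidechain", "mainchain")

#: Roles treated as backbone-like when choosing overlap margins.
BACKBONE_LIKE = frozenset({"backbone", "sugar", "phosphate"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class StructureError(ValueError):
    """Raised for unreadable input structures or missing models."""


class ConversionError(ValueError):
    """Raised when a residue cannot be coarse-grained."""


# ---------------------------------------------------------------------------
# Mapping


@dataclass(frozen=True)
class BeadSpec:
    """One bead definition inside a residue mapping entry."""

    bead_name: str
    role: str
    type_code: int
    charge: float
    source_atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.source_atoms:
            raise ValueError(f"bead {self.bead_name}: source_atoms must be non-empty")
        if self.type_code < 0:
            raise ValueError(f"bead {self.bead_name}: type_code must be >= 0")
        if self.role not in ROLES:
            raise ValueError(f"bead {self.bead_name}: unknown role {self.role!r}")


NUCLEOTIDE_NAMES = frozenset({"A", "C", "G", "U"})
PYRIMIDINES = frozenset({"C", "U"})
PURINES = frozenset({"A", "G"})


class CGMapping:
    """residue_name -> ordered list of :class:`BeadSpec`."""

    def __init__(self, entries: dict[str, list[BeadSpec]]):
        for res, beads in entries.items():
            n = len(beads)
            if res in NUCLEOTIDE_NAMES and n not in (6, 7):
                raise ValueError(f"nucleotide {res} maps to {n} beads, expected 6 or 7")
            if res not in NUCLEOTIDE_NAMES and n not in (3, 4):
                raise ValueError(f"amino acid {res} maps to {n} beads, expected 3 or 4")
        self._entries = {res: list(beads) for res, beads in entries.items()}

    def __contains__(self, residue_name: str) -> bool:
        return residue_name in self._entries

    def __getitem__(self, residue_name: str) -> list[BeadSpec]:
        return self._entries[residue_name]

    def residue_names(self) -> list[str]:
        return list(self._entries)

    def bead_count(self, residue_name: str) -> int:
        return len(self._entries[residue_name])

    @classmethod
    def from_table(cls, path: str | Path) -> "CGMapping":
        """Load a mapping from a TSV table.

        Columns: residue_name, bead_name, role, type_code, charge,
        source_atoms (comma-joined atom names).
        """
        entries: dict[str, list[BeadSpec]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                res, bead, role, code, charge, atoms = line.split("\t")
                entries.setdefault(res, []).append(
                    BeadSpec(
                        bead_name=bead,
                        role=role,
                        type_code=int(code),
                        charge=float(charge),
                        source_atoms=tuple(a.strip() for a in atoms.split(",")),
                    )
                )
        return cls(entries)

    @classmethod
    def default(cls) -> "CGMapping":
        """The mapping table shipped with the package."""
        with resources.as_file(
            resources.files("ssrna_fragdock.data") / "mapping.tsv"
        ) as p:
            return cls.from_table(p)


# ---------------------------------------------------------------------------
# CG structures


@dataclass(frozen=True)
class CGBead:
    """A single coarse-grained bead (convenience view; bulk data lives in
    :class:`CGStructure` arrays)."""

    name: str
    position: np.ndarray
    type_code: int
    charge: float
    residue_index: int
    chain_id: str
    role: str


class CGStructure:
    """Ordered collection of CG beads with residue bookkeeping.

    Bead attributes are stored as parallel numpy arrays so that geometric
    operations stay vectorised.  ``residues`` is an ordered list of
    ``(chain_id, residue_index, residue_name)`` tuples; ``residue_index`` is
    the author residue number of the source structure.
    """

    def __init__(
        self,
        coords: np.ndarray,
        type_codes: np.ndarray,
        charges: np.ndarray,
        residue_indices: np.ndarray,
        chain_ids: np.ndarray,
        roles: np.ndarray,
        bead_names: np.ndarray,
        residues: list[tuple[str, int, str]],
    ):
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.type_codes = np.asarray(type_codes, dtype=int)
        self.charges = np.asarray(charges, dtype=float)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.roles = np.asarray(roles, dtype=object)
        self.bead_names = np.asarray(bead_names, dtype=object)
        self.residues = list(residues)
        for arr in (self.type_codes, self.charges, self.residue_indices,
                    self.chain_ids, self.roles, self.bead_names):
            if len(arr) != n:
                raise ValueError("CGStructure arrays must have equal length")
        if n and not np.all(np.isfinite(self.coords)):
            raise ValueError("bead positions must be finite")
        keys = {(c, r) for c, r, _ in self.residues}
        for cid, ridx in zip(self.chain_ids, self.residue_indices):
            if (cid, int(ridx)) not in keys:
                raise ValueError(f"bead references unknown residue {(cid, ridx)}")

    # -- basics ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def com(self) -> np.ndarray:
        """Unweighted mean of bead positions."""
        return self.coords.mean(axis=0)

    @property
    def beads(self) -> list[CGBead]:
        return [
            CGBead(
                name=self.bead_names[i],
                position=self.coords[i],
                type_code=int(self.type_codes[i]),
                charge=float(self.charges[i]),
                residue_index=int(self.residue_indices[i]),
                chain_id=self.chain_ids[i],
                role=self.roles[i],
            )
            for i in range(len(self))
        ]

    def copy(self) -> "CGStructure":
        return CGStructure(
            self.coords.copy(), self.type_codes.copy(), self.charges.copy(),
            self.residue_indices.copy(), self.chain_ids.copy(),
            self.roles.copy(), self.bead_names.copy(), list(self.residues),
        )

    def with_coords(self, coords: np.ndarray) -> "CGStructure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(out.coords) != len(self):
            raise ValueError("coordinate count mismatch")
        return out

    def select(self, mask: np.ndarray) -> "CGStructure":
        """Subset by boolean bead mask; keeps only referenced residues."""
        mask = np.asarray(mask, dtype=bool)
        kept = {(c, int(r)) for c, r in
                zip(self.chain_ids[mask], self.residue_indices[mask])}
        residues = [t for t in self.residues if (t[0], t[1]) in kept]
        return CGStructure(
            self.coords[mask], self.type_codes[mask], self.charges[mask],
            self.residue_indices[mask], self.chain_ids[mask],
            self.roles[mask], self.bead_names[mask], residues,
        )

    def select_residues(self, chain_id: str, residue_indices) -> "CGStructure":
        wanted = set(int(r) for r in residue_indices)
        mask = np.array(
            [c == chain_id and int(r) in wanted
             for c, r in zip(self.chain_ids, self.residue_indices)],
            dtype=bool,
        )
        return self.select(mask)

    @staticmethod
    def empty() -> "CGStructure":
        z = np.empty((0,))
        return CGStructure(np.empty((0, 3)), z, z, z,
                           np.empty(0, dtype=object), np.empty(0, dtype=object),
                           np.empty(0, dtype=object), [])

    @staticmethod
    def concatenate(parts: list["CGStructure"]) -> "CGStructure":
        parts = [p for p in parts if len(p)]
        if not parts:
            return CGStructure.empty()
        residues: list[tuple[str, int, str]] = []
        seen = set()
        for p in parts:
            for t in p.residues:
                if (t[0], t[1]) not in seen:
                    seen.add((t[0], t[1]))
                    residues.append(t)
        return CGStructure(
            np.vstack([p.coords for p in parts]),
            np.concatenate([p.type_codes for p in parts]),
            np.concatenate([p.charges for p in parts]),
            np.concatenate([p.residue_indices for p in parts]),
            np.concatenate([p.chain_ids for p in parts]),
            np.concatenate([p.roles for p in parts]),
            np.concatenate([p.bead_names for p in parts]),
            residues,
        )


# ---------------------------------------------------------------------------
# Rigid transforms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation (3x3, det +1) followed by a translation, in Angstrom."""

    rotation: np.ndarray
    translation: np.ndarray

    ORTHO_TOL = 1e-9

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    @classmethod
    def from_quat(cls, quat, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Quaternion in scalar-last (x, y, z, w) convention."""
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_quat(np.asarray(quat, float)).as_matrix(),
                   np.asarray(translation, float))

    @classmethod
    def random_rotation(cls, rng: np.random.Generator) -> "RigidTransform":
        """Uniformly random rotation (normalised 4-normal-deviate quaternion)."""
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        return cls.from_quat(q)

    def quat(self) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        return Rotation.from_matrix(self.rotation).as_quat()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def apply_transform(conformer: CGStructure, t: RigidTransform) -> CGStructure:
    """Rotate then translate every bead position; all metadata unchanged."""
    return conformer.with_coords(t.apply(conformer.coords))


# ---------------------------------------------------------------------------
# All-atom I/O and coarse-graining

_ATOM_ALIASES = {"O1P": "OP1", "O2P": "OP2", "O3P": "OP3"}


def _normalize_atom_name(name: str) -> str:
    name = name.strip().replace("*", "'")
    return _ATOM_ALIASES.get(name, name)


def load_structure(path: str | Path, model_index: int = 1, include_hetero: bool = False):
    """Read a PDB or mmCIF file into a biotite ``AtomArray``.

    Keeps the first altloc, excludes waters always and heteroatoms by
    default, preserves author residue numbering.  ``model_index`` is 1-based.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif"):
            from biotite.structure.io.pdbx import CIFFile, get_structure

            f = CIFFile.read(str(path))
            atoms = get_structure(f, model=model_index, altloc="first")
        else:
            from biotite.structure.io.pdb import PDBFile

            f = PDBFile.read(str(path))
            atoms = f.get_structure(model=model_index, altloc="first")
    except FileNotFoundError:
        raise
    except IndexError as exc:
        raise StructureError(f"{path}: model {model_index} not present") from exc
    except Exception as exc:  # biotite raises various parse errors
        msg = str(exc)
        if "model" in msg.lower():
            raise StructureError(f"{path}: model {model_index} not present: {msg}") from exc
        raise StructureError(f"{path}: cannot parse: {msg}") from exc

    keep = ~np.isin(atoms.res_name, list(WATER_NAMES))
    if not include_hetero:
        keep &= ~atoms.hetero
    atoms = atoms[keep]
    atoms.atom_name = np.array([_normalize_atom_name(a) for a in atoms.atom_name])
    return atoms


def iter_residues(atoms):
    """Yield (chain_id, res_id, res_name, atom_names, atom_coords) in file order."""
    import biotite.structure as struc

    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for i in range(len(starts) - 1):
        sl = slice(starts[i], starts[i + 1])
        yield (
            str(atoms.chain_id[starts[i]]),
            int(atoms.res_id[starts[i]]),
            str(atoms.res_name[starts[i]]),
            list(atoms.atom_name[sl]),
            atoms.coord[sl],
        )


def coarse_grain(atoms, mapping: CGMapping | None = None) -> CGStructure:
    """Convert an all-atom structure to beads using ``mapping``.

    One bead per mapping entry, positioned at the unweighted center of mass
    of its source atoms.  Residues without a mapping entry are skipped with a
    warning.  A residue missing more than half of the source atoms of any of
    its beads raises :class:`ConversionError`.
    """
    if mapping is None:
        mapping = CGMapping.default()
    coords, codes, charges, ridx, cids, roles, names = [], [], [], [], [], [], []
    residues: list[tuple[str, int, str]] = []
    if atoms is None or len(atoms) == 0:
        return CGStructure.empty()
    for chain_id, res_id, res_name, atom_names, atom_coords in iter_residues(atoms):
        if res_name not in mapping:
            logger.warning("no mapping entry for residue %s %s%d: skipped",
                           res_name, chain_id, res_id)
            continue
        name_to_xyz = {n: atom_coords[i] for i, n in enumerate(atom_names)}
        residues.append((chain_id, res_id, res_name))
        for spec in mapping[res_name]:
            present = [name_to_xyz[a] for a in spec.source_atoms if a in name_to_xyz]
            if len(present) * 2 < len(spec.source_atoms):
                raise ConversionError(
                    f"residue {res_name} {chain_id}{res_id}: bead {spec.bead_name} "
                    f"is missing {len(spec.source_atoms) - len(present)} of "
                    f"{len(spec.source_atoms)} source atoms"
                )
            coords.append(np.mean(present, axis=0))
            codes.append(spec.type_code)
            charges.append(spec.charge)
            ridx.append(res_id)
            cids.append(chain_id)
            roles.append(spec.role)
            names.append(spec.bead_name)
    if not coords:
        return CGStructure.empty()
    return CGStructure(np.array(coords), codes, charges, ridx,
                       np.array(cids, dtype=object), np.array(roles, dtype=object),
                       np.array(names, dtype=object), residues)


# ---------------------------------------------------------------------------
# CG-PDB output (one pseudo-atom per bead)


def _res_name_of(structure: CGStructure) -> dict[tuple[str, int], str]:
    return {(c, r): n for c, r, n in structure.residues}


def write_cg_pdb(structures: CGStructure | list[CGStructure], path: str | Path) -> None:
    """Write CG structures as (multi-model) PDB text.

    Bead name goes in the atom-name field; type code is stored in the
    occupancy column and charge in the B-factor column so a library can be
    round-tripped without the mapping.
    """
    if isinstance(structures, CGStructure):
        structures = [structures]
    lines: list[str] = []
    multi = len(structures) > 1
    for m, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        rn = _res_name_of(s)
        for i in range(len(s)):
            cid = s.chain_ids[i]
            ri = int(s.residue_indices[i])
            res = rn.get((cid, ri), "UNK")
            x, y, z = s.coords[i]
            lines.append(
                f"ATOM  {i + 1:5d} {s.bead_names[i]:<4.4s}{res:>4.4s}"
                f"{cid[:1]:>2.2s}{ri:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{int(s.type_codes[i]):6d}"
                f"{float(s.charges[i]):6.2f}          "
                f"{s.roles[i][:2].upper():>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cg_pdb(path: str | Path, mapping: CGMapping | None = None) -> list[CGStructure]:
    """Read CG structures written by :func:`write_cg_pdb`.

    Roles are recovered from ``mapping`` (bead name within residue entry);
    beads of unmapped residues fall back to a role guess from the stored
    element column.
    """
    if mapping is None:
        mapping = CGMapping.default()
    role_of: dict[tuple[str, str], str] = {}
    for res in mapping.residue_names():
        for spec in mapping[res]:
            role_of[(res, spec.bead_name)] = spec.role
    role_abbrev = {r[:2].upper(): r for r in ROLES}

    models: list[list] = [[]]
    for line in Path(path).read_text().splitlines():
        if line.startswith("ENDMDL"):
            models.append([])
        elif line.startswith("ATOM") or line.startswith("HETATM"):
            models[-1].append(line)
    out = []
    for records in models:
        if not records:
            continue
        coords, codes, charges, ridx, cids, roles, names = [], [], [], [], [], [], []
        residues, seen = [], set()
        for line in records:
            bead = line[12:16].strip()
            res = line[16:20].strip()
            cid = line[20:22].strip()
            ri = int(line[22:26])
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            codes.append(int(round(float(line[54:60]))))
            charges.append(float(line[60:66]))
            ridx.append(ri)
            cids.append(cid)
            names.append(bead)
            role = role_of.get((res, bead))
            if role is None:
                role = role_abbrev.get(line[76:78].strip().upper(), "backbone")
            roles.append(role)
            if (cid, ri) not in seen:
                seen.add((cid, ri))
                residues.append((cid, ri, res))
        out.append(CGStructure(np.array(coords), codes, charges, ridx,
                               np.array(cids, dtype=object),
                               np.array(roles, dtype=object),
                               np.array(names, dtype=object), residues))
    return out
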