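"""Trinucleotide conformer libraries.

Extraction of overlapping trinucleotide windows from protein-bound RNA
chains, canonicalisation of homo-pyrimidine / homo-purine fragments into the
UUU / AAA sequence classes, greedy redundancy removal, and best-fit queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cg import CGMapping, CGStructure, NUCLEOTIDE_NAMES, PURINES, PYRIMIDINES

logger = logging.getLogger(__name__)

SEQUENCE_CLASSES = ("UUU", "AAA", "other")


@dataclass(frozen=True)
class TrinucleotideFragment:
    """Three consecutive nucleotides cut from a protein-bound RNA chain."""

    conformer: CGStructure
    source_id: str
    chain_id: str
    start_residue: int
    native_sequence: str
    sequence_class: str
    contacts_protein: bool | None = None

    def __post_init__(self):
        n_res = len({(c, int(r)) for c, r in zip(self.conformer.chain_ids,
                                                 self.conformer.residue_indices)})
        if n_res != 3:
            raise ValueError(f"fragment must span exactly 3 residues, got {n_res}")
        if len(self.native_sequence) != 3:
            raise ValueError("native_sequence must have length 3")


def classify_sequence(seq: str) -> str:
    """UUU for three pyrimidines, AAA for three purines, else 'other'."""
    if all(c in PYRIMIDINES for c in seq):
        return "UUU"
    if all(c in PURINES for c in seq):
        return "AAA"
    return "other"


def _residue_letter(res_name: str) -> str | None:
    # accept plain and prefixed RNA residue names (A / RA / ADE-style not handled)
    name = res_name.strip()
    if name in NUCLEOTIDE_NAMES:
        return name
    if len(name) == 2 and name[0] == "R" and name[1] in NUCLEOTIDE_NAMES:
        return name[1]
    return None


def extract_trinucleotides(
    complexes: list[tuple[CGStructure, CGStructure]],
    contact_cutoff: float = 5.0,
    source_ids: list[str] | None = None,
) -> list[TrinucleotideFragment]:
    """Cut every RNA chain into sliding windows of 3 consecutive nucleotides.

    Windows spanning a break in author residue numbering are excluded.  Each
    fragment is tagged with whether any of its beads lies within
    ``contact_cutoff`` of a protein bead.
    """
    out: list[TrinucleotideFragment] = []
    if source_ids is None:
        source_ids = [f"complex{i + 1}" for i in range(len(complexes))]
    for (protein, rna), source_id in zip(complexes, source_ids):
        tree = cKDTree(protein.coords) if len(protein) else None
        by_chain: dict[str, list[tuple[int, str]]] = {}
        for cid, ridx, rname in rna.residues:
            letter = _residue_letter(rname)
            if letter is None:
                continue
            by_chain.setdefault(cid, []).append((ridx, letter))
        for cid, residues in by_chain.items():
            residues.sort(key=lambda t: t[0])
            for k in range(len(residues) - 2):
                window = residues[k:k + 3]
                nums = [w[0] for w in window]
                if nums[1] != nums[0] + 1 or nums[2] != nums[1] + 1:
                    continue  # chain break
                conformer = rna.select_residues(cid, nums)
                seq = "".join(w[1] for w in window)
                contacts = None
                if tree is not None:
                    d, _ = tree.query(conformer.coords, k=1)
                    contacts = bool(np.min(d) <= contact_cutoff)
                out.append(TrinucleotideFragment(
                    conformer=conformer, source_id=source_id, chain_id=cid,
                    start_residue=nums[0], native_sequence=seq,
                    sequence_class=classify_sequence(seq),
                    contacts_protein=contacts,
                ))
    return out


def canonicalize(frag: TrinucleotideFragment,
                 mapping: CGMapping | None = None) -> TrinucleotideFragment:
    """Re-type a homo-pyrimidine fragment as UUU or a homo-purine as AAA.

    Bead positions never move: beads are re-assigned the type codes and
    charges of the target residue's mapping entry (matched by bead name);
    beads with no counterpart in the target entry are dropped.  Mixed
    sequences are returned unchanged with class 'other'.
    """
    cls = classify_sequence(frag.native_sequence)
    if cls == "other":
        return replace(frag, sequence_class="other")
    if mapping is None:
        mapping = CGMapping.default()
    target_res = "U" if cls == "UUU" else "A"
    spec_of = {s.bead_name: s for s in mapping[target_res]}
    s = frag.conformer
    keep = np.array([name in spec_of for name in s.bead_names], dtype=bool)
    dropped = int((~keep).sum())
    if dropped:
        logger.debug("canonicalize: dropped %d beads without counterpart in %s",
                     dropped, target_res)
    sub = s.select(keep)
    codes = np.array([spec_of[n].type_code for n in sub.bead_names])
    charges = np.array([spec_of[n].charge for n in sub.bead_names])
    roles = np.array([spec_of[n].role for n in sub.bead_names], dtype=object)
    residues = [(c, r, target_res) for c, r, _ in sub.residues]
    conf = CGStructure(sub.coords, codes, charges, sub.residue_indices,
                       sub.chain_ids, roles, sub.bead_names, residues)
    return replace(frag, conformer=conf, sequence_class=cls)


def superposed_rmsd(a: CGStructure, b: CGStructure) -> float:
    """Least-squares optimal-superposition RMSD (proper rotation only)."""
    if len(a) != len(b):
        raise ValueError(f"bead count mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        return 0.0
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd / np.sqrt(len(a)))


@dataclass
class FragmentLibrary:
    """Per-sequence-class conformer sets with redundancy metadata."""

    classes: dict[str, list[TrinucleotideFragment]] = field(default_factory=dict)
    dedup_threshold: float | None = None
    provenance: list[str] = field(default_factory=list)

    def __getitem__(self, sequence_class: str) -> list[TrinucleotideFragment]:
        return self.classes[sequence_class]

    def size(self, sequence_class: str) -> int:
        return len(self.classes.get(sequence_class, []))

    def save(self, directory: str | Path) -> None:
        """One multi-model CG-PDB per class plus a TSV index."""
        from .cg import write_cg_pdb

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index_lines = ["#conformer_id\tsequence_class\tsource_id\tchain\t"
                       "start_residue\tnative_sequence"]
        for cls, frags in self.classes.items():
            if not frags:
                continue
            write_cg_pdb([f.conformer for f in frags], directory / f"{cls}.cgpdb")
            for i, f in enumerate(frags):
                index_lines.append(f"{i}\t{cls}\t{f.source_id}\t{f.chain_id}\t"
                                   f"{f.start_residue}\t{f.native_sequence}")
        (directory / "index.tsv").write_text("\n".join(index_lines) + "\n")

    @classmethod
    def load(cls, directory: str | Path,
             mapping: CGMapping | None = None) -> "FragmentLibrary":
        from .cg import read_cg_pdb

        directory = Path(directory)
        rows = []
        for line in (directory / "index.tsv").read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            rows.append(line.split("\t"))
        lib = cls()
        by_class: dict[str, list] = {}
        for conf_id, scls, source, chain, start, seq in rows:
            by_class.setdefault(scls, []).append((int(conf_id), source, chain,
                                                  int(start), seq))
        for scls, entries in by_class.items():
            structures = read_cg_pdb(directory / f"{scls}.cgpdb", mapping=mapping)
            frags = []
            for (conf_id, source, chain, start, seq), conf in zip(
                    sorted(entries), structures):
                frags.append(TrinucleotideFragment(
                    conformer=conf, source_id=source, chain_id=chain,
                    start_residue=start, native_sequence=seq,
                    sequence_class=scls))
            lib.classes[scls] = frags
        return lib


def deduplicate_library(frags: list[TrinucleotideFragment],
                        threshold: float | None = 0.2) -> FragmentLibrary:
    """Greedy redundancy removal in input order.

    A fragment is kept iff its superposed RMSD to every previously kept
    fragment exceeds ``threshold`` (pass ``None`` to keep everything).  The
    retained set is order-dependent by construction.
    """
    if threshold is not None and threshold <= 0:
        raise ValueError(f"dedup threshold must be positive, got {threshold}")
    classes = {f.sequence_class for f in frags}
    if len(classes) > 1:
        raise ValueError(f"fragments span multiple sequence classes: {sorted(classes)}")
    kept: list[TrinucleotideFragment] = []
    for f in frags:
        if threshold is None or all(
                superposed_rmsd(f.conformer, k.conformer) > threshold for k in kept):
            kept.append(f)
    cls = next(iter(classes)) if classes else "other"
    lib = FragmentLibrary(classes={cls: kept}, dedup_threshold=threshold)
    lib.provenance.append(
        f"deduplicate_library: {len(frags)} in, {len(kept)} kept, "
        f"threshold={threshold}")
    return lib


def best_fit(library: FragmentLibrary,
             target: TrinucleotideFragment) -> tuple[TrinucleotideFragment, float]:
    """Library conformer with minimal superposed RMSD to the target.

    Ties break to the lowest conformer index.
    """
    members = library.classes.get(target.sequence_class, [])
    if not members:
        raise ValueError(f"library class {target.sequence_class!r} is empty")
    best_i, best_r = 0, np.inf
    for i, cand in enumerate(members):
        r = superposed_rmsd(cand.conformer, target.conformer)
        if r < best_r:
            best_i, best_r = i, r
    return members[best_i], float(best_r)
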