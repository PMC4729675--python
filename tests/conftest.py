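"""Shared fixtures: text PDB fixtures, synthetic CG chains, toy pools."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ssrna_fragdock.cg import CGMapping, CGStructure, RigidTransform
from ssrna_fragdock.docking import DockingPool, ForceFieldParams, Pose
from ssrna_fragdock.toybench import make_scenario


def pdb_atom_line(serial, name, resname, chain, resseq, xyz, altloc=" ",
                  element="C", record="ATOM"):
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} "
            f"{chain}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00          {element:>2s}")


#: heavy atoms of an adenosine nucleotide (coordinates arbitrary but distinct)
ADENOSINE_ATOMS = [
    ("P", (0.0, 0.0, 0.0)), ("OP1", (1.0, 0.5, 0.0)), ("OP2", (-1.0, 0.5, 0.0)),
    ("O5'", (0.0, -1.0, 1.0)), ("C5'", (0.5, -1.5, 2.0)), ("C4'", (0.0, -1.0, 3.2)),
    ("O4'", (0.8, 0.1, 3.5)), ("C3'", (-1.4, -0.8, 3.6)), ("O3'", (-2.2, -1.9, 3.4)),
    ("C2'", (-1.2, -0.4, 5.0)), ("O2'", (-2.0, 0.7, 5.3)), ("C1'", (0.3, 0.0, 5.0)),
    ("N9", (1.0, 1.0, 5.8)), ("C4", (2.3, 1.4, 5.7)), ("N7", (0.6, 1.8, 6.8)),
    ("C8", (1.6, 2.5, 7.2)), ("C5", (2.7, 2.3, 6.6)), ("C6", (4.0, 2.8, 6.8)),
    ("N6", (4.4, 3.7, 7.7)), ("N1", (4.9, 2.3, 5.9)), ("C2", (4.5, 1.4, 5.0)),
    ("N3", (3.2, 0.9, 4.8)),
]


@pytest.fixture
def adenosine_pdb(tmp_path):
    lines = [pdb_atom_line(i + 1, n, "A", "B", 1, xyz,
                           element="P" if n == "P" else n[0])
             for i, (n, xyz) in enumerate(ADENOSINE_ATOMS)]
    lines.append("END")
    path = tmp_path / "adenosine.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def mapping():
    return CGMapping.default()


def make_cg_chain(res_numbers, res_name="U", chain_id="X", beads_per_res=2,
                  rng=None, spacing=6.0):
    """Synthetic CG RNA chain: ``beads_per_res`` beads per residue.

    Bead names/roles follow the default mapping's first entries so the
    structures are acceptable to overlap/canonicalisation code paths.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    names = ["PHO", "SG1", "SG2", "BS1", "BS2", "BS3"][:beads_per_res]
    roles = ["phosphate", "sugar", "sugar", "base", "base", "base"][:beads_per_res]
    coords, codes, charges, ridx, cids, rs, ns = [], [], [], [], [], [], []
    residues = []
    for k, num in enumerate(res_numbers):
        base = np.array([spacing * k, 0.0, 0.0])
        residues.append((chain_id, int(num), res_name))
        for b in range(beads_per_res):
            coords.append(base + rng.normal(scale=1.0, size=3))
            codes.append(b + 1)
            charges.append(0.0)
            ridx.append(int(num))
            cids.append(chain_id)
            rs.append(roles[b])
            ns.append(names[b])
    return CGStructure(np.array(coords), codes, charges, ridx,
                       np.array(cids, dtype=object), np.array(rs, dtype=object),
                       np.array(ns, dtype=object), residues)


@pytest.fixture(scope="session")
def scenario():
    return make_scenario(seed=7)


@pytest.fixture
def planted_pool(scenario):
    """Pool containing the exact planted poses (re-identified, rank-sorted)."""
    poses = []
    for i, p in enumerate(scenario.planted_poses):
        poses.append(Pose(pose_id=i + 1, conformer_id=p.conformer_id,
                          transform=p.transform, energy=-10.0 + i,
                          coords=p.coords.copy()))
    pool = DockingPool(poses=poses,
                       conformers=dict(scenario.planted_conformers))
    return pool.sort_and_rank()


def single_bead_ff(eps=1.0, R=3.0, attractive=True, **kw):
    """1-pair force field for closed-form docking checks."""
    kw.setdefault("cutoff_sq", None)
    kw.setdefault("com_restraint_k", 0.0)
    return ForceFieldParams(pair_table={(1, 2): (eps, R, attractive)},
                            dielectric_model=kw.pop("dielectric_model", "distance"),
                            **kw)


def single_bead_structure(xyz, type_code, charge=0.0, chain="Z", res=1):
    return CGStructure(np.array([xyz], dtype=float), [type_code], [charge],
                       [res], np.array([chain], dtype=object),
                       np.array(["sidechain"], dtype=object),
                       np.array(["X1"], dtype=object), [(chain, res, "TOY")])


def random_pose_pool(rng, scenario, n=30, radius=25.0):
    """Random placements of the scenario's conformers (no docking)."""
    poses = []
    cids = sorted(scenario.planted_conformers)
    for i in range(n):
        cid = cids[int(rng.integers(len(cids)))]
        conf = scenario.planted_conformers[cid]
        rot = RigidTransform.random_rotation(rng)
        t = RigidTransform(rot.rotation,
                           rng.normal(scale=radius, size=3))
        poses.append(Pose(pose_id=i, conformer_id=cid, transform=t,
                          energy=float(rng.normal()), coords=t.apply(conf.coords)))
    pool = DockingPool(poses=poses, conformers=dict(scenario.planted_conformers))
    return pool.sort_and_rank()
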