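"""Deterministic synthetic docking scenarios for end-to-end testing.

A toy receptor is a repulsive bead shell with a groove of attractive
"cradle" beads lining an 8-nucleotide RNA-like path.  Six overlapping
trinucleotide fragments threaded through the groove form the planted chain;
their conformers (plus perturbed decoy conformers) form the toy library, and
far-away random placements provide zero-propensity decoy poses.  Every
planted pose sits in a wide, type-matched energy funnel of the toy force
field, so ensemble docking recovers the chain at small scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cg import CGStructure, RigidTransform
from .docking import ForceFieldParams, Pose, fibonacci_sphere
from .library import FragmentLibrary, TrinucleotideFragment

# one toy nucleotide: 6 beads, local frame with +z pointing away from the
# receptor surface and +x along the chain
_NT_BEADS = [
    # name, role, base type, charge, local position (spread around the
    # nucleotide centre so per-bead cradle directions are well conditioned)
    ("PHO", "phosphate", 1, 0.0, (-2.0, 0.0, 2.2)),
    ("SG1", "sugar", 2, 0.0, (-0.3, 1.2, 0.9)),
    ("SG2", "sugar", 3, 0.0, (1.5, -0.6, 0.6)),
    ("BS1", "base", 10, 0.0, (2.0, 0.8, -1.4)),
    ("BS2", "base", 11, 0.0, (0.3, 1.4, -2.6)),
    ("BS3", "base", 12, 0.0, (-0.6, -1.4, -2.2)),
]
BASE_TYPES = tuple(b[2] for b in _NT_BEADS)
#: bead types are position-specific: base type + POSITION_STRIDE * nt index,
#: so each nucleotide slot of the groove attracts exactly the beads meant
#: for it and every conformer has a single strongly funnelled binding site
POSITION_STRIDE = 20
ATTRACTOR_OFFSET = 1000  # cradle type for fragment type t is t + 1000
SHELL_TYPE = 5000

#: contact distance between a fragment bead and its cradle attractor; the
#: 8-6 well width scales with it, so a generous distance keeps the energy
#: funnel wide enough for small start counts
CRADLE_DISTANCE = 6.0

N_NUCLEOTIDES = 8
N_FRAGMENTS = 6


def fragment_types() -> list[int]:
    return [t + POSITION_STRIDE * j for j in range(N_NUCLEOTIDES)
            for t in BASE_TYPES]


def toy_force_field(eps_match: float = 4.0, eps_cross: float = 0.0,
                    eps_shell: float = 0.5,
                    cutoff_sq: float = 400.0) -> ForceFieldParams:
    """Pair table for the toy scenario.

    Each fragment bead type is strongly attracted to its own cradle type
    (pair minimum exactly at the cradle contact distance), indifferent to
    every other cradle type by default, and repelled by the shell.  With
    zero cross terms the planted placement minimises every bead's matched
    pair simultaneously, so it is an energy minimum by construction.
    """
    R_match = CRADLE_DISTANCE / math.sqrt(4.0 / 3.0)
    table = {}
    types = fragment_types()
    for t in types:
        for t2 in types:
            eps, att = (eps_match, True) if t == t2 else (eps_cross, False)
            table[(t, t2 + ATTRACTOR_OFFSET)] = (eps, R_match, att)
        table[(t, SHELL_TYPE)] = (eps_shell, 3.0, False)
    return ForceFieldParams(pair_table=table, dielectric_model="distance",
                            cutoff_sq=cutoff_sq, com_restraint_k=0.0015)


def _nucleotide_frames(radius: float = 18.0, arc_step: float = 6.0,
                       twist_amp: float = 0.7,
                       radius_wobble: float = 2.5,
                       z_wobble: float = 2.0) -> list[tuple[np.ndarray, np.ndarray]]:
    """(origin, rotation matrix) per nucleotide along an equatorial arc.

    Twist about the radial axis plus radial and axial wobbles vary the local
    geometry so that the six overlapping fragments are genuinely distinct
    conformers (mutually > 1 A superposed RMSD).
    """
    frames = []
    dphi = arc_step / radius
    for i in range(N_NUCLEOTIDES):
        phi = i * dphi
        r_i = radius + radius_wobble * math.sin(1.3 * i)
        z_i = z_wobble * math.sin(0.9 * i + 1.0)
        u = np.array([math.cos(phi), math.sin(phi), 0.0])   # outward radial
        t = np.array([-math.sin(phi), math.cos(phi), 0.0])  # tangent
        n = np.array([0.0, 0.0, 1.0])
        M = np.column_stack([t, n, u])  # local x->tangent, y->z, z->radial
        tw = twist_amp * math.sin(1.1 * i + 0.4)
        ct, st = math.cos(tw), math.sin(tw)
        twist = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
        frames.append((r_i * u + z_i * n, M @ twist))
    return frames


def _nucleotide_structure(origin: np.ndarray, M: np.ndarray,
                          residue_index: int) -> CGStructure:
    coords = np.array([origin + M @ np.asarray(xyz) for *_, xyz in _NT_BEADS])
    names = [b[0] for b in _NT_BEADS]
    roles = [b[1] for b in _NT_BEADS]
    codes = [b[2] + POSITION_STRIDE * (residue_index - 1) for b in _NT_BEADS]
    charges = [b[3] for b in _NT_BEADS]
    return CGStructure(
        coords, codes, charges, [residue_index] * len(names),
        np.array(["T"] * len(names), dtype=object),
        np.array(roles, dtype=object), np.array(names, dtype=object),
        [("T", residue_index, "U")],
    )


@dataclass
class ToyScenario:
    """All inputs for a small end-to-end docking run, fixed by a seed."""

    seed: int
    receptor: CGStructure
    ff: ForceFieldParams
    ground_truth: list[CGStructure]          # planted fragments, world frame
    planted_conformers: dict[int, CGStructure]  # conformer_id -> centred frame
    planted_poses: list[Pose]                # exact planted placements
    library: FragmentLibrary
    decoy_poses: list[Pose]
    path_radius: float
    params: dict = field(default_factory=dict)


def make_scenario(
    seed: int = 0,
    n_decoy_conformers: int = 2,
    n_decoy_poses: int = 200,
    groove_depth: float = CRADLE_DISTANCE,
    shell_radius: float = 13.0,
    n_shell: int = 120,
    decoy_radius: float = 60.0,
) -> ToyScenario:
    """Build the synthetic receptor, planted chain, library and decoys.

    Deterministic for a fixed seed: the planted geometry and receptor are
    seed-independent; the seed drives conformer-frame rotations, decoy
    conformer jitter and decoy pose placement.
    """
    if n_decoy_conformers < 0 or n_decoy_poses < 0:
        raise ValueError("decoy counts must be >= 0")
    rng = np.random.default_rng(seed)
    frames = _nucleotide_frames()
    nucleotides = [_nucleotide_structure(o, M, i + 1)
                   for i, (o, M) in enumerate(frames)]

    ground_truth = [CGStructure.concatenate(nucleotides[i:i + 3])
                    for i in range(N_FRAGMENTS)]

    # receptor: a type-matched cradle attractor 'groove_depth' outward of
    # every planted bead along the bead's own radial direction from its
    # nucleotide centre (a loose cage locking both position and
    # orientation), plus a repulsive shell with the groove region carved out
    cradle_coords, cradle_types = [], []
    for nt in nucleotides:
        centre = nt.com
        for k in range(len(nt)):
            e = nt.coords[k] - centre
            e /= np.linalg.norm(e)
            cradle_coords.append(nt.coords[k] + groove_depth * e)
            cradle_types.append(int(nt.type_codes[k]) + ATTRACTOR_OFFSET)
    cradle_coords = np.array(cradle_coords)
    rna_coords = np.vstack([nt.coords for nt in nucleotides])
    shell = shell_radius * fibonacci_sphere(n_shell)
    near = np.vstack([cradle_coords, rna_coords])
    keep = np.array([np.linalg.norm(near - p, axis=1).min() > 6.0
                     for p in shell])
    shell = shell[keep]
    rec_coords = np.vstack([cradle_coords, shell])
    rec_types = cradle_types + [SHELL_TYPE] * len(shell)
    n_rec = len(rec_coords)
    receptor = CGStructure(
        rec_coords, rec_types, [0.0] * n_rec, list(range(1, n_rec + 1)),
        np.array(["R"] * n_rec, dtype=object),
        np.array(["sidechain"] * n_rec, dtype=object),
        np.array(["CR"] * n_rec, dtype=object),
        [("R", i + 1, "TOY") for i in range(n_rec)],
    )

    # conformers: each planted fragment centred on its COM and spun by a
    # seed-random rotation; the planted pose transform undoes both
    planted_conformers: dict[int, CGStructure] = {}
    planted_poses: list[Pose] = []
    for cid, frag in enumerate(ground_truth, start=1):
        com = frag.com
        spin = RigidTransform.random_rotation(rng)
        conf = frag.with_coords(spin.apply(frag.coords - com))
        planted_conformers[cid] = conf
        t = RigidTransform(spin.rotation.T, com)
        planted_poses.append(Pose(pose_id=-cid, conformer_id=cid, transform=t,
                                  energy=math.nan, coords=t.apply(conf.coords)))

    # library: planted conformers first, then jittered decoy conformers
    frags = []
    for cid in sorted(planted_conformers):
        frags.append(TrinucleotideFragment(
            conformer=planted_conformers[cid], source_id="toy", chain_id="T",
            start_residue=cid, native_sequence="UUU", sequence_class="UUU"))
    decoy_conf_ids = []
    for d in range(n_decoy_conformers):
        base = planted_conformers[1 + d % N_FRAGMENTS]
        jitter = rng.normal(scale=1.2, size=base.coords.shape)
        conf = base.with_coords(base.coords - base.coords.mean(axis=0) + jitter)
        conf = conf.with_coords(conf.coords - conf.coords.mean(axis=0))
        cid = N_FRAGMENTS + 1 + d
        decoy_conf_ids.append(cid)
        frags.append(TrinucleotideFragment(
            conformer=conf, source_id="toy-decoy", chain_id="T",
            start_residue=cid, native_sequence="UUU", sequence_class="UUU"))
    library = FragmentLibrary(classes={"UUU": frags})
    library.provenance.append(f"toybench seed={seed}")

    # decoy poses: isolated placements on a far sphere; Fibonacci spacing at
    # this radius keeps every pair of decoys (and any decoy-planted pair)
    # too distant to satisfy the overlap criterion, so their chain
    # propensity is zero by construction
    decoy_poses = []
    if n_decoy_poses:
        points = decoy_radius * fibonacci_sphere(n_decoy_poses)
        for k in range(n_decoy_poses):
            cid = 1 + int(rng.integers(N_FRAGMENTS))
            rot = RigidTransform.random_rotation(rng)
            t = RigidTransform(rot.rotation, points[k])
            decoy_poses.append(Pose(
                pose_id=10_000_000 + k, conformer_id=cid, transform=t,
                energy=0.0, coords=t.apply(planted_conformers[cid].coords)))

    return ToyScenario(
        seed=seed, receptor=receptor, ff=toy_force_field(),
        ground_truth=ground_truth, planted_conformers=planted_conformers,
        planted_poses=planted_poses, library=library, decoy_poses=decoy_poses,
        path_radius=18.0,
        params={"n_decoy_conformers": n_decoy_conformers,
                "n_decoy_poses": n_decoy_poses, "groove_depth": groove_depth},
    )
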