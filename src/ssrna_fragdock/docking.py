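"""Rigid-body docking of fragment conformers onto a coarse-grained receptor.

The pair potential is an 8-6 form  eps * ((R/r)^8 - (R/r)^6)  (the -r^6 term
flips to +r^6 for pairs flagged non-attractive) plus a Coulomb term
q_i q_j * 332.0636 / (eps(r) * r) with a constant or distance-dependent
(eps(r) = r) dielectric.  Minimisation runs on a pre-computed receptor grid
with trilinear interpolation; re-scoring is grid-free with a pair cutoff on
the squared distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cg import CGStructure, RigidTransform

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0636  # kcal/mol * Angstrom / e^2

#: Separation minimising the attractive 8-6 term: r* = R * sqrt(4/3).
PAIR_MINIMUM_FACTOR = math.sqrt(4.0 / 3.0)
#: Well depth at r*: E(r*) = -eps * 27/256.
PAIR_MINIMUM_DEPTH = -27.0 / 256.0


class UnknownPairError(KeyError):
    """A bead-type pair is absent from the force-field table."""


@dataclass
class ForceFieldParams:
    """Pairwise 8-6 + Coulomb parameters.

    ``pair_table`` maps (type_i, type_j) -> (epsilon kcal/mol, R Angstrom,
    attractive flag); it is symmetrised on construction.  ``cutoff_sq`` is
    the squared-distance threshold used for grid-free re-scoring (``None``
    disables the cutoff).  When ``squared_cutoff`` is False the same number
    is interpreted as a plain distance instead.
    """

    pair_table: dict[tuple[int, int], tuple[float, float, bool]]
    dielectric_model: str = "distance"  # "constant" | "distance"
    coulomb_scale: float = 1.0
    cutoff_sq: float | None = 50.0
    squared_cutoff: bool = True
    com_restraint_k: float = 0.0015  # kcal/mol/A^2

    def __post_init__(self):
        table = {}
        for (i, j), (eps, R, att) in self.pair_table.items():
            if eps < 0:
                raise ValueError(f"epsilon must be >= 0 for pair {(i, j)}")
            if R <= 0:
                raise ValueError(f"R must be > 0 for pair {(i, j)}")
            table[(i, j)] = (float(eps), float(R), bool(att))
            table[(j, i)] = (float(eps), float(R), bool(att))
        self.pair_table = table
        if self.dielectric_model not in ("constant", "distance"):
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")

    @property
    def cutoff_distance(self) -> float | None:
        if self.cutoff_sq is None:
            return None
        return math.sqrt(self.cutoff_sq) if self.squared_cutoff else self.cutoff_sq

    def lookup(self, types_a: np.ndarray, types_b: np.ndarray):
        """Dense (len(a), len(b)) epsilon / R / sign arrays for two type lists.

        Results are memoised per type-list pair (pools re-score thousands of
        poses against the same receptor)."""
        key = (tuple(int(t) for t in types_a), tuple(int(t) for t in types_b))
        cache = getattr(self, "_lookup_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_lookup_cache", cache)
        if key in cache:
            return cache[key]
        eps = np.empty((len(types_a), len(types_b)))
        R = np.empty_like(eps)
        sign = np.empty_like(eps)  # -1 attractive r^6 term, +1 repulsive
        for ia, ta in enumerate(types_a):
            for ib, tb in enumerate(types_b):
                try:
                    e, r0, att = self.pair_table[(int(ta), int(tb))]
                except KeyError:
                    raise UnknownPairError(
                        f"no force-field entry for type pair ({int(ta)}, {int(tb)})")
                eps[ia, ib], R[ia, ib] = e, r0
                sign[ia, ib] = -1.0 if att else 1.0
        cache[key] = (eps, R, sign)
        return eps, R, sign

    def to_table(self, path: str | Path) -> None:
        """Write the pair table in the :meth:`from_table` format."""
        lines = ["# type_i type_j epsilon R attractive"]
        for (i, j), (eps, R, att) in sorted(self.pair_table.items()):
            if i <= j:
                lines.append(f"{i} {j} {eps:g} {R:.6g} {int(att)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path, **kwargs) -> "ForceFieldParams":
        """Read a whitespace table: type_i type_j epsilon R attractive(0/1)."""
        table = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ti, tj, eps, R, att = line.split()
            table[(int(ti), int(tj))] = (float(eps), float(R), bool(int(att)))
        return cls(pair_table=table, **kwargs)


def pair_potential(r, eps, R, sign):
    """8-6 pair energy; ``sign`` is -1 for attractive, +1 for repulsive."""
    x2 = (R / r) ** 2
    return eps * (x2 ** 4 + sign * x2 ** 3)


def _coulomb(r, qq, ff: ForceFieldParams):
    if ff.dielectric_model == "distance":
        return COULOMB_CONSTANT * qq / (ff.coulomb_scale * r * r)
    return COULOMB_CONSTANT * qq / (ff.coulomb_scale * r)


def energy(
    protein: CGStructure,
    fragment: CGStructure,
    ff: ForceFieldParams,
    com_restraint: bool = False,
    use_cutoff: bool = True,
    fragment_coords: np.ndarray | None = None,
) -> float:
    """Direct-summation interaction energy between receptor and fragment.

    Pairs beyond the configured cutoff are excluded when ``use_cutoff``.
    With ``com_restraint`` a harmonic k*d^2 on the fragment-COM to
    receptor-COM distance is added.
    """
    fc = fragment.coords if fragment_coords is None else fragment_coords
    total = 0.0
    if len(protein) and len(fc):
        diff = protein.coords[:, None, :] - fc[None, :, :]
        r = np.sqrt((diff ** 2).sum(axis=-1))
        eps, R, sign = ff.lookup(protein.type_codes, fragment.type_codes)
        mask = r > 0
        if use_cutoff and ff.cutoff_distance is not None:
            mask &= r <= ff.cutoff_distance
        qq = np.outer(protein.charges, fragment.charges)
        rs = np.where(mask, r, 1.0)
        e = pair_potential(rs, eps, R, sign) + _coulomb(rs, qq, ff)
        total = float(e[mask].sum())
    if com_restraint and len(protein) and len(fc):
        d = np.linalg.norm(fc.mean(axis=0) - protein.com)
        total += ff.com_restraint_k * d * d
    return total


# ---------------------------------------------------------------------------
# Receptor grid


class ReceptorGrid:
    """Pre-computed per-bead-type potential and gradient lattices.

    ``potentials[t]`` holds the 8-6 energy of a type-``t`` probe bead at each
    lattice node; ``elec`` holds the electrostatic potential per unit probe
    charge.  Gradients are central-difference lattices of the potentials.
    Trilinear interpolation reproduces node values exactly.
    """

    def __init__(self, origin, spacing, shape, potentials, gradients,
                 elec, elec_gradient, receptor_com):
        self.origin = np.asarray(origin, dtype=float)
        self.spacing = float(spacing)
        self.shape = tuple(shape)
        self.potentials = potentials          # type -> (nx,ny,nz)
        self.gradients = gradients            # type -> (nx,ny,nz,3)
        self.elec = elec                      # (nx,ny,nz)
        self.elec_gradient = elec_gradient    # (nx,ny,nz,3)
        self.receptor_com = np.asarray(receptor_com, dtype=float)
        # stacked value lattices for fast fancy-indexed interpolation:
        # slot 0..T-1 per probe type, slot T for electrostatics
        self._slot_of = {int(t): i for i, t in enumerate(sorted(potentials))}
        pots = [potentials[t] for t in sorted(potentials)] + [elec]
        self._val = np.stack(pots)                      # (T+1, nx, ny, nz)
        self._shape_arr = np.asarray(shape)

    def slots_for(self, type_codes) -> np.ndarray:
        return np.array([self._slot_of[int(t)] for t in type_codes])

    def evaluate(self, type_codes, charges, coords, slots=None):
        """Interpolated energy and per-bead gradient for a probe bead set.

        The gradient is the exact within-cell derivative of the trilinear
        interpolant, so it is consistent with the energy (required for
        stable line searches).  Beads outside the grid box contribute zero.
        ``slots`` (from :meth:`slots_for`) may be passed to skip the
        type-code translation on repeated calls.
        """
        e, grad = self.evaluate_per_bead(type_codes, charges, coords, slots)
        return float(e.sum()), grad

    def evaluate_per_bead(self, type_codes, charges, coords, slots=None):
        """Per-bead interpolated energies and gradients (see evaluate)."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(coords)
        grad = np.zeros((n, 3))
        if not self.shape or min(self.shape) < 2:
            return np.zeros(n), grad
        if slots is None:
            slots = self.slots_for(type_codes)
        q = np.asarray(charges, dtype=float)
        g = (coords - self.origin) / self.spacing
        inside = np.all((g >= 0) & (g <= self._shape_arr - 1), axis=1)
        gc = np.clip(g, 0, self._shape_arr - 1 - 1e-9)
        i0 = np.minimum(gc.astype(int), self._shape_arr - 2)
        f = gc - i0
        x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
        fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
        e = np.zeros(n)
        elec_slot = self._val.shape[0] - 1
        inv_h = 1.0 / self.spacing
        for dx, wx, sx in ((0, 1 - fx, -1.0), (1, fx, 1.0)):
            for dy, wy, sy in ((0, 1 - fy, -1.0), (1, fy, 1.0)):
                for dz, wz, sz in ((0, 1 - fz, -1.0), (1, fz, 1.0)):
                    xi, yi, zi = x0 + dx, y0 + dy, z0 + dz
                    v = self._val[slots, xi, yi, zi] \
                        + q * self._val[elec_slot, xi, yi, zi]
                    e += (wx * wy * wz) * v
                    grad[:, 0] += sx * (wy * wz) * v * inv_h
                    grad[:, 1] += sy * (wx * wz) * v * inv_h
                    grad[:, 2] += sz * (wx * wy) * v * inv_h
        e[~inside] = 0.0
        grad[~inside] = 0.0
        return e, grad


def build_grid(
    protein: CGStructure,
    ff: ForceFieldParams,
    spacing: float = 1.0,
    padding: float = 10.0,
    probe_types: list[int] | None = None,
    use_cutoff: bool = True,
    core_clamp: float = 1000.0,
) -> ReceptorGrid:
    """Tabulate receptor potentials on a lattice covering the protein box.

    Node energies above ``core_clamp`` (deep inside bead cores) are clamped
    so that interpolated gradients stay finite near the receptor surface.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if probe_types is None:
        probe_types = sorted({t for pair in ff.pair_table for t in pair})
    if len(protein) == 0:
        zero = np.zeros((2, 2, 2))
        zvec = np.zeros((2, 2, 2, 3))
        return ReceptorGrid(np.zeros(3), spacing, (2, 2, 2),
                            {int(t): zero for t in probe_types},
                            {int(t): zvec for t in probe_types},
                            zero, zvec, np.zeros(3))
    lo = protein.coords.min(axis=0) - padding
    hi = protein.coords.max(axis=0) + padding
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    axes = [lo[k] + spacing * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    n_nodes = len(nodes)
    cut = ff.cutoff_distance if use_cutoff else None

    flat = {int(t): np.zeros(n_nodes) for t in probe_types}
    elec_flat = np.zeros(n_nodes)
    params = {int(t): ff.lookup(protein.type_codes, [t]) for t in probe_types}
    chunk = max(1, int(4e6 // max(1, len(protein))))
    for s in range(0, n_nodes, chunk):
        block = nodes[s:s + chunk]
        diff = block[:, None, :] - protein.coords[None, :, :]
        r = np.sqrt((diff ** 2).sum(axis=-1))
        r = np.maximum(r, 1e-6)
        within = r <= cut if cut is not None else np.ones_like(r, dtype=bool)
        for t in probe_types:
            eps, R, sign = params[int(t)]
            e = pair_potential(r, eps[:, 0][None, :], R[:, 0][None, :],
                               sign[:, 0][None, :])
            flat[int(t)][s:s + chunk] = np.where(within, e, 0.0).sum(axis=1)
        ecol = _coulomb(r, protein.charges[None, :], ff)
        elec_flat[s:s + chunk] = np.where(within, ecol, 0.0).sum(axis=1)

    potentials, gradients = {}, {}
    for t in probe_types:
        lattice = np.clip(flat[int(t)].reshape(shape), None, core_clamp)
        potentials[int(t)] = lattice
        gradients[int(t)] = np.stack(
            np.gradient(lattice, spacing, edge_order=2), axis=-1
        ).astype(np.float32)
    elec = np.clip(elec_flat.reshape(shape), -core_clamp, core_clamp)
    elec_grad = np.stack(
        np.gradient(elec, spacing, edge_order=2), axis=-1).astype(np.float32)
    return ReceptorGrid(lo, spacing, shape, potentials, gradients,
                        elec, elec_grad, protein.com)


# ---------------------------------------------------------------------------
# Poses and pools


@dataclass
class Pose:
    """A rigid placement of one conformer with its energy and rank."""

    pose_id: int
    conformer_id: int
    transform: RigidTransform
    energy: float
    rank: int = 0
    coords: np.ndarray | None = None  # transformed bead coordinates (cache)

    @property
    def com(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class DockingPool:
    """Energy-sorted pose collection with provenance."""

    poses: list[Pose] = field(default_factory=list)
    conformers: dict[int, CGStructure] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.poses)

    def sort_and_rank(self) -> "DockingPool":
        self.poses.sort(key=lambda p: (p.energy, p.pose_id))
        for i, p in enumerate(self.poses, start=1):
            p.rank = i
        return self

    def check_sorted(self):
        es = [p.energy for p in self.poses]
        assert all(es[i] <= es[i + 1] for i in range(len(es) - 1))


# ---------------------------------------------------------------------------
# Start generation


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-equidistant unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


def generate_starts(n: int, radius: float, seed: int,
                    receptor_com) -> list[RigidTransform]:
    """Deterministic starting placements for a COM-centred conformer.

    COM positions sit on a Fibonacci lattice of the sphere of ``radius``
    around ``receptor_com``; orientations are uniform random rotations from
    the seeded generator.  The conformer is assumed centred at the origin, so
    the translation directly places its COM.
    """
    if n < 1:
        raise ValueError("need at least one start")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    receptor_com = np.asarray(receptor_com, dtype=float)
    points = receptor_com + radius * fibonacci_sphere(n)
    out = []
    for k in range(n):
        rot = RigidTransform.random_rotation(rng)
        out.append(RigidTransform(rot.rotation, points[k]))
    return out


# ---------------------------------------------------------------------------
# Minimisation

def direct_energy_gradient(protein: CGStructure, ff: ForceFieldParams,
                           type_codes, charges, coords):
    """Direct-summation energy and per-bead gradient (no cutoff, no
    restraint); used for the grid-free polish phase of minimisation."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if len(protein) == 0 or n == 0:
        return 0.0, np.zeros((n, 3))
    diff = coords[None, :, :] - protein.coords[:, None, :]  # (P, n, 3)
    r = np.sqrt((diff ** 2).sum(axis=-1))
    r = np.maximum(r, 1e-9)
    eps, R, sign = ff.lookup(protein.type_codes, type_codes)
    x2 = (R / r) ** 2
    x6 = x2 ** 3
    x8 = x2 ** 4
    e = eps * (x8 + sign * x6)
    dvdr = -(eps / r) * (8.0 * x8 + 6.0 * sign * x6)
    qq = np.outer(protein.charges, charges)
    if ff.dielectric_model == "distance":
        ec = COULOMB_CONSTANT * qq / (ff.coulomb_scale * r * r)
        dvdr += -2.0 * ec / r
    else:
        ec = COULOMB_CONSTANT * qq / (ff.coulomb_scale * r)
        dvdr += -ec / r
    e = e + ec
    grad = ((dvdr / r)[:, :, None] * diff).sum(axis=0)
    return float(e.sum()), grad


def _so3_left_jacobian(v: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(v)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    if theta < 1e-8:
        return np.eye(3) + 0.5 * K
    A = (1.0 - math.cos(theta)) / theta ** 2
    B = (theta - math.sin(theta)) / theta ** 3
    return np.eye(3) + A * K + B * (K @ K)


def minimize(
    pose: Pose,
    conformer: CGStructure,
    grid: ReceptorGrid,
    ff: ForceFieldParams,
    steps: int = 1000,
    gtol: float = 1e-4,
    protein: CGStructure | None = None,
) -> Pose:
    """Rigid-body local minimisation of a pose on the receptor grid.

    Six degrees of freedom (rotation vector about the fragment COM plus a
    translation) are optimised by L-BFGS-B with an analytic gradient; the COM
    restraint is active throughout.  The returned pose never has higher
    energy than the input.  A pose with non-finite starting energy is
    returned unchanged (flagged by energy = +inf) and logged.

    Trilinear grids put their local minima at lattice nodes, so when the
    receptor is supplied a short direct-summation polish phase refines the
    grid solution to the true minimum of the pair potential.
    """
    from scipy.optimize import minimize as scipy_minimize
    from scipy.spatial.transform import Rotation

    if steps < 1:
        raise ValueError("steps must be >= 1")
    base = pose.transform.apply(conformer.coords)
    center0 = base.mean(axis=0)
    local = base - center0
    codes, charges = conformer.type_codes, conformer.charges
    slots = grid.slots_for(codes)
    k_rest = ff.com_restraint_k
    rcom = grid.receptor_com

    def _rodrigues(rv):
        theta = np.linalg.norm(rv)
        K = np.array([[0, -rv[2], rv[1]], [rv[2], 0, -rv[0]],
                      [-rv[1], rv[0], 0]])
        if theta < 1e-12:
            return np.eye(3) + K
        return np.eye(3) + math.sin(theta) / theta * K \
            + (1.0 - math.cos(theta)) / theta ** 2 * (K @ K)

    def objective(x):
        rv, dt = x[:3], x[3:]
        Rm = _rodrigues(rv)
        center = center0 + dt
        coords = local @ Rm.T + center
        e, bead_grad = grid.evaluate(codes, charges, coords, slots=slots)
        d = center - rcom
        e += k_rest * float(d @ d)
        g_t = bead_grad.sum(axis=0) + 2.0 * k_rest * d
        # dE/d(rotvec) = J_l(rv)^T sum_b (y_b x g_b), y_b = rotated local coords
        y = coords - center
        torque = np.array([
            (y[:, 1] * bead_grad[:, 2] - y[:, 2] * bead_grad[:, 1]).sum(),
            (y[:, 2] * bead_grad[:, 0] - y[:, 0] * bead_grad[:, 2]).sum(),
            (y[:, 0] * bead_grad[:, 1] - y[:, 1] * bead_grad[:, 0]).sum(),
        ])
        g_rv = _so3_left_jacobian(rv).T @ torque
        return e, np.concatenate([g_rv, g_t])

    e0, _ = objective(np.zeros(6))
    if not np.isfinite(e0):
        logger.warning("pose %d: non-finite starting energy, skipped", pose.pose_id)
        return replace(pose, energy=float("inf"), coords=base)

    res = scipy_minimize(objective, np.zeros(6), jac=True, method="L-BFGS-B",
                         options={"maxiter": steps, "gtol": gtol,
                                  "maxcor": 10, "ftol": 1e-12})
    x = res.x if np.isfinite(res.fun) and res.fun <= e0 else np.zeros(6)
    e_final = min(float(objective(x)[0]), e0)

    if protein is not None:

        def direct_objective(z):
            rv, dt = z[:3], z[3:]
            Rm = _rodrigues(rv)
            center = center0 + dt
            coords = local @ Rm.T + center
            e, bead_grad = direct_energy_gradient(protein, ff, codes,
                                                  charges, coords)
            d = center - rcom
            e += k_rest * float(d @ d)
            g_t = bead_grad.sum(axis=0) + 2.0 * k_rest * d
            y = coords - center
            torque = np.array([
                (y[:, 1] * bead_grad[:, 2] - y[:, 2] * bead_grad[:, 1]).sum(),
                (y[:, 2] * bead_grad[:, 0] - y[:, 0] * bead_grad[:, 2]).sum(),
                (y[:, 0] * bead_grad[:, 1] - y[:, 1] * bead_grad[:, 0]).sum(),
            ])
            g_rv = _so3_left_jacobian(rv).T @ torque
            return e, np.concatenate([g_rv, g_t])

        e_start_direct, g_start = direct_objective(np.zeros(6))
        if np.linalg.norm(g_start) <= gtol:
            return replace(pose, energy=float(e_start_direct),
                           coords=base.copy())
        ed0 = direct_objective(x)[0]
        res2 = scipy_minimize(direct_objective, x, jac=True,
                              method="L-BFGS-B",
                              options={"maxiter": max(50, steps // 10),
                                       "gtol": gtol, "ftol": 1e-14})
        if np.isfinite(res2.fun) and res2.fun <= ed0:
            x = res2.x
            e_final = float(res2.fun)
        else:
            e_final = float(ed0)

    rv, dt = x[:3], x[3:]
    Rm = Rotation.from_rotvec(rv).as_matrix()
    delta = RigidTransform(Rm, center0 + dt - Rm @ center0)
    new_t = delta.compose(pose.transform)
    coords = new_t.apply(conformer.coords)
    return replace(pose, transform=new_t, energy=e_final, coords=coords)


def minimize_batch(
    transforms: list[RigidTransform],
    conformer: CGStructure,
    grid: ReceptorGrid,
    ff: ForceFieldParams,
    steps: int = 1000,
    gtol: float = 1e-4,
) -> list[tuple[RigidTransform, float]]:
    """Vectorised rigid-body minimisation of many starts of one conformer.

    Same objective as :func:`minimize` (grid energy + COM restraint), solved
    with adaptive-step projected gradient descent applied to all poses
    simultaneously: a step is accepted per pose only when it lowers that
    pose's energy, so every trajectory is monotone.  Used by the docking
    driver where per-pose quasi-Newton calls would dominate the runtime.
    """
    from scipy.spatial.transform import Rotation

    if steps < 1:
        raise ValueError("steps must be >= 1")
    P = len(transforms)
    if P == 0:
        return []
    local0 = conformer.coords - conformer.com
    n = len(local0)
    rg2 = float((local0 ** 2).sum(axis=1).mean()) or 1.0
    slots = np.tile(grid.slots_for(conformer.type_codes), P)
    charges = np.tile(conformer.charges, P)
    k_rest = ff.com_restraint_k
    rcom = grid.receptor_com

    rg = math.sqrt(rg2)
    slot_base = grid.slots_for(conformer.type_codes)
    charge_base = np.asarray(conformer.charges, dtype=float)

    R_tot = np.stack([t.rotation for t in transforms])       # (P,3,3)
    center = np.stack([t.translation + t.rotation @ conformer.com
                       for t in transforms])
    # local coordinates rotated into each pose's current orientation
    cur_local = np.einsum("pij,nj->pni", R_tot, local0)

    def batch_eval(local, cen):
        m = len(cen)
        coords = (local + cen[:, None, :]).reshape(-1, 3)
        e_b, g_b = grid.evaluate_per_bead(
            None, np.tile(charge_base, m), coords,
            slots=np.tile(slot_base, m))
        e = e_b.reshape(m, n).sum(axis=1)
        g = g_b.reshape(m, n, 3)
        d = cen - rcom
        e = e + k_rest * (d * d).sum(axis=1)
        g_t = g.sum(axis=1) + 2.0 * k_rest * d
        g_w = np.cross(local, g).sum(axis=1)
        return e, g_t, g_w

    e_cur, g_t, g_w = batch_eval(cur_local, center)
    bad = ~np.isfinite(e_cur)
    if bad.any():
        logger.warning("%d poses with non-finite start energy skipped",
                       int(bad.sum()))
        e_cur = np.where(bad, np.inf, e_cur)
    # trust-region steps: move `alpha` Angstrom along the normalised
    # negative gradient (rotation scaled by the radius of gyration so a unit
    # step moves surface beads about one Angstrom); grow on success, shrink
    # on rejection
    alpha = np.full(P, 1.0)
    active = np.isfinite(e_cur)
    finite = active.copy()
    for it in range(steps):
        if it and it % 100 == 0:
            # revive poses whose step size collapsed on rough terrain but
            # whose gradient is still large (mid-descent freeze)
            gn = np.sqrt((g_t ** 2).sum(axis=1) + (g_w ** 2).sum(axis=1) / rg2)
            frozen = finite & ~active & (gn > gtol)
            alpha[frozen] = 0.25
            active |= frozen
        ii = np.flatnonzero(active)
        if not len(ii):
            break
        gt_i, gw_i = g_t[ii], g_w[ii] / rg
        norm6 = np.sqrt((gt_i ** 2).sum(axis=1) + (gw_i ** 2).sum(axis=1))
        norm6 = np.maximum(norm6, 1e-12)
        scale = (alpha[ii] / norm6)[:, None]
        d_t = -scale * gt_i
        d_w = -scale * gw_i / rg
        R_step = Rotation.from_rotvec(d_w).as_matrix()
        trial_local = np.einsum("pij,pnj->pni", R_step, cur_local[ii])
        trial_center = center[ii] + d_t
        e_new, g_t_new, g_w_new = batch_eval(trial_local, trial_center)
        better = np.isfinite(e_new) & (e_new < e_cur[ii])
        acc = ii[better]
        cur_local[acc] = trial_local[better]
        center[acc] = trial_center[better]
        R_tot[acc] = R_step[better] @ R_tot[acc]
        e_cur[acc] = e_new[better]
        g_t[acc] = g_t_new[better]
        g_w[acc] = g_w_new[better]
        alpha[acc] = np.minimum(alpha[acc] * 1.4, 3.0)
        rej = ii[~better]
        alpha[rej] *= 0.5
        gnorm = np.sqrt((g_t[ii] ** 2).sum(axis=1)
                        + (g_w[ii] ** 2).sum(axis=1) / rg2)
        active[ii] = (gnorm > gtol) & (alpha[ii] > 1e-6)
    out = []
    for p in range(P):
        t = RigidTransform(R_tot[p], center[p] - R_tot[p] @ conformer.com)
        out.append((t, float(e_cur[p])))
    return out


def rescore(pose: Pose, conformer: CGStructure, protein: CGStructure,
            ff: ForceFieldParams) -> Pose:
    """Grid-free energy with the pair cutoff applied; no COM restraint."""
    coords = pose.coords
    if coords is None:
        coords = pose.transform.apply(conformer.coords)
    e = energy(protein, conformer, ff, com_restraint=False, use_cutoff=True,
               fragment_coords=coords)
    return replace(pose, energy=float(e), coords=coords)


# ---------------------------------------------------------------------------
# Pool operations


def pose_rmsd(a: Pose, b: Pose) -> float:
    """Ligand-RMSD between two poses of equal bead count (no superposition)."""
    return float(np.sqrt(((a.coords - b.coords) ** 2).sum(axis=1).mean()))


def deduplicate_poses(pool: DockingPool, tol: float = 0.05) -> DockingPool:
    """Drop poses within ``tol`` ligand-RMSD of a better-scored kept pose.

    Only poses of the same conformer are compared.  The pool must be sorted
    by energy; ranks are recomputed afterwards.
    """
    pool.check_sorted()
    kept: list[Pose] = []
    kept_by_conf: dict[int, list[int]] = {}
    coms = np.array([p.com for p in pool.poses]) if pool.poses else np.empty((0, 3))
    tree = cKDTree(coms) if len(coms) else None
    # RMSD >= COM distance, so only poses with nearby COMs can collide
    neighbours = tree.query_ball_point(coms, tol) if tree is not None else []
    index_of = {id(p): i for i, p in enumerate(pool.poses)}
    for i, p in enumerate(pool.poses):
        cand = kept_by_conf.get(p.conformer_id, [])
        near = set(neighbours[i])
        dup = any(j in near and pose_rmsd(p, pool.poses[j]) < tol for j in cand)
        if not dup:
            kept.append(p)
            kept_by_conf.setdefault(p.conformer_id, []).append(i)
    out = DockingPool(poses=kept, conformers=pool.conformers,
                      provenance=dict(pool.provenance))
    out.provenance["dedup_tol"] = tol
    return out.sort_and_rank()


def select_top(pool: DockingPool, fraction: float) -> DockingPool:
    """Keep the ceil(fraction * N) best-energy poses; recompute ranks."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not pool.poses:
        return DockingPool(conformers=pool.conformers,
                           provenance=dict(pool.provenance))
    pool.check_sorted()
    n_keep = math.ceil(fraction * len(pool.poses))
    kept = []
    for p in pool.poses[:n_keep]:
        q = replace(p)
        q.coords = p.coords
        kept.append(q)
    out = DockingPool(poses=kept, conformers=pool.conformers,
                      provenance=dict(pool.provenance))
    out.provenance["top_fraction"] = fraction
    return out.sort_and_rank()


# ---------------------------------------------------------------------------
# Driver


def dock_conformers(
    protein: CGStructure,
    conformers: dict[int, CGStructure],
    ff: ForceFieldParams,
    n_starts: int = 30000,
    start_radius: float = 75.0,
    seed: int = 0,
    steps: int = 1000,
    grid: ReceptorGrid | None = None,
    grid_spacing: float = 1.0,
    grid_padding: float = 10.0,
    dedup_tol: float = 0.05,
    top_fraction: float | None = 0.2,
    polish_top: int = 200,
    polish_steps: int = 200,
) -> DockingPool:
    """Full per-conformer ensemble docking.

    Conformers are centred on their COM, started on the sphere, minimised on
    the grid (vectorised batch descent, then quasi-Newton polish of the
    ``polish_top`` best-energy placements), re-scored without the grid,
    sorted, de-duplicated, and the top fraction is kept.  Deterministic for
    a fixed seed.
    """
    if grid is None:
        probe_types = sorted({int(t) for c in conformers.values()
                              for t in c.type_codes})
        grid = build_grid(protein, ff, spacing=grid_spacing,
                          padding=grid_padding, probe_types=probe_types)
    centred = {cid: c.with_coords(c.coords - c.com)
               for cid, c in conformers.items()}
    pool = DockingPool(conformers=centred,
                       provenance={"seed": seed, "n_starts": n_starts,
                                   "start_radius": start_radius})
    pid = 0
    for cid in sorted(centred):
        conf = centred[cid]
        starts = generate_starts(n_starts, start_radius, seed + cid, protein.com)
        results = minimize_batch(starts, conf, grid, ff, steps=steps)
        energies = np.array([e for _, e in results])
        polish = set(np.argsort(energies, kind="stable")[:polish_top].tolist())
        for k, (t, e) in enumerate(results):
            if np.isfinite(e):
                pose = Pose(pose_id=pid, conformer_id=cid, transform=t,
                            energy=e, coords=t.apply(conf.coords))
                if k in polish:
                    pose = minimize(pose, conf, grid, ff, steps=polish_steps,
                                    protein=protein)
                pose = rescore(pose, conf, protein, ff)
                pool.poses.append(pose)
            pid += 1
    pool.sort_and_rank()
    pool = deduplicate_poses(pool, tol=dedup_tol)
    if top_fraction is not None:
        pool = select_top(pool, top_fraction)
    return pool
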