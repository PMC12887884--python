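"""Rigid-body Brownian dynamics with the three-contact reaction criterion.

The glycan diffuses as a rigid body around a fixed fibril under the
screened-Coulomb force field (Ermak-McCammon overdamped propagation).
Trajectories start uniformly on the b-sphere and end when either

* the reaction criterion fires: at least ``reaction_min_contacts`` pairs of
  glycan sulfur reference atoms and fibril basic-residue reference atoms
  (Lys NZ / Arg CZ, solvent-exposed only) are simultaneously within
  ``reaction_distance`` (default 7.5 Å, 3 contacts), or
* the glycan crosses the q-sphere (escape), or
* the step budget is exhausted.

The timestep switches from ``dt_far`` (1.0 ps) to ``dt_near`` (0.01 ps)
whenever any glycan reference atom comes within ``near_shell`` of a fibril
reference atom.  Association rates can be recovered from the bound fraction
with the Northrup-Allison-McCammon formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (KB, stokes_einstein_dt, stokes_einstein_dr,
                        water_viscosity)
from .electrostatics import SolventParams, debye_length
from .geometry import Pose, random_rotation, rotation_from_rotvec


@dataclass
class BDParams:
    solvent: SolventParams = field(default_factory=SolventParams)
    dt_far: float = 1.0                 # ps
    dt_near: float = 0.01               # ps
    near_shell: float = 15.0            # Å (2 x reaction distance)
    reaction_distance: float = 7.5      # Å
    reaction_min_contacts: int = 3
    b_radius: float | None = None       # Å; default from fibril + Debye
    q_radius: float | None = None       # Å; default 10 x b_radius
    max_steps: int = 10_000_000
    hydrodynamic_radius: float = 8.0    # Å (short GAG)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.dt_near <= self.dt_far):
            raise ValueError("need 0 < dt_near <= dt_far")
        if self.reaction_min_contacts < 1:
            raise ValueError("reaction_min_contacts must be >= 1")
        if self.reaction_distance <= 0:
            raise ValueError("reaction_distance must be positive")
        if (self.b_radius is not None and self.q_radius is not None
                and not self.b_radius < self.q_radius):
            raise ValueError("b_radius must be smaller than q_radius")

    @property
    def viscosity(self) -> float:
        """Solvent viscosity in Pa s."""
        return (self.solvent.relative_viscosity
                * water_viscosity(self.solvent.temperature))

    @property
    def d_translation(self) -> float:
        """Stokes-Einstein translational diffusion coefficient, Å^2/ps."""
        return stokes_einstein_dt(self.hydrodynamic_radius,
                                  self.solvent.temperature, self.viscosity)

    @property
    def d_rotation(self) -> float:
        """Stokes-Einstein-Debye rotational diffusion coefficient, rad^2/ps."""
        return stokes_einstein_dr(self.hydrodynamic_radius,
                                  self.solvent.temperature, self.viscosity)

    @property
    def kbt(self) -> float:
        return KB * self.solvent.temperature

    def resolved_radii(self, fibril) -> tuple[float, float]:
        """b/q radii, defaulting to bounding sphere + 3 Debye lengths and
        10x that, respectively."""
        b = self.b_radius
        if b is None:
            lam = debye_length(self.solvent)
            lam = min(lam, 20.0)   # salt-free guard
            b = fibril.bounding_radius + 3.0 * lam
        q = self.q_radius if self.q_radius is not None else 10.0 * b
        if not b < q:
            raise ValueError("b_radius must be smaller than q_radius")
        return b, q


@dataclass
class TrajectoryOutcome:
    status: str                   # "reacted" | "escaped" | "max_steps"
    site: int | None              # residue number, set iff reacted
    final_pose: Pose
    n_steps: int
    stream_id: tuple

    def __post_init__(self):
        if (self.status == "reacted") != (self.site is not None):
            raise ValueError("site must be set iff status is 'reacted'")


@dataclass
class ReferenceAtomSets:
    """Reaction-criterion reference atoms for both binding partners."""

    glycan_refs: np.ndarray        # (S, 3) sulfur positions, body frame
    fibril_refs: np.ndarray        # (M, 3) NZ/CZ positions, world frame
    fibril_res_numbers: np.ndarray  # (M,)

    @staticmethod
    def from_models(fibril, glycan) -> "ReferenceAtomSets":
        fpos, fres, _ = fibril.bd_reference_atoms()
        if len(fpos) == 0:
            raise ValueError("fibril has no solvent-exposed basic reference atoms")
        gpos = glycan.sulfur_positions
        if len(gpos) == 0:
            raise ValueError("glycan has no sulfur reference atoms")
        return ReferenceAtomSets(gpos, fpos, fres)


def bd_step(pose: Pose, params: BDParams, force: np.ndarray,
            torque: np.ndarray, dt: float, rng: np.random.Generator) -> Pose:
    """One overdamped step: drift (D/kT)·F·dt plus sqrt(2 D dt) noise.

    Draws 3 translational normals first, then 3 rotational normals, so a
    caller replaying the same generator state can reconstruct the update.
    """
    if not (np.all(np.isfinite(force)) and np.all(np.isfinite(torque))):
        raise FloatingPointError("non-finite force/torque in BD step")
    dt_ = float(dt)
    dtrans = params.d_translation
    drot = params.d_rotation
    xi_t = rng.standard_normal(3)
    xi_r = rng.standard_normal(3)
    dr = (dtrans / params.kbt) * force * dt_ + np.sqrt(2 * dtrans * dt_) * xi_t
    dw = (drot / params.kbt) * torque * dt_ + np.sqrt(2 * drot * dt_) * xi_r
    return Pose(rotation_from_rotvec(dw) @ pose.rotation,
                pose.translation + dr)


def check_reaction(pose: Pose, refs: ReferenceAtomSets,
                   params: BDParams) -> int | None:
    """Apply the contact-count reaction criterion to one pose.

    Counts (glycan sulfur, fibril reference atom) pairs within the reaction
    distance; if at least ``reaction_min_contacts`` pairs exist, returns the
    residue number (pooled across layers) with the most pairs, breaking ties
    toward the lowest residue number.  Otherwise returns None.
    """
    world = pose.apply(refs.glycan_refs)
    d2 = np.sum((world[:, None, :] - refs.fibril_refs[None, :, :]) ** 2,
                axis=2)
    within = d2 <= params.reaction_distance ** 2
    n_pairs = int(within.sum())
    if n_pairs < params.reaction_min_contacts:
        return None
    per_atom = within.sum(axis=0)                 # pairs per fibril ref atom
    residues = np.unique(refs.fibril_res_numbers)
    counts = np.array([per_atom[refs.fibril_res_numbers == r].sum()
                       for r in residues])
    best = counts.max()
    return int(residues[counts == best].min())


def _b_surface_pose(glycan, center: np.ndarray, b: float,
                    rng: np.random.Generator) -> Pose:
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    rot = random_rotation(rng)
    body_centroid = glycan.ring_centroids.mean(axis=0)
    t = center + b * u - rot @ body_centroid
    return Pose(rot, t)


def run_trajectory(fibril, glycan, params: BDParams,
                   rng: np.random.Generator,
                   stream_id: tuple = (0,)) -> TrajectoryOutcome:
    """Propagate one trajectory from the b-surface to reaction or escape.

    Single-trajectory front end of the ensemble propagator; consumes the
    supplied generator exactly as :func:`run_ensemble` consumes its
    per-trajectory substreams.
    """
    return _run_batch(fibril, glycan, params, [tuple(stream_id)],
                      rngs=[rng])[0]


def _rotations_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Batched Rodrigues: (B, 3) rotation vectors -> (B, 3, 3) matrices."""
    theta = np.linalg.norm(v, axis=1)
    safe = np.maximum(theta, 1e-300)
    axis = v / safe[:, None]
    zeros = np.zeros_like(theta)
    K = np.stack([
        np.stack([zeros, -axis[:, 2], axis[:, 1]], axis=1),
        np.stack([axis[:, 2], zeros, -axis[:, 0]], axis=1),
        np.stack([-axis[:, 1], axis[:, 0], zeros], axis=1),
    ], axis=1)
    eye = np.broadcast_to(np.eye(3), (len(v), 3, 3))
    out = (eye + np.sin(theta)[:, None, None] * K
           + (1.0 - np.cos(theta))[:, None, None] * (K @ K))
    tiny = theta < 1e-12
    if tiny.any():
        out[tiny] = eye[tiny] + _skew_batch(v[tiny])
    return out


def _skew_batch(v: np.ndarray) -> np.ndarray:
    zeros = np.zeros(len(v))
    return np.stack([
        np.stack([zeros, -v[:, 2], v[:, 1]], axis=1),
        np.stack([v[:, 2], zeros, -v[:, 0]], axis=1),
        np.stack([-v[:, 1], v[:, 0], zeros], axis=1),
    ], axis=1)


_NOISE_CHUNK = 256


def _run_batch(fibril, glycan, params: BDParams, stream_ids,
               rngs=None) -> list:
    """Propagate one batch of trajectories in lockstep (vectorized).

    Every trajectory consumes its own RNG substream in exactly the order
    the sequential :func:`run_trajectory` path would (initial pose draws,
    then 6 normals per step), so batched and sequential runs produce
    identical outcomes.
    """
    from .electrostatics import COULOMB_K, WALL_EPS, WALL_SIGMA, R_CLAMP

    refs = ReferenceAtomSets.from_models(fibril, glycan)
    b, q = params.resolved_radii(fibril)
    center = fibril.centroid
    src_pos = fibril.charge_positions
    src_q = fibril.charge_values
    body_q_pos = glycan.charge_positions
    q_vals = glycan.charge_values
    body_centroid = glycan.ring_centroids.mean(axis=0)
    body_refs = refs.glycan_refs
    f_refs = refs.fibril_refs
    f_res = refs.fibril_res_numbers
    residues = np.unique(f_res)
    res_onehot = (f_res[None, :] == residues[:, None]).astype(float)

    B = len(stream_ids)
    if rngs is None:
        rngs = [np.random.default_rng(np.random.SeedSequence(sid))
                for sid in stream_ids]
    R, T = np.empty((B, 3, 3)), np.empty((B, 3))
    for m, rng in enumerate(rngs):
        pose = _b_surface_pose(glycan, center, b, rng)
        R[m] = pose.rotation
        T[m] = pose.translation
    # noise buffers are filled lazily, one chunk per trajectory substream
    noise = np.empty((B, _NOISE_CHUNK, 6))
    ptr = np.full(B, _NOISE_CHUNK, dtype=int)
    status = np.full(B, "", dtype=object)
    site = np.full(B, -1)
    n_steps_arr = np.zeros(B, dtype=int)
    active = np.arange(B)

    kappa = params.solvent.kappa
    eps = params.solvent.dielectric
    dtrans = params.d_translation
    drot = params.d_rotation
    kbt = params.kbt
    rd2 = params.reaction_distance ** 2
    ns2 = params.near_shell ** 2
    qq = np.outer(q_vals, src_q)                             # (m, n)
    src2 = np.sum(src_pos * src_pos, axis=1)                 # (n,)
    fref2 = np.sum(f_refs * f_refs, axis=1)                  # (f,)
    wall12 = WALL_EPS * WALL_SIGMA ** 12
    step = 0
    while len(active) and step < params.max_steps:
        Ra, Ta = R[active], T[active]
        RaT = Ra.transpose(0, 2, 1)
        # reaction / near-shell bookkeeping on reference atoms
        wrefs = body_refs @ RaT + Ta[:, None, :]             # (B, s, 3)
        d2 = (np.sum(wrefs * wrefs, axis=2)[:, :, None] + fref2
              - 2.0 * (wrefs @ f_refs.T))                    # (B, s, f)
        within = d2 <= rd2
        n_pairs = within.sum(axis=(1, 2))
        near = (d2 <= ns2).any(axis=(1, 2))
        reacting = near & (n_pairs >= params.reaction_min_contacts)
        if reacting.any():
            per_atom = within[reacting].sum(axis=1)          # (Br, f)
            per_res = per_atom @ res_onehot.T                # (Br, n_res)
            best = per_res.max(axis=1, keepdims=True)
            # lowest residue number among the tied maxima
            hit = [residues[np.flatnonzero(row == m_)].min()
                   for row, m_ in zip(per_res, best[:, 0])]
            idx = active[reacting]
            status[idx] = "reacted"
            site[idx] = hit
            n_steps_arr[idx] = step
        keep = ~reacting
        active = active[keep]
        if not len(active):
            break
        Ra, RaT, Ta, near = Ra[keep], RaT[keep], Ta[keep], near[keep]
        # forces/torques: F_i = c_i.sum * x_i - c_i @ src (pairwise central)
        world_q = body_q_pos @ RaT + Ta[:, None, :]          # (B, m, 3)
        r2 = (np.sum(world_q * world_q, axis=2)[:, :, None] + src2
              - 2.0 * (world_q @ src_pos.T))                 # (B, m, n)
        r = np.sqrt(np.maximum(r2, R_CLAMP * R_CLAMP))
        inv_r = 1.0 / r
        e_el = (COULOMB_K / eps) * qq * np.exp(-kappa * r) * inv_r
        coeff = (e_el * (1.0 + kappa * r)
                 + 12.0 * wall12 * inv_r ** 12) * inv_r * inv_r
        per_charge = (coeff.sum(axis=2)[:, :, None] * world_q
                      - coeff @ src_pos)                     # (B, m, 3)
        force = per_charge.sum(axis=1)
        centroid = Ra @ body_centroid + Ta
        lever = world_q - centroid[:, None, :]
        torque = np.stack([
            (lever[:, :, 1] * per_charge[:, :, 2]
             - lever[:, :, 2] * per_charge[:, :, 1]).sum(axis=1),
            (lever[:, :, 2] * per_charge[:, :, 0]
             - lever[:, :, 0] * per_charge[:, :, 2]).sum(axis=1),
            (lever[:, :, 0] * per_charge[:, :, 1]
             - lever[:, :, 1] * per_charge[:, :, 0]).sum(axis=1),
        ], axis=1)
        # per-trajectory noise from the buffered substreams
        exhausted = active[ptr[active] == _NOISE_CHUNK]
        for idx in exhausted:
            noise[idx] = rngs[idx].standard_normal((_NOISE_CHUNK, 6))
            ptr[idx] = 0
        xi = noise[active, ptr[active]]
        ptr[active] += 1
        dt = np.where(near, params.dt_near, params.dt_far)[:, None]
        dr = (dtrans / kbt) * force * dt + np.sqrt(2 * dtrans * dt) * xi[:, :3]
        dw = (drot / kbt) * torque * dt + np.sqrt(2 * drot * dt) * xi[:, 3:]
        R[active] = _rotations_from_rotvec(dw) @ Ra
        T[active] = Ta + dr
        step += 1
        centroid = np.einsum("bij,j->bi", R[active], body_centroid) + T[active]
        escaped = np.linalg.norm(centroid - center, axis=1) > q
        if escaped.any():
            idx = active[escaped]
            status[idx] = "escaped"
            n_steps_arr[idx] = step
            active = active[~escaped]
    if len(active):
        status[active] = "max_steps"
        n_steps_arr[active] = step
    return [
        TrajectoryOutcome(
            status=str(status[m]),
            site=int(site[m]) if status[m] == "reacted" else None,
            final_pose=Pose(R[m].copy(), T[m].copy()),
            n_steps=int(n_steps_arr[m]),
            stream_id=tuple(stream_ids[m]))
        for m in range(B)
    ]


def run_ensemble(fibril_conformations, glycan_poses, n_per_pair: int,
                 params: BDParams, batch_size: int = 200) -> list:
    """Run ``n_per_pair`` trajectories per (fibril, glycan) pair.

    Each trajectory has its own RNG substream keyed by
    ``(seed, fibril index, glycan index, replicate)``, so the outcome list
    is reproducible and independent of execution order or batching.
    Propagation is vectorized across trajectories in batches.
    """
    if not fibril_conformations or not glycan_poses:
        raise ValueError("conformation and glycan lists must be nonempty")
    outcomes = []
    for i, fib in enumerate(fibril_conformations):
        for j, gly in enumerate(glycan_poses):
            sids = [(params.seed, i, j, r) for r in range(n_per_pair)]
            for start in range(0, len(sids), batch_size):
                outcomes.extend(_run_batch(fib, gly, params,
                                           sids[start:start + batch_size]))
    return outcomes


def nam_rate(bound_fraction: float, b_radius: float, q_radius: float,
             d_translation: float) -> float:
    """Northrup-Allison-McCammon association rate from the bound fraction.

    k = k_D(b) beta / (1 - (1 - beta) k_D(b)/k_D(q)), with
    k_D(r) = 4 pi D r the diffusion-limited rate to an absorbing sphere.
    Units follow ``d_translation`` (Å^3/ps per molecule pair for Å^2/ps).
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError("bound_fraction must be in [0, 1]")
    if b_radius <= 0 or q_radius <= 0 or b_radius >= q_radius:
        raise ValueError("need 0 < b_radius < q_radius")
    kd_b = 4.0 * np.pi * d_translation * b_radius
    kd_q = 4.0 * np.pi * d_translation * q_radius
    beta = bound_fraction
    return kd_b * beta / (1.0 - (1.0 - beta) * kd_b / kd_q)
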