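"""Samplers for the model ensembles the oligomer searches require.

Three generators: random-coil C-terminal tail conformers (the residues
leading to the transmembrane anchor are unresolved in crystal structures
and must be modelled flexibly), random rigid-body tetramers built by
docking two copies of the dimer in uniformly random mutual orientations
with surfaces in contact, and D2-symmetric trans-tetramers in which the
second dimer faces the first across a putative inter-membrane interface.

All samplers are deterministic under a fixed seed and reject models with
inter-unit clashes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from oligostate.structure import (
    AssemblyModel,
    ClashError,
    RigidTransform,
    StructureModel,
    ONE_LETTER,
    kabsch_rmsd,
    rmsd_symm,
)

__all__ = [
    "SamplerConfig",
    "sample_tail_conformers",
    "sample_tetramers",
    "generate_d2_tetramers",
    "dimer_c2_axis",
]


@dataclass
class SamplerConfig:
    """Acceptance rules for rigid-body tetramer sampling.

    contact_min / min_contact_atoms define "surfaces in contact"; no
    atom pair of different units may come closer than clash_floor.
    """

    n_models: int = 100
    seed: int = 0
    contact_min: float = 5.0
    clash_floor: float = 1.5
    min_contact_atoms: int = 10
    dedup_rmsd: float = 2.0
    max_attempts_factor: int = 10_000

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be ≥ 1")
        if self.contact_min <= self.clash_floor:
            raise ValueError("contact_min must exceed clash_floor")


# ---------------------------------------------------------------------------
# Flexible tail sampling

_CA_BOND = 3.8  # Å, trans-peptide Cα–Cα virtual bond


def sample_tail_conformers(model: StructureModel, tail_sequence: str,
                           n: int = 1, seed: int = 0,
                           clash_dist: float = 3.0,
                           max_rejections: int = 1000) -> list[StructureModel]:
    """Grow random-coil Cα-trace tails on the C-terminus of every chain.

    Each tail residue adds one Cα pseudo-atom 3.8 Å from the previous
    one; the direction is drawn coil-like (virtual bond angle ~120°±25°,
    uniform dihedral) and redrawn on a clash with any existing atom.
    Body coordinates are untouched.  Returns ``n`` conformers.
    """
    codes = []
    for c in str(tail_sequence).upper():
        if c not in ONE_LETTER:
            raise ValueError(f"unknown residue code {c!r} in tail sequence")
        codes.append(ONE_LETTER[c])
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(_grow_tails(model, codes, rng, clash_dist, max_rejections))
    return out


def _grow_tails(model: StructureModel, codes: list[str], rng,
                clash_dist: float, max_rejections: int) -> StructureModel:
    chains = model.chains
    add_chain, add_num, add_name, add_atom, add_xyz = [], [], [], [], []
    body = model.coords
    for chain in chains:
        chain_tail_start = len(add_xyz)
        mask = model.chain_mask(chain)
        last_num = int(model.residue_numbers[mask].max())
        res_mask = mask & (model.residue_numbers == last_num)
        ca_mask = res_mask & (model.atom_names == "CA")
        anchor_idx = np.nonzero(ca_mask if ca_mask.any() else res_mask)[0][0]
        prev = model.coords[anchor_idx]
        # previous-bond direction: anchor minus chain centroid as a fallback
        prev_dir = prev - model.coords[mask].mean(axis=0)
        if np.linalg.norm(prev_dir) < 1e-9:
            prev_dir = np.array([0.0, 0.0, 1.0])
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        for j, code in enumerate(codes):
            rejections = 0
            while True:
                direction = _coil_step(prev_dir, rng)
                cand = prev + _CA_BOND * direction
                # clash-check against the body and other chains' tails;
                # a disordered tail may approach itself (coil statistics)
                others = add_xyz[:chain_tail_start]
                obstacles = np.vstack([body, np.array(others)]) if others else body
                if np.min(np.linalg.norm(obstacles - cand, axis=1)) >= clash_dist:
                    break
                rejections += 1
                if rejections >= max_rejections:
                    raise RuntimeError(
                        f"persistent clash growing tail residue {j} of chain {chain}")
            add_chain.append(chain)
            add_num.append(last_num + 1 + j)
            add_name.append(code)
            add_atom.append("CA")
            add_xyz.append(cand)
            prev_dir = direction
            prev = cand
    return StructureModel(
        np.concatenate([model.chain_ids, np.array(add_chain, dtype=object)]),
        np.concatenate([model.residue_numbers, np.array(add_num, dtype=int)]),
        np.concatenate([model.residue_names, np.array(add_name, dtype=object)]),
        np.concatenate([model.atom_names, np.array(add_atom, dtype=object)]),
        np.vstack([model.coords, np.array(add_xyz)]),
        np.concatenate([model.masses, np.full(len(add_xyz), 110.0)]),
        np.concatenate([model.elements, np.array(["C"] * len(add_xyz), dtype=object)]),
        provenance=model.provenance + "+tails",
    )


def _coil_step(prev_dir: np.ndarray, rng) -> np.ndarray:
    """Next Cα–Cα direction: uniform on the sphere (freely-jointed coil).

    Direction memory is left out deliberately: the tails modelled here
    are short disordered stretches whose ensemble statistics should
    follow freely-jointed-chain behaviour; steric rejection against the
    body supplies the only stiffness.
    """
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Random rigid-body tetramers

def _contact_translation(base_tree: cKDTree, moved: np.ndarray,
                         direction: np.ndarray, config: SamplerConfig,
                         rng) -> np.ndarray | None:
    """Slide a rotated copy along ``direction`` until surfaces touch.

    Bisects the approach distance so that the minimum inter-unit
    distance lies in [clash_floor, contact_min]; returns the translation
    or None when no acceptable placement exists on this line.
    """
    span = moved.max(axis=0) - moved.min(axis=0)
    far = float(np.linalg.norm(span)) * 2.0 + 50.0
    lo, hi = 0.0, far      # lo: inside/clashing, hi: far/free

    def min_dist(t):
        d, _ = base_tree.query(moved + t * direction, k=1)
        return float(d.min())

    if min_dist(far) < config.clash_floor:
        return None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < config.clash_floor:
            lo = mid
        else:
            hi = mid
        if hi - lo < 0.05:
            break
    t = hi
    if min_dist(t) > config.contact_min:
        return None
    return t * direction


def sample_tetramers(dimer: AssemblyModel | StructureModel,
                     config: SamplerConfig) -> list[AssemblyModel]:
    """Random tetramers: second dimer in uniform random orientation, docked.

    Rotations are uniform over SO(3); the rotated copy approaches along a
    uniformly random direction until in contact (≥ min_contact_atoms
    atom pairs within contact_min, none below clash_floor).  Accepted
    models are de-duplicated at ``dedup_rmsd`` under the symmetric RMSD.
    """
    base = dimer.realize() if isinstance(dimer, AssemblyModel) else dimer
    rng = np.random.default_rng(config.seed)
    tree = cKDTree(base.coords)
    center = base.coords.mean(axis=0)
    accepted: list[AssemblyModel] = []
    attempts = 0
    max_attempts = config.n_models * config.max_attempts_factor
    while len(accepted) < config.n_models and attempts < max_attempts:
        attempts += 1
        R = Rotation.random(random_state=rng).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        moved = (base.coords - center) @ R.T + center
        shift = _contact_translation(tree, moved, direction, config, rng)
        if shift is None:
            continue
        placed = moved + shift
        d, _ = tree.query(placed, k=1)
        n_contacts = int((d <= config.contact_min).sum())
        if n_contacts < config.min_contact_atoms or d.min() < config.clash_floor:
            continue
        # x ↦ R(x−c)+c+shift  ≡  Rx + (c − Rc + shift)
        tr = RigidTransform(R, center - R @ center + shift)
        try:
            model = AssemblyModel(base, [RigidTransform.identity(), tr],
                                  state_label="tetramer",
                                  model_id=f"tet_{len(accepted):05d}",
                                  clash_floor=config.clash_floor)
        except ClashError:
            continue
        if config.dedup_rmsd > 0 and any(
                rmsd_symm(model, prev) < config.dedup_rmsd
                for prev in accepted):
            continue
        accepted.append(model)
    if len(accepted) < config.n_models:
        rate = len(accepted) / max(attempts, 1)
        if rate < 1e-4:
            raise RuntimeError(
                f"tetramer acceptance rate {rate:.2e} too low; relax contact "
                "parameters")
    return accepted


# ---------------------------------------------------------------------------
# D2-symmetric trans-tetramers

def dimer_c2_axis(dimer: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """C2 axis (unit vector) and centroid of a homodimer.

    The rotation superposing chain A onto chain B of a symmetric dimer
    is a 2-fold; its rotation axis is the dimer's symmetry axis.
    """
    chains = dimer.chains
    if len(chains) != 2:
        raise ValueError("C2 axis is defined for a two-chain dimer")
    a = dimer.coords[dimer.chain_mask(chains[0])]
    b = dimer.coords[dimer.chain_mask(chains[1])]
    if len(a) != len(b):
        raise ValueError("chains differ in atom count; cannot superpose")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = bc.T @ ac
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rot = Rotation.from_matrix(R)
    axis = rot.as_rotvec()
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        raise ValueError("chains already superposed; no 2-fold found")
    return axis / norm, dimer.coords.mean(axis=0)


def generate_d2_tetramers(dimer: AssemblyModel | StructureModel,
                          n_orientations: int = 12,
                          clash_floor: float = 1.5,
                          contact_min: float = 5.0,
                          symmetry_tol: float = 0.5) -> list[AssemblyModel]:
    """D2 trans-tetramers: the second dimer flipped 180° across the interface.

    For each of ``n_orientations`` sweep angles about the dimer's C2
    axis, the second copy is rotated 180° about a perpendicular axis and
    displaced *along the C2 axis* until the units are in contact.  A
    flip about a perpendicular axis plus a translation along the C2 axis
    is the unique way to keep both 2-folds as point symmetries, i.e. D2.
    Placements that stay clashed or break D2 within ``symmetry_tol`` Å
    are skipped.
    """
    base = dimer.realize() if isinstance(dimer, AssemblyModel) else dimer
    c2, centroid = dimer_c2_axis(base)
    # orthonormal frame with e3 = C2 axis
    a = np.array([1.0, 0.0, 0.0])
    if abs(c2 @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(c2, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c2, e1)
    tree = cKDTree(base.coords)
    config = SamplerConfig(n_models=1, contact_min=contact_min,
                           clash_floor=clash_floor)
    out: list[AssemblyModel] = []
    for k in range(n_orientations):
        phi = 2.0 * np.pi * k / n_orientations
        flip_axis = np.cos(phi) * e1 + np.sin(phi) * e2
        R = Rotation.from_rotvec(np.pi * flip_axis).as_matrix()
        moved = (base.coords - centroid) @ R.T + centroid
        shift = None
        for sign in (1.0, -1.0):
            shift = _contact_translation(tree, moved, sign * c2, config, rng=None)
            if shift is not None:
                break
        if shift is None:
            continue
        tr = RigidTransform(R, centroid - R @ centroid + shift)
        try:
            model = AssemblyModel(base, [RigidTransform.identity(), tr],
                                  state_label="tetramer",
                                  model_id=f"d2_{k:02d}", clash_floor=clash_floor)
        except ClashError:
            continue
        if _d2_deviation(model, c2, flip_axis) > symmetry_tol:
            continue
        out.append(model)
    if not out:
        raise RuntimeError("no clash-free D2 placement found")
    return out


def _d2_deviation(model: AssemblyModel, axis1: np.ndarray,
                  axis2: np.ndarray) -> float:
    """Worst direct RMSD of the tetramer vs itself under each D2 rotation.

    Uses unfit (no-superposition) RMSD minimised over equivalent chain
    permutations: a superposed RMSD would be blind to whether the
    rotation is actually a symmetry of the model.
    """
    s = model.realize()
    coords = s.coords
    center = coords.mean(axis=0)
    chains = s.chains
    blocks = [np.nonzero(s.chain_mask(c))[0] for c in chains]
    sizes = [len(b) for b in blocks]
    worst = 0.0
    axes = [axis1, axis2, np.cross(axis1, axis2)]
    import itertools as _it
    for ax in axes:
        ax = ax / np.linalg.norm(ax)
        R = Rotation.from_rotvec(np.pi * ax).as_matrix()
        rotated = (coords - center) @ R.T + center
        best = np.inf
        for perm in _it.permutations(range(len(blocks))):
            if [sizes[i] for i in perm] != sizes:
                continue
            diff = coords[np.concatenate(blocks)] \
                - rotated[np.concatenate([blocks[i] for i in perm])]
            best = min(best, float(np.sqrt((diff ** 2).sum() / len(coords))))
        worst = max(worst, best)
    return worst
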