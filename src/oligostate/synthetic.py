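"""Ground-truth generators for every input class the pipeline consumes.

Every generator is deterministic under a fixed seed and returns, next to
the dataset, a :class:`SimulationTruth` record carrying the generating
parameters — true surface distances, mixture weights, lifetimes,
particle classes — sufficient to compute every downstream expected value
without re-simulation.  Generated structures use pseudo-atoms of uniform
1.7 Å radius on parametric shapes; this reproduces the geometric
features that matter for surface-distance and scattering tests (a
convex body, a wall with a detour, two lobes) without pretending to be
real protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from oligostate.saxs import SAXSProfile
from oligostate.structure import AssemblyModel, StructureModel
from oligostate.xlms import NOT_ACCESSIBLE, CrossLink, SolventGrid

__all__ = [
    "ToyStructureSpec",
    "SimulationTruth",
    "make_toy_structure",
    "simulate_crosslinks",
    "simulate_saxs",
    "simulate_bead_image",
    "simulate_decay",
]


@dataclass
class SimulationTruth:
    """Record of generating parameters emitted with every dataset."""

    kind: str
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return str(o)
        text = json.dumps({"kind": self.kind, "params": self.params},
                          indent=2, default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class ToyStructureSpec:
    """Parametric toy structure: shape, chains, designated linkable sites."""

    n_chains: int = 2
    atoms_per_chain: int = 150
    shape: str = "sphere-shell"          # sphere-shell | slab-with-aperture | two-lobe
    labeled_sites: tuple[int, ...] = (1, 50, 100)
    seed: int = 0
    radius: float = 12.0                 # Å, lobe/shell radius
    separation: float = 26.0             # Å, chain-centre spacing
    symmetric: bool = True               # 2-chain dimers get a true C2 axis

    def __post_init__(self):
        if self.n_chains < 1 or self.atoms_per_chain < 4:
            raise ValueError("degenerate shape parameters")
        if any(s < 1 or s > self.atoms_per_chain for s in self.labeled_sites):
            raise ValueError("labeled sites outside residue range")


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Even points on a sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _chain_coords(spec: ToyStructureSpec, rng) -> np.ndarray:
    n, R = spec.atoms_per_chain, spec.radius
    if spec.shape == "sphere-shell":
        return _fibonacci_sphere(n, R)
    if spec.shape == "two-lobe":
        half = n // 2
        a = _fibonacci_sphere(half, R * 0.8) - np.array([R, 0, 0])
        b = _fibonacci_sphere(n - half, R * 0.8) + np.array([R, 0, 0])
        return np.vstack([a, b])
    if spec.shape == "slab-with-aperture":
        # a wall in the yz-plane with a central aperture, endpoints aside
        side = int(np.ceil(np.sqrt(n)))
        ys, zs = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        pts = np.column_stack([np.zeros(side * side),
                               (ys.ravel() - side / 2) * 2.0,
                               (zs.ravel() - side / 2) * 2.0])
        hole = np.linalg.norm(pts[:, 1:], axis=1) > 3.5   # aperture radius
        pts = pts[hole][:n]
        if len(pts) < n:   # backfill with a second layer
            extra = pts[: n - len(pts)] + np.array([2.0, 0, 0])
            pts = np.vstack([pts, extra])
        return pts
    raise ValueError(f"unknown shape {spec.shape!r}")


def make_toy_structure(spec: ToyStructureSpec,
                       compute_truth_sasd: bool = False,
                       truth_spacing: float = 0.5
                       ) -> tuple[StructureModel, SimulationTruth]:
    """Build a toy multi-chain structure with designated cross-linkable sites.

    Chains are copies of one parametric shape spaced ``separation`` Å
    apart along x, so the assembly is exactly symmetric.  With
    ``compute_truth_sasd`` the ground-truth surface distances between
    all labeled-site pairs are computed on a fine grid (Dijkstra at
    ``truth_spacing`` Å) and stored in the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    single = _chain_coords(spec, rng)
    chain_ids, resnums, coords = [], [], []
    letters = "ABCDEFGH"
    for c in range(spec.n_chains):
        if spec.symmetric and spec.n_chains == 2 and c == 1:
            # chain B = chain A rotated 180° about z through the
            # midpoint, so the dimer carries an exact C2 axis
            placed = np.column_stack([
                spec.separation - single[:, 0],
                -single[:, 1],
                single[:, 2]])
        else:
            placed = single + np.array([c * spec.separation, 0.0, 0.0])
        coords.append(placed)
        chain_ids.extend(letters[c] * len(single))
        resnums.extend(range(1, len(single) + 1))
    coords = np.vstack(coords)
    n = len(coords)
    model = StructureModel(
        np.array(list(chain_ids), dtype=object),
        np.array(resnums, dtype=int),
        np.array(["ALA"] * n, dtype=object),
        np.array(["CA"] * n, dtype=object),
        coords,
        np.full(n, 110.0),
        np.array(["X"] * n, dtype=object),
        provenance=f"toy:{spec.shape}",
    )
    truth = SimulationTruth("toy_structure", {
        "shape": spec.shape, "n_chains": spec.n_chains,
        "atoms_per_chain": spec.atoms_per_chain,
        "labeled_sites": list(spec.labeled_sites), "seed": spec.seed,
        "radius": spec.radius, "separation": spec.separation,
    })
    if compute_truth_sasd:
        grid = SolventGrid(model, spacing=truth_spacing, probe=1.4)
        sasds = {}
        sites = list(spec.labeled_sites)
        for i, sa in enumerate(sites):
            for sb in sites[i:]:
                for xl in [CrossLink(sa, sb)] if sa != sb else [CrossLink(sa, sb)]:
                    from oligostate.xlms import compute_sasd
                    res = compute_sasd(model, xl, prefilter_cutoff=None,
                                       grid=grid)
                    for r in res:
                        key = f"{sa}-{sb}:{r.variant}"
                        sasds[key] = (None if not np.isfinite(r.sasd)
                                      else float(r.sasd))
        truth.params["true_sasds"] = sasds
    return model, truth


# ---------------------------------------------------------------------------
# Cross-link sets

def simulate_crosslinks(model: StructureModel | AssemblyModel,
                        sites: list[int], cutoff: float = 33.0,
                        n_true: int = 8, fp_rate: float = 0.0,
                        seed: int = 0, grid_spacing: float = 1.0,
                        state: str = "dimer"
                        ) -> tuple[list[CrossLink], SimulationTruth]:
    """Draw true cross-links from accessible site pairs plus decoys.

    ``n_true`` pairs are sampled among site pairs whose best SASD on the
    model is ≤ cutoff; ⌈fp_rate·n_true⌉ decoys come from pairs with no
    compliant surface path.  Band labels follow the generating
    assembly's state.
    """
    from oligostate.xlms import compute_sasd
    from oligostate.structure import _as_structure
    s = _as_structure(model)
    rng = np.random.default_rng(seed)
    grid = SolventGrid(s, spacing=grid_spacing, probe=1.4)
    accessible, blocked = [], []
    sites = sorted(set(sites))
    for i, sa in enumerate(sites):
        for sb in sites[i:]:
            xl = CrossLink(sa, sb, frozenset({state}))
            res = compute_sasd(s, xl, prefilter_cutoff=cutoff, grid=grid)
            if not res:
                continue
            best = min((r.sasd for r in res), default=NOT_ACCESSIBLE)
            (accessible if best <= cutoff else blocked).append((xl, best))
    if len(accessible) < n_true:
        raise ValueError(f"only {len(accessible)} accessible site pairs; "
                         f"need {n_true}")
    n_fp = int(np.ceil(fp_rate * n_true))
    if len(blocked) < n_fp:
        raise ValueError(f"only {len(blocked)} non-accessible pairs for "
                         f"{n_fp} decoys")
    idx_t = rng.choice(len(accessible), size=n_true, replace=False)
    idx_f = rng.choice(len(blocked), size=n_fp, replace=False) if n_fp else []
    xls = [accessible[i][0] for i in idx_t] + [blocked[i][0] for i in idx_f]
    truth = SimulationTruth("crosslinks", {
        "n_true": n_true, "n_decoys": int(n_fp), "fp_rate": fp_rate,
        "cutoff": cutoff, "seed": seed,
        "true_pairs": [str(accessible[i][0]) for i in idx_t],
        "decoy_pairs": [str(blocked[i][0]) for i in idx_f],
        "true_sasds": {str(accessible[i][0]): accessible[i][1] for i in idx_t},
    })
    return xls, truth


# ---------------------------------------------------------------------------
# SAXS mixtures

def simulate_saxs(profiles: dict[str, SAXSProfile], weights,
                  noise_model: str = "gaussian-percent",
                  noise_level: float = 0.02, scale: float = 1.0,
                  seed: int = 0) -> tuple[SAXSProfile, SimulationTruth]:
    """Noisy profile of a known state mixture.

    I = scale · Σ wₖ Iₖ plus seeded noise; 2% relative Gaussian by
    default, or a Poisson-like model with variance ∝ intensity.  The σ
    column matches the applied noise level.
    """
    ids = list(profiles)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(ids):
        raise ValueError("one weight per profile required")
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    q = profiles[ids[0]].q
    for p in profiles.values():
        if len(p.q) != len(q) or not np.allclose(p.q, q):
            raise ValueError("mismatched q grids")
    rng = np.random.default_rng(seed)
    ideal = scale * sum(w * profiles[k].intensity for k, w in zip(ids, weights))
    if noise_model == "gaussian-percent":
        sigma = noise_level * ideal
        intensity = ideal + rng.normal(0.0, 1.0, size=len(q)) * sigma
    elif noise_model == "poisson-like":
        sigma = np.sqrt(np.clip(ideal, 1e-12, None)) * noise_level
        intensity = ideal + rng.normal(0.0, 1.0, size=len(q)) * sigma
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    sigma = np.clip(sigma, 1e-12 * max(float(ideal.max()), 1.0), None)
    profile = SAXSProfile(q, intensity, sigma, label="synthetic-mixture")
    truth = SimulationTruth("saxs_mixture", {
        "states": ids, "weights": weights, "scale": scale,
        "noise_model": noise_model, "noise_level": noise_level, "seed": seed,
    })
    return profile, truth


# ---------------------------------------------------------------------------
# Bead images

def simulate_bead_image(n_singles: int = 50, n_aggregates: int = 5,
                        aggregate_size_range: tuple[int, int] = (2, 4),
                        radius_px: int = 5,
                        image_size: tuple[int, int] = (512, 512),
                        seed: int = 0, background: int = 200,
                        foreground: int = 60, max_retries: int = 2000,
                        radius_jitter: float = 0.06
                        ) -> tuple[np.ndarray, SimulationTruth]:
    """Dark beads on a bright background with known aggregate composition.

    Singles are isolated disks; an aggregate is a chain of 2–4 touching
    disks.  Bead radii cycle through three discrete sizes
    (±``radius_jitter`` around nominal): real bead preparations are
    polydisperse at the few-percent level, and a non-zero, easily
    estimated spread is what makes the mean ± 2·sd classification rule
    well-posed.  The truth records every particle's class and pixel
    area.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    img = np.full((h, w), background, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    placed_centers: list[np.ndarray] = []
    particles = []

    def _disk_mask(cy, cx, r):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2

    def _free(centers, clearance):
        for c in centers:
            for p in placed_centers:
                if np.linalg.norm(c - p) < clearance:
                    return False
            if not (radius_px + 2 <= c[0] < h - radius_px - 2
                    and radius_px + 2 <= c[1] < w - radius_px - 2):
                return False
        return True

    clearance = 2 * radius_px + 6
    for kind, count in (("single", n_singles), ("aggregate", n_aggregates)):
        for _ in range(count):
            for attempt in range(max_retries):
                cy, cx = rng.uniform(0, h), rng.uniform(0, w)
                if kind == "single":
                    centers = [np.array([cy, cx])]
                else:
                    n_beads = int(rng.integers(aggregate_size_range[0],
                                               aggregate_size_range[1] + 1))
                    centers = [np.array([cy, cx])]
                    for _ in range(n_beads - 1):
                        ang = rng.uniform(0, 2 * np.pi)
                        step = 2 * radius_px - 1   # touching/overlapping
                        centers.append(centers[-1] +
                                       step * np.array([np.sin(ang), np.cos(ang)]))
                if _free(centers, clearance):
                    break
            else:
                raise RuntimeError("overcrowded placement: could not fit all "
                                   "particles")
            mask = np.zeros((h, w), dtype=bool)
            for c in centers:
                factor = 1.0 + radius_jitter * ((len(placed_centers)
                                                 + len(particles)) % 3 - 1)
                mask |= _disk_mask(c[0], c[1], radius_px * factor)
            img[mask] = foreground
            placed_centers.extend(centers)
            particles.append({"class": kind, "n_beads": len(centers),
                              "area_px": int(mask.sum()),
                              "centers": [list(map(float, c)) for c in centers]})
    truth = SimulationTruth("bead_image", {
        "n_singles": n_singles, "n_aggregates": n_aggregates,
        "radius_px": radius_px, "seed": seed, "image_size": list(image_size),
        "particles": particles,
        "single_area_analytic": float(np.pi * radius_px ** 2),
    })
    return img, truth


# ---------------------------------------------------------------------------
# TCSPC decays

def simulate_decay(tau, amplitudes=None, irf_width: float = 0.2,
                   total_counts: int = 100_000, bins: int = 512,
                   bin_width: float = 0.05, irf_t0: float | None = None,
                   background_rate: float = 0.0, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray, SimulationTruth]:
    """Photon-count decay histogram + matching IRF histogram.

    Photons draw a decay component with probability ∝ amplitude, an
    exponential delay with that component's τ, and a Gaussian IRF jitter
    (σ = ``irf_width`` ns, centred at ``irf_t0``).  Counts falling
    outside the acquisition window are redrawn.  Returns
    ``(histogram, irf_histogram, truth)``.
    """
    taus = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    amps = (np.ones_like(taus) if amplitudes is None
            else np.atleast_1d(np.asarray(amplitudes, dtype=float)))
    if len(amps) != len(taus) or np.any(amps < 0) or amps.sum() == 0:
        raise ValueError("invalid amplitudes")
    window = bins * bin_width
    if np.max(taus) > window / 3:
        import warnings
        warnings.warn("longest lifetime is a large fraction of the window; "
                      "truncation will bias fits", stacklevel=2)
    rng = np.random.default_rng(seed)
    if irf_t0 is None:
        irf_t0 = max(5.0 * irf_width, bin_width)
    # amplitudes are pre-exponential factors: the photon (intensity)
    # share of component k is A_k τ_k / Σ A_j τ_j
    probs = amps * taus / (amps * taus).sum()
    times = np.empty(0)
    while len(times) < total_counts:
        need = total_counts - len(times)
        comp = rng.choice(len(taus), size=need, p=probs)
        t = rng.exponential(taus[comp])
        if irf_width > 0:
            t = t + rng.normal(irf_t0, irf_width, size=need)
        else:
            t = t + irf_t0
        t = t[(t >= 0) & (t < window)]
        times = np.concatenate([times, t])
    times = times[:total_counts]
    hist, _ = np.histogram(times, bins=bins, range=(0, window))
    if background_rate > 0:
        hist = hist + rng.poisson(background_rate, size=bins)
    edges = np.arange(bins + 1) * bin_width
    if irf_width > 0:
        from scipy.stats import norm
        irf = np.diff(norm.cdf(edges, loc=irf_t0, scale=irf_width))
        irf = (irf * 1e6).astype(float)
    else:
        irf = np.zeros(bins)
        irf[int(irf_t0 / bin_width)] = 1e6
    truth = SimulationTruth("decay", {
        "taus": taus, "amplitudes": amps, "irf_width": irf_width,
        "irf_t0": irf_t0, "total_counts": total_counts, "bins": bins,
        "bin_width": bin_width, "seed": seed,
        "tau_avg": float((amps * taus).sum() / amps.sum()),
    })
    return hist.astype(float), irf, truth
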