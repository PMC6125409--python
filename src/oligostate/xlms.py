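"""Cross-linking MS restraints: SASD computation and MNXL model scoring.

A chemical cross-link between two lysines constrains their *solvent
accessible surface distance* (SASD): the shortest path between the two
residues that stays in solvent, outside the protein body.  For the DSS
cross-linker the empirical match threshold is 33 Å; cross-links whose
straight-line (Euclidean) distance already exceeds it cannot be matched
and skip the (expensive) path search.

Each matched SASD is rewarded by the MNXL score — a normal density
N(mu=18.62 Å, var=35.94 Å²) evaluated at the SASD — while SASDs above
the threshold, or residue pairs with no solvent path at all, are
penalised with −0.1.  Two adaptations handle homo-oligomers: every
intra- and inter-subunit variant of a cross-link is computed and only
the best-scoring variant counts (a symmetric model would otherwise be
rewarded twice for one observation), and when scoring tetramer models
against a dimer reference the penalty is waived for cross-links already
matched in the dimer, so tetramers are ranked purely by their ability to
explain the cross-links the dimer cannot.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from oligostate.structure import AssemblyModel, StructureModel, _as_structure

__all__ = [
    "CrossLink",
    "SASDResult",
    "MNXLParams",
    "ModelScore",
    "RestraintSet",
    "NOT_ACCESSIBLE",
    "parse_crosslinks",
    "euclidean_prefilter",
    "compute_sasd",
    "mnxl_score",
    "score_model",
    "assign_states",
    "symmetrize_restraints",
    "restraint_scan",
]

#: Sentinel for "no solvent path exists / excluded by prefilter".
NOT_ACCESSIBLE = float("inf")

VALID_BANDS = ("monomer", "dimer", "trimer", "tetramer")


@dataclass(frozen=True)
class CrossLink:
    """A residue-pair restraint with the SDS-PAGE band(s) it was seen in."""

    residue_a: int
    residue_b: int
    bands: frozenset[str] = frozenset({"dimer"})
    construct: str = "EX"

    def __post_init__(self):
        if self.residue_a > self.residue_b:
            object.__setattr__(self, "residue_a", self.residue_b)
            object.__setattr__(self, "residue_b", self.residue_a)
        bands = frozenset(self.bands)
        if not bands:
            raise ValueError("cross-link needs at least one band of origin")
        bad = bands - set(VALID_BANDS)
        if bad:
            raise ValueError(f"unknown band(s) {sorted(bad)}")
        object.__setattr__(self, "bands", bands)

    @property
    def is_self_pair(self) -> bool:
        """A residue linked to its own copy — requires two subunits."""
        return self.residue_a == self.residue_b

    @property
    def key(self) -> tuple[int, int]:
        return (self.residue_a, self.residue_b)

    def __str__(self) -> str:
        return f"{self.residue_a}-{self.residue_b}"


@dataclass(frozen=True)
class SASDResult:
    """One intra/inter variant of a cross-link measured on a model."""

    crosslink: CrossLink
    variant: str                # "intra:<chain>" or "inter:<chainA>-<chainB>"
    euclidean: float            # Å
    sasd: float                 # Å, or NOT_ACCESSIBLE
    chain_a: str = ""
    chain_b: str = ""

    @property
    def accessible(self) -> bool:
        return np.isfinite(self.sasd)


@dataclass(frozen=True)
class MNXLParams:
    """Scoring constants: Gaussian reward N(mu, dispersion) under cutoff, flat penalty above."""

    mu: float = 18.62               # Å
    dispersion: float = 35.94       # Å² (variance); set sigma_mode for σ
    cutoff: float = 33.0            # Å, DSS match threshold
    penalty: float = -0.1
    sigma_mode: bool = False        # treat dispersion as σ instead of σ²

    def __post_init__(self):
        if not (self.cutoff > self.mu > 0):
            raise ValueError("require cutoff > mu > 0")
        if self.dispersion <= 0 or self.penalty >= 0:
            raise ValueError("dispersion must be > 0 and penalty < 0")

    @property
    def variance(self) -> float:
        return self.dispersion ** 2 if self.sigma_mode else self.dispersion


@dataclass
class ModelScore:
    model_id: str
    per_crosslink: dict[tuple[int, int], float]
    matched: dict[tuple[int, int], bool]
    matched_count: int = 0
    nonaccessible_count: int = 0

    @property
    def total(self) -> float:
        return float(sum(self.per_crosslink.values()))


@dataclass(frozen=True)
class ChainRestraint:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    max_dist: float


@dataclass
class RestraintSet:
    restraints: list[ChainRestraint]
    symmetry_completed: bool = False

    def __len__(self) -> int:
        return len(self.restraints)


# ---------------------------------------------------------------------------
# Parsing

def parse_crosslinks(path) -> list[CrossLink]:
    """Read a cross-link TSV (columns residue_a, residue_b, bands, construct).

    ``bands`` is a comma- or plus-separated subset of
    monomer/dimer/trimer/tetramer.  Residue order is canonicalised and
    duplicate pairs are merged with the union of their bands.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_a", "residue_b", "bands"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns {sorted(required - set(df.columns))}")
    merged: dict[tuple, dict] = {}
    for i, row in df.iterrows():
        try:
            a, b = int(row["residue_a"]), int(row["residue_b"])
            bands = frozenset(
                str(row["bands"]).replace("+", ",").replace(";", ",").split(","))
            bands = frozenset(s.strip().lower() for s in bands if s.strip())
            construct = str(row.get("construct", "EX")).strip() or "EX"
            xl = CrossLink(min(a, b), max(a, b), bands, construct)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed cross-link row {i + 2}: {exc}") from exc
        key = (xl.key, xl.construct)
        if key in merged:
            merged[key]["bands"] |= set(xl.bands)
        else:
            merged[key] = {"xl": xl, "bands": set(xl.bands)}
    return [CrossLink(e["xl"].residue_a, e["xl"].residue_b,
                      frozenset(e["bands"]), e["xl"].construct)
            for e in merged.values()]


def load_text_named_crosslinks() -> list[CrossLink]:
    """The packaged fixture of text-named cross-linked lysine pairs."""
    from importlib import resources
    ref = resources.files("oligostate.data") / "crosslinks_text_named.tsv"
    with resources.as_file(ref) as path:
        return parse_crosslinks(path)


# ---------------------------------------------------------------------------
# Endpoints and variants

def _endpoint_atoms(model: StructureModel, residue: int,
                    atom_name: str = "CA") -> dict[str, np.ndarray]:
    """Per-chain coordinates of the endpoint atom of one residue."""
    out: dict[str, np.ndarray] = {}
    mask = (model.residue_numbers == residue) & (model.atom_names == atom_name)
    if not mask.any():
        # toy structures may carry pseudo-atoms with other names
        mask = model.residue_numbers == residue
        idx = np.nonzero(mask)[0]
        for i in idx:
            out.setdefault(str(model.chain_ids[i]), model.coords[i])
        if not out:
            raise ValueError(f"endpoint residue {residue} absent from model")
        return out
    for i in np.nonzero(mask)[0]:
        out[str(model.chain_ids[i])] = model.coords[i]
    return out


def _variants(model: StructureModel, xl: CrossLink):
    """All intra/inter chain placements of a cross-link on a model."""
    ends_a = _endpoint_atoms(model, xl.residue_a)
    ends_b = _endpoint_atoms(model, xl.residue_b)
    seen = set()
    for ca, pa in ends_a.items():
        for cb, pb in ends_b.items():
            if xl.is_self_pair and ca == cb:
                continue  # a residue cannot link to itself
            key = frozenset([(ca, xl.residue_a), (cb, xl.residue_b)])
            if key in seen:
                continue
            seen.add(key)
            kind = "intra" if ca == cb else "inter"
            label = f"{kind}:{ca}" if kind == "intra" else f"inter:{ca}-{cb}"
            yield label, ca, cb, pa, pb


def euclidean_prefilter(model: AssemblyModel | StructureModel, xl: CrossLink,
                        cutoff: float = 33.0) -> list[dict]:
    """Euclidean distances of every variant, flagged keep/exclude vs cutoff.

    Variants longer than the cutoff in a straight line cannot have a
    compliant surface path (SASD ≥ Euclidean) and are excluded from the
    path search; downstream they count as non-accessible.
    """
    s = _as_structure(model)
    rows = []
    for label, ca, cb, pa, pb in _variants(s, xl):
        d = float(np.linalg.norm(pa - pb))
        rows.append({"variant": label, "chain_a": ca, "chain_b": cb,
                     "euclidean": d, "keep": d <= cutoff})
    return rows


# ---------------------------------------------------------------------------
# SASD grid

#: offsets and Euclidean lengths of the 26-neighbourhood
_OFFSETS = np.array([o for o in itertools.product((-1, 0, 1), repeat=3)
                     if o != (0, 0, 0)], dtype=int)
_OFFSET_LEN = np.linalg.norm(_OFFSETS, axis=1)


class SolventGrid:
    """Voxelisation of a structure's solvent space.

    Voxels within (vdW radius + probe) of any atom are blocked; the
    remainder is solvent.  Shortest solvent paths use 26-connectivity
    with Euclidean edge weights (1, √2, √3 × spacing).
    """

    def __init__(self, model: StructureModel, spacing: float = 1.0,
                 probe: float = 1.4, margin: float = 6.0):
        self.spacing = float(spacing)
        self.probe = float(probe)
        coords = model.coords
        radii = model.vdw_radii()
        self.origin = coords.min(axis=0) - margin
        upper = coords.max(axis=0) + margin
        self.shape = tuple(np.ceil((upper - self.origin) / spacing).astype(int) + 1)
        self.blocked = np.zeros(self.shape, dtype=bool)
        # stamp each atom's inflated sphere onto the grid
        rmax_vox = int(np.ceil((radii.max() + probe) / spacing)) + 1
        rng = np.arange(-rmax_vox, rmax_vox + 1)
        cube = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1)
        cube_d = np.linalg.norm(cube, axis=-1) * spacing
        for xyz, r in zip(coords, radii):
            center = np.round((xyz - self.origin) / spacing).astype(int)
            local = cube[cube_d <= r + probe + 1e-9] + center
            ok = np.all((local >= 0) & (local < np.array(self.shape)), axis=1)
            local = local[ok]
            self.blocked[local[:, 0], local[:, 1], local[:, 2]] = True
        # solvent = free space connected to the box boundary; interior
        # cavities sealed off from bulk solvent are not accessible
        from scipy import ndimage
        labels, _ = ndimage.label(~self.blocked, structure=np.ones((3, 3, 3)))
        boundary_labels = set()
        for ax in range(3):
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[ax] = face
                boundary_labels |= set(np.unique(labels[tuple(sl)]))
        boundary_labels.discard(0)
        self.solvent = np.isin(labels, sorted(boundary_labels))
        self._graph = None

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_of(self, xyz: np.ndarray) -> np.ndarray:
        return np.round((np.asarray(xyz) - self.origin) / self.spacing).astype(int)

    def center_of(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk) * self.spacing

    def nearest_free_voxel(self, xyz: np.ndarray,
                           search_radius: float = 8.0,
                           toward: np.ndarray | None = None) -> np.ndarray | None:
        """Closest solvent voxel to a point, or None if buried.

        With ``toward`` given, ties among near-equidistant surface voxels
        are broken toward the partner endpoint (minimising
        |v − xyz| + |v − toward|), so the exit point of a buried-ish atom
        faces its cross-link partner rather than an arbitrary side.
        """
        if not hasattr(self, "_free_voxels"):
            self._free_voxels = np.argwhere(self.solvent)
            self._free_tree = (cKDTree(self.center_of(self._free_voxels))
                               if len(self._free_voxels) else None)
        if self._free_tree is None:
            return None
        xyz = np.asarray(xyz, float)
        d, idx = self._free_tree.query(xyz, k=1)
        if d > search_radius:
            return None
        if toward is None:
            return self._free_voxels[idx]
        cand = self._free_tree.query_ball_point(xyz, d + 1.5 * self.spacing)
        centers = self.center_of(self._free_voxels[cand])
        cost = (np.linalg.norm(centers - xyz, axis=1)
                + np.linalg.norm(centers - np.asarray(toward, float), axis=1))
        return self._free_voxels[cand[int(np.argmin(cost))]]

    def _flat(self, ijk: np.ndarray) -> int:
        return int(np.ravel_multi_index(tuple(ijk), self.shape))

    def graph(self) -> sparse.csr_matrix:
        """Sparse 26-connected adjacency over solvent voxels (Å weights)."""
        if self._graph is not None:
            return self._graph
        free = self.solvent
        idx = np.arange(self.n_voxels).reshape(self.shape)
        rows, cols, data = [], [], []
        for off, length in zip(_OFFSETS, _OFFSET_LEN):
            # half the offsets suffice: the graph is symmetrised below
            if tuple(off) < (0, 0, 0):
                continue
            src_sl, dst_sl = [], []
            for ax in range(3):
                o = int(off[ax])
                if o == 1:
                    src_sl.append(slice(0, -1))
                    dst_sl.append(slice(1, None))
                elif o == -1:
                    src_sl.append(slice(1, None))
                    dst_sl.append(slice(0, -1))
                else:
                    src_sl.append(slice(None))
                    dst_sl.append(slice(None))
            both = free[tuple(src_sl)] & free[tuple(dst_sl)]
            rows.append(idx[tuple(src_sl)][both])
            cols.append(idx[tuple(dst_sl)][both])
            data.append(np.full(int(both.sum()), length * self.spacing))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.concatenate(data)
        g = sparse.csr_matrix((data, (rows, cols)),
                              shape=(self.n_voxels, self.n_voxels))
        self._graph = g + g.T
        return self._graph

    def surface_distance(self, a: np.ndarray, b: np.ndarray) -> float:
        """Shortest solvent path (Å) between two atom positions.

        Includes the straight legs from each atom to its nearest solvent
        voxel, which keeps the result ≥ the Euclidean distance.
        Returns NOT_ACCESSIBLE when either endpoint is buried or no path
        exists.
        """
        va = self.nearest_free_voxel(a, toward=b)
        vb = self.nearest_free_voxel(b, toward=a)
        if va is None or vb is None:
            return NOT_ACCESSIBLE
        src, dst = self._flat(va), self._flat(vb)
        if src == dst:
            mid = 0.0
        else:
            dist = dijkstra(self.graph(), directed=False, indices=src,
                            min_only=False, limit=np.inf)
            mid = float(dist[dst])
            if not np.isfinite(mid):
                return NOT_ACCESSIBLE
        leg_a = float(np.linalg.norm(np.asarray(a) - self.center_of(va)))
        leg_b = float(np.linalg.norm(np.asarray(b) - self.center_of(vb)))
        total = leg_a + mid + leg_b
        # grid quantisation can undercut the straight line by < one voxel
        return max(total, float(np.linalg.norm(np.asarray(a) - np.asarray(b))))


def compute_sasd(model: AssemblyModel | StructureModel, xl: CrossLink,
                 grid_spacing: float = 1.0, probe: float = 1.4,
                 prefilter_cutoff: float | None = 33.0,
                 grid: SolventGrid | None = None) -> list[SASDResult]:
    """SASD of every intra/inter variant of one cross-link on a model.

    Variants failing the Euclidean prefilter (or with a buried endpoint)
    are reported with ``sasd = NOT_ACCESSIBLE``.  Passing a prebuilt
    ``grid`` amortises voxelisation across cross-links.
    """
    s = _as_structure(model)
    if grid is None:
        grid = SolventGrid(s, spacing=grid_spacing, probe=probe)
    results = []
    for label, ca, cb, pa, pb in _variants(s, xl):
        eu = float(np.linalg.norm(pa - pb))
        if prefilter_cutoff is not None and eu > prefilter_cutoff:
            sasd = NOT_ACCESSIBLE
        else:
            sasd = grid.surface_distance(pa, pb)
        results.append(SASDResult(xl, label, eu, sasd, ca, cb))
    return results


# ---------------------------------------------------------------------------
# Scoring

def mnxl_score(sasd: float | SASDResult, params: MNXLParams = MNXLParams()) -> float:
    """Score one SASD: N(mu, var) density if ≤ cutoff, else the flat penalty."""
    value = sasd.sasd if isinstance(sasd, SASDResult) else float(sasd)
    if not np.isfinite(value) or value > params.cutoff:
        return params.penalty
    var = params.variance
    return float(np.exp(-((value - params.mu) ** 2) / (2.0 * var))
                 / np.sqrt(2.0 * np.pi * var))


def score_model(model: AssemblyModel | StructureModel, xls: list[CrossLink],
                params: MNXLParams = MNXLParams(),
                reference: ModelScore | None = None,
                grid_spacing: float = 1.0, probe: float = 1.4,
                model_id: str | None = None,
                grid: SolventGrid | None = None) -> ModelScore:
    """Aggregate MNXL score of a model against a cross-link set.

    Per cross-link only the best variant counts; with a dimer
    ``reference``, cross-links already matched there contribute 0 instead
    of the penalty when unmatched here (tetramers are ranked by the
    cross-links the dimer cannot explain, not punished for the ones it
    already does).
    """
    s = _as_structure(model)
    if grid is None and xls:
        grid = SolventGrid(s, spacing=grid_spacing, probe=probe)
    per: dict[tuple[int, int], float] = {}
    matched: dict[tuple[int, int], bool] = {}
    n_match = n_nonacc = 0
    for xl in xls:
        results = compute_sasd(s, xl, prefilter_cutoff=params.cutoff, grid=grid)
        if results:
            best = max(mnxl_score(r, params) for r in results)
        else:
            best = params.penalty
        is_match = best > 0
        if not is_match and reference is not None and reference.matched.get(xl.key):
            best = 0.0
        per[xl.key] = best
        matched[xl.key] = is_match
        n_match += int(is_match)
        n_nonacc += int(not is_match)
    mid = model_id if model_id is not None else (
        model.model_id if isinstance(model, AssemblyModel) else "model")
    return ModelScore(mid, per, matched, n_match, n_nonacc)


def assign_states(xls: list[CrossLink],
                  state_models: dict[str, AssemblyModel | StructureModel],
                  params: MNXLParams = MNXLParams(),
                  grid_spacing: float = 1.0, probe: float = 1.4) -> dict[CrossLink, str]:
    """Assign each cross-link to the oligomeric state that explains it best.

    Rules, in order:

    * cross-links seen exclusively in monomer bands are intra-subunit by
      construction → monomer (unless a self-pair, which needs two copies
      of the residue and therefore two subunits);
    * otherwise the state whose model gives the cross-link its highest
      MNXL score wins, ties broken toward the smaller oligomer.
    """
    order = {"monomer": 0, "dimer": 1, "trimer": 2, "tetramer": 3, "other": 4}
    names = sorted(state_models, key=lambda s: order.get(s, 99))
    scores: dict[str, ModelScore] = {}
    for name in names:
        s = _as_structure(state_models[name])
        grid = SolventGrid(s, spacing=grid_spacing, probe=probe)
        scores[name] = score_model(s, xls, params, grid=grid, model_id=name)
    out: dict[CrossLink, str] = {}
    for xl in xls:
        if xl.bands == frozenset({"monomer"}) and not xl.is_self_pair:
            out[xl] = "monomer"
            continue
        candidates = [n for n in names if not (xl.is_self_pair and n == "monomer")]
        best = max(candidates,
                   key=lambda n: (scores[n].per_crosslink[xl.key], -order.get(n, 99)))
        out[xl] = best
    return out


# ---------------------------------------------------------------------------
# Restraint preprocessing / ensemble scanning (DisVis-style)

def symmetrize_restraints(xls: list[CrossLink], tetramer: AssemblyModel,
                          max_dist: float = 33.0,
                          chain_pairing: dict[str, str] | None = None) -> RestraintSet:
    """Chain-assign cross-links on a tetramer and add symmetric counterparts.

    Each cross-link is assigned the chain pair that minimises its
    Euclidean distance in the given model (homo-oligomer cross-links are
    chain-ambiguous).  Symmetry is then imposed: with chains paired by
    the tetramer's 2-fold (A↔C, B↔D by default for chains in realization
    order), every restraint gets its symmetry mate, skipping duplicates.
    """
    s = _as_structure(tetramer)
    chains = s.chains
    if len(chains) != 4:
        raise ValueError(f"expected a 4-chain tetramer, got {len(chains)} chains")
    if chain_pairing is None:
        # realization order A,B from dimer 1 then C,D from dimer 2:
        # the 2-fold swaps the dimers, pairing A↔C and B↔D
        chain_pairing = {chains[0]: chains[2], chains[2]: chains[0],
                         chains[1]: chains[3], chains[3]: chains[1]}
    restraints: list[ChainRestraint] = []
    seen: set[tuple] = set()

    def _add(ca, ra, cb, rb):
        key = frozenset([(ca, ra), (cb, rb)])
        if key in seen:
            return
        seen.add(key)
        restraints.append(ChainRestraint(ca, ra, cb, rb, max_dist))

    for xl in xls:
        best = None
        for label, ca, cb, pa, pb in _variants(s, xl):
            d = float(np.linalg.norm(pa - pb))
            if best is None or d < best[0]:
                best = (d, ca, cb)
        if best is None:
            continue
        _, ca, cb = best
        _add(ca, xl.residue_a, cb, xl.residue_b)
        _add(chain_pairing[ca], xl.residue_a, chain_pairing[cb], xl.residue_b)
    return RestraintSet(restraints, symmetry_completed=True)


def restraint_scan(ensemble: list[AssemblyModel],
                   restraints: RestraintSet) -> pd.DataFrame:
    """Count satisfied restraints per model over an ensemble.

    A restraint is satisfied when the Euclidean distance between its
    chain-assigned endpoints is ≤ its max_dist.  Reporting the full
    satisfaction table (rather than only perfect models) tolerates
    false-positive cross-links, as in accessible-interaction-space
    analysis.  Returns a DataFrame with columns model_id, satisfied,
    n_restraints, best (bool).
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    rows = []
    for i, model in enumerate(ensemble):
        s = _as_structure(model)
        count = 0
        for r in restraints.restraints:
            try:
                pa = _endpoint_atoms(s, r.res_a)[r.chain_a]
                pb = _endpoint_atoms(s, r.res_b)[r.chain_b]
            except (KeyError, ValueError):
                continue
            if np.linalg.norm(pa - pb) <= r.max_dist:
                count += 1
        rows.append({"model_id": model.model_id or f"model_{i}",
                     "satisfied": count, "n_restraints": len(restraints)})
    df = pd.DataFrame(rows)
    df["best"] = df["satisfied"] == df["satisfied"].max()
    return df
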