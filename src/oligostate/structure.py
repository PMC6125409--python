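"""Atomic structures, rigid assemblies and their geometric measures.

Coordinates are stored in ångström throughout.  A :class:`StructureModel`
holds a flat table of heavy atoms with chain identity and author residue
numbering; an :class:`AssemblyModel` realizes a homo-oligomer by applying
a list of rigid transforms to a base structure, relabelling the chains of
each unit.  On top of these the module provides the measures used to
characterise candidate oligomers: mass-weighted radius of gyration,
molecular mass, the Cα–Cα distance between chain N-termini,
chain-permutation-aware RMSD, greedy leader clustering, and a geometric
plausibility test for membrane-spanning (trans) tetramers based on the
orientation of the membrane-anchor residues of the two dimer halves.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "AssemblyModel",
    "ClusterResult",
    "RigidTransform",
    "read_structure",
    "write_pdb",
    "build_assembly",
    "radius_of_gyration",
    "molecular_mass",
    "mass_from_concentration",
    "nterm_distance",
    "rmsd_symm",
    "kabsch_rmsd",
    "cluster_models",
    "trans_plausibility",
]

# Average atomic masses (Da) for the elements found in proteins.
ELEMENT_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "X": 12.011,  # pseudo-atoms in toy structures
}

# Average residue masses (Da) of amino-acid residues *in a chain*
# (i.e. monoisotopic water already removed); add one water per chain.
RESIDUE_MASS = {
    "GLY": 57.052, "ALA": 71.079, "SER": 87.078, "PRO": 97.117,
    "VAL": 99.133, "THR": 101.105, "CYS": 103.144, "LEU": 113.160,
    "ILE": 113.160, "ASN": 114.104, "ASP": 115.088, "GLN": 128.131,
    "LYS": 128.174, "GLU": 129.115, "MET": 131.197, "HIS": 137.141,
    "PHE": 147.177, "ARG": 156.188, "TYR": 163.176, "TRP": 186.213,
}
WATER_MASS = 18.015

# Van der Waals radii (Å) used when voxelising structures.
VDW_RADIUS = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "X": 1.70,
}

ONE_LETTER = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL",
    "T": "THR", "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN",
    "D": "ASP", "Q": "GLN", "K": "LYS", "E": "GLU", "M": "MET",
    "H": "HIS", "F": "PHE", "R": "ARG", "Y": "TYR", "W": "TRP",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: chain, author residue number/name, atom name, xyz."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    coordinates: tuple[float, float, float]
    mass: float
    element: str


class StructureError(ValueError):
    """Raised for unparseable files, empty selections or bad compositions."""


@dataclass
class StructureModel:
    """Flat atom table of a (multi-chain) structure.

    Parallel numpy arrays keep geometry vectorisable; ``atom_records()``
    gives a record view when needed.
    """

    chain_ids: np.ndarray          # object / str
    residue_numbers: np.ndarray    # int
    residue_names: np.ndarray      # str, 3-letter codes
    atom_names: np.ndarray         # str
    coords: np.ndarray             # (n, 3) float, Å
    masses: np.ndarray             # float, Da
    elements: np.ndarray           # str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in ("chain_ids", "residue_numbers", "residue_names",
                     "atom_names", "masses", "elements"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise StructureError(f"field {name} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        if n == 0:
            raise StructureError("empty selection: structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise StructureError("non-positive atom mass")
        key = list(zip(self.chain_ids, self.residue_numbers, self.atom_names))
        if len(set(key)) != n:
            raise StructureError("duplicate (chain, residue, atom) triple")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_ids == chain

    def select(self, mask: np.ndarray, provenance: str | None = None) -> "StructureModel":
        return StructureModel(
            self.chain_ids[mask], self.residue_numbers[mask],
            self.residue_names[mask], self.atom_names[mask],
            self.coords[mask], self.masses[mask], self.elements[mask],
            provenance if provenance is not None else self.provenance,
        )

    def atom_coords(self, chain: str, residue: int, atom: str = "CA") -> np.ndarray:
        """Coordinates of one named atom; raises if absent."""
        mask = (self.chain_ids == chain) & (self.residue_numbers == residue) \
            & (self.atom_names == atom)
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise StructureError(f"atom {atom} of residue {residue} in chain {chain} not found")
        return self.coords[idx[0]]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = replace(self)
        out.coords = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return out

    def atom_records(self):
        for i in range(self.n_atoms):
            yield AtomRecord(
                str(self.chain_ids[i]), int(self.residue_numbers[i]),
                str(self.residue_names[i]), str(self.atom_names[i]),
                tuple(self.coords[i]), float(self.masses[i]), str(self.elements[i]),
            )

    def vdw_radii(self) -> np.ndarray:
        return np.array([VDW_RADIUS.get(str(e).upper(), 1.7) for e in self.elements])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R x + t with R orthonormal."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix not orthonormal within 1e-8")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


class ClashError(ValueError):
    """Two assembly units approach closer than the clash floor."""


@dataclass
class AssemblyModel:
    """A homo-oligomer: one base structure replicated by rigid transforms.

    ``realize()`` materialises the assembly as a single StructureModel with
    chains of unit *k* relabelled ``<chain>{k}`` (unit 0 keeps bare labels
    when only one unit exists).
    """

    base: StructureModel
    units: list[RigidTransform]
    state_label: str = "other"
    model_id: str = ""
    clash_floor: float = 1.5
    allow_clash: bool = False
    _realized: StructureModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("assembly needs at least one transform")
        if not self.allow_clash and len(self.units) > 1:
            d = self.min_interunit_distance()
            if d < self.clash_floor:
                raise ClashError(
                    f"inter-unit clash: minimum distance {d:.2f} Å "
                    f"below floor {self.clash_floor} Å")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit_coords(self, k: int) -> np.ndarray:
        return self.units[k].apply(self.base.coords)

    def min_interunit_distance(self) -> float:
        from scipy.spatial import cKDTree
        best = np.inf
        coords = [self.unit_coords(k) for k in range(self.n_units)]
        for i in range(self.n_units):
            tree = cKDTree(coords[i])
            for j in range(i + 1, self.n_units):
                d, _ = tree.query(coords[j], k=1)
                best = min(best, float(d.min()))
        return best

    def realize(self) -> StructureModel:
        if self._realized is not None:
            return self._realized
        if self.n_units == 1:
            model = self.base.transformed(self.units[0].rotation, self.units[0].translation)
            self._realized = model
            return model
        parts = []
        for k, tr in enumerate(self.units):
            chains = np.array([f"{c}{k}" for c in self.base.chain_ids], dtype=object)
            parts.append((chains, tr.apply(self.base.coords)))
        self._realized = StructureModel(
            np.concatenate([p[0] for p in parts]),
            np.tile(self.base.residue_numbers, self.n_units),
            np.tile(self.base.residue_names, self.n_units),
            np.tile(self.base.atom_names, self.n_units),
            np.vstack([p[1] for p in parts]),
            np.tile(self.base.masses, self.n_units),
            np.tile(self.base.elements, self.n_units),
            provenance=f"assembly[{self.state_label}] of ({self.base.provenance})",
        )
        return self._realized


@dataclass
class ClusterResult:
    cluster_assignments: dict[str, int]
    representatives: list[str]
    cutoff: float


def _as_structure(model: StructureModel | AssemblyModel) -> StructureModel:
    return model.realize() if isinstance(model, AssemblyModel) else model


# ---------------------------------------------------------------------------
# I/O

def read_structure(path, fmt: str | None = None,
                   residue_range: tuple[int, int] | None = None,
                   drop_hydrogens: bool = True) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path : str or Path
        Structure file.  Format is inferred from the extension unless
        ``fmt`` is one of ``"pdb"`` / ``"mmcif"``.
    residue_range : (lo, hi), optional
        Inclusive author-numbering window; atoms outside are dropped.
    drop_hydrogens : bool
        Hydrogens (and waters) are removed by default.
    """
    path = str(path)
    try:
        if fmt == "pdb" or (fmt is None and path.lower().endswith(".pdb")):
            st = gemmi.read_pdb(path)
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path!r}: {exc}") from exc

    chain_ids, resnums, resnames, atnames, coords, masses, elements = \
        [], [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            num = res.seqid.num
            if residue_range is not None and not (residue_range[0] <= num <= residue_range[1]):
                continue
            for atom in res:
                el = atom.element.name.upper()
                if drop_hydrogens and el in ("H", "D"):
                    continue
                chain_ids.append(chain.name)
                resnums.append(num)
                resnames.append(res.name)
                atnames.append(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                masses.append(ELEMENT_MASS.get(el, atom.element.weight or 12.011))
                elements.append(el)
    if not coords:
        raise StructureError(f"empty selection reading {path!r} (range={residue_range})")
    return StructureModel(
        np.array(chain_ids, dtype=object), np.array(resnums, dtype=int),
        np.array(resnames, dtype=object), np.array(atnames, dtype=object),
        np.array(coords, dtype=float), np.array(masses, dtype=float),
        np.array(elements, dtype=object), provenance=path,
    )


def write_pdb(model: StructureModel | AssemblyModel, path) -> None:
    """Write a fixed-width PDB file (fixture/interchange use)."""
    model = _as_structure(model)
    with open(path, "w") as fh:
        serial = 0
        for rec in model.atom_records():
            serial += 1
            name = rec.atom_name
            # PDB column alignment: 1–3 char names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = rec.coordinates
            fh.write(
                f"ATOM  {serial:5d} {name_field}{'':1s}{rec.residue_name:>3s} "
                f"{str(rec.chain_id)[:1]:1s}{rec.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {rec.element:>2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Assemblies and measures

def build_assembly(base: StructureModel, transforms, state_label: str = "other",
                   clash_floor: float = 1.5, allow_clash: bool = False,
                   model_id: str = "") -> AssemblyModel:
    """Realize an oligomer from a base structure and explicit rigid transforms."""
    units = [t if isinstance(t, RigidTransform) else RigidTransform(*t) for t in transforms]
    return AssemblyModel(base, units, state_label=state_label,
                         clash_floor=clash_floor, allow_clash=allow_clash,
                         model_id=model_id)


def radius_of_gyration(model: StructureModel | AssemblyModel) -> float:
    """Mass-weighted radius of gyration in Å (bare coordinates, no hydration).

    Scattering-derived Rg of a hydrated particle typically exceeds this
    value by ~1 Å.
    """
    s = _as_structure(model)
    if s.n_atoms < 2:
        warnings.warn("radius of gyration of a single atom is 0", stacklevel=2)
        return 0.0
    w = s.masses / s.masses.sum()
    com = w @ s.coords
    return float(np.sqrt(np.sum(w * np.sum((s.coords - com) ** 2, axis=1))))


def molecular_mass(model, kind: str = "average") -> float:
    """Molecular mass in kDa of a structure, assembly or residue sequence.

    Sequences may be given as a string of one-letter codes or an iterable
    of three-letter codes; one water per chain terminates the chain.
    """
    if isinstance(model, (StructureModel, AssemblyModel)):
        s = _as_structure(model)
        return float(s.masses.sum()) / 1000.0
    if isinstance(model, str):
        codes = []
        for c in model.upper():
            if c not in ONE_LETTER:
                raise StructureError(f"unknown residue code {c!r}")
            codes.append(ONE_LETTER[c])
    else:
        codes = [str(c).upper() for c in model]
    if not codes:
        raise StructureError("empty selection: no residues")
    total = WATER_MASS
    for code in codes:
        if code not in RESIDUE_MASS:
            raise StructureError(f"unknown residue code {code!r}")
        total += RESIDUE_MASS[code]
    return total / 1000.0


def mass_from_concentration(mass_conc_mg_ml: float, molar_conc_uM: float,
                            n_subunits: int = 1) -> float:
    """Molar mass (kDa) implied by a mass ↔ molar concentration equivalence.

    ``mg/ml ÷ µM`` gives the subunit molar mass in kDa directly
    (mg/ml = g/l; µM = µmol/l); multiply by ``n_subunits`` for the
    oligomer mass when the molar concentration counts subunits.
    """
    if mass_conc_mg_ml <= 0 or molar_conc_uM <= 0:
        raise ValueError("concentrations must be positive")
    return n_subunits * 1000.0 * mass_conc_mg_ml / molar_conc_uM


def nterm_distance(dimer: AssemblyModel | StructureModel) -> float:
    """Distance (nm) between the N-terminal Cα atoms of a dimer's two chains."""
    s = _as_structure(dimer)
    chains = s.chains
    if len(chains) != 2:
        raise StructureError(f"expected exactly 2 chains, got {len(chains)}")
    points = []
    for chain in chains:
        mask = s.chain_mask(chain)
        resnums = s.residue_numbers[mask]
        first = int(resnums.min())
        ca = mask & (s.residue_numbers == first) & (s.atom_names == "CA")
        idx = np.nonzero(ca)[0]
        if len(idx) == 0:
            raise StructureError(f"no Cα for N-terminal residue {first} of chain {chain}")
        points.append(s.coords[idx[0]])
    return float(np.linalg.norm(points[0] - points[1])) / 10.0


# ---------------------------------------------------------------------------
# RMSD and clustering

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Least-squares superposed RMSD of two matched coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    # proper rotation only
    ssd = (ac ** 2).sum() + (bc ** 2).sum() - 2.0 * (S[0] + S[1] + d * S[2])
    return float(np.sqrt(max(ssd, 0.0) / len(a)))


def _chain_groups(model: StructureModel) -> tuple[list[np.ndarray], list[tuple]]:
    """Per-chain coordinate blocks and their composition signatures."""
    coords, sigs = [], []
    for chain in model.chains:
        mask = model.chain_mask(chain)
        coords.append(model.coords[mask])
        sigs.append((tuple(model.residue_numbers[mask]), tuple(model.atom_names[mask])))
    return coords, sigs


def rmsd_symm(a: AssemblyModel | StructureModel,
              b: AssemblyModel | StructureModel,
              max_chains_permuted: int = 6) -> float:
    """Homo-oligomer RMSD: minimum over equivalent chain permutations.

    Chains with identical composition (same residue-number and atom-name
    sequence) are interchangeable — the symmetry of a homo-oligomer means
    e.g. swapping the two subunits of a dimer, or the two dimers of a
    tetramer, yields the same physical model.  The reported value is the
    minimum least-squares superposed RMSD over all such permutations.
    """
    sa, sb = _as_structure(a), _as_structure(b)
    if sa.n_atoms != sb.n_atoms:
        raise StructureError("composition mismatch: different atom counts")
    ga, siga = _chain_groups(sa)
    gb, sigb = _chain_groups(sb)
    if len(ga) != len(gb) or sorted(siga) != sorted(sigb):
        raise StructureError("composition mismatch between chain sets")
    n = len(gb)
    if n > max_chains_permuted:
        raise StructureError(f"too many chains ({n}) for exhaustive permutation")
    ref = np.vstack(ga)
    best = np.inf
    for perm in itertools.permutations(range(n)):
        if [sigb[i] for i in perm] != siga:
            continue
        best = min(best, kabsch_rmsd(ref, np.vstack([gb[i] for i in perm])))
    return best


def cluster_models(models: list[AssemblyModel], cutoff: float,
                   ids: list[str] | None = None) -> ClusterResult:
    """Greedy leader clustering under :func:`rmsd_symm`.

    Models are consumed in input order (callers pass them best-score
    first); a model joins the first cluster whose representative is within
    ``cutoff``, otherwise it founds a new cluster.
    """
    if not models:
        raise ValueError("no models to cluster")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ids is None:
        ids = [m.model_id or f"model_{i}" for i, m in enumerate(models)]
    reps: list[int] = []
    assignments: dict[str, int] = {}
    for i, model in enumerate(models):
        placed = False
        for ci, ri in enumerate(reps):
            if rmsd_symm(model, models[ri]) <= cutoff:
                assignments[ids[i]] = ci
                placed = True
                break
        if not placed:
            reps.append(i)
            assignments[ids[i]] = len(reps) - 1
    return ClusterResult(assignments, [ids[r] for r in reps], cutoff)


# ---------------------------------------------------------------------------
# Trans-plausibility

def trans_plausibility(tetramer: AssemblyModel,
                       anchor_residues: list[int] | None = None,
                       angle_threshold: float = 120.0) -> tuple[str, float]:
    """Judge whether a tetramer could bridge two opposing membranes.

    Each dimer unit carries membrane-anchor residues (the C-terminal
    stretch leading to the transmembrane helix).  For a trans-interaction
    the two dimers' anchors must face away from each other, towards the
    two opposing cells.  Operationally: the unit vectors from each dimer
    centroid to its mean anchor position must differ by at least
    ``angle_threshold`` degrees (inclusive), and the two anchor-point sets
    must be separable by a plane through the tetramer centroid.

    Returns ``("plausible" | "implausible", angle_degrees)``.
    """
    if tetramer.n_units != 2:
        raise StructureError("trans-plausibility is defined for two dimer units")
    base = tetramer.base
    if anchor_residues is None:
        # default: last resolved residue of each base chain
        anchor_residues = sorted({int(base.residue_numbers[base.chain_mask(c)].max())
                                  for c in base.chains})
    anchor_mask = np.isin(base.residue_numbers, anchor_residues)
    ca = anchor_mask & (base.atom_names == "CA")
    if ca.any():
        anchor_mask = ca
    if not anchor_mask.any():
        raise StructureError(f"anchor residues {anchor_residues} not found")

    dirs, anchor_sets, centroids = [], [], []
    for k in range(2):
        coords = tetramer.unit_coords(k)
        centroid = coords.mean(axis=0)
        anchors = coords[anchor_mask]
        v = anchors.mean(axis=0) - centroid
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise StructureError("anchor direction degenerate (anchors at centroid)")
        dirs.append(v / norm)
        anchor_sets.append(anchors)
        centroids.append(centroid)

    cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))

    # plane separability: project both anchor sets on the inter-anchor axis
    center = np.vstack([tetramer.unit_coords(k) for k in range(2)]).mean(axis=0)
    axis = anchor_sets[1].mean(axis=0) - anchor_sets[0].mean(axis=0)
    separable = False
    if np.linalg.norm(axis) > 1e-9:
        axis = axis / np.linalg.norm(axis)
        proj0 = (anchor_sets[0] - center) @ axis
        proj1 = (anchor_sets[1] - center) @ axis
        separable = bool(proj0.max() < proj1.min() + 1e-9)

    plausible = (angle >= angle_threshold - 1e-9) and separable
    return ("plausible" if plausible else "implausible", angle)
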