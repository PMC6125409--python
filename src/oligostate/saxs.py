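"""Small-angle X-ray scattering: profiles, analytics, fits, equilibrium.

Scattering profiles are I(q) with q = 4π sin(θ)/λ in Å⁻¹.  Model
profiles are computed with the Debye formula over residue-level
scatterers (Cα-centred, per-residue electron counts), which is adequate
for the *relative* comparisons the analysis needs (dimer vs tetramer,
state weights); no hydration layer is added and intensities carry
arbitrary units.

Provided analytics: Guinier radius of gyration, Porod-volume molecular
weight, concentration-series merging, single-profile χ² fitting, a
multi-state ensemble fit (beam-search enumeration of state combinations
with non-negative weights), and the closed-form dimer ↔ tetramer
mass-action equilibrium used to predict how much tetramer *would* be
present at a given concentration if the association constant were as
hypothesised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from oligostate.structure import AssemblyModel, StructureModel, _as_structure

__all__ = [
    "SAXSProfile",
    "GuinierResult",
    "MultiStateFit",
    "MultiStateModel",
    "MultiStateResults",
    "read_profile",
    "write_profile",
    "compute_profile",
    "sphere_profile",
    "guinier_rg",
    "estimate_mw",
    "merge_profiles",
    "fit_profile",
    "multistate_fit",
    "tetramer_fraction",
]

# Electron counts of amino-acid residues as chain units (neutral forms).
RESIDUE_ELECTRONS = {
    "GLY": 30, "ALA": 38, "SER": 46, "PRO": 52, "VAL": 54, "THR": 54,
    "CYS": 54, "LEU": 62, "ILE": 62, "ASN": 60, "ASP": 60, "GLN": 68,
    "LYS": 70, "GLU": 68, "MET": 70, "HIS": 72, "PHE": 78, "ARG": 84,
    "TYR": 86, "TRP": 98,
}
#: fallback weight for unknown residues / pseudo-residues
DEFAULT_RESIDUE_ELECTRONS = 58.0

ELEMENT_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15,
                     "SE": 34, "X": 6}

#: default mass per Porod volume, kDa/Å³ (protein density ≈ 1.37 g/cm³)
POROD_MASS_DENSITY = 0.83e-3


@dataclass
class SAXSProfile:
    """q / I / σ arrays (q in Å⁻¹, intensities in arbitrary units)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    concentration: float | None = None   # mg/ml
    label: str = ""

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is None:
            self.sigma = np.full_like(self.intensity, np.nan)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, I, sigma lengths differ")
        if np.any(np.diff(self.q) <= 0) or np.any(self.q < 0):
            raise ValueError("q must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return len(self.q)

    def interpolated_to(self, q: np.ndarray) -> np.ndarray:
        """Model intensity resampled onto another q grid."""
        return np.interp(q, self.q, self.intensity)


@dataclass
class GuinierResult:
    Rg: float
    I0: float
    fit_range: tuple[float, float]
    qmaxRg: float
    n_points: int


def read_profile(path, concentration: float | None = None) -> SAXSProfile:
    """Read a 3-column (q, I, σ) whitespace text profile; '#' comments."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"profile {path!r} needs at least 2 columns")
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return SAXSProfile(data[:, 0], data[:, 1], sigma,
                       concentration=concentration, label=str(path))


def write_profile(profile: SAXSProfile, path) -> None:
    sig = np.where(np.isfinite(profile.sigma), profile.sigma, 0.0)
    header = "q(A^-1) I(a.u.) sigma"
    np.savetxt(path, np.column_stack([profile.q, profile.intensity, sig]),
               header=header)


# ---------------------------------------------------------------------------
# Profile computation

def _scatterers(model: StructureModel, level: str) -> tuple[np.ndarray, np.ndarray]:
    if level == "atom":
        f = np.array([ELEMENT_ELECTRONS.get(str(e).upper(), 6)
                      for e in model.elements], dtype=float)
        return model.coords, f
    # residue level: one Cα-centred scatterer per residue
    positions, weights = [], []
    keys = list(zip(model.chain_ids, model.residue_numbers))
    df_index = pd.MultiIndex.from_tuples(keys)
    order = pd.unique(df_index)
    groups: dict = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    for k in order:
        idx = groups[tuple(k)]
        names = model.atom_names[idx]
        ca = [i for i, n in zip(idx, names) if n == "CA"]
        pos = model.coords[ca[0]] if ca else model.coords[idx].mean(axis=0)
        resname = str(model.residue_names[idx[0]]).upper()
        positions.append(pos)
        weights.append(RESIDUE_ELECTRONS.get(resname, DEFAULT_RESIDUE_ELECTRONS))
    return np.asarray(positions), np.asarray(weights, dtype=float)


def compute_profile(model: AssemblyModel | StructureModel, q_grid: np.ndarray,
                    level: str = "residue", sigma_frac: float | None = None) -> SAXSProfile:
    """Debye-sum scattering profile of a structure.

    I(q) = Σ_ij f_i f_j sin(q r_ij)/(q r_ij); I(0) = (Σ f)².  ``level``
    selects residue-level (default) or atom-level scatterers.  A σ column
    proportional to I is attached when ``sigma_frac`` is given.
    """
    s = _as_structure(model)
    q = np.asarray(q_grid, dtype=float)
    pos, f = _scatterers(s, level)
    diff = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    ff = f[:, None] * f[None, :]
    intensity = np.empty_like(q)
    for i, qi in enumerate(q):
        # np.sinc(x) = sin(πx)/(πx) → pass qr/π
        intensity[i] = float(np.sum(ff * np.sinc(qi * r / np.pi)))
    sigma = sigma_frac * intensity if sigma_frac else None
    label = getattr(model, "model_id", "") or "debye"
    return SAXSProfile(q, intensity, sigma, label=label)


def sphere_profile(radius: float, q_grid: np.ndarray, i0: float = 1.0) -> SAXSProfile:
    """Analytic profile of a uniform sphere (form-factor amplitude squared)."""
    q = np.asarray(q_grid, dtype=float)
    x = q * radius
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3
    amp = np.where(x < 1e-8, 1.0, amp)
    return SAXSProfile(q, i0 * amp ** 2, label=f"sphere R={radius}")


# ---------------------------------------------------------------------------
# Guinier / Porod analytics

def guinier_rg(profile: SAXSProfile, qmaxRg_limit: float = 1.3,
               min_points: int = 5, max_iter: int = 50) -> GuinierResult:
    """Guinier fit: ln I vs q² on the largest low-q window with qmax·Rg ≤ limit.

    The window is iterated to self-consistency: fit → shrink window to
    q ≤ limit/Rg → refit, until stable.  Weighted least squares when the
    profile carries uncertainties.
    """
    q, I, sig = profile.q, profile.intensity, profile.sigma
    mask = q > 0
    q, I, sig = q[mask], I[mask], sig[mask]
    hi = len(q)
    for _ in range(max_iter):
        if hi < min_points:
            raise ValueError("too few points in the Guinier window")
        qw, Iw, sw = q[:hi], I[:hi], sig[:hi]
        if np.any(Iw <= 0):
            raise ValueError("non-positive intensities in the Guinier window")
        x = qw ** 2
        y = np.log(Iw)
        if np.all(np.isfinite(sw)) and np.all(sw > 0):
            w = (Iw / sw) ** 2          # var(ln I) = (σ/I)²
        else:
            w = np.ones_like(x)
        W = w.sum()
        xm, ym = (w * x).sum() / W, (w * y).sum() / W
        cov = (w * (x - xm) * (y - ym)).sum()
        var = (w * (x - xm) ** 2).sum()
        slope = cov / var
        if slope >= 0:
            warnings.warn("non-decreasing Guinier region: aggregation or "
                          "inter-particle repulsion suspected", stacklevel=2)
            return GuinierResult(0.0, float(np.exp(ym - slope * xm)),
                                 (float(qw[0]), float(qw[-1])), 0.0, hi)
        rg = float(np.sqrt(-3.0 * slope))
        new_hi = int(np.searchsorted(q, qmaxRg_limit / rg, side="right"))
        new_hi = max(new_hi, min_points)
        if new_hi >= hi:
            i0 = float(np.exp(ym - slope * xm))
            return GuinierResult(rg, i0, (float(qw[0]), float(qw[-1])),
                                 float(qw[-1] * rg), hi)
        hi = new_hi
    raise RuntimeError("Guinier window failed to converge")


def estimate_mw(profile: SAXSProfile, q_max: float = 0.25,
                mass_density: float = POROD_MASS_DENSITY) -> float:
    """Molecular weight (kDa) from the Porod invariant.

    Q = ∫₀^qmax q² I(q) dq (the 0→q_min gap filled by Guinier
    extrapolation), Vp = 2π² I(0)/Q, MW = Vp × mass_density.  The
    default density calibration (0.83×10⁻³ kDa/Å³ ≈ 1.37 g/cm³) is the
    standard protein value; the estimate is scale-invariant.
    """
    if profile.q[-1] < q_max:
        raise ValueError(f"profile must extend to q ≥ {q_max} Å⁻¹")
    g = guinier_rg(profile)
    mask = profile.q <= q_max
    q, I = profile.q[mask], profile.intensity[mask]
    # analytic Guinier fill-in from 0 to the first measured q
    q_fill = np.linspace(0, q[0], 20, endpoint=False)
    I_fill = g.I0 * np.exp(-(q_fill * g.Rg) ** 2 / 3.0)
    qq = np.concatenate([q_fill, q])
    II = np.concatenate([I_fill, I])
    Q = float(np.trapezoid(qq ** 2 * II, qq))
    # Porod tail: beyond q_max assume I ≈ K/q⁴, contributing K/q_max
    tail = q >= 0.8 * q_max
    K = float(np.mean(q[tail] ** 4 * I[tail]))
    Q += K / q_max
    vp = 2.0 * np.pi ** 2 * g.I0 / Q
    return vp * mass_density


# ---------------------------------------------------------------------------
# Merging and fitting

def _scale_to(reference: SAXSProfile, other: SAXSProfile,
              q_lo: float, q_hi: float) -> float:
    """Least-squares factor putting ``other`` on the reference scale."""
    mask = (reference.q >= q_lo) & (reference.q <= q_hi)
    if not mask.any():
        raise ValueError("no overlap between profiles for scaling")
    qs = reference.q[mask]
    ir = reference.intensity[mask]
    io = other.interpolated_to(qs)
    return float((ir * io).sum() / (io * io).sum())


def merge_profiles(low: list[SAXSProfile], high: list[SAXSProfile],
                   q_low_max: float = 0.15, q_high_min: float = 0.12) -> SAXSProfile:
    """Merge a concentration series into one composite profile.

    Low-concentration profiles contribute the small-angle region
    (q < ``q_low_max``, where inter-particle effects at high
    concentration would distort the data) and high-concentration
    profiles the wide-angle region (q > ``q_high_min``, where their
    better counting statistics matter).  All members are least-squares
    scaled to the first low profile inside the overlap, averaged
    pointwise per region, and averaged across both groups inside the
    overlap; uncertainties are the standard error of the member mean
    (member σ when only one member contributes).
    """
    if q_high_min >= q_low_max:
        raise ValueError("no overlap: require q_high_min < q_low_max")
    if not low or not high:
        raise ValueError("both concentration groups must be non-empty")
    ref = low[0]
    q_out = ref.q[ref.q < q_low_max]
    q_tail = high[0].q[high[0].q >= q_low_max]
    q_out = np.concatenate([q_out, q_tail])

    def _group_mean(group, qs):
        stack = []
        for p in group:
            c = _scale_to(ref, p, q_high_min, q_low_max)
            stack.append(c * p.interpolated_to(qs))
        arr = np.vstack(stack)
        mean = arr.mean(axis=0)
        if len(group) > 1:
            sem = arr.std(axis=0, ddof=1) / np.sqrt(len(group))
        else:
            p = group[0]
            sem = (np.interp(qs, p.q, np.where(np.isfinite(p.sigma), p.sigma, 0.0))
                   * _scale_to(ref, p, q_high_min, q_low_max))
        return mean, sem

    I_out = np.empty_like(q_out)
    S_out = np.empty_like(q_out)
    for i, qi in enumerate(q_out):
        use_low = qi < q_low_max
        use_high = qi > q_high_min
        vals, sems = [], []
        if use_low:
            m, s = _group_mean(low, np.array([qi]))
            vals.append(m[0]); sems.append(s[0])
        if use_high:
            m, s = _group_mean(high, np.array([qi]))
            vals.append(m[0]); sems.append(s[0])
        I_out[i] = np.mean(vals)
        S_out[i] = np.sqrt(np.mean(np.square(sems))) / np.sqrt(len(vals))
    return SAXSProfile(q_out, I_out, S_out, label="merged")


def fit_profile(exp: SAXSProfile, model_profile: SAXSProfile) -> tuple[float, float]:
    """χ² and optimal scale of a model profile against data.

    The scale c minimising Σ[(I_exp − c·I_mod)/σ]² has the closed form
    c = Σ(I_e I_m/σ²) / Σ(I_m²/σ²); χ² is the minimum divided by N.
    """
    sig = exp.sigma
    if not np.all(np.isfinite(sig)) or np.any(sig <= 0):
        raise ValueError("experimental profile needs positive uncertainties")
    im = model_profile.interpolated_to(exp.q)
    c = float((exp.intensity * im / sig ** 2).sum() / (im ** 2 / sig ** 2).sum())
    chi2 = float(np.mean(((exp.intensity - c * im) / sig) ** 2))
    return chi2, c


# ---------------------------------------------------------------------------
# Multi-state fitting

@dataclass
class MultiStateFit:
    """One fitted combination: states, weights (Σ=1), overall scale, χ²."""

    states: tuple[str, ...]
    weights: np.ndarray
    scale: float
    chi2: float

    @property
    def n_states(self) -> int:
        return len(self.states)

    def weight_of(self, state: str) -> float:
        for s, w in zip(self.states, self.weights):
            if s == state:
                return float(w)
        return 0.0


class MultiStateModel:
    """Ensemble multi-state fit of a SAXS profile (statsmodels-style).

    Parameters
    ----------
    exp : SAXSProfile
        The experimental (or synthetic) profile, with uncertainties.
    ensemble : dict[str, SAXSProfile]
        Candidate single-state model profiles keyed by model id.
    """

    def __init__(self, exp: SAXSProfile, ensemble: dict[str, SAXSProfile]):
        if not ensemble:
            raise ValueError("empty ensemble")
        self.exp = exp
        self.ensemble = dict(ensemble)
        sig = exp.sigma
        if not np.all(np.isfinite(sig)) or np.any(sig <= 0):
            raise ValueError("experimental profile needs positive uncertainties")
        self._b = exp.intensity / sig
        self._columns = {k: p.interpolated_to(exp.q) / sig
                         for k, p in self.ensemble.items()}

    def _solve(self, states: tuple[str, ...]) -> tuple[np.ndarray, float]:
        A = np.column_stack([self._columns[s] for s in states])
        coef, _ = nnls(A, self._b)
        resid = self._b - A @ coef
        chi2 = float(np.mean(resid ** 2))
        return coef, chi2

    def fit(self, max_states: int = 4, beam_width: int = 10_000,
            min_weight: float = 0.01,
            improvement_threshold: float = 1e-3) -> "MultiStateResults":
        """Beam-search enumeration of state combinations.

        All 1-state fits are enumerated; the ``beam_width`` best k-state
        combinations are each expanded by every ensemble member to form
        the (k+1)-state candidates.  Weights are solved by non-negative
        least squares and renormalised; states below ``min_weight`` are
        dropped.  The selected number of states is the smallest k whose
        successor improves relative χ by less than
        ``improvement_threshold`` (0.1%).
        """
        ids = sorted(self.ensemble)
        per_n: dict[int, MultiStateFit] = {}
        # 1-state enumeration
        scored = []
        for mid in ids:
            coef, chi2 = self._solve((mid,))
            scored.append((chi2, (mid,), coef))
        scored.sort(key=lambda t: t[0])
        per_n[1] = self._finalize(scored[0], min_weight)
        beam = scored[:beam_width]
        for k in range(2, max_states + 1):
            seen: set[frozenset] = set()
            candidates = []
            for chi2, states, _ in beam:
                for mid in ids:
                    if mid in states:
                        continue
                    key = frozenset(states) | {mid}
                    if key in seen:
                        continue
                    seen.add(key)
                    combo = tuple(sorted(states + (mid,)))
                    coef, c2 = self._solve(combo)
                    candidates.append((c2, combo, coef))
            if not candidates:
                break
            candidates.sort(key=lambda t: t[0])
            per_n[k] = self._finalize(candidates[0], min_weight)
            beam = candidates[:beam_width]
        return MultiStateResults(self, per_n, improvement_threshold)

    @staticmethod
    def _finalize(entry, min_weight: float) -> MultiStateFit:
        chi2, states, coef = entry
        total = coef.sum()
        if total <= 0:
            return MultiStateFit(states, np.zeros(len(states)), 0.0, chi2)
        weights = coef / total
        keep = weights >= min_weight
        if keep.sum() and not keep.all():
            states = tuple(s for s, k in zip(states, keep) if k)
            coef = coef[keep]
            total = coef.sum()
            weights = coef / total
        return MultiStateFit(tuple(states), weights, float(total), chi2)


class MultiStateResults:
    """Fits per state count plus the selected parsimonious combination."""

    def __init__(self, model: MultiStateModel, per_n: dict[int, MultiStateFit],
                 improvement_threshold: float):
        self.model = model
        self.per_n = per_n
        ns = sorted(per_n)
        selected = ns[-1]
        for k in ns[:-1]:
            chi_k = np.sqrt(per_n[k].chi2)
            chi_next = np.sqrt(per_n[k + 1].chi2)
            if chi_k <= 0 or (chi_k - chi_next) / chi_k < improvement_threshold:
                selected = k
                break
        self.selected_n = selected

    @property
    def best(self) -> MultiStateFit:
        return self.per_n[self.selected_n]

    def summary(self) -> str:
        lines = ["Multi-state SAXS fit",
                 "=" * 42,
                 f"{'n':>3} {'chi2':>10}  states (weights)"]
        for n in sorted(self.per_n):
            f = self.per_n[n]
            mark = "*" if n == self.selected_n else " "
            states = ", ".join(f"{s}:{w:.3f}" for s, w in zip(f.states, f.weights))
            lines.append(f"{mark}{n:>2} {f.chi2:>10.4f}  {states}")
        lines.append(f"selected n_states = {self.selected_n}")
        return "\n".join(lines)


def multistate_fit(exp: SAXSProfile, ensemble: dict[str, SAXSProfile],
                   max_states: int = 4, beam_width: int = 10_000,
                   min_weight: float = 0.01) -> MultiStateResults:
    """Functional wrapper around :class:`MultiStateModel`."""
    return MultiStateModel(exp, ensemble).fit(max_states=max_states,
                                              beam_width=beam_width,
                                              min_weight=min_weight)


# ---------------------------------------------------------------------------
# Mass-action equilibrium

def tetramer_fraction(Kd: float, total_dimer_conc: float) -> float:
    """Mass fraction of material in tetramers for the 2 D ↔ T equilibrium.

    ``Kd = [D]²/[T]`` (µM) and conservation ``[D] + 2[T] = C`` give the
    closed form [D] = Kd(−1 + √(1 + 8C/Kd))/4; the returned fraction is
    1 − [D]/C.  At C = Kd exactly half the material is tetrameric.
    """
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    C = float(total_dimer_conc)
    if C < 0:
        raise ValueError("concentration must be non-negative")
    if C == 0:
        return 0.0
    D = Kd * (-1.0 + np.sqrt(1.0 + 8.0 * C / Kd)) / 4.0
    return float(1.0 - D / C)
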