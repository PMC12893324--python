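"""Structure handling and spatial analysis of allosteric effects.

Distances are measured between heavy atoms (hydrogens are discarded on
parsing).  The central quantity is the per-residue minimum heavy-atom
distance to a set of active-site reference selections (a bound ligand and/or
catalytic residues); allosteric effect sizes are then modelled as an
exponential decay a*exp(k*d) of the per-site mean |ddGa| with distance d,
summarised by the half-decay distance d_half = ln(2)/|k|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "DecayFit",
    "parse_pdb",
    "read_pdb",
    "min_distance_to_active_site",
    "fit_exponential_decay",
    "half_decay",
    "directional_decay",
    "matched_subsample_decay_test",
    "site_clustering_test",
    "distance_corrected_effects",
]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: Tuple[float, float, float]


@dataclass
class Residue:
    res_seq: int
    name: str
    atoms: List[Atom]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def ca(self) -> Optional[np.ndarray]:
        for a in self.atoms:
            if a.name == "CA":
                return np.asarray(a.xyz, dtype=float)
        return None


@dataclass
class StructureModel:
    """Heavy-atom protein structure plus named ligand groups.

    Coordinates are in Angstrom, in the frame of the source file (the frame
    matters: directional decay is quantified along these axes).
    """

    residues: List[Residue]
    ligands: Dict[str, np.ndarray] = field(default_factory=dict)

    def residue(self, res_seq: int) -> Residue:
        for r in self.residues:
            if r.res_seq == res_seq:
                return r
        raise KeyError(f"residue {res_seq} not in structure")

    @property
    def res_seqs(self) -> List[int]:
        return [r.res_seq for r in self.residues]

    def ca_coords(self) -> Dict[int, np.ndarray]:
        out = {}
        for r in self.residues:
            ca = r.ca
            if ca is not None:
                out[r.res_seq] = ca
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed copy (used for invariance checks)."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_res = [
            Residue(
                r.res_seq,
                r.name,
                [Atom(a.name, a.element, tuple(rot @ np.asarray(a.xyz) + t)) for a in r.atoms],
            )
            for r in self.residues
        ]
        new_lig = {k: v @ rot.T + t for k, v in self.ligands.items()}
        return StructureModel(new_res, new_lig)


class PDBParseError(ValueError):
    pass


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _validate_atom_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(f"line {i}: ATOM/HETATM record too short")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"line {i}: malformed coordinate fields") from exc


def parse_pdb(text: str) -> StructureModel:
    """Parse PDB text into a heavy-atom StructureModel.

    Only altloc ' ' or 'A' atoms are retained and hydrogens are dropped.
    HETATM groups (except waters) are exposed as named ligands keyed by
    residue name.  Malformed fixed-column records raise PDBParseError with
    the offending line number.
    """
    import gemmi

    _validate_atom_lines(text)
    st = gemmi.read_pdb_string(text)
    st.setup_entities()
    residues: List[Residue] = []
    ligands: Dict[str, List[List[float]]] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = []
            for atom in res:
                if atom.altloc not in ("\x00", "", "A", " "):
                    continue
                if atom.element.name in ("H", "D"):
                    continue
                atoms.append(Atom(atom.name, atom.element.name, (atom.pos.x, atom.pos.y, atom.pos.z)))
            if not atoms:
                continue
            is_het = res.het_flag == "H"
            if is_het:
                if res.name in _WATER_NAMES:
                    continue
                ligands.setdefault(res.name, []).extend([list(a.xyz) for a in atoms])
            else:
                residues.append(Residue(res.seqid.num, res.name, atoms))
    return StructureModel(residues, {k: np.array(v, float) for k, v in ligands.items()})


def read_pdb(path) -> StructureModel:
    with open(path) as fh:
        return parse_pdb(fh.read())


def _reference_coords(s: StructureModel, refs: Sequence) -> Tuple[np.ndarray, set]:
    """Stack heavy-atom coordinates of the reference selections.

    Each ref is ("ligand", name), ("residue", res_seq) or a bare int
    (residue number).  Returns (coords, set of reference residue numbers).
    """
    blocks = []
    ref_residues = set()
    for ref in refs:
        if isinstance(ref, int):
            ref = ("residue", ref)
        kind, key = ref
        if kind == "ligand":
            if key not in s.ligands:
                raise KeyError(f"ligand group {key!r} not found in structure")
            blocks.append(s.ligands[key])
        elif kind == "residue":
            try:
                blocks.append(s.residue(int(key)).coords)
            except KeyError:
                raise KeyError(f"reference residue {key} not found in structure")
            ref_residues.add(int(key))
        else:
            raise ValueError(f"unknown reference kind {kind!r}")
    if not blocks:
        raise ValueError("empty reference selection")
    return np.vstack(blocks), ref_residues


def min_distance_to_active_site(s: StructureModel, refs: Sequence) -> Dict[int, float]:
    """Per-residue minimum heavy-atom distance (A) to the reference set.

    Residues that are themselves part of the reference selections are
    assigned distance 0 (they anchor the decay at d = 0).
    """
    ref_xyz, ref_residues = _reference_coords(s, refs)
    out: Dict[int, float] = {}
    for r in s.residues:
        if r.res_seq in ref_residues:
            out[r.res_seq] = 0.0
        else:
            out[r.res_seq] = float(cdist(r.coords, ref_xyz).min())
    return out


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential y = a * exp(k * d).

    ``amplitude`` is the effect size at distance 0, ``rate`` the signed
    decay constant in 1/A, ``d_half`` = ln(2)/|k| the distance halving the
    effect (inf when k = 0).
    """

    amplitude: float
    rate: float
    ci95_k: float
    d_half: float
    n_points: int


class DecayFitError(RuntimeError):
    def __init__(self, message: str, init: Optional[Tuple[float, float]] = None):
        super().__init__(message)
        self.init = init


def half_decay(k: float) -> float:
    """Half-decay distance ln(2)/|k| in Angstrom."""
    if k == 0:
        raise ValueError("half-decay undefined for k = 0")
    return math.log(2.0) / abs(k)


def _loglinear_init(d: np.ndarray, y: np.ndarray, eps: float = 1e-6) -> Tuple[float, float]:
    z = np.log(y + eps)
    b, loga = np.polyfit(d, z, 1)
    return float(np.exp(loga)), float(b)


def fit_exponential_decay(d, y, eps: float = 1e-6) -> DecayFit:
    """Nonlinear least-squares fit of y = a*exp(b*d).

    Initialised from a log-linear regression of ln(y + eps) on d, then
    refined by Levenberg-Marquardt.  The 95% CI on the rate comes from the
    asymptotic covariance of the NLS estimate.
    """
    d = np.asarray(d, float)
    y = np.asarray(y, float)
    if d.size < 3:
        raise ValueError("need at least 3 points for a decay fit")
    if np.any(y < 0):
        raise ValueError("effect magnitudes must be non-negative")
    a0, b0 = _loglinear_init(d, y, eps)
    try:
        popt, pcov = curve_fit(
            lambda x, a, b: a * np.exp(b * x), d, y, p0=(a0, b0), maxfev=10000
        )
    except RuntimeError as exc:
        raise DecayFitError(f"decay fit did not converge: {exc}", init=(a0, b0))
    a, k = float(popt[0]), float(popt[1])
    var_k = float(pcov[1, 1]) if np.all(np.isfinite(pcov)) else np.nan
    ci95 = 1.959963984540054 * math.sqrt(var_k) if var_k >= 0 else np.nan
    d_half = half_decay(k) if k != 0 else float("inf")
    return DecayFit(amplitude=a, rate=k, ci95_k=ci95, d_half=d_half, n_points=int(d.size))


def directional_decay(
    s: StructureModel,
    site_effects: Mapping[int, float],
    refs: Sequence,
    axis: str,
    sign: Optional[str],
    slab: float = 10.0,
) -> DecayFit:
    """Decay of per-site mean |ddGa| along one coordinate axis.

    The origin is the heavy-atom centroid of the reference selections.
    Residues are kept if their displacement along each of the two
    non-queried axes is <= ``slab`` in absolute value and their signed
    displacement along ``axis`` matches ``sign`` ('+' or '-'; None keeps
    both).  The fit is against |axial displacement|.
    """
    axes = {"x": 0, "y": 1, "z": 2}
    if axis not in axes:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}")
    ref_xyz, _ = _reference_coords(s, refs)
    origin = ref_xyz.mean(axis=0)
    ai = axes[axis]
    others = [v for k, v in axes.items() if k != axis]
    ds, ys = [], []
    for r in s.residues:
        if r.res_seq not in site_effects:
            continue
        disp = r.coords.mean(axis=0) - origin
        if abs(disp[others[0]]) > slab or abs(disp[others[1]]) > slab:
            continue
        if sign == "+" and disp[ai] < 0:
            continue
        if sign == "-" and disp[ai] > 0:
            continue
        ds.append(abs(disp[ai]))
        ys.append(site_effects[r.res_seq])
    if len(ds) < 3:
        raise ValueError(
            f"only {len(ds)} residues selected for axis {axis}{sign or ''}; need >= 3"
        )
    return fit_exponential_decay(np.array(ds), np.array(ys))


def _loglinear_slopes(d: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Row-wise OLS slope of z on d (both 2-D, one row per subsample)."""
    dm = d - d.mean(axis=1, keepdims=True)
    zm = z - z.mean(axis=1, keepdims=True)
    return (dm * zm).sum(axis=1) / (dm * dm).sum(axis=1)


def matched_subsample_decay_test(
    inactivating: Tuple[np.ndarray, np.ndarray],
    activating: Tuple[np.ndarray, np.ndarray],
    n_subsamples: int = 10000,
    seed: int = 0,
    n_bins: int = 10,
    eps: float = 1e-6,
) -> Tuple[float, float]:
    """Effect-size-matched comparison of decay rates.

    Subsamples the inactivating set (ddGa > 0), with replacement, to match
    the size and |ddGa| distribution of the activating set (decile bins of
    the activating magnitudes), fits a decay rate per subsample, and
    returns (p, median subsample k) where p is the fraction of subsamples
    whose decay is no stronger than the activating set's (rate >= the
    activating rate): a small p means effect-matched inactivating
    mutations decay more steeply with distance than activating ones.
    Rates use the closed-form log-linear estimator (slope of
    ln(|effect| + eps) on distance).
    """
    d_in, y_in = (np.asarray(v, float) for v in inactivating)
    d_ac, y_ac = (np.asarray(v, float) for v in activating)
    if d_in.size == 0 or d_ac.size == 0:
        raise ValueError("both mutation sets must be non-empty")
    mag_in = np.abs(y_in)
    mag_ac = np.abs(y_ac)
    # decile bins of the activating magnitudes
    qs = np.quantile(mag_ac, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    ac_bin = np.clip(np.searchsorted(qs, mag_ac, side="right") - 1, 0, n_bins - 1)
    in_bin = np.clip(np.searchsorted(qs, mag_in, side="right") - 1, 0, n_bins - 1)
    bin_counts = np.bincount(ac_bin, minlength=n_bins)
    pool = [np.flatnonzero(in_bin == b) for b in range(n_bins)]
    empty = [b for b in range(n_bins) if bin_counts[b] > 0 and pool[b].size == 0]
    if empty:
        raise ValueError(f"no inactivating mutations available in magnitude bins {empty}")

    k_act = _loglinear_slopes(d_ac[None, :], np.log(mag_ac + eps)[None, :])[0]

    rng = np.random.default_rng(seed)
    n = int(mag_ac.size)
    ks = np.empty(n_subsamples)
    z_in = np.log(mag_in + eps)
    chunk = max(1, min(n_subsamples, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_subsamples:
        m = min(chunk, n_subsamples - done)
        idx = np.empty((m, n), dtype=np.intp)
        col = 0
        for b in range(n_bins):
            c = int(bin_counts[b])
            if c == 0:
                continue
            idx[:, col : col + c] = rng.choice(pool[b], size=(m, c), replace=True)
            col += c
        ks[done : done + m] = _loglinear_slopes(d_in[idx], z_in[idx])
        done += m
    p = float(np.mean(ks >= k_act))
    return p, float(np.median(ks))


def site_clustering_test(
    sites: Iterable[int],
    s: StructureModel,
    n_random: int = 1000,
    mode: str = "pairwise",
    seed: int = 0,
) -> float:
    """Spatial clustering / connectivity test for a residue set.

    Observed statistic: median of Ca-Ca pairwise distances between sites
    (mode="pairwise") or median of each site's minimum distance to any
    other site (mode="connectivity").  The null resamples equal-sized
    residue subsets; p = fraction of null medians <= the observed median.
    """
    sites = sorted(set(int(x) for x in sites))
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    ca = s.ca_coords()
    missing = [x for x in sites if x not in ca]
    if missing:
        raise KeyError(f"sites missing from structure (or lacking CA): {missing}")
    res_seqs = sorted(ca)
    coords = np.array([ca[r] for r in res_seqs])
    dm = squareform(pdist(coords))
    index = {r: i for i, r in enumerate(res_seqs)}
    site_idx = np.array([index[x] for x in sites])

    def stat(idx: np.ndarray) -> float:
        sub = dm[np.ix_(idx, idx)]
        if mode == "pairwise":
            iu = np.triu_indices(len(idx), k=1)
            return float(np.median(sub[iu]))
        elif mode == "connectivity":
            np.fill_diagonal(sub, np.inf)
            return float(np.median(sub.min(axis=1)))
        raise ValueError(f"unknown mode {mode!r}")

    obs = stat(site_idx)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_random):
        idx = rng.choice(len(res_seqs), size=len(sites), replace=False)
        if stat(idx) <= obs:
            n_le += 1
    return n_le / n_random


def distance_corrected_effects(d, y, span: float = 0.75) -> np.ndarray:
    """Residuals of a loess smooth of y on d.

    Used to compare effect sizes across residue groups (e.g. secondary
    structure classes) after removing the global distance trend.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    d = np.asarray(d, float)
    y = np.asarray(y, float)
    if d.size < 10:
        raise ValueError("need at least 10 points")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(y, d, frac=span, return_sorted=False)
    return y - fitted
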