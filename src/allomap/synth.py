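"""Synthetic-study generator with known ground truth.

Emulates the statistical structure of a paired activity/abundance deep
mutational scan of an enzyme domain: a tiled mutagenesis library (all
single substitutions per tile, each in ~10 genetic backgrounds), two
phenotypes generated from the three-state folding-and-activation model
through per-assay-and-block affine transformations with Gaussian noise, a
toy 3-D structure with a designated active site, state-specific contact
lists and overlapping surface-pocket sets.

Planted ddGa effects follow an exponential distance law: inhibitory
(positive) effects at "allosteric" and active-site positions have
per-position mean magnitude a*exp(k*d) against the paired structure, while
activating (negative) effects at designated sites are distance independent
— the asymmetry the downstream decay analysis is designed to detect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .spatial import Atom, Residue, StructureModel, min_distance_to_active_site
from .thermo import (
    AA_ALPHABET,
    DEFAULT_CONSTANTS,
    EnergyModel,
    FitnessObservation,
    Genotype,
    MutationID,
    ThermoConstants,
    fraction_folded,
    fraction_folded_active,
)

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


class InvalidConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All generator settings; the defaults define the emulated study.

    The default domain covers 269 positions split into 5 tiles with 10
    genetic backgrounds per tile, matching the design of a tiled kinase
    domain scan; effect-size distributions are spike-and-slab per position
    class (see docs/methods.md).
    """

    n_positions: int = 269
    n_tiles: int = 5
    backgrounds_per_tile: int = 10
    # position-class fractions (among non-active-site positions)
    frac_core: float = 0.25
    frac_allosteric: float = 0.25
    frac_activating: float = 0.08
    n_active_site: int = 3
    # effect-size distributions (kcal/mol)
    neutral_sd: float = 0.1
    core_ddgf_shape: float = 2.0
    core_ddgf_scale: float = 0.6
    ddg_cap: float = 2.5
    decay_amplitude: float = 1.5  # |ddGa| at the active site
    decay_rate: float = -0.07  # 1/A, planted exponential distance law
    allosteric_lognorm_sd: float = 0.25
    activating_sd: float = 0.75
    # wild-type energies and per-experiment output layers
    wt_dGf: float = -1.0
    wt_dGa: float = 0.0
    noise_frac: float = 0.1  # noise sd as a fraction of the fitness range
    noiseless: bool = False
    plant_dead_background: bool = False

    def validate(self) -> None:
        if self.n_positions < 2 * self.n_tiles:
            raise InvalidConfigError(
                f"n_positions={self.n_positions} < 2 x n_tiles={self.n_tiles}"
            )
        for name in ("frac_core", "frac_allosteric", "frac_activating"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.noise_frac < 0:
            raise InvalidConfigError("noise_frac must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """True energies and observation-layer parameters behind a study."""

    wt_sequence: str
    tile_bounds: List[Tuple[int, int]]
    ddGf: Dict[MutationID, float]
    ddGa: Dict[MutationID, float]
    wt_dGf: float
    wt_dGa: float
    affine: Dict[Tuple[str, int], Tuple[float, float]]
    noise_sd: Dict[Tuple[str, int], float]
    seed: int
    # generator metadata (not required by consumers, useful for testing)
    position_class: Dict[int, str] = field(default_factory=dict)
    distance: Dict[int, float] = field(default_factory=dict)
    active_site: List[int] = field(default_factory=list)

    def tile_of(self, position: int) -> int:
        hits = [
            t for t, (lo, hi) in enumerate(self.tile_bounds, start=1) if lo <= position <= hi
        ]
        if len(hits) != 1:
            raise ValueError(f"position {position} in {len(hits)} tiles")
        return hits[0]

    def to_energy_model(self, n_states: int = 3) -> EnergyModel:
        return EnergyModel(
            ddGf=dict(self.ddGf),
            ddGa=dict(self.ddGa),
            wt_dGf=self.wt_dGf,
            wt_dGa=self.wt_dGa,
            affine=dict(self.affine),
            n_states=n_states,
        )


@dataclass
class SyntheticStudy:
    truth: GroundTruth
    observations: List[FitnessObservation]
    structure: StructureModel
    contacts_active: List[Tuple[str, str, str]]
    contacts_inactive: List[Tuple[str, str, str]]
    pockets: List["PocketSpec"]
    annotations: pd.DataFrame


@dataclass(frozen=True)
class PocketSpec:
    structure_id: str
    pocket_id: str
    residues: frozenset
    druggability: float


# ---------------------------------------------------------------------------
# structure


def generate_structure(
    n_residues: int,
    seed: int,
    sequence: Optional[str] = None,
    n_active_site: int = 3,
) -> Tuple[StructureModel, List[int]]:
    """Compact self-avoiding 3-D backbone with >= 4 heavy atoms per residue.

    Consecutive C-alpha atoms are 3.8 A apart; a pull toward the origin
    keeps the chain globular so residue-to-active-site distances span a
    usable range.  Returns the structure and a spatially clustered
    active-site residue selection (pairwise C-alpha distance < 12 A).
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    rng = np.random.default_rng(seed)
    step = 3.8
    clash = 3.4
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        prev = coords[i - 1]
        placed = False
        pull = 0.35
        for attempt in range(400):
            direction = rng.normal(size=3) - pull * prev / (np.linalg.norm(prev) + step)
            direction /= np.linalg.norm(direction)
            cand = prev + step * direction
            d = np.linalg.norm(coords[: max(i - 1, 0)] - cand, axis=1)
            if i < 2 or d.min() > clash:
                coords[i] = cand
                placed = True
                break
            if attempt % 50 == 49:
                pull *= 0.5  # relax compactness if stuck
        if not placed:
            raise RuntimeError("self-avoiding walk failed; try another seed")

    if sequence is None:
        sequence = "".join(rng.choice(list(AA_ALPHABET), size=n_residues))
    residues = []
    for i, ca in enumerate(coords):
        # local frame for pseudo side-chain/backbone atoms
        u = rng.normal(size=(4, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        atoms = [
            Atom("N", "N", tuple(ca + 1.46 * u[0])),
            Atom("CA", "C", tuple(ca)),
            Atom("C", "C", tuple(ca + 1.52 * u[1])),
            Atom("O", "O", tuple(ca + 1.52 * u[1] + 1.23 * u[2])),
            Atom("CB", "C", tuple(ca + 1.54 * u[3])),
        ]
        residues.append(Residue(i + 1, AA3[sequence[i]], atoms))
    structure = StructureModel(residues)

    centroid = coords.mean(axis=0)
    center_idx = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
    d_to_center = np.linalg.norm(coords - coords[center_idx], axis=1)
    order = np.argsort(d_to_center)
    active = [int(order[0]) + 1]
    for j in order[1:]:
        if len(active) == n_active_site:
            break
        if all(np.linalg.norm(coords[j] - coords[a - 1]) < 12.0 for a in active):
            active.append(int(j) + 1)
    return structure, sorted(active)


# ---------------------------------------------------------------------------
# ground truth


def _tile_bounds(n_positions: int, n_tiles: int) -> List[Tuple[int, int]]:
    edges = np.linspace(0, n_positions, n_tiles + 1).astype(int)
    return [(int(edges[i]) + 1, int(edges[i + 1])) for i in range(n_tiles)]


def generate_truth(
    config: GeneratorConfig,
    seed: int,
    structure: Optional[StructureModel] = None,
    active_site: Optional[Sequence[int]] = None,
) -> GroundTruth:
    """Draw ground-truth energies with planted spatial structure.

    Position classes: active-site and "allosteric" positions carry
    inhibitory ddGa with per-position mean magnitude a*exp(k*d) (d = min
    heavy-atom distance to the active site of the paired structure);
    "activating" positions carry negative ddGa of distance-independent
    magnitude; "core" positions carry Gamma-distributed destabilizing
    ddGf; everything else is neutral (ddGf ~ N(0, sd), ddGa = 0).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_positions
    if structure is None:
        structure, active_site = generate_structure(
            n, seed, n_active_site=config.n_active_site
        )
    if active_site is None:
        raise ValueError("active_site must accompany an explicit structure")
    active_site = sorted(active_site)
    seq3 = {r.res_seq: r.name for r in structure.residues}
    inv3 = {v: k for k, v in AA3.items()}
    wt_sequence = "".join(inv3[seq3[i + 1]] for i in range(n))

    distance = min_distance_to_active_site(
        structure, [("residue", r) for r in active_site]
    )

    # assign position classes
    positions = np.arange(1, n + 1)
    rest = np.array([p for p in positions if p not in active_site])
    rng.shuffle(rest)
    n_allo = int(round(config.frac_allosteric * rest.size))
    n_act = int(round(config.frac_activating * rest.size))
    allo = set(rest[:n_allo].tolist())
    acti = set(rest[n_allo : n_allo + n_act].tolist())
    remaining = rest[n_allo + n_act :]
    n_core = int(round(config.frac_core * rest.size))
    core = set(remaining[:n_core].tolist())
    klass = {}
    for p in positions:
        if p in active_site:
            klass[int(p)] = "active_site"
        elif p in allo:
            klass[int(p)] = "allosteric"
        elif p in acti:
            klass[int(p)] = "activating"
        elif p in core:
            klass[int(p)] = "core"
        else:
            klass[int(p)] = "neutral"

    ddGf: Dict[MutationID, float] = {}
    ddGa: Dict[MutationID, float] = {}
    for p in positions:
        p = int(p)
        wt = wt_sequence[p - 1]
        muts = [MutationID(p, wt, aa) for aa in AA_ALPHABET if aa != wt]
        k = klass[p]
        if k == "core":
            f = rng.gamma(config.core_ddgf_shape, config.core_ddgf_scale, size=19)
            f = np.minimum(f, config.ddg_cap)
        else:
            f = rng.normal(0.0, config.neutral_sd, size=19)
        if k in ("active_site", "allosteric"):
            target_mean = config.decay_amplitude * np.exp(
                config.decay_rate * distance[p]
            )
            mags = rng.lognormal(0.0, config.allosteric_lognorm_sd, size=19)
            mags *= target_mean / mags.mean()  # exact per-position mean
            a = np.minimum(mags, config.ddg_cap + 1.0)
        elif k == "activating":
            a = -np.abs(rng.normal(0.0, config.activating_sd, size=19))
        else:
            a = np.zeros(19)
        for m, fv, av in zip(muts, f, a):
            ddGf[m] = float(fv)
            ddGa[m] = float(av)

    affine: Dict[Tuple[str, int], Tuple[float, float]] = {}
    noise_sd: Dict[Tuple[str, int], float] = {}
    for assay in ("abundance", "activity"):
        for block in range(1, config.n_tiles + 1):
            intercept = float(rng.normal(0.0, 0.05))
            slope = float(rng.uniform(0.8, 1.2))
            affine[(assay, block)] = (intercept, slope)
            # the state probability spans (0, 1), so the fitness range is
            # the affine slope; sigma is a fixed fraction of that range
            noise_sd[(assay, block)] = max(config.noise_frac, 1e-4) * abs(slope)

    return GroundTruth(
        wt_sequence=wt_sequence,
        tile_bounds=_tile_bounds(n, config.n_tiles),
        ddGf=ddGf,
        ddGa=ddGa,
        wt_dGf=config.wt_dGf,
        wt_dGa=config.wt_dGa,
        affine=affine,
        noise_sd=noise_sd,
        seed=seed,
        position_class=klass,
        distance={int(k): float(v) for k, v in distance.items()},
        active_site=list(active_site),
    )


# ---------------------------------------------------------------------------
# library


class BackgroundError(ValueError):
    pass


def _pick_backgrounds(
    truth: GroundTruth, tile: int, n_backgrounds: int, dead: bool = False
) -> List[MutationID]:
    """Single-mutant backgrounds at fixed quantile spacing of true effects.

    Half the slots follow quantiles of the true ddGf distribution (spread
    toward the destabilizing side, which probes the folding transition),
    half follow ddGa (spread toward the activating/low side, which moves
    variants into the sensitive part of the activity curve).  Together the
    backgrounds span weak-to-strong effects on both energies, constraining
    the nonlinear fit.
    """
    lo, hi = truth.tile_bounds[tile - 1]
    muts = [m for m in truth.ddGf if lo <= m.position <= hi]
    muts.sort(key=str)
    n_mut = n_backgrounds - 1  # WT occupies one slot
    chosen: List[MutationID] = []
    n_f = (n_mut + 1) // 2
    n_a = n_mut - n_f
    q_f = np.linspace(0.1, 0.97, max(n_f, 1))
    q_a = np.geomspace(0.01, 0.6, max(n_a, 1))
    for energy, qs in ((truth.ddGf, q_f[:n_f]), (truth.ddGa, q_a[:n_a])):
        vals = np.array([energy[m] for m in muts])
        for q in qs:
            target = np.quantile(vals, q)
            order = np.argsort(np.abs(vals - target))
            for j in order:
                if muts[j] not in chosen:
                    chosen.append(muts[j])
                    break
    if dead and chosen:
        # replace the last slot with the most doubly-deleterious single:
        # a saturated background with an extremely narrow fitness range
        worst = max(muts, key=lambda m: truth.ddGf[m] + max(truth.ddGa[m], 0.0))
        if worst not in chosen:
            chosen[-1] = worst
    return chosen[:n_mut]


def generate_library(
    truth: GroundTruth,
    backgrounds_per_tile: int = 10,
    backgrounds: Optional[Mapping[int, Sequence[MutationID]]] = None,
    plant_dead_background: bool = False,
) -> List[Genotype]:
    """Tiled library: all singles per tile, in every genetic background.

    Within each tile the library holds, for each background (wild type
    plus ``backgrounds_per_tile - 1`` singles), every substitution at every
    tile position.  Substitutions at a background's own mutated position
    replace it (yielding other singles); all other substitutions yield
    background x single doubles.  Genotypes are deduplicated per tile.
    """
    genotypes: List[Genotype] = []
    for tile, (lo, hi) in enumerate(truth.tile_bounds, start=1):
        if backgrounds is not None:
            bg_muts = list(backgrounds.get(tile, []))
            for m in bg_muts:
                if not lo <= m.position <= hi:
                    raise BackgroundError(
                        f"background mutation {m} outside tile {tile} [{lo},{hi}]"
                    )
        else:
            bg_muts = _pick_backgrounds(
                truth,
                tile,
                backgrounds_per_tile,
                dead=plant_dead_background and tile == len(truth.tile_bounds),
            )
        seen = set()
        tile_genotypes: List[Genotype] = []

        def add(muts: frozenset, bg_id: str):
            if muts not in seen:
                seen.add(muts)
                tile_genotypes.append(
                    Genotype(mutations=muts, tile=tile, background_id=bg_id)
                )

        add(frozenset(), "WT")
        all_backgrounds = [("WT", None)] + [(str(m), m) for m in bg_muts]
        for bg_id, bg_mut in all_backgrounds:
            base = frozenset() if bg_mut is None else frozenset([bg_mut])
            if bg_mut is not None:
                add(base, bg_id)
            for pos in range(lo, hi + 1):
                wt = truth.wt_sequence[pos - 1]
                for aa in AA_ALPHABET:
                    if aa == wt:
                        continue
                    m = MutationID(pos, wt, aa)
                    if bg_mut is not None and pos == bg_mut.position:
                        new = frozenset([m])  # replaces the background mutation
                    else:
                        new = base | {m}
                    add(new, bg_id)
        genotypes.extend(tile_genotypes)
    return genotypes


# ---------------------------------------------------------------------------
# observations


def _predict_many(
    truth: GroundTruth,
    genotypes: Sequence[Genotype],
    const: ThermoConstants = DEFAULT_CONSTANTS,
) -> Dict[str, np.ndarray]:
    """Vectorised noiseless phenotypes for all genotypes x assays."""
    dGf = np.full(len(genotypes), truth.wt_dGf)
    dGa = np.full(len(genotypes), truth.wt_dGa)
    for i, g in enumerate(genotypes):
        for m in g.mutations:
            dGf[i] += truth.ddGf[m]
            dGa[i] += truth.ddGa[m]
    pf = fraction_folded(dGf, const)
    pfa = fraction_folded_active(dGf, dGa, const)
    out = {}
    blocks = np.array([g.tile for g in genotypes])
    for assay, p in (("abundance", pf), ("activity", pfa)):
        y = np.empty(len(genotypes))
        for b in np.unique(blocks):
            c, m = truth.affine[(assay, int(b))]
            sel = blocks == b
            y[sel] = c + m * p[sel]
        out[assay] = y
    return out


def generate_observations(
    truth: GroundTruth,
    genotypes: Sequence[Genotype],
    seed: int = 0,
    noiseless: bool = False,
    const: ThermoConstants = DEFAULT_CONSTANTS,
    construct: str = "kd_only",
    calibrate_noise_frac: Optional[float] = None,
) -> List[FitnessObservation]:
    """Fitness observations for both assays with per-experiment noise.

    The recorded sigma always equals the generating noise sd of the
    (assay, block) experiment, also in noiseless mode.  When
    ``calibrate_noise_frac`` is given, the noise sd of each experiment is
    (re)set to that fraction of the realised noiseless fitness range of
    the experiment (and written back into ``truth.noise_sd``).
    """
    rng = np.random.default_rng(seed)
    noiseless_y = _predict_many(truth, genotypes, const)
    if calibrate_noise_frac is not None:
        blocks = np.array([g.tile for g in genotypes])
        for assay in ("abundance", "activity"):
            for b in np.unique(blocks):
                yb = noiseless_y[assay][blocks == b]
                rng_y = float(yb.max() - yb.min())
                truth.noise_sd[(assay, int(b))] = max(
                    calibrate_noise_frac * rng_y, 1e-4
                )
    observations: List[FitnessObservation] = []
    for assay in ("abundance", "activity"):
        y0 = noiseless_y[assay]
        sds = np.array([truth.noise_sd[(assay, g.tile)] for g in genotypes])
        noise = np.zeros_like(y0) if noiseless else rng.normal(0.0, sds)
        for g, y, sd, e in zip(genotypes, y0, sds, noise):
            observations.append(
                FitnessObservation(
                    genotype=g,
                    assay=assay,
                    block=g.tile,
                    fitness=float(y + e),
                    sigma=float(sd),
                    construct=construct,
                )
            )
    return observations


# ---------------------------------------------------------------------------
# contacts, pockets, annotations


def _atom_id(res: Residue, atom: str = "CB") -> str:
    return f"A:{res.name}:{res.res_seq}:{atom}"


def generate_contacts(
    structure: StructureModel,
    seed: int,
    n_static: int = 30,
    n_active_only: int = 15,
    n_inactive_only: int = 15,
    n_swapping: int = 10,
    n_noise: int = 10,
) -> Tuple[List[Tuple[str, str, str]], List[Tuple[str, str, str]]]:
    """State-specific contact rows in the getcontacts atom dialect.

    Returns (active_rows, inactive_rows) of (itype, atom1, atom2); noise
    rows use excluded interaction types (water bridges, vdw) that the
    parser must drop.
    """
    rng = np.random.default_rng(seed)
    residues = structure.residues
    ca = np.array([r.ca for r in residues])
    from scipy.spatial.distance import squareform, pdist

    dm = squareform(pdist(ca))
    pairs = [
        (i, j)
        for i in range(len(residues))
        for j in range(i + 2, len(residues))
        if dm[i, j] < 9.0
    ]
    rng.shuffle(pairs)
    types = ["sb", "pc", "hbss", "hbsb"]
    active, inactive = [], []
    it = iter(pairs)

    def take() -> Tuple[Residue, Residue]:
        i, j = next(it)
        return residues[i], residues[j]

    try:
        for _ in range(n_static):
            a, b = take()
            t = str(rng.choice(types))
            row = (t, _atom_id(a), _atom_id(b))
            active.append(row)
            inactive.append(row)
        for _ in range(n_active_only):
            a, b = take()
            active.append((str(rng.choice(types)), _atom_id(a), _atom_id(b)))
        for _ in range(n_inactive_only):
            a, b = take()
            inactive.append((str(rng.choice(types)), _atom_id(a), _atom_id(b)))
        for _ in range(n_swapping):
            a, b = take()
            c, d = take()
            t = str(rng.choice(types))
            active.append((t, _atom_id(a), _atom_id(b)))
            inactive.append((t, _atom_id(a), _atom_id(c)))
        for _ in range(n_noise):
            a, b = take()
            t = str(rng.choice(["wb", "vdw", "hp"]))
            (active if rng.random() < 0.5 else inactive).append(
                (t, _atom_id(a), _atom_id(b))
            )
    except StopIteration:
        pass  # small structures yield fewer contacts
    return active, inactive


def generate_pockets(
    structure: StructureModel,
    seed: int,
    n_centers: int = 6,
    n_structures: int = 3,
    radius: float = 9.0,
) -> List[PocketSpec]:
    """Overlapping pocket sets replicated across pseudo-structures.

    Each pocket is the residue set within ``radius`` A (C-alpha) of a
    center residue; replicas across structures jitter membership by one or
    two residues so clustering by overlap has work to do.  Druggability is
    uniform on [2, 10], so some pockets fall below the usual >= 5 filter.
    """
    rng = np.random.default_rng(seed)
    ca = np.array([r.ca for r in structure.residues])
    res_seqs = np.array(structure.res_seqs)
    centers = rng.choice(len(res_seqs), size=min(n_centers, len(res_seqs)), replace=False)
    pockets: List[PocketSpec] = []
    for ci, c in enumerate(centers):
        d = np.linalg.norm(ca - ca[c], axis=1)
        members = set(res_seqs[d <= radius].tolist())
        drug = float(rng.uniform(2.0, 10.0))
        for s in range(n_structures):
            jittered = set(members)
            for r in rng.choice(sorted(members), size=min(2, len(members)), replace=False):
                if rng.random() < 0.5 and len(jittered) > 2:
                    jittered.discard(int(r))
            pockets.append(
                PocketSpec(
                    structure_id=f"struct{s + 1}",
                    pocket_id=f"p{ci + 1}",
                    residues=frozenset(int(x) for x in jittered),
                    druggability=drug + float(rng.normal(0, 0.2)),
                )
            )
    return pockets


_SSE_CYCLE = ["helix", "strand", "loop", "turn"]


def generate_annotations(
    structure: StructureModel,
    truth: Optional[GroundTruth] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-residue rSASA and secondary-structure annotations.

    Core positions (if a truth is supplied) get low rSASA; secondary
    structure is assigned in contiguous runs of 6-12 residues cycling
    helix/strand/loop/turn, each run a distinct element (H1, S1, ...).
    """
    rng = np.random.default_rng(seed)
    rows = []
    counters = {s: 0 for s in _SSE_CYCLE}
    i = 0
    seqs = structure.res_seqs
    run_idx = 0
    while i < len(seqs):
        sse = _SSE_CYCLE[run_idx % len(_SSE_CYCLE)]
        counters[sse] += 1
        element = f"{sse[0].upper()}{counters[sse]}"
        run_len = int(rng.integers(6, 13))
        for r in seqs[i : i + run_len]:
            if truth is not None and truth.position_class.get(r) == "core":
                rsasa = float(rng.beta(2, 10))
            else:
                rsasa = float(min(rng.beta(5, 3) * 1.2, 1.2))
            rows.append(
                {
                    "residue": r,
                    "rsasa": rsasa,
                    "sse_type": sse,
                    "sse_element": element,
                    "active_site": bool(truth and r in truth.active_site),
                }
            )
        i += run_len
        run_idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study


def generate_study(config: GeneratorConfig, seed: int) -> SyntheticStudy:
    """End-to-end synthetic study: truth, library, observations, structure,
    contacts, pockets and annotations, all deterministic in the seed."""
    config.validate()
    structure, active_site = generate_structure(
        config.n_positions, seed, n_active_site=config.n_active_site
    )
    truth = generate_truth(config, seed, structure=structure, active_site=active_site)
    genotypes = generate_library(
        truth,
        backgrounds_per_tile=config.backgrounds_per_tile,
        plant_dead_background=config.plant_dead_background,
    )
    observations = generate_observations(
        truth,
        genotypes,
        seed=seed + 1,
        noiseless=config.noiseless,
        calibrate_noise_frac=config.noise_frac,
    )
    contacts_active, contacts_inactive = generate_contacts(structure, seed + 2)
    pockets = generate_pockets(structure, seed + 3)
    annotations = generate_annotations(structure, truth, seed + 4)
    return SyntheticStudy(
        truth=truth,
        observations=observations,
        structure=structure,
        contacts_active=contacts_active,
        contacts_inactive=contacts_inactive,
        pockets=pockets,
        annotations=annotations,
    )
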