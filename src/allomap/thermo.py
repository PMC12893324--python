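"""Three-state folding-and-activation thermodynamics.

The enzyme is modelled with three states: unfolded-inactive (ui),
folded-inactive (fi) and folded-active (fa).  ``dGf`` is the free energy of
folding (ui -> fi) and ``dGa`` the free energy of activation of the folded
enzyme (fi -> fa), both in kcal/mol.  Boltzmann weights of the states give
the fraction of molecules that are folded (abundance phenotype) and the
fraction that are folded *and* active (activity phenotype).  Mutational
effects on the two energies are assumed additive across substitutions, so a
genotype's energies are the wild-type energies plus the sum of its
per-mutation ddG values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Tuple

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Gas constant in kcal/(mol K).
R_KCAL = 0.001987

#: Default temperature: 30 degC, the growth temperature of the yeast assays.
T_DEFAULT = 303.15


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature defining the energy scale RT."""

    R: float = R_KCAL
    T: float = T_DEFAULT

    @property
    def RT(self) -> float:
        return self.R * self.T

    def __post_init__(self) -> None:
        if not self.R * self.T > 0:
            raise ValueError("R*T must be positive")


DEFAULT_CONSTANTS = ThermoConstants()


@dataclass(frozen=True, order=True)
class MutationID:
    """A single amino-acid substitution, 1-based full-length numbering."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"wt and mutant residue identical: {self}")
        if self.wt_aa not in AA_ALPHABET or self.mut_aa not in AA_ALPHABET:
            raise ValueError(f"unknown amino acid in {self}")

    def __str__(self) -> str:  # e.g. "L|317|P"
        return f"{self.wt_aa}|{self.position}|{self.mut_aa}"

    @classmethod
    def from_string(cls, s: str) -> "MutationID":
        wt, pos, mut = s.split("|")
        return cls(position=int(pos), wt_aa=wt, mut_aa=mut)


@dataclass(frozen=True)
class Genotype:
    """A variant: a set of substitutions plus library bookkeeping."""

    mutations: FrozenSet[MutationID]
    tile: int = 1
    background_id: str = "WT"

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError("genotype carries >1 mutation at one position")

    @property
    def order(self) -> int:
        return len(self.mutations)

    def __str__(self) -> str:
        if not self.mutations:
            return "WT"
        return ";".join(str(m) for m in sorted(self.mutations))

    @classmethod
    def from_string(cls, s: str, tile: int = 1, background_id: str = "WT") -> "Genotype":
        muts: frozenset = frozenset(
            MutationID.from_string(tok) for tok in s.split(";") if tok and tok != "WT"
        )
        return cls(mutations=muts, tile=tile, background_id=background_id)


@dataclass(frozen=True)
class FitnessObservation:
    """One variant x assay x block fitness measurement with its error."""

    genotype: Genotype
    assay: str  # "activity" | "abundance"
    block: int
    fitness: float
    sigma: float
    construct: str = "kd_only"  # or "full_length"

    def __post_init__(self) -> None:
        if not np.isfinite(self.fitness):
            raise ValueError("non-finite fitness")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass
class EnergyModel:
    """Per-mutation energies plus per-experiment affine output layers.

    ``affine`` maps (assay, block) -> (intercept, slope) applied to the
    relevant state probability.  ``n_states`` selects the phenotype model:
    2 (activity also driven by folding alone), 3 (default) or 4 (two
    independent active conformations; per-mutation ddGa2 in ``ddGa2``).
    """

    ddGf: Dict[MutationID, float] = field(default_factory=dict)
    ddGa: Dict[MutationID, float] = field(default_factory=dict)
    wt_dGf: float = 0.0
    wt_dGa: float = 0.0
    affine: Dict[Tuple[str, int], Tuple[float, float]] = field(default_factory=dict)
    n_states: int = 3
    ddGa2: Dict[MutationID, float] = field(default_factory=dict)
    wt_dGa2: float = 0.0


def _stable_softmax_weight(log_w: np.ndarray) -> np.ndarray:
    """exp(log_w) / sum over last axis, guarded against overflow."""
    m = np.max(log_w, axis=-1, keepdims=True)
    e = np.exp(log_w - m)
    return e / np.sum(e, axis=-1, keepdims=True)


def fraction_folded(dGf, const: ThermoConstants = DEFAULT_CONSTANTS):
    """Two-state fraction folded, 1 / (1 + exp(dGf/RT)).

    Strictly decreasing in ``dGf``; 0.5 at dGf = 0.  Accepts scalars or
    arrays.  Overflow-safe for arbitrarily large |dGf|/RT.
    """
    x = np.asarray(dGf, dtype=float) / const.RT
    # scipy.special.expit(-x) == 1/(1+e^x), stable on both tails
    from scipy.special import expit

    out = expit(-x)
    return float(out) if np.isscalar(dGf) else out


def fraction_folded_active(dGf, dGa, const: ThermoConstants = DEFAULT_CONSTANTS):
    """Three-state fraction folded-and-active.

    p_fa = w_fa / (1 + w_fi + w_fa) with w_fi = exp(-dGf/RT) and
    w_fa = exp(-(dGf+dGa)/RT); equivalently
    1 / (1 + exp(dGa/RT) * (1 + exp(dGf/RT))).
    """
    f = np.asarray(dGf, dtype=float) / const.RT
    a = np.asarray(dGa, dtype=float) / const.RT
    f, a = np.broadcast_arrays(f, a)
    log_w = np.stack([np.zeros_like(f), -f, -(f + a)], axis=-1)
    p = _stable_softmax_weight(log_w)[..., 2]
    if np.isscalar(dGf) and np.isscalar(dGa):
        return float(p)
    return p


def state_fractions(dGf, dGa, const: ThermoConstants = DEFAULT_CONSTANTS):
    """Occupancies (p_ui, p_fi, p_fa); sums to 1 exactly."""
    f = np.asarray(dGf, dtype=float) / const.RT
    a = np.asarray(dGa, dtype=float) / const.RT
    f, a = np.broadcast_arrays(f, a)
    log_w = np.stack([np.zeros_like(f), -f, -(f + a)], axis=-1)
    p = _stable_softmax_weight(log_w)
    return p[..., 0], p[..., 1], p[..., 2]


def fraction_active_four_state(
    dGf, dGa1, dGa2, const: ThermoConstants = DEFAULT_CONSTANTS
):
    """Four-state activity: summed occupancy of two active conformations.

    States ui, fi, fa1, fa2 with energies 0, dGf, dGf+dGa1, dGf+dGa2
    relative to unfolded; the two active states carry independent
    per-mutation energies.
    """
    f = np.asarray(dGf, dtype=float) / const.RT
    a1 = np.asarray(dGa1, dtype=float) / const.RT
    a2 = np.asarray(dGa2, dtype=float) / const.RT
    f, a1, a2 = np.broadcast_arrays(f, a1, a2)
    log_w = np.stack([np.zeros_like(f), -f, -(f + a1), -(f + a2)], axis=-1)
    p = _stable_softmax_weight(log_w)
    out = p[..., 2] + p[..., 3]
    if all(np.isscalar(v) for v in (dGf, dGa1, dGa2)):
        return float(out)
    return out


class MissingParameterError(KeyError):
    """A genotype references a mutation absent from the energy model."""


def genotype_energies(g: Genotype, model: EnergyModel) -> Tuple[float, float]:
    """Additive genotype energies (dGf, dGa) = wild type + sum of ddG."""
    dGf = model.wt_dGf
    dGa = model.wt_dGa
    for m in g.mutations:
        if m not in model.ddGf or m not in model.ddGa:
            raise MissingParameterError(f"no energy parameters for mutation {m}")
        dGf += model.ddGf[m]
        dGa += model.ddGa[m]
    return dGf, dGa


def predict_fitness(
    g: Genotype,
    model: EnergyModel,
    assay: str,
    block: int,
    const: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Affine-transformed state probability for one assay x block.

    Abundance reads out the two-state fraction folded; activity reads out
    the model's active fraction (three-state by default, folding-driven for
    n_states=2, two-conformation sum for n_states=4).
    """
    if (assay, block) not in model.affine:
        raise KeyError(f"no affine parameters for assay={assay!r}, block={block}")
    intercept, slope = model.affine[(assay, block)]
    dGf, dGa = genotype_energies(g, model)
    if assay == "abundance" or model.n_states == 2:
        p = fraction_folded(dGf, const)
    elif model.n_states == 3:
        p = fraction_folded_active(dGf, dGa, const)
    elif model.n_states == 4:
        dGa2 = model.wt_dGa2 + sum(model.ddGa2.get(m, 0.0) for m in g.mutations)
        p = fraction_active_four_state(dGf, dGa, dGa2, const)
    else:
        raise ValueError(f"n_states must be 2, 3 or 4, got {model.n_states}")
    return intercept + slope * p
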