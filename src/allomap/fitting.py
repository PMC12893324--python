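"""Global fitting of energy models to paired activity/abundance fitness.

The fit minimises the error-weighted squared loss

    L(theta) = sum_i (y_i - yhat_i)^2 / sigma_i^2

jointly over all assays and blocks, sharing the per-mutation energies
across experiments while each (assay, block) experiment gets its own
affine output layer.  yhat is the affine-transformed state probability of
the two-, three- or four-state Boltzmann model with additive genotype
energies.  Optimisation is deterministic full-batch trust-region least
squares with an analytic sparse Jacobian; no regularisation is applied.

Cross-validation follows the study design: folds partition the *double*
mutants, wild-type and single-mutant variants always stay in training
(singles are the parameters of interest and appear in many doubles).
Parameter uncertainty is the spread of refits across the cross-validation
training subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares
from scipy.special import expit

from .thermo import (
    DEFAULT_CONSTANTS,
    EnergyModel,
    FitnessObservation,
    MutationID,
    ThermoConstants,
)

__all__ = [
    "FitResult",
    "CVResult",
    "UnderIdentifiedError",
    "fit",
    "crossvalidate",
    "explainable_variance",
    "estimate_uncertainty",
]


class UnderIdentifiedError(ValueError):
    pass


@dataclass
class _Encoded:
    X: sp.csr_matrix  # n_obs x n_mutations genotype indicator
    y: np.ndarray
    w: np.ndarray  # 1/sigma^2
    group: np.ndarray  # (assay, block) index per row
    is_activity: np.ndarray  # bool per row
    mutations: List[MutationID]
    groups: List[Tuple[str, int]]
    genotype_key: List[frozenset]
    order: np.ndarray  # mutation count per row


def _encode(observations: Sequence[FitnessObservation]) -> _Encoded:
    # canonical row order makes the fit invariant to input permutation
    obs = sorted(
        observations, key=lambda o: (o.assay, o.block, str(o.genotype), o.construct)
    )
    mutations = sorted({m for o in obs for m in o.genotype.mutations}, key=str)
    m_index = {m: j for j, m in enumerate(mutations)}
    groups = sorted({(o.assay, o.block) for o in obs})
    g_index = {g: j for j, g in enumerate(groups)}
    rows, cols = [], []
    for i, o in enumerate(obs):
        for m in o.genotype.mutations:
            rows.append(i)
            cols.append(m_index[m])
    X = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(obs), len(mutations))
    )
    y = np.array([o.fitness for o in obs])
    w = np.array([1.0 / o.sigma**2 for o in obs])
    group = np.array([g_index[(o.assay, o.block)] for o in obs])
    is_activity = np.array([o.assay == "activity" for o in obs])
    genotype_key = [frozenset(o.genotype.mutations) for o in obs]
    order = np.array([len(k) for k in genotype_key])
    return _Encoded(X, y, w, group, is_activity, mutations, groups, genotype_key, order)


def _unpack(theta: np.ndarray, M: int, G: int, n_states: int):
    n_energy = {2: 1, 3: 2, 4: 3}[n_states]
    blocks = [theta[i * M : (i + 1) * M] for i in range(n_energy)]
    off = n_energy * M
    wts = theta[off : off + n_energy]
    off += n_energy
    c = theta[off : off + G]
    m = theta[off + G : off + 2 * G]
    return blocks, wts, c, m


def _probabilities(theta, enc: _Encoded, n_states: int, rt: float):
    """State probabilities per row plus their energy derivatives.

    Returns (p, dp/ddGf, list of dp/ddGa_k) in kcal/mol units, using
    overflow-guarded log-sum-exp weights throughout.
    """
    M, G = len(enc.mutations), len(enc.groups)
    blocks, wts, c, m = _unpack(theta, M, G, n_states)
    act = enc.is_activity
    s = (wts[0] + enc.X @ blocks[0]) / rt
    p = np.empty_like(s)
    dps = np.empty_like(s)
    dpt: List[np.ndarray] = []

    ab = ~act if n_states >= 3 else np.ones_like(act, dtype=bool)
    pf = expit(-s[ab])
    p[ab] = pf
    dps[ab] = -pf * (1.0 - pf) / rt

    if n_states >= 3:
        t1 = (wts[1] + enc.X @ blocks[1]) / rt
        if n_states == 3:
            lw = np.stack(
                [np.zeros_like(s[act]), -s[act], -(s[act] + t1[act])], axis=-1
            )
            e = np.exp(lw - lw.max(axis=-1, keepdims=True))
            Z = e.sum(axis=-1)
            pu, pfa = e[:, 0] / Z, e[:, 2] / Z
            p[act] = pfa
            dps[act] = -pfa * pu / rt
            d1 = np.zeros_like(s)
            d1[act] = -pfa * (1.0 - pfa) / rt
            dpt = [d1]
        else:
            t2 = (wts[2] + enc.X @ blocks[2]) / rt
            lw = np.stack(
                [
                    np.zeros_like(s[act]),
                    -s[act],
                    -(s[act] + t1[act]),
                    -(s[act] + t2[act]),
                ],
                axis=-1,
            )
            e = np.exp(lw - lw.max(axis=-1, keepdims=True))
            Z = e.sum(axis=-1)
            pu = e[:, 0] / Z
            p2, p3 = e[:, 2] / Z, e[:, 3] / Z
            pact = p2 + p3
            p[act] = pact
            dps[act] = -pact * pu / rt
            d1 = np.zeros_like(s)
            d2 = np.zeros_like(s)
            d1[act] = -p2 * (1.0 - pact) / rt
            d2[act] = -p3 * (1.0 - pact) / rt
            dpt = [d1, d2]
    return p, dps, dpt, c, m


def _residuals(theta, enc: _Encoded, n_states: int, rt: float) -> np.ndarray:
    p, _, _, c, m = _probabilities(theta, enc, n_states, rt)
    sw = np.sqrt(enc.w)
    return sw * (enc.y - (c[enc.group] + m[enc.group] * p))


def _jacobian(theta, enc: _Encoded, n_states: int, rt: float) -> sp.csr_matrix:
    G = len(enc.groups)
    n = len(enc.y)
    p, dps, dpt, c, m = _probabilities(theta, enc, n_states, rt)
    sw = np.sqrt(enc.w)
    mg = m[enc.group]
    cols = []
    a = -sw * mg * dps
    cols.append(enc.X.multiply(a[:, None]).tocsr())
    wt_cols = [a]
    for d in dpt:
        b = -sw * mg * d
        cols.append(enc.X.multiply(b[:, None]).tocsr())
        wt_cols.append(b)
    for v in wt_cols:
        cols.append(sp.csr_matrix(v.reshape(-1, 1)))
    rows = np.arange(n)
    cols.append(sp.csr_matrix((-sw, (rows, enc.group)), shape=(n, G)))
    cols.append(sp.csr_matrix((-sw * p, (rows, enc.group)), shape=(n, G)))
    return sp.hstack(cols).tocsr()


@dataclass
class FitResult:
    model: EnergyModel
    loss: float
    loss_trace: List[float]
    n_obs: int
    converged: bool
    mev: Dict[Tuple[str, int], float] = field(default_factory=dict)
    fev: Dict[Tuple[str, int], float] = field(default_factory=dict)
    ddGf_sd: Optional[Dict[MutationID, float]] = None
    ddGa_sd: Optional[Dict[MutationID, float]] = None
    cv_r2: Optional[List[float]] = None

    @property
    def cv_r2_median(self) -> Optional[float]:
        return float(np.median(self.cv_r2)) if self.cv_r2 else None


def _initial_theta(enc: _Encoded, n_states: int, rng: np.random.Generator, jitter: float):
    M, G = len(enc.mutations), len(enc.groups)
    n_energy = {2: 1, 3: 2, 4: 3}[n_states]
    theta = np.zeros(n_energy * M + n_energy + 2 * G)
    wt0 = {2: [-1.0], 3: [-1.0, 0.0], 4: [-1.0, 0.0, 0.5]}[n_states]
    theta[n_energy * M : n_energy * M + n_energy] = wt0
    c = np.empty(G)
    m = np.empty(G)
    for j in range(G):
        yg = enc.y[enc.group == j]
        lo, hi = np.quantile(yg, [0.02, 0.98])
        c[j] = lo
        m[j] = max(hi - lo, 1e-3)
    theta[-2 * G : -G] = c
    theta[-G:] = m
    if jitter > 0:
        theta = theta + rng.normal(0.0, jitter, size=theta.size)
    return theta


def fit(
    observations: Sequence[FitnessObservation],
    n_states: int = 3,
    const: ThermoConstants = DEFAULT_CONSTANTS,
    exclude_backgrounds: Sequence[str] = (),
    seed: int = 0,
    max_nfev: int = 300,
    n_restarts: int = 1,
    record_trace: bool = True,
    energy_bounds: Tuple[float, float] = (-4.0, 4.0),
) -> FitResult:
    """Fit the energy model by weighted least squares.

    Observations from backgrounds listed in ``exclude_backgrounds`` are
    dropped before fitting (used for degenerate, narrow-range backgrounds).
    Deterministic for a fixed seed; with ``n_restarts > 1`` the best of
    several jittered initialisations is kept.  The loss trace records
    accepted (cost-decreasing) optimizer steps.

    Energy parameters are box-bounded (default +-4 kcal/mol): far outside
    the dynamic range of any fitness assay the loss is flat in the energy,
    and unbounded estimates of such saturated effects would drift
    arbitrarily with noise.  Affine parameters are unbounded.
    """
    if n_states not in (2, 3, 4):
        raise ValueError("n_states must be 2, 3 or 4")
    if exclude_backgrounds:
        excl = set(exclude_backgrounds)
        observations = [
            o for o in observations if o.genotype.background_id not in excl
        ]
    if not observations:
        raise ValueError("no observations to fit")
    assays = {o.assay for o in observations}
    if n_states >= 3 and assays != {"activity", "abundance"}:
        raise UnderIdentifiedError(
            "activation energies are under-identified without both an "
            f"activity and an abundance assay (got {sorted(assays)})"
        )
    enc = _encode(observations)

    # warn when a mutation is seen in fewer than 2 genetic backgrounds
    bg_of: Dict[MutationID, set] = {}
    for o in observations:
        for m in o.genotype.mutations:
            bg_of.setdefault(m, set()).add(o.genotype.background_id)
    lonely = [m for m, bgs in bg_of.items() if len(bgs) < 2]
    if lonely:
        warnings.warn(
            f"{len(lonely)} mutations observed in <2 genetic backgrounds; "
            "their energies may be poorly constrained"
        )

    rng = np.random.default_rng(seed)
    rt = const.RT
    trace: List[float] = []

    def residuals(th):
        r = _residuals(th, enc, n_states, rt)
        if record_trace:
            loss = float(r @ r)
            if not trace or loss < trace[-1]:
                trace.append(loss)
        return r

    M_, G_ = len(enc.mutations), len(enc.groups)
    n_energy = {2: 1, 3: 2, 4: 3}[n_states]
    lb = np.full(n_energy * (M_ + 1) + 2 * G_, -np.inf)
    ub = np.full_like(lb, np.inf)
    lb[: n_energy * (M_ + 1)] = energy_bounds[0]
    ub[: n_energy * (M_ + 1)] = energy_bounds[1]

    best = None
    for r_i in range(max(1, n_restarts)):
        theta0 = _initial_theta(enc, n_states, rng, jitter=0.0 if r_i == 0 else 0.2)
        res = least_squares(
            residuals,
            np.clip(theta0, lb + 1e-6, ub - 1e-6),
            jac=lambda th: _jacobian(th, enc, n_states, rt),
            method="trf",
            tr_solver="lsmr",
            x_scale="jac",
            bounds=(lb, ub),
            max_nfev=max_nfev,
            ftol=1e-8,
            xtol=1e-12,
            gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    res = best

    M, G = len(enc.mutations), len(enc.groups)
    blocks, wts, c, m = _unpack(res.x, M, G, n_states)
    zeros = {mu: 0.0 for mu in enc.mutations}
    model = EnergyModel(
        ddGf={mu: float(v) for mu, v in zip(enc.mutations, blocks[0])},
        ddGa=(
            {mu: float(v) for mu, v in zip(enc.mutations, blocks[1])}
            if n_states >= 3
            else dict(zeros)
        ),
        wt_dGf=float(wts[0]),
        wt_dGa=float(wts[1]) if n_states >= 3 else 0.0,
        affine={g: (float(c[j]), float(m[j])) for j, g in enumerate(enc.groups)},
        n_states=n_states,
        ddGa2=(
            {mu: float(v) for mu, v in zip(enc.mutations, blocks[2])}
            if n_states == 4
            else {}
        ),
        wt_dGa2=float(wts[2]) if n_states == 4 else 0.0,
    )
    converged = bool(res.status > 0)
    if not converged and len(trace) > 20:
        # an exhausted evaluation budget on a flat plateau (no meaningful
        # loss decrease over the final accepted steps) is convergence in
        # every sense that matters for the estimates
        tail = trace[-max(5, len(trace) // 10) :]
        per_step = (tail[0] - tail[-1]) / max(len(tail) - 1, 1)
        converged = per_step <= 1e-5 * max(tail[0], 1.0)
    result = FitResult(
        model=model,
        loss=float(2.0 * res.cost),
        loss_trace=trace,
        n_obs=len(observations),
        converged=converged,
    )
    for g in enc.groups:
        sel = [o for o in observations if (o.assay, o.block) == g]
        yv = np.array([o.fitness for o in sel])
        sv = np.array([o.sigma for o in sel])
        try:
            mev, fev = explainable_variance(yv, sv)
            result.mev[g], result.fev[g] = mev, fev
        except ValueError:
            pass
    return result


def explainable_variance(
    fitness: np.ndarray, sigmas: np.ndarray
) -> Tuple[float, float]:
    """Maximum explainable variance and its fraction of total variance.

    MEV = Var(fitness) - mean(sigma^2); FEV = MEV / Var(fitness).  Variants
    whose errors fall in the top 15th percentile are discarded first to
    keep outlier errors from dominating the technical-variance estimate.
    MEV is clipped at 0 (with a warning) when technical variance exceeds
    the observed variance.
    """
    fitness = np.asarray(fitness, float)
    sigmas = np.asarray(sigmas, float)
    if fitness.size < 2:
        raise ValueError("need at least 2 variants")
    cutoff = np.quantile(sigmas, 0.85)
    keep = sigmas <= cutoff
    y = fitness[keep]
    s = sigmas[keep]
    var = float(np.var(y))
    if var == 0:
        raise ValueError("zero fitness variance after error filtering")
    mev = var - float(np.mean(s**2))
    if mev < 0:
        warnings.warn("technical variance exceeds fitness variance; MEV clipped to 0")
        return 0.0, 0.0
    return mev, mev / var


def _predict_encoded(enc: _Encoded, model: EnergyModel, rt: float) -> np.ndarray:
    """Predictions for encoded rows from a fitted model (same row order)."""
    ddGf = np.array([model.ddGf.get(m, 0.0) for m in enc.mutations])
    s = model.wt_dGf + enc.X @ ddGf
    if model.n_states >= 3:
        ddGa = np.array([model.ddGa.get(m, 0.0) for m in enc.mutations])
        t = model.wt_dGa + enc.X @ ddGa
    p = np.empty(len(enc.y))
    act = enc.is_activity if model.n_states >= 3 else np.zeros(len(enc.y), bool)
    p[~act] = expit(-s[~act] / rt)
    if model.n_states == 3:
        from .thermo import fraction_folded_active

        p[act] = fraction_folded_active(s[act], t[act])
    elif model.n_states == 4:
        from .thermo import fraction_active_four_state

        ddGa2 = np.array([model.ddGa2.get(m, 0.0) for m in enc.mutations])
        t2 = model.wt_dGa2 + enc.X @ ddGa2
        p[act] = fraction_active_four_state(s[act], t[act], t2[act])
    c = np.array([model.affine[g][0] for g in enc.groups])
    m_ = np.array([model.affine[g][1] for g in enc.groups])
    return c[enc.group] + m_[enc.group] * p


@dataclass
class CVResult:
    r2_per_fold: List[float]
    fold_models: List[EnergyModel]
    fold_of: Dict[frozenset, int]

    @property
    def r2_median(self) -> float:
        return float(np.median(self.r2_per_fold))


def crossvalidate(
    observations: Sequence[FitnessObservation],
    n_states: int = 3,
    k_folds: int = 10,
    seed: int = 0,
    const: ThermoConstants = DEFAULT_CONSTANTS,
    **fit_kwargs,
) -> CVResult:
    """k-fold cross-validation held out on double mutants.

    The folds are a disjoint cover of the unique double-mutant genotypes;
    wild type and singles are always in training.  Returns the held-out
    R^2 per fold (pooled over assays) and the per-fold models.
    """
    doubles = sorted(
        {frozenset(o.genotype.mutations) for o in observations if o.genotype.order == 2},
        key=lambda k: str(sorted(str(m) for m in k)),
    )
    if len(doubles) < k_folds:
        raise ValueError(f"only {len(doubles)} double mutants for {k_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(doubles))
    fold_of = {doubles[j]: int(i % k_folds) for i, j in enumerate(perm)}
    r2s: List[float] = []
    models: List[EnergyModel] = []
    for fold in range(k_folds):
        train = [
            o
            for o in observations
            if fold_of.get(frozenset(o.genotype.mutations)) != fold
        ]
        test = [
            o
            for o in observations
            if fold_of.get(frozenset(o.genotype.mutations)) == fold
        ]
        fr = fit(
            train, n_states=n_states, const=const, seed=seed,
            **{"record_trace": False, **fit_kwargs},
        )
        enc_test = _encode(test)
        yhat = _predict_encoded(enc_test, fr.model, const.RT)
        ss_res = float(np.sum((enc_test.y - yhat) ** 2))
        ss_tot = float(np.sum((enc_test.y - enc_test.y.mean()) ** 2))
        r2s.append(1.0 - ss_res / ss_tot)
        models.append(fr.model)
    return CVResult(r2_per_fold=r2s, fold_models=models, fold_of=fold_of)


def estimate_uncertainty(
    observations: Sequence[FitnessObservation],
    n_states: int = 3,
    n_replicates: int = 10,
    seed: int = 0,
    const: ThermoConstants = DEFAULT_CONSTANTS,
    cv: Optional[CVResult] = None,
    **fit_kwargs,
) -> Tuple[Dict[MutationID, float], Dict[MutationID, float]]:
    """Per-parameter SD across an ensemble of cross-validation refits.

    Each replicate is the model fitted on one CV training subset; the
    reported SD (kcal/mol) is the standard deviation of each energy across
    the ensemble.  A precomputed CVResult can be reused.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if cv is None:
        cv = crossvalidate(
            observations, n_states=n_states, k_folds=n_replicates, seed=seed,
            const=const, **fit_kwargs,
        )
    muts = sorted({m for mod in cv.fold_models for m in mod.ddGf}, key=str)
    f_mat = np.array([[mod.ddGf.get(m, np.nan) for m in muts] for mod in cv.fold_models])
    a_mat = np.array([[mod.ddGa.get(m, np.nan) for m in muts] for mod in cv.fold_models])
    ddGf_sd = {m: float(np.nanstd(f_mat[:, j], ddof=1)) for j, m in enumerate(muts)}
    ddGa_sd = {m: float(np.nanstd(a_mat[:, j], ddof=1)) for j, m in enumerate(muts)}
    return ddGf_sd, ddGa_sd
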