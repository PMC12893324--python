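"""ddGa prediction from sequence/structure features, and the full-length
vs kinase-domain-only regulatory comparison (dddGa).

Prediction uses ordinary least squares on one-hot encoded categorical
features (wild-type and mutant residue, secondary-structure type and
element, contact class) plus rSASA and exponentially transformed
distances dtr = exp(k*d) (k = -0.063 1/A by default, the decay constant
of inhibitory allosteric effects), evaluated by 10-fold cross-validation.

The regulatory comparison regresses full-length ddGa on KD-only ddGa and
takes the residuals as dddGa estimates; z scores combine the errors of
both constructs, with one-sided tests per flagged direction and BH-FDR
within direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .spatial import StructureModel
from .stats import bh_fdr
from .thermo import MutationID

__all__ = [
    "RegulatoryDelta",
    "distance_transform",
    "fit_ddga_predictor",
    "compare_constructs",
    "cluster_regulatory_sites",
]

DEFAULT_DECAY_K = -0.063  # 1/A

CATEGORICAL_FEATURES = ("wt_aa", "mut_aa", "sse_type", "sse_element", "contact_class")
NUMERIC_FEATURES = ("rsasa", "dtr_catalytic", "dtr_nucleotide")


def distance_transform(d, k: float = DEFAULT_DECAY_K):
    """Exponential distance transform dtr = exp(k*d), in (0, 1] for d>=0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(k * d)
    return float(out) if out.ndim == 0 else out


def _design(rows: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    cols = []
    for f in features:
        if f in CATEGORICAL_FEATURES:
            cols.append(pd.get_dummies(rows[f].astype(str), prefix=f, dtype=float))
        else:
            cols.append(rows[[f]].astype(float))
    return pd.concat(cols, axis=1)


@dataclass
class PredictorResult:
    r2_per_fold: List[float]
    coef: pd.Series
    features: Tuple[str, ...]

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_per_fold))

    @property
    def r2_median(self) -> float:
        return float(np.median(self.r2_per_fold))


def fit_ddga_predictor(
    rows: pd.DataFrame,
    target: str = "ddGa",
    features: Optional[Sequence[str]] = None,
    folds: int = 10,
    seed: int = 0,
    exclude_active_site: bool = True,
) -> PredictorResult:
    """Linear ddGa predictor with k-fold cross-validated R^2.

    ``rows`` holds one mutation per row with feature columns and the
    observed target.  Active-site mutations (boolean column
    ``active_site``) are excluded when present.  Single-feature models are
    supported by passing a shorter ``features`` list.  Collinear columns
    are harmless for prediction (least-squares pseudo-inverse).
    """
    if features is None:
        features = [
            f
            for f in (*CATEGORICAL_FEATURES, *NUMERIC_FEATURES)
            if f in rows.columns
        ]
    if exclude_active_site and "active_site" in rows.columns:
        rows = rows.loc[~rows["active_site"].astype(bool)]
    rows = rows.reset_index(drop=True)
    X = _design(rows, features)
    y = rows[target].to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    r2s = []
    for train, test in kf.split(X):
        model = LinearRegression()
        model.fit(X.iloc[train], y[train])
        yhat = model.predict(X.iloc[test])
        ss_res = float(np.sum((y[test] - yhat) ** 2))
        ss_tot = float(np.sum((y[test] - y[test].mean()) ** 2))
        r2s.append(1.0 - ss_res / ss_tot)
    full = LinearRegression().fit(X, y)
    coef = pd.Series(full.coef_, index=X.columns)
    return PredictorResult(r2_per_fold=r2s, coef=coef, features=tuple(features))


@dataclass
class RegulatoryDelta:
    """Change in allosteric effect caused by the regulatory domains."""

    mutation: MutationID
    dddGa: float  # residual of the FL ~ KD regression, kcal/mol
    z: float
    p: float
    fdr: float
    flag: str  # "more_activating_fl" | "more_inhibitory_fl" | ""


def compare_constructs(
    est_fl: pd.DataFrame,
    est_kd: pd.DataFrame,
    dddg_threshold: float = 1.0,
    fdr_cut: float = 0.1,
) -> List[RegulatoryDelta]:
    """Full-length vs KD-only comparison via regression residuals.

    Both inputs need columns mutation (string), ddGa_mean, ddGa_sd.  The
    FL means are regressed on the KD means (unweighted, intercept +
    slope); residuals estimate dddGa (full-length minus KD); z = residual
    / sqrt(sd_FL^2 + sd_KD^2).  One-sided normal p per direction, BH-FDR
    within direction; flagged when |dddGa| > threshold and FDR < cut.
    """
    merged = est_fl.merge(est_kd, on="mutation", suffixes=("_fl", "_kd"))
    if len(merged) < 10:
        raise ValueError(f"only {len(merged)} shared mutations; need >= 10")
    x = merged["ddGa_mean_kd"].to_numpy(dtype=float)
    y = merged["ddGa_mean_fl"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sd = np.sqrt(
        merged["ddGa_sd_fl"].to_numpy(dtype=float) ** 2
        + merged["ddGa_sd_kd"].to_numpy(dtype=float) ** 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, resid / sd, np.sign(resid) * np.inf)
    # one-sided p in the direction of each residual
    p = sps.norm.sf(np.abs(z))
    neg = resid < 0
    fdr = np.ones_like(p)
    for mask in (neg, ~neg):  # BH within each direction
        if mask.any():
            fdr[mask] = bh_fdr(p[mask])
    out = []
    for i, mut in enumerate(merged["mutation"]):
        flag = ""
        if resid[i] < -dddg_threshold and fdr[i] < fdr_cut:
            flag = "more_activating_fl"
        elif resid[i] > dddg_threshold and fdr[i] < fdr_cut:
            flag = "more_inhibitory_fl"
        out.append(
            RegulatoryDelta(
                mutation=MutationID.from_string(mut),
                dddGa=float(resid[i]),
                z=float(z[i]),
                p=float(p[i]),
                fdr=float(fdr[i]),
                flag=flag,
            )
        )
    return out


def cluster_regulatory_sites(
    deltas: Sequence[RegulatoryDelta],
    structure: StructureModel,
    flag: str = "more_activating_fl",
    min_mutations_per_site: int = 2,
    cut_distance: float = 10.0,
) -> pd.DataFrame:
    """Spatially cluster sites with recurrent regulatory deltas.

    Sites with at least ``min_mutations_per_site`` flagged mutations are
    clustered hierarchically (average linkage) on pairwise C-alpha
    distances and cut at ``cut_distance`` A.  A single qualifying site is
    returned as a singleton cluster.
    """
    counts: Dict[int, int] = {}
    for d in deltas:
        if d.flag == flag:
            counts[d.mutation.position] = counts.get(d.mutation.position, 0) + 1
    sites = sorted(r for r, n in counts.items() if n >= min_mutations_per_site)
    if not sites:
        return pd.DataFrame(columns=["residue", "cluster"]).assign(cut_distance=cut_distance)
    ca = structure.ca_coords()
    missing = [s for s in sites if s not in ca]
    if missing:
        raise KeyError(f"sites missing C-alpha coordinates: {missing}")
    if len(sites) == 1:
        df = pd.DataFrame({"residue": sites, "cluster": [1]})
    else:
        coords = np.array([ca[s] for s in sites])
        Z = linkage(pdist(coords), method="average")
        labels = fcluster(Z, t=cut_distance, criterion="distance")
        df = pd.DataFrame({"residue": sites, "cluster": labels.astype(int)})
    df.attrs["cut_distance"] = cut_distance
    return df
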