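"""Surface-pocket clustering and allosteric prioritisation.

Pockets detected on multiple structures of the same protein are collapsed
into unique pockets by hierarchical clustering on 1 minus the
Szymkiewicz-Simpson overlap coefficient of their residue sets, after
filtering on a minimum druggability score.  Unique pockets are then scored
with per-residue ddGa summaries and Fisher-exact enrichment of activating
and inactivating mutations, aggregated as medians across the member
structures, and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import EnergyEstimate, bh_fdr, fisher_enrichment
from .synth import PocketSpec

__all__ = [
    "UniquePocket",
    "overlap_coefficient",
    "cluster_pockets",
    "score_pockets",
]


def overlap_coefficient(a: Set, b: Set) -> float:
    """Szymkiewicz-Simpson overlap |A & B| / min(|A|, |B|)."""
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(set(a) & set(b)) / min(len(a), len(b))


@dataclass
class UniquePocket:
    pocket_id: str
    members: List[PocketSpec]
    residues: frozenset  # union over members

    @property
    def n_structures(self) -> int:
        return len({m.structure_id for m in self.members})

    @property
    def median_druggability(self) -> float:
        return float(np.median([m.druggability for m in self.members]))

    @property
    def max_druggability(self) -> float:
        return float(max(m.druggability for m in self.members))

    # scoring summaries, filled by score_pockets
    scores: Dict[str, float] = field(default_factory=dict)


def cluster_pockets(
    pockets: Sequence[PocketSpec],
    druggability_min: float = 5.0,
    method: str = "average",
    cut_height: float = 0.75,
) -> List[UniquePocket]:
    """Collapse per-structure pockets into unique pockets.

    Pockets below ``druggability_min`` are removed, the remainder
    clustered agglomeratively on 1 - overlap coefficient and cut at
    ``cut_height``.  Input order does not matter: pockets are sorted by
    (structure_id, pocket_id) before clustering, which fixes tie-breaks.
    """
    kept = sorted(
        (p for p in pockets if p.druggability >= druggability_min),
        key=lambda p: (p.structure_id, p.pocket_id),
    )
    if not kept:
        raise ValueError("no pockets survive the druggability filter")
    if len(kept) == 1:
        return [UniquePocket("U1", list(kept), frozenset(kept[0].residues))]
    n = len(kept)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - overlap_coefficient(kept[i].residues, kept[j].residues)
            dm[i, j] = dm[j, i] = d
    Z = linkage(squareform(dm, checks=False), method=method)
    labels = fcluster(Z, t=cut_height, criterion="distance")
    out = []
    for ci in sorted(set(labels), key=lambda c: min(i for i in range(n) if labels[i] == c)):
        members = [kept[i] for i in range(n) if labels[i] == ci]
        residues = frozenset().union(*(m.residues for m in members))
        out.append(UniquePocket(f"U{len(out) + 1}", members, residues))
    return out


def _member_scores(
    member: PocketSpec,
    site_ddga: Mapping[int, float],
    class_counts: Mapping[int, Mapping[str, int]],
    totals: Mapping[str, int],
    n_mutations_total: int,
) -> Optional[Dict[str, float]]:
    vals = [site_ddga[r] for r in member.residues if r in site_ddga]
    if not vals:
        return None
    out = {
        "mean_ddga": float(np.mean(vals)),
        "max_ddga": float(np.max(vals)),
        "min_ddga": float(np.min(vals)),
    }
    for kind in ("activating", "inactivating"):
        sig_in = sum(class_counts.get(r, {}).get(kind, 0) for r in member.residues)
        n_in = sum(class_counts.get(r, {}).get("n", 0) for r in member.residues)
        sig_out = totals[kind] - sig_in
        n_out = n_mutations_total - n_in
        res = fisher_enrichment(
            (sig_in, n_in - sig_in), (sig_out, n_out - sig_out)
        )
        out[f"or_{kind}"] = res.odds_ratio
        out[f"p_{kind}"] = res.p_value
    return out


def score_pockets(
    unique_pockets: Sequence[UniquePocket],
    estimates: Sequence[EnergyEstimate],
    site_ddga: Optional[Mapping[int, float]] = None,
) -> pd.DataFrame:
    """Score unique pockets with ddGa summaries and class enrichments.

    Per member pocket: mean/max/min of per-residue mean ddGa over covered
    residues, plus Fisher-exact ORs of activating and inactivating
    mutations against the rest of the domain.  Unique-pocket values are
    medians across members; enrichment p-values are BH-FDR-corrected
    across unique pockets; output is ranked by inactivating enrichment.
    Pockets whose residues carry no energy data are scored as missing.
    """
    from .stats import site_mean_ddga

    if site_ddga is None:
        site_ddga = site_mean_ddga(estimates)
    class_counts: Dict[int, Dict[str, int]] = {}
    totals = {"activating": 0, "inactivating": 0}
    for e in estimates:
        d = class_counts.setdefault(e.mutation.position, {"n": 0})
        d["n"] = d.get("n", 0) + 1
        for kind in ("activating", "inactivating"):
            if kind in e.labels:
                d[kind] = d.get(kind, 0) + 1
                totals[kind] += 1
    n_total = len(estimates)

    rows = []
    for up in unique_pockets:
        per_member = [
            s
            for m in up.members
            if (s := _member_scores(m, site_ddga, class_counts, totals, n_total))
            is not None
        ]
        row = {
            "pocket_id": up.pocket_id,
            "n_structures": up.n_structures,
            "n_residues": len(up.residues),
            "median_druggability": up.median_druggability,
            "max_druggability": up.max_druggability,
        }
        if not per_member:
            row.update({k: np.nan for k in (
                "mean_ddga", "max_ddga", "min_ddga",
                "or_activating", "p_activating", "or_inactivating", "p_inactivating",
            )})
        else:
            for key in per_member[0]:
                row[key] = float(np.median([s[key] for s in per_member]))
        rows.append(row)
        up.scores = {k: v for k, v in row.items() if isinstance(v, float)}
    df = pd.DataFrame(rows)
    for kind in ("activating", "inactivating"):
        p = df[f"p_{kind}"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        fdr = np.full(len(df), np.nan)
        if ok.any():
            fdr[ok] = bh_fdr(p[ok])
        df[f"fdr_{kind}"] = fdr
    df = df.sort_values(
        ["or_inactivating", "median_druggability"], ascending=[False, False]
    ).reset_index(drop=True)
    return df
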