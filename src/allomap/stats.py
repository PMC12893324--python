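"""Mutation classification and residue-level enrichment statistics.

Mutations are classified by their energy effects with one-sided z tests
against a +-0.5 kcal/mol boundary (destabilizing / stabilizing on ddGf,
inactivating / activating on ddGa), with Benjamini-Hochberg FDR control
per energy.  Residue-level enrichment of mutation classes uses Fisher's
exact test against the rest of the domain as background; "major
allosteric sites" are non-active-site residues enriched in
activity-modulating mutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .thermo import MutationID

__all__ = [
    "EnergyEstimate",
    "EnrichmentResult",
    "classify",
    "bh_fdr",
    "fisher_enrichment",
    "major_allosteric_sites",
    "site_mean_ddga",
]


@dataclass
class EnergyEstimate:
    """Per-mutation energy means and SDs with classification labels."""

    mutation: MutationID
    ddGf_mean: float
    ddGf_sd: float
    ddGa_mean: float
    ddGa_sd: float
    labels: Set[str] = field(default_factory=set)
    fdr_f: float = float("nan")
    fdr_a: float = float("nan")


@dataclass
class EnrichmentResult:
    group: object
    counts: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float
    fdr: float = float("nan")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _one_sided_p(mean: float, sd: float, boundary: float, direction: str) -> float:
    """P(effect does not exceed the boundary) under N(mean, sd).

    direction "greater": H1 is effect > +boundary, p = Phi((boundary-mean)/sd);
    direction "less": H1 is effect < -boundary, p = Phi((mean+boundary)/sd).
    sd = 0 degenerates to 0/1 depending on which side the mean lies.
    """
    if direction == "greater":
        z = (boundary - mean) / sd if sd > 0 else -math.inf * np.sign(mean - boundary)
    else:
        z = (mean + boundary) / sd if sd > 0 else math.inf * np.sign(mean + boundary)
    if not np.isfinite(z):
        return 0.0 if (mean > boundary if direction == "greater" else mean < -boundary) else 1.0
    return float(sps.norm.cdf(z))


def classify(
    estimates: Sequence[EnergyEstimate],
    threshold: float = 0.5,
    fdr_cut: float = 0.1,
) -> List[EnergyEstimate]:
    """Label mutations by energy effect with z tests + BH-FDR.

    A label is assigned iff |mean| exceeds ``threshold`` (kcal/mol) in the
    label's direction and the BH-FDR of the corresponding one-sided z test
    (per energy, across all tested mutations) is below ``fdr_cut``.
    """
    if not estimates:
        return []
    for energy in ("ddGf", "ddGa"):
        means = np.array([getattr(e, f"{energy}_mean") for e in estimates])
        sds = np.array([getattr(e, f"{energy}_sd") for e in estimates])
        # two one-sided families share one FDR per energy: each mutation is
        # tested against the boundary on the side its mean points to
        p = np.ones(len(estimates))
        for i, (mean, sd) in enumerate(zip(means, sds)):
            direction = "greater" if mean >= 0 else "less"
            p[i] = _one_sided_p(mean, sd, threshold, direction)
        fdr = bh_fdr(p)
        for i, e in enumerate(estimates):
            if energy == "ddGf":
                e.fdr_f = float(fdr[i])
            else:
                e.fdr_a = float(fdr[i])
    for e in estimates:
        e.labels = set()
        if e.ddGf_mean > threshold and e.fdr_f < fdr_cut:
            e.labels.add("destabilizing")
        if e.ddGf_mean < -threshold and e.fdr_f < fdr_cut:
            e.labels.add("stabilizing")
        if e.ddGa_mean > threshold and e.fdr_a < fdr_cut:
            e.labels.add("inactivating")
        if e.ddGa_mean < -threshold and e.fdr_a < fdr_cut:
            e.labels.add("activating")
    return list(estimates)


def fisher_enrichment(
    in_group: Tuple[int, int], out_group: Tuple[int, int], group: object = None
) -> EnrichmentResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    ``in_group`` = (hits, non-hits) inside the group, ``out_group`` the
    same outside.  OR is the sample odds ratio (a*d)/(b*c), reported as
    inf (or 0) when a zero cell makes it degenerate; the p-value remains
    the exact two-sided hypergeometric probability.
    """
    a, b = in_group
    c, d = out_group
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(group=group, counts=((a, b), (c, d)), odds_ratio=float(odds), p_value=float(p))


def _is_activity_modulating(e: EnergyEstimate, kinds: Iterable[str]) -> bool:
    return bool(e.labels & set(kinds))


def major_allosteric_sites(
    estimates: Sequence[EnergyEstimate],
    active_site: Iterable[int],
    or_cut: float = 2.0,
    fdr_cut: float = 0.1,
    kinds: Tuple[str, ...] = ("inactivating", "activating"),
    p_cut: Optional[float] = None,
) -> pd.DataFrame:
    """Residues outside the active site enriched in activity mutations.

    Per residue, a Fisher's exact test compares its count of
    activity-modulating mutations (labels in ``kinds``) to the rest of the
    domain; BH-FDR runs across residues.  Returns the residues passing
    OR > ``or_cut`` and FDR < ``fdr_cut`` (or p < ``p_cut`` when given,
    which replaces the FDR criterion — used for activating-site calls),
    excluding active-site residues.  The full per-residue table is in the
    result's attrs["table"].
    """
    active_site = set(int(x) for x in active_site)
    if not active_site:
        warnings.warn("empty active-site set; no residues will be excluded")
    by_res: Dict[int, List[EnergyEstimate]] = {}
    for e in estimates:
        by_res.setdefault(e.mutation.position, []).append(e)
    residues = sorted(by_res)
    total_sig = sum(
        _is_activity_modulating(e, kinds) for e in estimates
    )
    total = len(estimates)
    rows = []
    for r in residues:
        sig = sum(_is_activity_modulating(e, kinds) for e in by_res[r])
        n_r = len(by_res[r])
        res = fisher_enrichment(
            (sig, n_r - sig), (total_sig - sig, (total - n_r) - (total_sig - sig)), group=r
        )
        rows.append(
            {
                "residue": r,
                "n_mutations": n_r,
                "n_significant": sig,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    if p_cut is not None:
        passing = (table["odds_ratio"] > or_cut) & (table["p_value"] < p_cut)
    else:
        passing = (table["odds_ratio"] > or_cut) & (table["fdr"] < fdr_cut)
    passing &= ~table["residue"].isin(active_site)
    passing &= table["n_significant"] > 0
    out = table.loc[passing].reset_index(drop=True)
    out.attrs["table"] = table
    return out


def site_mean_ddga(
    estimates: Sequence[EnergyEstimate], weighted: bool = True
) -> Dict[int, float]:
    """Per-residue mean ddGa, 1/sd^2-weighted when SDs are available."""
    by_res: Dict[int, List[EnergyEstimate]] = {}
    for e in estimates:
        by_res.setdefault(e.mutation.position, []).append(e)
    out = {}
    for r, es in by_res.items():
        vals = np.array([e.ddGa_mean for e in es])
        sds = np.array([e.ddGa_sd for e in es])
        if weighted and np.all(sds > 0):
            w = 1.0 / sds**2
            out[r] = float(np.sum(w * vals) / np.sum(w))
        else:
            out[r] = float(vals.mean())
    return out
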