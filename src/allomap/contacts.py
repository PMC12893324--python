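"""Noncovalent contact tables and contact-dynamics classification.

Consumes state-specific contact tables in the getcontacts tab-separated
dialect (comment lines starting '#'; columns frame, interaction-type,
atom1, atom2 with atoms as chain:resname:resid:atom).  Only salt bridges
(sb), pi-cation (pc), side chain-side chain hydrogen bonds (hbss) and side
chain-backbone hydrogen bonds (hbsb) are retained — the types that differ
between active and inactive conformations.  Residues are then classified
by how their contact partners change between the two states: active-only,
inactive-only, swapping (different partners in each state), static
(identical partners) or none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "ContactRecord",
    "ResidueContactClass",
    "RETAINED_TYPES",
    "parse_contacts",
    "collapse_contacts",
    "classify_residue_dynamics",
    "compare_class_effects",
]

#: interaction types retained for conformational-state analysis
RETAINED_TYPES = ("sb", "pc", "hbss", "hbsb")


@dataclass(frozen=True)
class ContactRecord:
    interaction_type: str
    residue_a: int
    residue_b: int
    state: str = ""

    def __post_init__(self):
        if self.residue_a == self.residue_b:
            raise ValueError("self-contact")
        if self.residue_a > self.residue_b:  # canonical unordered pair
            a, b = self.residue_b, self.residue_a
            object.__setattr__(self, "residue_a", a)
            object.__setattr__(self, "residue_b", b)

    @property
    def pair(self) -> Tuple[int, int]:
        return (self.residue_a, self.residue_b)


@dataclass(frozen=True)
class ResidueContactClass:
    residue: int
    interaction_type: str
    klass: str  # active_only | inactive_only | swapping | static | none


class ContactParseError(ValueError):
    pass


def _parse_atom(token: str) -> Tuple[str, str, int, str]:
    parts = token.split(":")
    if len(parts) != 4:
        raise ContactParseError(f"malformed atom identifier {token!r}")
    chain, resname, resid, atom = parts
    try:
        return chain, resname, int(resid), atom
    except ValueError:
        raise ContactParseError(f"non-integer residue id in {token!r}")


def parse_contacts(tsv_text: str, state: str = "") -> List[ContactRecord]:
    """Parse getcontacts rows into residue-level contact records.

    Atom-level rows are mapped to residue pairs; rows whose interaction
    type is not one of the four retained types are dropped, as are
    self-pairs.  Duplicate (pair, type) rows collapse to one record.
    """
    records: Set[ContactRecord] = set()
    for line in tsv_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 3:  # frame column omitted
            itype, a1, a2 = fields
        elif len(fields) >= 4:
            itype, a1, a2 = fields[1], fields[2], fields[3]
        else:
            raise ContactParseError(f"expected >= 3 tab-separated fields: {line!r}")
        if itype not in RETAINED_TYPES:
            continue
        _, _, ra, _ = _parse_atom(a1)
        _, _, rb, _ = _parse_atom(a2)
        if ra == rb:
            continue
        records.add(ContactRecord(itype, ra, rb, state))
    return sorted(records, key=lambda r: (r.interaction_type, r.pair))


def collapse_contacts(records: Iterable[ContactRecord]) -> List[ContactRecord]:
    """Deduplicate contacts; sb takes precedence over hbss on one pair.

    A pair annotated both as salt bridge and side chain-side chain
    hydrogen bond is reported once, as a salt bridge.  Idempotent.
    """
    by_key: Set[Tuple[str, Tuple[int, int]]] = set()
    state = ""
    for r in records:
        by_key.add((r.interaction_type, r.pair))
        state = r.state or state
    out = []
    for itype, pair in sorted(by_key):
        if itype == "hbss" and ("sb", pair) in by_key:
            continue
        out.append(ContactRecord(itype, pair[0], pair[1], state))
    return out


def classify_residue_dynamics(
    active: Iterable[ContactRecord], inactive: Iterable[ContactRecord]
) -> List[ResidueContactClass]:
    """Classify residues by contact-partner changes between states.

    Per (residue, interaction type): comparing the partner sets P_active
    and P_inactive gives none / static / active_only / inactive_only /
    swapping (both non-empty but different).
    """
    partners: Dict[Tuple[int, str], Tuple[Set[int], Set[int]]] = {}

    def collect(records, slot):
        for r in records:
            for res, other in ((r.residue_a, r.residue_b), (r.residue_b, r.residue_a)):
                key = (res, r.interaction_type)
                partners.setdefault(key, (set(), set()))[slot].add(other)

    collect(collapse_contacts(active), 0)
    collect(collapse_contacts(inactive), 1)
    out = []
    for (res, itype), (pa, pi) in sorted(partners.items()):
        if not pa and not pi:
            klass = "none"
        elif pa == pi:
            klass = "static"
        elif not pi:
            klass = "active_only"
        elif not pa:
            klass = "inactive_only"
        else:
            klass = "swapping"
        out.append(ResidueContactClass(res, itype, klass))
    return out


def residue_class_map(
    classes: Iterable[ResidueContactClass],
) -> Dict[int, str]:
    """One overall label per residue across interaction types.

    A residue engaged in contacts in both states (possibly via different
    types) is 'swapping' if any type swaps, else 'both'; otherwise the
    label follows the side(s) on which it has contacts.
    """
    by_res: Dict[int, Set[str]] = {}
    for c in classes:
        if c.klass != "none":
            by_res.setdefault(c.residue, set()).add(c.klass)
    out = {}
    for res, ks in by_res.items():
        if "swapping" in ks:
            out[res] = "swapping"
        elif ks == {"static"}:
            out[res] = "static"
        elif ks <= {"active_only", "static"} and "active_only" in ks:
            out[res] = "active_only" if ks == {"active_only"} else "both"
        elif ks <= {"inactive_only", "static"} and "inactive_only" in ks:
            out[res] = "inactive_only" if ks == {"inactive_only"} else "both"
        else:
            out[res] = "both"
    return out


def compare_class_effects(
    classes: Iterable[ResidueContactClass],
    effects: Mapping[int, Sequence[float]],
    min_n: int = 3,
) -> pd.DataFrame:
    """Pairwise rank-sum tests of |ddGa| between contact classes.

    ``effects`` maps residue -> iterable of |ddGa| values for its
    mutations.  Per interaction type, every pair of classes with at least
    ``min_n`` mutations is compared with a two-sided Wilcoxon rank-sum
    test; p-values are BH-adjusted across all comparisons.  Classes with
    fewer than ``min_n`` values are skipped (noted in the 'skipped'
    attr).
    """
    pooled: Dict[Tuple[str, str], List[float]] = {}
    for c in classes:
        if c.klass == "none":
            continue
        vals = effects.get(c.residue)
        if vals is None:
            continue
        pooled.setdefault((c.interaction_type, c.klass), []).extend(
            abs(v) for v in vals
        )
    rows = []
    skipped = []
    types = sorted({t for t, _ in pooled})
    for itype in types:
        klasses = sorted(k for t, k in pooled if t == itype)
        usable = []
        for k in klasses:
            if len(pooled[(itype, k)]) >= min_n:
                usable.append(k)
            else:
                skipped.append((itype, k))
        for i in range(len(usable)):
            for j in range(i + 1, len(usable)):
                a = pooled[(itype, usable[i])]
                b = pooled[(itype, usable[j])]
                stat, p = sps.ranksums(a, b)
                rows.append(
                    {
                        "interaction_type": itype,
                        "class_a": usable[i],
                        "class_b": usable[j],
                        "n_a": len(a),
                        "n_b": len(b),
                        "statistic": float(stat),
                        "p_value": float(p),
                    }
                )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_fdr(df["p_value"].to_numpy())
    df.attrs["skipped"] = skipped
    return df


def write_classes_tsv(classes: Sequence[ResidueContactClass], path) -> None:
    pd.DataFrame(
        [
            {"residue": c.residue, "interaction_type": c.interaction_type, "class": c.klass}
            for c in classes
        ]
    ).to_csv(path, sep="\t", index=False)
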