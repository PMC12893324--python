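"""Tabular and structural file formats.

Fitness tables, energy tables and truth tables are plain TSV; structures
are minimal single-chain PDB files (written through gemmi); contact tables
use the getcontacts tab-separated dialect; pockets go to TSV with
comma-joined residue sets.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .spatial import StructureModel
from .thermo import FitnessObservation, Genotype, MutationID


def observations_to_frame(observations: Sequence[FitnessObservation]) -> pd.DataFrame:
    rows = [
        {
            "genotype": str(o.genotype),
            "background_id": o.genotype.background_id,
            "tile": o.genotype.tile,
            "assay": o.assay,
            "block": o.block,
            "construct": o.construct,
            "fitness": o.fitness,
            "sigma": o.sigma,
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


def write_fitness_tsv(observations: Sequence[FitnessObservation], path) -> None:
    observations_to_frame(observations).to_csv(path, sep="\t", index=False)


def read_fitness_tsv(path) -> List[FitnessObservation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        g = Genotype.from_string(
            row.genotype, tile=int(row.tile), background_id=str(row.background_id)
        )
        out.append(
            FitnessObservation(
                genotype=g,
                assay=str(row.assay),
                block=int(row.block),
                fitness=float(row.fitness),
                sigma=float(row.sigma),
                construct=str(getattr(row, "construct", "kd_only")),
            )
        )
    return out


def write_energy_tsv(
    ddGf: Dict[MutationID, float],
    ddGa: Dict[MutationID, float],
    path,
    ddGf_sd: Dict[MutationID, float] | None = None,
    ddGa_sd: Dict[MutationID, float] | None = None,
) -> None:
    """Energy table mirroring per-mutation mean/SD columns in kcal/mol."""
    muts = sorted(set(ddGf) | set(ddGa), key=str)
    df = pd.DataFrame(
        {
            "mutation": [str(m) for m in muts],
            "ddGf_mean": [ddGf.get(m, np.nan) for m in muts],
            "ddGf_sd": [(ddGf_sd or {}).get(m, np.nan) for m in muts],
            "ddGa_mean": [ddGa.get(m, np.nan) for m in muts],
            "ddGa_sd": [(ddGa_sd or {}).get(m, np.nan) for m in muts],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_energy_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["mutation_id"] = df["mutation"].map(MutationID.from_string)
    df["position"] = df["mutation_id"].map(lambda m: m.position)
    return df


def write_structure_pdb(structure: StructureModel, path, chain: str = "A") -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for res in structure.residues:
        r = gemmi.Residue()
        r.name = res.name
        r.seqid = gemmi.SeqId(res.res_seq, " ")
        for atom in res.atoms:
            a = gemmi.Atom()
            a.name = atom.name
            a.element = gemmi.Element(atom.element)
            a.pos = gemmi.Position(*atom.xyz)
            a.occ = 1.0
            r.add_atom(a)
        ch.add_residue(r)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_contacts_tsv(rows: Iterable[Tuple[str, str, str]], path) -> None:
    """getcontacts static-contact dialect: comment header then
    frame <tab> interaction-type <tab> atom1 <tab> atom2."""
    with open(path, "w") as fh:
        fh.write("# total_frames:1 beg:0 end:0\n")
        fh.write("# frame\tinteraction_type\tatom_1\tatom_2\n")
        for itype, a1, a2 in rows:
            fh.write(f"0\t{itype}\t{a1}\t{a2}\n")


def write_pockets_tsv(pockets, path) -> None:
    rows = [
        {
            "structure_id": p.structure_id,
            "pocket_id": p.pocket_id,
            "druggability": p.druggability,
            "residues": ",".join(str(r) for r in sorted(p.residues)),
        }
        for p in pockets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pockets_tsv(path):
    from .synth import PocketSpec

    df = pd.read_csv(path, sep="\t")
    return [
        PocketSpec(
            structure_id=str(r.structure_id),
            pocket_id=str(r.pocket_id),
            residues=frozenset(int(x) for x in str(r.residues).split(",")),
            druggability=float(r.druggability),
        )
        for r in df.itertuples(index=False)
    ]


def write_truth_tsv(truth, path) -> None:
    muts = sorted(truth.ddGf, key=str)
    df = pd.DataFrame(
        {
            "mutation": [str(m) for m in muts],
            "ddGf": [truth.ddGf[m] for m in muts],
            "ddGa": [truth.ddGa[m] for m in muts],
            "position_class": [truth.position_class.get(m.position, "") for m in muts],
            "distance": [truth.distance.get(m.position, np.nan) for m in muts],
        }
    )
    df.to_csv(path, sep="\t", index=False)
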