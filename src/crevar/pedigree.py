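"""Pedigree structures and PED-format I/O.

Families carry a disease group (one of the seven congenital cranial
dysinnervation phenotype categories) and an inheritance/phenotype subgroup;
both drive which inheritance searches and which cell-type peak sets apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Individual", "Pedigree", "read_ped", "write_ped",
           "DISEASE_GROUPS", "SUBGROUPS"]

DISEASE_GROUPS = (
    "CFEOM", "FNP", "DRS", "CFP", "Moebius", "Ptosis", "Ptosis/MGJWS",
)
SUBGROUPS = (
    "familial/syndromic", "familial/isolated",
    "sporadic-trio/syndromic", "sporadic-trio/isolated",
)

_MISSING = "0"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0  # 1 male, 2 female, 0 unknown
    affected: bool = False


@dataclass
class Pedigree:
    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)
    disease_group: str | None = None
    subgroup: str | None = None
    incomplete_penetrance: bool = False

    def __post_init__(self) -> None:
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise ValueError(
                        f"{self.family_id}: parent {pid} of "
                        f"{ind.individual_id} not in pedigree"
                    )
        if self.members and not any(i.affected for i in self.members.values()):
            raise ValueError(f"{self.family_id}: no affected member")

    def add(self, ind: Individual) -> None:
        self.members[ind.individual_id] = ind

    @property
    def affected(self) -> list[Individual]:
        return [i for i in self.members.values() if i.affected]

    @property
    def unaffected(self) -> list[Individual]:
        return [i for i in self.members.values() if not i.affected]

    def trios(self) -> list[tuple[Individual, Individual, Individual]]:
        """(child, father, mother) triples with both parents present."""
        out = []
        for ind in self.members.values():
            if ind.father_id and ind.mother_id:
                out.append(
                    (ind, self.members[ind.father_id], self.members[ind.mother_id])
                )
        return out

    def sample_ids(self) -> list[str]:
        return list(self.members)


def read_ped(ped_path, families_path=None) -> list[Pedigree]:
    """Read a 6-column PED file; optional families TSV adds group metadata.

    The families table has columns family_id, disease_group, subgroup and
    optionally incomplete_penetrance (0/1).
    """
    df = pd.read_csv(
        ped_path, sep=r"\s+", header=None, comment="#", dtype=str,
        names=["family_id", "individual_id", "father_id", "mother_id",
               "sex", "phenotype"],
    )
    meta = {}
    if families_path is not None:
        fdf = pd.read_csv(families_path, sep="\t", dtype=str)
        for row in fdf.itertuples(index=False):
            meta[row.family_id] = row
    peds: dict[str, Pedigree] = {}
    for fam_id, sub in df.groupby("family_id", sort=False):
        members = {}
        for row in sub.itertuples(index=False):
            members[row.individual_id] = Individual(
                individual_id=row.individual_id,
                father_id=None if row.father_id == _MISSING else row.father_id,
                mother_id=None if row.mother_id == _MISSING else row.mother_id,
                sex=int(row.sex),
                affected=row.phenotype == "2",
            )
        m = meta.get(fam_id)
        peds[fam_id] = Pedigree(
            family_id=fam_id, members=members,
            disease_group=getattr(m, "disease_group", None) if m else None,
            subgroup=getattr(m, "subgroup", None) if m else None,
            incomplete_penetrance=bool(int(getattr(m, "incomplete_penetrance", 0) or 0))
            if m else False,
        )
    return list(peds.values())


def write_ped(pedigrees, ped_path, families_path=None) -> None:
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.members.values():
                fh.write(
                    "\t".join([
                        ped.family_id, ind.individual_id,
                        ind.father_id or _MISSING, ind.mother_id or _MISSING,
                        str(ind.sex), "2" if ind.affected else "1",
                    ]) + "\n"
                )
    if families_path is not None:
        rows = [
            (p.family_id, p.disease_group or "", p.subgroup or "",
             int(p.incomplete_penetrance))
            for p in pedigrees
        ]
        pd.DataFrame(
            rows, columns=["family_id", "disease_group", "subgroup",
                           "incomplete_penetrance"]
        ).to_csv(families_path, sep="\t", index=False)
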