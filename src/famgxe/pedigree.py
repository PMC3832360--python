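"""Pedigree parsing, validation and additive relationship matrices.

A pedigree is a collection of independent families; within each family the
expected additive genetic relationship between two members is twice the
kinship coefficient, 2*phi, computed by the classical recursion

    phi(i, j) = 1/2 [ phi(fa_i, j) + phi(mo_i, j) ]   (j not a descendant of i)
    phi(i, i) = 1/2 [ 1 + phi(fa_i, mo_i) ]

processed in parental (topological) order.  Members of different families
are unrelated by construction: the relationship matrix is block-diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

MISSING_PARENT_CODES = {"0", "", "na", "none", "nan"}

SEX_CODES = {
    "1": "male",
    "2": "female",
    "0": "unknown",
    "m": "male",
    "f": "female",
    "male": "male",
    "female": "female",
    "unknown": "unknown",
    "u": "unknown",
}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, duplicate ids, sex conflicts)."""


def _norm_parent(token) -> str | None:
    if token is None:
        return None
    s = str(token).strip()
    if s.lower() in MISSING_PARENT_CODES:
        return None
    return s


def _norm_sex(token) -> str:
    s = str(token).strip().lower()
    if s not in SEX_CODES:
        raise PedigreeError(f"unrecognized sex code {token!r}")
    return SEX_CODES[s]


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids are None for founders."""

    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # 'male' | 'female' | 'unknown'

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """Validated set of individuals partitioned into independent families.

    Input order is preserved.  Parent references must resolve within the
    same family; single known parents are allowed; founders have both
    parents missing.
    """

    individuals: list[Individual]
    _by_id: dict[str, Individual] = field(init=False, repr=False)
    _families: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        self._families = {}
        for ind in self.individuals:
            if ind.individual_id in self._by_id:
                raise PedigreeError(
                    f"duplicate individual id {ind.individual_id!r}"
                )
            self._by_id[ind.individual_id] = ind
            self._families.setdefault(ind.family_id, []).append(
                ind.individual_id
            )
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self, strict_sex: bool = False) -> None:
        for ind in self.individuals:
            for pid, role, ok_sex in (
                (ind.father_id, "father", "male"),
                (ind.mother_id, "mother", "female"),
            ):
                if pid is None:
                    continue
                if pid == ind.individual_id:
                    raise PedigreeError(
                        f"{ind.individual_id!r} is its own {role}"
                    )
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.individual_id!r} not in pedigree"
                    )
                if parent.family_id != ind.family_id:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.individual_id!r} is in a "
                        f"different family ({parent.family_id!r})"
                    )
                if parent.sex not in (ok_sex, "unknown"):
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.individual_id!r} has sex "
                        f"{parent.sex!r}"
                    )
        # acyclicity, checked per family via topological sort
        for fam in self._families:
            self._topological_order(fam)

    def _topological_order(self, family_id: str) -> list[str]:
        """Ids of one family sorted so that parents precede children."""
        members = self._families[family_id]
        children: dict[str, list[str]] = {m: [] for m in members}
        indeg = {m: 0 for m in members}
        for m in members:
            ind = self._by_id[m]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    children[pid].append(m)
                    indeg[m] += 1
        order: list[str] = []
        queue = [m for m in members if indeg[m] == 0]
        while queue:
            cur = queue.pop()
            order.append(cur)
            for ch in children[cur]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(members):
            raise PedigreeError(
                f"ancestry cycle detected in family {family_id!r}"
            )
        return order

    # -- accessors -----------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]

    @property
    def families(self) -> dict[str, list[str]]:
        """Family id -> member ids, in input order."""
        return {k: list(v) for k, v in self._families.items()}

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id


@dataclass
class RelationshipMatrix:
    """Symmetric matrix of expected additive relationships 2*phi.

    Values lie in [0, 2]; the diagonal is 1 + f (inbreeding coefficient),
    exactly 1 for non-inbred individuals; entries between members of
    different families are zero.
    """

    ids: list[str]
    values: np.ndarray
    family_of: dict[str, str]

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = [self._index[i] for i in ids]
        return RelationshipMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            family_of={i: self.family_of[i] for i in ids},
        )

    def family_blocks(self) -> Iterator[tuple[str, list[str], np.ndarray]]:
        """Yield (family_id, member ids, dense 2*phi block) per family."""
        groups: dict[str, list[str]] = {}
        for i in self.ids:
            groups.setdefault(self.family_of[i], []).append(i)
        for fam, members in groups.items():
            idx = [self._index[m] for m in members]
            yield fam, members, self.values[np.ix_(idx, idx)]


def read_pedigree(path: str | Path, dialect: str = "linkage") -> Pedigree:
    """Read a pedigree file in LINKAGE (whitespace) or headered CSV dialect.

    Both dialects carry columns family, id, father, mother, sex; missing
    parents are coded "0", empty, or "NA"; sex codes are 1/2/0 or
    male/female/unknown.
    """
    path = Path(path)
    if dialect == "linkage":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["family", "id", "father", "mother", "sex"],
            dtype=str,
            comment="#",
        )
    elif dialect == "csv":
        df = pd.read_csv(path, dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"family", "id", "father", "mother", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"missing pedigree columns: {sorted(missing)}")
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    individuals = [
        Individual(
            individual_id=str(row.id).strip(),
            family_id=str(row.family).strip(),
            father_id=_norm_parent(row.father),
            mother_id=_norm_parent(row.mother),
            sex=_norm_sex(row.sex),
        )
        for row in df.itertuples()
    ]
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path: str | Path, dialect: str = "linkage") -> None:
    """Write a pedigree in the same dialects read_pedigree consumes."""
    sex_out = {"male": "1", "female": "2", "unknown": "0"}
    rows = [
        (
            ind.family_id,
            ind.individual_id,
            ind.father_id or "0",
            ind.mother_id or "0",
            sex_out[ind.sex],
        )
        for ind in ped.individuals
    ]
    df = pd.DataFrame(rows, columns=["family", "id", "father", "mother", "sex"])
    if dialect == "linkage":
        df.to_csv(path, sep="\t", header=False, index=False)
    elif dialect == "csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")


def kinship2(ped: Pedigree) -> RelationshipMatrix:
    """Expected additive relationship (2*phi) for every within-family pair.

    Uses the recursive kinship algorithm in parental order; cross-family
    entries are zero without computation.
    """
    ids = ped.ids
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    out = np.zeros((n, n))
    for fam, members in ped.families.items():
        order = ped._topological_order(fam)
        m = len(order)
        pos = {i: k for k, i in enumerate(order)}
        phi = np.zeros((m, m))
        for k, iid in enumerate(order):
            ind = ped[iid]
            fa = pos.get(ind.father_id) if ind.father_id else None
            mo = pos.get(ind.mother_id) if ind.mother_id else None
            # phi with everyone processed earlier
            for j in range(k):
                v = 0.0
                if fa is not None:
                    v += 0.5 * phi[fa, j]
                if mo is not None:
                    v += 0.5 * phi[mo, j]
                phi[k, j] = phi[j, k] = v
            self_phi = 0.5
            if fa is not None and mo is not None:
                self_phi = 0.5 * (1.0 + phi[fa, mo])
            phi[k, k] = self_phi
        gidx = np.array([index[i] for i in order])
        out[np.ix_(gidx, gidx)] = 2.0 * phi
    family_of = {ind.individual_id: ind.family_id for ind in ped.individuals}
    return RelationshipMatrix(ids=ids, values=out, family_of=family_of)


def family_summary(ped: Pedigree, phenotyped: Iterable[str]) -> dict:
    """Counts by family role and mean number of phenotyped members per family.

    Roles: fathers/mothers are individuals who appear as a parent of someone
    in their family (or are parent-generation founders with offspring
    present); sons/daughters are individuals with at least one known parent.
    The mean family size is reported to 1 decimal; an empty phenotyped set
    yields a missing mean.
    """
    phen = set(phenotyped)
    unknown = phen - set(ped.ids)
    if unknown:
        raise ValueError(
            f"phenotyped ids not in pedigree: {sorted(unknown)[:5]}"
        )
    parent_ids = set()
    for ind in ped.individuals:
        if ind.father_id:
            parent_ids.add(ind.father_id)
        if ind.mother_id:
            parent_ids.add(ind.mother_id)
    counts = {"fathers": 0, "mothers": 0, "sons": 0, "daughters": 0, "other": 0}
    for iid in phen:
        ind = ped[iid]
        if iid in parent_ids or (ind.is_founder and ind.sex != "unknown"):
            if ind.sex == "male":
                counts["fathers"] += 1
            elif ind.sex == "female":
                counts["mothers"] += 1
            else:
                counts["other"] += 1
        elif not ind.is_founder:
            if ind.sex == "male":
                counts["sons"] += 1
            elif ind.sex == "female":
                counts["daughters"] += 1
            else:
                counts["other"] += 1
        else:
            counts["other"] += 1
    n_families = len({ped[i].family_id for i in phen}) if phen else 0
    mean_size = round(len(phen) / n_families, 1) if n_families else math.nan
    return {
        "n_phenotyped": len(phen),
        "n_families": n_families,
        "mean_family_size": mean_size,
        "role_counts": counts,
    }
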