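"""Twin-family pedigrees and the additive genetic relationship matrix.

A pedigree is a flat list of individuals with optional parent links, a sex,
and a zygosity tag. Families are independent sampling units: the additive
genetic relationship matrix A (twice the kinship matrix) is block-diagonal
by family, with MZ co-twins treated as genetically identical (A = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

MALE = "male"
FEMALE = "female"

AGE_MIN = 7.0
AGE_MAX = 50.0


class PedigreeError(ValueError):
    """Malformed pedigree structure (bad parent links, cycles, zygosity)."""


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Optional[str] = None  # "male" / "female" / None
    zygosity: str = "none"  # "MZ", "DZ", or "none"
    age: Optional[float] = None
    in_analysis: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """Ordered collection of individuals, indexed by family.

    Parents must appear before their offspring. Construction validates the
    structural invariants and raises :class:`PedigreeError` listing every
    violation found.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self.index = {ind.individual_id: i for i, ind in enumerate(self.individuals)}
        self.family_index: dict[str, list[str]] = {}
        for ind in self.individuals:
            self.family_index.setdefault(ind.family_id, []).append(ind.individual_id)
        self._validate()
        self._arrays: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[self.index[individual_id]]

    def _validate(self) -> None:
        errors: list[str] = []
        if len(self.index) != len(self.individuals):
            seen: set[str] = set()
            for ind in self.individuals:
                if ind.individual_id in seen:
                    errors.append(f"duplicate individual id {ind.individual_id!r}")
                seen.add(ind.individual_id)
        for pos, ind in enumerate(self.individuals):
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                if pid == ind.individual_id:
                    errors.append(f"{ind.individual_id}: is its own {role}")
                    continue
                if pid not in self.index:
                    errors.append(f"{ind.individual_id}: unknown {role} {pid!r}")
                    continue
                parent = self.individuals[self.index[pid]]
                if parent.family_id != ind.family_id:
                    errors.append(
                        f"{ind.individual_id}: {role} {pid!r} is in family "
                        f"{parent.family_id!r}, not {ind.family_id!r}"
                    )
                if self.index[pid] >= pos:
                    errors.append(
                        f"{ind.individual_id}: {role} {pid!r} appears after the child"
                    )
            if (ind.father_id is None) != (ind.mother_id is None):
                errors.append(f"{ind.individual_id}: exactly one parent recorded")
            if ind.age is not None and not (AGE_MIN <= ind.age <= AGE_MAX):
                errors.append(f"{ind.individual_id}: age {ind.age} outside [7, 50]")
        # MZ-tagged individuals must come in same-parent groups of >= 2
        for fam, ids in self.family_index.items():
            mz = [self[i] for i in ids if self[i].zygosity == "MZ"]
            if len(mz) == 1:
                errors.append(f"family {fam}: lone MZ-tagged individual {mz[0].individual_id}")
            if len(mz) >= 2:
                parents = {(m.father_id, m.mother_id) for m in mz}
                if len(parents) > 1:
                    errors.append(f"family {fam}: MZ-tagged members do not share parents")
        if errors:
            raise PedigreeError("; ".join(errors))

    # ------------------------------------------------------------------
    # Array views used by the simulators (computed once, cached)
    # ------------------------------------------------------------------
    def arrays(self) -> dict:
        if self._arrays is None:
            n = len(self.individuals)
            father = np.full(n, -1, dtype=np.int64)
            mother = np.full(n, -1, dtype=np.int64)
            for i, ind in enumerate(self.individuals):
                if ind.father_id is not None:
                    father[i] = self.index[ind.father_id]
                if ind.mother_id is not None:
                    mother[i] = self.index[ind.mother_id]
            # MZ representative: first MZ-tagged member of the same group
            mz_rep = np.arange(n, dtype=np.int64)
            groups: dict[tuple, int] = {}
            for i, ind in enumerate(self.individuals):
                if ind.zygosity == "MZ":
                    key = (ind.family_id, ind.father_id, ind.mother_id)
                    mz_rep[i] = groups.setdefault(key, i)
            # topological levels: founders are level 0, children one past parents
            level = np.zeros(n, dtype=np.int64)
            for i in range(n):
                f, m = father[i], mother[i]
                if f >= 0:
                    level[i] = max(level[f], level[m]) + 1
            in_analysis = np.array([ind.in_analysis for ind in self.individuals])
            self._arrays = {
                "father": father,
                "mother": mother,
                "mz_rep": mz_rep,
                "level": level,
                "in_analysis": in_analysis,
            }
        return self._arrays

    def analysis_ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals if ind.in_analysis]


def kinship_matrix(pedigree: Pedigree, family_id: str) -> tuple[list[str], np.ndarray]:
    """Kinship coefficients for one family by the recursive tabular method.

    MZ co-twins are duplicates of a single genome: the later twin's row is a
    copy of the representative's, and their mutual kinship equals the
    representative's self-kinship.
    """
    ids = pedigree.family_index[family_id]
    pos = {iid: k for k, iid in enumerate(ids)}
    arr = pedigree.arrays()
    n = len(ids)
    phi = np.zeros((n, n))
    for k, iid in enumerate(ids):
        ind = pedigree[iid]
        gi = pedigree.index[iid]
        rep = arr["mz_rep"][gi]
        if rep != gi:
            r = pos[pedigree.individuals[rep].individual_id]
            phi[k, :k] = phi[r, :k]
            phi[:k, k] = phi[:k, r]
            phi[k, r] = phi[r, k] = phi[r, r]
            phi[k, k] = phi[r, r]
            continue
        f = pos.get(ind.father_id) if ind.father_id is not None else None
        m = pos.get(ind.mother_id) if ind.mother_id is not None else None
        phi[k, k] = 0.5 * (1.0 + (phi[f, m] if f is not None else 0.0))
        for j in range(k):
            val = 0.0
            if f is not None:
                val = 0.5 * (phi[f, j] + phi[m, j])
            phi[k, j] = phi[j, k] = val
    return ids, phi


def relationship_blocks(
    pedigree: Pedigree, ids: Optional[Sequence[str]] = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-family blocks of the additive relationship matrix A = 2*kinship.

    Returns ``(positions, block)`` pairs where ``positions`` indexes into
    ``ids`` (default: all analysis individuals in pedigree order). Individuals
    in ``ids`` may be any subset of the pedigree; relationships are computed
    on the full family and then restricted, so excluded connecting ancestors
    are still accounted for.
    """
    if ids is None:
        ids = pedigree.analysis_ids()
    pos_of = {iid: k for k, iid in enumerate(ids)}
    unknown = [i for i in ids if i not in pedigree.index]
    if unknown:
        raise PedigreeError(f"ids not in pedigree: {unknown[:5]}")
    blocks = []
    for fam in pedigree.family_index:
        fam_ids, phi = kinship_matrix(pedigree, fam)
        keep = [k for k, iid in enumerate(fam_ids) if iid in pos_of]
        if not keep:
            continue
        positions = np.array([pos_of[fam_ids[k]] for k in keep], dtype=np.int64)
        A = 2.0 * phi[np.ix_(keep, keep)]
        blocks.append((positions, A))
    return blocks


def relationship_matrix(
    pedigree: Pedigree, ids: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Dense additive relationship matrix over ``ids`` (block-diagonal by family)."""
    if ids is None:
        ids = pedigree.analysis_ids()
    n = len(ids)
    A = np.zeros((n, n))
    for positions, block in relationship_blocks(pedigree, ids):
        A[np.ix_(positions, positions)] = block
    return A
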