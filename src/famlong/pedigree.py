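"""Pedigree parsing and kinship coefficients.

Pedigrees are read from linkage-format PED text (pre-MAKEPED, first five
whitespace-delimited columns: family id, individual id, father id, mother id,
sex; ``0`` marks a missing parent).  Kinship coefficients ``phi`` are computed
per family by the standard tabular recursion and can be rescaled to the
expected additive genetic correlation ``2*phi`` (unit diagonal for non-inbred
individuals), which is the default scale used by the covariance model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

MISSING_PARENT = "0"

__all__ = [
    "PedigreeError",
    "PedRecord",
    "Pedigree",
    "KinshipMatrix",
    "parse_ped",
    "kinship_matrix",
    "kinship_matrices",
    "relationship_matrix",
    "write_kinship",
    "read_kinship",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad reference, duplicate id, cycle)."""


@dataclass(frozen=True)
class PedRecord:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown


@dataclass
class Pedigree:
    """A set of families, each a directed acyclic parent->child structure.

    Member order within a family is the order of first appearance in the
    source file; it is the authoritative row order for every matrix built
    downstream.
    """

    records: list[PedRecord]
    _families: dict[str, list[str]] = field(init=False, repr=False)
    _index: dict[tuple[str, str], PedRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        index: dict[tuple[str, str], PedRecord] = {}
        for rec in self.records:
            key = (rec.family_id, rec.individual_id)
            if key in index:
                raise PedigreeError(
                    f"duplicate individual id {rec.individual_id!r} in family "
                    f"{rec.family_id!r}"
                )
            index[key] = rec
            fams.setdefault(rec.family_id, []).append(rec.individual_id)
        object.__setattr__(self, "_families", fams)
        object.__setattr__(self, "_index", index)
        self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def family_ids(self) -> list[str]:
        return list(self._families)

    @property
    def n_individuals(self) -> int:
        return len(self.records)

    def members(self, family_id: str) -> list[str]:
        try:
            return list(self._families[family_id])
        except KeyError:
            raise PedigreeError(f"unknown family id {family_id!r}") from None

    def record(self, family_id: str, individual_id: str) -> PedRecord:
        try:
            return self._index[(family_id, individual_id)]
        except KeyError:
            raise PedigreeError(
                f"unknown individual {individual_id!r} in family {family_id!r}"
            ) from None

    def founders(self, family_id: str) -> list[str]:
        return [
            i
            for i in self.members(family_id)
            if self.record(family_id, i).father_id is None
            and self.record(family_id, i).mother_id is None
        ]

    def has_unique_individual_ids(self) -> bool:
        ids = [r.individual_id for r in self.records]
        return len(ids) == len(set(ids))

    def _validate(self) -> None:
        for rec in self.records:
            for parent in (rec.father_id, rec.mother_id):
                if parent is not None and (rec.family_id, parent) not in self._index:
                    raise PedigreeError(
                        f"individual {rec.individual_id!r} in family "
                        f"{rec.family_id!r} references unknown parent {parent!r}"
                    )
        for fid in self._families:
            self.topological_order(fid)  # raises on cycles

    def topological_order(self, family_id: str) -> list[str]:
        """Members of a family ordered parents-before-children (Kahn).

        Ties are broken by file order, so the result is deterministic.
        """
        members = self.members(family_id)
        children: dict[str, list[str]] = {m: [] for m in members}
        indeg = {m: 0 for m in members}
        for m in members:
            rec = self.record(family_id, m)
            for parent in (rec.father_id, rec.mother_id):
                if parent is not None:
                    children[parent].append(m)
                    indeg[m] += 1
        order: list[str] = []
        ready = [m for m in members if indeg[m] == 0]
        while ready:
            cur = ready.pop(0)
            order.append(cur)
            newly = []
            for child in children[cur]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    newly.append(child)
            # keep file order among newly ready nodes
            ready = sorted(ready + newly, key=members.index)
        if len(order) != len(members):
            cycle = [m for m in members if indeg[m] > 0]
            raise PedigreeError(
                f"cyclic parent-child relation in family {family_id!r} "
                f"involving {cycle}"
            )
        return order


def _parse_sex(token: str) -> int:
    return int(token) if token in ("1", "2") else 0


def parse_ped(source: str | Path | TextIO, *, missing: str = MISSING_PARENT) -> Pedigree:
    """Parse linkage PED text into a :class:`Pedigree`.

    ``source`` may be a path, an open text stream, or the file content
    itself (anything containing a newline is treated as content).  Rows need
    at least five whitespace-delimited columns; extra columns (phenotype,
    genotypes) are ignored.  Blank lines and ``#`` comments are skipped.
    """
    if isinstance(source, Path):
        stream: TextIO = open(source)
    elif isinstance(source, str):
        stream = io.StringIO(source) if "\n" in source else open(source)
    else:
        stream = source
    records: list[PedRecord] = []
    with stream:
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 5:
                raise PedigreeError(
                    f"line {lineno}: expected at least 5 columns, got {len(cols)}"
                )
            fid, iid, fa, mo, sex = cols[:5]
            records.append(
                PedRecord(
                    family_id=fid,
                    individual_id=iid,
                    father_id=None if fa == missing else fa,
                    mother_id=None if mo == missing else mo,
                    sex=_parse_sex(sex),
                )
            )
    if not records:
        raise PedigreeError("empty pedigree file")
    try:
        return Pedigree(records)
    except PedigreeError as err:
        raise PedigreeError(str(err)) from None


@dataclass
class KinshipMatrix:
    """Kinship coefficients phi for one family.

    ``member_order`` (file order) defines row/column order; the diagonal is
    ``0.5 * (1 + f)`` with ``f`` the inbreeding coefficient.
    """

    family_id: str
    member_order: tuple[str, ...]
    phi: np.ndarray

    def index(self, individual_id: str) -> int:
        return self.member_order.index(individual_id)

    def submatrix(self, individual_ids: Iterable[str]) -> "KinshipMatrix":
        ids = tuple(individual_ids)
        idx = [self.index(i) for i in ids]
        return KinshipMatrix(self.family_id, ids, self.phi[np.ix_(idx, idx)])


def kinship_matrix(ped: Pedigree, family_id: str) -> KinshipMatrix:
    """Kinship matrix of one family by the tabular recursion.

    Processing members parents-before-children, with founders phi(a,b)=0 and

        phi(a,a) = 0.5 * (1 + phi(father_a, mother_a))
        phi(a,b) = 0.5 * (phi(father_a, b) + phi(mother_a, b))   (b earlier)

    where a term with a missing parent is 0.
    """
    members = ped.members(family_id)
    order = ped.topological_order(family_id)
    pos = {m: i for i, m in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for a in order:
        ia = pos[a]
        rec = ped.record(family_id, a)
        fa = pos.get(rec.father_id) if rec.father_id is not None else None
        mo = pos.get(rec.mother_id) if rec.mother_id is not None else None
        phi[ia, ia] = 0.5 * (1.0 + (phi[fa, mo] if fa is not None and mo is not None else 0.0))
        for b in order:
            ib = pos[b]
            if ib >= ia:
                continue  # b must precede a, so a is not an ancestor of b
            val = 0.0
            if fa is not None:
                val += 0.5 * phi[fa, ib]
            if mo is not None:
                val += 0.5 * phi[mo, ib]
            phi[ia, ib] = phi[ib, ia] = val
    # reorder to file order
    file_idx = [pos[m] for m in members]
    phi = phi[np.ix_(file_idx, file_idx)]
    return KinshipMatrix(family_id, tuple(members), phi)


def relationship_matrix(kin: KinshipMatrix, scale: float = 2.0) -> np.ndarray:
    """Return ``scale * phi``; ``scale=2`` gives the additive genetic
    correlation matrix (unit diagonal for non-inbred individuals)."""
    if scale not in (1, 2):
        raise ValueError("scale must be 1 (phi) or 2 (genetic correlation)")
    return float(scale) * kin.phi


def write_kinship(kinships: Iterable[KinshipMatrix], path: str | Path) -> None:
    """Write kinship coefficients as long-format TSV (FID, ID1, ID2, phi),
    upper triangle including self-pairs."""
    rows = []
    for kin in kinships:
        n = len(kin.member_order)
        for i in range(n):
            for j in range(i, n):
                rows.append(
                    (kin.family_id, kin.member_order[i], kin.member_order[j], kin.phi[i, j])
                )
    df = pd.DataFrame(rows, columns=["FID", "ID1", "ID2", "phi"])
    df.to_csv(path, sep="\t", index=False)


def read_kinship(path: str | Path) -> dict[str, KinshipMatrix]:
    """Read the long-format TSV written by :func:`write_kinship`."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "ID1": str, "ID2": str})
    out: dict[str, KinshipMatrix] = {}
    for fid, grp in df.groupby("FID", sort=False):
        order: list[str] = []
        for iid in pd.concat([grp["ID1"], grp["ID2"]]):
            if iid not in order:
                order.append(iid)
        pos = {m: i for i, m in enumerate(order)}
        phi = np.zeros((len(order), len(order)))
        for _, r in grp.iterrows():
            i, j = pos[r["ID1"]], pos[r["ID2"]]
            phi[i, j] = phi[j, i] = r["phi"]
        out[str(fid)] = KinshipMatrix(str(fid), tuple(order), phi)
    return out


def kinship_matrices(ped: Pedigree) -> dict[str, KinshipMatrix]:
    """Kinship matrices for every family in the pedigree."""
    return {fid: kinship_matrix(ped, fid) for fid in ped.family_ids}
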