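"""Pedigree handling and the additive genetic relationship matrix.

A pedigree is a set of individuals with (possibly unknown) dam and sire
links.  The additive genetic relationship matrix A — twice the kinship
coefficient off the diagonal, one plus the inbreeding coefficient on the
diagonal — is what gives the animal model its genetic covariance
structure: the genetic random effect u satisfies cov(u) = A * sigma2_a.

Unknown parents are treated as unrelated, non-inbred founders, the
standard convention of Henderson's tabular method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: tokens accepted as "parent unknown" in pedigree CSV files
UNKNOWN_TOKENS = {"", "na", "nan", "none", "unknown", "0"}


class PedigreeError(ValueError):
    """Fatal pedigree validation problem (cycle, duplicate, self-parent)."""


@dataclass(frozen=True)
class PedigreeRecord:
    individual: str
    dam: str | None
    sire: str | None
    group: str | None = None
    sex: str = "unknown"


@dataclass
class Pedigree:
    """Validated pedigree with a parents-before-offspring ordering."""

    records: list[PedigreeRecord]
    order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.individual for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PedigreeError(f"duplicate individual id(s): {sorted(dupes)}")
        self._by_id = {r.individual: r for r in self.records}
        if not self.order:
            self.order = _topological_order(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual: str) -> bool:
        return individual in self._by_id

    def record(self, individual: str) -> PedigreeRecord:
        return self._by_id[individual]

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        r = self._by_id[individual]
        return r.dam, r.sire

    def groups(self) -> dict[str, str | None]:
        return {r.individual: r.group for r in self.records}

    def mother_map(self) -> dict[str, str | None]:
        """Individual -> dam (None when unknown)."""
        return {r.individual: r.dam for r in self.records}


@dataclass
class RelatednessMatrix:
    """Additive relatedness A over an ordered id list.

    ``index`` maps id -> row/column so downstream code never relies on
    positional agreement with any other table.
    """

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.index = {i: k for k, i in enumerate(self.ids)}

    def value(self, i: str, j: str) -> float:
        return float(self.A[self.index[i], self.index[j]])

    def submatrix(self, ids: list[str]) -> "RelatednessMatrix":
        """Restriction of A to ``ids`` (marginal of the genetic MVN)."""
        idx = np.array([self.index[i] for i in ids])
        return RelatednessMatrix(list(ids), self.A[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _is_unknown(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return str(token).strip().lower() in UNKNOWN_TOKENS


def _topological_order(records: list[PedigreeRecord]) -> list[str]:
    g = nx.DiGraph()
    for r in records:
        g.add_node(r.individual)
        for p in (r.dam, r.sire):
            if p is not None:
                g.add_edge(p, r.individual)
    try:
        # lexicographic tie-break keeps the order deterministic
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise PedigreeError(f"pedigree contains a parent-link cycle: {path}")


def build_pedigree(rows: list[dict]) -> Pedigree:
    """Validate raw pedigree rows and promote unlisted parents to founders.

    Each row needs keys individual/dam/sire and may carry group/sex.
    """
    records: list[PedigreeRecord] = []
    listed: set[str] = set()
    named_parents: list[str] = []
    for row in rows:
        ind = str(row["individual"]).strip()
        dam = None if _is_unknown(row.get("dam")) else str(row["dam"]).strip()
        sire = None if _is_unknown(row.get("sire")) else str(row["sire"]).strip()
        if dam == ind or sire == ind:
            raise PedigreeError(f"individual {ind!r} is listed as its own parent")
        group = None if _is_unknown(row.get("group")) else str(row["group"]).strip()
        sex = row.get("sex")
        sex = "unknown" if _is_unknown(sex) else str(sex).strip().lower()
        records.append(PedigreeRecord(ind, dam, sire, group, sex))
        listed.add(ind)
        named_parents += [p for p in (dam, sire) if p is not None]
    for p in dict.fromkeys(named_parents):  # preserves first-mention order
        if p not in listed:
            records.append(PedigreeRecord(p, None, None, None, "unknown"))
    return Pedigree(records)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (columns individual, dam, sire[, group, sex])."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = {"individual", "dam", "sire"} - set(cols)
    if missing:
        raise PedigreeError(f"pedigree CSV missing column(s): {sorted(missing)}")
    rows = [
        {k: row.get(cols[k]) for k in cols}
        for row in df.to_dict(orient="records")
    ]
    return build_pedigree(rows)


def add_founders(ped: Pedigree, individuals: list[str],
                 groups: dict[str, str] | None = None) -> Pedigree:
    """Add sampled individuals missing from the pedigree as founders.

    Long-term hormone datasets routinely include animals with no known
    relatives; they enter the A matrix as unrelated founders.
    """
    new = [i for i in dict.fromkeys(individuals) if i not in ped]
    if not new:
        return ped
    warnings.warn(
        f"{len(new)} sampled individual(s) absent from the pedigree were "
        "added as unrelated founders", stacklevel=2)
    records = list(ped.records) + [
        PedigreeRecord(i, None, None, (groups or {}).get(i), "unknown")
        for i in new
    ]
    return Pedigree(records)


def additive_relationship_matrix(ped: Pedigree) -> RelatednessMatrix:
    """Henderson's tabular method.

    Walking the pedigree parents-first:
      A[i,i] = 1 + 0.5 * A[dam(i), sire(i)]
      A[i,j] = 0.5 * (A[j, dam(i)] + A[j, sire(i)])   for j before i,
    with an unknown parent contributing 0.
    """
    order = ped.order
    n = len(order)
    pos = {ind: k for k, ind in enumerate(order)}
    A = np.zeros((n, n))
    for k, ind in enumerate(order):
        dam, sire = ped.parents(ind)
        d = pos[dam] if dam is not None else -1
        s = pos[sire] if sire is not None else -1
        if k:
            row = np.zeros(k)
            if d >= 0:
                row += A[d, :k]
            if s >= 0:
                row += A[s, :k]
            A[k, :k] = A[:k, k] = 0.5 * row
        A[k, k] = 1.0 + (0.5 * A[d, s] if d >= 0 and s >= 0 else 0.0)
    return RelatednessMatrix(list(order), A)


def kinship_oracle(ped: Pedigree, i: str, j: str) -> float:
    """Additive relatedness of (i, j) by direct recursion on kinship.

    Independent of the tabular method: applies the defining recursion
    phi(i,j) = 0.5*(phi(dam_i,j) + phi(sire_i,j)) for i below j in the
    pedigree and phi(i,i) = 0.5*(1 + phi(dam_i, sire_i)), with unknown
    parents contributing 0.  Returns 2*phi(i,j) for i != j and
    1 + F(i) = 2*phi(i,i) for i == j.  Exponential-time; small pedigrees
    only.
    """
    for k in (i, j):
        if k not in ped:
            raise KeyError(f"unknown individual id {k!r}")
    depth = {ind: k for k, ind in enumerate(ped.order)}

    def phi(a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if a == b:
            dam, sire = ped.parents(a)
            return 0.5 * (1.0 + phi(dam, sire))
        # recurse through the parents of the lower (later-born) member
        lower, other = (a, b) if depth[a] >= depth[b] else (b, a)
        dam, sire = ped.parents(lower)
        return 0.5 * (phi(dam, other) + phi(sire, other))

    return 2.0 * phi(i, j)
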