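"""Pedigrees and pedigree-based relationship matrices.

This module parses, validates and topologically orders pedigree tables and
builds the two covariance structures of the additive + dominance animal
model:

* the numerator (additive) relationship matrix ``A``, computed by the
  classical tabular (recursive) method — ``a_ii = 1 + 0.5 a(s_i, d_i)`` and
  ``a_ij = 0.5 (a(j, s_i) + a(j, d_i))`` with unknown parents contributing
  zero; and
* the dominance relationship matrix ``D`` for a non-inbred base,
  ``d_ij = 0.25 (a(s_i, s_j) a(d_i, d_j) + a(s_i, d_j) a(d_i, s_j))`` with
  unit diagonal.

A gene-dropping Monte-Carlo estimator of both matrices is provided as an
independent oracle: founder alleles are dropped through the pedigree by
Mendelian sampling and relationship coefficients are estimated from
identity-by-descent frequencies.

Founders (unknown parents) are assumed unrelated and non-inbred.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN",
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "GeneDropResult",
    "read_pedigree",
    "write_pedigree",
    "topological_order",
    "additive_relationship_matrix",
    "dominance_relationship_matrix",
    "gene_drop_relationships",
]

#: canonical in-memory representation of an unknown parent
UNKNOWN = None

# tokens treated as "unknown parent" when reading CSV files
_MISSING_TOKENS = {"", "0", "NA", "na", ".", "-"}

#: canonical pedigree CSV column order
PEDIGREE_COLUMNS = ("animal", "sire", "dam", "line", "sex", "hatch", "generation")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, missing parents)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: its parents, line label and fixed-effect covariates.

    ``sire``/``dam`` are ``None`` when unknown.  ``line`` is the genetic
    group label (e.g. sire line ``LK``, dam line ``SUT``, cross ``KR``).
    """

    animal: str
    sire: str | None = None
    dam: str | None = None
    line: str = ""
    sex: str = ""
    hatch: str = ""
    generation: int = 0


class Pedigree:
    """An immutable, validated sequence of :class:`PedigreeRecord`.

    Construction enforces unique animal identifiers, parents present as
    records, and acyclicity (no animal is its own ancestor).  Record order
    is preserved as given; use :func:`topological_order` to obtain a
    parents-first ordering, which the matrix constructors require.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        self._records: tuple[PedigreeRecord, ...] = tuple(records)
        ids = [r.animal for r in self._records]
        seen: set[str] = set()
        for a in ids:
            if a in seen:
                raise PedigreeError(f"duplicate animal identifier {a!r}")
            seen.add(a)
        self._index: dict[str, int] = {a: i for i, a in enumerate(ids)}
        for r in self._records:
            for parent in (r.sire, r.dam):
                if parent is not None and parent not in self._index:
                    raise PedigreeError(
                        f"animal {r.animal!r} references parent {parent!r} "
                        "which is not in the pedigree (pass add_missing_founders=True "
                        "to read_pedigree to auto-create founder records)"
                    )
        self._check_acyclic()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, i: int) -> PedigreeRecord:
        return self._records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self._records == other._records

    def __repr__(self) -> str:
        return f"<Pedigree of {len(self)} animals>"

    # -- accessors ----------------------------------------------------------

    @property
    def records(self) -> tuple[PedigreeRecord, ...]:
        return self._records

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.animal for r in self._records)

    def index(self, animal: str) -> int:
        return self._index[animal]

    def __contains__(self, animal: str) -> bool:
        return animal in self._index

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire, dam) positional indices per record; -1 encodes unknown."""
        s = np.array(
            [self._index[r.sire] if r.sire is not None else -1 for r in self._records],
            dtype=np.int64,
        )
        d = np.array(
            [self._index[r.dam] if r.dam is not None else -1 for r in self._records],
            dtype=np.int64,
        )
        return s, d

    @property
    def is_ordered(self) -> bool:
        """True when every parent precedes all of its offspring."""
        s, d = self.parent_indices()
        own = np.arange(len(self))
        return bool(np.all(s < own) and np.all(d < own))

    # -- validation helpers -------------------------------------------------

    def _check_acyclic(self) -> None:
        n = len(self._records)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i, r in enumerate(self._records):
            for parent in (r.sire, r.dam):
                if parent is not None:
                    p = self._index[parent]
                    children[p].append(i)
                    indeg[i] += 1
        queue = [i for i in range(n) if indeg[i] == 0]
        done = 0
        while queue:
            i = queue.pop()
            done += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if done < n:
            cycle = self._find_cycle()
            raise PedigreeError(
                "pedigree contains an ancestry cycle: " + " -> ".join(cycle)
            )

    def _find_cycle(self) -> list[str]:
        # walk parent links from any node until an id repeats
        for start in range(len(self._records)):
            path: list[int] = []
            pos: dict[int, int] = {}
            node = start
            while node is not None and node not in pos:
                pos[node] = len(path)
                path.append(node)
                r = self._records[node]
                nxt = None
                for parent in (r.sire, r.dam):
                    if parent is not None:
                        nxt = self._index[parent]
                        break
                node = nxt
            if node is not None:
                cyc = path[pos[node]:] + [node]
                return [self._records[i].animal for i in cyc]
        return []

    # -- conversion ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Canonical pedigree table; unknown parents as empty strings."""
        return pd.DataFrame(
            {
                "animal": [r.animal for r in self._records],
                "sire": [r.sire if r.sire is not None else "" for r in self._records],
                "dam": [r.dam if r.dam is not None else "" for r in self._records],
                "line": [r.line for r in self._records],
                "sex": [r.sex for r in self._records],
                "hatch": [r.hatch for r in self._records],
                "generation": [r.generation for r in self._records],
            }
        )


def _clean(token: str) -> str:
    return str(token).strip()


def read_pedigree(
    path,
    dialect: Mapping[str, str] | None = None,
    add_missing_founders: bool = False,
) -> Pedigree:
    """Read a pedigree CSV (columns ``animal,sire,dam[,line,sex,hatch,generation]``).

    Parameters
    ----------
    path : str, Path or file-like
        CSV with a header row; UTF-8.  Unknown parents are encoded as an
        empty field or ``0``.
    dialect : mapping, optional
        Maps canonical column names to the names used in the file, e.g.
        ``{"animal": "ID", "sire": "FATHER"}``.
    add_missing_founders : bool
        When True, parents referenced but not listed are auto-created as
        founder records (unknown parents, generation 0).  The default is to
        reject such files so data errors surface.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file lacks required column {col!r}")

    def parent(token: str) -> str | None:
        t = _clean(token)
        return None if t in _MISSING_TOKENS else t

    records = []
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        gen_raw = _clean(rowd.get("generation", "0"))
        records.append(
            PedigreeRecord(
                animal=_clean(rowd["animal"]),
                sire=parent(rowd["sire"]),
                dam=parent(rowd["dam"]),
                line=_clean(rowd.get("line", "")),
                sex=_clean(rowd.get("sex", "")),
                hatch=_clean(rowd.get("hatch", "")),
                generation=int(gen_raw) if gen_raw else 0,
            )
        )
    if add_missing_founders:
        known = {r.animal for r in records}
        founders = []
        seen: set[str] = set()
        for r in records:
            for p in (r.sire, r.dam):
                if p is not None and p not in known and p not in seen:
                    founders.append(PedigreeRecord(animal=p))
                    seen.add(p)
        records = founders + records
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the canonical pedigree CSV (round-trips with :func:`read_pedigree`)."""
    ped.to_frame().to_csv(path, index=False)


def topological_order(ped: Pedigree) -> Pedigree:
    """Reorder records so every parent precedes all of its offspring.

    The ordering is stable: among animals whose parents are already placed,
    input order is preserved.  Idempotent on ordered pedigrees.
    """
    n = len(ped)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, r in enumerate(ped):
        for parent in (r.sire, r.dam):
            if parent is not None:
                children[ped.index(parent)].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) < n:  # pragma: no cover - constructor already rejects cycles
        raise PedigreeError("pedigree contains an ancestry cycle")
    return Pedigree(ped[i] for i in order)


@dataclass(frozen=True)
class RelationshipMatrix:
    """A symmetric relationship (covariance-structure) matrix over animals.

    ``kind`` is one of ``"additive"``, ``"dominance"`` or ``"identity"``.
    Additive diagonals equal ``1 + F_i`` (``F_i`` the inbreeding
    coefficient); the dominance diagonal is fixed at 1 (non-inbred
    convention, as in standard animal-breeding software).
    """

    kind: str
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("matrix dimension does not match number of ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @classmethod
    def identity(cls, ids: Sequence[str]) -> "RelationshipMatrix":
        return cls("identity", tuple(ids), np.eye(len(ids)))

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, i: str, j: str) -> float:
        """Entry by animal identifiers."""
        idx = {a: k for k, a in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_triplets(self) -> pd.DataFrame:
        """Lower triangle (including diagonal) as (row_id, col_id, value)."""
        rows, cols = np.tril_indices(len(self.ids))
        return pd.DataFrame(
            {
                "row_id": [self.ids[i] for i in rows],
                "col_id": [self.ids[j] for j in cols],
                "value": self.values[rows, cols],
            }
        )

    def write_triplets(self, path) -> None:
        """Whitespace-free triplet CSV export of the lower triangle."""
        self.to_triplets().to_csv(path, index=False)


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    Requires a topologically ordered pedigree (parents before offspring);
    unknown parents contribute zero, i.e. founders are unrelated and
    non-inbred.
    """
    if not ped.is_ordered:
        raise PedigreeError(
            "pedigree must be topologically ordered; call topological_order() first"
        )
    n = len(ped)
    s, d = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        if i:
            row = np.zeros(i)
            if si >= 0:
                row += A[si, :i]
            if di >= 0:
                row += A[di, :i]
            A[i, :i] = 0.5 * row
            A[:i, i] = A[i, :i]
    return RelationshipMatrix("additive", ped.ids, A)


def dominance_relationship_matrix(
    ped: Pedigree, A: RelationshipMatrix | None = None
) -> RelationshipMatrix:
    """Dominance relationship matrix D from the pedigree and its A matrix.

    ``d_ij = 0.25 (a(s_i,s_j) a(d_i,d_j) + a(s_i,d_j) a(d_i,s_j))`` for
    animals with both parents known; off-diagonals involving an animal with
    any unknown parent are zero, and the diagonal is fixed at 1.
    """
    if A is None:
        A = additive_relationship_matrix(ped)
    if tuple(A.ids) != ped.ids:
        raise ValueError("A matrix ids do not match the pedigree")
    n = len(ped)
    s, d = ped.parent_indices()
    Av = A.values
    D = np.eye(n)
    known = (s >= 0) & (d >= 0)
    idx = np.flatnonzero(known)
    for pos, i in enumerate(idx):
        js = idx[pos + 1:]
        if js.size == 0:
            continue
        dij = 0.25 * (
            Av[s[i], s[js]] * Av[d[i], d[js]] + Av[s[i], d[js]] * Av[d[i], s[js]]
        )
        D[i, js] = dij
        D[js, i] = dij
    return RelationshipMatrix("dominance", ped.ids, D)


@dataclass(frozen=True)
class GeneDropResult:
    """Monte-Carlo relationship estimates with entrywise standard errors."""

    additive: RelationshipMatrix
    dominance: RelationshipMatrix
    additive_se: np.ndarray
    dominance_se: np.ndarray
    n_reps: int


def gene_drop_relationships(
    ped: Pedigree, n_reps: int, seed: int, chunk_size: int = 2000
) -> GeneDropResult:
    """Estimate A and D by gene dropping (Monte-Carlo IBD simulation).

    Each founder carries two globally unique alleles; every rep drops
    alleles through the pedigree by Mendelian sampling.  The additive
    relationship is estimated as twice the probability that randomly drawn
    alleles are identical by descent (equivalently, the mean IBD match
    count divided by two) and the dominance relationship as the probability
    that the two genotypes are entirely IBD as a pair.  An animal with an
    unknown parent receives a unique phantom-founder allele on that side.

    Deterministic for a given seed.  This estimator is intentionally
    independent of the tabular constructors and serves as their oracle.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not ped.is_ordered:
        raise PedigreeError("pedigree must be topologically ordered")
    n = len(ped)
    s, d = ped.parent_indices()
    rng = np.random.default_rng(seed)

    sum_cnt = np.zeros((n, n))      # sum of IBD match counts (0..4)
    sum_cnt2 = np.zeros((n, n))     # sum of squared counts
    sum_dom = np.zeros((n, n))      # sum of both-alleles-IBD indicators

    done = 0
    while done < n_reps:
        m = min(chunk_size, n_reps - done)
        al = np.empty((n, 2, m), dtype=np.int64)
        pick = np.arange(m)
        for i in range(n):
            for side, parent in ((0, s[i]), (1, d[i])):
                if parent < 0:
                    # phantom founder allele, unique to this animal/side
                    al[i, side, :] = 2 * n + 2 * i + side
                else:
                    choice = rng.integers(0, 2, size=m)
                    al[i, side, :] = al[parent, choice, pick]
        a0 = al[:, 0, :]
        a1 = al[:, 1, :]
        eq00 = a0[:, None, :] == a0[None, :, :]
        eq01 = a0[:, None, :] == a1[None, :, :]
        eq10 = a1[:, None, :] == a0[None, :, :]
        eq11 = a1[:, None, :] == a1[None, :, :]
        cnt = (
            eq00.astype(np.uint8)
            + eq01.astype(np.uint8)
            + eq10.astype(np.uint8)
            + eq11.astype(np.uint8)
        )
        dom = (eq00 & eq11) | (eq01 & eq10)
        sum_cnt += cnt.sum(axis=2)
        sum_cnt2 += (cnt.astype(np.uint16) ** 2).sum(axis=2)
        sum_dom += dom.sum(axis=2)
        done += m

    # additive per-rep value is count/2; on the diagonal this equals 1 + F-indicator
    mean_add = 0.5 * sum_cnt / n_reps
    var_add = np.maximum(0.25 * sum_cnt2 / n_reps - mean_add**2, 0.0)
    se_add = np.sqrt(var_add / n_reps)
    p_dom = sum_dom / n_reps
    se_dom = np.sqrt(np.maximum(p_dom * (1 - p_dom), 0.0) / n_reps)
    np.fill_diagonal(p_dom, 1.0)
    np.fill_diagonal(se_dom, 0.0)

    mean_add = 0.5 * (mean_add + mean_add.T)  # exact symmetry against roundoff
    return GeneDropResult(
        additive=RelationshipMatrix("additive", ped.ids, mean_add),
        dominance=RelationshipMatrix("dominance", ped.ids, p_dom),
        additive_se=0.5 * (se_add + se_add.T),
        dominance_se=0.5 * (se_dom + se_dom.T),
        n_reps=n_reps,
    )
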