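"""Pedigree handling and pedigree-derived relatedness structures.

A pedigree is the backbone of the animal model: it implies the numerator
relationship matrix A (expected additive relatedness), its sparse inverse
(the object the mixed-model equations actually need), and per-individual
inbreeding coefficients F.  All three are computed here from a validated,
topologically sorted pedigree table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

UNKNOWN = -1
_UNKNOWN_TOKENS = {"0", "NA", "", "nan", "None", "NaN", "<NA>"}

#: dense A-matrix guard: above this many individuals `amatrix` refuses to
#: allocate the full matrix and callers should work with `ainverse` instead.
DENSE_CAP = 20_000


class PedigreeError(ValueError):
    """Structural, referential, or duplication error in a pedigree."""


@dataclass
class Pedigree:
    """Validated pedigree, sorted parents-before-offspring.

    Attributes
    ----------
    ids : list of str
        Individual identifiers in topological order.
    sire, dam : ndarray of int
        Positional parent indices into ``ids``; ``UNKNOWN`` (-1) if absent.
    cohort : ndarray of int
        Birth/entry year per individual.
    population : list of str
        Population label per individual.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    cohort: np.ndarray
    population: list
    index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {iid: k for k, iid in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise PedigreeError("duplicate individual ids in pedigree")

    def __len__(self):
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def founders(self) -> np.ndarray:
        """Boolean mask: both parents unknown."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)

        def _name(ix):
            return np.where(ix == UNKNOWN, "NA", ids[np.clip(ix, 0, None)])

        return pd.DataFrame(
            {
                "id": ids,
                "sire": _name(self.sire),
                "dam": _name(self.dam),
                "cohort": self.cohort,
                "population": self.population,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _toposort(ids, sire_tok, dam_tok, cohort, population):
    """Kahn sort with deterministic tie-break (cohort, then id)."""
    n = len(ids)
    order = sorted(range(n), key=lambda k: (cohort[k], str(ids[k])))
    pos = {}
    out = []
    pending = list(order)
    # repeated passes; a valid pedigree terminates, a cycle stalls
    guard = 0
    while pending:
        progressed = []
        rest = []
        for k in pending:
            s, d = sire_tok[k], dam_tok[k]
            if (s is None or s in pos) and (d is None or d in pos):
                pos[ids[k]] = len(out)
                out.append(k)
                progressed.append(k)
            else:
                rest.append(k)
        if not progressed:
            stuck = [ids[k] for k in rest[:5]]
            raise PedigreeError(
                f"pedigree contains a cycle (self-ancestry) involving: {stuck}"
            )
        pending = rest
        guard += 1
        if guard > n + 1:  # pragma: no cover
            raise PedigreeError("topological sort failed to terminate")
    return out


def from_frame(df: pd.DataFrame) -> Pedigree:
    """Build a validated Pedigree from a dataframe with columns
    id, sire, dam, cohort, population."""
    df = df.copy()
    ids = [str(x) for x in df["id"]]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)
        dup = sorted(dup[dup.duplicated()].unique())[:5]
        raise PedigreeError(f"duplicate individual id(s): {dup}")

    def _tok(v):
        s = str(v).strip()
        return None if s in _UNKNOWN_TOKENS else s

    sire_tok = [_tok(v) for v in df["sire"]]
    dam_tok = [_tok(v) for v in df["dam"]]
    cohort = np.asarray(df["cohort"], dtype=int)
    population = [str(x) for x in df["population"]]

    for k, iid in enumerate(ids):
        if sire_tok[k] == iid or dam_tok[k] == iid:
            raise PedigreeError(f"individual {iid!r} listed as its own parent")

    # auto-insert parents that never appear as individuals, as founders of
    # the earliest cohort (field pedigrees routinely omit such rows)
    known = set(ids)
    ghosts = []
    for toks in (sire_tok, dam_tok):
        for t in toks:
            if t is not None and t not in known:
                ghosts.append(t)
                known.add(t)
    if ghosts:
        logger.warning(
            "auto-inserting %d parent-only individual(s) as founders: %s%s",
            len(ghosts), ghosts[:5], "..." if len(ghosts) > 5 else "",
        )
        first = int(cohort.min()) if len(cohort) else 0
        ids = ghosts + ids
        sire_tok = [None] * len(ghosts) + sire_tok
        dam_tok = [None] * len(ghosts) + dam_tok
        cohort = np.concatenate([np.full(len(ghosts), first, dtype=int), cohort])
        population = [population[0] if population else "NA"] * len(ghosts) + population

    order = _toposort(ids, sire_tok, dam_tok, cohort, population)
    ids_o = [ids[k] for k in order]
    pos = {iid: i for i, iid in enumerate(ids_o)}

    def _ix(toks):
        return np.array(
            [UNKNOWN if toks[k] is None else pos[toks[k]] for k in order], dtype=np.int64
        )

    ped = Pedigree(
        ids=ids_o,
        sire=_ix(sire_tok),
        dam=_ix(dam_tok),
        cohort=cohort[order],
        population=[population[k] for k in order],
    )
    # parents precede offspring by construction; assert the invariant anyway
    idx = np.arange(ped.n)
    for par in (ped.sire, ped.dam):
        m = par != UNKNOWN
        if np.any(par[m] >= idx[m]):
            raise PedigreeError("internal: topological order violated")
    return ped


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV (columns id, sire, dam, cohort, population;
    unknown parents encoded as 0, NA, or empty) and validate it."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam", "cohort", "population"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing column(s): {sorted(missing)}")
    return from_frame(df)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficient F per individual.

    F_i is the kinship of i's parents: F_i = a(sire, dam) / 2 on the
    additive-relationship scale.  Computed by memoized coancestry recursion,
    so no dense A is ever formed.  Individuals with an unknown parent get 0.
    """
    sire, dam = ped.sire, ped.dam
    memo = {}

    def kin(i, j):
        # kinship f(i,j); additive relationship a = 2f
        if i == UNKNOWN or j == UNKNOWN:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        v = memo.get(key)
        if v is not None:
            return v
        if i == j:
            v = 0.5 * (1.0 + kin(sire[i], dam[i]))
        else:
            # j is the later individual in topological order
            v = 0.5 * (kin(i, sire[j]) + kin(i, dam[j]))
        memo[key] = v
        return v

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * ped.n + 100))
    try:
        F = np.zeros(ped.n)
        for i in range(ped.n):
            if sire[i] != UNKNOWN and dam[i] != UNKNOWN:
                F[i] = kin(sire[i], dam[i])
    finally:
        sys.setrecursionlimit(old)
    return F


def amatrix(ped: Pedigree, cap: int = DENSE_CAP) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular recursion.

    a(i, j) = (a(j, sire_i) + a(j, dam_i)) / 2 for j earlier than i and
    a(i, i) = 1 + a(sire_i, dam_i) / 2; unknown parents contribute zero.
    """
    n = ped.n
    if n > cap:
        raise MemoryError(
            f"dense A for {n} individuals exceeds cap {cap}; use ainverse()"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row_s = A[s, :i] if s != UNKNOWN else 0.0
        row_d = A[d, :i] if d != UNKNOWN else 0.0
        if i:
            A[i, :i] = 0.5 * (row_s + row_d)
            A[:i, i] = A[i, :i]
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


def ainverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of individual i is
    d_i = 1/2 - (F_s + F_d)/4 (both parents known), 3/4 - F_p/4 (one
    known), or 1 (founder); A^-1 accumulates alpha_i = 1/d_i over the
    (i, sire, dam) triplets.
    """
    if F is None:
        F = inbreeding(ped)
    if len(F) != ped.n:
        raise ValueError("inbreeding vector length does not match pedigree")
    n = ped.n
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = F[s] if s != UNKNOWN else 0.0
        fd = F[d] if d != UNKNOWN else 0.0
        if s != UNKNOWN and d != UNKNOWN:
            dii = 0.5 - 0.25 * (fs + fd)
        elif s != UNKNOWN or d != UNKNOWN:
            fp = fs if s != UNKNOWN else fd
            dii = 0.75 - 0.25 * fp
        else:
            dii = 1.0
        al = 1.0 / dii
        add(i, i, al)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * al)
                add(p, i, -0.5 * al)
                add(p, p, 0.25 * al)
        if s != UNKNOWN and d != UNKNOWN:
            add(s, d, 0.25 * al)
            add(d, s, 0.25 * al)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def write_matrixmarket(mat, path) -> None:
    """Export A or A^-1 as a MatrixMarket coordinate file."""
    sp_mat = sp.coo_matrix(mat)
    from scipy.io import mmwrite

    mmwrite(str(path), sp_mat, symmetry="symmetric")
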