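"""Pedigree data model, kinship, relatedness, inbreeding, sibships, matrilines.

The pedigree is a directed acyclic graph of parent links over individually
recognised animals.  Founders (both parents unknown) are assumed unrelated and
non-inbred — the conservative convention for a study population whose
matriline founders are the females alive when monitoring began.

Kinship is computed by the tabular (recursive) method: processing individuals
parents-first,

    K(i, i) = 0.5 * (1 + K(father_i, mother_i))
    K(i, j) = 0.5 * (K(father_i, j) + K(mother_i, j))      (j already placed)

with an unknown parent contributing 0.  ``relatedness`` is the additive
(numerator) relationship r = 2 K, the convention under which an
aunt–half-niece pair scores 0.125 and adding a shared father raises the pair
to 0.375.  Wright's inbreeding coefficient of an individual is the kinship of
its parents; individuals with an unknown parent have f = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FEMALE",
    "MALE",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "CycleError",
    "UnknownIdError",
    "compute_kinship",
    "compute_inbreeding",
    "relatedness",
    "full_sibship_sizes",
    "matriline_of",
]

FEMALE = "F"
MALE = "M"

_COLUMNS = [
    "id",
    "sex",
    "birth_year",
    "death_year",
    "mother_id",
    "father_id",
    "matriline_id",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad link, sex mismatch, ...)."""


class CycleError(PedigreeError):
    """Parent links form a cycle."""


class UnknownIdError(KeyError):
    """An individual id is not present in the pedigree."""


def _norm_sex(s) -> str:
    s = str(s).strip().upper()
    if s in ("F", "FEMALE"):
        return FEMALE
    if s in ("M", "MALE"):
        return MALE
    raise PedigreeError(f"unrecognised sex {s!r}")


class Pedigree:
    """Collection of individuals keyed by id with mother/father links.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``id, sex, birth_year, death_year, mother_id, father_id,
        matriline_id``; missing entries (unknown parent, unknown year)
        are NA/empty.  ``sex`` accepts ``F``/``M`` or ``female``/``male``.
    validate : bool
        Check the structural invariants (default True).
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        df = table.copy()
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[_COLUMNS].reset_index(drop=True)
        df["id"] = df["id"].astype(str)
        df["sex"] = df["sex"].map(_norm_sex)
        for col in ("birth_year", "death_year"):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        for col in ("mother_id", "father_id", "matriline_id"):
            df[col] = df[col].astype(object)
            blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
            df.loc[blank, col] = None
            df.loc[~blank, col] = df.loc[~blank, col].astype(str)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate ids: {dupes}")

        self._df = df
        self._pos = {i: k for k, i in enumerate(df["id"])}
        n = len(df)
        self._mother = np.full(n, -1, dtype=np.int64)
        self._father = np.full(n, -1, dtype=np.int64)
        for k, (mid, fid) in enumerate(zip(df["mother_id"], df["father_id"])):
            if mid is not None:
                if mid not in self._pos:
                    raise PedigreeError(f"mother {mid!r} of {df['id'][k]!r} not in pedigree")
                self._mother[k] = self._pos[mid]
            if fid is not None:
                if fid not in self._pos:
                    raise PedigreeError(f"father {fid!r} of {df['id'][k]!r} not in pedigree")
                self._father[k] = self._pos[fid]
        if validate:
            self._validate()
        self._topo = self._topological_order()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records, validate: bool = True) -> "Pedigree":
        """Build from an iterable of dicts with the standard columns."""
        return cls(pd.DataFrame.from_records(list(records)), validate=validate)

    @classmethod
    def read_csv(cls, path, validate: bool = True) -> "Pedigree":
        return cls(pd.read_csv(path, dtype={"id": str}), validate=validate)

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    # -- basic access -----------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, iid) -> bool:
        return str(iid) in self._pos

    @property
    def ids(self) -> list[str]:
        return list(self._df["id"])

    @property
    def sexes(self) -> np.ndarray:
        return self._df["sex"].to_numpy()

    @property
    def mother_idx(self) -> np.ndarray:
        """Positional index of each mother (-1 if unknown)."""
        return self._mother

    @property
    def father_idx(self) -> np.ndarray:
        return self._father

    def position(self, iid) -> int:
        try:
            return self._pos[str(iid)]
        except KeyError:
            raise UnknownIdError(str(iid)) from None

    def sex_of(self, iid) -> str:
        return self._df["sex"].iat[self.position(iid)]

    def parents_of(self, iid) -> tuple[str | None, str | None]:
        k = self.position(iid)
        return self._df["mother_id"].iat[k], self._df["father_id"].iat[k]

    @property
    def founders(self) -> list[str]:
        mask = (self._mother < 0) & (self._father < 0)
        return list(self._df.loc[mask, "id"])

    # -- validation and ordering ------------------------------------------

    def _validate(self) -> None:
        df = self._df
        for k in range(len(df)):
            iid = df["id"].iat[k]
            m, f = self._mother[k], self._father[k]
            if m >= 0 and df["sex"].iat[m] != FEMALE:
                raise PedigreeError(f"mother of {iid!r} is not female")
            if f >= 0 and df["sex"].iat[f] != MALE:
                raise PedigreeError(f"father of {iid!r} is not male")
            by = df["birth_year"].iat[k]
            for p in (m, f):
                if p >= 0 and pd.notna(by) and pd.notna(df["birth_year"].iat[p]):
                    if not df["birth_year"].iat[p] < by:
                        raise PedigreeError(
                            f"parent {df['id'].iat[p]!r} not born before {iid!r}"
                        )

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self._df)))
        for k in range(len(self._df)):
            for p in (self._mother[k], self._father[k]):
                if p >= 0:
                    g.add_edge(p, k)
        return g

    def _topological_order(self) -> np.ndarray:
        """Parents-first order: generation depth, ties by birth_year then id."""
        g = self._graph()
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"pedigree contains a cycle through {cyc[0]}")
        depth = np.zeros(len(self._df), dtype=np.int64)
        for k in nx.topological_sort(g):
            for p in (self._mother[k], self._father[k]):
                if p >= 0:
                    depth[k] = max(depth[k], depth[p] + 1)
        by = self._df["birth_year"].to_numpy(dtype=float, na_value=np.inf)
        order = sorted(
            range(len(self._df)),
            key=lambda k: (depth[k], by[k], self._df["id"].iat[k]),
        )
        return np.asarray(order, dtype=np.int64)

    # -- derived pedigrees -------------------------------------------------

    def with_fathers(self, new_fathers: dict[str, str]) -> "Pedigree":
        """Return a copy with the given offspring assigned new sires.

        Mothers and all other metadata are untouched; this is the primitive
        behind the simulated (sire-resampled) pedigrees.
        """
        df = self._df.copy()
        pos = self._pos
        for calf, sire in new_fathers.items():
            if calf not in pos:
                raise UnknownIdError(calf)
            if sire is not None and sire not in pos:
                raise UnknownIdError(sire)
            df.loc[pos[calf], "father_id"] = sire
        return Pedigree(df, validate=False)


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients for every pair in a pedigree."""

    ids: list[str]
    values: np.ndarray  # (n, n) symmetric, diag = 0.5 (1 + f)

    def __post_init__(self):
        self._pos = {i: k for k, i in enumerate(self.ids)}

    def __getitem__(self, pair) -> float:
        i, j = pair
        try:
            return float(self.values[self._pos[str(i)], self._pos[str(j)]])
        except KeyError as e:
            raise UnknownIdError(str(e.args[0])) from None

    def relatedness(self, i, j) -> float:
        """Additive relatedness r = 2 K(i, j) for two distinct individuals."""
        if str(i) == str(j):
            raise ValueError("relatedness is defined for distinct individuals; "
                             "use the inbreeding coefficient for self-pairs")
        return 2.0 * self[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the tabular method in parents-first order."""
    n = len(ped)
    K = np.zeros((n, n))
    mo, fa = ped.mother_idx, ped.father_idx
    for i in ped._topo:
        m, f = mo[i], fa[i]
        if m >= 0 and f >= 0:
            kii = 0.5 * (1.0 + K[f, m])
        else:
            kii = 0.5
        if m >= 0 and f >= 0:
            row = 0.5 * (K[m, :] + K[f, :])
        elif m >= 0:
            row = 0.5 * K[m, :]
        elif f >= 0:
            row = 0.5 * K[f, :]
        else:
            row = np.zeros(n)
        row[i] = kii
        K[i, :] = row
        K[:, i] = row
    return KinshipMatrix(ped.ids, K)


def compute_inbreeding(ped: Pedigree, kin: KinshipMatrix | None = None) -> pd.Series:
    """Wright's f per individual: kinship of the parents, 0 if any unknown."""
    if kin is None:
        kin = compute_kinship(ped)
    mo, fa = ped.mother_idx, ped.father_idx
    f = np.zeros(len(ped))
    both = (mo >= 0) & (fa >= 0)
    f[both] = kin.values[fa[both], mo[both]]
    return pd.Series(f, index=ped.ids, name="f")


def relatedness(kin: KinshipMatrix, i, j) -> float:
    """Additive relatedness r = 2 K(i, j)."""
    return kin.relatedness(i, j)


def full_sibship_sizes(ped: Pedigree) -> tuple[list[int], float]:
    """Sizes of full sibships (offspring grouped by (mother, father) pair).

    Only offspring with both parents known enter the partition.  Returns the
    multiset of sizes and its mean (nan for an empty partition).
    """
    df = ped.to_frame()
    both = df["mother_id"].notna() & df["father_id"].notna()
    if not both.any():
        return [], float("nan")
    sizes = df.loc[both].groupby(["mother_id", "father_id"]).size()
    return sizes.tolist(), float(sizes.mean())


def matriline_of(ped: Pedigree, iid) -> str | None:
    """Terminal maternal ancestor of an individual.

    Follows mother links until a female with no known mother is reached; that
    female's id is the matriline.  The chain passes through the mother
    regardless of the focal individual's sex.  A male whose own mother is
    unknown has no traceable maternal line and gets None.
    """
    k = ped.position(iid)
    seen = set()
    while True:
        if k in seen:
            raise CycleError(f"maternal cycle through {ped.ids[k]!r}")
        seen.add(k)
        m = ped.mother_idx[k]
        if m < 0:
            if ped.sexes[k] == MALE:
                return None
            return ped.ids[k]
        k = m


def matriline_table(ped: Pedigree) -> pd.Series:
    """Matriline (terminal maternal ancestor) for every individual.

    Uses the stored matriline_id when present, otherwise traces mother links.
    """
    out = {}
    df = ped.to_frame()
    stored = dict(zip(df["id"], df["matriline_id"]))
    for iid in ped.ids:
        out[iid] = stored.get(iid) or matriline_of(ped, iid)
    return pd.Series(out, name="matriline")
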