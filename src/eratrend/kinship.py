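"""Pedigree-based numerator relationship matrix (A-matrix) and sibship summaries.

The numerator relationship matrix holds Wright's expected additive
relationships among individuals: a_ii = 1 + F_i (F_i the inbreeding
coefficient) and a_ij twice the coefficient of coancestry. It is built from
parentage records by the tabular method and is the covariance kernel (up to
sigma^2_g) of additive genetic values in the second-stage mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import PedigreeError

logger = logging.getLogger(__name__)

UNKNOWN = ""  # sentinel for an unknown parent in CSV form

PEDIGREE_COLUMNS = ["genotype", "parent1", "parent2", "release_year"]


@dataclass
class Pedigree:
    """Ordered parentage records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``genotype``, ``parent1``, ``parent2`` (empty string or NaN
        for unknown) and optional ``release_year`` (NaN for non-released
        ancestral lines).
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.records.copy()
        for col in ("parent1", "parent2"):
            if col not in df.columns:
                df[col] = UNKNOWN
            df[col] = df[col].fillna(UNKNOWN).astype(str).replace("nan", UNKNOWN)
        if "release_year" not in df.columns:
            df["release_year"] = np.nan
        df["genotype"] = df["genotype"].astype(str)
        if df["genotype"].duplicated().any():
            dups = df.loc[df["genotype"].duplicated(), "genotype"].tolist()
            raise PedigreeError(f"duplicate genotype ids in pedigree: {dups}")
        self.records = df[PEDIGREE_COLUMNS].reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.records["genotype"].tolist()

    def __len__(self) -> int:
        return len(self.records)

    def released(self) -> pd.DataFrame:
        """Records with a known release year."""
        return self.records[self.records["release_year"].notna()]

    def terminal_ids(self) -> list[str]:
        """Individuals that are nobody's parent (trial-entry candidates)."""
        parents = set(self.records["parent1"]) | set(self.records["parent2"])
        parents.discard(UNKNOWN)
        return [g for g in self.ids if g not in parents]

    def topological_order(self) -> list[str]:
        """Ids ordered parents-before-offspring; raises on cycles."""
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        known = set(self.ids)
        for row in self.records.itertuples(index=False):
            for p in (row.parent1, row.parent2):
                if p != UNKNOWN and p in known:
                    g.add_edge(p, row.genotype)
        try:
            order = list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible as exc:
            raise PedigreeError("pedigree contains a cycle") from exc
        return order

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype={"genotype": str, "parent1": str, "parent2": str},
                         keep_default_na=True)
        return cls(df)


def build_nrm(pedigree: Pedigree) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular method.

    Individuals are processed parents-first; for individual i with parents
    (p, q):  a_ij = (a_jp + a_jq) / 2 for earlier j, and
    a_ii = 1 + a_pq / 2.  Unknown parents contribute zero, i.e. they are
    treated as unique unrelated, non-inbred founders.  A parent id that never
    appears as a genotype row is treated the same way, with a logged warning.

    Returns a symmetric labelled DataFrame ordered like the pedigree records.
    """
    order = pedigree.topological_order()
    pos = {g: k for k, g in enumerate(order)}
    rec = pedigree.records.set_index("genotype")
    known = set(pedigree.ids)

    n = len(order)
    a = np.zeros((n, n))
    for i, gid in enumerate(order):
        p1, p2 = rec.loc[gid, "parent1"], rec.loc[gid, "parent2"]
        for p in (p1, p2):
            if p != UNKNOWN and p not in known:
                logger.warning(
                    "pedigree: parent %r of %r not in records; treated as founder",
                    p, gid,
                )
        i1 = pos.get(p1, None) if p1 in known else None
        i2 = pos.get(p2, None) if p2 in known else None
        for j in range(i):
            v = 0.0
            if i1 is not None:
                v += a[j, i1]
            if i2 is not None:
                v += a[j, i2]
            a[i, j] = a[j, i] = 0.5 * v
        a[i, i] = 1.0 + (0.5 * a[i1, i2] if (i1 is not None and i2 is not None) else 0.0)

    # restore the original record order
    idx = [pos[g] for g in pedigree.ids]
    a = a[np.ix_(idx, idx)]
    return pd.DataFrame(a, index=pedigree.ids, columns=pedigree.ids)


def count_sibships(nrm: pd.DataFrame, threshold: float = 0.0) -> int:
    """Number of relatedness clusters in an NRM.

    Builds the graph whose edges join pairs with a_ij > ``threshold`` and
    counts connected components (isolated individuals count as singleton
    clusters). This is an explicit proxy for the visual "sibship" counts one
    reads off an NRM heatmap.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(nrm.index)
    arr = nrm.to_numpy()
    ii, jj = np.where(np.triu(arr, k=1) > threshold)
    for i, j in zip(ii, jj):
        g.add_edge(nrm.index[i], nrm.index[j])
    return nx.number_connected_components(g)


def nrm_to_csv(nrm: pd.DataFrame, path) -> None:
    nrm.to_csv(path, index_label="genotype")


def nrm_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="genotype")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def subset_nrm(nrm: pd.DataFrame, ids) -> pd.DataFrame:
    """Principal submatrix for the given genotype ids (order preserved)."""
    missing = [g for g in ids if g not in nrm.index]
    if missing:
        raise KeyError(f"genotypes absent from NRM: {missing}")
    return nrm.loc[list(ids), list(ids)]
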