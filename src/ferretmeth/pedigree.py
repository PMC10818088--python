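"""Pedigrees and the additive relationship matrix.

The additive (numerator) relationship matrix A gives the expected proportion
of alleles shared identical-by-descent between individuals; its diagonal is
1 + F with F the inbreeding coefficient.  A (or a matrix proportional to it)
is the covariance of the kinship random effect in the binomial mixed model —
the scale is absorbed by the genetic variance component, so A is used
directly by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

PEDIGREE_COLUMNS = ["id", "sire", "dam"]


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree TSV (columns id, sire, dam; 'NA' marks founders)."""
    ped = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
    if missing:
        raise FormatError(f"pedigree file missing columns: {missing}")
    ped = ped[PEDIGREE_COLUMNS].replace({"NA": None})
    return ped.where(pd.notna(ped), None)


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    out = pedigree.fillna("NA")
    out.to_csv(path, sep="\t", index=False)


def _toposort(pedigree: pd.DataFrame) -> list[str]:
    """Order ids so parents precede offspring; raise on cycles/unknown parents."""
    ids = list(pedigree["id"])
    if len(set(ids)) != len(ids):
        raise FormatError("duplicated individual ID in pedigree")
    parents = {
        row["id"]: tuple(p for p in (row["sire"], row["dam"]) if p is not None)
        for _, row in pedigree.iterrows()
    }
    known = set(ids)
    for ind, pars in parents.items():
        for p in pars:
            if p not in known:
                raise FormatError(f"unknown parent ID {p!r} for individual {ind!r}")
    order: list[str] = []
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    for root in ids:
        if state.get(root) == 1:
            continue
        stack = [(root, iter(parents[root]))]
        state[root] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if state.get(p) == 0:
                    raise FormatError(f"pedigree cycle involving {p!r}")
                if state.get(p) != 1:
                    state[p] = 0
                    stack.append((p, iter(parents[p])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                state[node] = 1
                order.append(node)
    return order


@dataclass
class KinshipMatrix:
    """Symmetric additive relationship matrix with aligned individual IDs."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        if (np.diag(self.values) < 1.0 - 1e-10).any():
            raise ValueError("kinship diagonal must be >= 1 (1 + F)")
        if (self.values < -1e-10).any():
            raise ValueError("kinship entries must be non-negative")
        eigmin = np.linalg.eigvalsh(self.values).min()
        if eigmin < -1e-8:
            raise ValueError(f"kinship matrix not PSD (min eigenvalue {eigmin:g})")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids) -> "KinshipMatrix":
        ids = list(ids)
        idx = [self.ids.index(i) for i in ids]
        return KinshipMatrix(ids, self.values[np.ix_(idx, idx)])

    def for_samples(self, individual_of_sample: dict[str, str]) -> pd.DataFrame:
        """Expand to sample level: K[s, t] = A[ind(s), ind(t)].

        Samples from the same individual share its genetic value, so rows are
        duplicated; the result stays positive semi-definite.
        """
        samples = list(individual_of_sample)
        pos = {ind: k for k, ind in enumerate(self.ids)}
        idx = [pos[individual_of_sample[s]] for s in samples]
        vals = self.values[np.ix_(idx, idx)]
        return pd.DataFrame(vals, index=samples, columns=samples)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.8f")


def additive_relationship(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Tabular-method additive relationship matrix from a pedigree.

    Founders get a_ii = 1; for non-founder j with parents s, d:
    a_ij = (a_is + a_id) / 2 for earlier i, and a_jj = 1 + a_sd / 2.
    Raises on cycles or unknown parent IDs.
    """
    order = _toposort(pedigree)
    parents = {
        row["id"]: (row["sire"], row["dam"]) for _, row in pedigree.iterrows()
    }
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for j, ind in enumerate(order):
        sire, dam = parents[ind]
        si = pos[sire] if sire is not None else None
        di = pos[dam] if dam is not None else None
        for i in range(j):
            a = 0.0
            if si is not None:
                a += 0.5 * A[i, si]
            if di is not None:
                a += 0.5 * A[i, di]
            A[i, j] = A[j, i] = a
        if si is not None and di is not None:
            A[j, j] = 1.0 + 0.5 * A[si, di]
        else:
            A[j, j] = 1.0
    # return in the pedigree's original row order
    original = list(pedigree["id"])
    idx = [pos[i] for i in original]
    return KinshipMatrix(original, A[np.ix_(idx, idx)])
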