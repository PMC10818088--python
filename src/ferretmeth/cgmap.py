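"""CGmap methylome I/O, coverage filtering, uniting, and summary statistics.

A methylome is held as a :class:`pandas.DataFrame` with one row per cytosine and
columns ``chrom, base, pos, context, dinucleotide, level, m_count, total``
(the CGmap dialect: tab-separated, 1-based positions, ``base`` is C or G as a
strand proxy, ``context`` one of CG/CHG/CHH).  United multi-sample count data
live in :class:`CountMatrix`, the central object consumed by the association
scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

CGMAP_COLUMNS = [
    "chrom",
    "base",
    "pos",
    "context",
    "dinucleotide",
    "level",
    "m_count",
    "total",
]

VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH"})
SITE_KEY = ["chrom", "pos", "context"]


def read_cgmap(path) -> pd.DataFrame:
    """Read and validate a CGmap file.

    Raises :class:`FormatError` (naming the 1-based line number) for unknown
    context tokens, ``m_count > total``, negative counts, or a methylation
    level inconsistent with the counts.  An empty file yields an empty
    methylome with a logged warning.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CGMAP_COLUMNS,
            dtype={
                "chrom": str,
                "base": str,
                "pos": np.int64,
                "context": str,
                "dinucleotide": str,
                "level": np.float64,
                "m_count": np.int64,
                "total": np.int64,
            },
        )
    except pd.errors.EmptyDataError:
        logger.warning("CGmap file %s is empty", path)
        return pd.DataFrame(columns=CGMAP_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed CGmap content: {exc}") from exc

    bad = ~df["context"].isin(VALID_CONTEXTS)
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise FormatError(
            f"{path}: line {line}: unknown context token "
            f"{df.loc[df.index[bad][0], 'context']!r}"
        )
    bad = (df["m_count"] > df["total"]) | (df["m_count"] < 0)
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise FormatError(f"{path}: line {line}: m_count outside [0, total]")
    covered = df["total"] > 0
    bad = covered & (
        (df["level"] - df["m_count"] / df["total"].where(covered, 1)).abs() > 1e-6
    )
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise FormatError(f"{path}: line {line}: level inconsistent with counts")
    return df


def write_cgmap(methylome: pd.DataFrame, path) -> None:
    """Write a methylome in CGmap dialect (level printed to 6 decimals)."""
    out = methylome.copy()
    out["level"] = out["level"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", header=False, index=False, columns=CGMAP_COLUMNS)


def filter_coverage(methylome: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Retain records with ``total >= min_coverage`` (inclusive threshold)."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    return methylome[methylome["total"] >= min_coverage].reset_index(drop=True)


@dataclass
class CountMatrix:
    """Per-CpG methylated / total read counts across united samples.

    ``m`` and ``total`` are aligned DataFrames indexed by the site key
    (chrom, pos, context) — chrom lexicographic, pos ascending — with one
    column per sample.
    """

    m: pd.DataFrame
    total: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            self.samples = list(self.m.columns)
        if list(self.m.columns) != list(self.total.columns):
            raise ValueError("m and total columns disagree")
        if not self.m.index.equals(self.total.index):
            raise ValueError("m and total site indexes disagree")

    @property
    def n_sites(self) -> int:
        return self.m.shape[0]

    @property
    def n_samples(self) -> int:
        return self.m.shape[1]

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.m[samples].copy(), self.total[samples].copy(), samples)

    def site_frame(self) -> pd.DataFrame:
        """Site keys as a plain DataFrame (chrom, pos, context)."""
        return self.m.index.to_frame(index=False)


def unite(methylomes: dict[str, pd.DataFrame]) -> CountMatrix:
    """Intersect site sets across samples and assemble a :class:`CountMatrix`.

    ``methylomes`` maps sample ID to a (typically coverage-filtered)
    methylome.  Only sites present in every sample are retained; counts are
    preserved exactly.
    """
    if len(methylomes) == 0:
        raise ValueError("unite requires at least one methylome")
    ids = list(methylomes)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample ID in unite input")

    m_cols, t_cols = [], []
    for sid, meth in methylomes.items():
        dup = meth.duplicated(subset=SITE_KEY)
        if dup.any():
            raise FormatError(f"sample {sid}: duplicated site keys")
        indexed = meth.set_index(SITE_KEY)
        m_cols.append(indexed["m_count"].rename(sid))
        t_cols.append(indexed["total"].rename(sid))
    m = pd.concat(m_cols, axis=1, join="inner")
    total = pd.concat(t_cols, axis=1, join="inner")
    m = m.sort_index()
    total = total.reindex(m.index)
    if m.shape[0] == 0:
        logger.warning("unite: site intersection across %d samples is empty", len(ids))
    return CountMatrix(m.astype(np.int64), total.astype(np.int64), ids)


def methylation_frequency(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell methylation frequency m_count / total (fractions in [0, 1])."""
    totals = matrix.total.to_numpy()
    if (totals == 0).any():
        raise ValueError("methylation frequency undefined at total = 0")
    return matrix.m / matrix.total


def conversion_efficiency(
    methylome: pd.DataFrame, control_chrom: str, weighted: bool = False
) -> float:
    """Bisulfite conversion efficiency from an unmethylated spike-in genome.

    Returns 1 minus the mean methylation frequency over sites on
    ``control_chrom``.  The default averages per-site MF unweighted; with
    ``weighted=True`` the mean is read-weighted (pooled counts).
    """
    control = methylome[methylome["chrom"] == control_chrom]
    control = control[control["total"] > 0]
    if control.shape[0] == 0:
        raise ValueError(f"no covered sites on control chromosome {control_chrom!r}")
    if weighted:
        mf = control["m_count"].sum() / control["total"].sum()
    else:
        mf = (control["m_count"] / control["total"]).mean()
    return 1.0 - float(mf)


def context_summary(methylome: pd.DataFrame) -> dict:
    """Mean MF per sequence context plus the CG-only record subset.

    Returns ``{"mean_mf": {context: mean or None}, "cg_only": DataFrame}``.
    Contexts absent from the methylome map to None.  Downstream matrix
    construction consumes only the CG subset.
    """
    covered = methylome[methylome["total"] > 0]
    mf = covered["m_count"] / covered["total"]
    means: dict[str, float | None] = {}
    for ctx in sorted(VALID_CONTEXTS):
        sel = covered["context"] == ctx
        means[ctx] = float(mf[sel].mean()) if sel.any() else None
    cg_only = methylome[methylome["context"] == "CG"].reset_index(drop=True)
    return {"mean_mf": means, "cg_only": cg_only}


def export_mf_matrix(matrix: CountMatrix, path) -> None:
    """Write the MF matrix as TSV with site-key columns plus one per sample."""
    mf = methylation_frequency(matrix)
    out = mf.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
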