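"""Quality control: PCA of methylation frequency and PC-covariate screening.

Samples are the observations and CpG sites the variables; sites are centred
(no unit-variance scaling by default) and decomposed by SVD, mirroring a
plain prcomp-style PCA.  Principal-component scores are then screened
against design covariates — Kruskal-Wallis for categorical covariates,
Pearson correlation (t on n - 2 df) for continuous ones — to surface
structure such as tissue type or conversion-rate gradients before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Sample scores (samples x components) and variance-explained fractions."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    n_dropped_zero_variance: int = 0

    def __post_init__(self):
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if (evr < -1e-12).any():
            raise ValueError("negative variance-explained fraction")
        if evr.sum() > 1.0 + 1e-9:
            raise ValueError("variance-explained fractions sum beyond 1")
        if (np.diff(evr) > 1e-12).any():
            raise ValueError("variance-explained must be non-increasing")
        self.explained_variance_ratio = evr

    def plot(self, color_by: pd.Series | None = None, ax=None):
        """Scatter of PC1 vs PC2, optionally coloured by a sample label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs, ys = self.scores.iloc[:, 0], self.scores.iloc[:, 1]
        if color_by is None:
            ax.scatter(xs, ys)
        else:
            for label, idx in color_by.groupby(color_by).groups.items():
                ax.scatter(xs.loc[idx], ys.loc[idx], label=str(label))
            ax.legend()
        ax.set_xlabel(f"PC1 ({self.explained_variance_ratio[0]:.1%})")
        ax.set_ylabel(f"PC2 ({self.explained_variance_ratio[1]:.1%})")
        return ax


def pca_methylation(mf_matrix: pd.DataFrame, scale: bool = False) -> PcaResult:
    """PCA of a methylation-frequency matrix (sites x samples).

    Sites with zero variance across samples are dropped (logged).  Scores are
    reproducible up to a sign flip per component.
    """
    if mf_matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if mf_matrix.isna().any().any():
        raise ValueError("PCA input contains missing cells; unite first")

    X = mf_matrix.to_numpy(dtype=float).T  # samples x sites
    var = X.var(axis=0)
    keep = var > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("pca_methylation: dropped %d zero-variance sites", dropped)
    X = X[:, keep]
    if X.shape[1] == 0:
        # e.g. identical samples: no variance anywhere, all scores zero
        n = mf_matrix.shape[1]
        n_comp = max(min(n - 1, mf_matrix.shape[0]), 1)
        cols = [f"PC{k + 1}" for k in range(n_comp)]
        return PcaResult(
            scores=pd.DataFrame(0.0, index=mf_matrix.columns, columns=cols),
            explained_variance_ratio=np.zeros(n_comp),
            n_dropped_zero_variance=dropped,
        )
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)

    n_comp = min(X.shape[0] - 1, X.shape[1])
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = (U * s)[:, :n_comp]
    total_var = (s**2).sum()
    evr = (s[:n_comp] ** 2) / total_var if total_var > 0 else np.zeros(n_comp)
    cols = [f"PC{k + 1}" for k in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=mf_matrix.columns, columns=cols),
        explained_variance_ratio=evr,
        n_dropped_zero_variance=dropped,
    )


@dataclass
class CovariateTest:
    covariate: str
    kind: str
    statistic: float
    df: float
    pvalue: float
    p_at_floor: bool = False


def pc_covariate_association(
    scores: pd.Series, covariate: pd.Series, kind: str
) -> CovariateTest:
    """Test one PC against one covariate.

    ``kind='categorical'``: Kruskal-Wallis H with chi-square p on
    (levels - 1) df.  ``kind='continuous'``: Pearson r converted to t on
    (n - 2) df, two-sided.  A perfectly collinear continuous covariate is
    reported at the machine floor with ``p_at_floor`` set.
    """
    if len(scores) != len(covariate):
        raise ValueError("scores and covariate lengths differ")
    name = covariate.name or "covariate"
    if kind == "categorical":
        groups = [
            np.asarray(scores[covariate == lev], dtype=float)
            for lev in pd.unique(covariate)
        ]
        if len(groups) < 2:
            raise ValueError("categorical covariate needs >= 2 levels")
        stat, p = stats.kruskal(*groups)
        return CovariateTest(name, kind, float(stat), float(len(groups) - 1), float(p))
    if kind == "continuous":
        x = np.asarray(covariate, dtype=float)
        y = np.asarray(scores, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("constant continuous covariate")
        n = len(x)
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= 1.0 - 1e-12:
            return CovariateTest(name, kind, float("inf"), float(n - 2),
                                 float(np.nextafter(0, 1)), p_at_floor=True)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        return CovariateTest(name, kind, float(t), float(n - 2), float(p))
    raise ValueError(f"unknown covariate kind {kind!r}")


def screen_pcs(
    pca: PcaResult,
    covariates: pd.DataFrame,
    kinds: dict[str, str],
    n_pcs: int = 5,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Test the first ``n_pcs`` PCs against each covariate; tidy results.

    Raw p-values by default; optional BH adjustment across the whole screen.
    """
    rows = []
    n_pcs = min(n_pcs, pca.scores.shape[1])
    for pc in pca.scores.columns[:n_pcs]:
        for cov, kind in kinds.items():
            res = pc_covariate_association(pca.scores[pc], covariates[cov], kind)
            rows.append(
                {
                    "pc": pc,
                    "covariate": cov,
                    "kind": kind,
                    "statistic": res.statistic,
                    "df": res.df,
                    "pvalue": res.pvalue,
                }
            )
    out = pd.DataFrame(rows)
    if bh_adjust and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["pvalue_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def resolve_replicates(
    replicate_pairs: list[tuple[str, str]],
    efficiencies: dict[str, float],
    mf_matrix: pd.DataFrame,
) -> tuple[list[str], pd.DataFrame]:
    """Resolve technical replicate pairs against a united MF matrix.

    Keeps the member with the higher conversion efficiency (ties keep the
    lexicographically first sample ID, logged) and reports the Pearson
    concordance of methylation frequency between pair members over shared
    sites.  Returns (retained sample columns, concordance table).
    """
    cols = list(mf_matrix.columns)
    drop = []
    rows = []
    for a, b in replicate_pairs:
        for sid in (a, b):
            if sid not in cols:
                raise ValueError(f"replicate sample {sid} missing from matrix")
            if sid not in efficiencies:
                raise ValueError(f"no efficiency for replicate sample {sid}")
        r = float(np.corrcoef(mf_matrix[a], mf_matrix[b])[0, 1])
        ea, eb = efficiencies[a], efficiencies[b]
        if ea > eb:
            keep, lose = a, b
        elif eb > ea:
            keep, lose = b, a
        else:
            keep, lose = sorted((a, b))
            logger.info("replicate tie between %s and %s; keeping %s", a, b, keep)
        drop.append(lose)
        rows.append({"kept": keep, "dropped": lose, "concordance_r": r})
    retained = [c for c in cols if c not in set(drop)]
    return retained, pd.DataFrame(rows)
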