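"""Per-CpG binomial mixed model with a kinship random effect.

For one CpG site with methylated counts y_j out of r_j reads in sample j,

    y_j ~ Binomial(r_j, pi_j)
    logit(pi_j) = mu + covars_j' gamma + x_j beta + g_j + e_j
    g ~ N(0, sigma_g2 * K),   e_j ~ N(0, sigma_e2) independent,

where K is the (sample-expanded) additive relationship matrix.  The model is
fitted by penalized quasi-likelihood (PQL): iterate a working linear mixed
model on z = eta + (y - r pi)/(r pi (1 - pi)) with weights w = r pi (1 - pi),
estimating (sigma_g2, sigma_e2) by restricted likelihood on a bounded
log scale at each step, until the fixed effects stabilise.  Wald p-values
come from beta/se against a standard normal.  With both variance components
pinned to zero the procedure reduces exactly to IRLS for a plain binomial
GLM.

The module follows the statsmodels model/results convention:
:class:`BinomialMixedModel` holds data, ``fit()`` returns
:class:`BinomialMixedModelResults`; :class:`MethylationAssociation` scans a
:class:`~ferretmeth.cgmap.CountMatrix` site by site and its ``fit()`` returns
:class:`AssociationScanResults` with the per-site table, genomic-inflation
summary, and QQ diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

_LOG_BOUNDS = (np.log(1e-8), np.log(10.0))


@dataclass
class AssociationConfig:
    """Settings for a per-tissue association scan.

    ``predictor`` is one of avg_litter_size / sperm_count_per_ml /
    testes_firmness; it is standardized (mean 0, sd 1) before fitting, so
    reported betas are per-sd effects (the transform is recorded in the
    results).  ``var_bounds`` bound both variance components on the logit
    scale; ``clip`` bounds the working probabilities away from 0 and 1.
    """

    predictor: str = "avg_litter_size"
    covariates: tuple[str, ...] = ("age_at_sampling",)
    max_iterations: int = 50
    tolerance: float = 1e-5
    clip: float = 1e-6
    var_bounds: tuple[float, float] = (1e-8, 10.0)
    use_kinship: bool = True

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (0.0 < self.clip < 0.5):
            raise ValueError("clip must be in (0, 0.5)")


@dataclass
class SiteAssociationResult:
    """Per-site effect estimate and variance components."""

    site: tuple
    beta: float | None
    se: float | None
    wald_p: float | None
    sigma_g2: float | None
    sigma_e2: float | None
    converged: bool
    skip_reason: str = "none"


class BinomialMixedModel:
    """Binomial mixed model for one site (statsmodels-style model object).

    Parameters
    ----------
    methylated, total : array-like
        Per-sample methylated and total read counts (total >= 1).
    exog : array-like or DataFrame
        Fixed-effect design matrix including the intercept column.
    kinship : ndarray or DataFrame, optional
        Sample-level covariance of the genetic random effect (K).  Defaults
        to the identity.
    """

    def __init__(self, methylated, total, exog, kinship=None, exog_names=None):
        self.y = np.asarray(methylated, dtype=float)
        self.r = np.asarray(total, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.X = exog
        n = len(self.y)
        if len(self.r) != n or self.X.shape[0] != n:
            raise ValueError("lengths of counts and design disagree")
        if (self.r < 1).any():
            raise ValueError("every sample needs total >= 1")
        if (self.y < 0).any() or (self.y > self.r).any():
            raise ValueError("methylated counts outside [0, total]")
        if kinship is None:
            kinship = np.eye(n)
        self.K = np.asarray(getattr(kinship, "values", kinship), dtype=float)
        if self.K.shape != (n, n):
            raise ValueError("kinship matrix not aligned to samples")
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )

    # -- restricted likelihood of the working LMM ---------------------------

    def _reml_nll(self, log_s, D, z):
        sg, se = np.exp(log_s)
        n = len(z)
        V = sg * self.K + np.diag(se + D)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        Vi_X = cho_solve((c, low), self.X)
        Vi_z = cho_solve((c, low), z)
        XtViX = self.X.T @ Vi_X
        try:
            beta = np.linalg.solve(XtViX, self.X.T @ Vi_z)
        except np.linalg.LinAlgError:
            return np.inf
        resid = z - self.X @ beta
        quad = resid @ cho_solve((c, low), resid)
        logdet_V = 2.0 * np.log(np.diag(c)).sum()
        sign, logdet_X = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return 0.5 * (logdet_V + logdet_X + quad)

    def _estimate_variances(self, D, z, start):
        lo, hi = _LOG_BOUNDS
        # coarse log-grid start, then bounded quasi-Newton refinement
        grid = np.log(np.array([1e-6, 0.01, 0.1, 0.5, 2.0]))
        best = (np.inf, np.clip(np.log(start), lo, hi))
        for a in grid:
            for b in grid:
                val = self._reml_nll((a, b), D, z)
                if val < best[0]:
                    best = (val, np.array([a, b]))
        x0 = best[1]
        res = optimize.minimize(
            self._reml_nll,
            x0,
            args=(D, z),
            method="L-BFGS-B",
            bounds=[(lo, hi), (lo, hi)],
        )
        log_s = res.x if res.fun <= best[0] else best[1]
        return tuple(np.exp(log_s))

    def _gls(self, sg, se, D, z):
        V = sg * self.K + np.diag(se + D)
        c, low = cho_factor(V, lower=True)
        Vi_X = cho_solve((c, low), self.X)
        Vi_z = cho_solve((c, low), z)
        XtViX = self.X.T @ Vi_X
        cov = np.linalg.inv(XtViX)
        beta = cov @ (self.X.T @ Vi_z)
        resid = z - self.X @ beta
        # BLUP of the combined random effect g + e
        Sigma = sg * self.K + se * np.eye(len(z))
        u = Sigma @ cho_solve((c, low), resid)
        return beta, cov, u

    def _kr_covariance(self, sg, se, D):
        """Kenward-Roger adjusted covariance of the fixed effects.

        Per-site REML variance components at small n are noisy; the plain
        GLS covariance ignores that uncertainty and understates the se.  The
        adjustment adds the first-order correction
        Phi + 2 Phi [sum_ij W_ij (Q_ij - P_i Phi P_j)] Phi with G_1 = K,
        G_2 = I (the covariance is linear in the components, so the
        second-derivative term vanishes).  Falls back to the plain
        covariance if the variance-component information is singular.
        """
        n = len(D)
        V = sg * self.K + np.diag(se + D)
        Vi = np.linalg.inv(V)
        Vi_X = Vi @ self.X
        XtViX = self.X.T @ Vi_X
        Phi = np.linalg.inv(XtViX)
        P_proj = Vi - Vi_X @ Phi @ Vi_X.T
        G = (self.K, np.eye(n))
        # REML information of (sigma_g2, sigma_e2)
        info = np.empty((2, 2))
        PG = [P_proj @ Gi for Gi in G]
        for i in range(2):
            for j in range(2):
                info[i, j] = 0.5 * np.trace(PG[i] @ PG[j])
        try:
            W = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return Phi
        if not np.isfinite(W).all():
            return Phi
        Pmats = [-Vi_X.T @ Gi @ Vi_X for Gi in G]
        mid = np.zeros_like(Phi)
        for i in range(2):
            for j in range(2):
                Qij = Vi_X.T @ G[i] @ Vi @ G[j] @ Vi_X
                mid += W[i, j] * (Qij - Pmats[i] @ Phi @ Pmats[j])
        adjusted = Phi + 2.0 * Phi @ mid @ Phi
        # guard against a non-PSD correction at degenerate sites
        if (np.diag(adjusted) <= 0).any():
            return Phi
        return adjusted

    def fit(
        self,
        sigma_g2: float | None = None,
        sigma_e2: float | None = None,
        max_iter: int = 50,
        tol: float = 1e-6,
        clip: float = 1e-6,
    ) -> "BinomialMixedModelResults":
        """PQL fit; pass both sigmas to pin the variance components.

        Pinning both to zero reproduces a plain binomial GLM (IRLS).
        """
        pinned = sigma_g2 is not None and sigma_e2 is not None
        sg = 0.1 if sigma_g2 is None else float(sigma_g2)
        se_var = 0.1 if sigma_e2 is None else float(sigma_e2)

        p0 = np.clip((self.y + 0.5) / (self.r + 1.0), clip, 1 - clip)
        eta = logit(p0)
        beta_prev = np.full(self.X.shape[1], np.inf)
        beta = beta_prev
        cov = None
        converged = False
        for _ in range(max_iter):
            pi = np.clip(expit(eta), clip, 1 - clip)
            w = self.r * pi * (1.0 - pi)
            z = eta + (self.y - self.r * pi) / w
            D = 1.0 / w
            if not pinned:
                sg, se_var = self._estimate_variances(D, z, (max(sg, 1e-6), max(se_var, 1e-6)))
            beta, cov, u = self._gls(sg, se_var, D, z)
            eta = self.X @ beta + u
            if np.max(np.abs(beta - beta_prev)) < tol:
                converged = True
                break
            beta_prev = beta
        if not pinned:
            # account for variance-component uncertainty in the se
            pi = np.clip(expit(eta), clip, 1 - clip)
            w = self.r * pi * (1.0 - pi)
            cov = self._kr_covariance(sg, se_var, 1.0 / w)
        bse = np.sqrt(np.diag(cov))
        return BinomialMixedModelResults(
            model=self,
            params=beta,
            bse=bse,
            sigma_g2=sg,
            sigma_e2=se_var,
            converged=converged,
        )


@dataclass
class BinomialMixedModelResults:
    """Estimates, uncertainties, and diagnostics for one fitted site."""

    model: BinomialMixedModel
    params: np.ndarray
    bse: np.ndarray
    sigma_g2: float
    sigma_e2: float
    converged: bool

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        lines = [
            "Binomial mixed model (PQL)",
            f"  n samples: {len(self.model.y)}   converged: {self.converged}",
            f"  sigma_g2: {self.sigma_g2:.4g}   sigma_e2: {self.sigma_e2:.4g}",
            f"  {'term':<18}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>10}",
        ]
        for name, b, s, z, p in zip(
            self.model.exog_names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            lines.append(f"  {name:<18}{b:>10.4f}{s:>10.4f}{z:>8.2f}{p:>10.3g}")
        return "\n".join(lines)


def fit_site_bmm(
    y,
    r,
    x,
    covars=None,
    K=None,
    config: AssociationConfig | None = None,
    sigma_g2: float | None = None,
    sigma_e2: float | None = None,
) -> SiteAssociationResult:
    """Fit one site and package the predictor's effect.

    ``x`` is the predictor column (already on whatever scale the caller
    wants betas reported on); ``covars`` optional extra columns.  Monomorphic
    sites (all y = 0 or all y = r) and constant predictors are skipped.
    """
    config = config or AssociationConfig()
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.all(y == 0) or np.all(y == r):
        return SiteAssociationResult(
            (), None, None, None, None, None, False, "monomorphic"
        )
    if np.ptp(x) == 0:
        return SiteAssociationResult(
            (), None, None, None, None, None, False, "constant-predictor"
        )
    cols = [np.ones_like(x), x]
    names = ["intercept", "predictor"]
    if covars is not None:
        covars = np.atleast_2d(np.asarray(covars, dtype=float))
        if covars.shape[0] != len(x):
            covars = covars.T
        for j in range(covars.shape[1]):
            cols.append(covars[:, j])
            names.append(f"covar{j}")
    X = np.column_stack(cols)
    model = BinomialMixedModel(y, r, X, kinship=K, exog_names=names)
    res = model.fit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        max_iter=config.max_iterations,
        tol=config.tolerance,
        clip=config.clip,
    )
    return SiteAssociationResult(
        site=(),
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        wald_p=float(res.pvalues[1]),
        sigma_g2=float(res.sigma_g2),
        sigma_e2=float(res.sigma_e2),
        converged=bool(res.converged),
        skip_reason="none",
    )


class MethylationAssociation:
    """Site-by-site association scan over a united count matrix.

    Parameters
    ----------
    matrix : CountMatrix
        United, coverage-filtered counts (CG sites only).
    phenotypes : DataFrame
        One row per sample (indexable by sample_id) providing the predictor
        and covariates; ``testes_firmness`` is derived from ``testes_status``.
    kinship : DataFrame, optional
        Sample-level K aligned to the matrix columns.
    """

    def __init__(self, matrix, phenotypes: pd.DataFrame, kinship=None,
                 config: AssociationConfig | None = None):
        self.matrix = matrix
        self.config = config or AssociationConfig()
        pheno = phenotypes.set_index("sample_id") if "sample_id" in phenotypes else phenotypes
        missing = [s for s in matrix.samples if s not in pheno.index]
        if missing:
            raise ValueError(f"phenotype missing for samples: {missing}")
        self.phenotypes = pheno.loc[matrix.samples]
        if kinship is not None:
            kvals = getattr(kinship, "values", kinship)
            if isinstance(kinship, pd.DataFrame):
                kinship = kinship.loc[matrix.samples, matrix.samples].to_numpy()
            else:
                kinship = np.asarray(kvals, dtype=float)
        self.kinship = kinship

        x_raw = self._predictor_values()
        sd = x_raw.std()
        if sd == 0:
            self.x = np.zeros_like(x_raw)
        else:
            self.x = (x_raw - x_raw.mean()) / sd
        self.predictor_center = float(x_raw.mean())
        self.predictor_scale = float(sd)
        self.covars = self._covariate_matrix()

    def _predictor_values(self) -> np.ndarray:
        name = self.config.predictor
        if name == "testes_firmness":
            from .samples import firmness_numeric

            vals = firmness_numeric(self.phenotypes["testes_status"])
        else:
            vals = self.phenotypes[name]
        arr = np.asarray(vals, dtype=float)
        if np.isnan(arr).any():
            raise ValueError(f"predictor {name!r} undefined for some samples")
        return arr

    def _covariate_matrix(self) -> np.ndarray | None:
        if not self.config.covariates:
            return None
        cols = []
        for c in self.config.covariates:
            v = np.asarray(self.phenotypes[c], dtype=float)
            cols.append(v - v.mean())
        return np.column_stack(cols)

    def fit(self, progress: bool = False) -> "AssociationScanResults":
        rows = []
        m_all = self.matrix.m.to_numpy()
        t_all = self.matrix.total.to_numpy()
        sites = list(self.matrix.m.index)
        for i, site in enumerate(sites):
            res = fit_site_bmm(
                m_all[i],
                t_all[i],
                self.x,
                covars=self.covars,
                K=self.kinship if self.config.use_kinship else None,
                config=self.config,
            )
            chrom, pos, context = site
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "context": context,
                    "beta": res.beta,
                    "se": res.se,
                    "p": res.wald_p,
                    "sigma_g2": res.sigma_g2,
                    "sigma_e2": res.sigma_e2,
                    "converged": res.converged,
                    "skip_reason": res.skip_reason,
                }
            )
            if progress and (i + 1) % 200 == 0:
                logger.info("association scan: %d/%d sites", i + 1, len(sites))
        table = pd.DataFrame(rows)
        return AssociationScanResults(
            table=table,
            config=self.config,
            predictor_center=self.predictor_center,
            predictor_scale=self.predictor_scale,
        )


@dataclass
class AssociationScanResults:
    """Association table plus calibration diagnostics for one analysis."""

    table: pd.DataFrame
    config: AssociationConfig
    predictor_center: float
    predictor_scale: float

    @property
    def fitted(self) -> pd.DataFrame:
        return self.table[self.table["skip_reason"] == "none"]

    def inflation_factor(self) -> float:
        """Genomic inflation: median observed chi-square over its theoretical
        median under the null."""
        p = self.fitted["p"].dropna().to_numpy()
        if len(p) == 0:
            return float("nan")
        chi2 = stats.chi2.isf(p, df=1)
        return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))

    def qq(self) -> "QqDiagnostics":
        return qq_diagnostics(self.fitted["p"].dropna().to_numpy())

    def summary(self) -> str:
        n = len(self.table)
        fitted = self.fitted
        skipped = self.table["skip_reason"].value_counts().to_dict()
        skipped.pop("none", None)
        lines = [
            f"Association scan: predictor={self.config.predictor} "
            f"(standardized; center={self.predictor_center:.4g}, "
            f"scale={self.predictor_scale:.4g})",
            f"  sites: {n}  fitted: {len(fitted)}  skipped: {skipped or 0}",
            f"  non-converged: {int((~fitted['converged']).sum())}",
            f"  genomic inflation factor: {self.inflation_factor():.3f}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class QqDiagnostics:
    """Expected-vs-observed -log10 p quantiles and a deviation summary."""

    expected: np.ndarray
    observed: np.ndarray
    slope: float
    direction: str

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.expected, self.observed, s=8)
        lim = max(self.expected.max(), self.observed.max())
        ax.plot([0, lim], [0, lim], color="grey", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax


def qq_diagnostics(p_values) -> QqDiagnostics:
    """Pair sorted observed p-values with uniform order statistics.

    The slope (least squares through the origin on the -log10 scale) is ~1
    for well-calibrated p-values, >1 under inflation, <1 under deflation.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no finite p-values")
    m = len(p)
    expected = -np.log10(np.arange(1, m + 1) / (m + 1.0))[::-1]
    observed = -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))[::-1]
    denom = (expected**2).sum()
    slope = float((expected * observed).sum() / denom) if denom > 0 else float("nan")
    if slope > 1.05:
        direction = "inflation"
    elif slope < 0.95:
        direction = "deflation"
    else:
        direction = "calibrated"
    return QqDiagnostics(expected, observed, slope, direction)


def fit_all_sites(
    matrix,
    phenotypes: pd.DataFrame,
    kinship=None,
    config: AssociationConfig | None = None,
    progress: bool = False,
) -> AssociationScanResults:
    """Functional wrapper: scan every site of a count matrix."""
    return MethylationAssociation(matrix, phenotypes, kinship, config).fit(progress)
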