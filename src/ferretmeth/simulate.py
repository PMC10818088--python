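"""Synthetic RRBS methylomes with kinship structure and phenotype effects.

Emulates the statistical structure the association pipeline assumes: a small
pedigreed cohort sampled across up to three tissues, over-dispersed binomial
methylation counts at moderate depth, a logit-scale per-site generative model

    logit(pi) = baseline + x * beta_true + age_c * age_gamma
                + tissue_shift + g + e,

with g drawn jointly over individuals with covariance sigma_g2 * A (A the
additive relationship matrix), e independent N(0, sigma_e2), and an
unmethylated lambda spike-in chromosome whose apparent methylation reflects
only bisulfite conversion failure.  The predictor x is standardized (mean 0,
sd 1 over the design) before the effect is applied, so ``beta_causal`` is on
the same standardized scale the association scan reports.

Each CG site draws from its own random stream keyed by (seed, scaffold,
site), so subsetting sites never perturbs the remaining sites' data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import InvalidConfigError
from .pedigree import additive_relationship
from .samples import load_reference_table

LAMBDA_CHROM = "lambda"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the profiled ex situ design: ~20x depth, CG methylation
    centred at 0.5 versus ~0.003 outside CG, conversion efficiency 0.994,
    sperm hypermethylated and testes mildly hypomethylated relative to blood.
    """

    n_individuals: int = 9
    tissues: dict[str, float] = field(
        default_factory=lambda: {"Blood": 0.0, "Testes": -0.3, "Sperm": 0.5}
    )
    n_sites: int = 300
    n_scaffolds: int = 3
    depth_mean: float = 20.0
    baseline_mf_cg: float = 0.5
    mf_chh_chg: float = 0.003
    frac_causal: float = 0.05
    beta_causal: float = 1.0
    sigma_g2: float = 0.3
    sigma_e2: float = 0.5
    age_gamma: float = 0.05
    conversion_efficiency: float = 0.994
    n_lambda_sites: int = 200
    n_noncg_sites: int = 50
    baseline_logit_sd: float = 1.5
    predictor: str = "avg_litter_size"
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "baseline_mf_cg": self.baseline_mf_cg,
            "mf_chh_chg": self.mf_chh_chg,
            "frac_causal": self.frac_causal,
            "conversion_efficiency": self.conversion_efficiency,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise InvalidConfigError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_individuals": self.n_individuals,
            "n_sites": self.n_sites,
            "n_scaffolds": self.n_scaffolds,
            "n_lambda_sites": self.n_lambda_sites,
        }
        for name, value in counts.items():
            if value < 1:
                raise InvalidConfigError(f"{name} must be positive, got {value}")
        if self.n_noncg_sites < 0:
            raise InvalidConfigError("n_noncg_sites must be >= 0")
        if self.depth_mean <= 0:
            raise InvalidConfigError("depth_mean must be positive")
        if min(self.sigma_g2, self.sigma_e2) < 0:
            raise InvalidConfigError("variance components must be >= 0")
        if not self.tissues:
            raise InvalidConfigError("at least one tissue required")


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    seed: int,
    offspring_per_generation: int | None = None,
) -> pd.DataFrame:
    """Random multi-generation pedigree (columns id, sire, dam).

    Each generation adds offspring whose sire and dam are two distinct
    earlier individuals; founders have no parents.
    """
    if n_founders < 2:
        raise InvalidConfigError("need at least 2 founders")
    if n_generations < 0:
        raise InvalidConfigError("n_generations must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    n_off = offspring_per_generation or n_founders
    rows = [(f"I{i + 1}", None, None) for i in range(n_founders)]
    for _ in range(n_generations):
        pool = [r[0] for r in rows]
        for _ in range(n_off):
            sire, dam = rng.choice(len(pool), size=2, replace=False)
            rows.append((f"I{len(rows) + 1}", pool[sire], pool[dam]))
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


def reference_design(individuals: list[str]) -> list[tuple[str, str]]:
    """Map 9 individuals onto the packaged 22-sample / 3-tissue pattern."""
    ref = load_reference_table()
    studbooks = sorted(ref["studbook_no"].unique())
    if len(individuals) != len(studbooks):
        raise InvalidConfigError(
            f"reference design needs {len(studbooks)} individuals, "
            f"got {len(individuals)}"
        )
    mapping = dict(zip(studbooks, individuals))
    return [
        (mapping[row.studbook_no], row.tissue)
        for row in ref.itertuples()
    ]


@dataclass
class SimulatedDataset:
    methylomes: dict[str, pd.DataFrame]
    phenotypes: pd.DataFrame
    pedigree: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _site_positions(rng: np.random.Generator, n_sites: int) -> np.ndarray:
    """RRBS-like positions: short within-fragment gaps, long between-fragment
    jumps, so runs of nearby CpGs exist for cluster calling."""
    # one (n, 2) draw so the gap sequence is a stable prefix in n_sites
    u = rng.random((n_sites, 2))
    gaps = np.where(
        u[:, 0] < 0.7,
        2 + np.floor(u[:, 1] * 38.0),
        200 + np.floor(u[:, 1] * 1800.0),
    ).astype(np.int64)
    return 100 + np.cumsum(gaps)


def _draw_phenotypes(
    rng: np.random.Generator,
    design: list[tuple[str, str]],
) -> pd.DataFrame:
    individuals = sorted({ind for ind, _ in design})
    # lifetime average litter size: zero-inflated over (0, 5]
    litter = {
        ind: 0.0 if rng.random() < 0.3 else round(float(rng.uniform(1.0, 5.0)), 1)
        for ind in individuals
    }
    rows = []
    tissue_counter: dict[str, int] = {}
    base_date = pd.Timestamp("2018-01-01")
    for ind, tissue in design:
        k = tissue_counter.get(tissue, 0) + 1
        tissue_counter[tissue] = k
        sid = f"{tissue[0]}{k}_{ind}"
        age = int(rng.integers(2, 7))
        firm = "Firm" if rng.random() < 0.65 else "Not_Firm"
        if tissue == "Sperm":
            count = round(float(rng.lognormal(math.log(400.0), 0.8)), 1)
        else:
            count = None
        date = base_date + pd.Timedelta(days=int(rng.integers(0, 720)))
        rows.append(
            {
                "sample_id": sid,
                "studbook_no": ind,
                "name": ind,
                "tissue": tissue,
                "collection_date": date,
                "age_at_sampling": age,
                "avg_litter_size": litter[ind],
                "testes_status": firm,
                "sperm_count_per_ml": count,
                "replicate_flag": False,
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(
    config: SimulationConfig,
    pedigree: pd.DataFrame,
    design: list[tuple[str, str]] | None = None,
) -> SimulatedDataset:
    """Generate per-sample CGmap methylomes, phenotypes, and a truth table.

    ``design`` is a list of (individual, tissue) pairs; by default the last
    ``n_individuals`` pedigree members are crossed with every tissue.
    Identical config and seed give byte-identical output.
    """
    config.validate()
    if pedigree.shape[0] == 0:
        raise InvalidConfigError("pedigree is empty")
    ped_ids = list(pedigree["id"])
    if config.n_individuals > len(ped_ids):
        raise InvalidConfigError("pedigree smaller than n_individuals")
    individuals = ped_ids[-config.n_individuals:]
    if design is None:
        design = [(ind, t) for ind in individuals for t in config.tissues]
    for ind, tissue in design:
        if ind not in ped_ids:
            raise InvalidConfigError(f"design individual {ind!r} not in pedigree")
        if tissue not in config.tissues:
            raise InvalidConfigError(f"design tissue {tissue!r} not in config")
    if len(design) == 0:
        raise InvalidConfigError("empty sample design")

    pheno_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    phenotypes = _draw_phenotypes(pheno_rng, design)
    samples = list(phenotypes["sample_id"])
    sample_ind = list(phenotypes["studbook_no"])
    design_inds = sorted(set(sample_ind))

    A = additive_relationship(pedigree).subset(design_inds)
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(len(design_inds)))
    ind_pos = {ind: k for k, ind in enumerate(design_inds)}
    sample_ind_idx = np.array([ind_pos[i] for i in sample_ind])

    # standardized predictor and centred age (the generative fixed effects)
    x_raw = phenotypes[config.predictor].astype(float).to_numpy()
    if np.isnan(x_raw).any():
        raise InvalidConfigError(
            f"predictor {config.predictor!r} undefined for part of the design"
        )
    sd = x_raw.std()
    x = (x_raw - x_raw.mean()) / sd if sd > 0 else np.zeros_like(x_raw)
    age = phenotypes["age_at_sampling"].to_numpy(dtype=float)
    age_c = age - age.mean()
    shift = phenotypes["tissue"].map(config.tissues).to_numpy(dtype=float)

    # adjust the baseline-logit mean so that E[MF] ~ baseline_mf_cg despite
    # the logistic-normal smearing from baseline spread + random effects
    var_total = (
        config.baseline_logit_sd**2
        + config.sigma_g2 * float(np.diag(A.values).mean())
        + config.sigma_e2
    )
    mu_base = logit(config.baseline_mf_cg) * math.sqrt(1.0 + math.pi * var_total / 8.0)

    n_samp = len(samples)
    records: dict[str, list[dict]] = {sid: [] for sid in samples}
    truth_rows = []

    def trunc_poisson(rng, mean, size):
        d = rng.poisson(mean, size=size)
        while (d == 0).any():
            zero = d == 0
            d[zero] = rng.poisson(mean, size=int(zero.sum()))
        return d

    def emit(sid, chrom, pos, context, dinuc, m, t):
        records[sid].append(
            {
                "chrom": chrom,
                "base": "C",
                "pos": int(pos),
                "context": context,
                "dinucleotide": dinuc,
                "level": m / t,
                "m_count": int(m),
                "total": int(t),
            }
        )

    fail = 1.0 - config.conversion_efficiency
    for scaf_i in range(config.n_scaffolds):
        chrom = f"scaffold_{scaf_i + 1}"
        pos_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 5, scaf_i))
        )
        positions = _site_positions(pos_rng, config.n_sites)
        for site_i in range(config.n_sites):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 2, scaf_i, site_i))
            )
            baseline = mu_base + config.baseline_logit_sd * rng.standard_normal()
            causal = rng.random() < config.frac_causal
            beta = config.beta_causal if causal else 0.0
            g = (L @ rng.standard_normal(len(design_inds))) * math.sqrt(
                config.sigma_g2
            )
            e = rng.standard_normal(n_samp) * math.sqrt(config.sigma_e2)
            eta = baseline + x * beta + age_c * config.age_gamma + shift
            eta = eta + g[sample_ind_idx] + e
            pi = expit(eta)
            depth = trunc_poisson(rng, config.depth_mean, n_samp)
            m_true = rng.binomial(depth, pi)
            m_obs = m_true + rng.binomial(depth - m_true, fail)
            for j, sid in enumerate(samples):
                emit(sid, chrom, positions[site_i], "CG", "CG", m_obs[j], depth[j])
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(positions[site_i]),
                    "context": "CG",
                    "is_causal": bool(causal),
                    "beta_true": beta,
                    "baseline_logit": baseline,
                }
            )
        # sparse non-CG background at mf_chh_chg
        for k in range(config.n_noncg_sites):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, 4, scaf_i, k))
            )
            pos = int(positions[-1] + 100 + 37 * (k + 1))
            context = "CHH" if k % 2 == 0 else "CHG"
            dinuc = "CA" if context == "CHH" else "CT"
            depth = trunc_poisson(rng, config.depth_mean, n_samp)
            m_true = rng.binomial(depth, config.mf_chh_chg)
            m_obs = m_true + rng.binomial(depth - m_true, fail)
            for j, sid in enumerate(samples):
                emit(sid, chrom, pos, context, dinuc, m_obs[j], depth[j])

    # unmethylated lambda spike-in: apparent methylation = conversion failure
    for site_i in range(config.n_lambda_sites):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3, site_i)))
        pos = 50 + 23 * site_i
        depth = trunc_poisson(rng, config.depth_mean, n_samp)
        m_obs = rng.binomial(depth, fail)
        for j, sid in enumerate(samples):
            emit(sid, LAMBDA_CHROM, pos, "CG", "CG", m_obs[j], depth[j])

    methylomes = {
        sid: pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
        for sid, rows in records.items()
    }
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(methylomes, phenotypes, pedigree, truth, config)


def write_dataset(dataset: SimulatedDataset, directory) -> dict:
    """Write one CGmap per sample plus phenotype/pedigree/truth TSVs.

    Returns a manifest of written paths.  An empty dataset raises before any
    file is created.
    """
    from pathlib import Path

    from .cgmap import write_cgmap
    from .pedigree import write_pedigree

    if not dataset.methylomes or dataset.phenotypes.shape[0] == 0:
        raise InvalidConfigError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"cgmap": {}, "tables": {}}
    for sid, meth in dataset.methylomes.items():
        path = directory / f"{sid}.cgmap"
        write_cgmap(meth, path)
        manifest["cgmap"][sid] = str(path)

    pheno = dataset.phenotypes.copy()
    pheno["tissue"] = pheno["tissue"].where(~pheno["replicate_flag"], pheno["tissue"] + "*")
    pheno["collection_date"] = pd.to_datetime(pheno["collection_date"]).dt.strftime(
        "%m_%d_%Y"
    )
    pheno["sperm_count_per_ml"] = pheno["sperm_count_per_ml"].map(
        lambda v: "n/a" if pd.isna(v) else f"{v}"
    )
    pheno = pheno.drop(columns=["replicate_flag"])
    pheno_path = directory / "phenotypes.tsv"
    pheno.to_csv(pheno_path, sep="\t", index=False)
    manifest["tables"]["phenotypes"] = str(pheno_path)

    ped_path = directory / "pedigree.tsv"
    write_pedigree(dataset.pedigree, ped_path)
    manifest["tables"]["pedigree"] = str(ped_path)

    truth_path = directory / "truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.8f")
    manifest["tables"]["truth"] = str(truth_path)
    return manifest


def simulate_annotation(
    config: SimulationConfig, genes_per_scaffold: int = 4
) -> tuple[str, list[str]]:
    """Deterministic toy GFF3 annotation covering the simulated scaffolds.

    Genes are laid down over the position range the site generator uses, with
    alternating strand and two exons each.  Returns (gff3 text, gene ids).
    """
    lines = ["##gff-version 3"]
    gene_ids = []
    for scaf_i in range(config.n_scaffolds):
        chrom = f"scaffold_{scaf_i + 1}"
        pos_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 5, scaf_i))
        )
        span = int(_site_positions(pos_rng, config.n_sites)[-1]) + 500
        width = max(span // (genes_per_scaffold + 1), 400)
        for k in range(genes_per_scaffold):
            gid = f"GENE{scaf_i + 1}_{k + 1}"
            gene_ids.append(gid)
            start = 1 + k * width + width // 4
            end = start + width // 2
            strand = "+" if k % 2 == 0 else "-"
            exon1 = (start, start + width // 8)
            exon2 = (end - width // 8, end)
            lines.append(
                f"{chrom}\ttoy\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
            lines.append(
                f"{chrom}\ttoy\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}"
            )
            for xi, (a, b) in enumerate((exon1, exon2)):
                lines.append(
                    f"{chrom}\ttoy\texon\t{a}\t{b}\t.\t{strand}\t.\t"
                    f"ID={gid}.t1.e{xi + 1};Parent={gid}.t1"
                )
    return "\n".join(lines) + "\n", gene_ids


def simulate_gene_sets(gene_ids: list[str], n_terms: int, seed: int) -> str:
    """Toy GMT gene-set collection over the supplied gene universe."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 6)))
    lines = []
    for t in range(n_terms):
        size = int(rng.integers(2, max(3, len(gene_ids) // 2 + 1)))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        lines.append("\t".join([f"TERM:{t + 1:04d}", f"toy term {t + 1}", *members]))
    return "\n".join(lines) + "\n"


def simulate_interactions(gene_ids: list[str], seed: int) -> pd.DataFrame:
    """Toy undirected interaction edges with confidences in [0, 1]."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    rows = []
    for i, a in enumerate(gene_ids):
        for b in gene_ids[i + 1:]:
            if rng.random() < 0.4:
                rows.append((a, b, round(float(rng.uniform(0.3, 1.0)), 3)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
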