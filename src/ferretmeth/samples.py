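"""Sample/phenotype metadata handling.

Parses the study-design table (one row per banked sample: tissue type,
collection date, age at sampling, lifetime average litter size, testes status,
electroejaculation sperm count per mL) and computes design summaries,
replicate resolution, and reproductive arithmetic.  A transcription of the
22-sample ex situ black-footed ferret design ships with the package as a
fixture (``ferretmeth.samples.load_reference_table``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FormatError

ALLOWED_TISSUES = ("Blood", "Testes", "Sperm")
TABLE_COLUMNS = [
    "sample_id",
    "studbook_no",
    "name",
    "tissue",
    "collection_date",
    "age_at_sampling",
    "avg_litter_size",
    "testes_status",
    "sperm_count_per_ml",
]


def read_samples_table(path) -> pd.DataFrame:
    """Read and validate a sample/phenotype TSV.

    A trailing ``*`` on the tissue value marks an RRBS replicate; it is
    stripped into the boolean ``replicate_flag`` column.  ``sperm_count_per_ml``
    must be present exactly on Sperm rows ('n/a' elsewhere).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"samples table missing columns: {missing}")

    df = df.copy()
    df["replicate_flag"] = df["tissue"].str.endswith("*")
    df["tissue"] = df["tissue"].str.rstrip("*")
    bad = ~df["tissue"].isin(ALLOWED_TISSUES)
    if bad.any():
        raise FormatError(
            f"unknown tissue label {df.loc[bad, 'tissue'].iloc[0]!r} "
            f"(sample {df.loc[bad, 'sample_id'].iloc[0]})"
        )

    df["collection_date"] = pd.to_datetime(df["collection_date"], format="%m_%d_%Y")
    df["age_at_sampling"] = df["age_at_sampling"].astype(int)
    df["avg_litter_size"] = df["avg_litter_size"].astype(float)
    if (df["avg_litter_size"] < 0).any():
        raise FormatError("avg_litter_size must be >= 0")

    status = df["testes_status"].fillna("n/a")
    bad = ~status.isin(["Firm", "Not_Firm", "n/a"])
    if bad.any():
        raise FormatError(f"unknown testes_status {status[bad].iloc[0]!r}")

    raw_count = df["sperm_count_per_ml"].fillna("n/a")
    is_sperm = df["tissue"] == "Sperm"
    has_count = raw_count != "n/a"
    if (has_count & ~is_sperm).any():
        sid = df.loc[has_count & ~is_sperm, "sample_id"].iloc[0]
        raise FormatError(f"sperm count on non-Sperm sample {sid}")
    if (is_sperm & ~has_count).any():
        sid = df.loc[is_sperm & ~has_count, "sample_id"].iloc[0]
        raise FormatError(f"missing sperm count on Sperm sample {sid}")
    df["sperm_count_per_ml"] = pd.to_numeric(raw_count.replace("n/a", None))
    return df


def load_reference_table() -> pd.DataFrame:
    """The packaged 22-sample, 9-individual, 3-tissue study design."""
    ref = resources.files("ferretmeth.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        return read_samples_table(path)


def firmness_numeric(status: pd.Series) -> pd.Series:
    """Encode testes firmness Firm=1, Not_Firm=0 as a numeric predictor."""
    mapping = {"Firm": 1.0, "Not_Firm": 0.0}
    bad = ~status.isin(mapping)
    if bad.any():
        raise ValueError(f"cannot encode firmness value {status[bad].iloc[0]!r}")
    return status.map(mapping)


def resolve_replicate_pairs(
    records: pd.DataFrame,
    replicate_pairs: list[tuple[str, str]],
    efficiencies: dict[str, float],
) -> tuple[list[str], list[str]]:
    """Keep, per replicate pair, the copy with higher conversion efficiency.

    Ties keep the lexicographically first sample ID.  Returns
    (retained sample ids over the whole table, dropped ids).
    """
    dropped = []
    for a, b in replicate_pairs:
        for sid in (a, b):
            if sid not in set(records["sample_id"]):
                raise ValueError(f"replicate sample {sid} not in table")
            if sid not in efficiencies:
                raise ValueError(f"no conversion efficiency for replicate {sid}")
        ea, eb = efficiencies[a], efficiencies[b]
        if ea > eb:
            dropped.append(b)
        elif eb > ea:
            dropped.append(a)
        else:
            dropped.append(max(a, b))
    retained = [s for s in records["sample_id"] if s not in set(dropped)]
    return retained, dropped


def summarize_samples(
    records: pd.DataFrame,
    replicate_pairs: list[tuple[str, str]] | None = None,
    efficiencies: dict[str, float] | None = None,
) -> dict:
    """Design summary: per-tissue counts, individuals, tissue coverage.

    When replicate pairs are given, the pair member with the higher supplied
    conversion efficiency is retained before counting.
    """
    df = records
    if replicate_pairs:
        if efficiencies is None:
            raise ValueError("replicate pairs supplied without efficiencies")
        retained, dropped = resolve_replicate_pairs(df, replicate_pairs, efficiencies)
        df = df[df["sample_id"].isin(retained)]
    else:
        dropped = []

    per_tissue = df["tissue"].value_counts().to_dict()
    tissues_per_ind = df.groupby("studbook_no")["tissue"].nunique()
    testes = df[df["tissue"] == "Testes"]
    return {
        "n_samples": int(df.shape[0]),
        "n_per_tissue": {t: int(per_tissue.get(t, 0)) for t in ALLOWED_TISSUES},
        "n_individuals": int(df["studbook_no"].nunique()),
        "n_individuals_with_testes": int(testes["studbook_no"].nunique()),
        "testes_status_counts": testes["testes_status"].value_counts().to_dict(),
        "min_tissue_types_per_individual": int(tissues_per_ind.min()),
        "dropped_replicates": dropped,
    }


@dataclass
class ReproductiveSummary:
    mean_lifetime_offspring: float
    median_lifetime_offspring: float | None
    mean_litter_size: float
    implied_litters_ratio: float


def reproductive_summary(
    offspring: list[float] | None = None,
    litter_sizes: list[float] | None = None,
    mean_lifetime_offspring: float | None = None,
    mean_litter_size: float | None = None,
    median_lifetime_offspring: float | None = None,
) -> ReproductiveSummary:
    """Lifetime reproductive arithmetic for proven breeding males.

    Accepts either raw per-male records (lifetime offspring counts and litter
    sizes) or printed aggregates.  The implied litters ratio — the lifetime
    observed average litter count per male — is mean offspring divided by mean
    litter size, rounded to 2 decimals.
    """
    if offspring is not None:
        mean_lifetime_offspring = float(pd.Series(offspring).mean())
        median_lifetime_offspring = float(pd.Series(offspring).median())
    if litter_sizes is not None:
        mean_litter_size = float(pd.Series(litter_sizes).mean())
    if mean_lifetime_offspring is None or mean_litter_size is None:
        raise ValueError("need records or printed aggregates")
    if mean_litter_size == 0:
        raise ValueError("mean litter size is zero")
    ratio = round(mean_lifetime_offspring / mean_litter_size, 2)
    return ReproductiveSummary(
        mean_lifetime_offspring=mean_lifetime_offspring,
        median_lifetime_offspring=median_lifetime_offspring,
        mean_litter_size=mean_litter_size,
        implied_litters_ratio=ratio,
    )
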