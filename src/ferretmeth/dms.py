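"""Dual-percentile DMS calling, DMcluster aggregation, and Venn overlaps.

A differentially methylated site (DMS) is a CpG whose effect size falls in
the 1st or 99th percentile of the per-analysis beta distribution AND whose
p-value falls in the lowest 1st percentile.  Quantiles use linear
interpolation between order statistics over the non-skipped sites of that
analysis, and ties at a threshold are included.  Significant DMS are then
aggregated into DMclusters: maximal runs on one scaffold with consecutive
inter-cytosine gaps strictly below 40 bp; clusters with three or more
members feed the gene-network stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DmsSet:
    """Significant sites for one analysis, with the thresholds applied."""

    label: str
    sites: pd.DataFrame  # chrom, pos, context, beta, p (sorted by chrom, pos)
    beta_low: float
    beta_high: float
    p_threshold: float

    def __len__(self) -> int:
        return self.sites.shape[0]

    def site_keys(self) -> set[tuple]:
        return set(
            zip(self.sites["chrom"], self.sites["pos"], self.sites["context"])
        )

    def to_bed(self, path) -> None:
        """BED export, 0-based half-open; score = -log10 p."""
        out = pd.DataFrame(
            {
                "chrom": self.sites["chrom"],
                "start": self.sites["pos"] - 1,
                "end": self.sites["pos"],
                "name": self.label,
                "score": -np.log10(np.clip(self.sites["p"], 1e-300, None)),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


def select_outliers(
    association_table: pd.DataFrame,
    label: str = "analysis",
    beta_q: tuple[float, float] = (0.01, 0.99),
    p_q: float = 0.01,
    rank_cutoff: bool = False,
) -> DmsSet:
    """Call DMS by the dual-percentile rule over one analysis.

    Thresholds are linear-interpolation quantiles over non-skipped sites;
    both criteria are required jointly and comparisons are inclusive.  With
    ``rank_cutoff`` the p criterion becomes a strict rank cut at the lowest
    1% of sites instead of a quantile threshold.
    """
    fitted = association_table[association_table["skip_reason"] == "none"]
    fitted = fitted.dropna(subset=["beta", "p"])
    if fitted.shape[0] < 2:
        raise ValueError("need >= 2 non-skipped sites to define quantiles")

    beta = fitted["beta"].to_numpy(dtype=float)
    p = fitted["p"].to_numpy(dtype=float)
    b_lo = float(np.quantile(beta, beta_q[0]))
    b_hi = float(np.quantile(beta, beta_q[1]))
    p_thr = float(np.quantile(p, p_q))

    beta_mask = (beta <= b_lo) | (beta >= b_hi)
    if rank_cutoff:
        k = max(int(np.ceil(p_q * len(p))), 1)
        order = np.argsort(p, kind="stable")
        p_mask = np.zeros(len(p), dtype=bool)
        p_mask[order[:k]] = True
    else:
        p_mask = p <= p_thr
    selected = fitted[beta_mask & p_mask]
    selected = selected.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return DmsSet(label, selected[["chrom", "pos", "context", "beta", "p"]],
                  b_lo, b_hi, p_thr)


@dataclass
class DMCluster:
    """A maximal run of DMS with consecutive gaps < max_gap on one scaffold."""

    chrom: str
    positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> tuple[int, int]:
        return (self.positions[0], self.positions[-1])


@dataclass
class ClusterSet:
    clusters: list[DMCluster]
    network_subset: list[DMCluster] = field(default_factory=list)

    def to_bed(self, path) -> None:
        rows = [
            {
                "chrom": c.chrom,
                "start": c.span[0] - 1,
                "end": c.span[1],
                "name": f"n={c.size}",
            }
            for c in self.clusters
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def call_dmclusters(
    dms: DmsSet | pd.DataFrame, max_gap: int = 40, min_sites: int = 3
) -> ClusterSet:
    """Single linear scan per scaffold: a new cluster starts when the gap to
    the previous DMS is >= max_gap (strict < keeps the run) or the scaffold
    changes.  ``network_subset`` holds clusters with >= min_sites members."""
    sites = dms.sites if isinstance(dms, DmsSet) else dms
    ordered = sites.sort_values(["chrom", "pos"])
    if not ordered.index.equals(sites.index):
        logger.warning("call_dmclusters: input was unsorted; sorted internally")

    clusters: list[DMCluster] = []
    cur_chrom, cur_positions = None, []
    for chrom, pos in zip(ordered["chrom"], ordered["pos"]):
        if cur_chrom == chrom and cur_positions and pos - cur_positions[-1] < max_gap:
            cur_positions.append(int(pos))
        else:
            if cur_positions:
                clusters.append(DMCluster(cur_chrom, tuple(cur_positions)))
            cur_chrom, cur_positions = chrom, [int(pos)]
    if cur_positions:
        clusters.append(DMCluster(cur_chrom, tuple(cur_positions)))
    subset = [c for c in clusters if c.size >= min_sites]
    return ClusterSet(clusters, subset)


def overlap_sets(labeled_sets: dict[str, set]) -> dict[str, int]:
    """Counts for every region of the 2- or 3-set Venn partition.

    Region keys join member labels with '&' (e.g. 'blood&testes' is the
    region in exactly those two sets).  Disjoint region counts sum to the
    union size.
    """
    labels = list(labeled_sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError("overlap_sets handles 2 or 3 sets")
    union = set().union(*labeled_sets.values())
    counts: dict[str, int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = set(combo)
            region = set(union)
            for lab in labels:
                if lab in inside:
                    region &= labeled_sets[lab]
                else:
                    region -= labeled_sets[lab]
            counts["&".join(combo)] = len(region)
    return counts


def write_venn_json(counts: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
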