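"""Genomic annotation of DMS and DMclusters.

Sites are labelled promoter / exon / intron / intergenic against a gene
annotation (GFF3 or BED12), with precedence promoter > exon > intron.  The
promoter is the 2,000 bp window immediately upstream of each transcript's
TSS on its strand (clipped at the scaffold start); a symmetric +-2 kb window
is available behind a flag.  Intervals are stored 0-based half-open
internally; CGmap coordinates arriving 1-based are converted at the query
boundary and all user-facing reports stay 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError

logger = logging.getLogger(__name__)

PROMOTER_LENGTH = 2000
LABELS = ("promoter", "exon", "intron", "intergenic")


@dataclass
class FeatureIndex:
    """Per-scaffold interval trees for gene spans, exons, and promoters.

    Interval data payloads are gene IDs.  ``promoter_length`` is recorded for
    the manifest; trees are 0-based half-open.
    """

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    exons: dict[str, IntervalTree] = field(default_factory=dict)
    promoters: dict[str, IntervalTree] = field(default_factory=dict)
    promoter_length: int = PROMOTER_LENGTH

    def _add(self, trees: dict[str, IntervalTree], chrom, start0, end0, gene_id):
        if end0 <= start0:
            return
        trees.setdefault(chrom, IntervalTree()).addi(start0, end0, gene_id)

    def add_transcript(
        self,
        chrom: str,
        start0: int,
        end0: int,
        strand: str,
        gene_id: str,
        exons0: list[tuple[int, int]],
        symmetric_promoter: bool = False,
    ) -> None:
        """Register one transcript (coordinates 0-based half-open)."""
        if strand not in {"+", "-"}:
            raise FormatError(f"missing/invalid strand for {gene_id!r}")
        self._add(self.genes, chrom, start0, end0, gene_id)
        for a, b in exons0:
            self._add(self.exons, chrom, a, b, gene_id)
        L = self.promoter_length
        if strand == "+":
            tss = start0
            windows = [(max(tss - L, 0), tss)]
        else:
            tss = end0  # TSS is the last base; upstream lies to the right
            windows = [(tss, tss + L)]
        if symmetric_promoter:
            windows = [(max(tss - L, 0), tss + L)]
        for a, b in windows:
            self._add(self.promoters, chrom, a, b, gene_id)

    def query(self, chrom: str, pos1: int) -> tuple[str, list[str]]:
        """Label one site (1-based position); returns (label, gene ids)."""
        p0 = pos1 - 1
        prom = self.promoters.get(chrom)
        if prom:
            hits = prom[p0]
            if hits:
                return "promoter", sorted({h.data for h in hits})
        ex = self.exons.get(chrom)
        if ex:
            hits = ex[p0]
            if hits:
                return "exon", sorted({h.data for h in hits})
        gn = self.genes.get(chrom)
        if gn:
            hits = gn[p0]
            if hits:
                return "intron", sorted({h.data for h in hits})
        return "intergenic", []

    def known_scaffold(self, chrom: str) -> bool:
        return chrom in self.genes or chrom in self.promoters


def _parse_gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def build_feature_index(
    path, symmetric_promoter: bool = False, promoter_length: int = PROMOTER_LENGTH
) -> FeatureIndex:
    """Build a :class:`FeatureIndex` from GFF3 or BED12.

    GFF3 gene/mRNA/exon features are related through Parent attributes
    (transcripts of one gene are unioned implicitly by sharing the gene ID);
    a BED12 line is one transcript whose blocks are its exons.
    """
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _index_from_bed12(path, symmetric_promoter, promoter_length)
    return _index_from_gff3(path, symmetric_promoter, promoter_length)


def _index_from_gff3(path, symmetric_promoter, promoter_length) -> FeatureIndex:
    import gffutils

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: cannot parse GFF3: {exc}") from exc

    index = FeatureIndex(promoter_length=promoter_length)

    def gene_of(feature):
        cur = feature
        seen = set()
        while True:
            parents = list(db.parents(cur, featuretype="gene"))
            if parents:
                return parents[0].id
            up = list(db.parents(cur))
            up = [u for u in up if u.id not in seen]
            if not up:
                return cur.id
            seen.add(cur.id)
            cur = up[0]

    transcripts: dict[str, dict] = {}
    for ftype in ("mRNA", "transcript"):
        for tr in db.features_of_type(ftype):
            transcripts[tr.id] = {
                "chrom": tr.seqid,
                "start0": tr.start - 1,
                "end0": tr.end,
                "strand": tr.strand,
                "gene": gene_of(tr),
                "exons": [],
            }
    for ex in db.features_of_type("exon"):
        parent_ids = ex.attributes.get("Parent", [])
        for pid in parent_ids:
            if pid in transcripts:
                transcripts[pid]["exons"].append((ex.start - 1, ex.end))
    # genes without explicit transcripts become single-transcript genes
    for gene in db.features_of_type("gene"):
        has_tr = any(t["gene"] == gene.id for t in transcripts.values())
        if not has_tr:
            transcripts[gene.id] = {
                "chrom": gene.seqid,
                "start0": gene.start - 1,
                "end0": gene.end,
                "strand": gene.strand,
                "gene": gene.id,
                "exons": [],
            }
    for tr in transcripts.values():
        index.add_transcript(
            tr["chrom"],
            tr["start0"],
            tr["end0"],
            tr["strand"],
            tr["gene"],
            tr["exons"],
            symmetric_promoter=symmetric_promoter,
        )
    return index


def _index_from_bed12(path, symmetric_promoter, promoter_length) -> FeatureIndex:
    index = FeatureIndex(promoter_length=promoter_length)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}: line {lineno}: BED12 needs 12 fields")
            try:
                chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
                offsets = [int(v) for v in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}: line {lineno}: missing strand")
            exons = [(start0 + o, start0 + o + s) for o, s in zip(offsets, sizes)]
            index.add_transcript(
                chrom, start0, end0, strand, name, exons,
                symmetric_promoter=symmetric_promoter,
            )
    return index


def annotate_sites(sites: pd.DataFrame, index: FeatureIndex) -> pd.DataFrame:
    """Label sites (columns chrom, pos; 1-based) and attach gene IDs.

    Sites on scaffolds absent from the annotation are intergenic; their
    count is logged.  Gene IDs are comma-joined for multi-gene hits.
    """
    labels, gene_ids = [], []
    unknown = 0
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        if not index.known_scaffold(chrom):
            unknown += 1
            labels.append("intergenic")
            gene_ids.append("")
            continue
        label, genes = index.query(chrom, int(pos))
        labels.append(label)
        gene_ids.append(",".join(genes))
    if unknown:
        logger.warning("annotate_sites: %d sites on unannotated scaffolds", unknown)
    out = sites.copy()
    out["label"] = labels
    out["gene_id"] = gene_ids
    return out


def annotation_proportions(annotated: pd.DataFrame) -> dict[str, float]:
    counts = annotated["label"].value_counts()
    total = counts.sum()
    return {lab: float(counts.get(lab, 0)) / total for lab in LABELS}


def annotate_clusters(clusters, index: FeatureIndex) -> tuple[list[tuple], int]:
    """Per-cluster gene lists for network input.

    A cluster contributes every gene whose promoter/exon/intron overlaps any
    member site; clusters touching no gene are excluded and counted.
    Returns ([(cluster, sorted gene ids), ...], n_excluded).
    """
    kept, excluded = [], 0
    for cluster in clusters:
        genes: set[str] = set()
        for pos in cluster.positions:
            if not index.known_scaffold(cluster.chrom):
                continue
            label, hit = index.query(cluster.chrom, pos)
            genes.update(hit)
        if genes:
            kept.append((cluster, sorted(genes)))
        else:
            excluded += 1
    if excluded:
        logger.info("annotate_clusters: %d clusters without gene overlap", excluded)
    return kept, excluded
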