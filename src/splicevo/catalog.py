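"""Splice-site catalogue built from junction read counts.

A *junction table* holds, for every spliced-out intron, the number of
supporting spliced reads in each sample.  From it we derive donor and
acceptor *splice sites* (the 2-bp essential dinucleotide at each intron
end), estimate per-site usage fractions, and classify each site as
weak, alternative or constitutive.  Weak sites that are absent from the
gene annotation and show no conservation (GerpRS < 2) are flagged as
cryptic; the noisy-splicing statistics in :mod:`splicevo.noise` are
built on those flags.

Coordinate conventions
----------------------
Introns are stored 0-based half-open ``[start, end)``.  The donor site
is the first two intronic bases in transcribed orientation (``[start,
start+2)`` on '+', ``[end-2, end)`` on '-'); the acceptor is the last
two.  A site is identified by ``(chrom, strand, kind, pos)`` where
``pos`` is the leftmost genomic coordinate of the dinucleotide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: metadata columns of a junction table; all remaining columns are samples
JUNCTION_META_COLS = ["chrom", "start", "end", "strand", "gene_id"]

#: maximum intron span retained by the junction-table reader (bp)
MAX_INTRON_SPAN = 100_000

WEAK, ALTERNATIVE, CONSTITUTIVE = "weak", "alternative", "constitutive"


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene models: gene intervals, transcript coding status and the set of
    annotated introns.

    ``genes``: DataFrame with columns gene_id, chrom, start, end, strand.
    ``transcripts``: DataFrame with columns transcript_id, gene_id, coding
    (bool), n_exons, length; may be empty when only gene intervals are known.
    ``annotated_junctions``: set of (chrom, start, end) intron intervals
    present in the annotation.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transcript_id", "gene_id", "coding", "n_exons", "length"]
        )
    )
    annotated_junctions: set = field(default_factory=set)
    #: optional map gene_id -> set of (chrom,start,end) introns of coding exons
    coding_junctions: set = field(default_factory=set)
    #: optional exon table (transcript_id, chrom, start, end, strand)
    exons: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(self.genes.columns):
            raise ValueError(f"gene table must have columns {sorted(required)}")

    # -- annotated splice-site keys --------------------------------------
    def annotated_sites(self) -> set:
        """Site keys (chrom, strand, kind, pos) of all annotated introns."""
        strand_of = dict(zip(self.genes.chrom.astype(str) + ":" +
                             self.genes.start.astype(str), self.genes.strand))
        # junctions do not carry strand; infer from the containing gene
        sites = set()
        for chrom, start, end in self.annotated_junctions:
            strand = self._strand_at(chrom, start, end)
            if strand is None:
                continue
            sites |= set(junction_site_keys(chrom, start, end, strand))
        return sites

    def _strand_at(self, chrom, start, end):
        g = self.genes
        hit = g[(g.chrom == chrom) & (g.start <= start) & (g.end >= end)]
        if len(hit) == 0:
            return None
        return hit.strand.iloc[0]

    @classmethod
    def from_gtf(cls, path: str) -> "GeneAnnotation":
        """Build an annotation from a GTF file (gene/transcript/exon rows)."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique", disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        genes = []
        for g in db.features_of_type("gene"):
            genes.append(
                dict(gene_id=g.id, chrom=g.seqid, start=g.start - 1,
                     end=g.end, strand=g.strand)
            )
        tx_rows, junctions = [], set()
        for t in db.features_of_type("transcript"):
            exons = sorted(db.children(t, featuretype="exon"),
                           key=lambda e: e.start)
            gene_id = t.attributes.get("gene_id", [t.id])[0]
            coding = t.attributes.get("transcript_biotype",
                                      ["protein_coding"])[0] == "protein_coding"
            length = sum(e.end - e.start + 1 for e in exons)
            tx_rows.append(dict(transcript_id=t.id, gene_id=gene_id,
                                coding=coding, n_exons=len(exons),
                                length=length))
            for a, b in zip(exons[:-1], exons[1:]):
                junctions.add((t.seqid, a.end, b.start - 1))  # 0-based intron
        return cls(
            genes=pd.DataFrame(genes),
            transcripts=pd.DataFrame(tx_rows) if tx_rows else None,
            annotated_junctions=junctions,
        )


def junction_site_keys(chrom, start, end, strand):
    """Return ((donor key), (acceptor key)) for one intron."""
    if strand == "+":
        donor = (chrom, strand, "donor", start)
        acceptor = (chrom, strand, "acceptor", end - 2)
    else:
        donor = (chrom, strand, "donor", end - 2)
        acceptor = (chrom, strand, "acceptor", start)
    return donor, acceptor


def site_id_str(key) -> str:
    chrom, strand, kind, pos = key
    return f"{chrom}:{strand}:{'D' if kind == 'donor' else 'A'}:{pos}"


# ---------------------------------------------------------------------------
# junction table I/O and validation
# ---------------------------------------------------------------------------

def read_junctions(path: str) -> pd.DataFrame:
    """Read a junction TSV (meta columns + one count column per sample),
    dropping introns spanning more than 100 kb."""
    df = pd.read_csv(path, sep="\t")
    return validate_junctions(df)


def write_junctions(junctions: pd.DataFrame, path: str) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def validate_junctions(junctions: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in JUNCTION_META_COLS if c not in junctions.columns]
    if missing:
        raise ValueError(f"junction table missing columns {missing}")
    counts = junction_counts(junctions)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative junction counts")
    if (junctions.end <= junctions.start).any():
        raise ValueError("intron end must exceed intron start")
    span = junctions.end - junctions.start
    too_long = span > MAX_INTRON_SPAN
    if too_long.any():
        logger.info("dropping %d junctions spanning > %d bp",
                    int(too_long.sum()), MAX_INTRON_SPAN)
        junctions = junctions.loc[~too_long].reset_index(drop=True)
    return junctions


def junction_counts(junctions: pd.DataFrame) -> pd.DataFrame:
    """Sample count columns of a junction table."""
    return junctions[[c for c in junctions.columns
                      if c not in JUNCTION_META_COLS]]


def sample_columns(junctions: pd.DataFrame) -> list:
    return [c for c in junctions.columns if c not in JUNCTION_META_COLS]


# ---------------------------------------------------------------------------
# junction -> gene assignment
# ---------------------------------------------------------------------------

def assign_junctions(
    junctions: pd.DataFrame,
    annotation: GeneAnnotation,
    fpkm: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    fpkm_threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each junction to the unique gene containing it.

    Junctions overlapping several genes, no gene, or only genes whose
    expression never reaches ``fpkm_threshold`` (mean FPKM per condition,
    best condition) are dropped; the second return value logs one row per
    dropped junction with the reason (multi-gene / intergenic / low-fpkm).
    """
    if annotation is None:
        raise ValueError("gene annotation is required")
    # per-gene max over conditions of the mean FPKM
    if metadata is not None:
        cond_of = metadata.set_index("sample")["condition"]
        mean_by_cond = fpkm.T.groupby(fpkm.columns.map(cond_of)).mean().T
        gene_max_fpkm = mean_by_cond.max(axis=1)
    else:
        gene_max_fpkm = fpkm.mean(axis=1)

    genes = annotation.genes
    assigned, drop_rows = [], []
    for idx, row in junctions.iterrows():
        hits = genes[(genes.chrom == row.chrom)
                     & (genes.start <= row.start)
                     & (genes.end >= row.end)]
        if len(hits) == 0:
            drop_rows.append((idx, "intergenic"))
        elif len(hits) > 1:
            drop_rows.append((idx, "multi-gene"))
        else:
            gid = hits.gene_id.iloc[0]
            if gene_max_fpkm.get(gid, 0.0) > fpkm_threshold:
                assigned.append((idx, gid, hits.strand.iloc[0]))
            else:
                drop_rows.append((idx, "low-fpkm"))
    kept = junctions.loc[[i for i, _, _ in assigned]].copy()
    kept["gene_id"] = [g for _, g, _ in assigned]
    # unstranded junctions inherit the gene strand
    strands = np.asarray([s for _, _, s in assigned], dtype=object)
    if len(kept):
        blank = kept["strand"].isin([".", "", None]) | kept["strand"].isna()
        kept.loc[blank, "strand"] = strands[np.asarray(blank)]
    dropped = pd.DataFrame(
        [dict(junction_index=i, reason=r) for i, r in drop_rows])
    return kept.reset_index(drop=True), dropped


# ---------------------------------------------------------------------------
# splice sites
# ---------------------------------------------------------------------------

def _site_map(junctions: pd.DataFrame) -> dict:
    """Map site key -> list of junction row positions using that site."""
    sites: dict = {}
    for i, row in enumerate(junctions.itertuples(index=False)):
        d, a = junction_site_keys(row.chrom, row.start, row.end, row.strand)
        sites.setdefault(d, []).append(i)
        sites.setdefault(a, []).append(i)
    return sites


def site_usage(
    junctions: pd.DataFrame,
    include_nested: bool = False,
) -> pd.DataFrame:
    """Per-site usage fractions.

    For each site, the *most frequently spliced intron* is the junction of
    that site with the largest total read count.  The usage fraction is
    the ratio of reads supporting the site to reads overlapping that
    intron, where overlapping means sharing its donor or its acceptor
    boundary, plus introns fully containing it.  With
    ``include_nested=True`` any intron whose interval intersects the most
    frequent one also counts (the broader reading of "overlap").
    """
    counts = junction_counts(junctions).to_numpy()
    totals = counts.sum(axis=1)
    smap = _site_map(junctions)
    starts = junctions.start.to_numpy()
    ends = junctions.end.to_numpy()
    chroms = junctions.chrom.to_numpy()
    strands = junctions.strand.to_numpy()

    rows = []
    for key, jidx in smap.items():
        chrom, strand, kind, pos = key
        support = totals[jidx].sum()
        if support == 0:
            continue  # site dropped: usage undefined
        top = jidx[int(np.argmax(totals[jidx]))]
        same = (chroms == chroms[top]) & (strands == strands[top])
        share = same & ((starts == starts[top]) | (ends == ends[top]))
        contain = same & (starts <= starts[top]) & (ends >= ends[top])
        if include_nested:
            contain = same & (starts < ends[top]) & (ends > starts[top])
        overlap_mask = share | contain
        overlap = totals[overlap_mask].sum()
        rows.append(dict(
            site_id=site_id_str(key), chrom=chrom, strand=strand, kind=kind,
            pos=pos, n_reads_total=int(support),
            usage=float(support) / float(overlap),
            top_junction=int(top),
        ))
    return pd.DataFrame(rows)


def site_sample_reads(junctions: pd.DataFrame) -> pd.DataFrame:
    """Per-site, per-sample supporting read counts (sites x samples)."""
    smap = _site_map(junctions)
    counts = junction_counts(junctions)
    data = {site_id_str(k): counts.iloc[j].sum(axis=0) for k, j in smap.items()}
    return pd.DataFrame(data).T


def classify_activity(
    usage: pd.Series,
    mean_reads_by_condition: pd.DataFrame,
    min_reads_per_sample: float = 1.0,
    weak_usage: float = 0.05,
    constitutive_usage: float = 0.95,
) -> pd.Series:
    """Weak / alternative / constitutive activity classes.

    A site is *weak* when its mean supporting reads per sample stay below
    ``min_reads_per_sample`` in every condition, or when its usage
    fraction is below ``weak_usage``.  Among the remaining high-activity
    sites, usage above ``constitutive_usage`` marks a constitutive site;
    everything else is alternative.
    """
    high = (mean_reads_by_condition >= min_reads_per_sample).any(axis=1)
    high = high.reindex(usage.index, fill_value=False)
    cls = pd.Series(ALTERNATIVE, index=usage.index, dtype=object)
    cls[~high | (usage < weak_usage)] = WEAK
    cls[(cls != WEAK) & (usage > constitutive_usage)] = CONSTITUTIVE
    return cls


def flag_cryptic(catalog: pd.DataFrame, gerp_threshold: float = 2.0) -> pd.Series:
    """Cryptic flag: weak AND unannotated AND GerpRS below threshold.
    Sites with a missing conservation score are excluded (never cryptic)."""
    has_score = catalog.gerp_rs.notna()
    n_missing = int((~has_score).sum())
    if n_missing:
        logger.info("%d sites lack a GerpRS score; excluded from cryptic calls",
                    n_missing)
    return ((catalog.activity_class == WEAK)
            & (~catalog.annotated.astype(bool))
            & has_score
            & (catalog.gerp_rs < gerp_threshold))


def build_catalog(
    junctions: pd.DataFrame,
    annotation: GeneAnnotation,
    metadata: pd.DataFrame,
    gerp: pd.DataFrame | None = None,
    include_nested: bool = False,
) -> pd.DataFrame:
    """Build the full splice-site catalogue from gene-assigned junctions.

    ``metadata`` maps sample -> condition (columns sample, condition).
    ``gerp`` is a site-level conservation table (columns site_id, gerp_rs);
    alternatively per-site scores may be joined afterwards.
    Returns one row per site with usage, activity class, annotated/coding
    flags, conservation and cryptic flag.
    """
    cat = site_usage(junctions, include_nested=include_nested)
    if cat.empty:
        return cat
    # gene of the site = gene of its top junction
    cat["gene_id"] = junctions.gene_id.to_numpy()[cat.top_junction.to_numpy()]

    reads = site_sample_reads(junctions)
    cond_of = metadata.set_index("sample")["condition"]
    mean_by_cond = reads.T.groupby(reads.columns.map(cond_of)).mean().T
    mean_by_cond = mean_by_cond.reindex(cat.site_id).fillna(0.0)
    for cond in mean_by_cond.columns:
        cat[f"mean_reads_{cond}"] = mean_by_cond[cond].to_numpy()

    cat = cat.set_index("site_id", drop=False)
    cat["activity_class"] = classify_activity(cat.usage, mean_by_cond)

    ann_sites = {site_id_str(k) for k in annotation.annotated_sites()}
    cat["annotated"] = cat.site_id.isin(ann_sites)
    coding_sites = set()
    for chrom, start, end in annotation.coding_junctions:
        strand = annotation._strand_at(chrom, start, end)
        if strand is not None:
            coding_sites |= {site_id_str(k) for k in
                             junction_site_keys(chrom, start, end, strand)}
    cat["coding"] = cat.site_id.isin(coding_sites) if coding_sites else True

    if gerp is not None:
        score = gerp.set_index("site_id")["gerp_rs"]
        cat["gerp_rs"] = score.reindex(cat.index)
    else:
        cat["gerp_rs"] = np.nan
    cat["cryptic"] = flag_cryptic(cat)
    return cat.reset_index(drop=True)
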