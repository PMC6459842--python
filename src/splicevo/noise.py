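"""Noisy (erroneous) splicing statistics.

A splicing error is a spliced read joining a constitutive splice site to
a cryptic partner site (weak, unannotated, non-conserved).  The per-site
error fraction is the proportion of such reads among all reads that
start or end at the site; averaging over the constitutive coding sites
of a gene gives its noise rate, and averaging gene-level per-sample
rates over genes gives a per-sample noise level.  Correlates examined
here mirror the biology: noise rises with intron length, falls with
expression and transcription rate (intronic RPKM), and tracks the
expression of the NMD pathway that degrades mis-spliced transcripts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import catalog as cat

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-site error fractions
# ---------------------------------------------------------------------------

def _site_partner_counts(catalog: pd.DataFrame, junctions: pd.DataFrame):
    """For each constitutive coding site: per-sample (error, total) reads.

    A junction's contribution is an error when its *other* boundary site
    is flagged cryptic in the catalogue.
    """
    cryptic = set(catalog.loc[catalog.cryptic, "site_id"])
    eligible = catalog[(catalog.activity_class == cat.CONSTITUTIVE)
                       & catalog.coding.astype(bool)]
    counts = cat.junction_counts(junctions)
    per_site = {}
    for i, row in enumerate(junctions.itertuples(index=False)):
        d, a = cat.junction_site_keys(row.chrom, row.start, row.end,
                                      row.strand)
        d_id, a_id = cat.site_id_str(d), cat.site_id_str(a)
        for sid, partner in ((d_id, a_id), (a_id, d_id)):
            err, tot = per_site.setdefault(sid, [[], []])
            tot.append(i)
            if partner in cryptic:
                err.append(i)
    out = {}
    for sid in eligible.site_id:
        if sid not in per_site:
            continue
        err_idx, tot_idx = per_site[sid]
        out[sid] = (counts.iloc[err_idx].sum(axis=0),
                    counts.iloc[tot_idx].sum(axis=0))
    return out, eligible


def site_error_fractions(
    catalog: pd.DataFrame,
    junctions: pd.DataFrame,
    metadata: pd.DataFrame,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Error fractions at constitutive coding sites.

    Default: reads pooled over the samples of each condition (one column
    per condition).  With ``per_sample=True``, fractions are computed
    within each sample separately (one column per sample).  Sites with
    zero reads in a condition/sample are missing there.
    """
    partner, eligible = _site_partner_counts(catalog, junctions)
    if not partner:
        return pd.DataFrame()
    err = pd.DataFrame({sid: e for sid, (e, t) in partner.items()}).T
    tot = pd.DataFrame({sid: t for sid, (e, t) in partner.items()}).T
    if per_sample:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = err / tot.where(tot > 0)
        return frac
    cond_of = metadata.set_index("sample")["condition"]
    err_c = err.T.groupby(err.columns.map(cond_of)).sum().T
    tot_c = tot.T.groupby(tot.columns.map(cond_of)).sum().T
    with np.errstate(invalid="ignore", divide="ignore"):
        return err_c / tot_c.where(tot_c > 0)


def gene_noise_rates(
    catalog: pd.DataFrame,
    site_fractions: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene noise rates: unweighted mean of its sites' error fractions.

    Genes with no eligible constitutive coding site are absent from the
    output.  Works on condition-pooled or per-sample fraction tables.
    """
    gene_of = catalog.set_index("site_id")["gene_id"]
    frac = site_fractions.copy()
    frac["gene_id"] = gene_of.reindex(frac.index)
    frac = frac.dropna(subset=["gene_id"])
    return frac.groupby("gene_id").mean()


def sample_noise_rates(
    catalog: pd.DataFrame,
    junctions: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.Series:
    """Per-sample noise level: gene rates from within-sample site
    fractions, averaged across all genes."""
    frac = site_error_fractions(catalog, junctions, metadata, per_sample=True)
    gene_rates = gene_noise_rates(catalog, frac)
    return gene_rates.mean(axis=0)


# ---------------------------------------------------------------------------
# transcription-rate proxy
# ---------------------------------------------------------------------------

def intronic_rpkm(
    intronic_counts: pd.DataFrame,
    intron_lengths: pd.Series,
    library_sizes: pd.Series,
) -> pd.DataFrame:
    """Intronic RPKM: counts / (total intron kb x library millions).

    Genes with zero or missing total intron length are excluded."""
    lens = intron_lengths.reindex(intronic_counts.index)
    ok = lens.notna() & (lens > 0)
    if (~ok).any():
        logger.info("%d genes lack intron length; excluded", int((~ok).sum()))
    kb = lens[ok] / 1000.0
    millions = library_sizes.reindex(intronic_counts.columns) / 1e6
    return intronic_counts.loc[ok].div(kb, axis=0).div(millions, axis=1)


def mean_intron_length(annotation: cat.GeneAnnotation,
                       fpkm: pd.DataFrame,
                       fpkm_threshold: float = 1.0) -> pd.Series:
    """Mean intron length per gene, from the transcript with the most
    exons among transcripts of genes expressed above threshold (ties:
    longest transcript)."""
    if annotation.exons is None or annotation.transcripts is None:
        raise ValueError("annotation lacks exon/transcript detail")
    expressed = fpkm.mean(axis=1)
    out = {}
    for gene, tx in annotation.transcripts.groupby("gene_id"):
        if expressed.get(gene, 0.0) <= fpkm_threshold:
            continue
        best = tx.sort_values(["n_exons", "length"],
                              ascending=False).iloc[0]
        ex = annotation.exons[
            annotation.exons.transcript_id == best.transcript_id
        ].sort_values("start")
        if len(ex) < 2:
            continue
        gaps = ex.start.to_numpy()[1:] - ex.end.to_numpy()[:-1]
        out[gene] = float(gaps.mean())
    return pd.Series(out, name="mean_intron_length")


# ---------------------------------------------------------------------------
# correlates
# ---------------------------------------------------------------------------

def _spearman(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return dict(rho=np.nan, p_value=np.nan, n=int(ok.sum()),
                    defined=False)
    rho, p = stats.spearmanr(x[ok], y[ok])
    return dict(rho=float(rho), p_value=float(p), n=int(ok.sum()),
                defined=True)


def noise_correlates(
    gene_rates: pd.DataFrame,
    fpkm: pd.DataFrame,
    intron_lengths: pd.Series,
    transcription_rate: pd.Series,
    metadata: pd.DataFrame,
    baseline: str = "NS",
    min_genes: int = 50,
) -> dict:
    """Correlations of basal noise rates with gene features.

    Spearman correlations of the baseline noise rate with mean intron
    length, gene expression and the transcription-rate proxy; the partial
    rank correlation of noise with expression given transcription rate
    (regress the ranks of both on transcription-rate ranks and correlate
    the residuals); and paired Wilcoxon comparisons of gene noise rates
    in each stimulated condition against baseline.
    """
    genes = gene_rates.index
    if len(genes) < min_genes:
        raise ValueError(f"need at least {min_genes} genes")
    cond_of = metadata.set_index("sample")["condition"]
    base_cols = [s for s in fpkm.columns if cond_of.get(s) == baseline]
    expr = fpkm.loc[fpkm.index.intersection(genes), base_cols].mean(axis=1)
    noise_ns = gene_rates[baseline].reindex(genes)

    report = dict(
        vs_intron_length=_spearman(noise_ns,
                                   intron_lengths.reindex(genes)),
        vs_expression=_spearman(noise_ns, expr.reindex(genes)),
        vs_transcription_rate=_spearman(
            noise_ns, transcription_rate.reindex(genes)),
    )

    # partial rank correlation: noise ~ expression | transcription rate
    df = pd.DataFrame(dict(noise=noise_ns, expr=expr.reindex(genes),
                           tr=transcription_rate.reindex(genes))).dropna()
    if len(df) >= 3 and df.nunique().min() > 1:
        ranks = df.rank()
        X = np.column_stack([np.ones(len(ranks)), ranks.tr])
        rn = ranks.noise - X @ np.linalg.lstsq(X, ranks.noise, rcond=None)[0]
        re = ranks.expr - X @ np.linalg.lstsq(X, ranks.expr, rcond=None)[0]
        r = float(np.corrcoef(rn, re)[0, 1])
        n = len(df)
        t = r * np.sqrt((n - 3) / max(1 - r * r, 1e-12))
        report["partial_expression_given_transcription"] = dict(
            rho=r, p_value=float(2 * stats.t.sf(abs(t), n - 3)), n=n,
            defined=True)
    else:
        report["partial_expression_given_transcription"] = dict(
            rho=np.nan, p_value=np.nan, n=len(df), defined=False)

    stim = {}
    for cond in gene_rates.columns:
        if cond == baseline:
            continue
        paired = gene_rates[[baseline, cond]].dropna()
        d = paired[cond] - paired[baseline]
        if len(d) < 10 or np.allclose(d, 0):
            stim[cond] = dict(p_value=np.nan, median_shift=np.nan)
            continue
        p = float(stats.wilcoxon(d, alternative="greater").pvalue)
        stim[cond] = dict(p_value=p, median_shift=float(d.median()),
                          n=len(d))
    report["stimulated_vs_baseline"] = stim
    return report


# ---------------------------------------------------------------------------
# NMD coupling
# ---------------------------------------------------------------------------

def nmd_coupling(
    sample_noise: pd.Series,
    nmd_expression: pd.DataFrame,
) -> dict:
    """Couple per-sample noise to NMD-pathway expression.

    ``nmd_expression`` is NMD genes x samples (FPKM).  The genes are
    summarised by the first principal component of their standardised
    log-expression, with the sign oriented so that higher PC1 means
    higher mean NMD expression.  Returns the PC1 scores and the Spearman
    correlation with per-sample noise.
    """
    expr = nmd_expression.loc[:, sample_noise.index]
    if expr.shape[0] < 2:
        raise ValueError("need at least two NMD genes")
    x = np.log2(expr.to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("degenerate PC: NMD expression is constant")
    keep = sd > 0
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc1 = vt[0] * s[0]
    mean_expr = z.mean(axis=0)
    if np.corrcoef(pc1, mean_expr)[0, 1] < 0:
        pc1 = -pc1
    rho, p = stats.spearmanr(pc1, sample_noise.to_numpy(dtype=float))
    return dict(pc1=pd.Series(pc1, index=sample_noise.index),
                rho=float(rho), p_value=float(p))
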