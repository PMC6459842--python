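"""Alternative-splicing events: PSI quantification and downstream analyses.

An AS event is a local binary choice between a reference and an
alternative splicing of a gene region (types SE, RI, A3, A5, AF, AL,
MX), described by disjoint sets of inclusion and exclusion junctions.
PSI (percent spliced in) is estimated as a junction ratio with
junction-multiplicity normalisation: inclusion reads divided by the
number of inclusion junctions, likewise for exclusion, then
PSI = inc / (inc + exc).  This deterministic estimator replaces
isoform-level Bayesian PSI estimation and is unbiased for two-isoform
local events at adequate read depth.

Sample-level tables ("PSI matrix") are events x samples DataFrames with
values in [0, 1]; missing values (insufficient informative reads) are
allowed before imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import catalog as cat

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = ("modified_protein", "gain_of_function",
                      "loss_of_function", "non_coding")


def parse_junction_list(text: str) -> list:
    """Parse 'chr1:100-200;chr1:300-400' into (chrom, start, end) tuples."""
    out = []
    for token in str(text).split(";"):
        chrom, span = token.split(":")
        start, end = span.split("-")
        out.append((chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def compute_psi(
    events: pd.DataFrame,
    junctions: pd.DataFrame,
    min_informative_reads: int = 10,
) -> pd.DataFrame:
    """Events x samples PSI matrix.

    Per event and sample: inclusion reads / number of inclusion junctions
    over the same for exclusion; PSI = inc / (inc + exc).  Entries whose
    raw (un-normalised) informative read total falls below
    ``min_informative_reads`` are missing (NaN).
    """
    samples = cat.sample_columns(junctions)
    counts = junctions[samples].to_numpy(dtype=float)
    jindex = {(r.chrom, r.start, r.end): i
              for i, r in enumerate(junctions.itertuples(index=False))}

    rows = []
    for ev in events.itertuples(index=False):
        inc = parse_junction_list(ev.inclusion_junctions)
        exc = parse_junction_list(ev.exclusion_junctions)
        if set(inc) & set(exc):
            raise ValueError(
                f"event {ev.event_id}: inclusion and exclusion overlap")
        inc_idx = [jindex[j] for j in inc if j in jindex]
        exc_idx = [jindex[j] for j in exc if j in jindex]
        inc_raw = counts[inc_idx].sum(axis=0) if inc_idx else np.zeros(len(samples))
        exc_raw = counts[exc_idx].sum(axis=0) if exc_idx else np.zeros(len(samples))
        inc_n = inc_raw / max(len(inc), 1)
        exc_n = exc_raw / max(len(exc), 1)
        denom = inc_n + exc_n
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(denom > 0, inc_n / denom, np.nan)
        psi = np.where(inc_raw + exc_raw < min_informative_reads, np.nan, psi)
        rows.append(psi)
    return pd.DataFrame(rows, index=events.event_id.to_numpy(),
                        columns=samples)


def condition_means(psi: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-event mean PSI by condition (missing values ignored)."""
    cond_of = metadata.set_index("sample")["condition"]
    return psi.T.groupby(psi.columns.map(cond_of)).mean().T


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_events(
    events: pd.DataFrame,
    psi: pd.DataFrame,
    junctions: pd.DataFrame,
    fpkm: pd.DataFrame,
    metadata: pd.DataFrame,
    min_gene_fpkm: float = 10.0,
    min_intron_reads: int = 30,
    psi_bounds: tuple = (0.05, 0.95),
    max_missing: float = 0.05,
    min_minor_fpkm: float = 0.5,
) -> pd.DataFrame:
    """Keep events that pass all quality filters in at least one condition.

    Per condition, an event must come from a highly expressed gene (mean
    FPKM above ``min_gene_fpkm``), have every alternative intron supported
    by at least ``min_intron_reads`` spliced reads, a mean PSI inside
    ``psi_bounds``, at most ``max_missing`` missing sample values, and a
    minor isoform expressed above ``min_minor_fpkm`` (gene FPKM times the
    minor-isoform fraction).  Returns the retained subset of ``events``.
    """
    samples = cat.sample_columns(junctions)
    cond_of = metadata.set_index("sample")["condition"]
    conditions = metadata.condition.unique()
    jindex = {(r.chrom, r.start, r.end): i
              for i, r in enumerate(junctions.itertuples(index=False))}
    counts = junctions[samples]

    keep = []
    for ev in events.itertuples(index=False):
        introns = (parse_junction_list(ev.inclusion_junctions)
                   + parse_junction_list(ev.exclusion_junctions))
        jidx = [jindex[j] for j in introns if j in jindex]
        row = psi.loc[ev.event_id]
        ok_any = False
        for cond in conditions:
            cols = [s for s in samples if cond_of[s] == cond]
            gene_fpkm = fpkm.loc[ev.gene_id, cols].mean() \
                if ev.gene_id in fpkm.index else 0.0
            if gene_fpkm <= min_gene_fpkm:
                continue
            intron_reads = counts.iloc[jidx][cols].sum(axis=1)
            if len(jidx) < len(introns) or (intron_reads < min_intron_reads).any():
                continue
            vals = row[cols]
            if vals.isna().mean() > max_missing:
                continue
            m = vals.mean()
            if not (psi_bounds[0] < m < psi_bounds[1]):
                continue
            if gene_fpkm * min(m, 1 - m) <= min_minor_fpkm:
                continue
            ok_any = True
            break
        if ok_any:
            keep.append(ev.event_id)
    return events[events.event_id.isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def impute_knn(psi: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing PSI entries from the k nearest events.

    Distances are Euclidean over the samples both events observe (scaled
    to a per-sample average so partially missing rows are comparable).
    A missing entry becomes the mean of the k nearest events that observe
    that sample.  Output is complete and clipped to [0, 1].
    """
    x = psi.to_numpy(dtype=float).copy()
    if not np.isnan(x).any():
        return psi.copy()
    if np.isnan(x).all(axis=1).any():
        raise ValueError("event with all samples missing cannot be imputed")
    out = x.copy()
    obs = ~np.isnan(x)
    for i in np.flatnonzero((~obs).any(axis=1)):
        shared = obs & obs[i]                       # (n_events, n_samples)
        diff = np.where(shared, x - x[i], 0.0)
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = (diff ** 2).sum(axis=1) / n_shared
        d2[i] = np.inf
        d2[n_shared == 0] = np.inf
        for j in np.flatnonzero(~obs[i]):
            cand = np.flatnonzero(obs[:, j] & np.isfinite(d2))
            if len(cand) == 0:
                raise ValueError("no neighbour observes the missing sample")
            nearest = cand[np.argsort(d2[cand], kind="stable")[:k]]
            out[i, j] = x[nearest, j].mean()
    return pd.DataFrame(np.clip(out, 0.0, 1.0),
                        index=psi.index, columns=psi.columns)


# ---------------------------------------------------------------------------
# batch adjustment
# ---------------------------------------------------------------------------

def remove_batch(psi: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Adjust PSI for declared technical covariates by linear regression.

    Each event's PSI profile is regressed on the covariate design
    (categorical columns dummy-coded); the residuals plus the event's
    grand mean are returned, clipped to [0, 1]."""
    design = pd.get_dummies(covariates, drop_first=True, dtype=float)
    design = design.loc[psi.columns]
    X = np.column_stack([np.ones(len(design)), design.to_numpy()])
    Y = psi.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta + Y.mean(axis=1)
    return pd.DataFrame(np.clip(resid.T, 0, 1),
                        index=psi.index, columns=psi.columns)


# ---------------------------------------------------------------------------
# redundancy clustering
# ---------------------------------------------------------------------------

def cluster_redundant(
    psi: pd.DataFrame,
    events: pd.DataFrame,
    total_reads: pd.Series,
    min_abs_corr: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Collapse overlapping, correlated events to one representative each.

    Events whose boundary intervals overlap and whose PSI profiles have
    |Pearson r| above ``min_abs_corr`` are connected; clusters come from
    random-walk community detection (walktrap); the representative is the
    event with the most supporting spliced reads (ties: smallest
    event_id).  Returns events with ``cluster`` and ``representative``
    columns.
    """
    import igraph

    ev = events.reset_index(drop=True)
    n = len(ev)
    pairs = []
    vals = psi.loc[ev.event_id].to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ev.iloc[i], ev.iloc[j]
            if a.chrom != b.chrom or a.start >= b.end or b.start >= a.end:
                continue
            xi, xj = vals[i], vals[j]
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                continue
            r = np.corrcoef(xi[ok], xj[ok])[0, 1]
            if abs(r) > min_abs_corr:
                pairs.append((i, j))
    graph = igraph.Graph(n=n, edges=pairs)
    import random as _random
    _random.seed(seed)  # walktrap membership is deterministic given the graph
    membership = graph.community_walktrap().as_clustering().membership

    ev = ev.assign(cluster=membership)
    reads = total_reads.reindex(ev.event_id).to_numpy()
    rep = {}
    for c, grp in ev.groupby("cluster"):
        idx = grp.index.to_numpy()
        best = idx[np.lexsort((grp.event_id.to_numpy(),
                               -reads[idx]))][0]
        rep[c] = ev.event_id.iloc[best]
    ev["representative"] = ev.cluster.map(rep) == ev.event_id
    return ev


# ---------------------------------------------------------------------------
# functional classification
# ---------------------------------------------------------------------------

def classify_function(events: pd.DataFrame,
                      transcripts: pd.DataFrame) -> pd.Series:
    """Functional class of each event from its isoforms' coding status.

    modified_protein when both isoforms are protein-coding;
    loss_of_function when only the reference isoform is;
    gain_of_function when only the alternative isoform is;
    non_coding when neither is; 'unassigned' when an isoform has no
    mapped transcript.
    """
    coding = dict(zip(transcripts.transcript_id, transcripts.coding))
    out = []
    for ev in events.itertuples(index=False):
        ref = coding.get(ev.ref_transcript)
        alt = coding.get(ev.alt_transcript)
        if ref is None or alt is None:
            out.append("unassigned")
        elif ref and alt:
            out.append("modified_protein")
        elif ref:
            out.append("loss_of_function")
        elif alt:
            out.append("gain_of_function")
        else:
            out.append("non_coding")
    return pd.Series(out, index=events.event_id.to_numpy())


# ---------------------------------------------------------------------------
# differential splicing
# ---------------------------------------------------------------------------

def differential_splicing(
    psi: pd.DataFrame,
    metadata: pd.DataFrame,
    contrasts: list | None = None,
    baseline: str = "NS",
    populations: tuple = ("AFB", "EUB"),
    alpha: float = 0.05,
    min_dpsi: float = 0.05,
    min_pairs: int = 10,
    expressed: pd.DataFrame | None = None,
    gene_of: pd.Series | None = None,
) -> pd.DataFrame:
    """Wilcoxon tests for differential splicing, BH-corrected jointly.

    Condition contrasts (``("condition", cond)``) are paired by individual:
    a signed-rank test on within-individual PSI differences versus the
    baseline condition; the population contrast (``("population", cond)``)
    is an unpaired rank-sum test between the two populations within that
    condition.  Positive dPSI means higher PSI in the stimulated condition
    (or in the first population).  ``expressed`` optionally restricts
    condition contrasts to events of genes expressed (bool gene x condition
    frame; requires ``gene_of``).  BH correction pools all events and
    contrasts of the call; significance needs adjusted p < ``alpha`` and
    |dPSI| > ``min_dpsi``.
    """
    meta = metadata.set_index("sample")
    if contrasts is None:
        conds = [c for c in metadata.condition.unique() if c != baseline]
        contrasts = [("condition", c) for c in conds]

    rows = []
    for kind, cond in contrasts:
        cols = psi.columns
        if kind == "condition":
            stim = meta[meta.condition == cond]
            base = meta[meta.condition == baseline]
            common = np.intersect1d(stim.individual, base.individual)
            s_cols = stim[stim.individual.isin(common)].sort_values(
                "individual").index
            b_cols = base[base.individual.isin(common)].sort_values(
                "individual").index
            s_cols = [c for c in s_cols if c in cols]
            b_cols = [c for c in b_cols if c in cols]
            for event_id, row in psi.iterrows():
                if expressed is not None and gene_of is not None:
                    g = gene_of.get(event_id)
                    if g is not None and not (
                            expressed.at[g, cond] and
                            expressed.at[g, baseline]):
                        continue
                a = row[s_cols].to_numpy(dtype=float)
                b = row[b_cols].to_numpy(dtype=float)
                ok = ~np.isnan(a) & ~np.isnan(b)
                if ok.sum() < min_pairs:
                    logger.warning("event %s: only %d pairs for %s, skipped",
                                   event_id, int(ok.sum()), cond)
                    continue
                d = a[ok] - b[ok]
                dpsi = float(d.mean())
                if np.allclose(d, 0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(d, zero_method="wilcox",
                                             mode="auto").pvalue)
                rows.append(dict(event_id=event_id, contrast=f"{cond}-vs-NS",
                                 kind=kind, dpsi=dpsi, p_value=p))
        elif kind == "population":
            sub = meta[meta.condition == cond]
            a_cols = [c for c in sub[sub.population == populations[0]].index
                      if c in cols]
            b_cols = [c for c in sub[sub.population == populations[1]].index
                      if c in cols]
            for event_id, row in psi.iterrows():
                a = row[a_cols].dropna().to_numpy(dtype=float)
                b = row[b_cols].dropna().to_numpy(dtype=float)
                if len(a) < min_pairs or len(b) < min_pairs:
                    continue
                dpsi = float(a.mean() - b.mean())
                if np.ptp(np.concatenate([a, b])) == 0:
                    p = 1.0
                else:
                    p = float(stats.mannwhitneyu(
                        a, b, alternative="two-sided").pvalue)
                rows.append(dict(
                    event_id=event_id,
                    contrast=f"{populations[0]}-vs-{populations[1]}:{cond}",
                    kind=kind, dpsi=dpsi, p_value=p))
        else:
            raise ValueError(f"unknown contrast kind {kind!r}")

    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["p_adjusted"] = benjamini_hochberg(res.p_value.to_numpy())
    res["significant"] = ((res.p_adjusted < alpha)
                          & (res.dpsi.abs() > min_dpsi))
    return res


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up, with monotonicity enforcement)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# isoform diversity
# ---------------------------------------------------------------------------

def isoform_diversity(psi_means) -> float:
    """Shannon entropy of a gene's isoform repertoire (natural log).

    Treats the gene's AS events as independent binary choices:
    H = sum_j [-psi_j ln psi_j - (1-psi_j) ln(1-psi_j)], with 0 ln 0 = 0.
    """
    p = np.asarray(psi_means, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("PSI values must lie in [0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) \
            - np.where(p < 1, (1 - p) * np.log(1 - p), 0.0)
    return float(np.nansum(h))


def gene_entropy(psi: pd.DataFrame, metadata: pd.DataFrame,
                 gene_of: pd.Series) -> pd.DataFrame:
    """Per-gene, per-condition isoform diversity from event condition means."""
    means = condition_means(psi, metadata)
    means = means.assign(gene_id=gene_of.reindex(means.index))
    rows = {}
    for gene, grp in means.groupby("gene_id"):
        rows[gene] = {c: isoform_diversity(grp[c].dropna())
                      for c in grp.columns if c != "gene_id"}
    return pd.DataFrame(rows).T
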