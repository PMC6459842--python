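"""cis-mapping of splicing and expression QTLs.

The scan regresses a rank-normalised phenotype (event PSI or gene
expression) on SNP dosage plus covariates (genotype PCs for population
stratification), for every SNP within a 1 Mb window of the phenotype's
boundaries, separately per condition with both populations merged.
Genome-wide significance comes from a permutation FDR in which
genotypes are permuted within each population; condition sharing is
scored with approximate Bayes factors; response sQTLs (G x E) are
flagged from the association of within-individual PSI changes with
dosage; and the direction of coupling between splicing and expression
is resolved by likelihood-based causal model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# rank-normal transform
# ---------------------------------------------------------------------------

def rank_normal(x) -> np.ndarray:
    """Inverse-normal transform of ranks: Phi^-1((rank - 0.5)/n).

    Ties get average ranks.  Raises on a constant vector (degenerate
    phenotype)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x[~np.isnan(x)]) == 0:
        raise ValueError("degenerate phenotype: all values equal")
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.5) / ok.sum())
    return out


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y on [1, covariates] (Frisch–Waugh projection)."""
    n = y.shape[-1]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    return y - (X @ beta).T


# ---------------------------------------------------------------------------
# cis scan
# ---------------------------------------------------------------------------

def cis_scan(
    phenotypes: pd.DataFrame,
    positions: pd.DataFrame,
    dosages: np.ndarray,
    snp_pos: np.ndarray,
    snp_ids: np.ndarray,
    covariates: np.ndarray | None = None,
    window: int = 1_000_000,
    pre_normalized: bool = False,
) -> pd.DataFrame:
    """OLS scan of each phenotype against every SNP in its cis window.

    ``phenotypes``: phenotypes x observations (observations = individuals
    of one condition, columns aligned with the columns of ``dosages``).
    ``positions``: per-phenotype chrom/start/end boundaries (index =
    phenotype id).  ``dosages``: SNPs x observations (mean-imputed
    missing values upstream).  Phenotypes are rank-normalised here unless
    ``pre_normalized``.  Returns one row per tested (phenotype, SNP) with
    beta, se and the dosage-coefficient p-value.
    """
    n = phenotypes.shape[1]
    k_cov = 0 if covariates is None else covariates.shape[1]
    df = n - k_cov - 2
    if df <= 0:
        raise ValueError("not enough observations for the scan")

    G = _residualize(np.asarray(dosages, dtype=float), covariates)
    gss = (G ** 2).sum(axis=1)

    rows = []
    for pid, y in phenotypes.iterrows():
        y = y.to_numpy(dtype=float)
        if not pre_normalized:
            y = rank_normal(y)
        yr = _residualize(y[None, :], covariates)[0]
        yss = (yr ** 2).sum()
        lo = positions.at[pid, "start"] - window
        hi = positions.at[pid, "end"] + window
        in_win = np.flatnonzero((snp_pos >= lo) & (snp_pos <= hi))
        if len(in_win) == 0:
            continue
        g = G[in_win]
        gs = gss[in_win]
        usable = gs > 1e-12          # singular designs are skipped
        if (~usable).any():
            logger.debug("%d monomorphic/singular SNPs skipped", (~usable).sum())
        g, gs, idx = g[usable], gs[usable], in_win[usable]
        gy = g @ yr
        beta = gy / gs
        rss = np.maximum(yss - beta * gy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gs)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = 2 * stats.t.sf(np.abs(t), df)
        rows.append(pd.DataFrame(dict(
            phenotype_id=pid, snp=snp_ids[idx], beta=beta, se=se,
            p_value=p)))
    if not rows:
        return pd.DataFrame(columns=["phenotype_id", "snp", "beta", "se",
                                     "p_value"])
    return pd.concat(rows, ignore_index=True)


def peak_per_phenotype(scan: pd.DataFrame) -> pd.DataFrame:
    """Most significant SNP per phenotype."""
    if scan.empty:
        return scan
    idx = scan.groupby("phenotype_id").p_value.idxmin()
    return scan.loc[idx].reset_index(drop=True)


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages (negative or NaN) by the SNP mean."""
    d = np.asarray(dosages, dtype=float).copy()
    bad = ~np.isfinite(d) | (d < 0)
    if bad.any():
        means = np.where(bad, np.nan, d)
        fill = np.nanmean(means, axis=1)
        d[bad] = np.take(fill, np.nonzero(bad)[0])
    return d


def genotype_pcs(
    dosages: np.ndarray,
    maf: np.ndarray,
    n_components: int = 2,
    maf_min: float = 0.05,
    prune_r2: float = 0.8,
    pvalues: np.ndarray | None = None,
) -> np.ndarray:
    """PC1..PCk of the genotype matrix on LD-pruned common SNPs.

    Returns an (individuals x k) score matrix used as scan covariates."""
    keep = np.flatnonzero(maf >= maf_min)
    d = mean_impute(dosages[keep])
    pruned = ld_prune(d, prune_r2,
                      None if pvalues is None else pvalues[keep])
    d = d[pruned]
    mu = d.mean(axis=1, keepdims=True)
    sd = d.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (d - mu) / sd, 0.0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    return (vt[:n_components] * s[:n_components, None]).T


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def permute_within_population(
    rng: np.random.Generator,
    populations: np.ndarray,
) -> np.ndarray:
    """Permutation of individual indices that stays within populations."""
    order = np.arange(len(populations))
    for pop in pd.unique(populations):
        idx = np.flatnonzero(populations == pop)
        order[idx] = rng.permutation(idx)
    return order


def permutation_fdr(
    scan_min_p: pd.Series,
    perm_min_p: list,
    thresholds: np.ndarray | None = None,
    target_fdr: float = 0.05,
) -> dict:
    """Permutation-calibrated genome-wide p-value threshold.

    ``scan_min_p``: observed min-p per phenotype (across conditions).
    ``perm_min_p``: one such vector per permuted dataset.  For each
    candidate threshold t, FDR(t) = mean over permutations of the number
    of phenotypes with min-p < t, divided by the observed count.  The
    estimated FDR is made monotone (isotonic in t) before choosing the
    largest t with FDR <= ``target_fdr``.  Returns a dict with the chosen
    threshold (NaN when nothing is discoverable) and the FDR table.
    """
    if thresholds is None:
        thresholds = 10.0 ** np.linspace(-3, -50, 95)
    obs = np.asarray(scan_min_p, dtype=float)
    perms = [np.asarray(p, dtype=float) for p in perm_min_p]
    rows = []
    for t in thresholds:
        n_obs = int((obs < t).sum())
        n_null = float(np.mean([(p < t).sum() for p in perms]))
        # FDR = E[V / max(R, 1)]: zero rejections contribute zero
        fdr = n_null / max(n_obs, 1)
        rows.append(dict(threshold=t, n_observed=n_obs, mean_null=n_null,
                         fdr=fdr))
    tab = pd.DataFrame(rows).sort_values("threshold").reset_index(drop=True)
    # isotonic in t: estimated FDR may never decrease as t grows
    tab["fdr_monotone"] = np.maximum.accumulate(tab.fdr.to_numpy())
    ok = tab[(tab.fdr_monotone <= target_fdr) & (tab.n_observed > 0)]
    threshold = float(ok.threshold.max()) if len(ok) else np.nan
    return dict(threshold=threshold, table=tab)


# ---------------------------------------------------------------------------
# condition sharing
# ---------------------------------------------------------------------------

def _log_abf(beta: float, se: float, prior_var: float) -> float:
    """Wakefield approximate Bayes factor (log), active vs null effect."""
    v = se ** 2
    z2 = (beta / se) ** 2
    return float(0.5 * np.log(v / (v + prior_var))
                 + 0.5 * z2 * prior_var / (v + prior_var))


def condition_sharing(
    summaries: pd.DataFrame,
    n_per_condition: dict | int,
) -> dict:
    """Most probable configuration of conditions where a QTL is active.

    ``summaries``: one row per condition with columns condition, beta, se
    (the peak SNP's regression summary in that condition).  Each of the
    2^C - 1 nonzero activity configurations is scored by the sum of
    Wakefield log-ABFs of its active conditions, with a unit-information
    normal prior (prior variance n * se^2) on active effects and a
    uniform prior over configurations.  Conditions without a summary are
    excluded from the configuration space.  Returns the maximum-posterior
    configuration and its posterior probability.
    """
    from itertools import product

    tab = summaries.dropna(subset=["beta", "se"]).reset_index(drop=True)
    conds = list(tab.condition)
    if not conds:
        raise ValueError("no condition summaries")
    abf = {}
    for r in tab.itertuples(index=False):
        n = (n_per_condition if isinstance(n_per_condition, (int, float))
             else n_per_condition[r.condition])
        abf[r.condition] = _log_abf(r.beta, r.se, prior_var=n * r.se ** 2)

    configs, scores = [], []
    for mask in product([0, 1], repeat=len(conds)):
        if not any(mask):
            continue
        active = tuple(c for c, m in zip(conds, mask) if m)
        configs.append(active)
        scores.append(sum(abf[c] for c in active))
    scores = np.asarray(scores)
    post = np.exp(scores - scores.max())
    post /= post.sum()
    best = int(np.argmax(post))
    return dict(config=configs[best], posterior=float(post[best]),
                all_configs=dict(zip(configs, post)))


# ---------------------------------------------------------------------------
# response sQTLs
# ---------------------------------------------------------------------------

def rsqtl_test(
    delta_psi: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Association of within-individual PSI change with dosage.

    ``delta_psi``: per-individual PSI difference (stimulated - basal),
    rank-normalised here.  Returns (beta, p)."""
    y = rank_normal(delta_psi)
    yr = _residualize(y[None, :], covariates)[0]
    g = _residualize(np.asarray(dosage, float)[None, :], covariates)[0]
    gss = (g ** 2).sum()
    if gss < 1e-12:
        return np.nan, np.nan
    beta = (g @ yr) / gss
    df = len(y) - (0 if covariates is None else covariates.shape[1]) - 2
    rss = (yr ** 2).sum() - beta ** 2 * gss
    se = np.sqrt(max(rss, 0) / df / gss)
    t = beta / se if se > 0 else 0.0
    return float(beta), float(2 * stats.t.sf(abs(t), df))


def detect_rsqtl(
    p_basal: float,
    p_delta: float,
    fpkm_basal: float,
    fpkm_stimulated: float,
    min_fpkm: float = 10.0,
    basal_p_floor: float = 1e-3,
    delta_p_ceiling: float = 0.01,
) -> dict:
    """Response-sQTL decision for one (event, SNP, stimulation).

    Requires (i) gene expressed above ``min_fpkm`` both before and after
    stimulation, (ii) no significant basal association (p > 1e-3 at NS),
    (iii) significant association of the within-individual PSI change
    with dosage (p < 0.01).  Genes expressed only upon stimulation
    (basal FPKM < 10 with log2FC > 1) are classified separately."""
    expressed_both = (fpkm_basal > min_fpkm) and (fpkm_stimulated > min_fpkm)
    stimulation_specific = (
        fpkm_basal < min_fpkm
        and fpkm_stimulated > 0
        and np.log2(max(fpkm_stimulated, 1e-9)
                    / max(fpkm_basal, 1e-9)) > 1.0)
    flag = (expressed_both
            and p_basal > basal_p_floor
            and p_delta < delta_p_ceiling)
    return dict(rsqtl=bool(flag),
                stimulation_specific_gene=bool(stimulation_specific),
                expressed_both=bool(expressed_both))


# ---------------------------------------------------------------------------
# LD and eQTL overlap
# ---------------------------------------------------------------------------

def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def eqtl_overlap(sqtl_dosage, eqtl_dosage, r2_threshold: float = 0.8) -> dict:
    r2 = ld_r2(sqtl_dosage, eqtl_dosage)
    return dict(r2=r2, overlap=bool(np.isfinite(r2) and r2 > r2_threshold))


def ld_prune(
    dosages: np.ndarray,
    r2_threshold: float = 0.8,
    pvalues: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy LD pruning: keep the most significant SNP, drop neighbours
    with r^2 above threshold.  Returns indices of retained SNPs."""
    n = len(dosages)
    order = (np.argsort(pvalues, kind="stable") if pvalues is not None
             else np.arange(n))
    kept: list[int] = []
    for i in order:
        if all(not (np.isfinite(r := ld_r2(dosages[i], dosages[j]))
                    and r > r2_threshold) for j in kept):
            kept.append(int(i))
    return np.asarray(sorted(kept), dtype=int)


# ---------------------------------------------------------------------------
# causal model selection
# ---------------------------------------------------------------------------

def _ols_loglik(y: np.ndarray, X: np.ndarray) -> float:
    """Maximised Gaussian log-likelihood of y ~ X (ML variance)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    s2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1)


def partial_correlation(s, e, g) -> tuple[float, float]:
    """Correlation of s and e after removing the genotype effect."""
    X = np.column_stack([np.ones(len(g)), g])
    rs = s - X @ np.linalg.lstsq(X, s, rcond=None)[0]
    re = e - X @ np.linalg.lstsq(X, e, rcond=None)[0]
    if np.std(rs) == 0 or np.std(re) == 0:
        return np.nan, 1.0
    r = float(np.corrcoef(rs, re)[0, 1])
    n = len(g)
    t = r * np.sqrt((n - 3) / max(1 - r * r, 1e-12))
    return r, float(2 * stats.t.sf(abs(t), n - 3))


def causal_model_selection(
    g: np.ndarray,
    s: np.ndarray,
    e: np.ndarray,
    gate_alpha: float = 0.05,
    aic_margin: float = 2.0,
    min_n: int = 50,
) -> dict:
    """Direction of the splicing-expression link at a QTL.

    Two steps.  First, the partial correlation of splicing (s) and
    expression (e) given genotype (g): if not significant the label is
    'independent' (the QTL affects both traits, or only one, with no
    residual coupling).  Second, maximised Gaussian log-likelihoods of
    three directed models are compared by AIC:

    * causal:      g -> s -> e
    * reactive:    g -> e -> s
    * independent: g -> s and g -> e with independent residuals

    The best model wins unless its AIC advantage is below ``aic_margin``
    ('ambiguous').  Fewer than ``min_n`` observations: 'untested'.
    """
    g = np.asarray(g, float)
    s = np.asarray(s, float)
    e = np.asarray(e, float)
    n = len(g)
    if n < min_n:
        return dict(label="untested", n=n)
    r, p_gate = partial_correlation(s, e, g)
    if not (p_gate < gate_alpha):
        return dict(label="independent", partial_r=r, gate_p=p_gate, n=n)

    one = np.ones(n)
    Xg = np.column_stack([one, g])
    Xs = np.column_stack([one, s])
    Xe = np.column_stack([one, e])
    ll_causal = _ols_loglik(s, Xg) + _ols_loglik(e, Xs)
    ll_reactive = _ols_loglik(e, Xg) + _ols_loglik(s, Xe)
    ll_indep = _ols_loglik(s, Xg) + _ols_loglik(e, Xg)

    # all three models have 6 free parameters (two regressions with
    # intercept, slope and variance each), so AIC ranks by likelihood
    aic = {"causal": 2 * 6 - 2 * ll_causal,
           "reactive": 2 * 6 - 2 * ll_reactive,
           "independent": 2 * 6 - 2 * ll_indep}
    ranked = sorted(aic, key=aic.get)
    label = ranked[0]
    margin = aic[ranked[1]] - aic[ranked[0]]
    if margin < aic_margin:
        label = "ambiguous"
    return dict(label=label, aic=aic, margin=float(margin),
                partial_r=r, gate_p=p_gate, n=n)


# ---------------------------------------------------------------------------
# transcription-rate effect and annotation enrichment
# ---------------------------------------------------------------------------

def transcription_rate_effect(
    intronic_rpkm: np.ndarray,
    dosage: np.ndarray,
    population: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Effect of a QTL SNP on the transcription-rate proxy.

    OLS of rank-normalised intronic RPKM on dosage adjusting for the
    population of origin."""
    y = rank_normal(np.asarray(intronic_rpkm, float))
    pop_ind = pd.get_dummies(pd.Series(population),
                             drop_first=True, dtype=float).to_numpy()
    yr = _residualize(y[None, :], pop_ind)[0]
    g = _residualize(np.asarray(dosage, float)[None, :], pop_ind)[0]
    gss = (g ** 2).sum()
    if gss < 1e-12:
        return dict(beta=np.nan, p_value=np.nan, significant=False)
    beta = (g @ yr) / gss
    df = len(y) - pop_ind.shape[1] - 2
    rss = max((yr ** 2).sum() - beta ** 2 * gss, 0.0)
    se = np.sqrt(rss / df / gss)
    t = beta / se if se > 0 else 0.0
    p = float(2 * stats.t.sf(abs(t), df))
    return dict(beta=float(beta), p_value=p, significant=bool(p < alpha))


def annotation_enrichment(
    peak_snps,
    annotation_sets: dict,
    background_snps,
) -> pd.DataFrame:
    """Fisher's exact enrichment of peak SNPs in annotation SNP sets.

    ``background_snps`` is the scan's SNP universe (MAF-filtered,
    within-window SNPs); peak SNPs should already be LD-pruned.  Empty
    annotations are skipped.
    """
    peaks = set(peak_snps)
    background = set(background_snps)
    non_peaks = background - peaks
    rows = []
    for name, snps in annotation_sets.items():
        snps = set(snps) & background
        if not snps:
            logger.info("annotation %s is empty within background; skipped",
                        name)
            continue
        a = len(peaks & snps)
        b = len(peaks - snps)
        c = len(non_peaks & snps)
        d = len(non_peaks - snps)
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append(dict(annotation=name, n_overlap=a, odds_ratio=odds,
                         p_value=p))
    return pd.DataFrame(rows)
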