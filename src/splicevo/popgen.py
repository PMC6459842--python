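"""Population differentiation of splicing and selection signals.

Covers the decomposition of population PSI differences into a
genotype-mediated and a direct component, Weir–Cockerham/Hudson FST,
the integrated haplotype score (iHS), local outlier enrichment under a
beta-binomial model, and MAF-matched resampling enrichments of sQTLs in
archaic (introgressed) and GWAS SNP sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

def mediation_decompose(
    psi: np.ndarray,
    dosage: np.ndarray,
    population: np.ndarray,
    pop_a: str = "AFB",
    pop_b: str = "EUB",
    n_boot: int = 1000,
    seed: int = 0,
    dpsi_tol: float = 1e-6,
) -> dict:
    """Split the population PSI difference at an sQTL into a mediated
    and a direct part.

    The linear model Psi ~ dosage + population gives the per-allele
    effect beta and the direct (population) effect delta; the mediated
    part is zeta = 2 * beta * (f_a - f_b) with f the *empirical* mean
    allele frequencies of the modelled individuals, which makes
    zeta + delta equal the observed mean PSI difference (pop_a - pop_b)
    exactly.  The proportion mediated is tau = zeta / dPSI, undefined
    when |dPSI| < ``dpsi_tol``.  Percentile CIs come from a seeded
    nonparametric bootstrap over individuals, stratified by population.
    """
    psi = np.asarray(psi, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    population = np.asarray(population, dtype=object)
    a_mask = population == pop_a
    b_mask = population == pop_b
    if not a_mask.any() or not b_mask.any():
        raise ValueError("both populations must be present")
    keep = (a_mask | b_mask) & np.isfinite(psi) & np.isfinite(dosage)
    psi, dosage, a_mask = psi[keep], dosage[keep], a_mask[keep]

    def _decompose(y, d, in_a):
        X = np.column_stack([np.ones(len(y)), d, in_a.astype(float)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta, delta = float(coef[1]), float(coef[2])
        f_a = d[in_a].mean() / 2.0
        f_b = d[~in_a].mean() / 2.0
        zeta = 2.0 * beta * (f_a - f_b)
        dpsi = float(y[in_a].mean() - y[~in_a].mean())
        tau = zeta / dpsi if abs(dpsi) >= dpsi_tol else np.nan
        return beta, zeta, delta, dpsi, tau

    beta, zeta, delta, dpsi, tau = _decompose(psi, dosage, a_mask)

    rng = np.random.default_rng(seed)
    ia = np.flatnonzero(a_mask)
    ib = np.flatnonzero(~a_mask)
    boots = []
    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(ia, len(ia)), rng.choice(ib, len(ib))])
        in_a = np.arange(len(idx)) < len(ia)
        try:
            boots.append(_decompose(psi[idx], dosage[idx], in_a))
        except np.linalg.LinAlgError:   # degenerate resample
            continue
    boots = np.asarray(boots) if boots else np.empty((0, 5))

    def ci(col):
        v = boots[:, col]
        v = v[np.isfinite(v)]
        if len(v) < 10:
            return (np.nan, np.nan)
        return tuple(np.percentile(v, [2.5, 97.5]))

    return dict(beta=beta, zeta=zeta, delta=delta, dpsi=dpsi, tau=tau,
                tau_defined=bool(np.isfinite(tau)),
                zeta_ci=ci(1), delta_ci=ci(2), tau_ci=ci(4),
                n=len(psi))


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def fst(
    dosages: np.ndarray,
    population: np.ndarray,
    pop_a: str = "AFB",
    pop_b: str = "EUB",
    estimator: str = "wc",
) -> np.ndarray:
    """Per-SNP FST between two populations from diploid dosages.

    Default is the Weir–Cockerham (1984) two-population estimator with
    the full a/b/c variance components (uses observed heterozygosity);
    ``estimator='hudson'`` gives the Hudson estimator as a sensitivity
    check.  Negative estimates are retained.  SNPs monomorphic in the
    pooled sample are undefined (NaN).
    """
    d = np.asarray(dosages, dtype=float)
    population = np.asarray(population, dtype=object)
    masks = [population == pop_a, population == pop_b]
    if not all(m.any() for m in masks):
        raise ValueError("both populations must be present")
    n = np.array([m.sum() for m in masks], dtype=float)     # individuals
    p = np.stack([d[:, m].mean(axis=1) / 2.0 for m in masks])  # (2, snps)
    het = np.stack([(d[:, m] == 1).mean(axis=1) for m in masks])

    pooled = d.mean(axis=1) / 2.0
    poly = (pooled > 0) & (pooled < 1)

    if estimator == "hudson":
        # allele-count based Hudson estimator
        nc = 2 * n
        num = ((p[0] - p[1]) ** 2
               - p[0] * (1 - p[0]) / (nc[0] - 1)
               - p[1] * (1 - p[1]) / (nc[1] - 1))
        den = p[0] * (1 - p[1]) + p[1] * (1 - p[0])
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[~poly] = np.nan
        return out
    if estimator != "wc":
        raise ValueError(f"unknown estimator {estimator!r}")

    r = 2.0
    n_bar = n.mean()
    n_c = (r * n_bar - (n ** 2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n[:, None] * p).sum(axis=0) / (r * n_bar)
    s2 = (n[:, None] * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n[:, None] * het).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
        / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a / (a + b + c)
    out[~poly] = np.nan
    return out


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------

def ehh_decay(
    haplotypes: np.ndarray,
    focal: int,
    carrier_cols: np.ndarray,
    positions: np.ndarray,
    cutoff: float = 0.05,
) -> tuple[float, bool]:
    """Integrated EHH (iHH, in bp) for one allele class of one SNP.

    EHH starts at 1 at the focal SNP and decays as haplotypes carrying
    the focal allele are split by flanking markers; each side is
    integrated (trapezoid over physical distance) until EHH drops below
    ``cutoff``, including the segment on which it crosses.  Returns
    (iHH_left + iHH_right, unbounded) where ``unbounded`` is True when
    either side reaches the end of the data above the cutoff.
    """
    h = haplotypes[:, carrier_cols]
    n = h.shape[1]
    if n < 2:
        return np.nan, False
    pairs_total = n * (n - 1) / 2.0
    ihh = 0.0
    unbounded = False
    for step in (-1, 1):
        groups = {(): np.arange(n)}
        prev_ehh, prev_pos = 1.0, positions[focal]
        j = focal + step
        side_done = False
        while 0 <= j < len(positions):
            new_groups = {}
            for key, cols in groups.items():
                if len(cols) < 2:
                    continue
                alleles = h[j, cols]
                for val in (0, 1):
                    sub = cols[alleles == val]
                    if len(sub) >= 2:
                        new_groups[key + (val,)] = sub
            groups = new_groups
            ehh = sum(len(c) * (len(c) - 1) / 2.0
                      for c in groups.values()) / pairs_total
            dist = abs(positions[j] - prev_pos)
            ihh += 0.5 * (prev_ehh + ehh) * dist
            prev_ehh, prev_pos = ehh, positions[j]
            if ehh < cutoff:
                side_done = True
                break
            j += step
        if not side_done and prev_ehh >= cutoff:
            unbounded = True
    return ihh, unbounded


def ihs(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    min_daf: float = 0.05,
    cutoff: float = 0.05,
    bin_width: float = 0.02,
    standardize: bool = True,
) -> pd.DataFrame:
    """Integrated haplotype score per SNP.

    ``haplotypes``: SNPs x haplotypes, 1 = derived allele.  SNPs with
    derived-allele frequency outside [``min_daf``, 1 - ``min_daf``] are
    not scored.  Unstandardized iHS = ln(iHH_ancestral / iHH_derived)
    (negative for unusually long derived haplotypes); standardization is
    to mean 0, sd 1 within derived-frequency bins of width
    ``bin_width``.  SNPs whose EHH never decays below the cutoff before
    the data ends are flagged unbounded and excluded from scores.
    """
    H = np.asarray(haplotypes)
    positions = np.asarray(positions, dtype=float)
    daf = H.mean(axis=1)
    rows = []
    for i in range(H.shape[0]):
        f = daf[i]
        if not (min_daf <= f <= 1 - min_daf):
            rows.append((f, np.nan, False))
            continue
        der = np.flatnonzero(H[i] == 1)
        anc = np.flatnonzero(H[i] == 0)
        ihh_d, ub_d = ehh_decay(H, i, der, positions, cutoff)
        ihh_a, ub_a = ehh_decay(H, i, anc, positions, cutoff)
        unbounded = ub_d or ub_a
        if (unbounded or not np.isfinite(ihh_d) or not np.isfinite(ihh_a)
                or ihh_d <= 0 or ihh_a <= 0):
            rows.append((f, np.nan, unbounded))
            continue
        rows.append((f, float(np.log(ihh_a / ihh_d)), False))
    out = pd.DataFrame(rows, columns=["daf", "ihs_raw", "unbounded"])
    if not standardize:
        out["ihs"] = out.ihs_raw
        return out
    out["bin"] = np.minimum((out.daf / bin_width).astype(int),
                            int(1 / bin_width) - 1)
    out["ihs"] = np.nan
    for _, idx in out.groupby("bin").groups.items():
        v = out.loc[idx, "ihs_raw"]
        ok = v.notna()
        if ok.sum() < 2 or v[ok].std(ddof=1) == 0:
            continue
        out.loc[idx, "ihs"] = (v - v[ok].mean()) / v[ok].std(ddof=1)
    return out.drop(columns="bin")


# ---------------------------------------------------------------------------
# outlier enrichment
# ---------------------------------------------------------------------------

def empirical_rank_p(values: np.ndarray, focal_value: float) -> float:
    """Upper-tail empirical p of a focal statistic, mid-rank for ties."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan
    greater = (v > focal_value).sum()
    equal = (v == focal_value).sum()
    return float((greater + 0.5 * equal) / len(v))


def fit_beta_moments(proportions: np.ndarray) -> tuple[float, float] | None:
    """Method-of-moments beta fit; None when the fit is degenerate."""
    x = np.asarray(proportions, dtype=float)
    x = x[np.isfinite(x)]
    m, v = x.mean(), x.var(ddof=1) if len(x) > 1 else 0.0
    if v <= 1e-12 or m <= 0 or m >= 1 or v >= m * (1 - m):
        return None
    k = m * (1 - m) / v - 1
    return m * k, (1 - m) * k


def outlier_enrichment(
    scan_values: np.ndarray,
    positions: np.ndarray,
    focal_index: int,
    window: int = 100_000,
    top_frac: float = 0.05,
    min_snps: int = 5,
) -> dict:
    """Local enrichment of selection-scan outliers around a focal SNP.

    Outliers are the genome-wide top ``top_frac`` of the scanned values.
    The count of outliers in the ``window``-bp window centred on the
    focal SNP is compared with a beta-binomial whose (alpha, beta) come
    from a method-of-moments fit to the per-window outlier proportions
    genome-wide; a degenerate fit falls back to a binomial with the
    pooled rate (flagged).  Also reports the focal SNP's mid-rank
    empirical p.  Windows with fewer than ``min_snps`` informative SNPs
    are not testable.
    """
    v = np.asarray(scan_values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    ok = np.isfinite(v)
    threshold = np.quantile(v[ok], 1 - top_frac)
    is_outlier = ok & (v >= threshold)

    # genome-wide per-window outlier proportions for the beta fit
    bins = (pos // window).astype(int)
    props, sizes = [], []
    for b in np.unique(bins):
        m = ok & (bins == b)
        if m.sum() >= min_snps:
            props.append(is_outlier[m].sum() / m.sum())
            sizes.append(m.sum())
    props = np.asarray(props)

    focal_pos = pos[focal_index]
    in_win = ok & (np.abs(pos - focal_pos) <= window / 2)
    n_in = int(in_win.sum())
    k_obs = int(is_outlier[in_win].sum())
    if n_in < min_snps:
        raise ValueError(
            f"window has {n_in} informative SNPs (< {min_snps})")

    ab = fit_beta_moments(props) if len(props) >= 2 else None
    if ab is None:
        rate = is_outlier[ok].mean()
        p_enrich = float(stats.binom.sf(k_obs - 1, n_in, rate))
        fallback = True
    else:
        p_enrich = float(stats.betabinom.sf(k_obs - 1, n_in, *ab))
        fallback = False
    return dict(
        p_emp=empirical_rank_p(v, v[focal_index]),
        p_enrich=p_enrich, n_window=n_in, n_outliers=k_obs,
        threshold=float(threshold),
        binomial_fallback=fallback,
        alpha_beta=ab)


def beta_binomial_tail(k: int, n: int, alpha: float, beta: float) -> float:
    """P(X >= k) for X ~ BetaBinomial(n, alpha, beta)."""
    return float(stats.betabinom.sf(k - 1, n, alpha, beta))


# ---------------------------------------------------------------------------
# MAF-matched resampling enrichments
# ---------------------------------------------------------------------------

def maf_matched_null_counts(
    peak_snps,
    target_set: set,
    background_snps,
    maf: dict,
    n_resamples: int = 1000,
    seed: int = 0,
    bin_width: float = 0.02,
) -> tuple[int, np.ndarray]:
    """Observed overlap of peaks with a SNP set, plus null counts from
    frequency-matched resampling.

    Each null draw samples, per 2% MAF bin, as many background SNPs
    (without replacement) as there are peak SNPs in that bin, and counts
    how many fall in ``target_set``.  Bins with too few background SNPs
    sample with replacement (logged).
    """
    rng = np.random.default_rng(seed)
    peaks = list(peak_snps)
    background = np.asarray(list(background_snps), dtype=object)
    if len(background) == 0:
        raise ValueError("empty background")

    def bin_of(s):
        return min(int(maf[s] / bin_width), int(0.5 / bin_width) - 1)

    peak_bins = pd.Series([bin_of(s) for s in peaks]).value_counts()
    bg_by_bin = {}
    for s in background:
        bg_by_bin.setdefault(bin_of(s), []).append(s)

    observed = sum(s in target_set for s in peaks)
    nulls = np.zeros(n_resamples, dtype=int)
    for b, need in peak_bins.items():
        pool = np.asarray(bg_by_bin.get(b, []), dtype=object)
        if len(pool) == 0:
            raise ValueError(f"no background SNPs in MAF bin {b}")
        replace = len(pool) < need
        if replace:
            logger.warning("MAF bin %d: %d background SNPs for %d draws; "
                           "sampling with replacement", b, len(pool), need)
        in_target = np.fromiter((s in target_set for s in pool), dtype=bool,
                                count=len(pool))
        if replace:
            take = rng.integers(0, len(pool), size=(n_resamples, need))
        else:
            # per-draw sampling without replacement, vectorised: the
            # `need` smallest of i.i.d. uniforms index a uniform subset
            u = rng.random((n_resamples, len(pool)))
            take = np.argpartition(u, need - 1, axis=1)[:, :need]
        nulls += in_target[take].sum(axis=1)
    return observed, nulls


def archaic_enrichment(
    peak_snps,
    asnp_set,
    background_snps,
    maf: dict,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict:
    """Fold enrichment of sQTL peak SNPs in an archaic SNP set.

    ``asnp_set`` should already be extended to LD tags (r2 > 0.8) where
    appropriate; ``background_snps`` is the LD-pruned scan universe.
    fold = observed / mean null count; p = fraction of null draws with a
    count >= observed.
    """
    asnp_set = set(asnp_set)
    if not asnp_set:
        raise ValueError("empty archaic SNP set")
    obs, nulls = maf_matched_null_counts(
        peak_snps, asnp_set, background_snps, maf, n_resamples, seed)
    mean_null = float(nulls.mean())
    fold = obs / mean_null if mean_null > 0 else np.inf
    p = float((nulls >= obs).mean())
    return dict(observed=obs, mean_null=mean_null, fold=fold, p_value=p,
                n_resamples=n_resamples)


def gwas_overlap_enrichment(
    peak_snps,
    category_sets: dict,
    background_snps,
    maf: dict,
    n_resamples: int = 1000,
    seed: int = 0,
    min_category: int = 10,
) -> pd.DataFrame:
    """Per-category enrichment of sQTL peaks in GWAS-associated SNP sets.

    Categories with fewer than ``min_category`` SNPs are skipped.  The
    odds ratio compares the observed overlap odds with the mean-null
    overlap odds from frequency-matched resampling.
    """
    n_peaks = len(list(peak_snps))
    rows = []
    for i, (name, snps) in enumerate(sorted(category_sets.items())):
        snps = set(snps)
        if len(snps) < min_category:
            logger.info("category %s has %d SNPs (< %d); skipped",
                        name, len(snps), min_category)
            continue
        obs, nulls = maf_matched_null_counts(
            peak_snps, snps, background_snps, maf, n_resamples,
            seed=seed + i)
        mean_null = float(nulls.mean())
        if 0 < obs < n_peaks and 0 < mean_null < n_peaks:
            oratio = ((obs / (n_peaks - obs))
                      / (mean_null / (n_peaks - mean_null)))
        else:
            oratio = np.nan
        rows.append(dict(category=name, count=obs, mean_null=mean_null,
                         odds_ratio=oratio,
                         p_value=float((nulls >= obs).mean())))
    return pd.DataFrame(rows)
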