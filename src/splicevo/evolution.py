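"""Evolutionary analysis of splice sites.

Covers conservation classes (GerpRS), phylogenetic dating of splice
sites on a dated species tree from presence/absence of the essential
dinucleotide, detection of human-specific splice sites, and enrichment
tests for recent splice sites among immune genes (matched resampling)
or among stimulation-induced genes (logistic likelihood-ratio test).

Dating uses Dollo parsimony: a splice site arises once and may be lost
any number of times, so its origin is the most recent common ancestor
of all species in which it is observed.  Alignment gaps are treated as
missing data (uninformative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: FPKM bin edges used for expression matching throughout the package
EXPRESSION_BIN_EDGES = [1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, np.inf]


def expression_bin(fpkm) -> np.ndarray:
    """Assign genes to the standard FPKM bins (1,5], (5,10], ... (1000,inf).
    Values at or below 1 FPKM fall in bin 0 (below the first edge)."""
    return np.digitize(np.asarray(fpkm, dtype=float), EXPRESSION_BIN_EDGES,
                       right=True)


# ---------------------------------------------------------------------------
# dated species tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str
    age: float = 0.0
    parent: "str | None" = None
    children: list = field(default_factory=list)


class DatedTree:
    """Rooted ultrametric species tree with node ages in million years.

    Built from a Newick string with labelled internal nodes plus a
    node -> age mapping (leaves have age 0).  Exposes the ordered list of
    ancestors of a focal leaf (default ``human``), oldest first.
    """

    def __init__(self, newick: str, ages: dict, human: str = "human"):
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=False)
        self.nodes: dict[str, _Node] = {}
        self.human = human

        def label(nd):
            if nd.taxon is not None:
                return nd.taxon.label.replace(" ", "_")
            return (nd.label or "").replace(" ", "_")

        for nd in tree.preorder_node_iter():
            name = label(nd)
            if not name:
                raise ValueError("every node must be labelled")
            node = _Node(name=name, age=float(ages.get(name, 0.0)))
            if nd.parent_node is not None:
                pname = label(nd.parent_node)
                node.parent = pname
                self.nodes[pname].children.append(name)
            else:
                self.root = name
            self.nodes[name] = node

        self.leaves = [n for n, v in self.nodes.items() if not v.children]
        if human not in self.leaves:
            raise ValueError(f"{human!r} is not a leaf of the tree")
        for name, node in self.nodes.items():
            if node.parent is not None:
                if not node.age < self.nodes[node.parent].age:
                    raise ValueError(
                        f"non-ultrametric tree: age({name})={node.age} not "
                        f"below age({node.parent})="
                        f"{self.nodes[node.parent].age}")
        self._desc_cache: dict[str, frozenset] = {}

    # -- basic queries ----------------------------------------------------
    def age(self, name: str) -> float:
        return self.nodes[name].age

    def descendants(self, name: str) -> frozenset:
        """Leaf names descending from (and including, if a leaf) ``name``."""
        if name in self._desc_cache:
            return self._desc_cache[name]
        node = self.nodes[name]
        if not node.children:
            out = frozenset([name])
        else:
            out = frozenset().union(
                *(self.descendants(c) for c in node.children))
        self._desc_cache[name] = out
        return out

    def lineage(self, leaf: str | None = None) -> list:
        """Ancestors of ``leaf`` from the root down to the leaf itself."""
        leaf = leaf or self.human
        path = [leaf]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path[::-1]

    def mrca(self, leaves) -> str:
        leaves = set(leaves)
        unknown = leaves - set(self.leaves)
        if unknown:
            raise ValueError(f"not leaves of the tree: {sorted(unknown)}")
        # walk up from any member leaf; the first ancestor covering all
        # members is the MRCA
        node = next(iter(leaves))
        while not leaves <= self.descendants(node):
            node = self.nodes[node].parent
        return node


# ---------------------------------------------------------------------------
# conservation classes
# ---------------------------------------------------------------------------

def conservation_class(gerp_rs, threshold: float = 2.0) -> pd.Series:
    """'conserved' (GerpRS > 2) vs 'non-conserved'; zero or missing scores
    are 'excluded' (likely misaligned positions)."""
    g = pd.Series(np.asarray(gerp_rs, dtype=float))
    out = pd.Series("non-conserved", index=g.index, dtype=object)
    out[g > threshold] = "conserved"
    out[(g == 0) | g.isna()] = "excluded"
    return out


# ---------------------------------------------------------------------------
# phylogenetic dating (Dollo parsimony)
# ---------------------------------------------------------------------------

def date_site(presence: dict, tree: DatedTree) -> dict:
    """Date one splice site from its species presence pattern.

    ``presence`` maps species -> 1 (present), 0 (absent) or NA/None (gap,
    uninformative).  The origin is the MRCA of all present species (single
    gain, unlimited losses).  A site present in the focal human leaf only
    is dated to the human terminal branch: its reported age is the age of
    the human parent node, flagged ``human_specific``.
    """
    human = tree.human
    val = {sp: presence.get(sp) for sp in tree.leaves}
    informative = {sp for sp, v in val.items()
                   if v is not None and not (isinstance(v, float) and np.isnan(v))}
    present = {sp for sp in informative if val[sp] == 1}
    if human not in present:
        raise ValueError("focal (human) leaf must be present to date a site")
    support = len(informative) / len(tree.leaves)
    if present == {human}:
        parent = tree.nodes[human].parent
        return dict(origin_node=parent, age=tree.age(parent),
                    support=support, human_specific=True)
    origin = tree.mrca(present)
    return dict(origin_node=origin, age=tree.age(origin),
                support=support, human_specific=False)


def date_sites(presence: pd.DataFrame, tree: DatedTree) -> pd.DataFrame:
    """Vector version: rows are sites, columns species (1/0/NaN)."""
    rows = []
    for site_id, row in presence.iterrows():
        try:
            res = date_site(row.to_dict(), tree)
        except ValueError:
            continue
        res["site_id"] = site_id
        rows.append(res)
    return pd.DataFrame(rows).set_index("site_id")


def detect_human_specific(
    presence: pd.DataFrame,
    tree: DatedTree,
    primate_clade: str = "Primates",
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Sites present in human and absent in every aligned primate.

    Requires alignment (non-missing presence call) in more than
    ``min_coverage`` of the non-human primate lineages.  Restriction to
    active splice sites of coding exons is applied by the caller.
    """
    primates = sorted(tree.descendants(primate_clade) - {tree.human})
    sub = presence[primates]
    aligned = sub.notna()
    coverage = aligned.mean(axis=1)
    present_any = (sub == 1).any(axis=1)
    human_present = presence[tree.human] == 1
    keep = human_present & (coverage > min_coverage) & ~present_any
    out = pd.DataFrame({"coverage": coverage[keep]})
    out.index.name = "site_id"
    return out


# ---------------------------------------------------------------------------
# matched resampling of splice-site ages
# ---------------------------------------------------------------------------

def matched_age_resampling(
    target_genes,
    gene_table: pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean splice-site age of a target gene set vs matched background.

    ``gene_table`` has one row per gene with columns ``mean_site_age``
    (mean phylogenetic age of the gene's splice sites), ``gene_age``
    (age of its oldest site) and ``fpkm``.  Background genes are the
    non-target rows; each resample draws, for every target gene, a random
    background gene from the same (gene-age, expression-bin) stratum.  A
    normal distribution fitted to the null means yields a two-sided p.
    """
    rng = np.random.default_rng(seed)
    tab = gene_table.copy()
    tab["expr_bin"] = expression_bin(tab["fpkm"])
    target_genes = [g for g in target_genes if g in tab.index]
    is_target = tab.index.isin(target_genes)
    background = tab[~is_target]

    strata = {}
    for key, grp in background.groupby(["gene_age", "expr_bin"]):
        strata[key] = grp["mean_site_age"].to_numpy()

    matched_pools, kept = [], []
    for g in target_genes:
        key = (tab.at[g, "gene_age"], tab.at[g, "expr_bin"])
        pool = strata.get(key)
        if pool is None or len(pool) == 0:
            logger.warning("no background genes in stratum %s; gene %s dropped",
                           key, g)
            continue
        matched_pools.append(pool)
        kept.append(g)
    if not kept:
        raise ValueError("no target gene could be matched to background")

    observed = float(tab.loc[kept, "mean_site_age"].mean())
    null = np.empty(n_resamples)
    for b in range(n_resamples):
        null[b] = np.mean([pool[rng.integers(len(pool))]
                           for pool in matched_pools])
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        p = 1.0
    else:
        p = float(2 * stats.norm.sf(abs(observed - mu) / sd))
    return dict(observed_mean_age=observed, null_mean=mu, null_sd=sd,
                p_value=min(p, 1.0), n_genes=len(kept),
                n_resamples=n_resamples)


# ---------------------------------------------------------------------------
# logistic enrichment of non-conserved sites in upregulated genes
# ---------------------------------------------------------------------------

def conservation_logistic_lrt(site_table: pd.DataFrame) -> dict:
    """Effect of gene upregulation on the probability a site is conserved.

    ``site_table`` has one row per splice site with boolean ``conserved``,
    boolean ``upregulated`` (gene log2FC > 1 in at least one condition)
    and integer ``expr_bin``.  Fits conserved ~ upregulated + C(expr_bin)
    by logistic regression and tests `upregulated` with a likelihood-ratio
    test against the nested model.  Returns OR, LRT p-value and a
    ``separation`` flag (penalised fallback fit).
    """
    import statsmodels.api as sm

    tab = site_table.copy()
    y = tab["conserved"].astype(float).to_numpy()
    up = tab["upregulated"].astype(float).to_numpy()
    if up.min() == up.max():
        raise ValueError("degenerate covariate: upregulated is constant")
    bins = pd.get_dummies(tab["expr_bin"], drop_first=True, dtype=float)
    x_full = np.column_stack([np.ones(len(y)), up, bins.to_numpy()])
    x_red = np.column_stack([np.ones(len(y)), bins.to_numpy()])

    separation = False
    try:
        full = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
        red = sm.Logit(y, x_red).fit(disp=0, maxiter=200)
        beta = full.params[1]
        llr = 2 * (full.llf - red.llf)
        if not np.isfinite(llr) or abs(beta) > 15:
            raise RuntimeError("separation suspected")
    except Exception:
        separation = True
        # ridge-penalised fits; LRT on penalised log-likelihoods
        full = sm.Logit(y, x_full).fit_regularized(
            alpha=1.0, L1_wt=0.0, disp=0)
        red = sm.Logit(y, x_red).fit_regularized(
            alpha=1.0, L1_wt=0.0, disp=0)
        beta = full.params[1]
        llr = max(0.0, 2 * (sm.Logit(y, x_full).loglike(full.params)
                            - sm.Logit(y, x_red).loglike(red.params)))
    p = float(stats.chi2.sf(max(llr, 0.0), df=1))
    return dict(odds_ratio=float(np.exp(beta)), p_value=p,
                log_or=float(beta), separation=separation)
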