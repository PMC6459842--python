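"""Synthetic cohorts emulating the monocyte stimulation study design.

The generator produces everything the downstream pipeline consumes, for
two populations of African- (AFB) and European-descent (EUB) donors
whose monocytes are profiled at rest (NS) and after four stimulations
(LPS, Pam3CSK4, R848, IAV):

* phased genotypes with population-specific allele frequencies
  (Balding–Nichols divergence or user-supplied frequency pairs),
  optionally with planted high-differentiation SNPs or selective sweeps;
* a junction read-count table per gene, with constitutive introns whose
  reads leak to cryptic partner sites at a planted error rate (modulated
  per condition and by a latent NMD-activity variable), and one cassette
  (skipped-exon) event per gene whose inclusion fraction responds to
  planted sQTL effects and condition shifts;
* gene expression (FPKM) with planted eQTL effects and NMD-pathway
  genes driven by the latent NMD activity; intronic read counts as a
  transcription-rate proxy;
* per-site conservation scores and a species presence/absence matrix on
  a dated vertebrate tree with planted origin nodes;
* a truth ledger recording every planted effect for parameter-recovery
  tests.

Simulation starts at junction counts; no read-level data are produced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import catalog as cat
from .evolution import DatedTree

CONDITIONS = ("NS", "LPS", "Pam3CSK4", "R848", "IAV")

#: NMD pathway genes summarised by their first principal component
NMD_GENES = ("UPF1", "UPF2", "UPF3", "SMG1", "SMG2", "SMG3", "SMG4",
             "SMG5", "SMG6", "SMG7", "SMG8", "SMG9")

#: condition-wise multiplier on the baseline splicing-error rate
DEFAULT_NOISE_MULTIPLIERS = {"NS": 1.0, "LPS": 1.25, "Pam3CSK4": 1.25,
                             "R848": 1.45, "IAV": 1.6}

#: condition-wise mean of the latent NMD activity (lower upon stimulation)
NMD_ACTIVITY_MEAN = {"NS": 0.0, "LPS": -0.5, "Pam3CSK4": -0.5,
                     "R848": -0.8, "IAV": -1.0}


# ---------------------------------------------------------------------------
# species tree used for the conservation / phylogeny emulation
# ---------------------------------------------------------------------------

def build_species_tree() -> tuple[str, dict]:
    """Newick string with labelled nodes and node -> age (MY) mapping."""
    topo = (
        "Vertebrata",
        [("Amniota",
          [("Theria",
            [("Boreoeutheria",
              [("Euarchontoglires",
                [("Primates",
                  [("Haplorrhini",
                    [("Simiiformes",
                      [("Catarrhini",
                        [("Hominoidea",
                          [("Hominidae",
                            [("Homininae",
                              [("Hominini", ["human", "chimp"]),
                               "gorilla"]),
                             "orangutan"]),
                           "gibbon"]),
                         ("Cercopithecidae",
                          ["macaque",
                           ("Papionini", ["baboon", "vervet"])])]),
                       ("Platyrrhini", ["marmoset", "squirrel_monkey"])]),
                     "tarsier"]),
                   ("Strepsirrhini", ["mouse_lemur", "bushbaby"])]),
                 "mouse"]),
               "dog"]),
             "opossum"]),
           "chicken"]),
         "zebrafish"])

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        name, children = node
        return "(" + ",".join(to_newick(c) for c in children) + ")" + name

    newick = to_newick(topo) + ";"
    ages = {
        "Hominini": 6.5, "Homininae": 9.0, "Hominidae": 16.0,
        "Hominoidea": 20.0, "Papionini": 12.0, "Cercopithecidae": 15.0,
        "Catarrhini": 29.0, "Platyrrhini": 20.0, "Simiiformes": 43.0,
        "Haplorrhini": 60.0, "Strepsirrhini": 59.0, "Primates": 74.0,
        "Euarchontoglires": 90.0, "Boreoeutheria": 96.0, "Theria": 173.0,
        "Amniota": 320.0, "Vertebrata": 450.0,
    }
    return newick, ages


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the study design (two populations of 100 male donors,
    five conditions) at a gene count small enough for desk-scale runs.
    ``sqtl_effects`` / ``eqtl_effects`` may be given explicitly (lists of
    dicts, see :func:`default_effects`) or left ``None`` to be drawn.
    sQTL betas are interpreted on the PSI scale (change in PSI per
    alternative allele near the gene's baseline PSI) and planted on the
    logit scale with a slope-matched conversion; liabilities are
    truncated to [0.01, 0.99].
    """

    n_individuals_per_pop: tuple = (100, 100)
    conditions: tuple = CONDITIONS
    n_genes: int = 30
    n_sites_per_gene: int = 4        # constitutive introns per gene
    n_snps_per_gene: int = 10
    read_depth: float = 50.0         # mean spliced reads per site per sample
    sqtl_effects: list | None = None
    eqtl_effects: list | None = None
    causal_links: list | None = None  # dicts: gene, snp, model, b_gs, b_se
    pop_freq_pairs: np.ndarray | None = None   # (n_snps, 2): f_AFB, f_EUB
    fst_divergence: float = 0.1      # Balding-Nichols F
    noise_error_rate: float | np.ndarray | None = None  # per-gene in [0,1]
    baseline_psi: float | np.ndarray | None = None      # per-gene in (0,1)
    noise_stim_multiplier: dict = field(
        default_factory=lambda: dict(DEFAULT_NOISE_MULTIPLIERS))
    nmd_coupling: float = -0.5       # NMD expression -> error survival
    selection_sites: list = field(default_factory=list)
    frac_sqtl_genes: float = 0.2
    frac_eqtl_genes: float = 0.2
    frac_responsive_genes: float = 0.4
    frac_low_expressed: float = 0.1
    psi_individual_sd: float = 0.25  # logit-scale residual between donors
    batch_shift: float = 0.0         # optional planted batch effect (logit)
    alignment_dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_individuals_per_pop, int):
            self.n_individuals_per_pop = (self.n_individuals_per_pop,) * 2
        if self.pop_freq_pairs is not None:
            f = np.asarray(self.pop_freq_pairs, dtype=float)
            if ((f < 0) | (f > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")
            self.pop_freq_pairs = f
        if self.noise_error_rate is not None:
            r = np.atleast_1d(np.asarray(self.noise_error_rate, dtype=float))
            if ((r < 0) | (r > 1)).any():
                raise ValueError("noise_error_rate must lie in [0, 1]")
        if self.baseline_psi is not None:
            b = np.atleast_1d(np.asarray(self.baseline_psi, dtype=float))
            if ((b <= 0) | (b >= 1)).any():
                raise ValueError("baseline_psi must lie in (0, 1)")
        for v in self.noise_stim_multiplier.values():
            if v < 0:
                raise ValueError("noise multipliers must be non-negative")
        if not 0 <= self.alignment_dropout < 1:
            raise ValueError("alignment_dropout must lie in [0, 1)")

    @property
    def n_snps(self) -> int:
        if self.pop_freq_pairs is not None:
            return len(self.pop_freq_pairs)
        return self.n_genes * self.n_snps_per_gene


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """SNPs x individuals dosage matrix with phased haplotypes.

    The REF allele is ancestral by construction; ALT is derived.
    ``dosages`` has shape (n_snps, n_individuals) with values {0, 1, 2}.
    ``haplotypes`` has shape (n_snps, 2 * n_individuals), haplotypes of
    one individual adjacent.
    """

    def __init__(self, snp_ids, chrom, pos, ref, alt, haplotypes,
                 individuals, populations):
        self.snp_ids = np.asarray(snp_ids, dtype=object)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.haplotypes = np.asarray(haplotypes, dtype=np.int8)
        self.individuals = np.asarray(individuals, dtype=object)
        self.populations = np.asarray(populations, dtype=object)
        self.dosages = (self.haplotypes[:, 0::2]
                        + self.haplotypes[:, 1::2]).astype(np.int8)
        self.ancestral_is_ref = np.ones(len(self.snp_ids), dtype=bool)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __len__(self) -> int:
        return len(self.snp_ids)

    def loc(self, snp_id) -> int:
        return self._index[snp_id]

    def allele_freq(self, population: str | None = None) -> np.ndarray:
        """Derived (ALT) allele frequency, optionally within one population."""
        if population is None:
            d = self.dosages
        else:
            d = self.dosages[:, self.populations == population]
        return d.mean(axis=1) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1 - f)

    # -- I/O --------------------------------------------------------------
    def write_vcf(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                     'Description="Ancestral allele">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            for c in pd.unique(self.chrom):
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.individuals) + "\n")
            h = self.haplotypes
            for i in range(len(self)):
                gts = "\t".join(f"{h[i, 2*j]}|{h[i, 2*j+1]}"
                                for j in range(len(self.individuals)))
                fh.write(f"{self.chrom[i]}\t{self.pos[i] + 1}\t"
                         f"{self.snp_ids[i]}\t{self.ref[i]}\t{self.alt[i]}\t"
                         f".\tPASS\tAA={self.ref[i]}\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path: str, populations: dict | None = None
                 ) -> "GenotypeMatrix":
        """Read a (phased) VCF with cyvcf2; ``populations`` maps individual
        id -> population label (default: first three id characters)."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        pops = [populations[s] if populations else s[:3] for s in individuals]
        ids, chroms, poss, refs, alts, haps = [], [], [], [], [], []
        for var in vcf:
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            chroms.append(var.CHROM)
            poss.append(var.POS - 1)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            gt = np.asarray(var.genotype.array())[:, :2]
            haps.append(gt.reshape(-1))
        return cls(ids, chroms, poss, refs, alts,
                   np.asarray(haps), individuals, pops)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw phased genotypes for the two populations.

    Per-SNP population allele frequencies come from ``pop_freq_pairs`` or
    a Balding–Nichols model with divergence ``fst_divergence``; haplotype
    alleles are Bernoulli draws at the population frequency.  Planted
    selection sites override frequencies ('fst' kind) or copy an extended
    haplotype onto derived-allele carriers ('sweep' kind).
    """
    rng = np.random.default_rng(config.seed)
    n_afb, n_eub = config.n_individuals_per_pop
    n_snps = config.n_snps

    if config.pop_freq_pairs is not None:
        freqs = config.pop_freq_pairs
    else:
        f_anc = rng.uniform(0.05, 0.95, n_snps)
        F = config.fst_divergence
        a, b = f_anc * (1 - F) / F, (1 - f_anc) * (1 - F) / F
        freqs = np.column_stack([rng.beta(a, b), rng.beta(a, b)])

    # positions on a toy contig: one 1 Mb block per gene
    n_per_gene = max(1, int(np.ceil(n_snps / max(config.n_genes, 1))))
    pos = []
    for g in range(config.n_genes):
        lo, hi = g * 1_000_000 + 20_000, (g + 1) * 1_000_000 - 20_000
        k = min(n_per_gene, n_snps - len(pos))
        pos.extend(sorted(rng.integers(lo, hi, k)))
        if len(pos) >= n_snps:
            break
    while len(pos) < n_snps:  # more SNPs than gene blocks can hold
        pos.append(pos[-1] + 1000)
    pos = np.asarray(pos[:n_snps])

    individuals = ([f"AFB{i:03d}" for i in range(n_afb)]
                   + [f"EUB{i:03d}" for i in range(n_eub)])
    populations = np.array(["AFB"] * n_afb + ["EUB"] * n_eub, dtype=object)

    def _site_index(spec):
        if "snp" in spec:       # id of the form snpNNNNN
            return int(str(spec["snp"]).removeprefix("snp"))
        if "snp_index" in spec:
            return int(spec["snp_index"])
        return int(rng.integers(n_snps))

    # selection overrides on frequencies, before drawing haplotypes
    selection_truth = []
    for spec in config.selection_sites:
        idx = _site_index(spec)
        if spec.get("kind", "fst") == "fst":
            freqs[idx] = (spec.get("f_afb", 0.95), spec.get("f_eub", 0.05))
            selection_truth.append(dict(kind="fst", snp_index=idx,
                                        f_afb=float(freqs[idx, 0]),
                                        f_eub=float(freqs[idx, 1])))

    hap = np.empty((n_snps, 2 * (n_afb + n_eub)), dtype=np.int8)
    hap[:, :2 * n_afb] = (
        rng.random((n_snps, 2 * n_afb)) < freqs[:, [0]]).astype(np.int8)
    hap[:, 2 * n_afb:] = (
        rng.random((n_snps, 2 * n_eub)) < freqs[:, [1]]).astype(np.int8)

    # sweep planting: one extended derived haplotype background
    for spec in config.selection_sites:
        if spec.get("kind") != "sweep":
            continue
        idx = _site_index(spec)
        daf = float(spec.get("derived_freq", 0.2))
        flank = int(spec.get("flank_bp", 300_000))
        pop = spec.get("population")  # None = both
        cols = np.arange(hap.shape[1])
        if pop is not None:
            ind_mask = populations == pop
            cols = cols[np.repeat(ind_mask, 2)]
        n_car = max(2, int(round(daf * len(cols))))
        carriers = rng.choice(cols, size=n_car, replace=False)
        template = int(rng.choice(carriers))
        region = np.flatnonzero(np.abs(pos - pos[idx]) <= flank)
        hap[np.ix_(region, carriers)] = hap[region, template][:, None]
        hap[idx, :] = 0
        hap[idx, carriers] = 1
        selection_truth.append(dict(kind="sweep", snp_index=idx,
                                    derived_freq=daf, flank_bp=flank,
                                    population=pop))

    snp_ids = [f"snp{i:05d}" for i in range(n_snps)]
    gm = GenotypeMatrix(snp_ids, ["chr1"] * n_snps, pos,
                        ["A"] * n_snps, ["G"] * n_snps, hap,
                        individuals, populations)
    gm.selection_truth = selection_truth
    return gm


# ---------------------------------------------------------------------------
# gene structures
# ---------------------------------------------------------------------------

@dataclass
class _GeneStructure:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    constitutive: list          # canonical (start, end) introns
    cryptic_acc: list           # donor-side cryptic junctions
    cryptic_don: list           # acceptor-side cryptic junctions
    inc_up: tuple
    inc_down: tuple
    skip: tuple
    intron_length: int
    exons_inclusion: list       # exon (start, end) of the inclusion isoform
    exons_exclusion: list


def _build_gene_structures(config: SimConfig, intron_lengths) -> list:
    structures = []
    exon = 150
    for g in range(config.n_genes):
        il = int(intron_lengths[g])
        gid = f"gene{g:03d}"
        strand = "+" if g % 2 == 0 else "-"
        x = g * 1_000_000 + 100_000
        gstart = x
        exons, constitutive, cr_acc, cr_don = [], [], [], []
        x += 200  # first exon
        exons.append((gstart, x))
        for _ in range(config.n_sites_per_gene):
            s, e = x, x + il
            constitutive.append((s, e))
            cr_acc.append((s, s + 150))      # donor joined to cryptic acceptor
            cr_don.append((e - 150, e))      # cryptic donor joined to acceptor
            x = e + exon
            exons.append((e, x))
        # cassette exon: inc_up + cassette + inc_down vs skip
        a1 = x
        b1 = a1 + il
        cass = (b1, b1 + 120)
        a2 = cass[1]
        b2 = a2 + il
        last = (b2, b2 + 300)
        structures.append(_GeneStructure(
            gene_id=gid, chrom="chr1", strand=strand, start=gstart,
            end=last[1], constitutive=constitutive, cryptic_acc=cr_acc,
            cryptic_don=cr_don, inc_up=(a1, b1), inc_down=(a2, b2),
            skip=(a1, b2), intron_length=il,
            exons_inclusion=exons + [cass, last],
            exons_exclusion=exons + [last],
        ))
    return structures


def _annotation_from_structures(structures, func_classes) -> cat.GeneAnnotation:
    genes, tx, junctions, coding_junctions, exon_rows = [], [], set(), set(), []
    for st, fc in zip(structures, func_classes):
        genes.append(dict(gene_id=st.gene_id, chrom=st.chrom, start=st.start,
                          end=st.end, strand=st.strand))
        for s, e in st.constitutive + [st.inc_up, st.inc_down, st.skip]:
            junctions.add((st.chrom, s, e))
        for s, e in st.constitutive:
            coding_junctions.add((st.chrom, s, e))
        ref_coding = fc in ("modified_protein", "loss_of_function")
        alt_coding = fc in ("modified_protein", "gain_of_function")
        tx.append(dict(transcript_id=f"{st.gene_id}.t1", gene_id=st.gene_id,
                       coding=ref_coding,
                       n_exons=len(st.exons_inclusion),
                       length=sum(b - a for a, b in st.exons_inclusion)))
        tx.append(dict(transcript_id=f"{st.gene_id}.t2", gene_id=st.gene_id,
                       coding=alt_coding,
                       n_exons=len(st.exons_exclusion),
                       length=sum(b - a for a, b in st.exons_exclusion)))
        for tid, exons in ((f"{st.gene_id}.t1", st.exons_inclusion),
                           (f"{st.gene_id}.t2", st.exons_exclusion)):
            for a, b in sorted(exons):
                exon_rows.append(dict(transcript_id=tid, gene_id=st.gene_id,
                                      chrom=st.chrom, start=a, end=b,
                                      strand=st.strand))
    return cat.GeneAnnotation(genes=pd.DataFrame(genes),
                              transcripts=pd.DataFrame(tx),
                              annotated_junctions=junctions,
                              coding_junctions=coding_junctions,
                              exons=pd.DataFrame(exon_rows))


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SimConfig
    genotypes: GenotypeMatrix
    junctions: pd.DataFrame
    fpkm: pd.DataFrame
    intronic_counts: pd.DataFrame
    metadata: pd.DataFrame
    annotation: cat.GeneAnnotation
    events: pd.DataFrame
    gerp: pd.DataFrame
    presence: pd.DataFrame
    tree: DatedTree
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.genotypes.write_vcf(out / "genotypes.vcf")
        cat.write_junctions(self.junctions, out / "junctions.tsv")
        self.fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        self.intronic_counts.to_csv(out / "intronic_counts.tsv", sep="\t")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.events.to_csv(out / "events.tsv", sep="\t", index=False)
        self.gerp.to_csv(out / "gerp.tsv", sep="\t", index=False)
        self.presence.to_csv(out / "presence.tsv", sep="\t")
        newick, ages = build_species_tree()
        (out / "tree.nwk").write_text(newick + "\n")
        pd.DataFrame(sorted(ages.items()),
                     columns=["node", "age_my"]).to_csv(
            out / "node_ages.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)
        write_gtf(self.annotation, out / "genes.gtf")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def write_gtf(annotation: cat.GeneAnnotation, path) -> None:
    """Write genes/transcripts/exons as a minimal GTF (1-based closed)."""
    tx = annotation.transcripts
    coding_of = (dict(zip(tx.transcript_id, tx.coding))
                 if tx is not None and len(tx) else {})
    with open(path, "w") as fh:
        for g in annotation.genes.itertuples(index=False):
            fh.write(f"{g.chrom}\tsplicevo\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n")
            if annotation.exons is None:
                continue
            ex = annotation.exons[annotation.exons.gene_id == g.gene_id]
            for tid, sub in ex.groupby("transcript_id"):
                biotype = ("protein_coding" if coding_of.get(tid, True)
                           else "processed_transcript")
                attrs = (f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                         f'transcript_biotype "{biotype}";')
                fh.write(f"{g.chrom}\tsplicevo\ttranscript\t"
                         f"{sub.start.min() + 1}\t{sub.end.max()}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")
                for r in sub.sort_values("start").itertuples(index=False):
                    fh.write(f"{g.chrom}\tsplicevo\texon\t{r.start + 1}\t"
                             f"{r.end}\t.\t{g.strand}\t.\t{attrs}\n")


def default_effects(config: SimConfig, genotypes: GenotypeMatrix,
                    rng: np.random.Generator) -> tuple[list, list]:
    """Draw default sQTL and eQTL effect lists when none are supplied.

    sQTL sharing configurations mirror the study's sharing spectrum:
    most planted effects act in all five conditions, a minority in a
    single condition.
    """
    n_genes = config.n_genes
    conds = list(config.conditions)
    maf = genotypes.maf()
    pos = genotypes.pos

    def pick_snp(g):
        lo, hi = g * 1_000_000, (g + 1) * 1_000_000
        ok = np.flatnonzero((pos >= lo) & (pos < hi) & (maf >= 0.05))
        if len(ok) == 0:
            ok = np.flatnonzero(maf >= 0.05)
        return int(rng.choice(ok))

    sqtl, eqtl = [], []
    for g in rng.choice(n_genes, max(1, int(config.frac_sqtl_genes * n_genes)),
                        replace=False):
        beta = float(rng.uniform(0.1, 0.3) * rng.choice([-1, 1]))
        u = rng.random()
        if u < 0.7:
            betas = {c: beta for c in conds}
        elif u < 0.85:
            only = conds[int(rng.integers(1, len(conds)))]
            betas = {c: (beta if c == only else 0.0) for c in conds}
        else:
            active = rng.random(len(conds)) < 0.6
            active[0] = True
            betas = {c: (beta if a else 0.0) for c, a in zip(conds, active)}
        sqtl.append(dict(gene=f"gene{g:03d}",
                         snp=str(genotypes.snp_ids[pick_snp(g)]),
                         beta_psi=betas))
    for g in rng.choice(n_genes, max(1, int(config.frac_eqtl_genes * n_genes)),
                        replace=False):
        eqtl.append(dict(gene=f"gene{g:03d}",
                         snp=str(genotypes.snp_ids[pick_snp(g)]),
                         beta_log2=float(rng.uniform(0.3, 0.8)
                                         * rng.choice([-1, 1]))))
    return sqtl, eqtl


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (deterministic given the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    genotypes = simulate_genotypes(config)
    n_genes = config.n_genes
    conds = list(config.conditions)
    gene_ids = [f"gene{g:03d}" for g in range(n_genes)]

    # --- per-gene latent parameters -------------------------------------
    if config.noise_error_rate is None:
        noise_rate = 10 ** rng.uniform(-3.0, np.log10(0.05), n_genes)
    else:
        noise_rate = np.broadcast_to(
            np.atleast_1d(np.asarray(config.noise_error_rate, float)),
            (n_genes,)).copy()
    z = ((np.log10(np.maximum(noise_rate, 1e-6)) + 2.15) / 0.85)
    intron_len = np.clip(
        np.round(10 ** (3.0 + 0.35 * z + rng.normal(0, 0.1, n_genes))),
        400, 50_000).astype(int)
    log2_base_fpkm = 5.2 - 0.6 * z + rng.normal(0, 0.8, n_genes)
    low = rng.random(n_genes) < config.frac_low_expressed
    log2_base_fpkm[low] = rng.uniform(-3.0, -0.5, int(low.sum()))

    if config.baseline_psi is None:
        base_psi = np.clip(rng.uniform(0.25, 0.75, n_genes), 0.05, 0.95)
    else:
        base_psi = np.broadcast_to(
            np.atleast_1d(np.asarray(config.baseline_psi, float)),
            (n_genes,)).copy()
    base_logit = logit(base_psi)

    # condition responsiveness (expression log2FC and splicing shifts)
    responsive = rng.random(n_genes) < config.frac_responsive_genes
    log2fc = np.zeros((n_genes, len(conds)))
    dpsi_shift = np.zeros((n_genes, len(conds)))
    shift_prob = {"LPS": 0.35, "Pam3CSK4": 0.35, "R848": 0.55, "IAV": 0.65}
    for j, c in enumerate(conds):
        if c == "NS":
            continue
        hit = responsive & (rng.random(n_genes) < shift_prob.get(c, 0.4))
        log2fc[:, j] = np.where(
            responsive, rng.normal(0, 1.0, n_genes), 0.0)
        dpsi_shift[hit, j] = (rng.uniform(0.05, 0.2, int(hit.sum()))
                              * rng.choice([-1, 1], int(hit.sum())))

    func_classes = rng.choice(
        ["modified_protein", "loss_of_function", "gain_of_function",
         "non_coding"], n_genes, p=[0.56, 0.20, 0.17, 0.07])

    structures = _build_gene_structures(config, intron_len)
    annotation = _annotation_from_structures(structures, func_classes)

    # --- samples ---------------------------------------------------------
    individuals = genotypes.individuals
    n_ind = len(individuals)
    samples, meta_rows = [], []
    for c in conds:
        for i, ind in enumerate(individuals):
            s = f"{ind}-{c}"
            samples.append(s)
            meta_rows.append(dict(sample=s, individual=ind,
                                  population=genotypes.populations[i],
                                  condition=c,
                                  batch=int(i % 2),
                                  lib_size=float(rng.normal(30e6, 2e6))))
    metadata = pd.DataFrame(meta_rows)
    n_samp = len(samples)
    cond_idx = np.repeat(np.arange(len(conds)), n_ind)

    # latent NMD activity per sample, and the NMD-pathway gene expression
    mu = np.array([NMD_ACTIVITY_MEAN.get(c, -0.6) for c in conds])
    nmd_latent = rng.normal(mu[cond_idx], 0.3)
    nmd_fpkm = 2 ** (np.log2(20.0)
                     + 0.7 * nmd_latent[None, :]
                     + rng.normal(0, 0.15, (len(NMD_GENES), n_samp)))

    # --- planted genetic effects -----------------------------------------
    if config.sqtl_effects is None or config.eqtl_effects is None:
        d_sqtl, d_eqtl = default_effects(config, genotypes, rng)
        sqtl_effects = (config.sqtl_effects if config.sqtl_effects is not None
                        else d_sqtl)
        eqtl_effects = (config.eqtl_effects if config.eqtl_effects is not None
                        else d_eqtl)
    else:
        sqtl_effects, eqtl_effects = config.sqtl_effects, config.eqtl_effects
    causal_links = config.causal_links or []

    gene_index = {g: i for i, g in enumerate(gene_ids)}

    def _check(entry):
        if entry["gene"] not in gene_index:
            raise ValueError(f"effect on absent gene {entry['gene']!r}")
        if entry["snp"] not in genotypes._index:
            raise ValueError(f"effect on absent SNP {entry['snp']!r}")

    for e in list(sqtl_effects) + list(eqtl_effects) + list(causal_links):
        _check(e)

    # --- PSI liabilities --------------------------------------------------
    dos_ind = genotypes.dosages  # (n_snps, n_ind)
    lia = np.tile(base_logit[:, None], (1, n_samp))
    lia += dpsi_shift[:, cond_idx] / (base_psi * (1 - base_psi))[:, None]
    ind_noise = rng.normal(0, config.psi_individual_sd, (n_genes, n_ind))
    lia += ind_noise[:, np.tile(np.arange(n_ind), len(conds))]
    if config.batch_shift:
        batch = metadata.batch.to_numpy()
        lia += config.batch_shift * batch[None, :]

    sqtl_truth = []
    for eff in sqtl_effects:
        gi = gene_index[eff["gene"]]
        si = genotypes.loc(eff["snp"])
        # secant-matched conversion: the logit-scale effect is chosen so
        # that the PSI change from dosage 0 to 2 equals 2 * beta_psi
        # (clipped at the liability truncation bounds), keeping the
        # per-allele PSI interpretation of beta accurate
        p0 = base_psi[gi]
        beta_logit = {
            c: 0.0 if b == 0 else
            float((logit(np.clip(p0 + 2 * b, 0.011, 0.989)) - logit(p0)) / 2)
            for c, b in eff["beta_psi"].items()}
        d = dos_ind[si][np.tile(np.arange(n_ind), len(conds))]
        bvec = np.array([beta_logit.get(conds[j], 0.0) for j in cond_idx])
        lia[gi] += bvec * d
        sqtl_truth.append(dict(gene=eff["gene"], snp=eff["snp"],
                               event=f"{eff['gene']}.SE1",
                               beta_psi=eff["beta_psi"],
                               beta_logit=beta_logit))

    # --- expression -------------------------------------------------------
    log2fpkm = (log2_base_fpkm[:, None] + log2fc[:, cond_idx]
                + rng.normal(0, 0.3, (n_genes, n_samp)))
    eqtl_truth = []
    for eff in eqtl_effects:
        gi = gene_index[eff["gene"]]
        si = genotypes.loc(eff["snp"])
        d = dos_ind[si][np.tile(np.arange(n_ind), len(conds))]
        log2fpkm[gi] += eff["beta_log2"] * d
        eqtl_truth.append(dict(gene=eff["gene"], snp=eff["snp"],
                               beta_log2=eff["beta_log2"]))

    # --- causal links between splicing and expression --------------------
    causal_truth = []
    for link in causal_links:
        gi = gene_index[link["gene"]]
        si = genotypes.loc(link["snp"])
        d = dos_ind[si][np.tile(np.arange(n_ind), len(conds))]
        model = link["model"]
        b_gs = float(link.get("b_gs", 0.5))
        b_se = float(link.get("b_se", 0.6))
        if model == "causal":            # g -> s -> e
            lia[gi] += b_gs * (d - d.mean())
            log2fpkm[gi] += b_se * (lia[gi] - lia[gi].mean())
        elif model == "reactive":        # g -> e -> s
            log2fpkm[gi] += b_gs * (d - d.mean())
            lia[gi] += b_se * (log2fpkm[gi] - log2fpkm[gi].mean())
        elif model == "independent":     # g -> s, g -> e
            lia[gi] += b_gs * (d - d.mean())
            log2fpkm[gi] += b_se * (d - d.mean())
        else:
            raise ValueError(f"unknown causal model {model!r}")
        causal_truth.append(dict(gene=link["gene"], snp=link["snp"],
                                 model=model, b_gs=b_gs, b_se=b_se))

    fpkm = pd.DataFrame(2.0 ** log2fpkm, index=gene_ids, columns=samples)
    fpkm = pd.concat([fpkm, pd.DataFrame(nmd_fpkm, index=list(NMD_GENES),
                                         columns=samples)])

    psi = np.clip(expit(lia), 0.01, 0.99)

    # --- junction read counts --------------------------------------------
    mult = np.array([config.noise_stim_multiplier.get(c, 1.0) for c in conds])
    survival = np.exp(config.nmd_coupling * nmd_latent)
    err = np.clip(noise_rate[:, None] * mult[cond_idx][None, :]
                  * survival[None, :], 0.0, 0.4)

    depth = config.read_depth
    jrows, counts = [], []
    for g, st in enumerate(structures):
        lam_err = depth * err[g] / (1 - err[g])
        for (s, e), (cs, ce), (ds, de) in zip(
                st.constitutive, st.cryptic_acc, st.cryptic_don):
            canonical = rng.poisson(depth, n_samp)
            e_d = rng.poisson(lam_err)
            e_a = rng.poisson(lam_err)
            jrows.append((st.chrom, s, e, st.strand, st.gene_id))
            counts.append(canonical)
            jrows.append((st.chrom, cs, ce, st.strand, st.gene_id))
            counts.append(e_d)
            jrows.append((st.chrom, ds, de, st.strand, st.gene_id))
            counts.append(e_a)
        # each junction is covered at the full rate of its isoform: both
        # inclusion junctions at depth * psi, the skip junction at
        # depth * (1 - psi)
        j_up = rng.poisson(depth * psi[g])
        j_down = rng.poisson(depth * psi[g])
        j_skip = rng.poisson(depth * (1 - psi[g]))
        for (s, e), c in ((st.inc_up, j_up), (st.inc_down, j_down),
                          (st.skip, j_skip)):
            jrows.append((st.chrom, s, e, st.strand, st.gene_id))
            counts.append(c)
    junctions = pd.DataFrame(jrows, columns=cat.JUNCTION_META_COLS)
    junctions = pd.concat(
        [junctions, pd.DataFrame(np.asarray(counts), columns=samples)], axis=1)

    # --- intronic read counts (transcription-rate proxy) ------------------
    lam = (2.0 ** (0.8 * log2fpkm)) * (intron_len[:, None] / 1000.0) * 0.5
    intronic = pd.DataFrame(rng.poisson(lam), index=gene_ids, columns=samples)

    # --- events table -----------------------------------------------------
    ev_rows = []
    for st, fc in zip(structures, func_classes):
        ev_rows.append(dict(
            event_id=f"{st.gene_id}.SE1", gene_id=st.gene_id, type="SE",
            inclusion_junctions=_fmt_junctions(st.chrom,
                                               [st.inc_up, st.inc_down]),
            exclusion_junctions=_fmt_junctions(st.chrom, [st.skip]),
            start=st.inc_up[0], end=st.skip[1], chrom=st.chrom,
            strand=st.strand, ref_transcript=f"{st.gene_id}.t1",
            alt_transcript=f"{st.gene_id}.t2", functional_class=fc))
    events = pd.DataFrame(ev_rows)

    # --- conservation + phylogeny ----------------------------------------
    gerp, presence, tree, origins = simulate_conservation_and_phylogeny(
        config, structures, rng)

    truth = dict(
        genes=[dict(gene_id=gene_ids[g], noise_rate=float(noise_rate[g]),
                    base_fpkm=float(2 ** log2_base_fpkm[g]),
                    baseline_psi=float(base_psi[g]),
                    intron_length=int(intron_len[g]),
                    low_expressed=bool(low[g]),
                    functional_class=str(func_classes[g]),
                    log2fc={c: float(log2fc[g, j])
                            for j, c in enumerate(conds)},
                    dpsi_shift={c: float(dpsi_shift[g, j])
                                for j, c in enumerate(conds)})
               for g in range(n_genes)],
        sqtl=sqtl_truth, eqtl=eqtl_truth, causal=causal_truth,
        selection=getattr(genotypes, "selection_truth", []),
        nmd_coupling=config.nmd_coupling,
        noise_multipliers=dict(config.noise_stim_multiplier),
        site_origins=origins,
        batch_shift=config.batch_shift,
    )

    return SyntheticCohort(
        config=config, genotypes=genotypes, junctions=junctions, fpkm=fpkm,
        intronic_counts=intronic, metadata=metadata, annotation=annotation,
        events=events, gerp=gerp, presence=presence, tree=tree, truth=truth)


def _fmt_junctions(chrom, introns) -> str:
    return ";".join(f"{chrom}:{s}-{e}" for s, e in introns)


# ---------------------------------------------------------------------------
# conservation scores, presence matrix, dated tree
# ---------------------------------------------------------------------------

def simulate_conservation_and_phylogeny(
    config: SimConfig,
    structures: list | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, DatedTree, dict]:
    """Per-site GerpRS scores, species presence matrix and dated tree.

    Canonical (constitutive and event) sites are drawn conserved with old
    planted origins; cryptic partner sites are non-conserved with recent
    origins.  Presence of a site in a species is determined by the planted
    origin node (present in all its leaf descendants, absent elsewhere),
    then degraded by ``alignment_dropout`` into missing calls.
    Returns (gerp table, presence matrix, tree, origin truth).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    newick, ages = build_species_tree()
    tree = DatedTree(newick, ages)
    if structures is None:
        if config.noise_error_rate is None:
            lens = np.full(config.n_genes, 1000)
        else:
            lens = np.full(config.n_genes, 1000)
        structures = _build_gene_structures(config, lens)

    site_rows = []  # (site_id, kind_of_site)
    for st in structures:
        for s, e in st.constitutive:
            d, a = cat.junction_site_keys(st.chrom, s, e, st.strand)
            site_rows += [(cat.site_id_str(d), "constitutive"),
                          (cat.site_id_str(a), "constitutive")]
        # the novel (cryptic) site of a partner junction is the boundary it
        # does NOT share with the canonical intron, whichever role (donor or
        # acceptor) that boundary plays on the gene's strand
        for s, e in st.cryptic_acc:  # shares the canonical start
            d, a = cat.junction_site_keys(st.chrom, s, e, st.strand)
            novel = a if a[3] == e - 2 else d
            site_rows.append((cat.site_id_str(novel), "cryptic"))
        for s, e in st.cryptic_don:  # shares the canonical end
            d, a = cat.junction_site_keys(st.chrom, s, e, st.strand)
            novel = d if d[3] == s else a
            site_rows.append((cat.site_id_str(novel), "cryptic"))
        for s, e in (st.inc_up, st.inc_down, st.skip):
            d, a = cat.junction_site_keys(st.chrom, s, e, st.strand)
            site_rows += [(cat.site_id_str(d), "alternative"),
                          (cat.site_id_str(a), "alternative")]
    seen, uniq = set(), []
    for sid, kind in site_rows:
        if sid not in seen:
            seen.add(sid)
            uniq.append((sid, kind))

    origin_choices = {
        "constitutive": (["Vertebrata", "Amniota", "Theria", "Catarrhini"],
                         [0.70, 0.15, 0.10, 0.05]),
        "alternative": (["Amniota", "Theria", "Boreoeutheria", "Simiiformes",
                         "Catarrhini"], [0.25, 0.30, 0.15, 0.15, 0.15]),
        "cryptic": (["human", "Hominini", "Homininae", "Catarrhini"],
                    [0.40, 0.30, 0.20, 0.10]),
    }
    gerp_params = {"constitutive": (4.5, 0.8), "alternative": (3.2, 1.0),
                   "cryptic": (0.8, 0.5)}

    leaves = tree.leaves
    gerp_rows, pres_rows, origins = [], [], {}
    for sid, kind in uniq:
        nodes, probs = origin_choices[kind]
        origin = str(rng.choice(nodes, p=probs))
        origins[sid] = origin
        mu, sd = gerp_params[kind]
        score = float(np.clip(rng.normal(mu, sd), -2, 6))
        if kind == "cryptic":
            score = min(score, 1.9)  # cryptic sites are non-conserved
        else:
            score = max(score, 2.1)
        gerp_rows.append(dict(site_id=sid, gerp_rs=score))
        desc = (tree.descendants(origin) if origin != "human"
                else frozenset(["human"]))
        row = {sp: (1.0 if sp in desc else 0.0) for sp in leaves}
        for sp in leaves:
            if sp != tree.human and rng.random() < config.alignment_dropout:
                row[sp] = np.nan
        row["site_id"] = sid
        pres_rows.append(row)

    gerp = pd.DataFrame(gerp_rows)
    presence = pd.DataFrame(pres_rows).set_index("site_id")[leaves]
    return gerp, presence, tree, origins


# ---------------------------------------------------------------------------
# small focused generators used by recovery studies
# ---------------------------------------------------------------------------

def simulate_causal_trio(model: str, n: int = 200, b_gs: float = 0.5,
                         b_se: float = 0.6, maf: float = 0.3,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (genotype, splicing, expression) from one causal structure.

    'causal' is g -> s -> e, 'reactive' is g -> e -> s, 'independent' is
    g -> s and g -> e with no s-e edge.  Phenotypes are Gaussian with
    unit residual variance.
    """
    rng = rng if rng is not None else np.random.default_rng()
    g = rng.binomial(2, maf, n).astype(float)
    if model == "causal":
        s = b_gs * g + rng.normal(0, 1, n)
        e = b_se * s + rng.normal(0, 1, n)
    elif model == "reactive":
        e = b_gs * g + rng.normal(0, 1, n)
        s = b_se * e + rng.normal(0, 1, n)
    elif model == "independent":
        s = b_gs * g + rng.normal(0, 1, n)
        e = b_se * g + rng.normal(0, 1, n)
    else:
        raise ValueError(f"unknown model {model!r}")
    return g, s, e
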