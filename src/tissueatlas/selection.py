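"""Polymorphism-based selection estimates: A/S ratios over gene sets.

Synonymous and non-synonymous site counts follow the unweighted
Nei-Gojobori (1986) scheme: at each codon position the synonymous site
fraction is the share of the three possible single-base changes that
preserve the amino acid, so every counted position contributes exactly one
site (three per codon). Changes creating a stop codon are
non-synonymous; a terminal stop codon is excluded from counting. The A/S
ratio of a gene set pools SNP and site counts across genes
(A = sum nonsyn SNPs / sum nonsyn sites, likewise S), and its 95% CI comes
from a percentile bootstrap that resamples genes with replacement, each
gene carrying its SNPs and sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import SnpRecord
from .stats import ChiSquareResult, two_by_two_chi2

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in STOPS
)

_CODON_TABLE = {}


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon]


@dataclass
class CodingGene:
    """A coding sequence in frame; a single terminal stop codon is permitted."""

    gene: str
    arm: str
    cds: str

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if set(self.cds) - set(BASES):
            raise ValueError(f"{self.gene}: ambiguous or non-ACGT bases in CDS")
        if len(self.cds) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {len(self.cds)} not divisible by 3")
        if len(self.cds) < 6:
            raise ValueError(f"{self.gene}: CDS shorter than two codons")
        codons = self.codons()
        internal = codons[:-1]
        if any(c in STOPS for c in internal):
            raise ValueError(f"{self.gene}: internal stop codon")

    def codons(self) -> list:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]

    def counted_codons(self) -> list:
        """Codons entering site counting: the terminal stop, if any, is dropped."""
        codons = self.codons()
        return codons[:-1] if codons[-1] in STOPS else codons


@dataclass
class SiteCounts:
    syn_sites: float
    nonsyn_sites: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.syn_sites + other.syn_sites, self.nonsyn_sites + other.nonsyn_sites)


@dataclass
class ASEstimate:
    """Pooled A/S estimate for a gene set, optionally with a bootstrap CI.

    ``ratio`` is None when undefined (no synonymous SNPs or sites in the set).
    """

    A: float
    S: float
    ratio: float | None
    n_genes: int
    n_syn_snps: int
    n_nonsyn_snps: int
    syn_sites: float
    nonsyn_sites: float
    ci_low: float | None = None
    ci_high: float | None = None
    B: int | None = None
    seed: int | None = None
    undefined_fraction: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@lru_cache(maxsize=64)
def codon_site_fractions(codon: str) -> tuple:
    """(synonymous, non-synonymous) site counts of one sense codon (sums to 3)."""
    if codon in STOPS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = sum(
            1
            for b in BASES
            if b != codon[pos] and _translate(codon[:pos] + b + codon[pos + 1 :]) == aa
        )
        syn += n_syn / 3.0
    return syn, 3.0 - syn


def count_sites(gene: CodingGene) -> SiteCounts:
    """Nei-Gojobori synonymous/non-synonymous site counts over the CDS."""
    syn = nonsyn = 0.0
    for codon in gene.counted_codons():
        s, n = codon_site_fractions(codon)
        syn += s
        nonsyn += n
    return SiteCounts(syn, nonsyn)


def classify_snp(gene: CodingGene, snp: SnpRecord) -> str:
    """synonymous iff the mutated codon encodes the same amino acid (stops are nonsyn)."""
    if snp.region != "coding":
        raise ValueError("only coding SNPs can be classified")
    pos0 = snp.cds_pos - 1
    if pos0 < 0 or pos0 >= len(gene.cds):
        raise ValueError(f"{gene.gene}:{snp.cds_pos} outside CDS")
    if gene.cds[pos0] != snp.ref:
        raise ValueError(
            f"{gene.gene}:{snp.cds_pos} ref {snp.ref} does not match CDS base {gene.cds[pos0]}"
        )
    ci = pos0 // 3
    codon = gene.cds[3 * ci : 3 * ci + 3]
    mutant = codon[: pos0 % 3] + snp.alt + codon[pos0 % 3 + 1 :]
    return "synonymous" if _translate(mutant) == _translate(codon) else "nonsynonymous"


def annotate_snps(genes: dict, snps) -> list:
    """Fill snp_class on every record (returns the same records)."""
    for snp in snps:
        snp.snp_class = classify_snp(genes[snp.gene], snp)
    return list(snps)


def _per_gene_counts(genes: dict, snps) -> tuple:
    names = sorted(genes)
    ix = {g: i for i, g in enumerate(names)}
    syn_sites = np.zeros(len(names))
    nonsyn_sites = np.zeros(len(names))
    syn_snps = np.zeros(len(names))
    nonsyn_snps = np.zeros(len(names))
    for g, i in ix.items():
        sc = count_sites(genes[g])
        syn_sites[i], nonsyn_sites[i] = sc.syn_sites, sc.nonsyn_sites
    for snp in snps:
        if snp.gene not in ix:
            raise ValueError(f"SNP on gene {snp.gene!r} absent from the gene set")
        cls = snp.snp_class or classify_snp(genes[snp.gene], snp)
        if cls == "synonymous":
            syn_snps[ix[snp.gene]] += 1
        else:
            nonsyn_snps[ix[snp.gene]] += 1
    return names, syn_snps, nonsyn_snps, syn_sites, nonsyn_sites


def _pooled_estimate(syn_snps, nonsyn_snps, syn_sites, nonsyn_sites, n_genes) -> ASEstimate:
    s_sites, n_sites = float(syn_sites.sum()), float(nonsyn_sites.sum())
    s_snps, n_snps = float(syn_snps.sum()), float(nonsyn_snps.sum())
    A = n_snps / n_sites if n_sites > 0 else 0.0
    S = s_snps / s_sites if s_sites > 0 else 0.0
    ratio = (A / S) if S > 0 else None
    return ASEstimate(A, S, ratio, n_genes, int(s_snps), int(n_snps), s_sites, n_sites)


def as_ratio(genes: dict, snps) -> ASEstimate:
    """Pooled A/S point estimate for a gene set (sites counted over all genes)."""
    if not genes:
        raise ValueError("empty gene set")
    _, syn_snps, nonsyn_snps, syn_sites, nonsyn_sites = _per_gene_counts(genes, snps)
    return _pooled_estimate(syn_snps, nonsyn_snps, syn_sites, nonsyn_sites, len(genes))


def as_ratio_from_rates(A: float, S: float) -> float:
    """A/S from already-computed per-site rates."""
    if S <= 0:
        raise ValueError("S must be positive for a defined ratio")
    return A / S


def bootstrap_as(genes: dict, snps, B: int = 10000, seed: int | None = None) -> ASEstimate:
    """Percentile-bootstrap 95% CI for the pooled A/S, resampling genes.

    Each bootstrap replicate draws |genes| genes with replacement (carrying
    their SNP and site counts) and recomputes the pooled ratio; the CI is the
    2.5/97.5 percentile over replicates where the ratio is defined, and the
    undefined fraction is reported.
    """
    if len(genes) < 2:
        raise ValueError("bootstrap needs at least two genes")
    if B < 100:
        raise ValueError("B must be at least 100")
    names, syn_snps, nonsyn_snps, syn_sites, nonsyn_sites = _per_gene_counts(genes, snps)
    est = _pooled_estimate(syn_snps, nonsyn_snps, syn_sites, nonsyn_sites, len(names))
    rng = np.random.default_rng(seed)
    n = len(names)
    idx = rng.integers(0, n, size=(B, n))
    rs_syn_snps = syn_snps[idx].sum(axis=1)
    rs_nonsyn_snps = nonsyn_snps[idx].sum(axis=1)
    rs_syn_sites = syn_sites[idx].sum(axis=1)
    rs_nonsyn_sites = nonsyn_sites[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = rs_nonsyn_snps / rs_nonsyn_sites
        s = rs_syn_snps / rs_syn_sites
        ratios = a / s
    defined = np.isfinite(ratios) & (rs_syn_snps > 0) & (rs_syn_sites > 0)
    if not defined.any():
        raise ValueError("A/S undefined in every bootstrap replicate")
    lo, hi = np.percentile(ratios[defined], [2.5, 97.5])
    est.ci_low, est.ci_high = float(lo), float(hi)
    est.B = B
    est.seed = seed
    est.undefined_fraction = float(1.0 - defined.mean())
    return est


def snp_density(n_snps: int, n_nucleotides: int) -> float:
    """SNPs per 1,000 nucleotides."""
    if n_nucleotides <= 0:
        raise ValueError("nucleotide count must be positive")
    return 1000.0 * n_snps / n_nucleotides


def as_contrast(set1, set2) -> ChiSquareResult:
    """2x2 chi-square comparing syn/nonsyn SNP counts between two gene sets.

    Each argument is a (genes, snps) pair; a significant statistic means the
    two sets differ in their A/S composition (e.g. X vs autosomes).
    """
    counts = []
    for genes, snps in (set1, set2):
        if not genes or not list(snps):
            raise ValueError("both sets need at least one gene and one SNP")
        _, syn_snps, nonsyn_snps, _, _ = _per_gene_counts(genes, snps)
        counts.append([syn_snps.sum(), nonsyn_snps.sum()])
    return two_by_two_chi2(np.asarray(counts))
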