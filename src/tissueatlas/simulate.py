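"""Synthetic atlas, orthologue and SNP data with planted ground truth.

Three generators emulate the study conditions so every downstream stage is
testable without external downloads:

* :func:`simulate_atlas` — a tissue x sex x replicate log2 expression
  matrix with paired PM/MM raw signal, planting sexually dimorphic,
  single-tissue ("narrow") and flat ("housekeeping") genes on top of a
  lognormal baseline (log2 mean 6, sd 1.5) with Gaussian log2 noise;
* :func:`simulate_orthologs` — two species' gene x tissue matrices with
  planted conserved co-expression clusters, a diverged fraction, and a
  five-species family table with planted origins and copy numbers;
* :func:`simulate_snps` — coding sequences of random sense codons and SNPs
  placed at a synonymous rate mu_s per synonymous site and
  mu_s x (target A/S) per non-synonymous site, per selection regime.

Truth is returned as a per-gene table; identical seeds give identical
output (and byte-identical files through the writers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionAtlas, SampleKey, SignalTable, SnpRecord
from .selection import BASES, SENSE_CODONS, STOPS, CodingGene, classify_snp, _translate

DEFAULT_TISSUES = (
    "head",
    "midgut",
    "salivary_gland",
    "malpighian_tubules",
    "carcass",
    "gonad",
    "accessory_gland",
)
ARM_PROPORTIONS = {"2R": 0.28, "2L": 0.24, "3R": 0.24, "3L": 0.14, "X": 0.10}


@dataclass
class SimConfig:
    """Atlas generator settings; defaults are the study conditions."""

    n_genes: int = 1000
    tissues: tuple = DEFAULT_TISSUES
    male_only_tissues: tuple = ("accessory_gland",)
    n_replicates: int = 4
    noise_sd: float = 0.25
    probe_pairs: int = 11
    frac_dimorphic: float = 0.15
    frac_narrow: float = 0.15
    frac_housekeeping: float = 0.10
    dimorphic_effect: float = 2.0  # log2
    baseline_mean: float = 6.0  # log2
    baseline_sd: float = 1.5
    broad_peak_range: tuple = (2.0, 4.0)
    baseline_clip: tuple = (3.5, 9.0)  # keep expressed genes inside the detected range
    pm_background: float = 50.0
    pm_noise_sd: float | None = None  # None: follow noise_sd (log-scale multiplicative)
    seed: int = 1729

    def __post_init__(self) -> None:
        if self.frac_dimorphic + self.frac_narrow + self.frac_housekeeping > 1:
            raise ValueError("planted fractions must sum to at most 1")
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates")


def _sample_cells(cfg: SimConfig):
    """All (tissue, sex) cells of the design; gonad is sex-resolved implicitly
    (ovary for females, testis for males) and some tissues are male-only."""
    cells = []
    for tissue in cfg.tissues:
        sexes = ("male",) if tissue in cfg.male_only_tissues else ("male", "female")
        for sex in sexes:
            cells.append((tissue, sex))
    return cells


def simulate_atlas(cfg: SimConfig):
    """Generate (ExpressionAtlas, SignalTable, truth DataFrame).

    The log2 matrix is baseline + planted effects + N(0, noise_sd) noise;
    PM = background + linear-scale signal and MM = background, both with
    multiplicative lognormal noise, so expressed genes show PM systematically
    above MM while silent genes have PM ~ MM. The truth table records each
    gene's planted role, its noiseless tau (computed from the deterministic
    mean profile) and its chromosome arm.
    """
    rng = np.random.default_rng(cfg.seed)
    cells = _sample_cells(cfg)
    n = cfg.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    probes = [f"{g}_p1" for g in genes]
    arms = rng.choice(
        list(ARM_PROPORTIONS), size=n, p=list(ARM_PROPORTIONS.values())
    )

    n_dim = int(round(cfg.frac_dimorphic * n))
    n_nar = int(round(cfg.frac_narrow * n))
    n_hk = int(round(cfg.frac_housekeeping * n))
    roles = np.array(
        ["dimorphic"] * n_dim
        + ["narrow"] * n_nar
        + ["housekeeping"] * n_hk
        + ["broad"] * (n - n_dim - n_nar - n_hk)
    )
    rng.shuffle(roles)

    baseline = np.clip(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n), *cfg.baseline_clip
    )
    both_sex = [(t, s) for t, s in cells if t not in cfg.male_only_tissues]
    mean = np.zeros((n, len(cells)))  # deterministic log2 means per (gene, cell)
    cell_ix = {c: j for j, c in enumerate(cells)}

    dim_tissue = np.full(n, "", dtype=object)
    dim_sex = np.full(n, "", dtype=object)
    dim_effect = np.zeros(n)
    nar_tissue = np.full(n, "", dtype=object)
    nar_sex = np.full(n, "", dtype=object)
    for i in range(n):
        role = roles[i]
        if role == "housekeeping":
            mean[i, :] = baseline[i]
        elif role == "narrow":
            t, s = cells[rng.integers(len(cells))]
            mean[i, cell_ix[(t, s)]] = max(baseline[i], 4.0)  # silent elsewhere (log2 = 0)
            nar_tissue[i], nar_sex[i] = t, s
        elif role == "dimorphic":
            t, s = both_sex[rng.integers(len(both_sex))]
            mean[i, :] = baseline[i]
            mean[i, cell_ix[(t, s)]] += cfg.dimorphic_effect
            dim_tissue[i], dim_sex[i] = t, s
            dim_effect[i] = cfg.dimorphic_effect
        else:  # broad: a moderate peak in one tissue (both sexes)
            mean[i, :] = baseline[i]
            t = cfg.tissues[rng.integers(len(cfg.tissues))]
            delta = rng.uniform(*cfg.broad_peak_range)
            for s in ("male", "female"):
                if (t, s) in cell_ix:
                    mean[i, cell_ix[(t, s)]] += delta

    # replicate-level log2 values
    columns = []
    for t, s in cells:
        for r in range(1, cfg.n_replicates + 1):
            columns.append((t, s, r))
    values = np.repeat(mean, cfg.n_replicates, axis=1)
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    vdf = pd.DataFrame(
        values,
        index=probes,
        columns=pd.MultiIndex.from_tuples(columns, names=["tissue", "sex", "replicate"]),
    )

    # paired PM/MM raw signal per probe set
    keys = [SampleKey(t, s, r) for t, s, r in columns]
    signal = np.power(2.0, values) - 1.0  # log2 value 0 -> silent
    signal[signal < 0] = 0.0
    pm_noise = cfg.pm_noise_sd if cfg.pm_noise_sd is not None else cfg.noise_sd
    shape = (len(probes), len(keys), cfg.probe_pairs)
    ln = np.log(2.0) * pm_noise  # same spread on the natural-log scale
    bg = cfg.pm_background
    e_bg_pm = np.exp(rng.normal(0.0, ln, size=shape)) if pm_noise > 0 else np.ones(shape)
    e_bg_mm = np.exp(rng.normal(0.0, ln, size=shape)) if pm_noise > 0 else np.ones(shape)
    e_sig = np.exp(rng.normal(0.0, ln, size=shape)) if pm_noise > 0 else np.ones(shape)
    pair_affinity = rng.uniform(0.5, 1.5, size=(len(probes), 1, cfg.probe_pairs))
    pm = bg * e_bg_pm + signal[:, :, None] * pair_affinity * e_sig
    mm = bg * e_bg_mm
    order = np.argsort(keys)  # canonical sample order, matching the TSV reader
    signals = SignalTable(
        probes, [keys[j] for j in order], pm[:, order], mm[:, order]
    )

    probe_to_gene = pd.Series(genes, index=probes)
    gene_to_arm = pd.Series(arms, index=genes)
    atlas = ExpressionAtlas(vdf, probe_to_gene, gene_to_arm)

    # noiseless tau per gene, sexes combined, for the truth table
    tissue_means = {}
    for t in cfg.tissues:
        js = [cell_ix[(t, s)] for s in ("male", "female") if (t, s) in cell_ix]
        tissue_means[t] = np.clip(mean[:, js], 0, None).mean(axis=1) if js else 0.0
    prof = pd.DataFrame(tissue_means, index=genes)
    with np.errstate(invalid="ignore"):
        xmax = prof.max(axis=1)
        tau0 = (1.0 - prof.div(xmax, axis=0)).sum(axis=1) / (prof.shape[1] - 1)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "probe": probes,
            "role": roles,
            "arm": arms,
            "dimorphic_tissue": dim_tissue,
            "dimorphic_sex": dim_sex,
            "dimorphic_effect": dim_effect,
            "narrow_tissue": nar_tissue,
            "narrow_sex": nar_sex,
            "tau_noiseless": tau0.to_numpy(),
        }
    )
    return atlas, signals, truth


@dataclass
class OrthologSimConfig:
    """Two-species RA-matrix generator settings."""

    n_pairs: int = 300
    tissues: tuple = DEFAULT_TISSUES[:6]
    n_clusters: int = 3
    cluster_size: int = 60
    within_r: float = 0.9
    diverged_fraction: float = 0.2
    peak_height: float = 8.0
    baseline: float = 2.0
    frac_expanded: float = 0.15
    outgroup_probs: dict = field(
        default_factory=lambda: {"Ce": 0.3, "Am": 0.2, "Tc": 0.2}
    )
    seed: int = 1729

    def __post_init__(self) -> None:
        if self.cluster_size < 2:
            raise ValueError("cluster size must be at least 2")
        if not 0 < self.within_r <= 1:
            raise ValueError("within-cluster correlation target must be in (0, 1]")
        if self.n_clusters * self.cluster_size > self.n_pairs:
            raise ValueError("clusters do not fit into n_pairs")


def _member_profile(center: np.ndarray, peak: int, sd_e: float, rng) -> np.ndarray:
    """Center plus iid noise, clipped so the planted peak tissue stays argmax."""
    v = center + rng.normal(0.0, sd_e, size=center.shape)
    cap = v[peak] - 0.1
    out = np.minimum(v, cap)
    out[peak] = v[peak]
    return np.clip(out, 0.01, None)


def simulate_orthologs(cfg: OrthologSimConfig):
    """Generate (Ag matrix, Dm matrix, families, truth DataFrame).

    Conserved pairs share a profile center (and hence the peak tissue);
    clustered pairs share their cluster's center, giving the target
    within-cluster correlation; diverged pairs get independent centers.
    Families carry planted outgroup memberships (origin labels) and planted
    Anopheles copy numbers.
    """
    rng = np.random.default_rng(cfg.seed)
    n_t = len(cfg.tissues)
    n = cfg.n_pairs
    ag_genes = [f"ag{i:05d}" for i in range(n)]
    dm_genes = [f"dm{i:05d}" for i in range(n)]

    cluster_id = np.full(n, -1)
    for c in range(cfg.n_clusters):
        cluster_id[c * cfg.cluster_size : (c + 1) * cfg.cluster_size] = c
    free = np.where(cluster_id == -1)[0]
    n_div = int(round(cfg.diverged_fraction * len(free)))
    diverged = np.zeros(n, dtype=bool)
    diverged[rng.choice(free, size=n_div, replace=False)] = True

    def random_center():
        peak = rng.integers(n_t)
        center = cfg.baseline + rng.normal(0.0, 0.3, size=n_t)
        center[peak] += cfg.peak_height * rng.uniform(0.6, 1.0)
        return center, int(peak)

    # distinct peak tissues per cluster so modules are separable
    peaks = rng.permutation(n_t)[: cfg.n_clusters]
    centers = {}
    for c, pk in enumerate(peaks):
        center = cfg.baseline + rng.normal(0.0, 0.3, size=n_t)
        center[pk] += cfg.peak_height
        centers[c] = (center, int(pk))

    ag = np.zeros((n, n_t))
    dm = np.zeros((n, n_t))
    peak_of = np.zeros((n, 2), dtype=int)
    for i in range(n):
        if cluster_id[i] >= 0:
            center, pk = centers[cluster_id[i]]
            var_c = float(np.var(center))
            sd_e = np.sqrt(var_c * (1.0 - cfg.within_r) / cfg.within_r)
            ag[i] = _member_profile(center, pk, sd_e, rng)
            dm[i] = _member_profile(center, pk, sd_e, rng)
            peak_of[i] = (pk, pk)
        elif diverged[i]:
            ca, pa = random_center()
            cb, pb = random_center()
            ag[i] = _member_profile(ca, pa, 0.5, rng)
            dm[i] = _member_profile(cb, pb, 0.5, rng)
            peak_of[i] = (pa, pb)
        else:
            center, pk = random_center()
            ag[i] = _member_profile(center, pk, 0.5, rng)
            dm[i] = _member_profile(center, pk, 0.5, rng)
            peak_of[i] = (pk, pk)

    ag_df = pd.DataFrame(ag, index=ag_genes, columns=list(cfg.tissues))
    dm_df = pd.DataFrame(dm, index=dm_genes, columns=list(cfg.tissues))

    from .crossspecies import OrthoFamily, family_origin

    families = []
    expanded = rng.random(n) < cfg.frac_expanded
    n_copies = np.where(expanded, rng.integers(2, 5, size=n), 1)
    origins = []
    extra_rows = []
    for i in range(n):
        members = {("Ag", ag_genes[i]), ("Dm", dm_genes[i])}
        for k in range(1, n_copies[i]):
            extra = f"ag{i:05d}x{k}"
            members.add(("Ag", extra))
            # duplicated copies acquire narrow, single-tissue profiles
            prof = np.full(n_t, 0.01)
            prof[rng.integers(n_t)] = cfg.baseline + cfg.peak_height
            extra_rows.append(pd.Series(prof, index=list(cfg.tissues), name=extra))
        u = rng.random()
        if u < cfg.outgroup_probs["Ce"]:
            members |= {("Ce", f"ce{i:05d}"), ("Am", f"am{i:05d}"), ("Tc", f"tc{i:05d}")}
        elif u < cfg.outgroup_probs["Ce"] + cfg.outgroup_probs["Am"]:
            members |= {("Am", f"am{i:05d}"), ("Tc", f"tc{i:05d}")}
        elif u < sum(cfg.outgroup_probs.values()):
            members.add(("Tc", f"tc{i:05d}"))
        fam = OrthoFamily(f"fam{i:05d}", frozenset(members))
        families.append(fam)
        origins.append(family_origin(fam))
    if extra_rows:
        ag_df = pd.concat([ag_df, pd.DataFrame(extra_rows)])

    truth = pd.DataFrame(
        {
            "gene_ag": ag_genes,
            "gene_dm": dm_genes,
            "family_id": [f.family_id for f in families],
            "cluster_id": cluster_id,
            "diverged": diverged,
            "peak_ag": [cfg.tissues[p] for p in peak_of[:, 0]],
            "peak_dm": [cfg.tissues[p] for p in peak_of[:, 1]],
            "origin": origins,
            "n_ag_copies": n_copies,
        }
    )
    return ag_df, dm_df, families, truth


def _change_tables():
    """Per sense codon: arrays of (offset 0-2, alt base, synonymous flag) for
    all 9 single-base changes."""
    tables = {}
    for codon in SENSE_CODONS:
        offs, alts, syn = [], [], []
        aa = _translate(codon)
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                offs.append(pos)
                alts.append(b)
                syn.append(_translate(mut) == aa)
        tables[codon] = (np.array(offs), np.array(alts), np.array(syn))
    return tables


_CHANGES = None


@dataclass
class SnpSimConfig:
    """CDS + SNP generator settings; one target A/S per selection regime."""

    regimes: dict = field(
        default_factory=lambda: {"neutral": (1.0, 167), "purifying": (0.5, 167), "positive": (2.0, 166)}
    )
    cds_codon_range: tuple = (100, 500)
    mu_s: float = 0.007  # synonymous SNPs per synonymous site
    x_fraction: float = 0.10
    seed: int = 1729

    def __post_init__(self) -> None:
        if self.mu_s <= 0:
            raise ValueError("mu_s must be positive")


def simulate_snps(cfg: SnpSimConfig):
    """Generate (genes dict, SnpRecords, truth DataFrame).

    Every CDS is a run of uniform random sense codons plus a terminal stop.
    Each possible synonymous single-base change becomes a SNP with
    probability mu_s / 3 (so the expected count is mu_s per synonymous site)
    and each non-synonymous change with probability mu_s x (target A/S) / 3.
    """
    global _CHANGES
    if _CHANGES is None:
        _CHANGES = _change_tables()
    rng = np.random.default_rng(cfg.seed)
    stop_codons = tuple(sorted(STOPS))
    genes = {}
    records = []
    rows = []
    i = 0
    for regime, (target, count) in cfg.regimes.items():
        for _ in range(count):
            name = f"s{i:05d}"
            n_codons = int(rng.integers(cfg.cds_codon_range[0], cfg.cds_codon_range[1] + 1))
            codons = [SENSE_CODONS[j] for j in rng.integers(len(SENSE_CODONS), size=n_codons)]
            cds = "".join(codons) + stop_codons[rng.integers(3)]
            arm = "X" if rng.random() < cfg.x_fraction else ["2R", "2L", "3R", "3L"][rng.integers(4)]
            gene = CodingGene(name, arm, cds)
            genes[name] = gene
            for ci, codon in enumerate(codons):
                offs, alts, syn = _CHANGES[codon]
                p = np.where(syn, cfg.mu_s / 3.0, cfg.mu_s * target / 3.0)
                hits = rng.random(9) < p
                for off, alt in zip(offs[hits], alts[hits]):
                    pos = 3 * ci + int(off) + 1
                    records.append(SnpRecord(name, pos, codon[int(off)], str(alt)))
            rows.append({"gene": name, "regime": regime, "target_as": target, "arm": arm})
            i += 1
    for rec in records:
        rec.snp_class = classify_snp(genes[rec.gene], rec)
    return genes, records, pd.DataFrame(rows)


def snp_config_for_regime(target: float, n_genes: int, mu_s: float = 0.007, seed: int = 1729) -> SnpSimConfig:
    """Single-regime convenience configuration."""
    name = {1.0: "neutral", 0.5: "purifying", 2.0: "positive"}.get(target, f"as{target}")
    return SnpSimConfig(regimes={name: (target, n_genes)}, mu_s=mu_s, seed=seed)
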