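"""Readers and writers for the external formats the pipeline touches.

Expression matrices, probe/gene annotation and gene sets travel as TSV;
coding sequences as FASTA; SNPs as VCF 4.x in CDS space (CHROM = gene id,
POS = 1-based position within the CDS, forward strand); dendrograms as
Newick. Internally all coordinates are 0-based half-open; the 1-based
convention exists only at these boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .trees import Dendrogram

logger = logging.getLogger("tissueatlas")

SEXES = ("male", "female", "combined")
ARMS = ("X", "2R", "2L", "3R", "3L")


@dataclass(frozen=True, order=True)
class SampleKey:
    """One array sample: a (tissue, sex, replicate) cell of the atlas."""

    tissue: str
    sex: str
    replicate: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not isinstance(self.replicate, (int, np.integer)) or self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate!r}")

    @classmethod
    def parse(cls, text: str) -> "SampleKey":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"sample key {text!r} is not 'tissue:sex:replicate'")
        tissue, sex, rep = parts
        try:
            rep_i = int(rep)
        except ValueError:
            raise ValueError(f"sample key {text!r}: replicate {rep!r} is not an integer")
        return cls(tissue, sex, rep_i)

    def __str__(self) -> str:
        return f"{self.tissue}:{self.sex}:{self.replicate}"


@dataclass
class ExpressionAtlas:
    """Probe x sample matrix of log2 intensities with probe/gene/arm annotation.

    ``values`` is indexed by probe with a (tissue, sex, replicate) column
    MultiIndex; ``probe_to_gene`` maps every probe in the matrix to exactly
    one gene; ``gene_to_arm`` maps genes to chromosome arms (or "unknown").
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    gene_to_arm: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v.columns, pd.MultiIndex) or v.columns.nlevels != 3:
            raise ValueError("values needs a (tissue, sex, replicate) column MultiIndex")
        keys = [SampleKey(t, s, int(r)) for t, s, r in v.columns]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (tissue, sex, replicate) sample keys")
        if v.index.has_duplicates:
            raise ValueError("duplicate probes in expression matrix")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains missing or non-finite cells")
        missing = v.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise ValueError(f"{len(missing)} probes lack gene annotation, e.g. {list(missing[:5])}")

    @property
    def sample_keys(self) -> list:
        return [SampleKey(t, s, int(r)) for t, s, r in self.values.columns]

    @property
    def tissues(self) -> list:
        return sorted({t for t, _, _ in self.values.columns})

    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.probe_to_gene.loc[self.values.index].unique()))

    def sex_values(self, tissue: str, sex: str) -> pd.DataFrame:
        """Replicate columns for one (tissue, sex) cell."""
        cols = [c for c in self.values.columns if c[0] == tissue and c[1] == sex]
        if not cols:
            raise KeyError(f"no samples for tissue={tissue!r} sex={sex!r}")
        return self.values[cols]

    def tissue_sexes(self, tissue: str) -> list:
        return sorted({s for t, s, _ in self.values.columns if t == tissue})


@dataclass
class ProbeSetSignal:
    """Paired perfect-match / mismatch raw intensities for one probe set."""

    probe_set: str
    pm: np.ndarray
    mm: np.ndarray

    def __post_init__(self) -> None:
        self.pm = np.asarray(self.pm, dtype=float)
        self.mm = np.asarray(self.mm, dtype=float)
        if self.pm.shape != self.mm.shape or self.pm.ndim != 1 or self.pm.size < 1:
            raise ValueError("pm and mm must be equal-length non-empty vectors")
        if np.any(self.pm <= 0) or np.any(self.mm <= 0):
            raise ValueError("pm and mm entries must be positive")


@dataclass
class SignalTable:
    """PM/MM signal for every probe set and sample, as dense arrays.

    pm/mm have shape (n_probes, n_samples, n_pairs); samples are keyed by
    (tissue, sex, replicate).
    """

    probes: list
    samples: list
    pm: np.ndarray
    mm: np.ndarray

    def __post_init__(self) -> None:
        self.pm = np.asarray(self.pm, dtype=float)
        self.mm = np.asarray(self.mm, dtype=float)
        shape = (len(self.probes), len(self.samples), self.pm.shape[2] if self.pm.ndim == 3 else 0)
        if self.pm.shape != shape or self.mm.shape != shape:
            raise ValueError("pm/mm shape inconsistent with probes x samples x pairs")

    def get(self, probe: str, key: SampleKey) -> ProbeSetSignal:
        i = self.probes.index(probe)
        j = self.samples.index(key)
        return ProbeSetSignal(probe, self.pm[i, j], self.mm[i, j])


@dataclass
class SnpRecord:
    """A single-nucleotide variant in CDS coordinates (1-based at I/O, stored 1-based)."""

    gene: str
    cds_pos: int
    ref: str
    alt: str
    snp_class: str | None = None  # synonymous | nonsynonymous once annotated
    region: str = "coding"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.gene}:{self.cds_pos} ref equals alt ({self.ref})")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide ref/alt are supported")


def read_expression_tsv(path, annotation_path) -> ExpressionAtlas:
    """Load a probe x sample expression TSV plus probe/gene/arm annotation.

    The expression header encodes samples as "tissue:sex:replicate". Probes
    missing from the annotation, and probes annotated to more than one gene,
    are hard errors reported with their locations.
    """
    probe_to_gene, gene_to_arm = read_annotation_tsv(annotation_path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    keys = []
    for col_i, col in enumerate(df.columns):
        try:
            keys.append(SampleKey.parse(str(col)))
        except ValueError as exc:
            raise ValueError(f"{path}: column {col_i + 2}: {exc}") from None
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate sample keys in header")
    bad = [
        (i + 2, p) for i, p in enumerate(df.index) if p not in probe_to_gene.index
    ]  # +2: header is line 1
    if bad:
        msg = ", ".join(f"line {ln}: {p}" for ln, p in bad[:10])
        raise ValueError(f"{path}: {len(bad)} probes absent from annotation ({msg})")
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for i, p in enumerate(df.index):
            for j, c in enumerate(df.columns):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at probe {p!r}, sample {c!r}"
                    ) from None
    if df.isna().to_numpy().any():
        raise ValueError(f"{path}: missing cells are not allowed")
    df.columns = pd.MultiIndex.from_tuples(
        [(k.tissue, k.sex, k.replicate) for k in keys], names=["tissue", "sex", "replicate"]
    )
    return ExpressionAtlas(df.astype(float), probe_to_gene, gene_to_arm)


def read_annotation_tsv(path) -> tuple[pd.Series, pd.Series]:
    """Read probe->gene and gene->arm maps; ambiguous probes are rejected and logged."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe", "gene", "arm"}
    if not required.issubset(ann.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    ambiguous = ann.groupby("probe")["gene"].nunique()
    ambiguous = set(ambiguous[ambiguous > 1].index)
    if ambiguous:
        logger.warning(
            "%d probes map to more than one gene and were rejected: %s",
            len(ambiguous),
            sorted(ambiguous)[:10],
        )
        ann = ann[~ann["probe"].isin(ambiguous)]
    ann = ann.drop_duplicates(subset="probe")
    probe_to_gene = ann.set_index("probe")["gene"]
    arm = ann.drop_duplicates(subset="gene").set_index("gene")["arm"].fillna("unknown")
    bad_arms = set(arm.unique()) - set(ARMS) - {"unknown"}
    if bad_arms:
        raise ValueError(f"{path}: unknown chromosome arm labels {sorted(bad_arms)}")
    return probe_to_gene, arm


def write_expression_tsv(atlas: ExpressionAtlas, path) -> None:
    df = atlas.values.copy()
    df.columns = [f"{t}:{s}:{r}" for t, s, r in df.columns]
    df.index.name = "probe"
    df.to_csv(path, sep="\t")


def write_annotation_tsv(atlas: ExpressionAtlas, path) -> None:
    rows = [
        (p, g, atlas.gene_to_arm.get(g, "unknown"))
        for p, g in atlas.probe_to_gene.items()
    ]
    pd.DataFrame(rows, columns=["probe", "gene", "arm"]).to_csv(path, sep="\t", index=False)


def read_cds_fasta(path) -> dict:
    """Read coding sequences; the arm is taken from an 'arm=XX' token in the description."""
    from .selection import CodingGene

    genes = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        arm = "unknown"
        for token in rec.description.split():
            if token.startswith("arm="):
                arm = token[4:]
        genes[rec.id] = CodingGene(rec.id, arm, str(rec.seq).upper())
    if not genes:
        raise ValueError(f"{path}: no sequences found")
    return genes


def write_cds_fasta(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes.values():
            fh.write(f">{g.gene} arm={g.arm}\n")
            for i in range(0, len(g.cds), 60):
                fh.write(g.cds[i : i + 60] + "\n")


def read_snps_vcf(path, cds) -> list:
    """Read CDS-space SNPs from a VCF; CHROM is the gene id, POS the 1-based CDS base.

    Multi-allelic rows are split into one record per ALT; indels are skipped
    (counted); REF mismatches and out-of-range positions are hard errors.
    """
    records = []
    n_indels = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            gene = rec.chrom
            if gene not in cds:
                raise ValueError(f"{path}: SNP on unknown gene {gene!r}")
            seq = cds[gene].cds
            pos = rec.pos
            if pos < 1 or pos > len(seq):
                raise ValueError(
                    f"{path}: {gene}:{pos} outside CDS of length {len(seq)}"
                )
            ref = rec.ref.upper()
            if len(ref) != 1:
                n_indels += len(rec.alts or ())
                continue
            if seq[pos - 1] != ref:
                raise ValueError(
                    f"{path}: {gene}:{pos} REF {ref} does not match CDS base {seq[pos - 1]}"
                )
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(alt) != 1 or alt not in "ACGT":
                    n_indels += 1
                    continue
                records.append(SnpRecord(gene, pos, ref, alt, region="coding"))
    if n_indels:
        logger.warning("skipped %d indel/non-SNV alleles", n_indels)
    return records


def write_snps_vcf(records, cds, path) -> None:
    """Write CDS-space SNPs, merging records at the same site into multi-allelic rows."""
    by_site = {}
    for r in records:
        by_site.setdefault((r.gene, r.cds_pos, r.ref), []).append(r.alt)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for gene in sorted(cds):
            fh.write(f"##contig=<ID={gene},length={len(cds[gene].cds)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (gene, pos, ref), alts in sorted(by_site.items()):
            fh.write(f"{gene}\t{pos}\t.\t{ref}\t{','.join(sorted(set(alts)))}\t.\t.\t.\n")


def read_gene_set_tsv(path) -> list:
    """One gene id per line (a 'gene' header is allowed)."""
    with open(path) as fh:
        genes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    if genes and genes[0].lower() == "gene":
        genes = genes[1:]
    if not genes:
        raise ValueError(f"{path}: empty gene set")
    return genes


def read_ortholog_map_tsv(path):
    """Family table with columns family_id, species, gene, relation."""
    from .crossspecies import OrthoFamily

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "species", "gene"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: ortholog map needs columns {sorted(required)}")
    families = []
    for fid, grp in df.groupby("family_id", sort=True):
        members = frozenset(zip(grp["species"], grp["gene"]))
        families.append(OrthoFamily(fid, members))
    return families


def write_newick(tree: Dendrogram, path) -> None:
    """Write a dendrogram as Newick; bootstrap supports become percent internal labels."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_signal_tsv(path) -> SignalTable:
    """Long-format PM/MM table: probe, tissue, sex, replicate, pair, pm, mm."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe", "tissue", "sex", "replicate", "pair", "pm", "mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: signal table needs columns {sorted(required)}")
    probes = sorted(df["probe"].unique())
    keys = sorted(
        {SampleKey(t, s, int(r)) for t, s, r in zip(df["tissue"], df["sex"], df["replicate"])}
    )
    pairs = sorted(df["pair"].unique())
    p_ix = {p: i for i, p in enumerate(probes)}
    k_ix = {k: i for i, k in enumerate(keys)}
    pr_ix = {p: i for i, p in enumerate(pairs)}
    pm = np.full((len(probes), len(keys), len(pairs)), np.nan)
    mm = np.full_like(pm, np.nan)
    ii = df["probe"].map(p_ix).to_numpy()
    jj = [
        k_ix[SampleKey(t, s, int(r))]
        for t, s, r in zip(df["tissue"], df["sex"], df["replicate"])
    ]
    kk = df["pair"].map(pr_ix).to_numpy()
    pm[ii, jj, kk] = df["pm"].to_numpy()
    mm[ii, jj, kk] = df["mm"].to_numpy()
    if np.isnan(pm).any() or np.isnan(mm).any():
        raise ValueError(f"{path}: incomplete probe x sample x pair grid")
    return SignalTable(probes, keys, pm, mm)


def write_signal_tsv(table: SignalTable, path) -> None:
    n_probes, n_samples, n_pairs = table.pm.shape
    with open(path, "w") as fh:
        fh.write("probe\ttissue\tsex\treplicate\tpair\tpm\tmm\n")
        for i, probe in enumerate(table.probes):
            for j, key in enumerate(table.samples):
                for k in range(n_pairs):
                    fh.write(
                        f"{probe}\t{key.tissue}\t{key.sex}\t{key.replicate}\t{k + 1}"
                        f"\t{table.pm[i, j, k]:.4f}\t{table.mm[i, j, k]:.4f}\n"
                    )
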