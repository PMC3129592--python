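"""Cross-species expression conservation.

Tissue panels and array platforms differ between species, so expression is
compared on relative abundance (RA): each gene's profile rescaled to
proportions across tissues. Co-expressed gene modules are extracted per
species by average-linkage clustering on 1 - Pearson correlation, keeping
maximal subtrees whose mean pairwise correlation exceeds a similarity
floor and that exceed a minimum size. Conservation is then quantified by
the hypergeometric overlap of modules through one-to-one orthologue pairs
(BH-corrected), and by bootstrap-supported Euclidean tissue dendrograms.
Gene families additionally get an origin clade (from outgroup membership)
and a single-copy/expanded label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

from .differential import bh_fdr
from .trees import Dendrogram

SPECIES = ("Ag", "Dm", "Tc", "Am", "Ce")
# outgroup precedence: deepest shared ancestor wins
_ORIGIN_RULES = (("Ce", "Metazoa"), ("Am", "Hymenoptera"), ("Tc", "Coleoptera"))


@dataclass(frozen=True)
class OrthoFamily:
    """A gene family over the five-species panel."""

    family_id: str
    members: frozenset  # of (species, gene)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id}: no members")
        bad = {sp for sp, _ in self.members} - set(SPECIES)
        if bad:
            raise ValueError(f"family {self.family_id}: unknown species {sorted(bad)}")

    def genes(self, species: str) -> list:
        return sorted(g for sp, g in self.members if sp == species)

    @property
    def relation(self) -> str:
        n_ag, n_dm = len(self.genes("Ag")), len(self.genes("Dm"))
        if n_ag == 1 and n_dm == 1:
            return "one-to-one"
        if min(n_ag, n_dm) <= 1:
            return "one-to-many"
        return "many-to-many"


@dataclass
class GeneCluster:
    genes: list
    mean_profile: pd.Series
    mean_correlation: float

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneClusterSet:
    clusters: list
    universe: list  # genes that entered clustering (constant rows excluded)
    unclustered: list
    excluded_constant: list = field(default_factory=list)


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse a probe x tissue matrix to genes by the per-tissue maximum.

    Unannotated probes are dropped; the tally is available as
    ``result.attrs['dropped_probes']``.
    """
    known = matrix.index.intersection(probe_to_gene.index)
    dropped = len(matrix.index) - len(known)
    sub = matrix.loc[known]
    out = sub.groupby(probe_to_gene.loc[known].values).max()
    out.attrs["dropped_probes"] = dropped
    return out


def combine_sexes(values: pd.DataFrame) -> pd.DataFrame:
    """Average sexes per tissue with equal weight (mean of the per-sex means).

    ``values`` has a (tissue, sex, replicate) column MultiIndex; a tissue
    sampled in one sex only keeps that sex's mean.
    """
    if values.columns.nlevels != 3:
        raise ValueError("expected (tissue, sex, replicate) columns")
    sex_means = values.T.groupby(level=["tissue", "sex"]).mean().T
    out = sex_means.T.groupby(level="tissue").mean().T
    if out.empty:
        raise ValueError("no tissue has any sex sampled")
    return out


def relative_abundance(matrix: pd.DataFrame, scale: str = "linear") -> pd.DataFrame:
    """Rescale each gene's profile to proportions across tissues (rows sum to 1).

    ``scale='log2'`` unlogs the values first. All-zero rows are excluded and
    listed in ``result.attrs['excluded']``; negative linear values are an
    error.
    """
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    x = matrix.astype(float)
    if scale == "log2":
        x = 2.0**x
    if (x.to_numpy() < 0).any():
        raise ValueError("negative linear expression values")
    totals = x.sum(axis=1)
    excluded = list(x.index[totals == 0])
    x = x[totals > 0]
    ra = x.div(x.sum(axis=1), axis=0)
    ra.attrs["excluded"] = excluded
    return ra


def gene_coexpression_clusters(
    ra: pd.DataFrame, min_similarity: float = 0.8, min_size: int = 50
) -> GeneClusterSet:
    """Extract co-expression modules from gene x tissue RA profiles.

    Average-linkage agglomeration on d = 1 - r; the tree is cut by emitting
    the maximal subtrees whose mean pairwise Pearson correlation exceeds
    ``min_similarity``, and of those only clusters with more than ``min_size``
    genes are reported (both thresholds strict).
    """
    if ra.shape[1] < 3:
        raise ValueError("need at least three tissues for meaningful correlations")
    x = ra.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = list(ra.index[sd == 0])
    keep = sd > 0
    x = x[keep]
    genes = list(ra.index[keep])
    n = len(genes)
    if n == 0:
        raise ValueError("all gene profiles are constant")
    if n <= min_size:
        return GeneClusterSet([], genes, list(genes), constant)
    corr = np.corrcoef(x)
    np.clip(corr, -1.0, 1.0, out=corr)
    dist = squareform(1.0 - corr, checks=False)
    np.maximum(dist, 0.0, out=dist)
    z = linkage(dist, method="average")

    leaves = {i: [i] for i in range(n)}
    colsum = {i: corr[i].copy() for i in range(n)}
    pairsum = {i: 0.0 for i in range(n)}
    mean_r = {}
    parent = {}
    for i, (a, b, _, _) in enumerate(z):
        a, b = int(a), int(b)
        node = n + i
        parent[a] = parent[b] = node
        cross = float(colsum[a][leaves[b]].sum())
        pairsum[node] = pairsum[a] + pairsum[b] + cross
        leaves[node] = leaves[a] + leaves[b]
        colsum[node] = colsum[a] + colsum[b]
        del colsum[a], colsum[b]
        k = len(leaves[node])
        mean_r[node] = pairsum[node] / (k * (k - 1) / 2.0)

    def qualifies(node: int) -> bool:
        return node >= n and mean_r[node] > min_similarity

    root = n + len(z) - 1
    clusters = []
    for node in range(n, root + 1):
        if qualifies(node) and (node == root or not qualifies(parent[node])):
            members = sorted(leaves[node])
            if len(members) > min_size:
                names = [genes[i] for i in members]
                clusters.append(
                    GeneCluster(
                        names,
                        ra.loc[names].mean(axis=0),
                        float(mean_r[node]),
                    )
                )
    clustered = {g for c in clusters for g in c.genes}
    return GeneClusterSet(
        clusters, genes, [g for g in genes if g not in clustered], constant
    )


def cluster_overlap(
    set_a: GeneClusterSet,
    set_b: GeneClusterSet,
    ortholog_pairs,
    q_bands=(0.05, 0.01),
) -> pd.DataFrame:
    """Hypergeometric overlap of two species' cluster sets through 1:1 orthologues.

    The universe is the one-to-one pairs whose genes entered both analyses;
    each cluster is mapped through the pairing and the upper-tail
    hypergeometric p of each cluster pair's overlap is BH-corrected across
    all pairs, with significance bands at the corrected 0.05/0.01 levels.
    """
    universe_a = set(set_a.universe)
    universe_b = set(set_b.universe)
    pairs = [(a, b) for a, b in ortholog_pairs if a in universe_a and b in universe_b]
    n_universe = len(pairs)
    if n_universe == 0:
        raise ValueError("no one-to-one orthologue pair present in both analyses")
    a_of = {a: i for i, (a, b) in enumerate(pairs)}
    b_of = {b: i for i, (a, b) in enumerate(pairs)}
    rows = []
    for ia, ca in enumerate(set_a.clusters):
        pa = {a_of[g] for g in ca.genes if g in a_of}
        for ib, cb in enumerate(set_b.clusters):
            pb = {b_of[g] for g in cb.genes if g in b_of}
            k = len(pa & pb)
            p = float(hypergeom.sf(k - 1, n_universe, len(pa), len(pb)))
            rows.append(
                {
                    "cluster_a": ia,
                    "cluster_b": ib,
                    "size_a": len(pa),
                    "size_b": len(pb),
                    "overlap": k,
                    "universe": n_universe,
                    "p_value": p,
                    "dropped_a": ca.size - len(pa),
                    "dropped_b": cb.size - len(pb),
                }
            )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q_value"] = bh_fdr(result["p_value"].to_numpy())
        loose, tight = max(q_bands), min(q_bands)
        result["band"] = np.where(
            result["q_value"] < tight,
            f"p<{tight}",
            np.where(result["q_value"] < loose, f"p<{loose}", "ns"),
        )
    return result


def tissue_dendrogram(matrix: pd.DataFrame, metric: str = "euclidean", method: str = "average") -> Dendrogram:
    """Hierarchical tree over items (tissues/samples); rows sorted by label first
    so equal-distance merges resolve deterministically."""
    if matrix.index.has_duplicates:
        raise ValueError("duplicate item labels")
    if len(matrix) < 2:
        raise ValueError("need at least two items")
    if matrix.isna().to_numpy().any():
        raise ValueError("missing features are not allowed")
    ordered = matrix.sort_index()
    z = linkage(pdist(ordered.to_numpy(dtype=float), metric=metric), method=method)
    return Dendrogram(list(ordered.index), z)


def bootstrap_support(
    matrix: pd.DataFrame,
    B: int = 10000,
    seed: int | None = None,
    metric: str = "euclidean",
    method: str = "average",
) -> Dendrogram:
    """Feature-resampling bootstrap support for every internal branch.

    Columns (genes) are resampled with replacement B times, the tree rebuilt,
    and each branch's support is the fraction of replicate trees containing
    the same leaf bipartition (topology only). Splits that are trivial as
    unrooted bipartitions get support 1.
    """
    if len(matrix) < 3:
        raise ValueError("bootstrap support needs at least three items")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two features")
    if B < 100:
        raise ValueError("B must be at least 100")
    base = tissue_dendrogram(matrix, metric, method)
    full = frozenset(base.labels)
    anchor = min(base.labels)

    def canonical(clade: frozenset):
        other = full - clade
        if len(clade) < 2 or len(other) < 2:
            return None
        return clade if anchor in clade else other

    counts: dict = {}
    targets = {}
    for clade, _ in base.clades():
        targets[clade] = canonical(clade)
        if targets[clade] is not None:
            counts[targets[clade]] = 0
    rng = np.random.default_rng(seed)
    ordered = matrix.sort_index()
    x = ordered.to_numpy(dtype=float)
    n_feat = x.shape[1]
    labels = list(ordered.index)
    for _ in range(B):
        cols = rng.integers(0, n_feat, size=n_feat)
        zb = linkage(pdist(x[:, cols], metric=metric), method=method)
        rep = Dendrogram(labels, zb)
        biparts = rep.bipartitions()
        for bp in counts:
            if bp in biparts:
                counts[bp] += 1
    supports = {}
    for clade, canon in targets.items():
        supports[clade] = 1.0 if canon is None else counts[canon] / B
    return Dendrogram(base.labels, base.linkage, supports)


def family_origin(family: OrthoFamily) -> str:
    """Deepest clade implied by outgroup membership (Ce > Am > Tc > Diptera-only)."""
    species = {sp for sp, _ in family.members}
    if not species & {"Ag", "Dm"}:
        raise ValueError(f"family {family.family_id}: no Anopheles or Drosophila member")
    for sp, clade in _ORIGIN_RULES:
        if sp in species:
            return clade
    return "Diptera"


def classify_family_copies(family: OrthoFamily) -> str:
    """single_copy iff the family holds exactly one Anopheles gene."""
    n_ag = len(family.genes("Ag"))
    if n_ag == 0:
        raise ValueError(f"family {family.family_id}: no Anopheles member")
    return "single_copy" if n_ag == 1 else "expanded"


def narrow_family_report(
    families,
    tau_ag: pd.DataFrame,
    tau_dm: pd.DataFrame,
    narrow_threshold: float = 0.85,
) -> tuple:
    """Two tables relating copy number, expression breadth and peak tissue.

    Table A counts, per peak tissue and family origin, members of expanded
    families with tau = 1 (strictly single-tissue expression). Table B counts
    single-copy one-to-one families whose two orthologues both have
    tau > ``narrow_threshold`` and share the same peak tissue. The tau tables
    need columns gene/tau/peak_tissue.
    """
    ag = tau_ag.set_index("gene")
    dm = tau_dm.set_index("gene")
    rows_a, rows_b = [], []
    for fam in families:
        origin = family_origin(fam)
        ag_genes = fam.genes("Ag")
        if not ag_genes:
            continue
        if classify_family_copies(fam) == "expanded":
            for g in ag_genes:
                if g in ag.index and ag.loc[g, "tau"] >= 1.0 - 1e-9:
                    rows_a.append(
                        {
                            "family_id": fam.family_id,
                            "gene": g,
                            "peak_tissue": ag.loc[g, "peak_tissue"],
                            "origin": origin,
                        }
                    )
        elif fam.relation == "one-to-one":
            g_ag, g_dm = ag_genes[0], fam.genes("Dm")[0]
            if g_ag not in ag.index or g_dm not in dm.index:
                continue
            if (
                ag.loc[g_ag, "tau"] > narrow_threshold
                and dm.loc[g_dm, "tau"] > narrow_threshold
                and ag.loc[g_ag, "peak_tissue"] == dm.loc[g_dm, "peak_tissue"]
            ):
                rows_b.append(
                    {
                        "family_id": fam.family_id,
                        "gene_ag": g_ag,
                        "gene_dm": g_dm,
                        "peak_tissue": ag.loc[g_ag, "peak_tissue"],
                        "origin": origin,
                    }
                )
    cols_a = ["family_id", "gene", "peak_tissue", "origin"]
    cols_b = ["family_id", "gene_ag", "gene_dm", "peak_tissue", "origin"]
    return (
        pd.DataFrame(rows_a, columns=cols_a),
        pd.DataFrame(rows_b, columns=cols_b),
    )


def one_to_one_pairs(families) -> list:
    """(Ag gene, Dm gene) for every one-to-one family."""
    return [
        (fam.genes("Ag")[0], fam.genes("Dm")[0])
        for fam in families
        if fam.relation == "one-to-one"
    ]
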