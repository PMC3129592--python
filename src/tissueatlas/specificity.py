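"""Tissue-breadth scoring with the tau statistic and intensity-rank enrichment.

tau = sum_i (1 - x_i / x_max) / (N - 1) over N tissues: 0 for a perfectly
flat profile, 1 for single-tissue expression. Profiles are per-tissue mean
log2 intensities floored at 0, with sexes combined by the mean of the
per-sex means and probes collapsed to genes by the per-tissue maximum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionAtlas
from .stats import ChiSquareResult

TAU_LOW = 0.15
TAU_HIGH = 0.85


def tau(profile) -> float:
    """Tissue-specificity index of a non-negative per-tissue expression vector."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs a vector over at least two tissues")
    if np.any(x < 0):
        raise ValueError("tau is undefined for negative expression values")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("undefined tau: all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def breadth_classify(tau_value: float, low: float = TAU_LOW, high: float = TAU_HIGH) -> str:
    """housekeeping below ``low``, narrow above ``high``, intermediate between (strict)."""
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    if not 0 <= tau_value <= 1:
        raise ValueError(f"tau must lie in [0, 1], got {tau_value}")
    if tau_value < low:
        return "housekeeping"
    if tau_value > high:
        return "narrow"
    return "intermediate"


def gene_tissue_profile(
    atlas: ExpressionAtlas, detection=None, floor: float = 0.0
) -> pd.DataFrame:
    """Gene x tissue mean log2 profile: sexes averaged, probes collapsed by max.

    When a detection table is supplied, tissues where a gene has no consensus
    detection in either sex contribute the floor (0) instead of their measured
    mean, so undetected tissues count as silent in tau.
    """
    from .crossspecies import collapse_probes

    per_sex = {}
    for tissue in atlas.tissues:
        sexes = atlas.tissue_sexes(tissue)
        means = [atlas.sex_values(tissue, s).mean(axis=1) for s in sexes]
        per_sex[tissue] = sum(means) / len(means)
    probe_mat = pd.DataFrame(per_sex)
    mat = collapse_probes(probe_mat, atlas.probe_to_gene)
    mat = mat.clip(lower=floor)
    if detection is not None:
        from .detection import gene_level_detection

        gene_det = gene_level_detection(detection, atlas.probe_to_gene)
        det_by_tissue = gene_det.T.groupby(level="tissue").any().T
        det_by_tissue = det_by_tissue.reindex(
            index=mat.index, columns=mat.columns, fill_value=False
        )
        mat = mat.where(det_by_tissue, floor)
    return mat


def tau_table(
    atlas: ExpressionAtlas,
    detection=None,
    low: float = TAU_LOW,
    high: float = TAU_HIGH,
) -> pd.DataFrame:
    """Per-gene tau, breadth class and peak tissue over the atlas."""
    mat = gene_tissue_profile(atlas, detection)
    rows = []
    for gene, profile in mat.iterrows():
        x = profile.to_numpy()
        if x.max() <= 0:
            continue  # undetected everywhere: tau undefined, gene skipped
        t = tau(x)
        rows.append((gene, t, breadth_classify(t, low, high), profile.idxmax()))
    return pd.DataFrame(rows, columns=["gene", "tau", "breadth", "peak_tissue"])


def top_decile_enrichment(gene_set, ranking, decile: float = 0.10) -> ChiSquareResult:
    """Chi-square test of a gene set's over-representation in the top intensity decile.

    ``ranking`` is every analysed gene ordered from highest to lowest
    intensity in one tissue; the 2x2 test compares the observed count of set
    members inside the top decile against the decile proportion (df = 1, no
    continuity correction).
    """
    ranking = list(ranking)
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if len(ranking) < 10:
        raise ValueError("ranking must contain at least 10 genes")
    missing = gene_set - set(ranking)
    if missing:
        raise ValueError(f"genes absent from ranking: {sorted(missing)[:5]}")
    k = int(len(ranking) * decile)
    top = set(ranking[:k])
    n_in = len(gene_set & top)
    n_set = len(gene_set)
    p0 = k / len(ranking)
    e_in = n_set * p0
    e_out = n_set - e_in
    stat = (n_in - e_in) ** 2 / e_in + ((n_set - n_in) - e_out) ** 2 / e_out
    from scipy.stats import chi2

    return ChiSquareResult(
        float(stat),
        1,
        float(chi2.sf(stat, 1)),
        ("in_top_decile", "below"),
        np.array([n_in, n_set - n_in]),
        np.array([e_in, e_out]),
        (np.array([n_in, n_set - n_in]) - np.array([e_in, e_out]))
        / np.sqrt([e_in, e_out]),
    )
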