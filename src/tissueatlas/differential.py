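"""Sex-biased and gonad-enriched differential expression.

Per tissue, each gene gets a two-group linear model on log2 intensities
(female vs male, or gonad vs carcass within one sex). With only a few
replicates per group the gene-wise residual variances are noisy, so they
are shrunk towards a common prior by empirical Bayes: the s² are modelled
as draws from a scaled inverse-chi-square prior (s0², d0) whose
hyperparameters are fitted by matching the moments of log s², and each
gene is tested with a moderated t on d0 + d degrees of freedom using the
posterior variance

    s̃² = (d0·s0² + d·s²) / (d0 + d).

Multiple testing is controlled by Benjamini-Hochberg q-values, and a gene
is only classified as biased when it passes both the q-value cut and a
fold-change rule on the model's log2 effect M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import chi2, t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import ExpressionAtlas


@dataclass
class ModeratedModelFit:
    """Gene-wise two-group fits with shared empirical-Bayes hyperparameters."""

    genes: pd.Index
    effect: np.ndarray  # M = log2(group1 mean) - log2(group2 mean)
    s2: np.ndarray  # residual variance per gene
    df_residual: float
    d0: float  # prior degrees of freedom (np.inf = complete shrinkage)
    s0_sq: float  # prior variance
    s2_tilde: np.ndarray  # posterior variance
    t: np.ndarray
    p_value: np.ndarray


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the monotone decreasing branch)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2: np.ndarray, df: float, d0: float | None = None):
    """Fit the scaled inverse-chi-square prior and return (d0, s0², s̃²).

    The fit matches the mean and variance of log s² against the theoretical
    moments implied by s² ~ s0² · F(df, d0) (digamma/trigamma moment match).
    Passing ``d0`` explicitly overrides the fit; d0 = 0 disables shrinkage and
    d0 = inf replaces every variance by the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if d0 is None:
        if ok.sum() < 2:
            # no information to fit a prior (e.g. noise-free data): no shrinkage
            return 0.0, 0.0, s2.copy()
        z = np.log(s2[ok])
        e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
        e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
        if e_var > 0:
            d0 = 2.0 * _trigamma_inverse(e_var)
            s0_sq = float(
                np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
            )
        else:
            d0 = np.inf
            s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = float(d0)
        s0_sq = float(np.mean(s2[ok])) if ok.any() else 0.0
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_tilde = s2.copy()
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_tilde


def _two_group_fit(a: np.ndarray, b: np.ndarray, genes: pd.Index, d0=None) -> ModeratedModelFit:
    """Moderated two-group comparison; a and b are genes x replicates on log2 scale."""
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two replicates")
    m = a.mean(axis=1) - b.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    d0_fit, s0_sq, s2_tilde = moderate_variances(s2, df, d0)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / se
    df_total = df + (0.0 if d0_fit == 0 else d0_fit)
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    # zero posterior variance and no prior: take the limit for a non-zero
    # effect (p -> 0) and flag a truly informationless gene (no effect, no
    # variance) as undefined
    degenerate = se == 0
    nonzero = degenerate & (m != 0)
    p[nonzero] = 0.0
    t[nonzero] = np.sign(m[nonzero]) * np.inf
    undefined = degenerate & (m == 0)
    p[undefined] = np.nan
    t[undefined] = np.nan
    return ModeratedModelFit(genes, m, s2, df, d0_fit, s0_sq, s2_tilde, t, p)


def _gene_matrix(atlas: ExpressionAtlas, tissue: str, sex: str, genes=None) -> pd.DataFrame:
    """Per-gene replicate matrix for one (tissue, sex): probes collapsed by max of means.

    Replicate structure is preserved by collapsing each gene to the probe with
    the highest mean intensity in the cell.
    """
    vals = atlas.sex_values(tissue, sex)
    gene_of = atlas.probe_to_gene.loc[vals.index]
    best = vals.mean(axis=1).groupby(gene_of.values).idxmax()
    mat = vals.loc[best.values]
    mat.index = best.index
    if genes is not None:
        mat = mat.loc[mat.index.intersection(genes)]
    return mat


def fit_sex_bias(
    atlas: ExpressionAtlas,
    tissue: str,
    fold_threshold_log2: float = 1.0,
    q_threshold: float = 0.05,
    genes=None,
    d0: float | None = None,
) -> pd.DataFrame:
    """Female-vs-male moderated comparison in one tissue.

    ``genes`` optionally restricts the analysis (e.g. to consensus-detected
    genes); filtering is the caller's responsibility. Returns one row per gene
    with M = log2(female) - log2(male), p, q and the class label; a gene is
    female_biased (male_biased) iff M >= fold_threshold_log2
    (M <= -fold_threshold_log2) and q < q_threshold.
    """
    fem = _gene_matrix(atlas, tissue, "female", genes)
    mal = _gene_matrix(atlas, tissue, "male", genes)
    shared = fem.index.intersection(mal.index)
    fit = _two_group_fit(
        fem.loc[shared].to_numpy(), mal.loc[shared].to_numpy(), shared, d0
    )
    return _classify(fit, tissue, fold_threshold_log2, q_threshold)


def _classify(fit: ModeratedModelFit, tissue, fold_threshold_log2, q_threshold) -> pd.DataFrame:
    q = np.full_like(fit.p_value, np.nan)
    ok = ~np.isnan(fit.p_value)
    if ok.any():
        q[ok] = bh_fdr(fit.p_value[ok])
    cls = np.where(
        (fit.effect >= fold_threshold_log2) & (q < q_threshold),
        "female_biased",
        np.where(
            (fit.effect <= -fold_threshold_log2) & (q < q_threshold),
            "male_biased",
            "unbiased",
        ),
    )
    return pd.DataFrame(
        {
            "gene": fit.genes,
            "tissue": tissue,
            "m_value": fit.effect,
            "p_value": fit.p_value,
            "q_value": q,
            "class": cls,
            "degenerate": np.isnan(fit.p_value),
        }
    ).reset_index(drop=True)


def gonad_enrichment(
    atlas: ExpressionAtlas,
    gonad_tissue: str,
    carcass_tissue: str,
    sex: str,
    m_threshold: float = 2.0,
    q_threshold: float = 0.05,
    genes=None,
    d0: float | None = None,
) -> pd.DataFrame:
    """Gonad-vs-carcass moderated comparison within one sex.

    A gene is enriched iff M = log2(gonad) - log2(carcass) strictly exceeds
    ``m_threshold`` and q < ``q_threshold``. Detection filtering, as for
    :func:`fit_sex_bias`, belongs to the caller.
    """
    gon = _gene_matrix(atlas, gonad_tissue, sex, genes)
    car = _gene_matrix(atlas, carcass_tissue, sex, genes)
    shared = gon.index.intersection(car.index)
    fit = _two_group_fit(
        gon.loc[shared].to_numpy(), car.loc[shared].to_numpy(), shared, d0
    )
    q = np.full_like(fit.p_value, np.nan)
    ok = ~np.isnan(fit.p_value)
    if ok.any():
        q[ok] = bh_fdr(fit.p_value[ok])
    enriched = (fit.effect > m_threshold) & (q < q_threshold)
    return pd.DataFrame(
        {
            "gene": fit.genes,
            "m_value": fit.effect,
            "p_value": fit.p_value,
            "q_value": q,
            "enriched": enriched,
        }
    ).reset_index(drop=True)


def dimorphism_summary(records: pd.DataFrame) -> dict:
    """Per-tissue biased counts, female:male ratio and 1:1 chi-square, plus the
    overall fraction of genes dimorphic in at least one tissue."""
    if records.empty:
        raise ValueError("no sex-bias records")
    per_tissue = {}
    for tissue, grp in records.groupby("tissue"):
        n_f = int((grp["class"] == "female_biased").sum())
        n_m = int((grp["class"] == "male_biased").sum())
        total = n_f + n_m
        if total > 0:
            expected = total / 2.0
            stat = (n_f - expected) ** 2 / expected + (n_m - expected) ** 2 / expected
            p = float(chi2.sf(stat, 1))
        else:
            stat, p = 0.0, 1.0
        per_tissue[tissue] = {
            "female_biased": n_f,
            "male_biased": n_m,
            "ratio_female_male": (n_f / n_m) if n_m else np.inf if n_f else np.nan,
            "chi2": float(stat),
            "p_value": p,
        }
    biased = records[records["class"] != "unbiased"]
    n_genes = records["gene"].nunique()
    frac = biased["gene"].nunique() / n_genes if n_genes else 0.0
    return {
        "per_tissue": per_tissue,
        "n_genes": int(n_genes),
        "n_dimorphic_genes": int(biased["gene"].nunique()),
        "fraction_dimorphic": float(frac),
    }
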