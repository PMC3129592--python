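"""Chromosome-arm distribution tests for gene sets.

The question is whether a gene set (e.g. testis-specific genes) is
distributed across chromosome arms as the background is — in particular
whether the X is depleted or enriched. The test is a goodness-of-fit
chi-square against the background arm proportions, with per-arm
standardized residuals giving the direction; when any expected count drops
below 1 the chi-square approximation is replaced by a seeded Monte-Carlo
multinomial p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import ARMS
from .stats import ChiSquareResult

logger = logging.getLogger("tissueatlas")


def arm_distribution(
    gene_set,
    background,
    arms=ARMS,
    mc_draws: int = 10000,
    seed: int | None = None,
) -> ChiSquareResult:
    """Goodness-of-fit of a gene set's arm counts against background proportions.

    ``background`` maps gene -> arm for the reference universe (all genes the
    set was drawn from); genes on arms outside ``arms`` ("unknown") are
    excluded and tallied in ``result.dropped``. Expected counts are the set
    size times the background arm proportions.
    """
    background = pd.Series(background)
    bg = background[background.isin(arms)]
    if bg.nunique() < 2:
        raise ValueError("background must span at least two arms")
    props = bg.value_counts(normalize=True).reindex(arms, fill_value=0.0)
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    set_arms = background.reindex(genes)
    dropped = int((~set_arms.isin(arms)).sum())
    if dropped:
        logger.info("arm_distribution: dropped %d genes with unknown arm", dropped)
    set_arms = set_arms[set_arms.isin(arms)]
    observed = set_arms.value_counts().reindex(arms, fill_value=0).to_numpy(dtype=float)
    n = observed.sum()
    if n == 0:
        raise ValueError("no gene in the set has a known arm")
    used = props.to_numpy() > 0
    obs = observed[used]
    p = props.to_numpy()[used]
    expected = n * p
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = used.sum() - 1
    if expected.min() < 1.0:
        logger.warning("expected arm count below 1; using Monte-Carlo multinomial p")
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(int(n), p, size=mc_draws)
        stats = ((draws - expected) ** 2 / expected).sum(axis=1)
        p_value = float((np.sum(stats >= stat - 1e-12) + 1) / (mc_draws + 1))
        method = f"Monte-Carlo multinomial ({mc_draws} draws)"
    else:
        p_value = float(chi2.sf(stat, df))
        method = "chi-squared goodness of fit"
    resid = (obs - expected) / np.sqrt(expected)
    result = ChiSquareResult(
        stat,
        int(df),
        p_value,
        tuple(np.asarray(arms)[used]),
        obs,
        expected,
        resid,
        method,
    )
    result.dropped = dropped
    return result
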