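"""Present/absent detection calls from paired PM/MM probe intensities.

A probe set is called by testing whether the per-pair discrimination score
R_i = (PM_i - MM_i) / (PM_i + MM_i) sits above a small positive threshold
tau_det, using a one-sided Wilcoxon signed-rank test with its exact
(sign-flip) null distribution. The p-value is mapped to present / marginal
/ absent by two alpha cut-offs, and replicate calls are collapsed to a
per-(tissue, sex) consensus by the "present in at least min_present
replicates" rule. This is the classic P/M/A parameterization of
short-oligo array detection; the defaults (tau_det = 0.015, alpha1 = 0.04,
alpha2 = 0.06) are the conventional ones and all three are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import ProbeSetSignal, SignalTable

EXACT_MAX_PAIRS = 25  # exact sign-flip null up to here, normal approximation beyond
MIN_PAIRS = 6


@dataclass
class DetectionCall:
    call: str  # present | marginal | absent
    p_value: float


@dataclass
class DetectionTable:
    """Consensus detection per (probe, tissue, sex) plus the replicate-level calls.

    ``consensus`` is probe x (tissue, sex) boolean; ``replicate_calls`` is
    probe x (tissue, sex, replicate) of P/M/A letters.
    """

    consensus: pd.DataFrame
    replicate_calls: pd.DataFrame | None = None

    def cells(self) -> list:
        return list(self.consensus.columns)


@lru_cache(maxsize=512)
def _tail_probs(ranks2: tuple) -> np.ndarray:
    """Exact P(W >= w) of the signed-rank sum under random sign flips.

    ``ranks2`` are the doubled (integer) midranks; the returned array is
    indexed by the doubled rank sum w2, so tail[w2] = P(2W >= w2).
    """
    total = int(sum(ranks2))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    tail = counts[::-1].cumsum()[::-1]
    return tail / counts.sum()


def signed_rank_p_greater(d: np.ndarray) -> float:
    """One-sided p for H1: median(d) > 0; exact for n <= 25, normal approx beyond.

    Zeros are dropped (Wilcoxon convention); ties receive midranks, which the
    exact sign-flip enumeration handles without approximation.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_PAIRS:
        ranks2 = tuple(sorted(int(round(2 * r)) for r in ranks))
        w2 = int(round(2 * w))
        return float(_tail_probs(ranks2)[w2])
    mean = n * (n + 1) / 4.0
    var = float(np.sum(ranks**2)) / 4.0
    z = (w - mean - 0.5) / np.sqrt(var)  # continuity-corrected
    return float(norm.sf(z))


def detect_probe(
    signal: ProbeSetSignal,
    tau_det: float = 0.015,
    alpha1: float = 0.04,
    alpha2: float = 0.06,
) -> DetectionCall:
    """P/M/A call for one probe set from its PM/MM pairs."""
    if not alpha1 < alpha2:
        raise ValueError("alpha1 must be < alpha2")
    if tau_det < 0:
        raise ValueError("tau_det must be >= 0")
    pm, mm = signal.pm, signal.mm
    if pm.size < MIN_PAIRS:
        raise ValueError(
            f"insufficient probe pairs: {pm.size} < {MIN_PAIRS} for a testable statistic"
        )
    denom = pm + mm
    if np.any(denom == 0):
        raise ValueError("PM + MM must be positive for every pair")
    r = (pm - mm) / denom
    p = signed_rank_p_greater(r - tau_det)
    if p < alpha1:
        call = "present"
    elif p < alpha2:
        call = "marginal"
    else:
        call = "absent"
    return DetectionCall(call, p)


def consensus_present(calls, min_present: int = 3) -> bool:
    """True iff at least ``min_present`` replicate calls are present (marginal excluded).

    More replicates than ``min_present`` must be supplied: an m-of-m rule has
    no room for a failed replicate and is rejected as a caller error.
    """
    letters = [c.call if isinstance(c, DetectionCall) else str(c) for c in calls]
    if len(letters) <= min_present:
        raise ValueError(
            f"need more than {min_present} replicates for an 'at least {min_present}' rule; "
            f"got {len(letters)}"
        )
    return sum(let in ("present", "P") for let in letters) >= min_present


def build_detection_table(
    signals: SignalTable,
    tau_det: float = 0.015,
    alpha1: float = 0.04,
    alpha2: float = 0.06,
    min_present: int = 3,
) -> DetectionTable:
    """Call every probe set in every sample and collapse replicates per (tissue, sex)."""
    cells = sorted({(k.tissue, k.sex) for k in signals.samples})
    sample_ix = {k: j for j, k in enumerate(signals.samples)}
    letters = {}
    consensus = {}
    for tissue, sex in cells:
        keys = sorted(k for k in signals.samples if k.tissue == tissue and k.sex == sex)
        for i, probe in enumerate(signals.probes):
            reps = []
            for k in keys:
                j = sample_ix[k]
                call = detect_probe(
                    ProbeSetSignal(probe, signals.pm[i, j], signals.mm[i, j]),
                    tau_det,
                    alpha1,
                    alpha2,
                )
                reps.append(call)
                letters[(probe, tissue, sex, k.replicate)] = call.call[0].upper()
            consensus[(probe, tissue, sex)] = consensus_present(reps, min_present)
    cons = pd.Series(consensus).unstack([1, 2]).astype(bool)
    cons = cons.loc[signals.probes]
    cons.columns.names = ["tissue", "sex"]
    reps_df = pd.Series(letters).unstack([1, 2, 3])
    reps_df = reps_df.loc[signals.probes]
    reps_df.columns.names = ["tissue", "sex", "replicate"]
    return DetectionTable(cons, reps_df)


def expressed_fraction(table: DetectionTable, tissue: str, sex: str) -> float:
    """Fraction of probes with consensus detection in one (tissue, sex) cell."""
    if table.consensus.empty:
        raise ValueError("empty detection table")
    if (tissue, sex) not in table.consensus.columns:
        raise KeyError(f"no detection calls for ({tissue}, {sex})")
    col = table.consensus[(tissue, sex)]
    return float(col.mean())


def gene_level_detection(table: DetectionTable, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe-level consensus to genes by logical OR over a gene's probes."""
    cons = table.consensus
    genes = probe_to_gene.loc[cons.index]
    return cons.groupby(genes.values).any()


def tissue_specific_detected(table: DetectionTable, probe_to_gene: pd.Series) -> set:
    """Genes detected in exactly one (tissue, sex) cell, as (gene, tissue, sex) triples."""
    if len({t for t, _ in table.consensus.columns}) < 2:
        raise ValueError("tissue-specific detection needs at least two tissues")
    gene_cons = gene_level_detection(table, probe_to_gene)
    counts = gene_cons.sum(axis=1)
    out = set()
    for gene in gene_cons.index[counts == 1]:
        row = gene_cons.loc[gene]
        tissue, sex = row.index[row.to_numpy().astype(bool)][0]
        out.add((gene, tissue, sex))
    return out
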