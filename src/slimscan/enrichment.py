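"""Target/decoy enrichment statistics for motif matches.

For each motif, the match counts on a target dataset and on its decoy are
compared.  The enrichment ratio is (n_target / n_target_aa) /
(n_decoy / n_decoy_aa) — counts normalised to dataset size in amino
acids, so datasets of different size are comparable.  A two-sided pooled
two-proportion z-test (residue positions as the denominator) gives a
p-value per motif, Benjamini-Hochberg adjustment across all motifs in the
table gives q-values, and motifs are called enriched (ratio >= 2,
q <= 0.05), depleted (ratio <= 0.5, q <= 0.05) or non-significant.

A ratio-vs-score-threshold curve shows how a PSSM score cut-off changes
the target/decoy ratio, the basis for choosing a working score threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motif_engine import MotifMatch

__all__ = [
    "EnrichmentRecord",
    "RatioCurve",
    "two_proportion_pvalue",
    "fisher_pvalue",
    "bh_adjust",
    "enrichment_table",
    "ratio_curve",
    "volcano_table",
]


@dataclass
class EnrichmentRecord:
    """Per-motif target/decoy comparison result."""

    motif: str
    n_target: int
    n_decoy: int
    n_target_aa: int
    n_decoy_aa: int
    ratio: float
    p_value: float
    q_value: float
    classification: str         # enriched | depleted | non_significant
    ratio_flagged: bool = False  # continuity rule applied (zero decoy count)

    @property
    def log2_ratio(self) -> float:
        if self.ratio == 0:
            return float("-inf")
        return math.log2(self.ratio)


@dataclass
class RatioCurve:
    """Target/decoy ratio as a function of the score threshold."""

    thresholds: list[float]
    target_counts: list[int]
    decoy_counts: list[int]
    ratios: list[float]
    flagged: list[bool] = field(default_factory=list)


def two_proportion_pvalue(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test.

    z = (k1/n1 - k2/n2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled
    p = (k1+k2)/(n1+n2); p-value = 2*(1 - Phi(|z|)).  Degenerate tables
    (both proportions 0 or both 1) return 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("denominator n must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled == 0.0 or pooled == 1.0:
        return 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def fisher_pvalue(k1: int, n1: int, k2: int, n2: int) -> float:
    """Fisher's exact two-sided p-value, for small-count tables."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def _ratio(k1: int, n1: int, k2: int, n2: int) -> tuple[float, bool]:
    """Per-aa normalised ratio with the zero-decoy continuity rule
    (0.5 added to both counts, flagged)."""
    if k2 == 0:
        if k1 == 0:
            return float("nan"), True
        return ((k1 + 0.5) / n1) / ((k2 + 0.5) / n2), True
    return (k1 / n1) / (k2 / n2), False


def enrichment_table(
    target_counts: Mapping[str, int],
    decoy_counts: Mapping[str, int],
    n_target_aa: int,
    n_decoy_aa: int,
    ratio_cut: float = 2.0,
    q_cut: float = 0.05,
    test: str = "z",
) -> list[EnrichmentRecord]:
    """Build the per-motif enrichment table.

    Both count maps must share the same motif keys.  p-values come from
    the two-proportion z-test (``test="fisher"`` switches to Fisher's
    exact) with residue counts as denominators; q-values from BH across
    all motifs in the table.  Classification: enriched iff
    ratio >= ratio_cut and q <= q_cut; depleted iff ratio <= 1/ratio_cut
    and q <= q_cut; otherwise non-significant.
    """
    if n_target_aa < 1 or n_decoy_aa < 1:
        raise ValueError("dataset sizes must be >= 1 residue")
    extra_t = sorted(set(target_counts) - set(decoy_counts))
    extra_d = sorted(set(decoy_counts) - set(target_counts))
    if extra_t or extra_d:
        raise ValueError(
            "motif keys differ between target and decoy counts: "
            f"target-only={extra_t}, decoy-only={extra_d}")
    pfunc = {"z": two_proportion_pvalue, "fisher": fisher_pvalue}[test]
    motifs = list(target_counts)
    pvals = [pfunc(target_counts[m], n_target_aa, decoy_counts[m], n_decoy_aa)
             for m in motifs]
    qvals = bh_adjust(pvals)
    records = []
    for motif, p, q in zip(motifs, pvals, qvals):
        k1, k2 = target_counts[motif], decoy_counts[motif]
        ratio, flagged = _ratio(k1, n_target_aa, k2, n_decoy_aa)
        if math.isnan(ratio):
            classification = "non_significant"
        elif ratio >= ratio_cut and q <= q_cut:
            classification = "enriched"
        elif ratio <= 1.0 / ratio_cut and q <= q_cut:
            classification = "depleted"
        else:
            classification = "non_significant"
        records.append(EnrichmentRecord(
            motif=motif, n_target=k1, n_decoy=k2,
            n_target_aa=n_target_aa, n_decoy_aa=n_decoy_aa,
            ratio=ratio, p_value=p, q_value=q,
            classification=classification, ratio_flagged=flagged))
    return records


def ratio_curve(
    target_matches: Sequence[MotifMatch],
    decoy_matches: Sequence[MotifMatch],
    thresholds: Sequence[float],
    n_target_aa: int | None = None,
    n_decoy_aa: int | None = None,
    normalize_per_aa: bool = True,
) -> RatioCurve:
    """Target/decoy ratio at ascending score thresholds.

    At threshold t only matches with score >= t are counted (t == 0 counts
    everything, scored or not).  With ``normalize_per_aa`` counts are
    divided by dataset sizes in residues before taking the ratio.
    Thresholds with a zero decoy count use the 0.5-continuity rule and are
    flagged.
    """
    thresholds = sorted(thresholds)
    if normalize_per_aa and (n_target_aa is None or n_decoy_aa is None):
        raise ValueError("normalize_per_aa requires n_target_aa and n_decoy_aa")
    if any(t > 0 for t in thresholds):
        for m in list(target_matches) + list(decoy_matches):
            if m.score is None:
                raise ValueError(
                    "matches must be scored when thresholds above 0 are used")

    def count_at(matches: Sequence[MotifMatch], t: float) -> int:
        if t <= 0:
            return len(matches)
        return sum(1 for m in matches if m.score is not None and m.score >= t)

    n1 = n_target_aa if normalize_per_aa else 1
    n2 = n_decoy_aa if normalize_per_aa else 1
    t_counts, d_counts, ratios, flags = [], [], [], []
    for t in thresholds:
        kt = count_at(target_matches, t)
        kd = count_at(decoy_matches, t)
        ratio, flagged = _ratio(kt, n1, kd, n2)
        t_counts.append(kt)
        d_counts.append(kd)
        ratios.append(ratio)
        flags.append(flagged)
    return RatioCurve(thresholds=list(thresholds), target_counts=t_counts,
                      decoy_counts=d_counts, ratios=ratios, flagged=flags)


def volcano_table(records: Sequence[EnrichmentRecord]):
    """Volcano-plot-ready DataFrame: log2 ratio vs -log10 q."""
    import pandas as pd

    return pd.DataFrame({
        "motif": [r.motif for r in records],
        "log2_ratio": [r.log2_ratio for r in records],
        "neg_log10_q": [-math.log10(r.q_value) if r.q_value > 0 else float("inf")
                        for r in records],
        "classification": [r.classification for r in records],
    })
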