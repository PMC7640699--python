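"""Gene-level somatic copy-number calls with purity adjustment, and
trunk/private concordance between paired samples.

Segment log2 tumor/normal ratios are assigned to genes (each sample gets
a value for the same gene universe, so samples are directly comparable);
gains and losses are called at +/- log2(1.5). Because low purity shrinks
ratios toward 1, a purity-adjusted ratio::

    adjusted = log2((r - 1) / purity + 1),  r = 2**log2_ratio

is substituted gene-wise whenever either sample of a pair passes the
unadjusted threshold. Under the standard mixture model for the observed
ratio, r = purity * CN/2 + (1 - purity), this adjustment recovers the
tumor ratio CN/2 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from metpair.io_formats import CNSegmentRecord

GAIN_THRESHOLD = float(np.log2(1.5))
LOSS_THRESHOLD = float(-np.log2(1.5))

#: ratio floor when the adjusted ratio would be non-positive
RATIO_FLOOR = 1.0 / 64


@dataclass(frozen=True)
class SCNAEventLabel:
    gene: str
    label: str  # trunk | primary_specific | metastasis_specific


def assign_gene_log2(segments: list[CNSegmentRecord],
                     gene_model: pd.DataFrame) -> pd.Series:
    """Per-gene log2 ratio for one sample from its segments.

    ``gene_model`` is BED-like: columns gene, chrom, start, end (1-based
    inclusive). A gene takes its containing segment's log2 ratio; a gene
    spanning several segments takes the coverage-length-weighted mean;
    an uncovered gene gets 0 (neutral) — uncovered genes are listed in
    the series' ``attrs['uncovered']``.
    """
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(gene_model.columns):
        raise ValueError(f"gene model needs columns {sorted(required)}")
    by_chrom: dict[str, list[CNSegmentRecord]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
    values = {}
    uncovered = []
    for row in gene_model.itertuples(index=False):
        segs = by_chrom.get(str(row.chrom), [])
        total_bp = 0
        acc = 0.0
        for seg in segs:
            lo = max(int(row.start), seg.start)
            hi = min(int(row.end), seg.end)
            if lo <= hi:
                span = hi - lo + 1
                total_bp += span
                acc += span * seg.log2_ratio
        if total_bp == 0:
            values[row.gene] = 0.0
            uncovered.append(row.gene)
        else:
            values[row.gene] = acc / total_bp
    out = pd.Series(values, name="log2_ratio")
    out.attrs["uncovered"] = uncovered
    return out


def purity_adjust(log2_ratio, purity: float):
    """Purity-adjusted log2 ratio: log2((2**log2_ratio - 1)/purity + 1).

    Accepts scalars or arrays. When the adjusted ratio would be <= 0
    (deep losses at low purity), it is clamped to a floor ratio of 1/64
    with a warning.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    ratio = np.power(2.0, np.asarray(log2_ratio, dtype=float))
    adjusted = (ratio - 1.0) / purity + 1.0
    bad = adjusted <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} adjusted ratio(s) <= 0; clamped to {RATIO_FLOOR}")
        adjusted = np.where(bad, RATIO_FLOOR, adjusted)
    out = np.log2(adjusted)
    return float(out) if np.isscalar(log2_ratio) else out


def call_gene(log2_ratio, gain_thr: float = GAIN_THRESHOLD,
              loss_thr: float = LOSS_THRESHOLD):
    """Call gain / neutral / loss from a (possibly adjusted) log2 ratio.

    Thresholds are inclusive: a value exactly at log2(1.5) is a gain.
    """
    arr = np.asarray(log2_ratio, dtype=float)
    calls = np.where(arr >= gain_thr, "gain",
                     np.where(arr <= loss_thr, "loss", "neutral"))
    return str(calls) if arr.ndim == 0 else calls


def gene_calls_for_pair(primary_log2: pd.Series, metastasis_log2: pd.Series,
                        purity_primary: float, purity_metastasis: float
                        ) -> pd.DataFrame:
    """Gene-level calls for a pair with the conditional purity adjustment.

    The adjustment is applied gene-wise, to both samples, only when
    either sample's unadjusted value passes the +/- log2(1.5) threshold.
    Returns a frame with adjusted values and calls per sample.
    """
    genes = primary_log2.index
    if not genes.equals(metastasis_log2.index):
        raise ValueError("pair must share one gene universe")
    p = primary_log2.values.astype(float)
    m = metastasis_log2.values.astype(float)
    trigger = ((p >= GAIN_THRESHOLD) | (p <= LOSS_THRESHOLD)
               | (m >= GAIN_THRESHOLD) | (m <= LOSS_THRESHOLD))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_adj = np.where(trigger, purity_adjust(p, purity_primary), p)
        m_adj = np.where(trigger, purity_adjust(m, purity_metastasis), m)
    return pd.DataFrame({
        "primary_log2": p_adj,
        "metastasis_log2": m_adj,
        "primary_call": call_gene(p_adj),
        "metastasis_call": call_gene(m_adj),
    }, index=genes)


def classify_scna_events(pair_calls: pd.DataFrame
                         ) -> tuple[list[SCNAEventLabel], dict[str, float]]:
    """Label genes as trunk / primary_specific / metastasis_specific.

    Trunk: the same non-neutral call in both samples. Specific:
    non-neutral in exactly one sample. Discordant directions (gain in one
    sample, loss in the other) count as one private event in each sample.
    Proportions are over labeled genes (a discordant gene contributes to
    both specific tallies).
    """
    labels: list[SCNAEventLabel] = []
    for gene, row in pair_calls.iterrows():
        pc, mc = row["primary_call"], row["metastasis_call"]
        if pc == "neutral" and mc == "neutral":
            continue
        if pc == mc:
            labels.append(SCNAEventLabel(gene, "trunk"))
        elif pc != "neutral" and mc != "neutral":
            labels.append(SCNAEventLabel(gene, "primary_specific"))
            labels.append(SCNAEventLabel(gene, "metastasis_specific"))
        elif pc != "neutral":
            labels.append(SCNAEventLabel(gene, "primary_specific"))
        else:
            labels.append(SCNAEventLabel(gene, "metastasis_specific"))
    n = len(labels)
    props = {lab: (sum(1 for x in labels if x.label == lab) / n if n else float("nan"))
             for lab in ("trunk", "primary_specific", "metastasis_specific")}
    return labels, props


def scna_burden(calls) -> tuple[int, int]:
    """(gain_count, loss_count) over one sample's gene calls."""
    arr = np.asarray(calls)
    return int(np.sum(arr == "gain")), int(np.sum(arr == "loss"))


def concordance_correlation(scna_shared_fraction, mutation_shared_fraction
                            ) -> tuple[float, float]:
    """Spearman correlation between per-patient SCNA and mutation
    shared fractions. Returns (rho, p)."""
    x = np.asarray(scna_shared_fraction, dtype=float)
    y = np.asarray(mutation_shared_fraction, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need matched vectors over at least 3 patients")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
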