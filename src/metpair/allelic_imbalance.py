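"""Allelic-imbalance detection, cross-sample sharing tests and labeling.

Allelic imbalance (AI) — unequal representation of the two parental
haplotypes over a region — leaves a phase-consistent footprint: at
phased heterozygous sites inside an AI region, the allele-count
deviation keeps pointing at the same haplotype. Under no AI the
deviation direction is a fair coin, so phase concordance over a region
is tested against 0.5 with an exact one-sided binomial test on the
majority-haplotype count (alpha = 1e-4).

Detection here is a documented sliding-window scan over phased sites
(window of 50 informative sites, 50% overlap, significant windows
merged); sharing of an event across a patient's samples re-applies the
same binomial test to each other sample's sites in the event's span, and
segments are labeled with the six-way scheme: normal, norm_specific,
private, shared, met_specific, trunk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from metpair.io_formats import PhasedSiteRecord

ALPHA = 1e-4

AI_LABELS = ("normal", "norm_specific", "private", "shared",
             "met_specific", "trunk")


@dataclass(frozen=True)
class AIEvent:
    """A detected allelic-imbalance region in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_sites: int
    concordant_sites: int
    p_value: float

    def __post_init__(self):
        if self.concordant_sites > self.n_sites:
            raise ValueError("concordant_sites > n_sites")
        if self.start > self.end:
            raise ValueError("start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AISegmentLabel:
    chrom: str
    start: int
    end: int
    label: str


def _deviation_haplotype(site: PhasedSiteRecord) -> int | None:
    """Haplotype the read-count deviation points at, or None for an
    uninformative (balanced) site.

    ``hap`` assigns the reference allele to haplotype ``hap``; more ref
    than alt reads therefore means deviation toward haplotype ``hap``.
    """
    if site.ref_count == site.alt_count:
        return None
    toward_ref = site.ref_count > site.alt_count
    return site.hap if toward_ref else 1 - site.hap


def phase_concordance(sites: list[PhasedSiteRecord]) -> tuple[int, int]:
    """(n informative sites, majority-haplotype deviation count) for a
    region. Balanced sites (ref == alt) are uninformative and excluded."""
    toward0 = 0
    toward1 = 0
    for site in sites:
        hap = _deviation_haplotype(site)
        if hap == 0:
            toward0 += 1
        elif hap == 1:
            toward1 += 1
    n = toward0 + toward1
    return n, max(toward0, toward1)


def binomial_sharing_test(n: int, k: int, alpha: float = ALPHA
                          ) -> tuple[float, bool]:
    """Exact upper-tail binomial test of phase concordance against 0.5.

    Returns (p, significant) with p = P(X >= k | n, 0.5); the region
    shows AI iff p < alpha.
    """
    if n < 1 or k > n or k < 0:
        raise ValueError("need 1 <= n and 0 <= k <= n")
    p = float(stats.binom.sf(k - 1, n, 0.5))
    return p, p < alpha


def detect_ai(sites: list[PhasedSiteRecord], window: int = 50,
              step: int = 25, alpha: float = ALPHA) -> list[AIEvent]:
    """Sliding-window AI scan over one sample's phased sites.

    Windows of ``window`` informative sites advance by ``step`` sites
    along each chromosome; each window is tested with
    :func:`binomial_sharing_test` and overlapping or adjacent significant
    windows are merged into maximal events. A chromosome with fewer than
    ``window`` informative sites is tested once as a whole (with a
    warning).
    """
    if not sites:
        return []
    sample_id = sites[0].sample_id
    by_chrom: dict[str, list[PhasedSiteRecord]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    events: list[AIEvent] = []
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(by_chrom[chrom], key=lambda s: s.pos)
        informative = [s for s in chrom_sites
                       if _deviation_haplotype(s) is not None]
        if not informative:
            continue
        if len(informative) < window:
            warnings.warn(
                f"chrom {chrom}: only {len(informative)} informative sites "
                f"(< window {window}); testing the whole chromosome once")
            windows = [(0, len(informative))]
        else:
            starts = list(range(0, len(informative) - window + 1, step))
            if starts[-1] + window < len(informative):
                starts.append(len(informative) - window)
            windows = [(s, s + window) for s in starts]
        sig: list[tuple[int, int, int, int, float]] = []
        for lo, hi in windows:
            n, k = phase_concordance(informative[lo:hi])
            p, shared = binomial_sharing_test(n, k, alpha)
            if shared:
                sig.append((informative[lo].pos, informative[hi - 1].pos,
                            n, k, p))
        events.extend(_merge_windows(sig, sample_id, chrom, informative, alpha))
    return events


def _merge_windows(sig, sample_id, chrom, informative, alpha):
    """Merge overlapping/adjacent significant windows into maximal events
    and re-test each merged span."""
    if not sig:
        return []
    sig.sort()
    merged: list[list[int]] = [[sig[0][0], sig[0][1]]]
    for start, end, *_ in sig[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    events = []
    for start, end in merged:
        span_sites = [s for s in informative if start <= s.pos <= end]
        n, k = phase_concordance(span_sites)
        p, _ = binomial_sharing_test(n, k, alpha)
        events.append(AIEvent(sample_id=sample_id, chrom=chrom, start=start,
                              end=end, n_sites=n, concordant_sites=k,
                              p_value=p))
    return events


def test_event_in_sample(event: AIEvent, sites: list[PhasedSiteRecord],
                         alpha: float = ALPHA) -> bool:
    """Does another sample show AI over this event's span?"""
    span = [s for s in sites
            if s.chrom == event.chrom and event.start <= s.pos <= event.end]
    n, k = phase_concordance(span)
    if n < 1:
        return False
    p, shared = binomial_sharing_test(n, k, alpha)
    return shared


def label_segments(events_by_sample: dict[str, list[AIEvent]],
                   sites_by_sample: dict[str, list[PhasedSiteRecord]],
                   roles: dict[str, str],
                   alpha: float = ALPHA) -> list[AISegmentLabel]:
    """Label genomic segments with the six-way AI sharing scheme.

    Segments are the atomic intervals obtained by splitting the union of
    all samples' event intervals at every boundary. Each segment is
    tested in every sample (detected events count as positive; other
    samples are re-tested over the segment span). Labels:

    - ``normal``: AI in no sample
    - ``norm_specific``: AI only in the normal sample
    - ``trunk``: AI in both primary and metastasis (all tumor samples)
    - ``met_specific``: AI only in metastasis samples (and not all tumors)
    - ``private``: AI in exactly one tumor sample, a primary
    - ``shared``: AI in several but not all tumor samples
    """
    samples = sorted(set(events_by_sample) | set(sites_by_sample))
    unknown = [s for s in samples if s not in roles]
    if unknown:
        raise ValueError(f"samples without a role: {unknown}")
    # atomic segmentation of the union of event intervals, per chromosome
    boundaries: dict[str, set[int]] = {}
    for evs in events_by_sample.values():
        for ev in evs:
            boundaries.setdefault(ev.chrom, set()).update((ev.start, ev.end + 1))
    labels: list[AISegmentLabel] = []
    for chrom in sorted(boundaries):
        cuts = sorted(boundaries[chrom])
        for lo, hi in zip(cuts, cuts[1:]):
            seg = (chrom, lo, hi - 1)
            positive = set()
            for sample in samples:
                if _segment_has_ai(seg, sample, events_by_sample,
                                   sites_by_sample, alpha):
                    positive.add(sample)
            labels.append(AISegmentLabel(chrom, lo, hi - 1,
                                         _label(positive, roles)))
    return labels


def _segment_has_ai(seg, sample, events_by_sample, sites_by_sample, alpha):
    chrom, lo, hi = seg
    for ev in events_by_sample.get(sample, []):
        if ev.chrom == chrom and ev.start <= hi and ev.end >= lo:
            return True
    span = [s for s in sites_by_sample.get(sample, [])
            if s.chrom == chrom and lo <= s.pos <= hi]
    n, k = phase_concordance(span)
    if n < 1:
        return False
    _, shared = binomial_sharing_test(n, k, alpha)
    return shared


def _label(positive: set[str], roles: dict[str, str]) -> str:
    if not positive:
        return "normal"
    tumor = {s for s, r in roles.items() if r in ("primary", "metastasis")}
    pos_tumor = positive & tumor
    if not pos_tumor:
        return "norm_specific"
    pos_roles = {roles[s] for s in pos_tumor}
    if pos_tumor == tumor or pos_roles == {"primary", "metastasis"}:
        return "trunk"
    if pos_roles == {"metastasis"}:
        return "met_specific"
    if len(pos_tumor) == 1:
        return "private"
    return "shared"


def ai_burden(events: list[AIEvent]) -> tuple[int, int]:
    """(number of AI segments, total genome size affected in bp)."""
    return len(events), int(sum(ev.length for ev in events))
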