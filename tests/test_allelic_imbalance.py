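import numpy as np
import pytest
from scipy import stats

from metpair.allelic_imbalance import (
    AIEvent,
    ai_burden,
    binomial_sharing_test,
    detect_ai,
    label_segments,
    phase_concordance,
)
from metpair.io_formats import PhasedSiteRecord


def site(pos, ref_count, alt_count, hap=0, chrom="1", sample="S1"):
    return PhasedSiteRecord(chrom, pos, hap, ref_count, alt_count, sample)


class TestPhaseConcordance:
    def test_all_toward_one_haplotype(self):
        sites = [site(i + 1, 30, 20) for i in range(20)]
        assert phase_concordance(sites) == (20, 20)

    def test_balanced_directions(self):
        sites = ([site(i + 1, 30, 20) for i in range(10)]
                 + [site(i + 100, 20, 30) for i in range(10)])
        assert phase_concordance(sites) == (20, 10)

    def test_tied_site_uninformative(self):
        sites = [site(1, 25, 25), site(2, 30, 20)]
        assert phase_concordance(sites) == (1, 1)

    def test_hap_label_flips_direction(self):
        # deviation toward ref with hap=1 points at haplotype 1
        a = [site(1, 30, 20, hap=0), site(2, 30, 20, hap=1)]
        assert phase_concordance(a) == (2, 1)


class TestBinomialSharingTest:
    def test_hand_values(self):
        p, shared = binomial_sharing_test(20, 20)
        assert p == pytest.approx(9.54e-7, abs=1e-6)
        assert p == pytest.approx(0.5**20)
        assert shared
        p, shared = binomial_sharing_test(20, 15)
        assert p == pytest.approx(0.0207, abs=1e-4)
        assert not shared
        p, shared = binomial_sharing_test(20, 10)
        assert p > 0.5 and not shared

    def test_matches_scipy_binomtest(self):
        for n, k in [(50, 39), (50, 30), (100, 70), (7, 7)]:
            ours, _ = binomial_sharing_test(n, k)
            ref = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_sharing_test(0, 0)
        with pytest.raises(ValueError):
            binomial_sharing_test(10, 11)

    def test_type_one_error_controlled(self):
        """Null calibration at n=50: empirical flag rate <= 2e-4."""
        rng = np.random.default_rng(99)
        n = 50
        x = rng.binomial(n, 0.5, size=100_000)
        k = np.maximum(x, n - x)
        flagged = np.array([binomial_sharing_test(n, int(kk))[1]
                            for kk in range(n // 2, n + 1)])
        rate = flagged[k - n // 2].mean()
        assert rate <= 2e-4

    def test_power_at_high_concordance(self):
        rng = np.random.default_rng(100)
        n = 50
        x = rng.binomial(n, 0.9, size=20_000)
        k = np.maximum(x, n - x)
        flagged = np.array([binomial_sharing_test(n, int(kk))[1]
                            for kk in range(n // 2, n + 1)])
        assert flagged[k - n // 2].mean() >= 0.99


class TestDetectAI:
    def _sites_with_region(self, rng, n_sites=600, lo=200, hi=399,
                           concordance=0.85, depth=50):
        sites = []
        for i in range(n_sites):
            hap = int(rng.integers(0, 2))
            if lo <= i <= hi:
                toward0 = rng.random() < concordance
                major = max(int(rng.binomial(depth, 0.65)), depth // 2 + 1)
                hap0 = major if toward0 else depth - major
            else:
                hap0 = int(rng.binomial(depth, 0.5))
            ref = hap0 if hap == 0 else depth - hap0
            sites.append(site(1000 * (i + 1), ref, depth - ref, hap=hap))
        return sites

    def test_synthetic_region_detected_with_bounded_error(self):
        rng = np.random.default_rng(42)
        sites = self._sites_with_region(rng)
        events = detect_ai(sites, window=50, step=25)
        assert len(events) == 1
        ev = events[0]
        # boundary error within one window span (50 sites x 1 kb spacing)
        assert abs(ev.start - 201_000) <= 50_000
        assert abs(ev.end - 400_000) <= 50_000
        assert ev.p_value < 1e-4

    def test_null_chromosome_rarely_flagged(self):
        rng = np.random.default_rng(43)
        false_events = 0
        n_windows = 0
        for _ in range(30):
            sites = self._sites_with_region(rng, n_sites=500, lo=0, hi=-1)
            n_windows += (500 - 50) // 25 + 1
            false_events += len(detect_ai(sites))
        # expected false windows ~ alpha * windows, far below 1 per run
        assert false_events <= max(2, int(2e-4 * n_windows) + 2)

    def test_short_chromosome_single_test_with_warning(self):
        rng = np.random.default_rng(44)
        sites = self._sites_with_region(rng, n_sites=30, lo=0, hi=29,
                                        concordance=0.99)
        with pytest.warns(UserWarning, match="whole chromosome"):
            events = detect_ai(sites, window=50)
        assert len(events) == 1

    def test_empty_input(self):
        assert detect_ai([]) == []


class TestLabelingAndBurden:
    def _event(self, sample, chrom="1", start=1000, end=5000):
        return AIEvent(sample_id=sample, chrom=chrom, start=start, end=end,
                       n_sites=50, concordant_sites=48, p_value=1e-9)

    def _concordant_sites(self, sample, chrom="1", lo=1000, hi=5000, n=60):
        pos = np.linspace(lo, hi, n).astype(int)
        return [site(int(p), 40, 10, hap=0, chrom=chrom, sample=sample)
                for p in pos]

    def _null_sites(self, sample, rng, chrom="1", lo=1000, hi=5000, n=60):
        pos = np.linspace(lo, hi, n).astype(int)
        out = []
        for p in pos:
            hap0 = int(rng.binomial(50, 0.5))
            out.append(site(int(p), hap0, 50 - hap0, hap=0, chrom=chrom,
                            sample=sample))
        return out

    def test_trunk_private_and_met_specific(self):
        rng = np.random.default_rng(7)
        roles = {"P": "primary", "M": "metastasis", "N": "normal"}
        # trunk region on chrom 1 (AI in P and M), met-only on chrom 2
        events = {
            "P": [self._event("P", "1")],
            "M": [self._event("M", "1"), self._event("M", "2")],
            "N": [],
        }
        sites = {
            "P": (self._concordant_sites("P", "1")
                  + self._null_sites("P", rng, "2")),
            "M": (self._concordant_sites("M", "1")
                  + self._concordant_sites("M", "2")),
            "N": (self._null_sites("N", rng, "1")
                  + self._null_sites("N", rng, "2")),
        }
        labels = label_segments(events, sites, roles)
        by_chrom = {l.chrom: l.label for l in labels}
        assert by_chrom["1"] == "trunk"
        assert by_chrom["2"] == "met_specific"

    def test_private_and_norm_specific(self):
        rng = np.random.default_rng(8)
        roles = {"P": "primary", "M": "metastasis", "N": "normal"}
        events = {"P": [self._event("P", "1")], "M": [],
                  "N": [self._event("N", "2")]}
        sites = {
            "P": (self._concordant_sites("P", "1")
                  + self._null_sites("P", rng, "2")),
            "M": (self._null_sites("M", rng, "1")
                  + self._null_sites("M", rng, "2")),
            "N": (self._null_sites("N", rng, "1")
                  + self._concordant_sites("N", "2")),
        }
        labels = label_segments(events, sites, roles)
        by_chrom = {l.chrom: l.label for l in labels}
        assert by_chrom["1"] == "private"
        assert by_chrom["2"] == "norm_specific"

    def test_every_segment_gets_exactly_one_label(self):
        rng = np.random.default_rng(9)
        roles = {"P": "primary", "M": "metastasis", "N": "normal"}
        events = {"P": [self._event("P", start=1000, end=3000)],
                  "M": [self._event("M", start=2000, end=5000)], "N": []}
        sites = {s: self._null_sites(s, rng) for s in roles}
        labels = label_segments(events, sites, roles)
        spans = [(l.start, l.end) for l in labels]
        assert len(spans) == len(set(spans))
        # atomic segmentation splits at every boundary
        assert len(labels) >= 3

    def test_burden(self):
        events = [self._event("P", start=1, end=100),
                  self._event("P", chrom="2", start=11, end=40)]
        assert ai_burden(events) == (2, 130)
        assert ai_burden([]) == (0, 0)

    def test_generator_regions_recovered(self, mono_patient):
        bundle, truth = mono_patient
        events = {sid: detect_ai(sites)
                  for sid, sites in bundle.phased_sites.items()}
        for sid, regions in truth.ai_regions.items():
            detected = {(e.chrom) for e in events[sid]}
            for chrom, start, end in regions:
                assert chrom in detected
        # normal sample stays clean
        normal_id = next(m.sample_id for m in bundle.meta
                         if m.role == "normal")
        assert events[normal_id] == []
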