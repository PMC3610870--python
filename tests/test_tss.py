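"""TSS detection/classification tests, including the exhaustive
per-position oracle the detector must agree with."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profiles
from nodtx.errors import ParameterError, StateError
from nodtx.io_formats import ContigProfile, GeneFeature, StrandProfiles
from nodtx.tss import (
    ClassificationParams,
    DetectionParams,
    TSSRecord,
    classify_tss,
    detect_candidates,
    detect_tss,
    summarize_classes,
)

# ---------------------------------------------------------------------------
# Independent oracle: plain-python, tests every position on its own.
# Positions with zero starts are provably never candidates (the peak rule
# requires starts[p] >= 1), so skipping them is an optimization only.
# ---------------------------------------------------------------------------

def oracle_detect(starts, coverage, strand, min_window_reads=280, window=7,
                  enrichment_factor=0.5):
    n = len(starts)
    h = window // 2
    candidates = []
    for p in range(n):
        if starts[p] < 1:
            continue
        lo, hi = max(0, p - h), min(n - 1, p + h)
        window_vals = [starts[q] for q in range(lo, hi + 1)]
        if sum(window_vals) < min_window_reads:
            continue
        if starts[p] != max(window_vals):
            continue
        if strand == "+":
            if any(starts[q] == starts[p] for q in range(lo, p)):
                continue
            up = coverage[p - 1] - sum(starts[q] for q in range(lo, p)) if p > 0 else 0
        else:
            if any(starts[q] == starts[p] for q in range(p + 1, hi + 1)):
                continue
            up = coverage[p + 1] - sum(starts[q] for q in range(p + 1, hi + 1)) if p < n - 1 else 0
        up = max(0, up)
        if up > 0 and starts[p] < (1 + enrichment_factor) * up:
            continue
        candidates.append(p)
    kept = []
    for p in sorted(candidates, key=lambda p: (-starts[p], p if strand == "+" else -p)):
        if all(abs(p - q) >= window for q in kept):
            kept.append(p)
    return sorted(kept)


def random_profile(rng, n=50_000, n_spikes=40, n_noise=800):
    starts = np.zeros(n, dtype=np.int64)
    for _ in range(n_spikes):
        starts[rng.integers(0, n)] += int(rng.integers(100, 700))
    noise_pos = rng.integers(0, n, size=n_noise)
    np.add.at(starts, noise_pos, rng.integers(1, 30, size=n_noise))
    # synthetic read-through coverage, >= starts everywhere
    coverage = starts + rng.integers(0, 250, size=n)
    return starts, coverage


class TestDetect:
    def test_all_zero_profiles(self):
        assert detect_tss(make_profiles(500)) == []

    def test_single_spike(self):
        profiles = make_profiles(500, starts_plus={100: 300})
        recs = detect_tss(profiles)
        assert len(recs) == 1
        r = recs[0]
        assert (r.position, r.strand, r.window_reads, r.starts) == (101, "+", 300, 300)
        assert r.enrichment == float("inf")

    def test_threshold_279_fails(self):
        profiles = make_profiles(500, starts_plus={100: 279})
        assert detect_tss(profiles) == []

    def test_threshold_280_passes(self):
        profiles = make_profiles(500, starts_plus={100: 280})
        assert len(detect_tss(profiles)) == 1

    def test_window_sum_reaches_threshold(self):
        # 3 x 100 within 7 nt: window sum 300 >= 280, peak at the max
        profiles = make_profiles(500, starts_plus={98: 90, 100: 120, 102: 90})
        recs = detect_tss(profiles)
        assert [r.position for r in recs] == [101]
        assert recs[0].window_reads == 300

    def test_read_through_coverage_blocks(self):
        # coverage[99]=300 entirely from upstream reads: 300 < 1.5 * 300
        profiles = make_profiles(
            500, starts_plus={100: 300}, coverage_plus={99: 300}
        )
        assert detect_tss(profiles) == []

    def test_minus_strand_spike(self):
        profiles = make_profiles(500, starts_minus={200: 300})
        recs = detect_tss(profiles)
        assert [(r.position, r.strand) for r in recs] == [(201, "-")]

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            DetectionParams(window=6)

    def test_normalization_requires_library_size(self):
        with pytest.raises(ParameterError):
            DetectionParams(normalize_per_million=True)

    def test_per_million_normalization(self):
        # threshold 280 rpm at 1M-read library -> 280 reads; at 100k -> 28
        profiles = make_profiles(500, starts_plus={100: 30})
        deep = DetectionParams(normalize_per_million=True, library_size=1_000_000)
        shallow = DetectionParams(normalize_per_million=True, library_size=100_000)
        assert detect_tss(profiles, deep) == []
        assert len(detect_tss(profiles, shallow)) == 1

    def test_proximity_dedup_keeps_stronger(self):
        # two candidates 3 nt apart, both isolated-window peaks is impossible
        # within one window; use 6 nt apart (< window 7)
        profiles = make_profiles(500, starts_plus={100: 400, 106: 500})
        recs = detect_tss(profiles)
        assert [r.position for r in recs] == [107]

    def test_proximity_tie_keeps_five_prime_most(self):
        profiles = make_profiles(500, starts_plus={100: 400, 106: 400})
        assert [r.position for r in detect_tss(profiles)] == [101]
        profiles = make_profiles(500, starts_minus={100: 400, 106: 400})
        assert [r.position for r in detect_tss(profiles)] == [107]

    def test_agrees_with_oracle_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            starts, coverage = random_profile(rng, n=20_000)
            for strand in "+-":
                prof = ContigProfile(20_000)
                if strand == "+":
                    prof.starts_plus, prof.coverage_plus = starts, coverage
                else:
                    prof.starts_minus, prof.coverage_minus = starts, coverage
                got = [r.position - 1 for r in detect_tss(StrandProfiles({"c": prof}))]
                assert got == oracle_detect(list(starts), list(coverage), strand)

    def test_threshold_monotonicity_on_candidates(self):
        rng = np.random.default_rng(13)
        starts, coverage = random_profile(rng, n=10_000)
        prof = ContigProfile(10_000)
        prof.starts_plus, prof.coverage_plus = starts, coverage
        profiles = StrandProfiles({"c": prof})
        prev = None
        for threshold in (600, 450, 280, 100):
            cand = {(r.position, r.strand) for r in
                    detect_candidates(profiles, DetectionParams(min_window_reads=threshold))}
            if prev is not None:
                assert prev <= cand  # lowering the threshold never removes
            prev = cand


class TestClassify:
    GENE = GeneFeature("g1", "c1", 1001, 2000, "+")

    @staticmethod
    def tss_at(position, strand):
        return TSSRecord("c1", position, strand, 300, 300, float("inf"))

    def classify_one(self, position, strand, genes=None, **kwargs):
        params = ClassificationParams(**kwargs) if kwargs else None
        recs = classify_tss([self.tss_at(position, strand)], genes or [self.GENE], params)
        return recs[0]

    def test_gtss_50_upstream(self):
        r = self.classify_one(951, "+")
        assert (r.tss_class, r.gene_id, r.offset) == ("gTSS", "g1", -50)

    def test_gtss_at_boundary_200(self):
        assert self.classify_one(801, "+").tss_class == "gTSS"

    def test_ntss_beyond_200(self):
        r = self.classify_one(751, "+")  # distance 250 > 200
        assert (r.tss_class, r.gene_id, r.offset) == ("nTSS", "", None)

    def test_itss_inside_gene(self):
        r = self.classify_one(1500, "+")
        assert (r.tss_class, r.offset) == ("iTSS", 499)

    def test_atss_opposite_strand(self):
        assert self.classify_one(1500, "-").tss_class == "aTSS"

    def test_ntss_far_from_gene(self):
        assert self.classify_one(500, "+").tss_class == "nTSS"

    def test_leaderless_offset_zero_is_gtss(self):
        r = self.classify_one(1001, "+")
        assert (r.tss_class, r.offset) == ("gTSS", 0)

    def test_first_base_excluded_from_itss(self):
        # at the first base the only same-strand label is gTSS (offset 0)
        assert self.classify_one(1001, "+").tss_class != "iTSS"

    def test_minus_strand_gene(self):
        gene = GeneFeature("g2", "c1", 1001, 2000, "-")
        r = self.classify_one(2050, "-", genes=[gene])
        assert (r.tss_class, r.offset) == ("gTSS", -50)
        r = self.classify_one(1500, "-", genes=[gene])
        assert (r.tss_class, r.offset) == ("iTSS", 500)

    def test_antisense_flank(self):
        r = self.classify_one(990, "-", antisense_flank=20)
        assert r.tss_class == "aTSS"
        assert self.classify_one(990, "-").tss_class == "nTSS"

    def test_priority_gtss_over_atss(self):
        genes = [self.GENE, GeneFeature("g2", "c1", 900, 1100, "-")]
        # 951+ is upstream of g1 (+) and inside g2 (-): priority picks gTSS
        assert self.classify_one(951, "+", genes=genes).tss_class == "gTSS"
        r = self.classify_one(
            951, "+", genes=genes, priority=("aTSS", "gTSS", "iTSS", "nTSS")
        )
        assert r.tss_class == "aTSS"

    def test_nearest_gene_wins(self):
        genes = [
            GeneFeature("gfar", "c1", 1100, 2000, "+"),
            GeneFeature("gnear", "c1", 1010, 1090, "+"),
        ]
        r = self.classify_one(1001, "+", genes=genes)
        assert (r.gene_id, r.offset) == ("gnear", -9)

    def test_summarize_counts(self):
        recs = [
            TSSRecord("c1", i + 1, "+", 300, 300, 1.0, c)
            for i, c in enumerate(["gTSS", "iTSS", "aTSS", "nTSS"])
        ]
        counts = summarize_classes(recs)
        assert counts == {"gTSS": 1, "iTSS": 1, "aTSS": 1, "nTSS": 1, "total": 4}

    def test_summarize_empty(self):
        assert summarize_classes([]) == {
            "gTSS": 0, "iTSS": 0, "aTSS": 0, "nTSS": 0, "total": 0
        }

    def test_summarize_rejects_unclassified(self):
        with pytest.raises(StateError):
            summarize_classes([self.tss_at(1, "+")])


@given(st.integers(0, 3000), st.sampled_from("+-"))
@settings(max_examples=200, deadline=None)
def test_classification_always_single_class(position, strand):
    genes = [
        GeneFeature("a", "c1", 500, 900, "+"),
        GeneFeature("b", "c1", 1200, 1600, "-"),
        GeneFeature("c", "c1", 1650, 2100, "+"),
    ]
    rec = TSSRecord("c1", position + 1, strand, 300, 300, 2.0)
    out = classify_tss([rec], genes)
    assert len(out) == 1
    assert out[0].tss_class in ("gTSS", "iTSS", "aTSS", "nTSS")
    counts = summarize_classes(out)
    assert counts["total"] == sum(counts[c] for c in ("gTSS", "iTSS", "aTSS", "nTSS"))
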