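"""Homozygosity mapping: marker calling thresholds, window scanning
against the explicit-enumeration oracle, coalescence, monotonicity and
planted-ROH recovery on synthetic maps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spex.roh_mapping import (
    HET,
    HOM,
    Marker,
    RohParameters,
    build_marker_map,
    classify_marker,
    coalesce_windows,
    map_homozygosity,
    oracle_scan,
    scan_windows,
)
from spex.synthetic_data import SimulationConfig, generate_marker_map

P = RohParameters()


def make_map(positions, calls, chrom="chr1"):
    """Build a marker map directly from truth calls (hom VAF 1, het 0.5,
    depth 50 everywhere so every classification is unambiguous)."""
    reads = {"hom": 50, "het": 25}
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": list(positions),
            "depth": 50,
            "variant_reads": [reads[c] for c in calls],
        }
    )
    return build_marker_map(df)


class TestClassifyMarker:
    @pytest.mark.parametrize(
        "depth,reads,call",
        [
            (20, 19, "homozygous"),    # f = 0.95 exactly
            (20, 10, "heterozygous"),  # f = 0.50
            (20, 16, "ambiguous"),     # f = 0.80, between the bands
            (8, 4, "ambiguous"),       # f = 0.50 but below the 10x het floor
            (20, 5, "ambiguous"),      # f = 0.25, below the het band
            (4, 4, "ambiguous"),       # f = 1.0 but below the 5x hom floor
            (20, 14, "heterozygous"),  # f = 0.70, band edge inclusive
        ],
    )
    def test_threshold_boundaries(self, depth, reads, call):
        assert classify_marker(depth, reads, P) == call

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="uncovered"):
            classify_marker(0, 0, P)


class TestBuildMarkerMap:
    def test_non_autosomes_excluded(self):
        df = pd.DataFrame(
            {"chrom": ["chrX"] * 3, "pos": [1, 2, 3], "depth": 30, "variant_reads": 30}
        )
        assert build_marker_map(df) == {}

    def test_depth_below_20_excluded(self):
        df = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 200], "depth": [19, 20], "variant_reads": [19, 20]}
        )
        m = build_marker_map(df)
        assert m["chr1"]["positions"].tolist() == [200]

    def test_unsorted_input_sorted_and_duplicates_collapsed_to_deeper(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [300, 100, 300],
                "depth": [25, 30, 40],
                "variant_reads": [25, 30, 40],
            }
        )
        m = build_marker_map(df)
        assert m["chr1"]["positions"].tolist() == [100, 300]
        assert m["chr1"]["depths"].tolist() == [30, 40]

    def test_markers_accepted_as_objects(self):
        m = build_marker_map([Marker("chr1", 100, 30, 30), Marker("chr2", 50, 30, 15)])
        assert set(m) == {"chr1", "chr2"}


class TestScanWindows:
    def test_all_hom_600_markers_gives_101_qualified_windows(self):
        positions = 1 + 1000 * np.arange(600)
        windows = scan_windows(make_map(positions, ["hom"] * 600), P)
        assert len(windows) == 101
        assert all(w.qualified for w in windows)

    def test_three_hets_disqualify(self):
        calls = ["hom"] * 500
        calls[10] = calls[20] = calls[30] = "het"
        windows = scan_windows(make_map(1 + 1000 * np.arange(500), calls), P)
        assert len(windows) == 1 and not windows[0].qualified
        assert windows[0].het_count == 3

    def test_oversized_gap_disqualifies(self):
        positions = list(1 + 1000 * np.arange(500))
        positions = positions[:250] + [p + 600_000 for p in positions[250:]]
        windows = scan_windows(make_map(positions, ["hom"] * 500), P)
        assert len(windows) == 1 and not windows[0].qualified
        assert windows[0].max_internal_gap_bp == 601_000

    def test_short_chromosome_yields_no_windows(self):
        windows = scan_windows(make_map([1, 2, 3], ["hom"] * 3), P)
        assert windows == []

    def test_single_marker_windows_gap_rule_vacuous(self):
        params = RohParameters(window_markers=1, max_het_per_window=0)
        m = make_map([1, 1_000_000, 9_000_000], ["hom", "het", "hom"])
        windows = scan_windows(m, params)
        assert [w.qualified for w in windows] == [True, False, True]


class TestOracleEquivalence:
    def test_exhaustive_small_patterns(self):
        """Every het/hom pattern of 10 markers, window of 3, two gap
        layouts — the incremental scan must equal the explicit oracle."""
        params = RohParameters(window_markers=3, max_het_per_window=1, max_gap_bp=10_000)
        for pattern in itertools.product(["hom", "het"], repeat=10):
            for positions in (
                1 + 1000 * np.arange(10),
                 1 + 6000 * np.arange(10),  # every gap exceeds the ceiling
            ):
                m = make_map(positions, list(pattern))
                assert scan_windows(m, params) == oracle_scan(m, params)

    @pytest.mark.parametrize("seed", range(10))
    def test_seeded_random_maps_5000_markers(self, seed):
        rng = np.random.default_rng(seed)
        n = 5000
        positions = np.cumsum(rng.integers(100, 650_000, size=n))
        depth = rng.integers(20, 60, size=n)
        reads = np.where(rng.random(n) < 0.5, depth, (depth * rng.uniform(0.2, 1.0, n)).astype(int))
        df = pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "depth": depth, "variant_reads": reads}
        )
        m = build_marker_map(df)
        assert scan_windows(m, P) == oracle_scan(m, P)


class TestCoalescence:
    def test_run_below_1mb_not_emitted(self):
        positions = 1 + 1500 * np.arange(550)  # ~0.82 Mb total span
        regions = map_homozygosity_from(positions, ["hom"] * 550)
        assert regions == []

    def test_run_above_1mb_emitted_with_full_span(self):
        positions = 1 + 3000 * np.arange(550)  # 1.65 Mb span
        regions = map_homozygosity_from(positions, ["hom"] * 550)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp, r.n_markers) == (1, 1 + 3000 * 549, 550)

    def test_disqualified_stretch_splits_regions(self):
        # two long hom runs separated by a dense het block
        calls = ["hom"] * 600 + ["het"] * 100 + ["hom"] * 600
        positions = 1 + 3000 * np.arange(1300)
        m = make_map(positions, calls)
        params = RohParameters(window_markers=100, max_het_per_window=2)
        regions = coalesce_windows(scan_windows(m, params), m, params)
        assert len(regions) == 2
        assert regions[0].end_bp < regions[1].start_bp

    def test_regions_never_overlap_and_meet_minimum(self):
        rng = np.random.default_rng(3)
        calls = ["hom" if u < 0.8 else "het" for u in rng.random(4000)]
        positions = 1 + 2000 * np.arange(4000)
        m = make_map(positions, calls)
        params = RohParameters(window_markers=50, max_het_per_window=2)
        regions = coalesce_windows(scan_windows(m, params), m, params)
        for r in regions:
            assert r.length_bp >= params.min_region_bp
        for a, b in zip(regions, regions[1:]):
            assert a.end_bp < b.start_bp


def map_homozygosity_from(positions, calls):
    reads = {"hom": 50, "het": 25}
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": list(positions),
            "depth": 50,
            "variant_reads": [reads[c] for c in calls],
        }
    )
    return map_homozygosity(df)


@pytest.fixture(scope="module")
def random_map():
    rng = np.random.default_rng(5)
    n = 3000
    positions = np.cumsum(rng.integers(500, 550_000, size=n))
    depth = rng.integers(20, 60, size=n)
    reads = np.where(rng.random(n) < 0.6, depth, depth // 2)
    return build_marker_map(
        pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "depth": depth, "variant_reads": reads}
        )
    )


class TestMonotonicity:

    @staticmethod
    def qualified_set(m, params):
        return {
            (w.chromosome, w.first_marker_index)
            for w in scan_windows(m, params)
            if w.qualified
        }

    def test_loosening_het_budget_never_shrinks_qualified_set(self, random_map):
        base = RohParameters(window_markers=200, max_het_per_window=2)
        for max_het in (3, 5, 10, 200):
            loose = RohParameters(window_markers=200, max_het_per_window=max_het)
            assert self.qualified_set(random_map, base) <= self.qualified_set(random_map, loose)

    def test_loosening_gap_ceiling_never_shrinks_qualified_set(self, random_map):
        base = RohParameters(window_markers=200, max_gap_bp=300_000)
        for gap in (400_000, 500_000, 10_000_000):
            loose = RohParameters(window_markers=200, max_gap_bp=gap)
            assert self.qualified_set(random_map, base) <= self.qualified_set(random_map, loose)

    def test_raising_min_region_never_grows_region_set(self, random_map):
        params = RohParameters(window_markers=100, max_het_per_window=5)
        windows = scan_windows(random_map, params)
        previous = None
        for min_bp in (500_000, 1_000_000, 2_000_000, 5_000_000):
            p = RohParameters(window_markers=100, max_het_per_window=5, min_region_bp=min_bp)
            regions = set(coalesce_windows(windows, random_map, p))
            if previous is not None:
                assert regions <= previous
            previous = regions


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(10))
    def test_2mb_plant_recovered_within_marker_resolution(self, seed):
        """A 2 Mb homozygous plant in an all-het background (5 kb grid,
        30x) is recovered as exactly one region with both boundaries
        within 10 kb (two marker spacings) of the plant."""
        cfg = SimulationConfig(
            seed=seed,
            genome=(("chr1", 20_000_000),),
            roh_plants=(("chr1", 10_000_000, 12_000_000),),
            marker_spacing_mode="fixed",
            marker_spacing_bp=5_000,
            mean_depth=30,
            het_truth_rate=1.0,
        )
        frame, _ = generate_marker_map(cfg)
        params = RohParameters(window_markers=300)
        regions = map_homozygosity(frame, params)
        assert len(regions) == 1
        r = regions[0]
        assert abs(r.start_bp - 10_000_000) <= 10_000
        assert abs(r.end_bp - 12_000_000) <= 10_000

    def test_all_het_genome_yields_no_regions(self):
        cfg = SimulationConfig(
            seed=0,
            genome=(("chr1", 10_000_000),),
            het_truth_rate=1.0,
            marker_spacing_mode="fixed",
        )
        frame, _ = generate_marker_map(cfg)
        assert map_homozygosity(frame, RohParameters(window_markers=300)) == []

    def test_het_contamination_budget(self):
        """2 het contaminants per 500 markers keep the plant detectable;
        5 per 500 suppress it."""
        n = 1000
        positions = 1 + 5_000 * np.arange(n)  # 5 Mb of markers
        for per500, expected_regions in ((2, 1), (5, 0)):
            calls = ["hom"] * n
            stride = 500 // per500
            for i in range(0, n, stride):
                calls[i] = "het"
            m = make_map(positions, calls)
            regions = coalesce_windows(scan_windows(m, P), m, P)
            assert len(regions) == expected_regions
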