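"""Depth normalization, CNV calling/merging, genotyping, Vst and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divscan as d
from divscan import io
from divscan.cnv import RawCall, should_merge

SAMPLES8 = ["case_1", "case_2"] + [f"control_{i + 1}" for i in range(6)]


def make_matrix(counts, samples=None, chrom="chr1", window_size=800, step=400):
    counts = np.asarray(counts)
    samples = samples or [f"s{i + 1}" for i in range(counts.shape[1])]
    starts = np.arange(counts.shape[0]) * step + 1
    return d.DepthWindowMatrix(
        chroms=np.array([chrom] * counts.shape[0]),
        starts=starts,
        counts=counts,
        samples=samples,
        window_size=window_size,
        step=step,
    )


class TestNormalizeDepth:
    def test_constant_counts_give_diploid(self):
        m = d.normalize_depth(make_matrix(np.full((20, 3), 50)))
        np.testing.assert_allclose(m.normalized, 2.0)

    def test_doubled_window_gives_four(self):
        counts = np.full((21, 1), 100)
        counts[10] = 200
        m = d.normalize_depth(make_matrix(counts))
        assert m.normalized[10, 0] == pytest.approx(4.0)

    def test_zero_median_sample_raises(self):
        counts = np.full((10, 2), 40)
        counts[:, 1] = 0
        with pytest.raises(ValueError, match="s2"):
            d.normalize_depth(make_matrix(counts))

    def test_simulated_gain_recovers_copy_number(self, cnv_cohort):
        """Mean normalized CN over a planted CN-3 interval lands in [2.8, 3.2]."""
        cfg, cohort = cnv_cohort
        m = d.DepthWindowMatrix.from_frame(io.read_depth_matrix(cohort.depth_matrix_path))
        d.normalize_depth(m)
        cnv = cfg.planted_cnvs[0]
        inside = (m.starts >= cnv.start) & (m.starts + m.window_size - 1 <= cnv.end)
        assert inside.sum() >= 50
        case_mean = m.normalized[inside][:, :2].mean()
        ctrl_mean = m.normalized[inside][:, 2:].mean()
        assert 2.8 <= case_mean <= 3.2
        assert 1.9 <= ctrl_mean <= 2.1

    def test_gc_correction_recenters_bins(self):
        rng = np.random.default_rng(4)
        gc = rng.uniform(0.2, 0.8, size=400)
        mult = 0.5 + gc  # depth responds linearly to GC
        counts = rng.poisson(200 * mult[:, None], size=(400, 2))
        m = make_matrix(counts)
        d.normalize_depth(m, gc=gc)
        # after per-decile recentering, GC bins should all sit near diploid
        for b in range(2, 8):
            sel = (gc * 10).astype(int) == b
            if sel.sum() > 10:
                assert np.median(m.normalized[sel]) == pytest.approx(2.0, abs=0.1)


class TestInitialCalls:
    def test_all_diploid_gives_no_calls(self):
        m = d.normalize_depth(make_matrix(np.full((50, 4), 80)))
        assert d.initial_calls(m) == []

    def test_single_run_detected_with_coordinates(self):
        counts = np.full((30, 2), 100)
        counts[10:20, 0] = 150  # normalized CN 3 in sample 1
        m = d.normalize_depth(make_matrix(counts))
        calls = d.initial_calls(m)
        assert len(calls) == 1
        call = calls[0]
        assert call.first_window == 10 and call.last_window == 19
        assert call.start == 10 * 400 + 1
        assert call.end == 19 * 400 + 800

    def test_run_shorter_than_min_windows_ignored(self):
        counts = np.full((30, 1), 100)
        counts[5:7, 0] = 200
        m = d.normalize_depth(make_matrix(counts))
        assert d.initial_calls(m, min_windows=3) == []

    def test_recovers_planted_cnvs_within_one_step(self):
        """Five planted CNVs >= 2400 bp recovered with <= 1 window-step error."""
        cfg = d.SimulationConfig(
            n_chromosomes=1,
            chromosome_length=300_000,
            snp_density=1e-4,
            planted_cnvs=tuple(
                d.PlantedCNV("chr1", s, s + ln - 1, cn, 2)
                for s, ln, cn in [
                    (20_001, 2_400, 4),
                    (60_001, 3_200, 3),
                    (100_001, 4_000, 0),
                    (150_001, 2_400, 1),
                    (200_001, 5_600, 5),
                ]
            ),
            mean_depth_per_sample=100.0,
            random_seed=31,
        )
        import tempfile

        cohort = d.simulate_cohort(cfg, tempfile.mkdtemp())
        m = d.DepthWindowMatrix.from_frame(io.read_depth_matrix(cohort.depth_matrix_path))
        d.normalize_depth(m)
        calls = d.initial_calls(m)
        for cnv in cfg.planted_cnvs:
            hit = [
                c for c in calls if abs(c.start - cnv.start) <= 400 and abs(c.end - cnv.end) <= 400
            ]
            assert hit, f"planted CNV at {cnv.start} not recovered"


class TestMerge:
    def _matrix_for(self, n_windows=60, seed=0):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.poisson(100, size=(n_windows, 8)), samples=SAMPLES8)
        return d.normalize_depth(m)

    def test_gap_exactly_twenty_percent_not_merged(self):
        m = self._matrix_for()
        # identical profiles so the correlation rule passes; combined length 4000
        m.normalized[0:5] = m.normalized[10:15] = np.tile(np.linspace(2, 4, 8), (5, 1))
        # calls: windows 0-4 (1..2400) and 10-14 (4001..6400); gap = 1600 < 800? build explicit
        a = RawCall("chr1", 1, 2000, 0, 4)
        b = RawCall("chr1", 2801, 4800, 10, 14)
        # gap = 800 = 0.2 * (2000 + 2000) exactly -> strict rule refuses
        assert not should_merge(a, b, m)

    def test_identical_profiles_zero_gap_merged(self):
        m = self._matrix_for()
        profile = np.tile(np.linspace(2, 4, 8), (10, 1))
        m.normalized[0:5] = profile[:5]
        m.normalized[5:10] = profile[5:]
        # window-grid coordinates: windows 0-4 span 1..2400, windows 5-9 span 2001..4400
        a = RawCall("chr1", 1, 2400, 0, 4)
        b = RawCall("chr1", 2001, 4400, 5, 9)
        assert should_merge(a, b, m)
        regions = d.merge_calls([a, b], m)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 4400)

    def test_uncorrelated_profiles_not_merged(self):
        m = self._matrix_for(seed=2)
        m.normalized[0:5] = np.tile(np.array([4.0, 2, 2, 2, 2, 2, 2, 2]), (5, 1))
        m.normalized[5:10] = np.tile(np.array([2.0, 2, 4, 2, 3, 2, 4, 2]), (5, 1))
        a = RawCall("chr1", 1, 2000, 0, 4)
        b = RawCall("chr1", 2001, 4000, 5, 9)
        assert not should_merge(a, b, m)

    def test_different_chromosomes_never_merge(self):
        m = self._matrix_for()
        a = RawCall("chr1", 1, 2000, 0, 4)
        b = RawCall("chr2", 2001, 4000, 5, 9)
        assert not should_merge(a, b, m)

    def test_two_samples_falls_back_to_distance_rule(self):
        rng = np.random.default_rng(1)
        m = d.normalize_depth(make_matrix(rng.poisson(100, size=(20, 2))))
        a = RawCall("chr1", 1, 2000, 0, 4)
        b = RawCall("chr1", 2001, 4000, 5, 9)
        assert should_merge(a, b, m)

    def test_unsorted_calls_raise(self):
        m = self._matrix_for()
        a = RawCall("chr1", 2001, 4000, 5, 9)
        b = RawCall("chr1", 1, 2000, 0, 4)
        with pytest.raises(ValueError, match="sorted"):
            d.merge_calls([a, b], m)


class TestGenotype:
    @pytest.mark.parametrize(
        "estimate,code",
        [(1.98, "AA"), (3.1, "AB"), (2.5, "AB"), (0.02, "D"), (1.2, "Ad"), (4.4, "BB"), (5.6, "M")],
    )
    def test_estimate_to_code(self, estimate, code):
        counts = np.full((5, 1), 100)
        m = d.normalize_depth(make_matrix(counts))
        m.normalized[:, 0] = estimate
        region = d.region_from_span(m, 0, 4)
        assert region.genotype_codes[0] == code

    def test_code_map(self):
        assert [d.genotype_code(c) for c in range(6)] == ["D", "Ad", "AA", "AB", "BB", "M"]
        with pytest.raises(ValueError):
            d.genotype_code(-1)


def vst_oracle(values, n_cases):
    """Brute-force variance decomposition, straight from its definition."""
    values = np.asarray(values, dtype=float)
    case, ctrl = values[:n_cases], values[n_cases:]
    vt = np.mean((values - values.mean()) ** 2)
    if vt == 0:
        return 0.0
    v1 = np.mean((case - case.mean()) ** 2)
    v2 = np.mean((ctrl - ctrl.mean()) ** 2)
    vs = (len(case) * v1 + len(ctrl) * v2) / len(values)
    return (vt - vs) / vt


class TestVst:
    CASE_IDX = np.array([0, 1])
    CTRL_IDX = np.arange(2, 8)

    def test_identical_samples_give_zero(self):
        assert d.vst(np.full(8, 1.3), self.CASE_IDX, self.CTRL_IDX) == 0.0

    def test_within_group_constant_gives_one(self):
        values = np.array([1.0, 1.0, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2])
        assert d.vst(values, self.CASE_IDX, self.CTRL_IDX) == pytest.approx(1.0)

    def test_frozen_example_matches_oracle(self):
        values = np.array([1.0, 0.8, 0.1, -0.1, 0.0, 0.2, -0.2, 0.1])
        expected = vst_oracle(values, 2)
        assert d.vst(values, self.CASE_IDX, self.CTRL_IDX) == pytest.approx(expected)
        assert 0.0 <= expected <= 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            d.vst(np.ones(8), np.array([], dtype=int), self.CTRL_IDX)

    @given(st.lists(st.floats(-3, 3), min_size=8, max_size=8), st.floats(-5, 5))
    @settings(max_examples=60, derandomize=True)
    def test_range_shift_and_swap_invariance(self, values, shift):
        values = np.asarray(values)
        v = d.vst(values, self.CASE_IDX, self.CTRL_IDX)
        assert 0.0 <= v <= 1.0 + 1e-12
        v_shift = d.vst(values + shift, self.CASE_IDX, self.CTRL_IDX)
        assert v_shift == pytest.approx(v, abs=1e-8)
        v_swap = d.vst(values, self.CTRL_IDX, self.CASE_IDX)
        assert v_swap == pytest.approx(v, abs=1e-12)

    def test_unweighted_variant_can_leave_unit_interval(self):
        # documents why size weighting is the default
        values = np.array([0.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert d.vst(values, self.CASE_IDX, self.CTRL_IDX, weighted=False) < 0.0


class TestFilterCandidates:
    def _region(self, chrom="chr1", start=1, length=2400, vst_val=0.4):
        counts = np.full((5, 8), 100)
        m = d.normalize_depth(make_matrix(counts, samples=SAMPLES8, chrom=chrom))
        r = d.region_from_span(m, 0, 4)
        r.chromosome, r.start, r.end = chrom, start, start + length - 1
        r.vst = vst_val
        return r

    def test_length_boundary_strict(self):
        assert d.filter_candidates([self._region(length=2000, vst_val=0.9)]) == []

    def test_table_pattern_region_retained(self):
        kept = d.filter_candidates([self._region(length=2400, vst_val=0.4357)])
        assert len(kept) == 1

    def test_vst_boundary_strict(self):
        assert d.filter_candidates([self._region(length=2400, vst_val=0.25)]) == []

    def test_sex_and_scaffold_excluded_by_default(self):
        regions = [
            self._region(chrom="chrX", length=5000, vst_val=0.9),
            self._region(chrom="scaffold_12", length=5000, vst_val=0.9),
            self._region(chrom="chr2", length=5000, vst_val=0.9),
        ]
        kept = d.filter_candidates(regions)
        assert [r.chromosome for r in kept] == ["chr2"]
        kept_all = d.filter_candidates(regions, autosomes_only=False)
        assert len(kept_all) == 3

    def test_matches_brute_force_over_random_regions(self):
        rng = np.random.default_rng(12)
        regions = []
        for _ in range(50):
            regions.append(
                self._region(length=int(rng.integers(500, 6000)), vst_val=float(rng.uniform(0, 1)))
            )
        kept = d.filter_candidates(regions, min_length=2000, min_vst=0.25)
        expected = [r for r in regions if r.length > 2000 and r.vst > 0.25]
        assert kept == expected


class TestAnnotateRegions:
    def _region(self, start, end, chrom="chr1"):
        counts = np.full((3, 8), 100)
        m = d.normalize_depth(make_matrix(counts, samples=SAMPLES8, chrom=chrom))
        r = d.region_from_span(m, 0, 2)
        r.chromosome, r.start, r.end = chrom, start, end
        r.vst = 0.5
        return r

    def test_downstream_gene_distance(self):
        """A gene starting 43,507 nt past the region end reports that gap."""
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100_000 + 43_507], "end": [150_000], "name": ["LHX8"]}
        )
        table = d.annotate_regions([self._region(98_001, 100_000)], genes)
        row = table.iloc[0]
        assert (row["gene"], row["distance"], row["orientation"]) == ("LHX8", 43_507, "downstream")

    def test_overlapping_gene_distance_zero(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [1500], "name": ["g"]})
        row = d.annotate_regions([self._region(1000, 3000)], genes).iloc[0]
        assert row["distance"] == 0 and row["orientation"] == "overlap"

    def test_empty_annotation_reports_intergenic(self):
        genes = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        row = d.annotate_regions([self._region(1000, 3000)], genes).iloc[0]
        assert row["orientation"] == "intergenic" and pd.isna(row["gene"])

    def test_matches_brute_force_nearest(self):
        rng = np.random.default_rng(23)
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": rng.integers(1, 50_000, size=30),
                "name": [f"g{i}" for i in range(30)],
            }
        )
        genes["end"] = genes["start"] + rng.integers(100, 3000, size=30)
        regions = [
            self._region(int(s), int(s) + 999) for s in rng.integers(1, 50_000, size=25)
        ]
        table = d.annotate_regions(regions, genes)
        for r, row in zip(regions, table.itertuples()):
            best = None
            for g in genes.itertuples():
                if g.start <= r.end and g.end >= r.start:
                    dist = 0
                elif g.start > r.end:
                    dist = g.start - r.end
                else:
                    dist = r.start - g.end
                if best is None or dist < best:
                    best = dist
            assert row.distance == best
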