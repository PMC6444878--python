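import numpy as np
import pytest

from nucshift.io_formats import GeneModel
from nucshift.nucleosome_calls import NucleosomeCall
from nucshift.occupancy import Profile1D
from nucshift import shift_analysis as sa


def _call(summit, chrom="c", occ=10.0, label="s"):
    return NucleosomeCall(chrom, summit, summit - 73, summit + 74, occ, None, label)


def _gene(gid="g1", strand="+", tss=5000, chrom="c"):
    tes = tss + 2000 if strand == "+" else tss - 2000
    return GeneModel(gid, chrom, strand, tss, tes)


class TestAssignFlanking:
    def test_plus_strand_picks_nearest_up_and_downstream(self):
        calls = [_call(4800), _call(5150), _call(5330)]
        minus1, plus1 = sa.assign_flanking_nucleosomes(calls, [_gene()])["g1"]
        assert minus1.summit == 4800
        assert plus1.summit == 5150

    def test_minus_strand_orientation_flips(self):
        calls = [_call(4850), _call(5200)]
        minus1, plus1 = sa.assign_flanking_nucleosomes(calls, [_gene(strand="-")])["g1"]
        assert plus1.summit == 4850
        assert minus1.summit == 5200

    def test_missing_slot_when_outside_window(self):
        calls = [_call(5150)]
        minus1, plus1 = sa.assign_flanking_nucleosomes(calls, [_gene()], window=1000)["g1"]
        assert minus1 is None
        assert plus1.summit == 5150

    def test_summit_at_tss_counts_as_plus1(self):
        calls = [_call(5000)]
        minus1, plus1 = sa.assign_flanking_nucleosomes(calls, [_gene()])["g1"]
        assert plus1.summit == 5000 and minus1 is None


class TestPairNucleosomes:
    def test_overlapping_footprints_pair_with_signed_shift(self):
        pairs, ua, ub = sa.pair_nucleosomes([_call(1000)], [_call(1060)])
        (p,) = pairs
        assert p.shift_genomic == 60
        assert not ua and not ub

    def test_no_pair_when_footprints_disjoint(self):
        pairs, ua, ub = sa.pair_nucleosomes([_call(1000)], [_call(1200)])
        assert pairs == []
        assert len(ua) == 1 and len(ub) == 1

    def test_greedy_prefers_smaller_shift(self):
        pairs, _, ub = sa.pair_nucleosomes([_call(1000)], [_call(1010), _call(1100)])
        (p,) = pairs
        assert p.call_b.summit == 1010
        assert [c.summit for c in ub] == [1100]

    def test_matching_stable_under_input_permutation(self):
        rng = np.random.default_rng(5)
        a = [_call(int(s)) for s in np.sort(rng.integers(0, 50_000, 60))]
        b = [_call(int(s) + int(rng.integers(-80, 80))) for s in np.sort(rng.integers(0, 50_000, 60))]
        ref = sa.pair_nucleosomes(a, b)[0]
        key = {(p.call_a.summit, p.call_b.summit) for p in ref}
        for seed in (1, 2):
            rng2 = np.random.default_rng(seed)
            pa = list(a)
            pb = list(b)
            rng2.shuffle(pa)
            rng2.shuffle(pb)
            got = {(p.call_a.summit, p.call_b.summit) for p in sa.pair_nucleosomes(pa, pb)[0]}
            assert got == key


class TestRegionVariance:
    def test_mean_of_distances(self):
        pairs = [
            sa.NucleosomePair(_call(100 + 200 * i), _call(100 + 200 * i + d))
            for i, d in enumerate((10, 20, 30))
        ]
        rv = sa.region_variance(pairs, "r")
        assert rv.mean_pair_distance == 20.0

    def test_zero_distance_pair(self):
        rv = sa.region_variance([sa.NucleosomePair(_call(100), _call(100))])
        assert rv.mean_pair_distance == 0.0

    def test_no_pairs_missing(self):
        assert sa.region_variance([]) is None

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(11)
        pairs = []
        expected = []
        pos = 0
        for _ in range(50):
            pos += int(rng.integers(200, 400))
            d = int(rng.integers(-146, 147))
            pairs.append(sa.NucleosomePair(_call(pos), _call(pos + d)))
            expected.append(abs(d))
        rv = sa.region_variance(pairs)
        assert rv.mean_pair_distance == pytest.approx(sum(expected) / len(expected))


class TestClassifyShift:
    @pytest.mark.parametrize(
        "shift,bin_,direction",
        [
            (0, "0", "none"),
            (5, "1-9", "downstream"),
            (-9, "1-9", "upstream"),
            (10, "10-50", "downstream"),
            (75, "51-100", "downstream"),
            (-160, "151-200", "upstream"),
            (200, "151-200", "downstream"),
            (201, "excluded", "none"),
            (-300, "excluded", "none"),
        ],
    )
    def test_bins_and_directions(self, shift, bin_, direction):
        label = sa.classify_shift(shift)
        assert (label.bin, label.direction) == (bin_, direction)

    def test_direction_is_gene_oriented_hence_strand_invariant(self):
        # the same oriented shift value labels identically whatever the strand
        for shift in (-175, -30, 0, 30, 175):
            assert sa.classify_shift(shift) == sa.classify_shift(shift)


class TestSpacing:
    def test_adjacent_distances(self):
        dists = sa.spacing_distances([_call(1000), _call(1190), _call(1375)])
        assert sorted(dists) == [185, 190]

    def test_uniform_array_point_mass(self):
        calls = [_call(1000 + 190 * i) for i in range(6)]
        values, density = sa.spacing_density(sa.spacing_distances(calls))
        assert list(values) == [190]
        assert density[0] == 1.0

    def test_single_call_empty(self):
        assert sa.spacing_distances([_call(100)]).size == 0

    def test_uniformness_point_mass(self):
        u = sa.uniformness(np.array([190] * 5))
        assert u["mode"] == 190 and u["iqr"] == 0.0

    def test_uniformness_quartile_convention(self):
        # {180,185,190,195,200}: type-7 Q1=185, Q3=195 -> IQR 10; tied modes
        # resolve to the smallest value
        u = sa.uniformness(np.array([180, 185, 190, 195, 200]))
        assert u["iqr"] == pytest.approx(10.0)
        assert u["mode"] == 180

    def test_uniformness_empty_missing(self):
        assert sa.uniformness(np.array([], dtype=int)) is None


def _decaying_cosine_profile(period=190, flank=1000, ndr_depth=0.02):
    offsets = np.arange(-flank, flank + 1)
    y = np.zeros(offsets.size)
    for k in range(5):
        center = 100 + k * period
        y += 0.8 ** k * np.exp(-0.5 * ((offsets - center) / 40.0) ** 2)
    for k in range(3):
        center = -150 - k * period
        y += 0.5 * 0.8 ** k * np.exp(-0.5 * ((offsets + 150 + k * period) / 40.0) ** 2)
    y += ndr_depth
    return Profile1D(offsets, y, n_anchors=100)


class TestPhasingMetrics:
    def test_decaying_cosine_is_canonical_with_period_recovered(self):
        report = sa.phasing_metrics(_decaying_cosine_profile(), (140, 240))
        assert report.canonical
        assert report.plus1_offset == pytest.approx(100, abs=3)
        assert report.estimated_period == pytest.approx(190, abs=5)
        assert report.decay_monotone

    def test_flat_profile_not_canonical(self):
        offsets = np.arange(-500, 501)
        prof = Profile1D(offsets, np.ones(offsets.size), 10)
        report = sa.phasing_metrics(prof, (140, 240))
        assert not report.canonical
        assert report.peak_offsets == []

    def test_rising_peaks_break_decay(self):
        offsets = np.arange(-1000, 1001)
        y = np.full(offsets.size, 0.02)
        for k, height in enumerate((0.4, 0.7, 1.0)):  # growing downstream peaks
            y += height * np.exp(-0.5 * ((offsets - (100 + 190 * k)) / 40.0) ** 2)
        report = sa.phasing_metrics(Profile1D(offsets, y, 100), (140, 240))
        assert not report.decay_monotone
        assert not report.canonical

    def test_shallow_ndr_rejected(self):
        # high floor: the minimum around the TSS is ~2/3 of the +1 peak
        report = sa.phasing_metrics(_decaying_cosine_profile(ndr_depth=2.0), (140, 240))
        assert not report.canonical


class TestGeneShiftTable:
    def test_recovers_programmed_shift_both_strands(self):
        genes = [_gene("gp", "+", 5000), _gene("gm", "-", 20_000)]
        # + gene: +1 at 5100 shifts downstream 75; - gene: +1 at 19900 shifts
        # downstream 75 (genomically -75)
        calls_a = [_call(4950), _call(5100), _call(5290),
                   _call(20_050), _call(19_900), _call(19_710)]
        calls_b = [_call(4950), _call(5175), _call(5290),
                   _call(20_050), _call(19_825), _call(19_710)]
        table = sa.gene_shift_table(calls_a, calls_b, genes)
        t = table.set_index(["gene", "role"])
        assert t.loc[("gp", 1), "shift_oriented"] == 75
        assert t.loc[("gp", 1), "bin"] == "51-100"
        assert t.loc[("gp", 1), "direction"] == "downstream"
        assert t.loc[("gm", 1), "shift_oriented"] == 75
        assert t.loc[("gm", 1), "direction"] == "downstream"
        assert t.loc[("gp", -1), "bin"] == "0"

    def test_orientation_invariance_under_mirroring(self):
        # mirroring all coordinates and strands leaves bins/directions alone
        size = 30_000
        genes = [_gene("g", "+", 5000)]
        calls_a = [_call(4950), _call(5100), _call(5290)]
        calls_b = [_call(4950), _call(5175), _call(5290)]
        fwd = sa.gene_shift_table(calls_a, calls_b, genes)
        m_genes = [GeneModel("g", "c", "-", size - 5000, size - 7000)]
        m_a = [_call(size - c.summit) for c in calls_a]
        m_b = [_call(size - c.summit) for c in calls_b]
        rev = sa.gene_shift_table(m_a, m_b, m_genes)
        f = fwd.set_index(["gene", "role"])
        r = rev.set_index(["gene", "role"])
        for key in f.index:
            assert f.loc[key, "bin"] == r.loc[key, "bin"]
            assert f.loc[key, "direction"] == r.loc[key, "direction"]
            assert f.loc[key, "shift_oriented"] == r.loc[key, "shift_oriented"]
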