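"""Cluster engine: linkage counting, cluster sizes, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trackdamage import (
    BD_SCHEME,
    SB_SCHEME,
    AnalysisParams,
    Site,
    class_fractions,
    classify_site,
    compute_ncl,
    count_linkages,
    events_per_extra_strand_break,
    generate_blob,
    generate_track,
    TrackParams,
)

from conftest import brute_force_ncl, brute_force_pairs, make_eventset

P10 = AnalysisParams(lc_bp=10.0)


class TestCountLinkages:
    def test_pair_within_range_links(self):
        es = make_eventset([[0, 0, 0], [3.0, 0, 0]])
        assert count_linkages(es, P10).n_link == 1

    def test_pair_out_of_range_does_not_link(self):
        es = make_eventset([[0, 0, 0], [3.5, 0, 0]])
        assert count_linkages(es, P10).n_link == 0

    def test_boundary_distance_is_closed(self):
        es = make_eventset([[0, 0, 0], [3.4, 0, 0]])
        assert count_linkages(es, P10).n_link == 1

    def test_three_mutually_close_events_give_three_pairs(self):
        es = make_eventset([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        lr = count_linkages(es, P10)
        assert lr.n_link == 3  # C(3,2), all-pairs convention
        assert sorted(map(tuple, lr.pairs)) == [(0, 1), (0, 2), (1, 2)]

    def test_empty_and_singleton_sets(self):
        assert count_linkages(make_eventset(np.empty((0, 3))), P10).n_link == 0
        assert count_linkages(make_eventset([[0, 0, 0]]), P10).n_link == 0

    @pytest.mark.parametrize("n,seed", [(50, 0), (300, 1), (800, 2)])
    def test_matches_brute_force_oracle(self, random_eventset, n, seed):
        es = random_eventset(n, seed)
        lr = count_linkages(es, P10)
        expected = brute_force_pairs(es.coords, P10.lc_nm)
        assert set(map(tuple, lr.pairs)) == expected

    def test_invariant_under_permutation(self, random_eventset):
        es = random_eventset(150, seed=7)
        perm = np.random.default_rng(1).permutation(150)
        from trackdamage import EventSet

        shuffled = EventSet(es.track_id[perm], es.coords[perm],
                            es.kind[perm], es.edep_eV[perm])
        assert count_linkages(shuffled, P10).n_link == count_linkages(es, P10).n_link

    def test_invariant_under_rigid_transform(self, random_eventset):
        from scipy.spatial.transform import Rotation

        es = random_eventset(150, seed=8)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = make_eventset(es.coords @ R.T + np.array([100.0, -50.0, 7.0]))
        lr0, lr1 = count_linkages(es, P10), count_linkages(moved, P10)
        assert lr1.n_link == lr0.n_link
        assert np.array_equal(np.sort(lr1.n_cl), np.sort(lr0.n_cl))

    def test_monotone_in_linkage_distance(self, random_eventset):
        es = random_eventset(300, seed=9)
        n_links = [count_linkages(es, AnalysisParams(lc)).n_link
                   for lc in (3.0, 5.0, 10.0)]
        assert n_links == sorted(n_links)

    def test_unique_pairing_is_a_matching(self, random_eventset):
        es = random_eventset(200, seed=10, extent_nm=8.0)
        lr = count_linkages(es, P10, pairing="unique")
        flat = lr.pairs.ravel().tolist()
        assert len(flat) == len(set(flat))  # each event in at most one pair
        assert lr.n_link <= count_linkages(es, P10).n_link

    def test_unknown_pairing_rejected(self, random_eventset):
        with pytest.raises(ValueError, match="pairing"):
            count_linkages(random_eventset(5, 0), P10, pairing="nearest")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=60), st.integers(min_value=0, max_value=10_000))
    def test_pair_count_matches_oracle_property(self, n, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-10, 10, size=(n, 3))
        es = make_eventset(coords) if n else make_eventset(np.empty((0, 3)))
        lr = count_linkages(es, P10)
        assert lr.n_link == len(brute_force_pairs(coords, P10.lc_nm))


class TestComputeNcl:
    def test_isolated_pair_counts_itself(self):
        es = make_eventset([[0, 0, 0], [1.0, 0, 0]])
        lr = count_linkages(es, P10)
        assert lr.n_cl.tolist() == [2]
        assert compute_ncl(lr.sites[0], es, P10) == 2

    def test_blob_site_sees_all_events(self):
        es = generate_blob(24, radius_nm=1.0, seed=4)
        lr = count_linkages(es, P10)
        site = lr.sites[0]
        assert compute_ncl(site, es, P10) == 24
        assert brute_force_ncl(es.coords, site.center, P10.lc_nm) == 24

    def test_event_exactly_at_radius_is_included(self):
        # pair midpoint at origin; third event at exactly lc_nm from it
        es = make_eventset([[-0.5, 0, 0], [0.5, 0, 0], [3.4, 0, 0]])
        lr = count_linkages(es, P10)
        center_site = [s for s in lr.sites if s.event_indices == (0, 1)][0]
        assert compute_ncl(center_site, es, P10) == 3

    def test_site_ncl_matches_brute_force(self, random_eventset):
        es = random_eventset(400, seed=12)
        lr = count_linkages(es, P10)
        for k in range(0, lr.n_link, max(1, lr.n_link // 25)):
            assert lr.n_cl[k] == brute_force_ncl(es.coords, lr.centers[k], P10.lc_nm)

    def test_ncl_monotone_in_linkage_distance(self, random_eventset):
        es = random_eventset(300, seed=13)
        lr5 = count_linkages(es, AnalysisParams(5.0))
        lr10 = count_linkages(es, AnalysisParams(10.0))
        pairs10 = {tuple(p): n for p, n in zip(map(tuple, lr10.pairs), lr10.n_cl)}
        for p, n5 in zip(map(tuple, lr5.pairs), lr5.n_cl):
            assert pairs10[p] >= n5


class TestClassification:
    def test_scheme_bin_edges(self):
        assert [(b.lower, b.upper) for b in BD_SCHEME.bins] == [(2, 11), (11, 20), (20, 29)]
        assert [(b.lower, b.upper) for b in SB_SCHEME.bins] == [(2, 14), (14, 26), (26, 38)]

    def test_sb_bin_width_derives_from_bd_spacing_and_ratio(self):
        """12 events per extra strand break = round(9 events per BD x 1.3)."""
        assert events_per_extra_strand_break() == 12
        widths = {b.upper - b.lower for b in SB_SCHEME.bins}
        assert widths == {12}

    @pytest.mark.parametrize(
        "n_cl,scheme,stream,label",
        [
            (6, BD_SCHEME, "sb", "DSB"),
            (6, BD_SCHEME, "bd", "BD/BD"),
            (15, BD_SCHEME, "sb", "DSB/BD"),
            (15, BD_SCHEME, "bd", "BD/BD/BD"),
            (24, BD_SCHEME, "sb", "DSB/BD/BD"),
            (24, BD_SCHEME, "bd", "BD/BD/BD/BD"),
            (6, SB_SCHEME, "sb", "DSB"),
            (15, SB_SCHEME, "sb", "DSB+"),
            (30, SB_SCHEME, "sb", "DSB++"),
            (10, BD_SCHEME, "sb", "DSB"),   # last integer of first bin
            (11, BD_SCHEME, "sb", "DSB/BD"),  # lower edge of second bin
        ],
    )
    def test_bin_lookup(self, n_cl, scheme, stream, label):
        assert classify_site(n_cl, scheme, stream=stream) == label

    def test_overflow_clamps_to_most_complex(self):
        assert classify_site(1000, BD_SCHEME) == "DSB/BD/BD"
        assert classify_site(38, SB_SCHEME) == "DSB++"

    def test_sub_pair_cluster_rejected(self):
        with pytest.raises(ValueError, match="not a complex-damage site"):
            classify_site(1, BD_SCHEME)

    def test_sb_scheme_has_no_bd_stream(self):
        with pytest.raises(ValueError, match="base-damage"):
            classify_site(6, SB_SCHEME, stream="bd")


class TestClassFractions:
    def test_uniform_blob_is_all_one_class(self):
        es = generate_blob(6, radius_nm=1.0, seed=1)
        cf = class_fractions(count_linkages(es, P10), BD_SCHEME)
        assert cf.fractions["DSB"] == 1.0
        assert cf.overflow_fraction == 0.0

    def test_two_equal_populations_split_evenly(self):
        # two tight blobs far apart: one with N_cl=6, one with N_cl=15,
        # weighted by pair counts C(6,2)=15 vs C(15,2)=105
        a = generate_blob(6, 1.0, seed=2)
        b = generate_blob(15, 1.0, seed=3)
        coords = np.vstack([a.coords, b.coords + 1000.0])
        cf = class_fractions(count_linkages(make_eventset(coords), P10), BD_SCHEME)
        assert cf.fractions["DSB"] == pytest.approx(15 / 120)
        assert cf.fractions["DSB/BD"] == pytest.approx(105 / 120)

    def test_fractions_sum_to_one_with_overflow(self, random_eventset):
        es = generate_track(TrackParams(400, mean_free_path_nm=1.0, seed=21))
        for scheme in (BD_SCHEME, SB_SCHEME):
            cf = class_fractions(count_linkages(es, P10), scheme)
            total = sum(cf.fractions.values()) + cf.overflow_fraction
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_fractions_match_brute_force_recount(self, random_eventset):
        es = generate_track(TrackParams(500, mean_free_path_nm=2.0, seed=22))
        lr = count_linkages(es, P10)
        cf = class_fractions(lr, BD_SCHEME)
        # independent recount from brute-force N_cl values
        pairs = brute_force_pairs(es.coords, P10.lc_nm)
        ncl = [brute_force_ncl(es.coords, 0.5 * (es.coords[i] + es.coords[j]), P10.lc_nm)
               for i, j in pairs]
        for b in BD_SCHEME.bins:
            expected = sum(1 for n in ncl if b.lower <= n < b.upper) / len(ncl)
            assert cf.fractions[b.label] == pytest.approx(expected, abs=1e-12)

    def test_empty_result_flags_empty(self):
        cf = class_fractions(count_linkages(make_eventset(np.empty((0, 3))), P10))
        assert cf.empty and cf.n_sites == 0
        assert all(v == 0.0 for v in cf.fractions.values())

    def test_denser_tracks_shift_mass_to_complex_classes(self):
        """Aggregation of events along the track drives damage complexity."""
        complex_mass = []
        for mfp in (1.0, 6.0):
            mass = []
            for seed in range(10):
                es = generate_track(TrackParams(400, mean_free_path_nm=mfp, seed=seed))
                cf = class_fractions(count_linkages(es, P10), BD_SCHEME)
                mass.append(1.0 - cf.fractions["DSB"])
            complex_mass.append(np.mean(mass))
        assert complex_mass[0] > complex_mass[1]
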