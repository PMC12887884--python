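"""Salt-bridge contact detection, per-frame counts, medians, frequency maps."""

import numpy as np
import pytest

import gagbind as g
from gagbind.contact_analysis import (ContactParams, ContactSeries,
                                      detect_contacts, frame_counts,
                                      frequency_map, median_bound)
from gagbind.geometry import Pose, random_rotation


def brute_force_contacts(pose, fibril, glycan, cutoff):
    cat_pos, cat_res, cat_layer, _ = fibril.cationic_atoms()
    ox_body, ox_ids = glycan.hcg_oxygens()
    ox = pose.apply(ox_body)
    found = set()
    for i in range(len(ox)):
        for a in range(len(cat_pos)):
            if np.linalg.norm(ox[i] - cat_pos[a]) <= cutoff:
                found.add((int(cat_res[a]), int(cat_layer[a]), int(ox_ids[i])))
    return found


class TestDetectContacts:
    def test_matches_brute_force_on_random_configurations(
            self, two_ladder_fibril, octasaccharide):
        from conftest import random_pose_near
        rng = np.random.default_rng(31)
        params = ContactParams()
        n_nonempty = 0
        for _ in range(100):
            pose = random_pose_near(two_ladder_fibril, rng, max_offset=5.0)
            got = detect_contacts(pose, two_ladder_fibril, octasaccharide,
                                  params)
            expected = brute_force_contacts(pose, two_ladder_fibril,
                                            octasaccharide, params.cutoff)
            assert got == expected
            n_nonempty += bool(got)
        assert n_nonempty >= 5          # the sample must exercise contacts

    def test_cutoff_boundary_inclusive(self):
        # one NZ ladder; place a single HCG oxygen at exactly 4.5 Å
        fib = g.build_fibril(g.build_cross_section("K"), 3)
        gly = g.build_glycan(2)
        nz = fib.positions[(fib.atom_names == "NZ")][0]
        oxy, ids = gly.hcg_oxygens()
        target = nz + np.array([4.5, 0.0, 0.0])
        pose = Pose(np.eye(3), target - oxy[0])
        contacts = detect_contacts(pose, fib, gly, ContactParams())
        assert any(h == ids[0] for _, _, h in contacts)

    def test_just_outside_cutoff_excluded(self):
        # minimal one-NZ / one-oxygen system isolates the boundary rule
        class OneNZ:
            def cationic_atoms(self):
                return (np.zeros((1, 3)), np.array([311]), np.array([0]),
                        np.array(["NZ"]))

        class OneOxygen:
            def __init__(self, d):
                self._d = d

            def hcg_oxygens(self):
                return np.array([[self._d, 0.0, 0.0]]), np.array([0])

        inside = detect_contacts(Pose(), OneNZ(), OneOxygen(4.5))
        outside = detect_contacts(Pose(), OneNZ(), OneOxygen(4.5 + 1e-6))
        assert inside == {(311, 0, 0)}
        assert outside == set()

    def test_monotone_in_cutoff(self, two_ladder_fibril, octasaccharide):
        from conftest import random_pose_near
        rng = np.random.default_rng(5)
        pose = random_pose_near(two_ladder_fibril, rng, max_offset=3.0)
        prev = set()
        for cutoff in (3.0, 4.5, 6.0, 9.0):
            cur = detect_contacts(pose, two_ladder_fibril, octasaccharide,
                                  ContactParams(cutoff))
            assert prev <= cur
            prev = cur


class TestFrameCounts:
    def test_empty_frame(self):
        assert frame_counts(set()) == (0, 0)

    def test_one_hcg_three_ladder_rungs(self):
        contacts = {(311, 0, 5), (311, 1, 5), (311, 2, 5)}
        assert frame_counts(contacts) == (3, 1)

    def test_two_hcgs_same_rung(self):
        contacts = {(311, 4, 2), (311, 4, 9)}
        assert frame_counts(contacts) == (1, 2)


class TestMedianBound:
    def _series(self, counts):
        # one synthetic contact per counted residue, distinct rungs
        s = ContactSeries()
        for c in counts:
            s.append({(311, layer, layer) for layer in range(c)})
        return s

    def test_odd_sample_median(self):
        med, dist = median_bound(self._series([3, 5, 6, 6, 7]), "residues")
        assert med == 6
        assert dist[6] == pytest.approx(0.4)

    def test_all_zero_frames(self):
        med, _ = median_bound(self._series([0, 0, 0]), "residues")
        assert med == 0

    def test_even_sample_uses_lower_median(self):
        med, _ = median_bound(self._series([2, 4]), "residues")
        assert med == 2          # lower median, not interpolated 3

    def test_site_filter_restricts_counts(self):
        s = ContactSeries()
        s.append({(311, 0, 1), (349, 0, 2)})
        med_all, _ = median_bound(s, "hcgs")
        med_311, _ = median_bound(s, "hcgs", site_filter={311})
        assert (med_all, med_311) == (2, 1)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            median_bound(ContactSeries(), "residues")


class TestFrequencyMap:
    def test_single_contact_single_frame(self, two_ladder_fibril,
                                         octasaccharide):
        hcg = next(h for h in octasaccharide.hcgs if h.group_type == "OS6X")
        series = ContactSeries()
        series.append({(6, 0, hcg.hcg_id)})
        fmap = frequency_map(series, octasaccharide, two_ladder_fibril)
        assert fmap.loc[(hcg.unit_index, "OS6X"), 6] == 1.0
        assert fmap.to_numpy().sum() == 1.0

    def test_half_frequency_over_two_frames(self, two_ladder_fibril,
                                            octasaccharide):
        hcg = octasaccharide.hcgs[0]
        series = ContactSeries()
        series.append({(1, 2, hcg.hcg_id)})
        series.append(set())
        fmap = frequency_map(series, octasaccharide, two_ladder_fibril)
        assert fmap.loc[(hcg.unit_index, hcg.group_type), 1] == 0.5

    def test_multilayer_contacts_pool_to_at_most_one(self, two_ladder_fibril,
                                                     octasaccharide):
        hcg = octasaccharide.hcgs[0]
        series = ContactSeries()
        series.append({(6, layer, hcg.hcg_id) for layer in range(8)})
        fmap = frequency_map(series, octasaccharide, two_ladder_fibril)
        assert fmap.to_numpy().max() <= 1.0
        assert fmap.loc[(hcg.unit_index, hcg.group_type), 6] == 1.0

    def test_cells_match_independent_indicator_means(self, two_ladder_fibril,
                                                     octasaccharide):
        rng = np.random.default_rng(23)
        hcgs = octasaccharide.hcgs
        series = ContactSeries()
        frames = []
        for _ in range(20):
            frame = {(int(rng.choice([1, 6])), int(rng.integers(0, 8)),
                      int(rng.choice([h.hcg_id for h in hcgs])))
                     for _ in range(rng.integers(0, 6))}
            frames.append(frame)
            series.append(frame)
        fmap = frequency_map(series, octasaccharide, two_ladder_fibril)
        key = {h.hcg_id: (h.unit_index, h.group_type) for h in hcgs}
        for (unit, group) in fmap.index:
            for res in fmap.columns:
                indicator = [any(r == res and key[h] == (unit, group)
                                 for r, _, h in fr) for fr in frames]
                assert fmap.loc[(unit, group), res] == pytest.approx(
                    np.mean(indicator))

    def test_sulfamido_column_optional(self, two_ladder_fibril,
                                       octasaccharide):
        hcg = next(h for h in octasaccharide.hcgs
                   if h.group_type == "N_sulfamido")
        series = ContactSeries()
        series.append({(1, 0, hcg.hcg_id)})
        with_n = frequency_map(series, octasaccharide, two_ladder_fibril)
        without = frequency_map(series, octasaccharide, two_ladder_fibril,
                                include_sulfamido=False)
        assert "N_sulfamido" in with_n.index.get_level_values("group")
        assert "N_sulfamido" not in without.index.get_level_values("group")
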