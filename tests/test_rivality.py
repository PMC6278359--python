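"""Rivality index (plain and weighted), CMODI, cliffs and borders."""

import numpy as np
import pytest

from rivality import (
    RivalityModel,
    SENTINEL,
    build_distance_model,
    cmodi,
    detect_borders,
    detect_cliffs,
    diffclass_before_nth,
    neighborhood_profile,
    rivality_plain,
    rivality_profile,
    rivality_weighted,
)

from conftest import brute_profile, brute_rivality, make_dataset, random_dataset


class TestPlainIndex:
    @pytest.mark.parametrize(
        "d_x,d_y,expected",
        [
            (0.1, 0.3, -0.5),
            (0.2, 0.2, 0.0),
            (0.3, 0.1, 0.5),
            (0.0, 0.4, -1.0),
            (0.4, 0.0, 1.0),
        ],
    )
    def test_formula(self, d_x, d_y, expected):
        assert rivality_plain(d_x, d_y) == pytest.approx(expected, abs=1e-15)

    def test_degenerate_zero_zero_sentinel(self):
        ri, flag = rivality_plain(0.0, 0.0, with_flag=True)
        assert ri == SENTINEL == -1e-6
        assert flag

    def test_tie_is_plain_zero_not_sentinel(self):
        ri, flag = rivality_plain(0.2, 0.2, with_flag=True)
        assert ri == 0.0 and not flag

    @pytest.mark.parametrize("bad", [(-0.1, 0.2), (np.inf, 0.2), (0.2, np.nan)])
    def test_invalid_distances_rejected(self, bad):
        with pytest.raises(ValueError):
            rivality_plain(*bad)

    def test_sign_law(self, rng):
        for _ in range(200):
            d_x, d_y = rng.uniform(0, 1, 2)
            ri = rivality_plain(d_x, d_y)
            assert -1.0 <= ri <= 1.0
            if d_x < d_y:
                assert ri < 0
            elif d_x > d_y:
                assert ri > 0


class TestNeighborhoodProfile:
    def prefix_case(self, ranked_classes, own, tn):
        """Build a 1-D dataset realizing a given rank-list class sequence."""
        # molecule of interest at 0; neighbors at increasing positions
        vals = [0.0] + [0.1 * (k + 1) for k in range(len(ranked_classes))]
        labels = [own] + list(ranked_classes)
        # pad to keep >= 2 per class
        vals += [5.0, 5.1, 6.0, 6.1]
        labels += [0, 0, 1, 1]
        ds = make_dataset(np.array(vals) / 10.0, labels)
        return build_distance_model(ds), np.asarray(labels)

    def test_prefix_b_b_a(self):
        m, labels = self.prefix_case([1, 1, 0], own=0, tn=1)
        p = neighborhood_profile(m, labels, 0, 1)
        assert (p.cn, p.cn_x, p.cn_y) == (3, 1, 2)
        assert p.w_x == pytest.approx(2 / 3)
        assert p.w_y == pytest.approx(1 / 3)

    def test_prefix_a_b(self):
        m, labels = self.prefix_case([0, 1], own=0, tn=1)
        p = neighborhood_profile(m, labels, 0, 1)
        assert (p.cn, p.cn_x, p.cn_y) == (2, 1, 1)
        assert p.w_x == p.w_y == 0.5

    def test_prefix_a_a_b_b_tn2(self):
        m, labels = self.prefix_case([0, 0, 1, 1], own=0, tn=2)
        p = neighborhood_profile(m, labels, 0, 2)
        assert (p.cn, p.cn_x, p.cn_y) == (4, 2, 2)
        assert p.w_x == p.w_y == 0.5

    def test_weights_sum_to_one(self, rng):
        for _ in range(20):
            ds = random_dataset(rng, min_per_class=4)
            m = build_distance_model(ds)
            for i in range(ds.n_molecules):
                for tn in (1, 2, 3):
                    p = neighborhood_profile(m, ds.labels, i, tn)
                    assert p.w_x + p.w_y == pytest.approx(1.0, abs=1e-12)
                    assert p.cn_x >= tn and p.cn_y >= tn
                    assert p.cn_x + p.cn_y == p.cn

    def test_infeasible_tn_names_molecule(self):
        ds = make_dataset(np.array([0.0, 0.1, 0.5, 0.6]), [0, 0, 1, 1])
        m = build_distance_model(ds)
        with pytest.raises(ValueError, match="molecule 0"):
            neighborhood_profile(m, ds.labels, 0, 2)


class TestWeightedIndex:
    def test_hand_worked_example(self):
        """d_x=0.3, d_y=0.1, prefix B,B,A: weighted RI = 0.7143."""
        # molecule 0 (class A) at 0; B at 0.1, B at 0.2, A at 0.3 + padding
        vals = np.array([0.0, 0.1, 0.2, 0.3, 5.0, 5.1, 6.0, 6.1]) / 10.0
        labels = [0, 1, 1, 0, 0, 0, 1, 1]
        ds = make_dataset(vals, labels)
        m = build_distance_model(ds)
        p = neighborhood_profile(m, ds.labels, 0, 1)
        assert (p.cn, p.cn_x, p.cn_y) == (3, 1, 2)
        ri = rivality_weighted(m, ds.labels, 0, 1)
        d_x, d_y = 0.03, 0.01
        expect = (d_x * 2 / 3 - d_y * 1 / 3) / (d_x * 2 / 3 + d_y * 1 / 3)
        assert ri == pytest.approx(expect, abs=1e-12)
        assert ri == pytest.approx(0.7143, abs=5e-5)

    def test_balanced_profile_reduces_to_plain(self, rng):
        """When CN_x = CN_y the weights cancel and weighted equals plain."""
        found = 0
        for _ in range(40):
            ds = random_dataset(rng, min_per_class=3)
            m = build_distance_model(ds)
            for i in range(ds.n_molecules):
                p = neighborhood_profile(m, ds.labels, i, 1)
                if p.cn_x != p.cn_y:
                    continue
                found += 1
                from rivality import first_neighbor

                d_x, _ = first_neighbor(m, ds.labels, i, True)
                d_y, _ = first_neighbor(m, ds.labels, i, False)
                assert rivality_weighted(m, ds.labels, i, 1) == pytest.approx(
                    rivality_plain(d_x, d_y), abs=1e-12
                )
        assert found > 10

    def test_zero_zero_sentinel(self):
        # three coincident molecules spanning both classes
        ds = make_dataset(np.array([0.3, 0.3, 0.3, 0.9, 0.8, 0.1]),
                          [0, 0, 1, 1, 0, 1])
        m = build_distance_model(ds)
        ri, flag = rivality_weighted(m, ds.labels, 0, 1, with_flag=True)
        assert ri == SENTINEL and flag

    def test_oracle_equivalence(self, rng):
        """Vectorized path matches naive re-derivation on random datasets."""
        for _ in range(40):
            ds = random_dataset(rng, min_per_class=4)
            m = build_distance_model(ds)
            vals, labels = ds.values(), ds.labels
            for i in range(ds.n_molecules):
                for tn in (0, 1, 2, 3):
                    if tn:
                        want_prof = brute_profile(vals, labels, i, tn)
                        got = neighborhood_profile(m, labels, i, tn)
                        assert (got.cn, got.cn_x, got.cn_y) == want_prof
                        got_ri = rivality_weighted(m, labels, i, tn)
                    else:
                        got_ri = rivality_profile(m, labels, (0,))[0][i, 0]
                    assert got_ri == pytest.approx(
                        brute_rivality(vals, labels, i, tn), abs=1e-12
                    )


class TestProfileAndResults:
    def test_separated_clusters_all_negative(self):
        ds = make_dataset(
            np.array([0.0, 0.001, 0.002, 0.1, 0.101, 0.102]) * 10.0 / 1.02,
            [0, 0, 0, 1, 1, 1],
        )
        ri, _ = rivality_profile(build_distance_model(ds), ds.labels, (1,))
        assert (ri < 0).all()

    def test_single_displaced_molecule_positive(self):
        # the displaced A point sits just beyond cluster B's rim: its own
        # nearest neighbor is a B molecule, yet every B molecule keeps a
        # closer same-class neighbor than the intruder
        vals = np.array([0.0, 0.01, 0.02, 1.0, 1.01, 1.02, 1.035])
        labels = [0, 0, 0, 1, 1, 1, 0]
        ds = make_dataset(vals / vals.max(), labels)
        ri, _ = rivality_profile(build_distance_model(ds), ds.labels, (1,))
        assert ri[6, 0] > 0
        assert (ri[:6, 0] < 0).all()

    def test_multi_tn_column_consistency(self, rng):
        ds = random_dataset(rng, min_per_class=4)
        m = build_distance_model(ds)
        multi, _ = rivality_profile(m, ds.labels, (0, 1, 2))
        for k, tn in enumerate((0, 1, 2)):
            single, _ = rivality_profile(m, ds.labels, (tn,))
            np.testing.assert_array_equal(multi[:, k], single[:, 0])

    def test_results_object_round_trip(self, separable_dataset):
        res = RivalityModel(separable_dataset).fit(tn_list=(0, 1))
        assert res.cmodi_[0] == 1.0 and res.cmodi_[1] == 1.0
        assert res.cliff_ids(1) == []
        frame = res.to_frame()
        assert list(frame.index) == list(separable_dataset.molecule_ids)
        assert "RI_plain" in frame.columns and "RI_TN1" in frame.columns
        assert "molecules: 8" in res.summary()


class TestCmodiAndDetection:
    def test_worked_example(self):
        per_class, overall = cmodi(
            [-0.5, 0.2, -0.1, SENTINEL], np.array([0, 0, 1, 1])
        )
        assert per_class[0] == 0.5 and per_class[1] == 1.0
        assert overall == 0.75

    @pytest.mark.parametrize(
        "ris,expected", [([-0.1, -0.9, -0.5, -1.0], 1.0), ([0.1, 0.9, 0.5, 1.0], 0.0)]
    )
    def test_extremes(self, ris, expected):
        _, overall = cmodi(ris, np.array([0, 0, 1, 1]))
        assert overall == expected

    def test_unweighted_class_mean(self):
        # imbalanced classes: CMODI is the plain mean of per-class fractions
        ris = [-1, -1, -1, 0.5, -1, 0.5]
        labels = np.array([0, 0, 0, 0, 1, 1])
        per_class, overall = cmodi(ris, labels)
        assert per_class[0] == 0.75 and per_class[1] == 0.5
        assert overall == pytest.approx(0.625)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cmodi([-0.5], np.array([0, 1]))

    def test_detect_cliffs_strict_positive(self):
        idx = detect_cliffs([-0.9, 0.01, 0.8, 0.0])
        assert list(idx) == [1, 2]

    def test_detect_borders_and_sentinel_exclusion(self):
        ris = [-0.005, 0.5, 0.002, SENTINEL]
        sent = [False, False, False, True]
        assert list(detect_borders(ris, 0.01, sent)) == [0, 2]
        assert list(detect_borders(ris, 1.5, sent)) == [0, 1, 2]
        with pytest.raises(ValueError):
            detect_borders(ris, 0.0)

    def test_cliff_iff_diffclass_intrusion(self, rng):
        """RI <= 0 at TN-free index <=> no different-class molecule precedes
        the first same-class neighbor (tie cases allowed either way)."""
        for _ in range(20):
            ds = random_dataset(rng)
            m = build_distance_model(ds)
            ri, _ = rivality_profile(m, ds.labels, (0,))
            for i in range(ds.n_molecules):
                count = diffclass_before_nth(m, ds.labels, i, 1, 1).diffclass_count
                if count == 0:
                    assert ri[i, 0] <= 0
                else:
                    assert ri[i, 0] >= 0
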