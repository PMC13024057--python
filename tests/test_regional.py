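"""Regional saliency indices: consensus, thresholds, ASI/SSI."""

import numpy as np
import pandas as pd
import pytest

from cephgrowth import phantom as ph
from cephgrowth import regional
from cephgrowth.saliency import SaliencyMap


class TestConsensusMask:
    def test_identical_masks_pass_through(self, rng):
        m = rng.random((16, 16)) > 0.5
        assert np.array_equal(regional.consensus_mask(np.stack([m, m, m])), m)

    def test_majority_of_three(self):
        masks = np.zeros((3, 4, 4), bool)
        masks[0, 1, 1] = masks[1, 1, 1] = True   # covered by 2 of 3
        masks[2, 2, 2] = True                     # covered by 1 of 3
        out = regional.consensus_mask(masks)
        assert out[1, 1] and not out[2, 2]

    def test_tie_included_at_half(self):
        masks = np.zeros((2, 2, 2), bool)
        masks[0, 0, 0] = True
        assert regional.consensus_mask(masks)[0, 0]

    def test_sandwiched_between_intersection_and_union(self, rng):
        masks = rng.random((7, 12, 12)) > 0.4
        cons = regional.consensus_mask(masks)
        inter = masks.all(axis=0)
        union = masks.any(axis=0)
        assert (inter <= cons).all() and (cons <= union).all()


class TestGroupThreshold:
    def test_constant_pool_returns_constant(self):
        thr = regional.group_threshold([np.full((8, 8), 3.0)] * 3)
        assert thr.t == 3.0

    def test_linear_interpolation_definition(self):
        pool = np.arange(1.0, 101.0).reshape(10, 10)
        thr = regional.group_threshold([pool], q=75.0)
        # closest-ranks linear interpolation on {1..100}
        assert thr.t == pytest.approx(np.percentile(np.arange(1, 101), 75))
        assert thr.t == pytest.approx(75.25)

    def test_default_quantile_is_75(self):
        thr = regional.group_threshold([np.zeros((4, 4))])
        assert thr.quantile == 75.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            regional.group_threshold([])


class TestRegionMeanIndex:
    def test_constant_map_above_threshold(self):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        value, n_s = regional.region_mean_index(np.full((8, 8), 2.0), mask, 1.5)
        assert value == 2.0 and n_s == 9

    def test_all_subthreshold_gives_zero(self):
        mask = np.ones((4, 4), bool)
        value, n_s = regional.region_mean_index(np.full((4, 4), 0.1), mask, 0.5)
        assert value == 0.0 and n_s == 0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            smap = rng.random((16, 16))
            mask = rng.random((16, 16)) > 0.6
            if not mask.any():
                mask[0, 0] = True
            t = float(rng.random())
            value, n_s = regional.region_mean_index(smap, mask, t)
            vals = [smap[i, j] for i in range(16) for j in range(16)
                    if mask[i, j] and smap[i, j] >= t]
            assert n_s == len(vals)
            expect = sum(vals) / len(vals) if vals else 0.0
            assert value == pytest.approx(expect, abs=1e-12)

    def test_boundary_pixel_counts_as_supra(self):
        mask = np.ones((2, 2), bool)
        smap = np.array([[0.5, 0.4], [0.6, 0.3]])
        value, n_s = regional.region_mean_index(smap, mask, 0.5)
        assert n_s == 2 and value == pytest.approx(0.55)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            regional.region_mean_index(np.ones((4, 4)), np.zeros((4, 4), bool),
                                       0.5)

    def test_raising_threshold_shrinks_support(self, rng):
        smap = rng.random((16, 16))
        mask = rng.random((16, 16)) > 0.5
        counts = [regional.region_mean_index(smap, mask, t)[1]
                  for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEnsembleIndex:
    def test_identical_masks_equal_single(self, rng):
        smap = rng.random((8, 8))
        mask = rng.random((8, 8)) > 0.5
        single, _ = regional.region_mean_index(smap, mask, 0.4)
        ens, _ = regional.ensemble_index(smap, np.stack([mask] * 4), 0.4)
        assert ens == pytest.approx(single, abs=1e-12)

    def test_two_masks_average(self, rng):
        smap = rng.random((8, 8))
        m1 = np.zeros((8, 8), bool)
        m1[:4] = True
        m2 = np.zeros((8, 8), bool)
        m2[4:] = True
        v1, _ = regional.region_mean_index(smap, m1, 0.2)
        v2, _ = regional.region_mean_index(smap, m2, 0.2)
        ens, _ = regional.ensemble_index(smap, np.stack([m1, m2]), 0.2)
        assert ens == pytest.approx((v1 + v2) / 2, abs=1e-12)


def _map(arr, sid="s", task="age"):
    arr = np.asarray(arr, dtype=np.float32)
    return SaliencyMap(sid, task, None, arr, arr, image_rect=arr)


class TestIndexTable:
    def _maskset(self, rng, shape=(16, 16), k=3):
        annot = {}
        for name in regional.REGION_ORDER:
            masks = rng.random((k,) + shape) > 0.7
            masks[:, 0, 0] = True  # never empty
            annot[name] = masks
        return ph.RegionMaskSet(group_key=None, truth={}, annotators=annot)

    def test_single_subject_group_equals_ensemble_value(self, rng):
        smap = rng.random((16, 16)).astype(np.float32)
        ms = self._maskset(rng)
        tab = regional.index_table({(9, "male"): [_map(smap)]},
                                   {(9, "male"): ms}, kind="ASI")
        t = float(np.percentile(smap, 75))
        for region in regional.REGION_ORDER:
            expect, _ = regional.ensemble_index(smap, ms.annotators[region], t)
            got = tab[(tab.region == region)].value.iloc[0]
            assert got == pytest.approx(expect, abs=1e-9)

    def test_all_zero_maps_give_zero_indices(self, rng):
        ms = self._maskset(rng)
        tab = regional.index_table(
            {(9, "male"): [_map(np.zeros((16, 16)))] * 3}, {(9, "male"): ms},
            kind="ASI")
        # threshold is 0 and every pixel equals it, so the index is the
        # mean of zeros
        assert (tab.value == 0).all()

    def test_three_subject_group_matches_bruteforce(self, rng):
        maps = [rng.random((16, 16)).astype(np.float32) for _ in range(3)]
        ms = self._maskset(rng)
        tab = regional.index_table({(7, "female"): [_map(m) for m in maps]},
                                   {(7, "female"): ms}, kind="ASI")
        pool = np.concatenate([m.ravel() for m in maps])
        t = float(np.percentile(pool, 75))
        for region in regional.REGION_ORDER:
            vals = []
            for m in maps:
                per_mask = []
                for am in ms.annotators[region]:
                    sel = m[am][m[am] >= t]
                    per_mask.append(sel.mean() if sel.size else 0.0)
                vals.append(np.mean(per_mask))
            got = tab[tab.region == region].value.iloc[0]
            # float32 maps: agreement to the float-pipeline tolerance
            assert got == pytest.approx(np.mean(vals), abs=1e-6)

    def test_asi_and_ssi_share_the_code_path(self, rng):
        maps = [_map(rng.random((16, 16))) for _ in range(2)]
        ms = self._maskset(rng)
        a = regional.index_table({(9, "male"): maps}, {(9, "male"): ms},
                                 kind="ASI")
        s = regional.index_table({(9, "male"): maps}, {(9, "male"): ms},
                                 kind="SSI")
        assert (a.value.to_numpy() == s.value.to_numpy()).all()
        assert (a.N_s.to_numpy() == s.N_s.to_numpy()).all()

    def test_scale_equivariance(self, rng):
        maps = [rng.random((16, 16)).astype(np.float64) for _ in range(3)]
        ms = self._maskset(rng)
        t1 = regional.index_table({(5, "male"): [_map(m) for m in maps]},
                                  {(5, "male"): ms}, kind="ASI")
        c = 3.7
        t2 = regional.index_table(
            {(5, "male"): [_map(m * c) for m in maps]}, {(5, "male"): ms},
            kind="ASI")
        assert np.allclose(t2.value.to_numpy(), c * t1.value.to_numpy(),
                           rtol=1e-6)

    def test_zero_jitter_ensemble_equals_truth_mask_value(self, quiet_spec,
                                                          rng):
        truth = ph.region_masks(quiet_spec, 10.0, "male")
        annot = ph.simulate_annotations(
            truth, k=5, jitter=ph.AnnotatorJitter(0, 0, 0, 0), seed=0)
        smap = rng.random((128, 128))
        t = float(np.percentile(smap, 75))
        for name in truth:
            single, _ = regional.region_mean_index(smap, truth[name], t)
            ens, _ = regional.ensemble_index(smap, annot[name], t)
            assert ens == pytest.approx(single, abs=1e-12)

    def test_table_columns_and_grid(self, rng):
        ms = self._maskset(rng)
        groups = {(a, s): [_map(rng.random((16, 16)))]
                  for a in (4, 5) for s in ("male", "female")}
        tab = regional.index_table(groups, {k: ms for k in groups}, kind="SSI")
        assert set(tab.columns) == {"kind", "sex", "age", "region", "value",
                                    "N_s", "n_subjects", "t"}
        assert len(tab) == 2 * 2 * 6
        assert (tab.kind == "SSI").all()
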