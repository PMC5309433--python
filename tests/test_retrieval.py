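"""Candidate enumeration, selection stages, and pipeline consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlacir import (
    FeatureVector,
    RetrievalConfig,
    area_select,
    build_tables,
    count_candidates,
    enumerate_candidates,
    extract_features,
    image_select,
    retrieve,
    similarity,
)
from hlacir.hlac import autocorrelation_stack
from hlacir.integral import FeatureIndex
from hlacir.region import Region


def _fv(values, n=100):
    return FeatureVector(values=np.asarray(values, dtype=float), normalized=True, n=n)


class TestSimilarity:
    def test_identity_is_zero(self):
        u = _fv([1.0, 2.0, 3.0])
        assert similarity(u, u) == 0.0

    def test_3_4_5_triangle(self):
        assert similarity(_fv([0.0, 0.0]), _fv([3.0, 4.0])) == 5.0

    def test_symmetry_and_component_selection(self, rng):
        u = _fv(rng.normal(size=25))
        v = _fv(rng.normal(size=25))
        assert similarity(u, v) == similarity(v, u)
        comps = np.array([1, 2, 3, 4])
        expected = float(np.linalg.norm(u.values[comps] - v.values[comps]))
        assert similarity(u, v, comps) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity(_fv([1.0]), _fv([1.0, 2.0]))


class TestEnumerateCandidates:
    def test_exact_size_grid_single_position(self):
        cfg = RetrievalConfig(scale_range_pct=0, position_stride_px=10)
        cands = enumerate_candidates(10, 10, 4, 4, cfg)
        assert len(cands) == 1
        assert tuple(cands[0]) == (0, 0, 4, 4)

    def test_exact_size_dense_grid_closed_form(self):
        cfg = RetrievalConfig(scale_range_pct=0, position_stride_px=1)
        assert count_candidates(10, 10, 4, 4, cfg) == 49  # (10-4+1)^2

    def test_no_fitting_size_returns_empty(self):
        cfg = RetrievalConfig(scale_range_pct=0, position_stride_px=1)
        assert len(enumerate_candidates(5, 5, 9, 9, cfg)) == 0

    def test_aspect_ratio_preserved_for_nonsquare_query(self):
        cfg = RetrievalConfig(scale_range_pct=10, position_stride_px=10)
        cands = enumerate_candidates(200, 200, 100, 50, cfg)
        ratios = cands[:, 3] / cands[:, 2]
        assert (np.abs(ratios - 0.5) < 0.05).all()
        assert cands[:, 2].min() == 90 and cands[:, 2].max() == 110

    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(20, 120),
        st.integers(20, 120),
        st.integers(5, 60),
        st.integers(5, 60),
        st.integers(1, 15),
    )
    def test_closed_form_count_matches_list_length(self, tw, th, qw, qh, stride):
        cfg = RetrievalConfig(position_stride_px=stride)
        assert count_candidates(tw, th, qw, qh, cfg) == len(
            enumerate_candidates(tw, th, qw, qh, cfg)
        )

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            RetrievalConfig(position_stride_px=0)


@pytest.fixture()
def small_entry(maskset25, rng):
    img = rng.integers(0, 256, (40, 40), dtype=np.uint8)
    return img, build_tables(img, maskset25, image_id="t")


class TestAreaSelect:
    def test_self_match_survives(self, maskset25, small_entry):
        img, entry = small_entry
        region = Region(10, 10, 8, 8)
        qf0 = extract_features(img, maskset25, region).values[0]
        cands = enumerate_candidates(40, 40, 8, 8, RetrievalConfig(scale_range_pct=0, position_stride_px=1))
        cfg = RetrievalConfig(area_sim_threshold=1e-9, area_rank_fraction=1.0)
        surv = area_select(entry, qf0, cands, cfg)
        assert any(tuple(c) == (10, 10, 8, 8) for c in surv)

    def test_zero_threshold_gives_empty(self, small_entry):
        _, entry = small_entry
        cands = enumerate_candidates(40, 40, 8, 8, RetrievalConfig(position_stride_px=5))
        cfg = RetrievalConfig(area_sim_threshold=0.0)
        assert len(area_select(entry, 100.0, cands, cfg)) == 0

    def test_disabled_filters_keep_everything(self, small_entry):
        _, entry = small_entry
        cands = enumerate_candidates(40, 40, 8, 8, RetrievalConfig(position_stride_px=5))
        cfg = RetrievalConfig(area_sim_threshold=np.inf, area_rank_fraction=1.0)
        assert len(area_select(entry, 100.0, cands, cfg)) == len(cands)

    def test_rank_fraction_bounds_survivors(self, small_entry):
        _, entry = small_entry
        cands = enumerate_candidates(
            40, 40, 8, 8, RetrievalConfig(scale_range_pct=0, position_stride_px=1)
        )
        cfg = RetrievalConfig(area_sim_threshold=np.inf, area_rank_fraction=0.10)
        surv = area_select(entry, 100.0, cands, cfg)
        # at least the 10% rank cut survives; ties at the cutoff may add a few
        assert 0 < len(surv) <= 0.2 * len(cands)


def _exhaustive_cfg(**kw):
    return RetrievalConfig(
        area_sim_threshold=np.inf,
        area_rank_fraction=1.0,
        stage0_threshold=np.inf,
        stage1_threshold=np.inf,
        **kw,
    )


class TestImageSelect:
    def _index_and_query(self, maskset25, rng, n_images=3, size=40):
        index = FeatureIndex(mask_variant="center_no_repeat")
        imgs = {}
        for i in range(n_images):
            img = rng.integers(0, 256, (size, size), dtype=np.uint8)
            iid = f"img{i}"
            imgs[iid] = img
            index.add(build_tables(img, maskset25, image_id=iid))
        region = Region(12, 9, 10, 10)
        qf = extract_features(imgs["img1"], maskset25, region)
        return index, imgs, region, qf

    def test_verbatim_query_retrieves_source_at_zero_distance(self, maskset25, rng):
        index, imgs, region, qf = self._index_and_query(maskset25, rng)
        cfg = _exhaustive_cfg(position_stride_px=1, scale_range_pct=0)
        result = retrieve(index, qf, (region.w, region.h), cfg)
        top = result.ranking[0]
        assert top.image_id == "img1"
        assert top.distance == 0.0
        assert top.region == region

    def test_zero_stage0_threshold_empties_result(self, maskset25, rng):
        index, _, region, qf = self._index_and_query(maskset25, rng)
        cfg = RetrievalConfig(stage0_threshold=0.0, position_stride_px=7)
        result = retrieve(index, qf, (region.w, region.h), cfg)
        assert result.ranking == []
        stages = dict((s, (i, c)) for s, i, c in result.stage_counts)
        assert stages["image_selection_order0"] == (0, 0)

    def test_survivor_counts_non_increasing(self, maskset25, rng):
        index, _, region, qf = self._index_and_query(maskset25, rng)
        result = retrieve(index, qf, (region.w, region.h), RetrievalConfig(position_stride_px=3))
        cands = [c for _, _, c in result.stage_counts]
        images = [i for _, i, c in result.stage_counts]
        assert all(a >= b for a, b in zip(cands, cands[1:]))
        assert all(a >= b for a, b in zip(images, images[1:]))

    def test_pipeline_matches_exhaustive_argmin(self, maskset25, rng):
        """With filters disabled, top-1 equals the brute-force full-vector argmin."""
        index, imgs, _, _ = self._index_and_query(maskset25, rng, n_images=2, size=60)
        query_img = rng.integers(0, 256, (60, 60), dtype=np.uint8)
        qreg = Region(20, 25, 18, 18)
        qf = extract_features(query_img, maskset25, qreg)
        cfg = _exhaustive_cfg(position_stride_px=4)
        result = retrieve(index, qf, (qreg.w, qreg.h), cfg)

        best = None
        for iid in sorted(imgs):
            stack = autocorrelation_stack(imgs[iid], maskset25)
            for x, y, w, h in enumerate_candidates(60, 60, qreg.w, qreg.h, cfg):
                raw = stack[:, y : y + h, x : x + w].sum(axis=(1, 2))
                d = float(np.linalg.norm(raw / (w * h) - qf.values))
                key = (d, iid, y, x, w, h)
                if best is None or key < best:
                    best = key
        top = result.ranking[0]
        assert (top.image_id, top.region.as_tuple()) == (
            best[1],
            (best[3], best[2], best[4], best[5]),
        )
        assert top.distance == pytest.approx(best[0])

    def test_deterministic_output_for_fixed_inputs(self, maskset25, rng):
        index, _, region, qf = self._index_and_query(maskset25, rng)
        cfg = RetrievalConfig(position_stride_px=3)
        r1 = retrieve(index, qf, (region.w, region.h), cfg)
        r2 = retrieve(index, qf, (region.w, region.h), cfg)
        assert r1.ranking == r2.ranking
        assert r1.stage_counts == r2.stage_counts
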