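import hashlib
import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from epiqc.artifact_checks import WarnLevel
from epiqc.data_io import ReviewDict, read_review
from epiqc.quality_maps import StatVolume
from epiqc.report import (
    QCBlock,
    RatingStore,
    alpha_opacity,
    build_report,
    montage_slice_indices,
    percentile_range,
    ratings_io,
    render_montage,
    two_sided_t_threshold,
)


class TestPercentileRange:
    def test_constant_volume(self):
        vol = np.full((4, 4, 4), -7.5)
        out = percentile_range(vol, np.ones((4, 4, 4), bool))
        assert out["thr"] == out["vmax"] == 7.5

    def test_matches_sort_oracle(self, rng):
        vals = rng.permutation(np.arange(1.0, 101.0)).reshape(10, 10, 1)
        out = percentile_range(vals, np.ones((10, 10, 1), bool))
        srt = np.sort(np.abs(vals).ravel())
        # linear-interpolation percentiles
        def pct(p):
            pos = p / 100 * (len(srt) - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
        assert out["thr"] == pytest.approx(pct(90))
        assert out["vmax"] == pytest.approx(pct(99))

    def test_all_zero_flagged_degenerate(self):
        out = percentile_range(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool))
        assert out["thr"] == out["vmax"] == 0.0
        assert out["degenerate"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            percentile_range(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestAlphaOpacity:
    @pytest.mark.parametrize(
        "v,expected", [(2.0, 1.0), (1.0, 0.25), (0.0, 0.0), (-2.0, 1.0), (3.0, 1.0)]
    )
    def test_quadratic_rule(self, v, expected):
        assert alpha_opacity(v, thr=2.0) == pytest.approx(expected)

    def test_vectorized(self):
        out = alpha_opacity(np.array([0.0, 1.0, 2.0, 4.0]), thr=2.0)
        np.testing.assert_allclose(out, [0.0, 0.25, 1.0, 1.0])

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            alpha_opacity(1.0, thr=0.0)


class TestTThreshold:
    def test_large_df_approaches_normal_limit(self):
        assert two_sided_t_threshold(10**7, 0.001) == pytest.approx(3.2905, abs=1e-3)

    @pytest.mark.parametrize("df", [1, 5, 10, 50])
    def test_defining_identity(self, df):
        thr = two_sided_t_threshold(df, 0.001)
        mass = stats.t.cdf(thr, df) - stats.t.cdf(-thr, df)
        assert mass == pytest.approx(1 - 0.001, abs=1e-10)

    def test_df10_matches_independent_quantile_oracle(self):
        # invert the CDF identity numerically through scipy.special.stdtr
        p = 0.001
        want = optimize.brentq(
            lambda t: (special.stdtr(10, t) - special.stdtr(10, -t)) - (1 - p),
            0.1, 100.0, xtol=1e-12,
        )
        assert two_sided_t_threshold(10, p) == pytest.approx(want, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sided_t_threshold(0, 0.001)
        with pytest.raises(ValueError):
            two_sided_t_threshold(10, 1.5)


class TestMontage:
    def _ball(self):
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, 18)] * 3, indexing="ij")
        vol = np.zeros((18, 18, 18))
        vol[(x**2 + y**2 + (z * 3) ** 2) < 0.5] = 100.0  # central third in z
        return vol

    def test_slices_intersect_automask(self):
        vol = self._ball()
        idx = montage_slice_indices(vol, plane="axial", n_slices=5)
        occupied = np.flatnonzero(vol.any(axis=(0, 1)))
        assert all(occupied[0] <= k <= occupied[-1] for k in idx)

    def test_single_slice_is_midpoint(self):
        vol = self._ball()
        occupied = np.flatnonzero(vol.any(axis=(0, 1)))
        idx = montage_slice_indices(vol, plane="axial", n_slices=1)
        assert idx == [int(round((occupied[0] + occupied[-1]) / 2))]

    def test_empty_automask_full_range_fallback(self):
        idx = montage_slice_indices(np.zeros((6, 6, 6)), "axial", 2)
        assert idx == [0, 5]

    def test_renders_underlay_and_overlay(self, tmp_path, rng):
        vol = self._ball()
        overlay = StatVolume(rng.normal(size=vol.shape), kind="corr")
        meta = render_montage(
            vol, overlay=overlay, path=tmp_path / "m.png", n_slices=3
        )
        assert Path(meta["path"]).exists()
        assert len(meta["slices"]) == 3


class TestRatings:
    def test_comment_on_unrated_block_applies_other(self):
        store = RatingStore(["vorig", "mot"])
        store.set_comment("mot", "check slice 12")
        assert store.get("mot") == {"rating": "?", "comment": "check slice 12"}

    def test_clear_resets_both(self):
        store = RatingStore(["mot"])
        store.set_rating("mot", "+")
        store.set_comment("mot", "fine")
        store.clear("mot")
        assert store.get("mot") == {"rating": "", "comment": ""}

    def test_cycle_order(self):
        store = RatingStore(["mot"])
        seen = []
        for _ in range(4):
            store.set_rating("mot", cycle=True)
            seen.append(store.get("mot")["rating"])
        assert seen == ["+", "x", "?", "+"]

    def test_save_load_round_trip(self, tmp_path):
        store = RatingStore(["vorig", "mot"])
        store.set_rating("vorig", "+")
        store.set_comment("mot", "odd stripe")
        store.set_rating("FINAL", "x")
        path = tmp_path / "r.json"
        ratings_io(store, "save", path=path)
        back = ratings_io(None, "load", path=path)
        assert back.to_dict() == store.to_dict()

    def test_multiplication_sign_normalized(self, tmp_path):
        path = tmp_path / "r.json"
        path.write_text(json.dumps({"mot": {"rating": "×", "comment": ""},
                                    "FINAL": {"rating": "", "comment": ""}}))
        store = RatingStore.load(path)
        assert store.get("mot")["rating"] == "x"

    def test_unknown_block_rejected(self):
        store = RatingStore(["mot"])
        with pytest.raises(KeyError):
            store.set_rating("nope", "+")

    @given(
        actions=st.lists(
            st.tuples(
                st.sampled_from(["rate", "comment", "clear", "cycle"]),
                st.sampled_from(["vorig", "mot", "FINAL"]),
                st.sampled_from(["+", "x", "?", ""]),
                st.text(max_size=8),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_comment_implies_rating_after_any_sequence(self, actions):
        store = RatingStore(["vorig", "mot"])
        for kind, block, rating, text in actions:
            if kind == "rate":
                store.set_rating(block, rating)
            elif kind == "comment":
                store.set_comment(block, text)
            elif kind == "cycle":
                store.set_rating(block, cycle=True)
            else:
                store.clear(block)
        for block in store.block_ids:
            entry = store.get(block)
            if entry["comment"]:
                assert entry["rating"] != ""


def _tiny_blocks(tmp_path, rng):
    Path(tmp_path).mkdir(parents=True, exist_ok=True)
    vol = rng.normal(size=(10, 10, 8)) + 50
    img = render_montage(vol, path=tmp_path / "img.png", n_slices=2)
    mot = QCBlock("mot", "mot: motion")
    mot.add_image(img["path"], "series")
    warns = QCBlock("warns", "warns: checks", warn=WarnLevel("severe", "flip"))
    warns.add_text("left-right flip suspected")
    return [mot, warns]


class TestBuildReport:
    def test_qsumm_renders_every_label(self, tmp_path, rng):
        review = ReviewDict({"TSNR average": 191.52, "censor fraction": 0.012397,
                             "AFNI version": "x"})
        out = build_report(_tiny_blocks(tmp_path, rng), review=review,
                          outdir=tmp_path / "QC", subject="s1")
        html = (out / "index.html").read_text()
        for label in review:
            assert label in html

    def test_menu_and_body_blocks_match(self, tmp_path, rng):
        out = build_report(_tiny_blocks(tmp_path, rng), outdir=tmp_path / "QC")
        html = (out / "index.html").read_text()
        import re
        menu = set(re.findall(r'href="#(\w+)"', html))
        body = set(re.findall(r'<section id="(\w+)"', html))
        assert menu == body

    def test_severe_block_styled_in_menu(self, tmp_path, rng):
        out = build_report(_tiny_blocks(tmp_path, rng), outdir=tmp_path / "QC")
        html = (out / "index.html").read_text()
        assert '<a href="#warns" class="warn-severe">' in html

    def test_rebuild_byte_identical(self, tmp_path, rng):
        review = ReviewDict({"TSNR average": 191.52})
        def digest(d):
            h = hashlib.sha256()
            for p in sorted(Path(d).rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()
        b1 = _tiny_blocks(tmp_path / "a", rng)
        out1 = build_report(b1, review=review, outdir=tmp_path / "QC1")
        rng2 = np.random.default_rng(20240611)
        b2 = _tiny_blocks(tmp_path / "b", rng2)
        out2 = build_report(b2, review=review, outdir=tmp_path / "QC2")
        assert digest(out1) == digest(out2)

    def test_review_copy_for_group_tools(self, tmp_path, rng):
        review = ReviewDict({"TSNR average": 191.52})
        out = build_report(_tiny_blocks(tmp_path, rng), review=review,
                          outdir=tmp_path / "QC", subject="s7")
        copy = read_review(out / "extra_info" / "out.ss_review.s7.json")
        assert copy == review

    def test_empty_report_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_report([], outdir=tmp_path / "QC")
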