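"""SeCo procedure: ensembles, thresholding, map assembly, selection."""

from types import SimpleNamespace

import numpy as np
import pytest

import seco
from seco.framework import (
    SeCoConfig,
    SeCoPoint,
    build_seco_map,
    run_ensemble,
    select_solution,
    select_solution_ssq_only,
    select_top_fraction,
)


def _sol(delta_ssq, run_id, wss=0.0, med_cv=None):
    return SimpleNamespace(delta_ssq=delta_ssq, run_id=run_id, wss=wss)


class TestConfig:
    def test_defaults_are_standard_operating_point(self):
        cfg = SeCoConfig(k_range=[2])
        assert cfg.n_total == 500
        assert cfg.fraction_f == 0.10
        assert cfg.n_sample == 50

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_total=1),
            dict(fraction_f=0.0),
            dict(fraction_f=1.5),
            dict(n_total=10, fraction_f=0.1),  # floor = 1 < 2
            dict(k_range=[]),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(n_total=100, fraction_f=0.5, k_range=[2], master_seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SeCoConfig(**base)


class TestEnsemble:
    def test_small_ensemble_reproducible(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        cfg = SeCoConfig(n_total=3, fraction_f=1.0, k_range=[2], master_seed=5)
        sols = run_ensemble(X, 2, cfg)
        assert len(sols) == 3
        assert [s.run_id for s in sols] == [1, 2, 3]
        assert [s.seed for s in sols] == [6, 7, 8]
        again = run_ensemble(X, 2, cfg)
        for a, b in zip(sols, again):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_identical_config_identical_delta_ssq_multiset(self, blob_data):
        X, _ = blob_data
        cfg = SeCoConfig(n_total=10, fraction_f=0.5, k_range=[3], master_seed=2)
        d1 = sorted(s.delta_ssq for s in run_ensemble(X, 3, cfg))
        d2 = sorted(s.delta_ssq for s in run_ensemble(X, 3, cfg))
        assert d1 == d2


class TestTopFraction:
    def test_five_hundred_at_decile_keeps_fifty(self):
        sols = [_sol(float(i), i) for i in range(500)]
        kept = select_top_fraction(sols, 0.10)
        assert len(kept) == 50
        assert kept[0].delta_ssq == 499.0

    def test_fraction_one_keeps_all_sorted(self):
        sols = [_sol(d, i) for i, d in enumerate([3.0, 9.0, 1.0])]
        kept = select_top_fraction(sols, 1.0)
        assert [s.delta_ssq for s in kept] == [9.0, 3.0, 1.0]

    def test_tie_at_cut_prefers_lower_run_index(self):
        sols = [_sol(5.0, 2), _sol(5.0, 1), _sol(9.0, 3), _sol(1.0, 4)]
        kept = select_top_fraction(sols, 0.5)
        assert [s.run_id for s in kept] == [3, 1]

    def test_threshold_correctness(self, blob_data):
        X, _ = blob_data
        cfg = SeCoConfig(n_total=20, fraction_f=0.3, k_range=[4], master_seed=0)
        sols = run_ensemble(X, 4, cfg)
        kept = select_top_fraction(sols, 0.3)
        kept_ids = {s.run_id for s in kept}
        dropped = [s for s in sols if s.run_id not in kept_ids]
        assert min(s.delta_ssq for s in kept) >= max(
            s.delta_ssq for s in dropped
        )

    def test_too_small_retention_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_top_fraction([_sol(1.0, 1)] * 10, 0.1)


class TestSelection:
    def test_single_point(self):
        pts = [SeCoPoint(2, 1, 5.0, 0.9, solution="only")]
        assert select_solution(pts) == "only"

    def test_med_cv_tie_broken_by_delta_ssq(self):
        pts = [
            SeCoPoint(2, 1, 5.0, 0.90, solution="a"),
            SeCoPoint(2, 2, 3.0, 0.99, solution="b"),
            SeCoPoint(2, 3, 4.0, 0.99, solution="c"),
        ]
        assert select_solution(pts) == "c"

    def test_order_invariance(self):
        pts = [
            SeCoPoint(2, 3, 4.0, 0.99, solution="c"),
            SeCoPoint(2, 1, 5.0, 0.90, solution="a"),
            SeCoPoint(2, 2, 3.0, 0.99, solution="b"),
        ]
        assert select_solution(pts) == "c"

    def test_all_med_cv_equal_reduces_to_ssq_selection(self):
        sols = [_sol(5.0, 1), _sol(7.0, 2), _sol(6.0, 3)]
        pts = [SeCoPoint(2, s.run_id, s.delta_ssq, 0.99, solution=s) for s in sols]
        assert select_solution(pts) is select_solution_ssq_only(sols)

    def test_ssq_only_picks_lowest_wss(self):
        sols = [
            SimpleNamespace(delta_ssq=10.0, run_id=1, wss=10.0),
            SimpleNamespace(delta_ssq=13.0, run_id=2, wss=7.0),
            SimpleNamespace(delta_ssq=11.0, run_id=3, wss=9.0),
        ]
        assert select_solution_ssq_only(sols).wss == 7.0


class TestMap:
    def test_clean_blobs_all_concordant(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.2, (30, 2)), rng.normal(8, 0.2, (30, 2))]
        )
        cfg = SeCoConfig(n_total=20, fraction_f=0.5, k_range=[2], master_seed=1)
        m = build_seco_map(X, cfg)
        assert len(m.points[2]) == 10
        assert all(p.med_cv == pytest.approx(1.0) for p in m.points[2])

    def test_map_determinism_end_to_end(self, blob_data):
        X, _ = blob_data
        cfg = SeCoConfig(n_total=12, fraction_f=0.5, k_range=[3, 4], master_seed=9)
        m1, m2 = build_seco_map(X, cfg), build_seco_map(X, cfg)
        assert m1.to_frame().equals(m2.to_frame())
        for k in (3, 4):
            np.testing.assert_array_equal(
                m1.selected()[k].labels, m2.selected()[k].labels
            )

    def test_frame_schema(self, blob_data):
        X, _ = blob_data
        cfg = SeCoConfig(n_total=6, fraction_f=0.5, k_range=[2], master_seed=0)
        frame = build_seco_map(X, cfg).to_frame()
        assert list(frame.columns) == ["k", "run_id", "delta_ssq", "med_cv"]
        assert (frame["med_cv"].between(0, 1)).all()
        assert (frame["delta_ssq"] >= 0).all()


def test_tightening_threshold_does_not_destabilise(spec10):
    """On benchmark-mixture data at k in {8, 9, 10}, tightening the retained
    fraction (0.7 -> 0.3 -> 0.1) does not decrease the minimum med(CV) of
    the retained set, on average over seeds."""
    mins = {0.7: [], 0.3: [], 0.1: []}
    for seed in range(3):
        X, _ = seco.sample_mixture(spec10, 2000, 100 + seed)
        for k in (8, 9, 10):
            cfg = SeCoConfig(
                n_total=60, fraction_f=1.0, k_range=[k],
                master_seed=1000 * seed + k,
            )
            sols = run_ensemble(X, k, cfg)
            for f in mins:
                kept = select_top_fraction(sols, f)
                med = seco.median_pairwise_concordance(kept)
                mins[f].append(med.min())
    means = {f: np.mean(v) for f, v in mins.items()}
    assert means[0.3] >= means[0.7] - 1e-12
    assert means[0.1] >= means[0.3] - 1e-12
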