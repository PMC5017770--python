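"""Estimator tests: rescaling, adaptive node selection, the full loop."""

import numpy as np
import pytest

from radarperm import (
    ComplexPermittivity,
    EstimatorConfig,
    FitnessEvaluator,
    GridSpec,
    PermittivityBox,
    RadarScan,
    adaptive_refine,
    estimate,
    refractive_index,
    rescale,
    select_new_nodes,
    subtract_calibration,
    suppress_skin,
)
from radarperm.io import fixture_phantom, make_fixture_scan
from radarperm.sobol import SobolIndices
from radarperm.sparse_grid import HierarchicalInterpolant, new_nodes_at_level

BOX = PermittivityBox(eps_i_range=(1.0, 10.0), eps_s_range=(2.0, 70.0))


class TestRescale:
    def test_endpoints(self):
        assert rescale(np.array([0.0, 0.0]), BOX) == (1.0, 2.0)
        assert rescale(np.array([1.0, 1.0]), BOX) == (10.0, 70.0)

    def test_midpoint(self):
        assert rescale(np.array([0.5, 0.5]), BOX) == (5.5, 36.0)

    def test_roundtrip_inverse(self):
        rng = np.random.default_rng(0)
        for z in rng.random((20, 2)):
            np.testing.assert_allclose(BOX.inverse(*rescale(z, BOX)), z, atol=1e-12)

    def test_outside_unit_square_rejected(self):
        with pytest.raises(ValueError):
            rescale(np.array([1.2, 0.5]), BOX)


class TestRefractiveIndex:
    @pytest.mark.parametrize(
        "eps_r,eps_i,expected",
        [(4.0, 0.0, 2.0), (1.0, 0.0, 1.0), (3.0, 4.0, 2.0)],
    )
    def test_closed_form(self, eps_r, eps_i, expected):
        assert refractive_index(ComplexPermittivity(eps_r, eps_i)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_losses_raise_the_index(self):
        lossless = refractive_index(ComplexPermittivity(4.0, 0.0))
        lossy = refractive_index(ComplexPermittivity(4.0, 2.0))
        assert lossy > lossless


class TestFitnessEvaluator:
    def test_each_zeta_imaged_once(self, processed_scan, single_phantom):
        ev = FitnessEvaluator(processed_scan, BOX, GridSpec(spacing=2.0),
                              single_phantom)
        z = np.array([0.5, 0.5])
        a = ev(z)
        b = ev(z)
        assert a == b
        assert ev.evaluations == 1
        assert ev.cache_hits == 1

    def test_true_permittivity_fitter_than_far_guess(
        self, processed_scan, single_phantom
    ):
        ev = FitnessEvaluator(processed_scan, BOX, GridSpec(), single_phantom)
        z_true = BOX.inverse(2.5, 25.0)
        z_far = BOX.inverse(9.0, 60.0)
        assert ev(z_true) > ev(z_far)

    def test_zero_scan_scores_zero_everywhere(self, processed_scan, single_phantom):
        zero = RadarScan(
            array=processed_scan.array,
            time_axis=processed_scan.time_axis,
            traces=np.zeros_like(processed_scan.traces),
        )
        ev = FitnessEvaluator(zero, BOX, GridSpec(spacing=2.0), single_phantom)
        for z in np.random.default_rng(0).random((5, 2)):
            assert ev(z) == 0.0


def _interp_for(func, levels=2):
    interp = HierarchicalInterpolant(2)
    for level in range(levels + 1):
        nodes = new_nodes_at_level(2, level)
        interp.add_nodes(nodes, [func(n.zeta) for n in nodes], stage=level)
    return interp


class TestSelectNewNodes:
    def test_converged_interpolant_selects_nothing(self):
        # linear target: surpluses vanish from level 2 and the interpolant
        # is unchanged between stages 1 and 3, so nothing is flagged
        interp = _interp_for(lambda z: z[0] + z[1], levels=3)
        sobol = SobolIndices(np.ones(2), np.ones(2))
        cfg = EstimatorConfig(random_inclusion_prob=0.0)
        out = select_new_nodes(interp, sobol, cfg, np.random.default_rng(0))
        assert out == []

    def test_sobol_steering_hand_trace_of_rules(self):
        # single spike at the node zeta = (0.25, 0.5): only that node is
        # flagged; with indices (1, 0) exactly its two dim-1 children are
        # added, with (1, 1) additionally its two dim-2 children
        spike_key = ((2, 0), (0, 0))
        f = lambda z: 1.0 if (z[0], z[1]) == (0.25, 0.5) else 0.0
        interp = _interp_for(f)
        cfg = EstimatorConfig(random_inclusion_prob=0.0)

        sobol_d1 = SobolIndices(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        out = select_new_nodes(interp, sobol_d1, cfg, np.random.default_rng(0))
        assert {n.key for n in out} == {
            ((3, 0), (0, 0)),
            ((3, 1), (0, 0)),
        }

        sobol_both = SobolIndices(np.ones(2), np.ones(2))
        out = select_new_nodes(interp, sobol_both, cfg, np.random.default_rng(0))
        assert {n.key for n in out} == {
            ((3, 0), (0, 0)),
            ((3, 1), (0, 0)),
            ((2, 0), (1, 0)),
            ((2, 0), (1, 1)),
        }

    def test_fixed_seed_reproducible_selection(self):
        interp = _interp_for(lambda z: np.sin(8 * z[0]) * np.cos(5 * z[1]))
        sobol = SobolIndices(np.ones(2), np.ones(2))
        cfg = EstimatorConfig(random_inclusion_prob=0.5, seed=3)
        pick = lambda: {
            n.key
            for n in select_new_nodes(
                interp, sobol, cfg, np.random.default_rng(cfg.seed)
            )
        }
        assert pick() == pick()


class TestAdaptiveRefine:
    def test_insensitive_dimension_suppressed(self):
        # constant in zeta2: its Sobol' index collapses and no node deepens it
        f = lambda z: float(np.sin(3 * z[0]) + z[0] ** 2)
        interp, term, history = adaptive_refine(
            f, 2, EstimatorConfig(seed=0, max_level=6, random_inclusion_prob=0.0)
        )
        assert history[-1][1] < 0.05
        assert all(n.levels[1] < 3 for n in interp.nodes)

    def test_samples_fewer_nodes_than_full_grid(self):
        f = lambda z: float(np.exp(-8 * ((z[0] - 0.3) ** 2 + (z[1] - 0.7) ** 2)))
        cfg = EstimatorConfig(seed=1, max_level=6)
        interp, _, _ = adaptive_refine(f, 2, cfg)
        assert len(interp) < 321  # full level-6 grid

    def test_final_interpolant_exact_at_sampled_nodes(self):
        f = lambda z: float(np.sin(6 * z[0]) * z[1])
        interp, _, _ = adaptive_refine(f, 2, EstimatorConfig(seed=0, max_level=5))
        for node in interp.nodes:
            assert interp.evaluate(node.zeta) == pytest.approx(node.value, abs=1e-12)


@pytest.fixture(scope="module")
def small_run(processed_scan, single_phantom):
    cfg = EstimatorConfig(seed=0, max_level=5)
    return estimate(processed_scan, BOX, GridSpec(), cfg, single_phantom)


class TestEstimate:
    def test_max_level_two_samples_the_full_13_node_grid(
        self, processed_scan, single_phantom
    ):
        cfg = EstimatorConfig(seed=0, max_level=2)
        res = estimate(processed_scan, BOX, GridSpec(spacing=2.0), cfg,
                       single_phantom)
        assert res.nodes_sampled == 13
        assert res.termination_reason == "max-level"

    def test_same_seed_bit_reproducible(self, processed_scan, single_phantom):
        cfg = EstimatorConfig(seed=5, max_level=4)
        r1 = estimate(processed_scan, BOX, GridSpec(spacing=2.0), cfg,
                      single_phantom)
        r2 = estimate(processed_scan, BOX, GridSpec(spacing=2.0), cfg,
                      single_phantom)
        assert r1.best_permittivities == r2.best_permittivities
        assert r1.nodes_sampled == r2.nodes_sampled
        assert {n.key for n in r1.interpolant.nodes} == {
            n.key for n in r2.interpolant.nodes
        }

    def test_best_fitness_dominates_secondary_maxima(self, small_run):
        for m in small_run.secondary_maxima:
            assert small_run.best_fitness >= m.fitness

    def test_workload_bounded_by_full_grid(self, small_run):
        assert small_run.nodes_sampled <= 145  # full level-5 grid

    def test_best_image_localises_the_scatterer(self, small_run):
        pos = small_run.best_image.argmax_position()
        assert np.linalg.norm(pos - [25.0, 0.0]) <= 5.0

    def test_empty_scan_rejected(self, single_phantom):
        from radarperm import circular_array

        scan = RadarScan(
            array=circular_array(3, 52.0),
            time_axis=np.array([0.0]),
            traces=np.zeros((3, 1)),
        )
        scan.traces = np.zeros((3, 0))
        scan.time_axis = np.zeros(0)
        with pytest.raises(ValueError):
            estimate(scan, BOX, GridSpec(), EstimatorConfig(), single_phantom)
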