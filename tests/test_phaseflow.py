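import numpy as np
import pytest

from statekinetics import phaseflow
from statekinetics.containers import EmbeddingState, VelocityField
from statekinetics.phaseflow import PhaseSimConfig


def field_with(velocity_embed, d=2):
    return VelocityField(
        gamma_hat=np.zeros(d),
        velocity_gene=np.asarray(velocity_embed, dtype=float),
        gene_ids=[f"axis_{i}" for i in range(d)],
        velocity_embed=np.asarray(velocity_embed, dtype=float),
    )


class TestPseudotimeMap:
    def test_k1_exact_at_reference(self, line_embedding):
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=1)
        q = line_embedding.coordinates[37:38]
        assert pm.predict(q)[0] == pytest.approx(line_embedding.pseudotime[37])

    def test_k2_equidistant_average(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0]])
        pm = phaseflow.PseudotimeMap(coords, np.array([0.0, 1.0]), k=2)
        assert pm.predict([[1.0, 0.0]])[0] == pytest.approx(0.5)

    def test_linear_truth_r2(self):
        """kNN-R on a linear pseudotime truth reaches r^2 >= 0.96 on
        held-out noiseless queries."""
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, (200, 2))
        pt = 3.0 * coords[:, 0]
        pm = phaseflow.PseudotimeMap(coords, pt, k=5)
        q = rng.uniform(1, 9, (100, 2))
        pred = pm.predict(q)
        truth = 3.0 * q[:, 0]
        ss_res = ((pred - truth) ** 2).sum()
        ss_tot = ((truth - truth.mean()) ** 2).sum()
        assert 1.0 - ss_res / ss_tot >= 0.96

    def test_k_exceeds_reference_rejected(self):
        with pytest.raises(ValueError, match="k must lie"):
            phaseflow.PseudotimeMap(np.zeros((3, 2)), np.zeros(3), k=4)

    def test_predictions_bounded_by_reference_range(self, line_embedding):
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=5)
        far = np.array([[1e6, 1e6], [-1e6, -1e6]])
        pred = pm.predict(far)
        lo, hi = line_embedding.pseudotime.min(), line_embedding.pseudotime.max()
        assert ((pred >= lo) & (pred <= hi)).all()


class TestDeltaPseudotime:
    def test_zero_velocity_zero_delta(self, line_embedding):
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=1)
        field = field_with(np.zeros((line_embedding.n_cells, 2)))
        dp = phaseflow.delta_pseudotime(line_embedding, field, pm)
        np.testing.assert_allclose(dp, 0.0, atol=1e-12)

    def test_aligned_velocity_positive_interior(self, line_embedding):
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=5)
        v = np.tile([0.3, 0.0], (line_embedding.n_cells, 1))
        dp = phaseflow.delta_pseudotime(line_embedding, field_with(v), pm)
        x = line_embedding.coordinates[:, 0]
        interior = (x > 1.0) & (x < 9.0)
        assert (dp[interior] > 0).all()

    def test_anti_aligned_velocity_negative_interior(self, line_embedding):
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=5)
        v = np.tile([-0.3, 0.0], (line_embedding.n_cells, 1))
        dp = phaseflow.delta_pseudotime(line_embedding, field_with(v), pm)
        x = line_embedding.coordinates[:, 0]
        interior = (x > 1.0) & (x < 9.0)
        assert (dp[interior] < 0).all()


class TestLineageRegression:
    def test_worked_example(self):
        """dp = {-2, 0, 2}: sd = 2, threshold -1, one regressing cell."""
        out = phaseflow.classify_lineage_regression(np.array([-2.0, 0.0, 2.0]))
        assert out["sigma"] == pytest.approx(2.0)
        assert out["threshold"] == pytest.approx(-1.0)
        np.testing.assert_array_equal(out["mask"], [True, False, False])
        assert out["fraction"] == pytest.approx(1.0 / 3.0)

    def test_all_positive_no_regression(self):
        out = phaseflow.classify_lineage_regression(np.array([0.5, 1.0, 2.0, 3.0]))
        assert out["fraction"] == 0.0

    def test_symmetric_two_point_law(self):
        """dp = +/-x equally: every -x value lies below -0.5 sigma, so
        the regressing fraction converges to 0.5."""
        dp = np.tile([1.0, -1.0], 5000)
        out = phaseflow.classify_lineage_regression(dp)
        assert out["fraction"] == pytest.approx(0.5, abs=1e-12)

    def test_constant_delta_warns_zero(self):
        with pytest.warns(UserWarning, match="sigma=0"):
            out = phaseflow.classify_lineage_regression(np.ones(5))
        assert out["fraction"] == 0.0

    def test_affine_invariance_of_fraction(self):
        rng = np.random.default_rng(1)
        dp = rng.normal(0.2, 1.5, 500)
        a = phaseflow.classify_lineage_regression(dp)
        b = phaseflow.classify_lineage_regression(dp * 7.3)
        np.testing.assert_array_equal(a["mask"], b["mask"])

    def test_frequency_curve_smoothing(self):
        rng = np.random.default_rng(2)
        dp = rng.normal(0, 1, 1000)
        pt = rng.uniform(0, 10, 1000)
        out = phaseflow.classify_lineage_regression(dp, pseudotime=pt, n_bins=10)
        curve = out["curve"]
        assert len(curve) == 10
        assert np.isfinite(curve["fraction_smooth"]).all()
        assert ((curve["se"].dropna() >= 0)).all()


class TestPhaseSimulation:
    def test_zero_field_constant_trajectories(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(100, 2))
        cfg = PhaseSimConfig(n_points=10, n_steps=50, seed=1, init_region="all")
        res = phaseflow.simulate_phase_points(coords, np.zeros((100, 2)), cfg)
        np.testing.assert_array_equal(res.terminal_positions, res.trajectories[:, 0])

    def test_uniform_field_net_displacement(self):
        """Uniform field (1,0), step 0.01, 100 steps: displacement (1,0)."""
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(200, 2), scale=10.0)
        vel = np.tile([1.0, 0.0], (200, 1))
        cfg = PhaseSimConfig(
            n_points=5, n_steps=100, step_size=0.01, seed=2,
            init_region="all", normalize_velocity=False,
        )
        res = phaseflow.simulate_phase_points(coords, vel, cfg)
        disp = res.terminal_positions - res.trajectories[:, 0]
        np.testing.assert_allclose(disp, np.tile([1.0, 0.0], (5, 1)), atol=1e-10)

    def test_linear_inward_field_contracts(self):
        """v(x) = -x on a dense sample: explicit Euler contracts every
        point toward the origin (terminal radius < 1e-3)."""
        rng = np.random.default_rng(3)
        coords = rng.uniform(-1, 1, (1_000_000, 2))
        cfg = PhaseSimConfig(
            n_points=5, n_steps=1500, step_size=0.01, seed=4,
            init_region="all", normalize_velocity=False,
        )
        res = phaseflow.simulate_phase_points(coords, -coords, cfg)
        radii = np.linalg.norm(res.terminal_positions, axis=1)
        assert (radii < 1e-3).all()

    def test_bit_reproducible_with_seed(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(200, 2))
        vel = rng.normal(size=(200, 2))
        cfg = PhaseSimConfig(n_points=20, n_steps=100, seed=6, init_region="all")
        a = phaseflow.simulate_phase_points(coords, vel, cfg)
        b = phaseflow.simulate_phase_points(coords, vel, cfg)
        np.testing.assert_array_equal(a.trajectories, b.trajectories)

    def test_trajectories_start_at_inits(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(100, 2))
        inits = coords[:7].copy()
        cfg = PhaseSimConfig(n_points=7, n_steps=10, seed=8, init_region="all")
        res = phaseflow.simulate_phase_points(
            coords, rng.normal(size=(100, 2)), cfg, init_positions=inits
        )
        np.testing.assert_array_equal(res.trajectories[:, 0], inits)

    def test_empty_init_region_rejected(self):
        coords = np.zeros((40, 2))
        cfg = PhaseSimConfig(n_points=5, n_steps=5, k_field=5)
        with pytest.raises(ValueError, match="primitive_activated"):
            phaseflow.simulate_phase_points(
                coords, np.zeros((40, 2)), cfg,
                timepoint=np.repeat("quiescent", 40),
            )

    def test_density_grid_counts_all_visits(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(100, 2))
        cfg = PhaseSimConfig(n_points=4, n_steps=25, seed=10, init_region="all")
        res = phaseflow.simulate_phase_points(coords, rng.normal(size=(100, 2)), cfg)
        assert res.density_grid.sum() == 4 * 26


class TestCompareProgression:
    def test_identical_fields_identical_curves(self, line_embedding):
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=3)
        coords = line_embedding.coordinates
        vel = np.tile([0.5, 0.0], (len(coords), 1))
        cfg = PhaseSimConfig(
            n_points=10, n_steps=50, seed=11, init_region="all",
            normalize_velocity=False, step_size=0.05,
        )
        a = phaseflow.simulate_phase_points(coords, vel, cfg)
        b = phaseflow.simulate_phase_points(coords, vel, cfg)
        comp = phaseflow.compare_progression(a, b, pm)
        np.testing.assert_array_equal(comp["delta"], 0.0)
        assert comp["terminal_centroid_distance"] == 0.0

    def test_half_speed_field_lags_then_converges(self, line_embedding):
        """Field B = 0.5 x field A on a 1-D manifold: B's mean inferred
        pseudotime is lower at early matched steps; both flows reach the
        manifold end."""
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=3)
        coords = line_embedding.coordinates
        # forward flow that dies out at the manifold end (x >= 9), so
        # both speeds share the same attracting zero set
        vx = np.clip(9.0 - coords[:, 0], 0.0, 1.0)
        vel = np.column_stack([vx, np.zeros_like(vx)])
        cfg = PhaseSimConfig(
            n_points=10, n_steps=1500, k_field=5, seed=12, init_region="all",
            normalize_velocity=False, step_size=0.05,
        )
        rng = np.random.default_rng(12)
        inits = coords[rng.integers(0, 30, 10)]
        a = phaseflow.simulate_phase_points(coords, vel, cfg, init_positions=inits)
        b = phaseflow.simulate_phase_points(coords, 0.5 * vel, cfg, init_positions=inits)
        comp = phaseflow.compare_progression(a, b, pm)
        assert (comp["delta"][5:50] > 0).all()
        assert comp["terminal_centroid_distance"] < 0.1

    def test_zero_field_flat_curve(self, line_embedding):
        pm = phaseflow.fit_pseudotime_map(line_embedding, k=3)
        coords = line_embedding.coordinates
        cfg = PhaseSimConfig(
            n_points=8, n_steps=30, seed=13, init_region="all",
            normalize_velocity=False,
        )
        rng = np.random.default_rng(13)
        inits = coords[rng.integers(0, len(coords), 8)]
        a = phaseflow.simulate_phase_points(
            coords, np.tile([1.0, 0.0], (len(coords), 1)), cfg, init_positions=inits
        )
        b = phaseflow.simulate_phase_points(
            coords, np.zeros((len(coords), 2)), cfg, init_positions=inits
        )
        comp = phaseflow.compare_progression(a, b, pm)
        assert np.ptp(comp["mean_pseudotime_b"]) == pytest.approx(0.0, abs=1e-12)


class TestVelocityDifference:
    def test_identical_groups_zero(self):
        v = np.tile(np.arange(4.0), (10, 1))
        mask = np.array([True] * 5 + [False] * 5)
        table = phaseflow.velocity_difference_by_direction(v, mask)
        np.testing.assert_allclose(table["velocity_difference"], 0.0)

    def test_signed_gene_ranks_first(self):
        v = np.zeros((6, 3))
        v[:3, 1] = 1.0   # forward cells
        v[3:, 1] = -1.0  # backward cells
        mask = np.array([False] * 3 + [True] * 3)
        table = phaseflow.velocity_difference_by_direction(v, mask, ["a", "b", "c"])
        assert table.iloc[0]["gene_id"] == "b"
        assert table.iloc[0]["velocity_difference"] == pytest.approx(2.0)
        assert table.iloc[0]["rank"] == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(14)
        v = rng.normal(size=(40, 25))
        mask = rng.random(40) < 0.4
        table = phaseflow.velocity_difference_by_direction(v, mask)
        brute = v[~mask].mean(axis=0) - v[mask].mean(axis=0)
        got = table.set_index("gene_id")["velocity_difference"]
        for i in range(25):
            assert got[f"g{i}"] == pytest.approx(brute[i], abs=1e-12)

    def test_empty_direction_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            phaseflow.velocity_difference_by_direction(
                np.ones((3, 2)), np.array([True, True, True])
            )
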