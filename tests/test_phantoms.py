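import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from vesselprox import (
    EmptySegmentError,
    ParameterError,
    PhantomSpec,
    SegmentationParams,
    analytic_enclosed_krogh_fraction,
    analytic_krogh_fraction,
    build_elements,
    generate_phantom,
    largest_connected_component,
    rarefy_network,
    segment_vessels,
    signed_distance_map,
)

from _oracles import monte_carlo_krogh_fraction


class TestAnalyticKroghFraction:
    def test_full_coverage_when_disc_reaches_cell_corner(self):
        # R_v + d >= spacing * sqrt(2)/2
        assert analytic_krogh_fraction(100.0, 10.0, 60.8) == 1.0
        assert analytic_krogh_fraction(100.0, 10.0, 100.0) == 1.0

    def test_disjoint_disc_regime_is_pi_r_squared(self):
        # R_v + d <= spacing/2: plain disc area over cell area
        f = analytic_krogh_fraction(100.0, 10.0, 20.0)
        assert f == pytest.approx(math.pi * 900 / 10000, rel=1e-12)
        assert f == pytest.approx(0.28274, abs=1e-5)

    @pytest.mark.parametrize("d", [20.0, 45.0, 55.0])
    def test_matches_monte_carlo_oracle(self, d):
        """Exact geometry agrees with 10^6-point sampling, including the
        disc-square intersection regime (spacing/2 < R < spacing*sqrt2/2)."""
        f = analytic_krogh_fraction(100.0, 10.0, d)
        mc = monte_carlo_krogh_fraction(100.0, 10.0, d, n_points=10**6, seed=42)
        assert f == pytest.approx(mc, abs=1e-3)

    def test_nondecreasing_in_distance(self):
        ds = np.linspace(1, 80, 40)
        fs = [analytic_krogh_fraction(100.0, 10.0, d) for d in ds]
        assert fs == sorted(fs)
        assert all(0 < f <= 1 for f in fs)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ParameterError):
            analytic_krogh_fraction(15.0, 10.0, 5.0)  # spacing < 2*radius
        with pytest.raises(ParameterError):
            analytic_krogh_fraction(100.0, 10.0, -1.0)


class TestGeneratePhantom:
    def test_same_spec_same_seed_is_bit_identical(self):
        spec = PhantomSpec("random_cylinders", domain_shape_um=(80, 80, 80),
                           voxel_size_um=4.0, vessel_radius_um=6.0,
                           n_cylinders=10, noise_sd=8.0, seed=11)
        v1, t1 = generate_phantom(spec)
        v2, t2 = generate_phantom(spec)
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(t1.vessel.data, t2.vessel.data)

    def test_noiseless_midpoint_threshold_recovers_truth_exactly(self):
        spec = PhantomSpec("krogh_array", domain_shape_um=(60, 200, 200),
                           voxel_size_um=2.0, vessel_radius_um=10.0,
                           spacing_um=100.0, enclosed=True, seed=0)
        vol, truth = generate_phantom(spec)
        mask, _ = segment_vessels(
            vol, SegmentationParams(sigma_px=0.0, threshold=110.0)
        )
        np.testing.assert_array_equal(mask.data, truth.vessel.data)

    def test_krogh_tissue_never_farther_than_cell_corner(self):
        """Spacing 100, R_v 10: max surface distance is 50*sqrt2 - 10 = 60.7 um,
        so the analytic fraction within 100 um is 1."""
        spec = PhantomSpec("krogh_array", domain_shape_um=(40, 200, 200),
                           voxel_size_um=2.0, vessel_radius_um=10.0,
                           spacing_um=100.0, seed=0)
        _, truth = generate_phantom(spec)
        assert truth.analytic_fraction_within[100.0] == 1.0
        d = signed_distance_map(truth.vessel)
        assert d.data.max() <= 50 * math.sqrt(2) - 10 + 2 * math.sqrt(3) + 1e-9

    def test_rasterized_vessel_fraction_converges_to_analytic(self):
        """Lattice volume fraction error roughly halves when the voxel
        size halves."""
        target = math.pi * 100 / 10000
        errs = []
        for voxel in (4.0, 2.0):
            spec = PhantomSpec("krogh_array", domain_shape_um=(40, 200, 200),
                               voxel_size_um=voxel, vessel_radius_um=10.0,
                               spacing_um=100.0, seed=0)
            _, truth = generate_phantom(spec)
            errs.append(abs(truth.vessel_volume_fraction - target))
        assert errs[1] < errs[0]
        assert errs[1] < 0.15 * target

    def test_enclosed_phantom_is_one_connected_component(self):
        spec = PhantomSpec("krogh_array", domain_shape_um=(60, 200, 200),
                           voxel_size_um=2.0, vessel_radius_um=10.0,
                           spacing_um=100.0, enclosed=True, seed=0)
        _, truth = generate_phantom(spec)
        _, n = ndi.label(truth.vessel.data,
                         structure=ndi.generate_binary_structure(3, 3))
        assert n == 1
        out = largest_connected_component(truth.vessel, 26)
        np.testing.assert_array_equal(out.data, truth.vessel.data)

    def test_enclosed_analytic_fraction_matches_fine_grid_estimate(self):
        spec = PhantomSpec("krogh_array", domain_shape_um=(148, 248, 248),
                           voxel_size_um=2.0, vessel_radius_um=10.0,
                           spacing_um=100.0, enclosed=True, wall_um=4.0, seed=0)
        f = analytic_enclosed_krogh_fraction(spec, 20.0)
        # dense continuum estimate on a 1 um point grid
        step = 1.0
        Z, Y, X = spec.domain_shape_um
        z = np.arange(step / 2, Z, step)
        y = np.arange(step / 2, Y, step)
        x = np.arange(step / 2, X, step)
        wall_z = np.minimum(z, Z - z) <= spec.wall_um + 20.0
        wall_y = np.minimum(y, Y - y) <= spec.wall_um + 20.0
        wall_x = np.minimum(x, X - x) <= spec.wall_um + 20.0
        # lateral distance to nearest lattice axis (period 100, origin-aligned)
        ry = np.minimum(y % 100.0, 100.0 - y % 100.0)
        rx = np.minimum(x % 100.0, 100.0 - x % 100.0)
        lat = np.hypot(ry[:, None], rx[None, :]) <= 30.0
        covered_yx = lat | wall_y[:, None] | wall_x[None, :]
        frac = (
            wall_z.mean()
            + (1 - wall_z.mean()) * covered_yx.mean()
        )
        assert f == pytest.approx(frac, abs=2e-3)
        assert analytic_enclosed_krogh_fraction(spec, 100.0) == 1.0

    def test_lattice_coverage_recovered_over_whole_box(self):
        """Smoothing + threshold + signed EDT + CDF over the whole box
        reproduce the pure lattice coverage: 0.28274 at 20 um, 1.0 at 100 um
        (domain an integer number of unit cells, voxel = d/10)."""
        from vesselprox import BinaryVolume, apply_threshold, gaussian_smooth
        from vesselprox.morphometry import proximity_profile

        spec = PhantomSpec("krogh_array", domain_shape_um=(40, 400, 400),
                           voxel_size_um=2.0, vessel_radius_um=10.0,
                           spacing_um=100.0, seed=0)
        vol, truth = generate_phantom(spec)
        mask = apply_threshold(gaussian_smooth(vol, 1.0), 110.0)
        organ = BinaryVolume(np.ones(mask.shape, bool), 2.0, kind="organ")
        prof = proximity_profile(signed_distance_map(mask), organ, [20.0, 100.0])
        assert prof.fraction_within(20.0) == pytest.approx(
            analytic_krogh_fraction(100.0, 10.0, 20.0), abs=0.02
        )
        assert prof.fraction_within(100.0) == 1.0

    def test_branching_tree_generates_nested_radii(self):
        spec = PhantomSpec("branching_tree", domain_shape_um=(200, 200, 200),
                           voxel_size_um=4.0, vessel_radius_um=12.0,
                           branch_levels=3, seed=5)
        elements = build_elements(spec)
        assert len(elements) == 2**4 - 1
        levels = {e.level for e in elements}
        assert levels == {0, 1, 2, 3}
        radii = sorted({e.radius_um for e in elements}, reverse=True)
        assert radii[0] == 12.0 and all(a > b for a, b in zip(radii, radii[1:]))

    def test_infeasible_specs_rejected(self):
        with pytest.raises(ParameterError):
            PhantomSpec("krogh_array", spacing_um=15.0, vessel_radius_um=10.0)
        with pytest.raises(ParameterError):
            PhantomSpec("random_cylinders", voxel_size_um=4.0, vessel_radius_um=2.0)
        with pytest.raises(ParameterError):
            PhantomSpec("not_a_geometry")


class TestRarefaction:
    def _spec(self, **kw):
        kw.setdefault("domain_shape_um", (80, 300, 300))
        kw.setdefault("voxel_size_um", 4.0)
        kw.setdefault("vessel_radius_um", 8.0)
        return PhantomSpec("random_cylinders", n_cylinders=20, **kw)

    def test_zero_removal_is_identity(self):
        spec = self._spec(seed=3)
        assert rarefy_network(spec, 0.0, seed=1) is spec

    def test_full_removal_gives_empty_network_and_downstream_error(self):
        spec = self._spec(seed=3)
        bare = rarefy_network(spec, 1.0, seed=1)
        vol, truth = generate_phantom(bare)
        assert truth.vessel.n_true == 0
        with pytest.raises(EmptySegmentError):
            segment_vessels(vol, SegmentationParams(sigma_px=0.0, threshold=110.0))

    def test_removal_count_is_floor_of_fraction(self):
        spec = self._spec(seed=3)
        out = rarefy_network(spec, 0.3, seed=1)
        assert len(out.removed_elements) == 6  # floor(0.3 * 20)
        assert len(build_elements(out)) == 14

    def test_tree_rarefaction_removes_only_terminal_branches(self):
        spec = PhantomSpec("branching_tree", domain_shape_um=(200, 200, 200),
                           voxel_size_um=4.0, vessel_radius_um=12.0,
                           branch_levels=3, seed=5)
        all_el = build_elements(spec)
        out = rarefy_network(spec, 0.5, seed=2)
        removed = [all_el[i] for i in out.removed_elements]
        assert removed and all(e.level == 3 for e in removed)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ParameterError):
            rarefy_network(self._spec(seed=0), 1.5, seed=1)

    def test_mean_coverage_nonincreasing_with_removal(self):
        """Mean fraction-within-100 um over 20 seeds decreases monotonically
        with the removal fraction (on ground-truth masks)."""
        means = []
        for frac in (0.0, 0.3, 0.6):
            vals = []
            for seed in range(20):
                spec = self._spec(seed=seed)
                spec = rarefy_network(spec, frac, seed=seed + 100)
                _, truth = generate_phantom(spec)
                d = signed_distance_map(truth.vessel)
                vals.append(float(np.mean(d.data <= 100.0)))
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]
        assert means[0] > means[2]
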