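"""Spatial seeding and hierarchical cycle transfer."""

import numpy as np
import pytest

import sixpackholo as sp
from sixpackholo._utils import TWO_PI, round_half_away, wrap_phase

from conftest import shifted_mask


def wrapped_map(phase, wl, **kw):
    return sp.PhaseMap(phase_rad=wrap_phase(phase), wavelength_nm=wl,
                       wrapped=True, **kw)


def unwrapped_map(phase, wl, **kw):
    return sp.PhaseMap(phase_rad=np.asarray(phase, dtype=float),
                       wavelength_nm=wl, wrapped=False, **kw)


class TestStandardUnwrap:
    def test_smooth_ramp_recovered_exactly(self):
        yy = np.linspace(0.0, 6 * np.pi, 128)[:, None] * np.ones((1, 64))
        out = sp.standard_unwrap(wrapped_map(yy, 692.0))
        residual = out.phase_rad - yy
        assert np.ptp(residual) < 1e-6  # constant offset only
        assert np.allclose(residual, TWO_PI * np.round(residual[0, 0] / TWO_PI))

    def test_smooth_map_unchanged_up_to_cycle_constant(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(rng.normal(0, 1, (64, 64)), 8) * 2.0
        out = sp.standard_unwrap(wrapped_map(smooth, 532.0))
        residual = out.phase_rad - smooth
        assert np.ptp(residual) < 1e-9

    def test_hard_3pi_step_not_recovered(self):
        """A discontinuity above 2 pi is information-theoretically lost."""
        truth = np.zeros((64, 64))
        truth[:, 32:] = 3 * np.pi
        out = sp.standard_unwrap(wrapped_map(truth, 490.0))
        err = np.abs(out.phase_rad - truth)
        assert err.max() >= TWO_PI - 1e-9

    def test_offset_referenced_to_background_region(self):
        phase = np.full((32, 32), 0.3)
        mask = np.zeros((32, 32), dtype=bool)
        mask[:8] = True
        out = sp.standard_unwrap(wrapped_map(phase, 692.0), background_mask=mask)
        assert np.allclose(out.phase_rad, 0.3)

    def test_pixelwise_integer_cycle_difference(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter

        phase = gaussian_filter(rng.normal(0, 2, (64, 64)), 4) * 3
        p = wrapped_map(phase, 692.0)
        out = sp.standard_unwrap(p)
        cycles = (out.phase_rad - p.phase_rad) / TWO_PI
        assert np.allclose(cycles, np.round(cycles), atol=1e-9)


class TestHierarchicalStep:
    def test_zero_in_zero_out(self):
        out = sp.hierarchical_step(
            unwrapped_map(np.zeros((8, 8)), 6206.67),
            wrapped_map(np.zeros((8, 8)), 2300.90),
        )
        assert np.allclose(out.phase_rad, 0.0)
        assert not out.wrapped

    def test_worked_channel_example(self):
        """Uniform true OPD -2730 nm transferred from the 6206.67 nm rung
        to the 2300.90 nm rung: one whole negative cycle is added."""
        l_n, l_next, opd = 6206.67, 2300.90, -2730.0
        phi_n = unwrapped_map(np.full((4, 4), TWO_PI * opd / l_n), l_n)
        phi_next = wrapped_map(np.full((4, 4), TWO_PI * opd / l_next), l_next)
        assert phi_n.phase_rad[0, 0] == pytest.approx(-2.7638, abs=3e-4)
        assert phi_next.phase_rad[0, 0] == pytest.approx(-1.1718, abs=1e-3)
        out = sp.hierarchical_step(phi_n, phi_next)
        i_n = (out.phase_rad - wrap_phase(phi_next.phase_rad)) / TWO_PI
        assert np.allclose(i_n, -1.0)
        assert out.phase_rad[0, 0] == pytest.approx(-7.455, abs=1e-3)
        assert out.phase_rad[0, 0] * l_next / TWO_PI == pytest.approx(
            -2730.0, abs=0.5
        )

    def test_half_cycle_ties_round_away_from_zero(self):
        """A residual of exactly half the next wavelength is pushed
        outward, symmetrically for both signs."""
        l_n, l_next = 2000.0, 1000.0
        for sign in (+1.0, -1.0):
            phi_n = unwrapped_map(
                np.full((2, 2), sign * TWO_PI * 1500.0 / l_n), l_n
            )
            phi_next = wrapped_map(np.zeros((2, 2)), l_next)
            out = sp.hierarchical_step(phi_n, phi_next)
            assert np.allclose(out.phase_rad, sign * TWO_PI * 2.0)
        assert round_half_away(0.5) == 1.0 and round_half_away(-0.5) == -1.0

    def test_order_violation_rejected(self):
        with pytest.raises(ValueError, match="not longer"):
            sp.hierarchical_step(
                unwrapped_map(np.zeros((4, 4)), 490.0),
                wrapped_map(np.zeros((4, 4)), 532.0),
            )

    def test_oracle_exhaustive_integer_search(self):
        """The rounded transfer equals brute-force minimization of the OPD
        mismatch over candidate cycle counts, pixel by pixel."""
        rng = np.random.default_rng(42)
        n = 2000
        for _ in range(20):
            wl = np.sort(rng.uniform(250.0, 7000.0, 2))
            l_next, l_n = float(wl[0]), float(wl[1] + 1.0)
            opd_true = rng.uniform(-3 * l_n, 3 * l_n, n)
            noise = rng.normal(0, 0.05 * l_next, n)
            phi_n = unwrapped_map(TWO_PI * (opd_true + noise) / l_n, l_n)
            phi_next = wrapped_map(TWO_PI * opd_true / l_next, l_next)
            out = sp.hierarchical_step(
                sp.PhaseMap(phi_n.phase_rad.reshape(1, -1), l_n, False),
                sp.PhaseMap(phi_next.phase_rad.reshape(1, -1), l_next, True),
            ).phase_rad.ravel()
            f_n = wrap_phase(phi_next.phase_rad) / TWO_PI
            opd_ref = phi_n.phase_rad * l_n / TWO_PI
            ks = np.arange(-50, 51)
            cand = (f_n[:, None] + ks[None, :]) * l_next
            best = ks[np.argmin(np.abs(opd_ref[:, None] - cand), axis=1)]
            oracle = TWO_PI * (best + f_n)
            assert np.allclose(out, oracle)

    def test_wrap_consistency(self):
        """Only whole cycles are added: the output wraps back to the input
        bit-exactly where no cycle was needed, to a few ulp elsewhere."""
        rng = np.random.default_rng(3)
        phi_next = wrapped_map(rng.uniform(-np.pi, np.pi, (32, 32)), 490.0)
        phi_n = unwrapped_map(rng.uniform(-20, 20, (32, 32)), 692.0)
        out = sp.hierarchical_step(phi_n, phi_next)
        cycles = (out.phase_rad - phi_next.phase_rad) / TWO_PI
        assert np.allclose(cycles, np.round(cycles), atol=1e-12)
        residual = wrap_phase(out.phase_rad) - phi_next.phase_rad
        assert np.abs(residual).max() < 1e-12
        zero_cycles = np.round(cycles) == 0
        assert np.array_equal(
            out.phase_rad[zero_cycles], phi_next.phase_rad[zero_cycles]
        )


class TestEstimateNoise:
    def test_constant_region_zero(self):
        assert sp.estimate_noise(np.full((50, 50), 7.0), np.s_[:, :]) == 0.0

    def test_gaussian_sigma_recovered(self):
        rng = np.random.default_rng(9)
        field = rng.normal(0.0, 55.0, (300, 300))
        est = sp.estimate_noise(field, np.s_[50:250, 50:250])
        assert est == pytest.approx(55.0, rel=0.02)

    def test_single_pixel_region_rejected(self):
        with pytest.raises(ValueError):
            sp.estimate_noise(np.zeros((10, 10)), np.s_[0:1, 0:1])


class TestHierarchicalUnwrap:
    def test_noiseless_channel_recovered_through_full_ladder(
        self, channel_phantom, left_stack
    ):
        ladder = sp.PhaseLadder(rungs=left_stack, fov="left")
        result = sp.hierarchical_unwrap(ladder)
        interior = shifted_mask(channel_phantom, "channel_interior", "left")
        mean = result.opd_nm[interior].mean()
        assert mean == pytest.approx(-2730.0, rel=0.01)

    def test_standard_unwrap_of_shortest_rung_fails_on_the_step(
        self, channel_phantom, left_stack
    ):
        """The 2 pi ambiguity: spatial unwrapping of the 490 nm map cannot
        see the ~5.6 missing cycles across the channel step."""
        m490 = [m for m in left_stack if m.wavelength_nm == 490.0][0]
        out = sp.standard_unwrap(
            m490,
            background_mask=shifted_mask(channel_phantom, "background", "left"),
        )
        interior = shifted_mask(channel_phantom, "channel_interior", "left")
        recovered = (out.phase_rad * 490.0 / TWO_PI)[interior].mean()
        assert abs(recovered) < 500.0
        assert abs(recovered - (-2730.0)) > 692.0

    def test_identical_wavelength_rungs_rejected(self):
        maps = [wrapped_map(np.zeros((8, 8)), 692.0) for _ in range(2)]
        with pytest.raises(ValueError, match="descending"):
            sp.PhaseLadder(rungs=maps, fov="left")

    def test_advisory_flag_when_noise_exceeds_half_wavelength(self):
        rng = np.random.default_rng(5)
        shape = (64, 64)
        # 6206.67 nm rung carrying ~400 nm OPD noise, next rung 692 nm:
        # 400 > 692/2, so the transition must be flagged.
        sigma_rad = 400.0 * TWO_PI / 6206.67
        maps = [
            wrapped_map(rng.normal(0, sigma_rad, shape), 6206.67),
            wrapped_map(np.zeros(shape), 692.0),
        ]
        result = sp.hierarchical_unwrap(
            sp.PhaseLadder(rungs=maps, fov="left"),
            noise_region=np.s_[8:56, 8:56],
        )
        assert result.flags
        assert "692" in result.flags[0]

    def test_wrap_consistency_at_every_rung(self, left_stack):
        """Each hierarchical rung differs from its wrapped input by whole
        cycles only (bit-exact where the cycle count is zero)."""
        ladder = sp.PhaseLadder(rungs=left_stack, fov="left")
        result = sp.hierarchical_unwrap(ladder)
        for rung, wrapped in zip(result.unwrapped[1:], left_stack[1:]):
            cycles = (rung.phase_rad - wrapped.phase_rad) / TWO_PI
            assert np.allclose(cycles, np.round(cycles), atol=1e-12)
            zero = np.round(cycles) == 0
            assert np.array_equal(
                rung.phase_rad[zero], wrapped.phase_rad[zero]
            )

    def test_final_rung_option(self, left_stack):
        ladder = sp.PhaseLadder(rungs=left_stack, fov="left")
        result = sp.hierarchical_unwrap(ladder, final_rung=3)
        chosen = result.unwrapped[3]
        assert np.allclose(
            result.opd_nm, chosen.phase_rad * chosen.wavelength_nm / TWO_PI
        )

    def test_two_rung_subset_ladder_accepted(self, left_stack):
        subset = [left_stack[0], left_stack[3]]  # 6206.67 -> 692
        result = sp.hierarchical_unwrap(sp.PhaseLadder(rungs=subset, fov="left"))
        assert len(result.unwrapped) == 2


class TestNoiseScaling:
    """OPD-domain noise follows the wavelength ratio of the combination."""

    def _noisy_channels(self, sigma, shape=(256, 256), seed=17):
        rng = np.random.default_rng(seed)
        return [
            sp.ComplexWavefront(
                field=np.exp(1j * rng.normal(0, sigma, shape)),
                wavelength_nm=wl, fov="left",
            )
            for wl in (692.0, 532.0, 490.0)
        ]

    def test_subtraction_map_noise_amplified_by_wavelength_ratio(self):
        sigma = 0.04
        maps = sp.nine_map_stack(self._noisy_channels(sigma))
        lam_d = maps[0].wavelength_nm
        predicted = np.sqrt(2) * sigma * lam_d / TWO_PI
        measured = maps[0].opd_nm.std()
        assert measured == pytest.approx(predicted, rel=0.15)

    def test_addition_maps_less_noisy_than_illumination_maps(self):
        maps = sp.nine_map_stack(self._noisy_channels(0.04))
        opd_noise = {round(m.wavelength_nm): m.opd_nm.std() for m in maps}
        worst_addition = max(opd_noise[k] for k in (301, 287, 255))
        best_illumination = min(opd_noise[k] for k in (692, 532, 490))
        assert worst_addition < best_illumination

    def test_hierarchical_output_inherits_shortest_rung_noise(self):
        """End of the ladder: noise comparable to the 255 nm rung's, an
        order of magnitude below the 6206.67 nm seed's."""
        sigma = 0.04
        maps = sp.nine_map_stack(self._noisy_channels(sigma))
        region = np.s_[32:224, 32:224]
        result = sp.hierarchical_unwrap(
            sp.PhaseLadder(rungs=maps, fov="left")
        )
        final_std = sp.estimate_noise(result.opd_nm, region)
        seed_std = sp.estimate_noise(
            sp.standard_unwrap(maps[0]).opd_nm, region
        )
        assert final_std < 0.2 * seed_std
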