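import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippocan.grid import (
    GridModule,
    band_response,
    lattice_vectors,
    rate_map,
    sample_poisson_rates,
    spatial_autocorrelation,
    superpose_stripes,
    unit_cell_offsets,
    von_mises_rate,
    wave_vectors,
)
from hippocan.stripe import StripePlate, relax_to_pattern, step_dynamics


@pytest.fixture(scope="module")
def module():
    return GridModule.regular(0.5, 12)


@pytest.fixture(scope="module")
def plate_triplet(calibrated_plate):
    """Three calibrated plates at 0/60/120 degrees, independently formed."""
    base, _ = calibrated_plate
    plates = []
    for i, th in enumerate((0.0, np.pi / 3, 2 * np.pi / 3)):
        p = StripePlate(theta=th)
        relax_to_pattern(p, seed=40 + i)
        p.displacement_gain = base.displacement_gain
        plates.append(p)
    return plates


class TestGeometry:
    def test_wave_vectors_sixty_degrees_apart(self):
        K = wave_vectors()
        assert np.allclose(np.linalg.norm(K, axis=1), 1.0)
        assert sum(np.outer(k, k) for k in K) == pytest.approx(1.5 * np.eye(2))

    def test_lattice_vectors_are_grid_periods(self):
        lam = 0.7
        a = lattice_vectors(lam)
        K = wave_vectors()
        # every wave direction sees an integer number of periods along both
        # primitive vectors
        assert np.allclose((a @ K.T) / lam, np.round((a @ K.T) / lam))

    def test_offsets_tile_unit_cell(self):
        c = unit_cell_offsets(1.0, 5)
        assert c.shape == (25, 2)
        assert len(np.unique(c.round(12), axis=0)) == 25


class TestVonMises:
    def test_peak_at_cell_phase(self, module):
        rates = von_mises_rate(module, module.phase_offsets[7])
        assert rates[7] == pytest.approx(module.n_max)

    def test_zero_kappa_is_flat(self):
        m = GridModule.regular(0.5, 4, kappa=0.0)
        rates = von_mises_rate(m, np.array([0.123, -0.456]))
        assert np.allclose(rates, m.n_max)

    def test_lattice_periodicity(self, module):
        x = np.array([0.07, 0.21])
        for T in module.lattice:
            assert von_mises_rate(module, x) == pytest.approx(
                von_mises_rate(module, x + T)
            )

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_rates_bounded(self, x, y):
        m = GridModule.regular(0.5, 3)
        rates = von_mises_rate(m, np.array([x, y]))
        assert np.all(rates > 0) and np.all(rates <= m.n_max + 1e-12)


class TestPoisson:
    def test_zero_mean_gives_zero_counts(self):
        m = GridModule.regular(0.5, 3, n_max=1e-12)
        counts = sample_poisson_rates(m, np.zeros(2), 1.0, seed=0)
        assert not counts.any()

    def test_empirical_mean_matches_rate(self, module, rng):
        x = np.array([0.1, 0.1])
        lam = von_mises_rate(module, x) * 2.0
        draws = np.stack(
            [sample_poisson_rates(module, x, 2.0, seed=rng) for _ in range(2000)]
        )
        se = np.sqrt(lam / 2000)
        assert (np.abs(draws.mean(axis=0) - lam) < 3 * se + 0.05).all()

    def test_seeded_draws_identical(self, module):
        a = sample_poisson_rates(module, np.ones(2), 1.0, seed=5)
        b = sample_poisson_rates(module, np.ones(2), 1.0, seed=5)
        assert np.array_equal(a, b)


def _autocorr_peak_angles(field, step):
    """Angles of the first ring of autocorrelation peaks, in degrees."""
    ac = spatial_autocorrelation(field)
    n = ac.shape[0]
    cy = (np.array(ac.shape) - 1) // 2
    ys, xs = np.indices(ac.shape)
    r = np.hypot(xs - cy[1], ys - cy[0]) * step
    ring = (r > 0.3) & (r < 0.9)  # around the expected lattice spacing
    angles = []
    acm = np.where(ring, ac, -np.inf)
    for _ in range(6):
        i, j = np.unravel_index(np.argmax(acm), ac.shape)
        ang = np.degrees(np.arctan2(j - cy[1], i - cy[0]))
        angles.append(ang % 360)
        # suppress the neighborhood of the found peak
        mask = np.hypot(xs - j, ys - i) < 0.25 / step
        acm[mask] = -np.inf
    return np.sort(np.asarray(angles))


class TestRateMap:
    def test_constant_field_round_trip(self):
        xs, ys, m = rate_map(lambda p: np.full(len(p), 2.5), (1.0, 1.0), 0.1)
        assert np.allclose(m, 2.5)

    def test_hexagonal_autocorrelation_of_grid_tuning(self):
        """Six autocorrelation peaks at 60-degree spacing (period 0.5 m)."""
        mod = GridModule(0.5, np.zeros((1, 2)))
        step = 0.02
        _, _, field = rate_map(
            lambda p: von_mises_rate(mod, p)[:, 0], (2.0, 2.0), step
        )
        angles = _autocorr_peak_angles(field, step)
        gaps = np.diff(np.concatenate([angles, [angles[0] + 360]]))
        assert len(angles) == 6
        assert np.allclose(gaps, 60.0, atol=10.0)

    def test_single_plate_map_is_striped(self, plate_triplet):
        """One plate's field varies along theta only (1-D periodicity)."""
        plate = plate_triplet[0]
        step = 0.01
        _, _, field = rate_map(
            lambda p: band_response(plate, p), (1.0, 1.0), step
        )
        # constant across theta (columns), periodic along theta (rows)
        assert np.allclose(field.std(axis=1), 0.0, atol=1e-9)
        prof = field[:, 0] - field[:, 0].mean()
        spec = np.abs(np.fft.rfft(prof))
        peak = np.argmax(spec[1:]) + 1
        wavelength = len(prof) * step / peak
        assert wavelength == pytest.approx(plate.physical_period, rel=0.1)


class TestSuperposition:
    def test_requires_sixty_degree_spacing(self, plate_triplet):
        bad = [plate_triplet[0], plate_triplet[0], plate_triplet[1]]
        with pytest.raises(ValueError, match="60 degrees"):
            superpose_stripes(bad, np.zeros((1, 2)))

    def test_additivity_before_rectification(self, plate_triplet):
        pts = np.random.default_rng(0).uniform(0, 1, (50, 2))
        total = superpose_stripes(plate_triplet, pts)
        parts = sum(band_response(p, pts) for p in plate_triplet)
        assert total == pytest.approx(np.maximum(parts, 0.0))

    def test_superposed_field_is_hexagonal(self, plate_triplet):
        step = 0.02
        L = plate_triplet[0].physical_period
        _, _, field = rate_map(
            lambda p: superpose_stripes(plate_triplet, p),
            (3 * L, 3 * L), step,
        )
        ac = spatial_autocorrelation(field)
        cy = (np.array(ac.shape) - 1) // 2
        ys, xs = np.indices(ac.shape)
        r = np.hypot(xs - cy[1], ys - cy[0]) * step
        ring = (r > 0.4 * L) & (r < 1.6 * L)
        acm = np.where(ring, ac, -np.inf)
        angles = []
        for _ in range(6):
            i, j = np.unravel_index(np.argmax(acm), ac.shape)
            angles.append(np.degrees(np.arctan2(j - cy[1], i - cy[0])) % 360)
            mask = np.hypot(xs - j, ys - i) < 0.5 * L / step
            acm[mask] = -np.inf
        gaps = np.diff(np.concatenate([np.sort(angles), [min(angles) + 360]]))
        assert np.allclose(gaps, 60.0, atol=15.0)

    def test_translation_equivariance(self, plate_triplet):
        """Shifting plate phases consistently translates the grid field.

        A displacement Delta whose projections on the three plate directions
        are integer cell counts (1, 1, 0 here) is realized by rolling each
        plate's pattern by that count; the superposed field must translate
        by Delta.
        """
        g = plate_triplet[0].displacement_gain
        delta = g * np.array([1.0, 1.0 / np.sqrt(3.0)])
        rolls = [
            int(round((p.direction @ delta) / p.displacement_gain))
            for p in plate_triplet
        ]
        assert rolls == [1, 1, 0]
        pts = np.random.default_rng(1).uniform(0.2, 0.8, (100, 2))
        before = superpose_stripes(plate_triplet, pts)
        shifted = []
        for p, r in zip(plate_triplet, rolls):
            q = p.copy()
            q.rates = np.roll(q.rates, r)
            shifted.append(q)
        after = superpose_stripes(shifted, pts + delta)
        assert np.corrcoef(before, after)[0, 1] > 0.98

    def test_pattern_flows_with_velocity(self, plate_triplet):
        """Constant velocity translates the assembled grid at the calibrated
        speed (cross-correlation peak displacement between snapshots)."""
        plates = [p.copy() for p in plate_triplet]
        v = np.array([0.3, 0.0])
        dt_total = 0.5
        step = 0.01
        _, _, before = rate_map(
            lambda p: superpose_stripes(plates, p), (1.0, 1.0), step
        )
        for p in plates:
            for _ in range(int(dt_total / 0.001)):
                step_dynamics(p, v, 0.001)
        _, _, after = rate_map(
            lambda p: superpose_stripes(plates, p), (1.0, 1.0), step
        )
        from scipy import signal

        xc = signal.fftconvolve(
            after - after.mean(), (before - before.mean())[::-1, ::-1], "same"
        )
        i, j = np.unravel_index(np.argmax(xc), xc.shape)
        center = (np.array(xc.shape) - 1) // 2
        shift = (np.array([i, j]) - center) * step
        expected = -v * dt_total  # pattern flow direction per sign convention
        assert min(
            np.linalg.norm(shift - expected), np.linalg.norm(shift + expected)
        ) < 0.06
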