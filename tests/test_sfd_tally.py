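"""SFD complex tally: weights, binning, finalization, oracle equivalence."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays as np_arrays

from sfdepth import (
    DepthGrid,
    DetectionEvent,
    LayerStack,
    SfdAccumulator,
    run_simulation,
    sfd_weight,
)
from sfdepth.sfd_tally import pvd_from_pzmax, pzmax_from_pvd
from sfdepth.transport import kernel_py, propagate_packet


class TestSfdWeight:
    def test_zero_frequency_identity(self):
        assert sfd_weight(0.7, 0.0, 123.4) == 0.7 + 0.0j

    def test_quarter_period_phase(self):
        xi = sfd_weight(1.0, 0.1, 2.5)
        assert xi == pytest.approx(cmath.exp(-1j * math.pi / 2), abs=1e-12)
        assert xi.real == pytest.approx(0.0, abs=1e-12)
        assert xi.imag == pytest.approx(-1.0, abs=1e-12)

    def test_zero_displacement(self):
        assert sfd_weight(0.5, 0.2, 0.0) == 0.5 + 0.0j

    @given(W=st.floats(1e-6, 1.0), fx=st.floats(0.0, 1.0), dx=st.floats(-50, 50))
    def test_modulus_preserves_weight(self, W, fx, dx):
        assert abs(sfd_weight(W, fx, dx)) == pytest.approx(W, rel=1e-12)


class TestDepthGrid:
    def test_defaults(self):
        g = DepthGrid()
        assert g.dz == 0.01 and g.z_cap == 40.0 and g.n_bins == 4000

    def test_bin_assignment_and_overflow(self):
        g = DepthGrid(dz=0.01, z_cap=1.0)
        assert g.bin_index(0.0) == 0
        assert g.bin_index(0.035) == 3
        assert g.bin_index(0.01) == 1  # lower edge inclusive
        assert g.bin_index(5.0) == g.n_bins  # overflow
        with pytest.raises(ValueError):
            g.bin_index(-0.1)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            DepthGrid(dz=0.0)
        with pytest.raises(ValueError):
            DepthGrid(dz=0.3, z_cap=1.0)


class TestAccumulator:
    def test_single_event_populates_zmax_bin_and_pvd_plateau(self):
        acc = SfdAccumulator([0.0], DepthGrid(dz=0.01, z_cap=0.1))
        acc.tally_event(DetectionEvent(W=0.6, dx=0.0, z_deepest=0.035))
        res = acc.finalize(n_launched=1)
        assert res.pzmax[0, 3] == 0.6
        assert np.all(res.pzmax[0, [0, 1, 2, 4]] == 0.0)
        assert np.all(res.pvd[0, :4].real == 0.6)
        assert res.pvd[0, 4].real == 0.0

    def test_two_events_same_bin_sum_complex(self):
        acc = SfdAccumulator([0.2], DepthGrid(dz=1.0, z_cap=3.0))
        e1 = DetectionEvent(W=0.5, dx=1.0, z_deepest=1.5)
        e2 = DetectionEvent(W=0.25, dx=-2.0, z_deepest=1.2)
        acc.tally_event(e1)
        acc.tally_event(e2)
        res = acc.finalize(n_launched=2)
        expected = (sfd_weight(0.5, 0.2, 1.0) + sfd_weight(0.25, 0.2, -2.0)) / 2
        assert res.pzmax[0, 1] == pytest.approx(expected, abs=1e-15)

    def test_overflow_event_preserves_rd(self):
        acc = SfdAccumulator([0.0], DepthGrid(dz=1.0, z_cap=2.0))
        acc.tally_event(DetectionEvent(W=0.3, dx=0.0, z_deepest=50.0))
        res = acc.finalize(n_launched=1)
        assert res.pzmax[0, -1] == 0.3  # overflow bin
        assert res.rd(0.0) == 0.3

    def test_normalization_by_launched_not_detected(self):
        acc = SfdAccumulator([0.0], DepthGrid(dz=1.0, z_cap=2.0))
        acc.tally_event(DetectionEvent(W=1.0, dx=0.0, z_deepest=0.5))
        res = acc.finalize(n_launched=4)
        assert res.rd(0.0) == 0.25

    def test_finalize_requires_packets(self):
        acc = SfdAccumulator([0.0])
        with pytest.raises(ValueError):
            acc.finalize(n_launched=0)


class TestPvdPzmaxConversions:
    def test_finite_differencing_example(self):
        pz = pzmax_from_pvd(np.array([0.62, 0.60, 0.59]))
        assert pz == pytest.approx([0.02, 0.01, 0.59])

    def test_all_zero(self):
        assert np.all(pvd_from_pzmax(np.zeros(5)) == 0.0)
        assert np.all(pzmax_from_pvd(np.zeros(5)) == 0.0)

    @settings(deadline=None)
    @given(np_arrays(np.complex128, (3, 20),
                     elements=st.complex_numbers(max_magnitude=10, allow_nan=False,
                                                 allow_infinity=False)))
    def test_round_trip_identity(self, a):
        assert np.allclose(pzmax_from_pvd(pvd_from_pzmax(a)), a, atol=1e-9)
        assert np.allclose(pvd_from_pzmax(pzmax_from_pvd(a)), a, atol=1e-9)


@pytest.fixture(scope="module")
def oracle_data(reference_stack):
    n = 1000
    fx = np.array([0.0, 0.1, 0.5])
    grid = DepthGrid(dz=0.05, z_cap=10.0)
    rng = np.random.Generator(np.random.PCG64(77))
    acc = SfdAccumulator(fx, grid)
    events, trajs = [], []
    for _ in range(n):
        event, traj = propagate_packet(reference_stack, rng, record_trajectory=True)
        if event is not None:
            acc.tally_event(event)
            events.append(event)
            trajs.append(traj)
    streaming = acc.finalize(n_launched=n)
    return n, fx, grid, events, trajs, streaming


class TestStreamingVsLiteralOracle:
    """The streaming zmax tally must equal a brute-force implementation
    that stores full trajectories and tallies the complex weight once at
    every midway surface the packet crossed, then differences."""

    def test_pvd_matches_per_surface_tally(self, oracle_data):
        n, fx, grid, events, trajs, streaming = oracle_data
        n_surf = grid.n_bins + 1
        z_surf = np.arange(n_surf) * grid.dz
        pvd_lit = np.zeros((fx.size, n_surf), dtype=complex)
        for event, traj in zip(events, trajs):
            zmax = traj[:, 2].max()
            crossed = z_surf <= zmax  # surface crossed iff max depth reaches it
            for k, f in enumerate(fx):
                pvd_lit[k, crossed] += sfd_weight(event.W, f, event.dx)
        pvd_lit /= n
        np.testing.assert_allclose(streaming.pvd, pvd_lit, rtol=1e-12, atol=1e-15)

    def test_pzmax_bins_bit_identical_to_direct_binning(self, oracle_data):
        n, fx, grid, events, trajs, streaming = oracle_data
        direct = np.zeros((fx.size, grid.n_bins + 1), dtype=complex)
        for event in events:
            b = grid.bin_index(event.z_deepest)
            for k, f in enumerate(fx):
                direct[k, b] += sfd_weight(event.W, f, event.dx)
        direct /= n
        assert np.array_equal(streaming.pzmax, direct)

    def test_rd_equals_mean_detected_weight(self, oracle_data):
        n, fx, grid, events, trajs, streaming = oracle_data
        wsum = sum(e.W for e in events)
        assert streaming.rd(0.0) == pytest.approx(wsum / n, rel=1e-12)
        # conservation: the bins sum to P_V&D at the surface
        np.testing.assert_allclose(streaming.pzmax.sum(axis=1), streaming.pvd[:, 0],
                                   rtol=1e-13)


@pytest.fixture(scope="module")
def small_run(reference_stack):
    fx = [0.0, 0.05, 0.1, 0.2, 0.3, 0.5]
    return run_simulation(reference_stack, fx, n_packets=60_000, seed=42,
                          grid=DepthGrid(dz=0.01, z_cap=20.0))


class TestSimulationProperties:

    def test_pvd_is_reverse_cumsum_of_pzmax(self, small_run):
        assert np.array_equal(small_run.pvd, pvd_from_pzmax(small_run.pzmax))

    def test_zero_frequency_row_real_nonnegative_nonincreasing(self, small_run):
        row = small_run.pzmax[0]
        assert np.all(row.imag == 0.0)
        assert np.all(row.real >= 0.0)
        pvd0 = small_run.pvd[0].real
        assert np.all(np.diff(pvd0) <= 1e-15)

    def test_imaginary_parts_consistent_with_zero(self, small_run):
        """Lateral symmetry of the pencil beam makes E[xi] real; the
        imaginary part must be noise."""
        im = small_run.pvd.imag
        sig = np.maximum(small_run.sigma_im, 1e-12)
        assert np.all(np.abs(im) < 4.0 * sig + 1e-9)

    def test_surface_value_nonincreasing_with_frequency(self, small_run):
        """Low-pass behaviour: modulated reflectance falls with fx."""
        rd = small_run.pvd[:, 0].real
        sig = small_run.sigma_re[:, 0]
        tol = 3.0 * np.sqrt(sig[1:] ** 2 + sig[:-1] ** 2)
        assert np.all(np.diff(rd) <= tol)

    def test_reproducibility_bit_identical(self, reference_stack, small_run):
        again = run_simulation(reference_stack, [0.0, 0.05, 0.1, 0.2, 0.3, 0.5],
                               n_packets=60_000, seed=42,
                               grid=DepthGrid(dz=0.01, z_cap=20.0))
        assert np.array_equal(again.pzmax, small_run.pzmax)
        assert np.array_equal(again.sigma_re, small_run.sigma_re)

    def test_csv_round_trip(self, small_run, tmp_path):
        from sfdepth.sfd_tally import SfdTallyResult

        csv, side = tmp_path / "t.csv", tmp_path / "t.json"
        small_run.save(csv, side)
        back = SfdTallyResult.load(csv, side)
        assert back.N == small_run.N
        np.testing.assert_allclose(back.pvd, small_run.pvd, rtol=1e-15)
        np.testing.assert_allclose(back.pzmax, small_run.pzmax, rtol=1e-15)
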