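"""Tissue-solver tests: diffusion operator, conservation, propagation
and the diffusion scaling laws."""

import numpy as np
import pytest

from fourcurrent.params import builtin_set
from fourcurrent.protocols import activation_times
from fourcurrent.stimulus import StimulusProtocol
from fourcurrent.tissue import (TissueGrid, TissueSimulation,
                                diffusion_term, fiber_tensor,
                                simulate_tissue)


def _gaussian_1d(grid, x0=1.0, sigma=0.25):
    x = grid.coordinates(0)
    return np.exp(-((x - x0) ** 2) / (2 * sigma ** 2))


class TestDiffusionTerm:
    def test_uniform_field_gives_zero(self):
        grid = TissueGrid.sheet(1.0, 1.0, dx=0.05, D=1e-3)
        out = diffusion_term(np.full(grid.shape, 0.7), grid)
        assert np.all(out == 0.0)

    def test_no_flux_conservation_scalar(self, rng):
        grid = TissueGrid.sheet(1.0, 1.0, dx=0.05, D=1e-3)
        V = rng.random(grid.shape)
        out = diffusion_term(V, grid)
        assert abs(out.sum()) < 1e-12 * np.abs(out).max()

    def test_no_flux_conservation_masked_tensor(self, rng):
        shape = (12, 14, 10)
        mask = np.zeros(shape, bool)
        mask[2:10, 3:12, 2:8] = True
        mask[5, 5, 4] = False  # a hole
        fibers = rng.normal(size=shape + (3,))
        tensor = fiber_tensor(fibers, 1e-3, 6.75e-5)
        grid = TissueGrid(shape=shape, dx=0.025, tensor=tensor, mask=mask)
        V = rng.random(shape)
        out = diffusion_term(V, grid)
        assert np.all(out[~mask] == 0.0)
        assert abs(out.sum()) < 1e-10 * np.abs(out).max()

    def test_matches_analytic_second_derivative(self):
        grid = TissueGrid.cable(2.0, dx=0.0025, D=1e-3)
        x = grid.coordinates(0)
        sigma = 0.25
        V = _gaussian_1d(grid, sigma=sigma)
        expect = 1e-3 * V * (((x - 1.0) / sigma ** 2) ** 2 - 1 / sigma ** 2)
        got = diffusion_term(V, grid)
        interior = slice(40, -40)  # away from the no-flux ends
        err = np.abs(got[interior] - expect[interior]).max()
        assert err < 2e-3 * np.abs(expect).max()

    def test_tensor_reduces_to_scalar(self, rng):
        shape = (9, 9, 9)
        V = rng.random(shape)
        iso = TissueGrid(shape=shape, dx=0.05, D=1e-3)
        fibers = np.zeros(shape + (3,))
        fibers[..., 0] = 1.0
        tensor = fiber_tensor(fibers, 1e-3, 1e-3)  # D_par = D_perp
        aniso = TissueGrid(shape=shape, dx=0.05, tensor=tensor)
        np.testing.assert_allclose(diffusion_term(V, iso),
                                   diffusion_term(V, aniso),
                                   rtol=0, atol=1e-14)


class TestGridValidation:
    def test_requires_exactly_one_diffusion_spec(self):
        with pytest.raises(ValueError):
            TissueGrid(shape=(10,), dx=0.02)
        with pytest.raises(ValueError):
            TissueGrid(shape=(10,), dx=0.02, D=1e-3,
                       tensor=np.zeros((10, 6)))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            TissueGrid(shape=(5, 5), dx=0.02, D=1e-3,
                       mask=np.zeros((5, 5), bool))

    def test_stability_bound_paper_defaults(self):
        # dt=0.01 < 0.02^2/(2*1e-3) = 0.2 in 1D
        assert TissueGrid.cable(8.0, 0.02, 1e-3).stability_dt() == \
            pytest.approx(0.2)
        sim = TissueSimulation(TissueGrid.cable(1.0, 0.02, 1e-3),
                               builtin_set("epi"), dt=0.01)
        assert sim.n_sub == 100
        with pytest.raises(ValueError, match="stability"):
            TissueSimulation(TissueGrid.cable(1.0, 0.02, 1e-3),
                             builtin_set("epi"), dt=0.5)
        with pytest.warns(UserWarning, match="stability"):
            TissueSimulation(TissueGrid.cable(1.0, 0.02, 1e-3),
                             builtin_set("epi"), dt=0.5,
                             on_unstable="warn")


class TestIntegration:
    def test_resting_field_is_fixed(self, epi):
        grid = TissueGrid.sheet(0.5, 0.5, dx=0.05, D=1e-3)
        res = simulate_tissue(grid, epi, StimulusProtocol(), duration=5.0,
                              probes=[(0.25, 0.25)])
        tr = res.probes[(0.25, 0.25)]
        assert np.all(tr.V == 0.0)
        assert np.all(res.final_state.h == 1.0)

    def test_pure_diffusion_conserves_total_voltage(self, rng):
        """With all conductances zero, sum(V) is invariant over 1e4
        explicit steps on a masked no-flux domain."""
        passive = builtin_set("epi", g_fi=0.0, g_si=0.0, g_so=0.0, g_to=0.0)
        mask = np.ones((40, 40), bool)
        mask[10:18, 10:18] = False
        grid = TissueGrid(shape=(40, 40), dx=0.02, D=1e-3, mask=mask)
        sim = TissueSimulation(grid, passive, dt=0.01)
        sim.state.V[:] = rng.random((40, 40)) * mask
        total0 = sim.state.V.sum()
        sim.advance(100.0)  # 1e4 steps
        assert sim.state.V.sum() == pytest.approx(total0, rel=1e-12)
        # and the field is smoothing toward uniform
        assert sim.state.V[mask].std() < 0.25

    def test_cable_single_wave_no_reflection(self, lrd, thresholds):
        grid = TissueGrid.cable(3.0, dx=0.02, D=1e-3)
        protocol = StimulusProtocol.single(
            1.5 * thresholds["lrd"],
            region=grid.box_region((0.0, 0.1)))
        probes = [0.5, 1.0, 1.5, 2.0, 2.5, 2.9]
        res = simulate_tissue(grid, lrd, protocol, duration=300.0,
                              probes=probes, sample_ms=0.5)
        acts = []
        for x in probes:
            at = activation_times(res.probes[(x,)])
            assert at.size == 1  # activates exactly once: no reflection
            acts.append(at[0])
        assert np.all(np.diff(acts) > 0)  # rightward monotone activation

    def test_nonfinite_detection(self, epi):
        grid = TissueGrid.cable(0.5, dx=0.02, D=1e-3)
        sim = TissueSimulation(grid, epi, dt=0.01)
        sim.state.V[3] = np.inf
        with pytest.raises(FloatingPointError, match="node"):
            sim.advance(2.0)


def _cable_cv(params, D, dx=0.02, dt=0.01, length=4.0, amp=3.0,
              probes=(1.5, 3.0), tensor_axis=None):
    if tensor_axis is None:
        grid = TissueGrid.cable(length, dx=dx, D=D)
    else:
        n = int(round(length / dx)) + 1
        fibers = np.zeros((n, 3))
        fibers[:, tensor_axis] = 1.0
        grid = TissueGrid(shape=(n,), dx=dx,
                          tensor=fiber_tensor(fibers, 1e-3, 6.75e-5))
    protocol = StimulusProtocol.single(
        amp, region=grid.box_region((0.0, 5 * dx)))
    res = simulate_tissue(grid, params, protocol, dt=dt,
                          duration=length / 0.01, probes=list(probes),
                          sample_ms=0.25)
    t = [activation_times(res.probes[(x,)])[0] for x in probes]
    return (probes[1] - probes[0]) / (t[1] - t[0]) * 1000.0


class TestPropagationScaling:
    def test_cv_scales_as_sqrt_D(self, lrd):
        # fine grid so the front is resolved at both diffusivities
        cv1 = _cable_cv(lrd, D=1e-3, dx=0.005, dt=0.0025)
        cv2 = _cable_cv(lrd, D=2e-3, dx=0.005, dt=0.0025)
        assert cv2 / cv1 == pytest.approx(np.sqrt(2.0), rel=0.05)

    def test_mesh_refinement_converges_monotonically(self, lrd):
        """CV approaches the fine-grid value from below as dx, dt are
        refined together (first-order scheme, under-resolved front)."""
        cvs = [_cable_cv(lrd, 1e-3, dx=0.02, dt=0.01),
               _cable_cv(lrd, 1e-3, dx=0.01, dt=0.005),
               _cable_cv(lrd, 1e-3, dx=0.005, dt=0.0025)]
        assert cvs[0] < cvs[1] < cvs[2]
        assert cvs[2] - cvs[1] < cvs[1] - cvs[0]

    def test_anisotropic_cv_ratio(self, lrd):
        """Along/across-fiber CV ratio approximates sqrt(D_par/D_perp);
        the cross-fiber cable is refined so that the slower, narrower
        front stays equally resolved."""
        ratio = np.sqrt(1e-3 / 6.75e-5)  # ~3.85
        cv_par = _cable_cv(lrd, None, dx=0.02, dt=0.01, tensor_axis=0)
        cv_perp = _cable_cv(lrd, None, dx=0.02 / ratio, dt=0.01,
                            length=1.2, probes=(0.4, 0.8), tensor_axis=1)
        assert cv_par / cv_perp == pytest.approx(ratio, rel=0.05)

    def test_2d_isotropy_of_front_speed(self, lrd):
        """A centrally ignited circular front travels equally fast along
        the axes and the diagonal (within 2% at dx = 0.01)."""
        grid = TissueGrid.sheet(2.4, 2.4, dx=0.01, D=1e-3)
        c = 1.2
        protocol = StimulusProtocol.single(
            4.0, region=grid.box_region((c - 0.05, c + 0.05),
                                        (c - 0.05, c + 0.05)))
        u = 1 / np.sqrt(2.0)
        pts = {"x": [(c + 0.4, c), (c + 0.9, c)],
               "y": [(c, c + 0.4), (c, c + 0.9)],
               "diag": [(c + 0.4 * u, c + 0.4 * u),
                        (c + 0.9 * u, c + 0.9 * u)]}
        probes = [pt for pair in pts.values() for pt in pair]
        res = simulate_tissue(grid, lrd, protocol, duration=120.0,
                              probes=probes, sample_ms=0.25)
        cvs = {}
        for key, (a, b) in pts.items():
            ta = activation_times(res.probes[tuple(a)])[0]
            tb = activation_times(res.probes[tuple(b)])[0]
            cvs[key] = 0.5 / (tb - ta)
        vals = list(cvs.values())
        assert max(vals) / min(vals) < 1.02

    def test_2d_plane_wave_parallel_isochrones(self, lrd, thresholds):
        grid = TissueGrid.sheet(1.5, 1.0, dx=0.02, D=1e-3)
        protocol = StimulusProtocol.single(
            1.5 * thresholds["lrd"],
            region=grid.box_region((0.0, 0.06), (0.0, 1.0)))
        ys = [0.2, 0.5, 0.8]
        probes = [(1.0, y) for y in ys]
        res = simulate_tissue(grid, lrd, protocol, duration=60.0,
                              probes=probes, sample_ms=0.25)
        acts = [activation_times(res.probes[pt])[0] for pt in probes]
        assert (max(acts) - min(acts)) < 0.01 * np.mean(acts)
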