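import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flapsim.flow import pressure_slice, swirling_strength, swirl_field
from flapsim.solver.core import FlowState, taylor_green_fields
from flapsim.solver.grid import StructuredGrid, uniform_periodic_grid


def _state(grid, u=None, v=None, w=None, p=None):
    nx, ny, nz = grid.shape
    return FlowState(
        u=np.zeros((nx + 1, ny, nz)) if u is None else u,
        v=np.zeros((nx, ny + 1, nz)) if v is None else v,
        w=np.zeros((nx, ny, nz + 1)) if w is None else w,
        p=np.zeros((nx, ny, nz)) if p is None else p)


class TestSwirlingStrength:
    def test_solid_body_rotation(self):
        # angular rate 2/s about z: eigenvalues 0, +-2i
        T = np.array([[0.0, -2.0, 0.0], [2.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        assert swirling_strength(T) == pytest.approx(2.0, rel=1e-12)

    def test_pure_strain_is_zero(self):
        assert swirling_strength(np.diag([1.0, -1.0, 0.0])) == 0.0

    def test_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=(2000, 3, 3))
        lam = swirling_strength(T)
        oracle = np.abs(np.linalg.eigvals(T).imag).max(axis=1)
        assert np.abs(lam - oracle).max() < 1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        T = rng.normal(size=(3, 3))
        # random rotation via QR of a Gaussian matrix
        Q, R = np.linalg.qr(rng.normal(size=(3, 3)))
        Q *= np.sign(np.diag(R))
        lam0 = swirling_strength(T)
        lam1 = swirling_strength(Q @ T @ Q.T)
        assert lam1 == pytest.approx(lam0, rel=1e-8, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_symmetric_tensor_is_zero(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        assert swirling_strength(0.5 * (A + A.T)) == 0.0

    def test_nonfinite_rejected(self):
        T = np.full((3, 3), np.nan)
        with pytest.raises(ValueError, match="finite"):
            swirling_strength(T)


class TestSwirlField:
    def test_uniform_flow_zero_everywhere(self):
        grid = uniform_periodic_grid((12, 12, 12), (1.0, 1.0, 1.0))
        st_ = _state(grid)
        st_.u[:] = 3.0
        lam = swirl_field(st_, grid)
        np.testing.assert_allclose(lam, 0.0, atol=1e-12)

    def test_taylor_green_pattern_symmetry(self):
        grid = uniform_periodic_grid((32, 32, 4),
                                     (2 * np.pi, 2 * np.pi, 1.0))
        u, v, w = taylor_green_fields(grid, nu=0.01, t=0.0)
        lam = swirl_field(_state(grid, u=u, v=v, w=w), grid)
        # z-invariant flow: field constant along z
        np.testing.assert_allclose(
            lam, np.broadcast_to(lam[:, :, :1], lam.shape), atol=1e-10)
        # vortex-center symmetry: shifting by half a period in x and y
        # maps the pattern onto itself (interior cells, away from the
        # one-sided edge stencils)
        sym = np.roll(np.roll(lam, 16, axis=0), 16, axis=1)
        dev = np.abs(lam - sym)[2:-2, 2:-2].max()
        assert dev < 0.05 * lam.max()

    def test_solid_cells_masked(self):
        grid = uniform_periodic_grid((8, 8, 8), (1.0, 1.0, 1.0))
        u, v, w = taylor_green_fields(grid, nu=0.01, t=0.0)
        st_ = _state(grid, u=u, v=v, w=w)
        st_.solid = np.zeros(grid.shape, dtype=bool)
        st_.solid[4, 4, 4] = True
        lam = swirl_field(st_, grid)
        assert lam[4, 4, 4] == 0.0


class TestPressureSlice:
    def test_constant_pressure_constant_slice(self):
        f = np.linspace(0, 1, 17)
        grid = StructuredGrid(f, f, f)
        st_ = _state(grid, p=np.full(grid.shape, 4.2))
        _, _, sl = pressure_slice(st_, grid, axis=1, coordinate=0.5)
        np.testing.assert_allclose(sl, 4.2)

    def test_linear_field_reproduced_exactly(self):
        f = np.linspace(0, 1, 17)
        grid = StructuredGrid(f, f, f)
        X, _, _ = np.meshgrid(grid.xc, grid.yc, grid.zc, indexing="ij")
        st_ = _state(grid, p=3.0 * X)
        xs, zs, sl = pressure_slice(st_, grid, axis=1, coordinate=0.37)
        np.testing.assert_allclose(
            sl, np.broadcast_to(3.0 * xs[:, None], sl.shape), atol=1e-12)

    def test_rho_scales_to_physical_pressure(self):
        f = np.linspace(0, 1, 9)
        grid = StructuredGrid(f, f, f)
        st_ = _state(grid, p=np.ones(grid.shape))
        _, _, sl = pressure_slice(st_, grid, axis=0, coordinate=0.5, rho=1.2)
        np.testing.assert_allclose(sl, 1.2)

    def test_plane_outside_domain_rejected(self):
        f = np.linspace(0, 1, 9)
        grid = StructuredGrid(f, f, f)
        with pytest.raises(ValueError, match="outside"):
            pressure_slice(_state(grid), grid, axis=2, coordinate=1.5)
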