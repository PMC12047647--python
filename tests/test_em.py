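"""Electroquasistatic solver: analytic slabs, conservation, superposition,
field derivation and grid-refinement consistency."""

import numpy as np
import pytest

from nibsim.conductivity import TensorField, isotropic_tensor_field
from nibsim.em import (_assemble, _solve_system, efield_from_potential,
                       electrode_patch, solve_potential)
from nibsim.phantom import build_sphere_phantom, place_electrodes_1010


def _solve_slab(sig_profile, n=(20, 12, 12), spacing=2.0, tol=1e-10):
    """Plate-electrode slab along x: full end faces at +-0.5 V."""
    t = np.zeros(n + (3, 3))
    for i in range(3):
        t[..., i, i] = np.asarray(sig_profile)[:, None, None]
    tf = TensorField(tensors=t, mask=np.ones(n, bool), units="S/m",
                     spacing=np.full(3, float(spacing)), origin=np.zeros(3))
    A, idx, N = _assemble(tf)
    fixed = np.zeros(N, bool)
    vals = np.zeros(N)
    i0, i1 = idx[0].ravel(), idx[-1].ravel()
    fixed[i0] = fixed[i1] = True
    vals[i0], vals[i1] = 0.5, -0.5
    phi_vec, _ = _solve_system(A, np.zeros(N), ~fixed, vals, N, tol, 20000)
    flux = A @ phi_vec
    phi = phi_vec.reshape(n)
    E = efield_from_potential(phi, tf.spacing, tf.mask)
    return phi, E, float(flux[i0].sum()), float(flux[i1].sum())


class TestSlabOracles:
    def test_parallel_plate_uniform_field(self):
        _, E, _, _ = _solve_slab(np.ones(20))
        d = 19 * 2e-3  # plate separation, m
        interior = E[0, 5:15]
        assert np.allclose(interior, 1.0 / d, rtol=0.01)
        assert np.abs(E[1:, 5:15]).max() < 1e-6 / d

    def test_two_layer_field_ratio(self):
        """sigma 1 / 0.5 at equal thickness: series conductance gives E2/E1 = 2."""
        sig = np.ones(20)
        sig[10:] = 0.5
        _, E, _, _ = _solve_slab(sig)
        e1 = E[0, 3:8].mean()
        e2 = E[0, 12:18].mean()
        assert e2 / e1 == pytest.approx(2.0, rel=0.01)

    def test_charge_conservation(self):
        _, _, ip, ineg = _solve_slab(np.ones(20))
        assert abs(ip + ineg) < 1e-3 * abs(ip)

    def test_anisotropic_homogeneous_interior_consistency(self, rng):
        """A linear potential is an exact solution for any uniform tensor."""
        n = (12, 12, 12)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        S = q @ np.diag([1.0, 0.5, 0.3]) @ q.T
        tf = TensorField(tensors=np.tile(S, n + (1, 1)), mask=np.ones(n, bool),
                         units="S/m", spacing=np.full(3, 2.0), origin=np.zeros(3))
        A, idx, N = _assemble(tf)
        X = np.indices(n).transpose(1, 2, 3, 0) * 2.0
        phi = (X * 1e-3) @ np.array([3.0, -2.0, 1.0])
        resid = A @ phi.ravel()
        deep = np.zeros(n, bool)
        deep[2:-2, 2:-2, 2:-2] = True
        assert np.abs(resid[deep.ravel()]).max() < 1e-12

    def test_system_matrix_symmetric_and_energy_positive(self, small_sigma, rng):
        A, _, N = _assemble(small_sigma)
        assert abs(A - A.T).max() < 1e-12
        x = rng.standard_normal(N)
        x -= x.mean()
        assert x @ (A @ x) > 0


class TestSpherePotential:
    def test_residual_and_charge_balance(self, small_sigma, small_montage):
        sol = solve_potential(small_sigma, small_montage, ("T7", "T8"), tol=1e-9)
        assert sol.residual <= 1e-8
        d = sol.drive
        assert abs(d["current_pos_A"] + d["current_neg_A"]) \
            < 1e-3 * abs(d["current_pos_A"])

    def test_dirichlet_patches_equipotential(self, small_sigma, small_montage):
        sol = solve_potential(small_sigma, small_montage, ("T7", "T8"))
        for lab, v in zip(("T7", "T8"), (0.5, -0.5)):
            patch = electrode_patch(small_sigma, small_montage.position_of(lab),
                                    small_montage.radius_mm)
            assert np.allclose(sol.phi[tuple(patch.T)], v)

    def test_richardson_grid_refinement(self):
        """Sphere with two point-like pads: half-spacing reference solve
        agrees within 2% RMS over the interior shell (unit-current scale)."""
        from nibsim.phantom import ElectrodeMontage
        from scipy.ndimage import map_coordinates
        sols = {}
        for h in (2.0, 1.0):
            ph = build_sphere_phantom(radii_mm=(40.0,), conductivities=(0.3,),
                                      spacing=h)
            mon = ElectrodeMontage(labels=["A", "B"],
                                   positions=np.array([[0.0, 0.0, 40.0],
                                                       [0.0, 0.0, -40.0]]),
                                   radius_mm=3.0, reference="B")
            sols[h] = (ph, solve_potential(isotropic_tensor_field(ph), mon,
                                           ("A", "B"), tol=1e-10))
        ph2, s2 = sols[2.0]
        ph1, s1 = sols[1.0]
        idx = np.argwhere(ph2.labels > 0)
        pos = ph2.origin + idx * ph2.spacing
        r = np.linalg.norm(pos, axis=1)
        sel = (r > 10) & (r < 30)
        fine = np.nan_to_num(s1.phi)
        phi_fine = map_coordinates(fine, ((pos[sel] - ph1.origin) / ph1.spacing).T,
                                   order=1) / s1.injected_current
        phi_coarse = s2.phi[tuple(idx[sel].T)] / s2.injected_current
        rms = np.sqrt(np.mean((phi_coarse - phi_fine) ** 2))
        assert rms / np.sqrt(np.mean(phi_fine**2)) < 0.02

    def test_overlapping_pads_rejected(self, small_sigma, small_phantom):
        mon = place_electrodes_1010(small_phantom, subset=["C3", "C1", "Cz"],
                                    reference="Cz", radius_mm=25.0)
        with pytest.raises(ValueError, match="overlap"):
            solve_potential(small_sigma, mon, ("C3", "C1"))


class TestEFieldFromPotential:
    def test_linear_potential_constant_field(self):
        n = (8, 8, 8)
        x = np.arange(8) * 2.0
        phi = np.broadcast_to(x[:, None, None] * 1e-3, n).copy()  # 1 V/m in x
        E = efield_from_potential(phi, np.full(3, 2.0), np.ones(n, bool))
        assert np.allclose(E[0], -1.0)
        assert np.allclose(E[1:], 0.0)

    def test_constant_potential_zero_field(self):
        n = (6, 6, 6)
        E = efield_from_potential(np.full(n, 0.3), np.full(3, 1.0), np.ones(n, bool))
        assert np.allclose(E, 0.0)

    def test_gradient_is_curl_free(self, rng):
        """Discrete curl of the central-difference gradient vanishes interior."""
        n = (12, 12, 12)
        phi = rng.standard_normal(n)
        from scipy.ndimage import gaussian_filter
        phi = gaussian_filter(phi, 2.0)
        E = efield_from_potential(phi, np.ones(3), np.ones(n, bool))

        def d(comp, ax):
            return np.gradient(comp, axis=ax)

        curl = np.stack([d(E[2], 1) - d(E[1], 2),
                         d(E[0], 2) - d(E[2], 0),
                         d(E[1], 0) - d(E[0], 1)])
        inner = curl[:, 2:-2, 2:-2, 2:-2]
        assert np.abs(inner).max() < 1e-3 * np.abs(E).max()


class TestFieldBasis:
    def test_pair_field_matches_direct_solve(self, small_sigma, small_montage,
                                             small_basis):
        sol = solve_potential(small_sigma, small_montage, ("C3", "C4"), tol=1e-10)
        E = efield_from_potential(sol.phi, sol.spacing_mm, sol.mask)
        direct = E * (1e-3 / sol.injected_current)
        via_basis = small_basis.pair_field("C3", "C4")
        mask = small_sigma.mask
        scale = np.abs(direct[:, mask]).max()
        assert np.abs((via_basis - direct)[:, mask]).max() < 1e-4 * scale

    def test_superposition_of_simultaneous_drives(self, small_sigma, small_montage,
                                                  small_basis):
        """phi(a and b driven together) = phi(a) + phi(b) to solver tolerance.

        Current-driven pads superpose: injecting both pads' current
        distributions in one Neumann solve reproduces the sum of the
        individual solutions (up to the free gauge constant).
        """
        A, idx, N = _assemble(small_sigma)
        solves = small_basis.meta["solves"]
        phis = []
        sources = []
        for lab in ("C3", "T8"):
            s = solves[lab]
            b = np.zeros(N)
            (ip, ineg), (wp, wn) = s["patch_idx"], s["patch_weights"]
            I = s["injected_current_A"]
            b[ip] += wp * I
            b[ineg] -= wn * I
            sources.append(b)
            fixed = np.zeros(N, bool)
            fixed[0] = True
            phi, _ = _solve_system(A, b, ~fixed, np.zeros(N), N, 1e-12, 40000)
            phis.append(phi)
        fixed = np.zeros(N, bool)
        fixed[0] = True
        both, _ = _solve_system(A, sources[0] + sources[1], ~fixed,
                                np.zeros(N), N, 1e-12, 40000)
        expect = phis[0] + phis[1]
        err = both - expect
        err -= err.mean()
        assert np.abs(err).max() < 1e-8 * np.abs(expect).max()

    def test_unit_current_scaling_exact(self, small_basis):
        f1 = small_basis.pair_field("C3", "C4", current_mA=1.0)
        f2 = small_basis.pair_field("C3", "C4", current_mA=2.0)
        assert np.array_equal(f2, 2.0 * f1)

    def test_reference_field_is_zero(self, small_basis):
        assert np.all(small_basis.field_of("Cz") == 0)

    def test_each_solve_normalized_to_unit_current(self, small_basis):
        for lab, info in small_basis.meta["solves"].items():
            assert info["injected_current_A"] > 0
            assert info["residual"] <= 1e-9
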