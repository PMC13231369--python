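"""Apparent molar volume / compressibility against independent total-property oracles."""

import numpy as np
import pytest

from solvatherm.apparent_properties import (
    apparent_molar_volume,
    isentropic_compressibility,
    apparent_molar_compressibility,
    propagate_uncertainty,
    uncertainty_components,
)


def volume_oracle(m, rho, rho0, M):
    # volume of solution holding 1 kg solvent, minus solvent volume, per mole
    return ((1 + m * M) / rho - 1 / rho0) / m


def compressibility_oracle(m, rho, rho0, Ks, Ks0, M):
    return ((1 + m * M) * Ks / rho - Ks0 / rho0) / m


class TestApparentMolarVolume:
    def test_density_match_limit(self):
        # rho == rho0 leaves only the intrinsic M/rho term
        assert apparent_molar_volume(0.2, 997.0, 997.0, 0.11912) == pytest.approx(
            0.11912 / 997.0, rel=1e-14)

    def test_known_value_from_oracle(self):
        v = apparent_molar_volume(0.1, 998.000, 997.047, 0.11912)
        assert v == pytest.approx(1.0978e-4, rel=1e-4)
        assert v == pytest.approx(volume_oracle(0.1, 998.000, 997.047, 0.11912), rel=1e-14)

    def test_linearity_in_density_difference(self):
        # at fixed rho*rho0 the excess term is linear in (rho - rho0)
        m, M = 0.1, 0.11912
        v1 = apparent_molar_volume(m, 998.0, 997.0, M)
        shift = 0.5
        v2 = apparent_molar_volume(m, 998.0 + shift, 997.0, M)
        expected = (M / (998.0 + shift) - M / 998.0) - shift / (m * (998.0 + shift) * 998.0)
        assert v2 - v1 == pytest.approx(expected, rel=1e-10)

    def test_undefined_at_infinite_dilution(self):
        with pytest.raises(ValueError, match="infinite dilution"):
            apparent_molar_volume(0.0, 998.0, 997.0, 0.11912)

    def test_oracle_equivalence_on_random_inputs(self, rng):
        for _ in range(1000):
            m = rng.uniform(0.01, 0.5)
            rho0 = rng.uniform(900, 1100)
            rho = rho0 + rng.uniform(-2, 5)
            M = rng.uniform(0.05, 0.3)
            got = apparent_molar_volume(m, rho, rho0, M)
            want = volume_oracle(m, rho, rho0, M)
            assert got == pytest.approx(want, rel=1e-12)


class TestIsentropicCompressibility:
    @pytest.mark.parametrize("u,rho,expected,rel", [
        (1000.0, 1000.0, 1.0e-9, 1e-14),
        (1496.7, 997.047, 4.477e-10, 1e-3),
    ])
    def test_values(self, u, rho, expected, rel):
        assert isentropic_compressibility(u, rho) == pytest.approx(expected, rel=rel)

    def test_scaling_invariance(self):
        # (u, rho) and (k*u, rho/k^2) give equal K_s
        k = 1.7
        assert isentropic_compressibility(1500.0, 1000.0) == pytest.approx(
            isentropic_compressibility(1500.0 * k, 1000.0 / k**2), rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            isentropic_compressibility(-1.0, 1000.0)


class TestApparentMolarCompressibility:
    def test_baseline_match_limit(self):
        Ks0, rho0, M = 4.48e-10, 997.0, 0.11912
        got = apparent_molar_compressibility(0.1, rho0, rho0, Ks0, Ks0, M)
        assert got == pytest.approx(M * Ks0 / rho0, rel=1e-12)

    def test_negative_when_hydration_shell_stiffer(self):
        # Ks*rho0 < Ks0*rho with small intrinsic term forces K_phi_s < 0
        got = apparent_molar_compressibility(0.1, 998.0, 997.0, 4.40e-10, 4.48e-10, 0.11912)
        assert got < 0

    def test_oracle_equivalence_on_random_inputs(self, rng):
        for _ in range(1000):
            m = rng.uniform(0.01, 0.5)
            rho0 = rng.uniform(900, 1100)
            rho = rho0 + rng.uniform(-2, 5)
            Ks0 = rng.uniform(3e-10, 6e-10)
            Ks = Ks0 * rng.uniform(0.9, 1.1)
            M = rng.uniform(0.05, 0.3)
            got = apparent_molar_compressibility(m, rho, rho0, Ks, Ks0, M)
            want = compressibility_oracle(m, rho, rho0, Ks, Ks0, M)
            assert got == pytest.approx(want, rel=1e-12)


class TestUncertaintyPropagation:
    ARGS = dict(m_A=0.1, rho=998.0, rho0=997.0, u=1500.0, u0=1497.0, M=0.11912)

    def test_zero_in_zero_out(self):
        sV, sK = propagate_uncertainty(**self.ARGS, sigma_rho=0.0, sigma_u=0.0)
        assert sV == 0.0 and sK == 0.0

    def test_matches_finite_difference_jacobian(self):
        # numerical-jacobian oracle; agreement to 1% at instrument-scale noise
        srho, su = 0.05, 0.4
        sV, sK = propagate_uncertainty(**self.ARGS, sigma_rho=srho, sigma_u=su)
        from solvatherm.apparent_properties import (apparent_molar_volume as V,
                                                    isentropic_compressibility as C,
                                                    apparent_molar_compressibility as K)
        a = self.ARGS

        def fV(rho, rho0):
            return V(a["m_A"], rho, rho0, a["M"])

        def fK(rho, rho0, u, u0):
            return K(a["m_A"], rho, rho0, C(u, rho), C(u0, rho0), a["M"])

        h = 1e-4
        dV = [(fV(a["rho"] + h, a["rho0"]) - fV(a["rho"] - h, a["rho0"])) / (2 * h),
              (fV(a["rho"], a["rho0"] + h) - fV(a["rho"], a["rho0"] - h)) / (2 * h)]
        num_sV = np.hypot(dV[0] * srho, dV[1] * srho)
        assert sV == pytest.approx(num_sV, rel=0.01)

        grads = []
        for i, name in enumerate(["rho", "rho0", "u", "u0"]):
            args_p = {k: a[k] for k in ["rho", "rho0", "u", "u0"]}
            args_m = dict(args_p)
            args_p[name] += h
            args_m[name] -= h
            grads.append((fK(**args_p) - fK(**args_m)) / (2 * h))
        sig = [srho, srho, su, su]
        num_sK = np.sqrt(sum((g * s) ** 2 for g, s in zip(grads, sig)))
        assert sK == pytest.approx(num_sK, rel=0.01)

    def test_sigma_scales_inversely_with_molality(self):
        sV1, _ = propagate_uncertainty(**{**self.ARGS, "m_A": 0.01},
                                       sigma_rho=0.05, sigma_u=0.4)
        sV2, _ = propagate_uncertainty(**{**self.ARGS, "m_A": 0.02},
                                       sigma_rho=0.05, sigma_u=0.4)
        assert sV1 / sV2 == pytest.approx(2.0, rel=0.01)

    def test_components_recombine_to_total(self):
        srho, su = 0.05, 0.4
        sV, sK = propagate_uncertainty(**self.ARGS, sigma_rho=srho, sigma_u=su)
        c = uncertainty_components(**self.ARGS, sigma_rho=srho, sigma_u=su)
        assert np.hypot(c["sigma_V_sol"], c["gV_rho0"]) == pytest.approx(sV, rel=1e-12)
        total_K = np.sqrt(c["sigma_K_sol"]**2 + c["gK_rho0"]**2 + c["gK_u0"]**2)
        assert total_K == pytest.approx(sK, rel=1e-12)

    def test_rejects_negative_sigma(self):
        with pytest.raises(ValueError):
            propagate_uncertainty(**self.ARGS, sigma_rho=-0.1, sigma_u=0.4)
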