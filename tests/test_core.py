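import dataclasses

import numpy as np
import pytest

from stenpol.core import (IntegrationError, MembraneState, initial_state,
                          langevin_amplitude, periodic_laplacian,
                          reaction_terms, simulate, step)
from stenpol.meanfield import activation_threshold, basal_equilibrium, rhs
from stenpol.params import (FeedbackSpec, Lattice, ModelSpec, SimSettings,
                            StenParams)

P = StenParams()


def uniform_state(ras=0.0, pip2=0.0, pkb=0.0, n=16):
    return MembraneState(ras=np.full(n, float(ras)),
                         pip2=np.full(n, float(pip2)),
                         pkb=np.full(n, float(pkb)))


class TestReactionTerms:
    def test_zero_state_gains(self):
        terms = reaction_terms(uniform_state(), P)
        g, l = terms["ras"]
        assert g == pytest.approx(P.a3 + P.a5)        # 0.2851 uM/s
        assert np.all(l == 0)
        for sp in ("pip2", "pkb"):
            _, loss = terms[sp]
            assert np.all(loss == 0)

    def test_high_pip2_shuts_production(self):
        terms = reaction_terms(uniform_state(pip2=1e6), P)
        assert terms["ras"][0] == pytest.approx(P.a5, rel=1e-6)

    def test_negative_concentration_rejected(self):
        st = uniform_state()
        st.ras[0] = -1.0
        with pytest.raises(ValueError):
            reaction_terms(st, P)

    def test_equilibrium_balances_every_species(self):
        # independent oracle: root of the coupled well-mixed system
        pt = basal_equilibrium(ModelSpec())
        assert pt.residual < 1e-10
        st = uniform_state(pt.ras, pt.pip2, pt.pkb)
        for sp, (g, l) in reaction_terms(st, P).items():
            assert np.allclose(g, l, atol=1e-10)


class TestLangevinAmplitude:
    def test_zero_reactions_zero_noise(self):
        assert np.all(langevin_amplitude(np.zeros(5), np.zeros(5), 0.5) == 0)

    def test_pkb_worked_example(self):
        # PKB at 1 uM with Ras at 1 uM: alpha*sqrt(c1 + c2)
        amp = langevin_amplitude(np.array([P.c2]), np.array([P.c1]), P.alpha)
        assert amp[0] == pytest.approx(0.091 * np.sqrt(0.0186 + 0.2160),
                                       abs=1e-5)
        assert amp[0] == pytest.approx(0.04408, abs=1e-5)

    def test_alpha_scales_increment_std(self):
        # doubling alpha doubles the Monte-Carlo std of the increments
        rng = np.random.default_rng(0)
        z = rng.standard_normal(10_000)
        g, l = np.full_like(z, 0.3), np.full_like(z, 0.1)
        s1 = np.std(langevin_amplitude(g, l, 0.091) * z)
        s2 = np.std(langevin_amplitude(g, l, 0.182) * z)
        assert s2 / s1 == pytest.approx(2.0, rel=1e-12)


class TestPeriodicLaplacian:
    def test_constant_field_is_flat(self):
        assert np.allclose(periodic_laplacian(np.full(32, 3.7), 0.25), 0.0)

    def test_lattice_sum_conserved(self):
        rng = np.random.default_rng(1)
        f = rng.random(64)
        assert periodic_laplacian(f, 0.5).sum() == pytest.approx(0.0, abs=1e-10)

    def test_cosine_eigenvector(self):
        # independent oracle: dense circulant matrix
        n, k, dx = 16, 1, 0.25
        f = np.cos(2 * np.pi * k * np.arange(n) / n)
        lam = -(2 - 2 * np.cos(2 * np.pi * k / n)) / dx ** 2
        mat = np.zeros((n, n))
        for i in range(n):
            mat[i, i] = -2 / dx ** 2
            mat[i, (i - 1) % n] = mat[i, (i + 1) % n] = 1 / dx ** 2
        assert np.allclose(mat @ f, lam * f, atol=1e-12)
        assert np.allclose(periodic_laplacian(f, dx), lam * f, atol=1e-12)


class TestStep:
    def test_equilibrium_is_noise_free_fixed_point(self):
        model = ModelSpec(sten=dataclasses.replace(P, alpha=0.0))
        st = initial_state(model, Lattice(n_points=16))
        out = step(st, model, dt=0.01, dx=0.25)
        for sp in ("ras", "pip2", "pkb"):
            before, after = getattr(st, sp), getattr(out, sp)
            assert np.allclose(after, before, atol=1e-12)

    def test_matches_compiled_kernel(self):
        # same Gaussian increments through both implementations
        model = ModelSpec(feedback=FeedbackSpec.model1(0.6, 0.4))
        lat = Lattice(n_points=32)
        st = initial_state(model, lat)
        rng = np.random.default_rng(3)
        z = {sp: rng.standard_normal(32)
             for sp in ("ras", "pip2", "pkb", "pact", "pmyo")}
        ref = step(st, model, dt=0.01, dx=lat.dx, noise=z)

        from stenpol import _kernel
        from stenpol.core import _flags, _par_vector
        arrs = {sp: getattr(st, sp).copy() for sp in
                ("ras", "pip2", "pkb", "pact", "pmyo")}
        zero = np.zeros(32)
        _kernel.advance_chunk(
            arrs["ras"], arrs["pip2"], arrs["pkb"], arrs["pact"],
            arrs["pmyo"], st.pten, zero.copy(), zero.copy(),
            z["ras"][None], z["pip2"][None], z["pkb"][None],
            z["pact"][None], z["pmyo"][None],
            _par_vector(model), 0.01, lat.dx, *_flags(model.feedback))
        for sp in ("ras", "pip2", "pkb", "pact", "pmyo"):
            assert np.allclose(arrs[sp], getattr(ref, sp), rtol=1e-12,
                               atol=1e-15), sp

    def test_noise_free_excursion_returns_to_rest(self):
        # supra-threshold kick fires and comes back; sub-threshold does not
        model = ModelSpec(sten=dataclasses.replace(P, alpha=0.0))
        pt = basal_equilibrium(model)
        # small probe resolves the excitability knee of the bare network
        thr = activation_threshold(model, pt, probe=0.2)
        lat = Lattice(n_points=16)
        settings = SimSettings(duration=600.0, seed=0, lattice=lat)

        def peak_and_final(delta):
            st = initial_state(model, lat)
            st.ras += delta           # uniform kick = well-mixed dynamics
            kymo = simulate(model, settings, initial=st)
            return kymo["ras"].max(), kymo["ras"][:, -1].max()

        peak_hi, final_hi = peak_and_final(3.0 * thr)
        peak_lo, _ = peak_and_final(0.3 * thr)
        assert peak_hi > 10 * peak_lo              # all-or-none response
        assert final_hi < 5 * pt.ras               # returned to rest


class TestSimulate:
    def test_zero_duration_returns_initial_column(self, bare_model):
        kymo = simulate(bare_model, SimSettings(duration=0.0, seed=0))
        assert kymo["ras"].shape[1] == 1
        pt = basal_equilibrium(bare_model)
        assert np.allclose(kymo["ras"][:, 0], pt.ras)

    def test_determinism_bitwise(self, bare_model):
        s = SimSettings(duration=30.0, seed=42)
        k1 = simulate(bare_model, s)
        k2 = simulate(bare_model, s)
        for sp in k1.data:
            assert np.array_equal(k1[sp], k2[sp])

    def test_different_seeds_differ(self, bare_model):
        k1 = simulate(bare_model, SimSettings(duration=30.0, seed=1))
        k2 = simulate(bare_model, SimSettings(duration=30.0, seed=2))
        assert not np.array_equal(k1["ras"], k2["ras"])

    def test_non_negativity(self, baseline_runs):
        for kymo in baseline_runs:
            for sp, arr in kymo.data.items():
                assert (arr >= 0).all(), sp

    def test_ras_pip2_anticorrelated(self, baseline_runs):
        for kymo in baseline_runs:
            r = np.corrcoef(kymo["ras"].ravel(), kymo["pip2"].ravel())[0, 1]
            assert r < -0.2

    def test_noise_free_uniform_converges_to_mean_field(self):
        model = ModelSpec(sten=dataclasses.replace(P, alpha=0.0))
        pt = basal_equilibrium(model)
        lat = Lattice(n_points=16)
        st = initial_state(model, lat)
        st.ras *= 1.05                      # start slightly off equilibrium
        settings = SimSettings(duration=4000.0, record_interval=100.0,
                               seed=0, lattice=lat)
        kymo = simulate(model, settings, initial=st)
        for sp, val in (("ras", pt.ras), ("pip2", pt.pip2), ("pkb", pt.pkb)):
            assert np.max(np.abs(kymo[sp][:, -1] - val)) < 1e-6
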