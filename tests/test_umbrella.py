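import numpy as np
import pytest

from fgpore.builder import make_free_cargo_system, make_inert_cargo
from fgpore.dynamics import LangevinParams
from fgpore.umbrella import (
    PMFProfile,
    UmbrellaWindow,
    WhamError,
    WindowSamples,
    convergence_report,
    plan_windows,
    run_window,
    synthetic_window_samples,
    wham,
)
from fgpore.units import KBT_300


class TestPlanWindows:
    def test_counting(self):
        windows = plan_windows(27.0, -5.0, 2.0)
        assert len(windows) == 17

    def test_default_stiffness_formula(self):
        w = plan_windows(0.0, 6.0, 1.5)[0]
        assert w.bias_stiffness == pytest.approx(4.0 * KBT_300 / 1.5**2, rel=1e-9)
        assert w.bias_stiffness == pytest.approx(4.43, abs=0.01)

    def test_reversed_ends_normalised(self):
        a = plan_windows(0.0, 6.0, 1.5)
        b = plan_windows(6.0, 0.0, 1.5)
        assert [w.center for w in a] == [w.center for w in b]

    def test_oversized_spacing_gives_single_window(self):
        assert len(plan_windows(0.0, 1.0, 5.0)) == 1

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            plan_windows(0.0, 1.0, 0.0)

    def test_equilibration_fraction(self):
        w = plan_windows(0.0, 4.0, 1.0, n_steps=10000)[0]
        assert w.equilibration_steps == 2000


class TestRunWindow:
    @pytest.fixture()
    def free_setup(self, ff):
        topo = make_free_cargo_system(make_inert_cargo(2.0), center=(0, 0, 3.0), params=ff)
        lang = LangevinParams(seed=21, friction=2.0)
        return topo, lang

    def test_stiff_bias_centers_samples(self, ff, free_setup):
        topo, lang = free_setup
        w = UmbrellaWindow(center=3.0, bias_stiffness=200.0, n_steps=20000,
                           equilibration_steps=2000, seed=21)
        s = run_window(topo, w, ff, lang, cargo_mass=12.0, cargo_friction=1.0)
        se = s.values.std() / np.sqrt(len(s.values) / 20)
        assert abs(s.values.mean() - 3.0) < 4 * se + 0.01

    def test_variance_matches_boltzmann(self, ff, free_setup):
        topo, lang = free_setup
        k = 50.0
        w = UmbrellaWindow(center=3.0, bias_stiffness=k, n_steps=60000,
                           equilibration_steps=4000, seed=22)
        s = run_window(topo, w, ff, lang, cargo_mass=12.0, cargo_friction=1.0)
        assert s.values.var() == pytest.approx(KBT_300 / k, rel=0.2)

    def test_determinism(self, ff):
        outs = []
        for _ in range(2):
            topo = make_free_cargo_system(make_inert_cargo(2.0), center=(0, 0, 1.0), params=ff)
            lang = LangevinParams(seed=5, friction=2.0)
            w = UmbrellaWindow(center=1.0, bias_stiffness=50.0, n_steps=2000,
                               equilibration_steps=400, seed=5)
            outs.append(run_window(topo, w, ff, lang).values)
        assert np.array_equal(outs[0], outs[1])

    def test_unknown_coordinate(self, ff, free_setup):
        topo, lang = free_setup
        w = UmbrellaWindow(center=0.0, bias_stiffness=10.0)
        with pytest.raises(ValueError):
            run_window(topo, w, ff, lang, coord="phi")


class TestWham:
    def test_flat_potential_recovers_flat_pmf(self):
        rng = np.random.default_rng(3)
        flat = lambda z: np.zeros_like(np.asarray(z, dtype=float))  # noqa: E731
        windows = plan_windows(-2.0, 2.0, 0.5, n_steps=0)
        samples = [
            synthetic_window_samples(flat, w, 4000, rng, -3.0, 3.0) for w in windows
        ]
        prof = wham(samples, bin_width=0.2, n_bootstrap=30, min_counts=50,
                    rng=np.random.default_rng(4))
        ok = np.isfinite(prof.G) & (np.abs(prof.z) <= 2.0)
        spread = prof.G[ok].max() - prof.G[ok].min()
        assert spread < 6 * prof.sigma[ok].mean()

    def test_harmonic_oracle_rmsd(self):
        kappa = 2.0
        U = lambda z: 0.5 * kappa * np.asarray(z) ** 2  # noqa: E731
        rng = np.random.default_rng(7)
        windows = plan_windows(-3.0, 3.0, 0.75, n_steps=0)
        samples = [
            synthetic_window_samples(U, w, 6000, rng, -4.5, 4.5) for w in windows
        ]
        prof = wham(samples, bin_width=0.1, n_bootstrap=0, min_counts=50)
        ok = np.isfinite(prof.G) & (np.abs(prof.z) <= 3.0)
        z, G = prof.z[ok], prof.G[ok]
        ana = U(z)
        off = np.mean(G - ana)
        rmsd = np.sqrt(np.mean((G - ana - off) ** 2))
        assert rmsd < 0.2

    def test_double_well_barrier_within_10_percent(self):
        h = 5.0
        U = lambda z: h * (np.asarray(z) ** 2 - 1.0) ** 2  # noqa: E731
        rng = np.random.default_rng(11)
        windows = plan_windows(-1.4, 1.4, 0.35, n_steps=0)
        samples = [
            synthetic_window_samples(U, w, 8000, rng, -2.0, 2.0) for w in windows
        ]
        prof = wham(samples, bin_width=0.1, n_bootstrap=0, min_counts=50)
        ok = np.isfinite(prof.G)
        z, G = prof.z[ok], prof.G[ok]
        barrier = G[np.abs(z).argmin()] - G.min()
        assert barrier == pytest.approx(h, rel=0.10)

    def test_non_overlap_error_names_gap(self):
        rng = np.random.default_rng(1)
        U = lambda z: np.zeros_like(np.asarray(z, dtype=float))  # noqa: E731
        w1 = UmbrellaWindow(center=0.0, bias_stiffness=500.0)
        w2 = UmbrellaWindow(center=5.0, bias_stiffness=500.0)
        samples = [
            synthetic_window_samples(U, w1, 500, rng, -1.0, 1.0),
            synthetic_window_samples(U, w2, 500, rng, 4.0, 6.0),
        ]
        with pytest.raises(WhamError, match="overlap"):
            wham(samples, bin_width=0.2)

    def test_split_window_invariance(self):
        """Splitting any window's samples into two half-windows with the
        same bias leaves the PMF unchanged up to the additive reference."""
        kappa = 2.0
        U = lambda z: 0.5 * kappa * np.asarray(z) ** 2  # noqa: E731
        rng = np.random.default_rng(5)
        windows = plan_windows(-2.0, 2.0, 0.5, n_steps=0)
        samples = [
            synthetic_window_samples(U, w, 4000, rng, -3.5, 3.5) for w in windows
        ]
        prof_a = wham(samples, bin_width=0.2, n_bootstrap=0, min_counts=1)
        split = []
        for s in samples:
            half = len(s.values) // 2
            split.append(WindowSamples(window=s.window, values=s.values[:half]))
            split.append(WindowSamples(window=s.window, values=s.values[half:]))
        prof_b = wham(split, bin_width=0.2, n_bootstrap=0, min_counts=1)
        ok = np.isfinite(prof_a.G) & np.isfinite(prof_b.G)
        diff = prof_a.G[ok] - prof_b.G[ok]
        assert np.abs(diff - diff.mean()).max() < 1e-6

    def test_bin_width_robustness_of_barrier(self):
        kappa = 2.0
        U = lambda z: 0.5 * kappa * np.asarray(z) ** 2  # noqa: E731
        rng = np.random.default_rng(9)
        windows = plan_windows(-3.0, 3.0, 0.75, n_steps=0)
        samples = [
            synthetic_window_samples(U, w, 6000, rng, -4.5, 4.5) for w in windows
        ]
        outs = {}
        for bw in (0.1, 0.2):
            prof = wham(samples, bin_width=bw, n_bootstrap=20, min_counts=50,
                        rng=np.random.default_rng(12))
            ok = np.isfinite(prof.G)
            z, G = prof.z[ok], prof.G[ok]
            sel = np.abs(z) <= 2.5
            outs[bw] = (G[sel].max() - G[sel].min(), prof.sigma[ok][sel].mean())
        d = abs(outs[0.1][0] - outs[0.2][0])
        assert d < 4 * max(outs[0.1][1], outs[0.2][1])

    def test_single_window(self):
        rng = np.random.default_rng(2)
        U = lambda z: np.zeros_like(np.asarray(z, dtype=float))  # noqa: E731
        w = UmbrellaWindow(center=0.0, bias_stiffness=5.0)
        prof = wham([synthetic_window_samples(U, w, 5000, rng, -3, 3)],
                    bin_width=0.2, n_bootstrap=0)
        assert np.isfinite(prof.G).sum() > 5


class TestPMFProfile:
    def test_shift_reference_region(self):
        z = np.linspace(0, 10, 21)
        prof = PMFProfile(z, z.copy(), np.zeros_like(z))
        shifted = prof.shifted((8.0, 10.0))
        sel = (z >= 8.0) & (z <= 10.0)
        assert np.mean(shifted.G[sel]) == pytest.approx(0.0, abs=1e-12)

    def test_shift_missing_region_raises(self):
        z = np.linspace(0, 10, 21)
        prof = PMFProfile(z, z.copy(), np.zeros_like(z))
        with pytest.raises(ValueError):
            prof.shifted((20.0, 30.0))


class TestConvergenceReport:
    def _prof(self, rng, n):
        U = lambda z: 0.5 * 2.0 * np.asarray(z) ** 2  # noqa: E731
        windows = plan_windows(-2.0, 2.0, 0.5, n_steps=0)
        samples = [synthetic_window_samples(U, w, n, rng, -3.5, 3.5) for w in windows]
        return wham(samples, bin_width=0.2, n_bootstrap=0, min_counts=20)

    def test_identical_campaigns_zero(self):
        prof = self._prof(np.random.default_rng(1), 2000)
        df = convergence_report({"a": prof, "b": prof})
        assert df["max_abs_diff"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_more_sampling_reduces_difference(self):
        # 1X vs a high-sampling anchor, compared to 4X vs the same anchor
        anchor = self._prof(np.random.default_rng(100), 64000)
        d = {}
        for label, n in (("1X", 1000), ("4X", 4000)):
            diffs = []
            for seed in range(4):
                p = self._prof(np.random.default_rng(seed + 1), n)
                diffs.append(
                    convergence_report({"a": anchor, "b": p})["max_abs_diff"].iloc[0]
                )
            d[label] = np.mean(diffs)
        assert d["4X"] < d["1X"]

    def test_mismatched_grids_regrid_with_warning(self):
        p1 = self._prof(np.random.default_rng(1), 2000)
        U = lambda z: 0.5 * 2.0 * np.asarray(z) ** 2  # noqa: E731
        windows = plan_windows(-2.0, 2.0, 0.5, n_steps=0)
        samples = [
            synthetic_window_samples(U, w, 2000, np.random.default_rng(2), -3.5, 3.5)
            for w in windows
        ]
        p2 = wham(samples, bin_width=0.31, n_bootstrap=0, min_counts=20)
        with pytest.warns(UserWarning, match="regridding"):
            df = convergence_report({"a": p1, "b": p2})
        assert len(df) == 1

    def test_requires_two_variants(self):
        with pytest.raises(ValueError):
            convergence_report({"a": None})
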