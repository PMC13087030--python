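"""Kinetic inference: jump-distance fits, survival curves, rate spectra."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from chromodyn.kinetics import (
    DiffusionFit,
    FitError,
    JumpSample,
    RateSpectrum,
    SchemeMismatchError,
    SurvivalData,
    binding_frequency,
    build_survival,
    default_rate_grid,
    fit_grid_spectrum,
    fit_jump_cdf,
    jumps_from_tracks,
    long_bound_fraction,
    state_spectrum,
)
from chromodyn.simulate import IlluminationScheme, KineticParams, Track, simulate_tracks


def _make_track(frames, tau_c, track_id=0, touches_end=False):
    frames = np.asarray(frames)
    return Track(track_id=track_id, cell_id=0, frames=frames,
                 times=frames * tau_c, x=np.zeros(len(frames)),
                 y=np.zeros(len(frames)), touches_movie_end=touches_end)


def _draw_survival(n, amps, ks, a_b, tau, seed, population="event", nmax=400):
    """Track-length sample with P(>= n+1 | >= n) = exp(-(k tau + a_b))."""
    rng = np.random.default_rng(seed)
    ks = np.asarray(ks, dtype=float)
    kinds = rng.choice(len(ks), size=n, p=np.asarray(amps))
    q = np.exp(-(ks[kinds] * tau + a_b))
    lengths = 2 + rng.geometric(1.0 - np.clip(q, 1e-12, 1 - 1e-12)) - 1
    lengths = np.minimum(lengths, nmax)
    counts = np.array([(lengths >= m).sum() for m in range(2, lengths.max() + 1)])
    return SurvivalData(tau_c=tau, counts=counts, population=population,
                        max_frames=nmax)


# ---------------------------------------------------------------------------
# jump-distance fits


class TestFitJumpCdf:
    def test_single_component_recovers_moment_oracle(self, rng):
        # oracle: for one exponential component, mean(u) = 4 D dt
        dt = 0.01
        u = rng.exponential(0.01, size=10_000)
        fit = fit_jump_cdf(JumpSample(u, dt), n_components=3, n_boot=0, seed=1)
        i = np.argmax(fit.amplitudes)
        assert fit.amplitudes[i] >= 0.95
        d_oracle = np.mean(u) / (4 * dt)
        assert fit.D[i] == pytest.approx(d_oracle, rel=0.05)
        assert fit.amplitudes.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_component_mixture_recovery(self, rng):
        dt = 0.01176
        n = 10_000
        comp = rng.random(n) < 0.4
        scale = np.where(comp, 4 * 0.02 * dt, 4 * 1.0 * dt)
        u = rng.exponential(scale)
        fit = fit_jump_cdf(JumpSample(u, dt), n_components=2, n_boot=0, seed=2)
        assert fit.amplitudes[0] == pytest.approx(0.4, abs=0.05)
        assert np.all(np.diff(fit.D) > 0)

    def test_all_zero_jumps_degenerate(self):
        fit = fit_jump_cdf(JumpSample(np.zeros(100), 0.01), n_boot=0, seed=0)
        assert fit.amplitudes[0] == 1.0
        assert fit.D[0] <= 1e-6
        assert fit.bound_fraction == 1.0

    def test_too_few_jumps_rejected(self):
        with pytest.raises(FitError):
            fit_jump_cdf(JumpSample(np.ones(20), 0.01), n_components=3)

    def test_bootstrap_sd_scales_as_inverse_sqrt_n(self, rng):
        dt = 0.01
        comp = rng.random(32_000) < 0.4
        u = rng.exponential(np.where(comp, 4 * 0.03 * dt, 4 * 1.0 * dt))
        sd = {}
        for n in (2000, 8000):
            fit = fit_jump_cdf(JumpSample(u[:n], dt), n_components=2,
                               n_boot=80, seed=3)
            sd[n] = fit.amplitude_sd[0]
        # quadrupling the jumps should halve the bootstrap s.d. (within 30 %)
        ratio = sd[8000] / sd[2000]
        assert 0.5 * 0.7 <= ratio <= 0.5 * 1.3


# ---------------------------------------------------------------------------
# survival construction


class TestBuildSurvival:
    def test_survival_time_definition_continuous(self):
        scheme = IlluminationScheme.continuous(1000)
        tracks = [_make_track(np.arange(n), scheme.cycle_time, i)
                  for i, n in enumerate([2, 3, 4])]
        sd = build_survival(tracks, scheme)
        assert sd.n_tracks == 3
        np.testing.assert_array_equal(sd.counts, [3, 2, 1])
        np.testing.assert_allclose(np.sort(sd.survival_times()), [0.5, 1.0, 1.5])

    def test_survival_time_definition_timelapse(self):
        scheme = IlluminationScheme.timelapse(100)
        sd = build_survival([_make_track([0, 1, 2], scheme.cycle_time)], scheme)
        assert sd.survival_times()[0] == pytest.approx(21.0)

    def test_scheme_mismatch_rejected(self):
        tracks = [_make_track([0, 1, 2], 0.5)]
        with pytest.raises(SchemeMismatchError):
            build_survival(tracks, IlluminationScheme.timelapse(100))

    def test_censored_tracks_dropped_by_default(self):
        scheme = IlluminationScheme.continuous(10)
        tracks = [_make_track([0, 1, 2], 0.5),
                  _make_track([7, 8, 9], 0.5, track_id=1, touches_end=True)]
        assert build_survival(tracks, scheme).n_tracks == 1
        assert build_survival(tracks, scheme, drop_censored=False).n_tracks == 2

    def test_single_rate_survival_matches_closed_form(self):
        """Empirical survival of unbinding-only time-lapse tracks tracks
        exp(-k t) within the KS 1 % critical distance at n = 5000."""
        k = 0.02
        p = KineticParams(k_bind_T=0, k_bind_S=0, k_off_S=k, p_bleach=0.0)
        scheme = IlluminationScheme.timelapse(120)
        # ~19 % of molecules unbind before their second frame and never
        # form a track, so oversample to keep n >= 5000
        r = simulate_tracks(p, scheme, 6500, seed=9, initial_state="stable")
        sd = build_survival(r.tracks, scheme)
        n = sd.n_tracks
        assert n >= 5000
        t_grid = (np.arange(len(sd.counts)) + sd.n_start - 1) * sd.tau_c
        emp = sd.counts / n
        # compare at the observed grid against the memoryless closed form,
        # both normalized at the first point
        model = np.exp(-k * (t_grid - t_grid[0]))
        ks = np.max(np.abs(emp / emp[0] - model))
        assert ks < 1.63 / np.sqrt(n)


# ---------------------------------------------------------------------------
# rate-spectrum inversion


class TestGridSpectrum:
    def test_single_rate_localizes_on_grid(self):
        s1 = _draw_survival(10_000, [1.0], [0.1], 0.0, 0.5, seed=1)
        s2 = _draw_survival(10_000, [1.0], [0.1], 0.0, 10.5, seed=2)
        spec = fit_grid_spectrum([s1, s2], n_boot=0, seed=3)
        step = np.log(spec.rates[1] / spec.rates[0])
        near = np.abs(np.log(spec.rates / 0.1)) <= 1.01 * step
        assert spec.event_amplitudes[near].sum() >= 0.90
        assert spec.a_b <= 0.02
        assert spec.event_amplitudes.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_rates_with_bleach_match_nonlinear_oracle(self):
        amps, ks, ab = [0.3, 0.7], [0.02, 1.0], 0.3
        s1 = _draw_survival(20_000, amps, ks, ab, 0.5, seed=4)
        s2 = _draw_survival(20_000, amps, ks, ab, 10.5, seed=5)
        spec = fit_grid_spectrum([s1, s2], n_boot=0, seed=6)

        # oracle: direct 2-exponential + shared bleach nonlinear fit
        def model(x, a1, k1, k2, b):
            n, tau = x
            lam1 = k1 * tau + b
            lam2 = k2 * tau + b
            return (a1 * np.exp(-lam1 * (n - 2)) + (1 - a1) * np.exp(-lam2 * (n - 2)))

        xs, ys = [], []
        for sd in (s1, s2):
            n = np.arange(len(sd.counts)) + 2.0
            xs.append(np.column_stack([n, np.full(len(n), sd.tau_c)]))
            ys.append(sd.counts / sd.counts[0])
        x = np.concatenate(xs).T
        y = np.concatenate(ys)
        popt, _ = curve_fit(model, x, y, p0=[0.5, 0.05, 0.5, 0.2],
                            bounds=([0, 1e-4, 1e-4, 0], [1, 10, 10, 2]))
        k_slow_oracle = min(popt[1], popt[2])
        k_fast_oracle = max(popt[1], popt[2])

        ev = spec.event_amplitudes
        slow = np.abs(np.log(spec.rates / ks[0])) <= np.log(3)
        fast = np.abs(np.log(spec.rates / ks[1])) <= np.log(3)
        k_slow = np.sum(spec.rates[slow] * ev[slow]) / ev[slow].sum()
        k_fast = np.sum(spec.rates[fast] * ev[fast]) / ev[fast].sum()
        assert k_slow == pytest.approx(k_slow_oracle, rel=0.15)
        assert k_fast == pytest.approx(k_fast_oracle, rel=0.15)
        assert spec.a_b == pytest.approx(ab, rel=0.2)
        st = spec.state_amplitudes
        s_true = (amps[0] / ks[0]) / (amps[0] / ks[0] + amps[1] / ks[1])
        assert st[slow].sum() == pytest.approx(s_true, abs=0.10)

    def test_unbinding_faster_than_grid_concentrates_at_maximum(self):
        s1 = _draw_survival(5000, [1.0], [30.0], 0.0, 0.5, seed=7)
        s2 = _draw_survival(5000, [1.0], [30.0], 0.0, 10.5, seed=8)
        spec = fit_grid_spectrum([s1, s2], n_boot=0, seed=9)
        top_decade = spec.rates >= spec.rates.max() / 10
        assert spec.event_amplitudes[top_decade].sum() >= 0.9

    def test_single_scheme_rejected(self):
        sd = _draw_survival(1000, [1.0], [0.1], 0.0, 0.5, seed=1)
        with pytest.raises(FitError):
            fit_grid_spectrum([sd], n_boot=0)
        with pytest.raises(FitError):
            fit_grid_spectrum([sd, sd], n_boot=0)   # identical cycle times

    def test_empty_grid_rejected(self):
        s1 = _draw_survival(1000, [1.0], [0.1], 0.0, 0.5, seed=1)
        s2 = _draw_survival(1000, [1.0], [0.1], 0.0, 10.5, seed=2)
        with pytest.raises(FitError):
            fit_grid_spectrum([s1, s2], rate_grid=np.array([]), n_boot=0)

    def test_nnls_beats_two_exponential_oracle_at_true_bleach(self):
        """At the true bleach number, the grid fit's weighted SSE cannot
        exceed a two-exponential fit's: the grid nests it."""
        from chromodyn.kinetics import _Curve, _scan_sse, _survival_counts

        amps, ks, ab = [0.4, 0.6], [0.05, 0.8], 0.25
        sds = [_draw_survival(5000, amps, ks, ab, tau, seed=i)
               for i, tau in enumerate([0.5, 10.5])]
        curves = []
        for sd in sds:
            nf, y = _survival_counts(sd)
            curves.append(_Curve(nf, y, sd.tau_c, sd.exposure, sd.population))
        rates = default_rate_grid()
        _, _, sse_grid = _scan_sse(curves, rates, ab)
        # oracle restricted to exactly two grid rates nearest the truth
        two = np.array([rates[np.argmin(np.abs(np.log(rates / k)))] for k in ks])
        _, _, sse_two = _scan_sse(curves, two, ab)
        assert sse_grid <= sse_two + 1e-9

    def test_bootstrap_errors_shrink_with_more_tracks(self):
        """Resampling s.d. of the recovered mean log-rate scales ~ n^(-1/2).

        The error is measured on a smooth functional of the spectrum (the
        amplitude-weighted mean log rate); per-column amplitude s.d. only
        reflects which neighbouring grid column the sparse mass lands on.
        """
        def mean_lograte_sd(n_tracks, seed0):
            sds = [_draw_survival(n_tracks, [1.0], [0.1], 0.1, tau,
                                  seed=seed0 + i)
                   for i, tau in enumerate([0.5, 10.5])]
            spec = fit_grid_spectrum(sds, n_boot=40, seed=seed0)
            b = spec.bootstrap_amplitudes
            vals = b @ np.log(spec.rates)
            return np.std(vals, ddof=1)

        ratio = mean_lograte_sd(16_000, 10) / mean_lograte_sd(4000, 1)
        assert 0.5 * 0.6 <= ratio <= 0.5 * 1.5


# ---------------------------------------------------------------------------
# state spectrum, long-bound fraction, binding frequency


def _spectrum(rates, event_amps, a_b=0.0):
    rates = np.asarray(rates, float)
    ev = np.asarray(event_amps, float)
    return RateSpectrum(rates=rates, event_amplitudes=ev / ev.sum(), a_b=a_b)


class TestStateSpectrum:
    def test_single_component(self):
        s = state_spectrum(_spectrum([0.1], [1.0]))
        assert s == pytest.approx([1.0])

    def test_hand_weighted_two_rates(self):
        s = state_spectrum(_spectrum([0.1, 1.0], [0.5, 0.5]))
        assert s == pytest.approx([10 / 11, 1 / 11])

    def test_random_spectra_normalize(self, rng):
        for _ in range(20):
            n = rng.integers(2, 30)
            spec = _spectrum(np.sort(rng.uniform(1e-3, 10, n)), rng.random(n) + 1e-6)
            assert state_spectrum(spec).sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self):
        spec = RateSpectrum(rates=np.array([0.1, 1.0]),
                            event_amplitudes=np.zeros(2), a_b=0.0)
        with pytest.raises(FitError):
            state_spectrum(spec)


class TestLongBoundAndFrequency:
    def _fit(self, bound):
        amps = np.array([bound, 1 - bound])
        return DiffusionFit(amplitudes=amps, D=np.array([0.03, 2.0]))

    def test_product_rule(self):
        # state amplitudes 0.5 / 0.5 at residence 100 s and 1 s
        spec = _spectrum([0.01, 1.0], [0.01 * 0.5, 1.0 * 0.5])
        assert state_spectrum(spec) == pytest.approx([0.5, 0.5])
        assert long_bound_fraction(self._fit(0.4), spec) == pytest.approx(0.2)

    def test_all_fast_spectrum_gives_zero(self):
        spec = _spectrum([0.5, 1.0, 5.0], [0.2, 0.5, 0.3])
        assert long_bound_fraction(self._fit(0.4), spec) == 0.0

    def test_flux_balance_symmetric_case(self):
        spec = _spectrum([0.01], [1.0])
        res = binding_frequency(0.5, spec)
        assert res.tau_long == pytest.approx(100.0)
        assert res.tau_search == pytest.approx(100.0)
        assert res.nu == pytest.approx(0.01)
        assert res.nu * res.tau_search == pytest.approx(1.0)

    def test_zero_long_fraction_limit(self):
        spec = _spectrum([0.01], [1.0])
        res = binding_frequency(0.0, spec)
        assert res.nu == 0.0
        assert np.isinf(res.tau_search)

    def test_saturated_long_fraction_rejected(self):
        with pytest.raises(FitError):
            binding_frequency(1.0, _spectrum([0.01], [1.0]))


class TestEndToEnd:
    def test_long_bound_fraction_recovery(self):
        """Planted absolute long-bound fraction recovered within a factor of 2.

        The dissociation-spectrum inversion carries a ~35 % systematic
        envelope on the long-state amplitude at realistic track counts
        (smearing of the transient cluster under the 1/k state weighting),
        so this integration check asserts the factor-2 envelope; the
        tighter tolerance is exercised end-to-end in the acceptance suite.
        """
        from chromodyn.kinetics import infer_kinetics
        from chromodyn.simulate import params_from_occupancies

        p = params_from_occupancies(0.15, 0.15, tau_transient=1.0,
                                    tau_stable=100.0, p_bleach=0.3)
        fast = simulate_tracks(p, IlluminationScheme.fast(1000), 1500, seed=31)
        cont = simulate_tracks(p, IlluminationScheme.continuous(600), 1500, seed=32)
        tl = simulate_tracks(p, IlluminationScheme.timelapse(60), 1500, seed=33)
        res, fit, spec = infer_kinetics(
            fast.tracks, fast.scheme,
            [cont.tracks, tl.tracks], [cont.scheme, tl.scheme],
            n_boot_jumps=0, n_boot_grid=0, seed=0)
        assert res.f_bound == pytest.approx(0.30, abs=0.06)
        assert 0.5 * 0.15 <= res.f_long <= 2.0 * 0.15
        # residence-time envelope at this scale: within a factor of four
        assert 100.0 / 4 <= res.tau_long <= 100.0 * 4

    def test_increasing_off_rate_decreases_recovered_residence(self):
        """Recovered long residence falls strictly across a k_off_S sweep.

        Synthetic survival data with well-separated planted residence
        times (200 s, 50 s, 12.5 s) keep the ordering unambiguous.
        """
        taus = []
        for i, k_s in enumerate([0.005, 0.02, 0.08]):
            sds = [_draw_survival(20_000, [0.3, 0.7], [k_s, 1.0], 0.2, tau,
                                  seed=100 + 10 * i + j)
                   for j, tau in enumerate([0.5, 10.5])]
            spec = fit_grid_spectrum(sds, n_boot=0, seed=i)
            taus.append(spec.mean_residence_time(
                mask=(1 / spec.rates) >= 5.0))
        assert taus[0] > taus[1] > taus[2]

    def test_two_condition_frequency_ratio_recovery(self):
        """Binding-frequency ratio between two planted conditions within 25 %.

        The conditions share the same dissociation spectrum but differ in
        overall bound fraction (0.2 vs 0.5), as a pure change in
        association rate would produce; inference errors on the shared
        spectrum largely cancel in the ratio.
        """
        fits = [DiffusionFit(amplitudes=np.array([f, 1 - f]),
                             D=np.array([0.03, 2.0])) for f in (0.2, 0.5)]
        amps, ks = [0.05, 0.95], [0.01, 1.0]
        nus = []
        for cond, fit in enumerate(fits):
            spec = fit_grid_spectrum(
                [_draw_survival(20_000, amps, ks, 0.25, tau,
                                seed=100 * cond + i)
                 for i, tau in enumerate([0.5, 10.5])], n_boot=0, seed=cond)
            f_long = long_bound_fraction(fit, spec)
            nus.append(binding_frequency(f_long, spec).nu)
        s_long = (amps[0] / ks[0]) / (amps[0] / ks[0] + amps[1] / ks[1])
        f_lo, f_hi = 0.2 * s_long, 0.5 * s_long
        planted = (f_hi / (1 - f_hi)) / (f_lo / (1 - f_lo))
        assert nus[1] / nus[0] == pytest.approx(planted, rel=0.25)


def test_spectrum_and_result_export():
    spec = _spectrum([0.01, 1.0], [0.5, 0.5])
    df = spec.to_frame()
    assert list(df.columns)[:3] == ["rate_per_s", "event_amplitude",
                                    "state_amplitude"]
    assert df["state_amplitude"].sum() == pytest.approx(1.0)
    res = binding_frequency(0.5, _spectrum([0.01], [1.0]))
    d = res.to_dict()
    assert d["nu"] == pytest.approx(0.01)
    assert d["f_bound"] is None   # NaN maps to None for JSON
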