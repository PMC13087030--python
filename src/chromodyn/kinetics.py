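"""Residence-time and binding-frequency inference from single-molecule tracks.

The chain of operations mirrors standard live-cell tracking practice:

1. ``fit_jump_cdf`` — fit the cumulative distribution of squared
   frame-to-frame displacements from fast movies with a multi-component
   diffusion model; the amplitude of the slowest component is the overall
   bound fraction.
2. ``build_survival`` / ``fit_grid_spectrum`` — pool fluorescence survival
   times of bound-molecule tracks from slow movies acquired under at least
   two illumination intervals and invert them into a non-negative spectrum
   of dissociation rates over a fixed log-spaced grid, with a single shared
   per-frame photobleaching number fitted globally (the different cycle
   times separate unbinding, which scales with real time, from bleaching,
   which scales with the illuminated-frame count).
3. ``long_bound_fraction`` / ``binding_frequency`` — combine bound fraction
   and the state-weighted spectrum into the absolute fraction of molecules
   bound longer than a threshold (50 s by default), the mean long residence
   time, and the binding frequency ν = 1 / search time under a three-state
   (free / transient / stable) flux balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .simulate import IlluminationScheme, Track

__all__ = [
    "JumpSample",
    "DiffusionFit",
    "SurvivalData",
    "RateSpectrum",
    "KineticsResult",
    "jumps_from_tracks",
    "fit_jump_cdf",
    "build_survival",
    "fit_grid_spectrum",
    "state_spectrum",
    "long_state_mask",
    "long_bound_fraction",
    "binding_frequency",
    "immobile_prefixes",
    "infer_kinetics",
]


class FitError(ValueError):
    pass


class SchemeMismatchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# jump-distance analysis


@dataclass
class JumpSample:
    """Squared frame-to-frame displacements at a common lag."""

    u: np.ndarray      # squared displacements, µm²
    dt: float          # lag between consecutive illuminated frames, s

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if np.any(self.u < 0):
            raise ValueError("squared displacements must be >= 0")
        if self.dt <= 0:
            raise ValueError("lag dt must be > 0")

    @property
    def n_jumps(self) -> int:
        return len(self.u)


def jumps_from_tracks(tracks: list, scheme: IlluminationScheme) -> JumpSample:
    """Collect squared displacements between consecutive illuminated frames."""
    us = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        consec = np.diff(tr.frames) == 1
        du = np.diff(tr.x) ** 2 + np.diff(tr.y) ** 2
        us.append(du[consec])
    u = np.concatenate(us) if us else np.array([])
    return JumpSample(u=u, dt=scheme.cycle_time)


@dataclass
class DiffusionFit:
    """Multi-component jump-distance fit.

    The bound fraction is the summed amplitude of every component whose
    apparent diffusion coefficient lies at or below ``bound_D_max``; with
    well-separated components this is simply the slowest amplitude A1
    (available as ``A1``), but summing is robust to the fit splitting the
    immobile population — whose apparent motion is localization error plus
    slow chromatin movement — across two slow components.
    """

    amplitudes: np.ndarray          # fractions, sum to 1, slowest first
    D: np.ndarray                   # apparent diffusion coefficients, ascending
    amplitude_sd: np.ndarray | None = None
    D_sd: np.ndarray | None = None
    n_jumps: int = 0
    sse: float = float("nan")
    converged: bool = True
    bound_D_max: float = 0.1        # µm²/s; immobile-component ceiling

    @property
    def A1(self) -> float:
        return float(self.amplitudes[0])

    @property
    def bound_fraction(self) -> float:
        return float(self.amplitudes[self.D <= self.bound_D_max].sum())


def _jump_cdf_model(u, amps, D, dt):
    return 1.0 - np.sum(
        amps[None, :] * np.exp(-u[:, None] / (4.0 * D[None, :] * dt)), axis=1
    )


def _unpack_theta(theta, n_components):
    w = theta[:n_components]
    d = theta[n_components:]
    amps = np.exp(w - w.max())
    amps = amps / amps.sum()
    D = np.cumsum(np.exp(d))
    return amps, D


def _fit_once(u_sorted, f_emp, dt, n_components, theta0):
    def resid(theta):
        amps, D = _unpack_theta(theta, n_components)
        return _jump_cdf_model(u_sorted, amps, D, dt) - f_emp

    sol = least_squares(resid, theta0, method="trf", max_nfev=400)
    return sol


def fit_jump_cdf(
    jumps: JumpSample,
    n_components: int = 3,
    n_boot: int = 400,
    boot_frac: float = 0.8,
    seed: int = 0,
    n_starts: int = 10,
    D_floor: float = 1e-6,
) -> DiffusionFit:
    """Fit F(u) = 1 - sum_i A_i exp(-u / (4 D_i dt)) to the empirical CDF.

    Amplitudes live on the simplex and diffusion coefficients are kept
    strictly ascending by reparameterization (softmax weights, cumulative
    log-increments); the fit is repeated from ``n_starts`` random starting
    points and the lowest residual sum of squares is kept.  Uncertainties
    are the s.d. over ``n_boot`` refits, each on a fraction ``boot_frac``
    of the jumps drawn without replacement, started from the full-data
    solution.
    """
    if jumps.n_jumps < 10 * n_components:
        raise FitError(
            f"need at least {10 * n_components} jumps for {n_components} "
            f"components, got {jumps.n_jumps}"
        )
    rng = np.random.default_rng(seed)
    u_sorted = np.sort(jumps.u)
    n = len(u_sorted)
    f_emp = np.arange(1, n + 1) / n

    if u_sorted[-1] <= 0.0:
        # every jump is zero: all mass in the slowest component at the floor
        amps = np.zeros(n_components)
        amps[0] = 1.0
        return DiffusionFit(
            amplitudes=amps,
            D=D_floor * (1.0 + np.arange(n_components)),
            n_jumps=n, sse=0.0,
        )

    # starting points: one deterministic start spanning the observed u
    # quantiles, the rest randomized around the mean-based scale
    d_scale = max(float(np.mean(u_sorted)) / (4.0 * jumps.dt), D_floor)
    qs = np.quantile(u_sorted[u_sorted > 0], np.linspace(0.1, 0.9, n_components))
    qs = np.maximum(qs / (4.0 * jumps.dt), D_floor)
    starts = [(np.zeros(n_components), np.sort(np.log(qs)))]
    for _ in range(max(n_starts - 1, 0)):
        starts.append((rng.normal(0, 1, n_components),
                       np.sort(np.log(d_scale) + rng.normal(0, 2.0, n_components))))
    best = None
    for w0, logd in starts:
        logd = logd + 1e-6 * np.arange(n_components)   # keep increments positive
        d0 = np.concatenate([[logd[0]], np.log(np.maximum(np.diff(np.exp(logd)), 1e-12))])
        sol = _fit_once(u_sorted, f_emp, jumps.dt, n_components,
                        np.concatenate([w0, d0]))
        if best is None or sol.cost < best.cost:
            best = sol
    amps, D = _unpack_theta(best.x, n_components)
    converged = bool(best.success)

    amp_sd = D_sd = None
    if n_boot > 0:
        m = max(int(round(boot_frac * n)), 10 * n_components)
        boots_a = np.empty((n_boot, n_components))
        boots_d = np.empty((n_boot, n_components))
        for b in range(n_boot):
            idx = rng.choice(n, size=m, replace=False)
            ub = np.sort(jumps.u[idx])
            fb = np.arange(1, m + 1) / m
            sol = _fit_once(ub, fb, jumps.dt, n_components, best.x)
            boots_a[b], boots_d[b] = _unpack_theta(sol.x, n_components)
        amp_sd = boots_a.std(axis=0, ddof=1)
        D_sd = boots_d.std(axis=0, ddof=1)

    return DiffusionFit(
        amplitudes=amps, D=np.maximum(D, D_floor),
        amplitude_sd=amp_sd, D_sd=D_sd,
        n_jumps=n, sse=2.0 * best.cost, converged=converged,
    )


# ---------------------------------------------------------------------------
# survival-time distributions


@dataclass
class SurvivalData:
    """Track survival counts for one illumination scheme.

    ``counts[i]`` is the number of tracks lasting at least ``i + 2``
    illuminated frames, so ``counts[0]`` is the number of usable tracks.

    ``population`` records how the tracks sample the binding-event
    distribution, which sets their amplitude weights in the spectrum fit:

    - ``"event"`` — each track is one binding event (amplitudes are event
      amplitudes as-is);
    - ``"initial"`` — tracks already bound when observation started, a
      length-biased sample whose amplitudes are occupancy-weighted (1/k);
    - ``"later"`` — events initiated during observation, carrying the
      partial-first-cycle detection factor (1 - exp(-k tau_c)) / (k tau_c).
    """

    tau_c: float                 # cycle time, s
    counts: np.ndarray           # N(n) for n = n_start, n_start + 1, ...
    n_censored: int = 0
    scheme_name: str = ""
    population: str = "event"
    max_frames: int = 10**9      # movie length cap for the observable tail
    n_start: int = 2             # shortest tallied track length, frames
    exposure: float = 0.0        # illuminated-frame duration, s
    share_scale: bool = True     # join the shared initial-ensemble scale

    @property
    def n_tracks(self) -> int:
        return int(self.counts[0]) if len(self.counts) else 0

    def survival_times(self) -> np.ndarray:
        """Per-track survival times (n_frames - 1) * tau_c, one per track."""
        lengths = []
        n_at = np.append(self.counts, 0)
        for i in range(len(self.counts)):
            lengths.extend([i + self.n_start] * int(n_at[i] - n_at[i + 1]))
        return (np.asarray(lengths) - 1) * self.tau_c


def build_survival(
    tracks: list,
    scheme: IlluminationScheme,
    drop_censored: bool = True,
    population: str = "event",
    min_frames: int = 2,
    time_tol: float = 1e-6,
) -> SurvivalData:
    """Tally how many tracks last at least n illuminated frames.

    The survival time of a track is (illuminated frames - 1) * cycle time.
    Tracks flagged as touching the end of the movie are censored and
    excluded when ``drop_censored``; a mismatch between the frame spacing
    in the tracks and the scheme's cycle time is rejected.

    ``population`` selects which tracks are tallied and how the spectrum
    fit weights their amplitudes (see :class:`SurvivalData`): ``"initial"``
    keeps only tracks that start on the first movie frame (molecules whose
    binding was already in progress), ``"later"`` keeps the rest, and the
    default ``"event"`` keeps everything and treats each track as one
    binding event.
    """
    if population not in ("event", "initial", "later"):
        raise ValueError(f"unknown population {population!r}")
    lengths = []
    n_censored = 0
    for tr in tracks:
        if len(tr) < 2:
            continue
        if population == "initial" and tr.frames[0] != 0:
            continue
        if population == "later" and tr.frames[0] == 0:
            continue
        spacing = np.diff(tr.times) / np.diff(tr.frames)
        if np.any(np.abs(spacing - scheme.cycle_time) > time_tol * max(1.0, scheme.cycle_time)):
            raise SchemeMismatchError(
                f"track {tr.track_id} spacing {spacing[0]:.4g}s does not match "
                f"cycle time {scheme.cycle_time:.4g}s of scheme '{scheme.name}'"
            )
        if tr.touches_movie_end:
            n_censored += 1
            if drop_censored:
                continue
        # frame span, so a single allowed gap frame still counts as survived
        lengths.append(int(tr.frames[-1] - tr.frames[0] + 1))
    lengths = [n for n in lengths if n >= min_frames]
    if lengths:
        lengths = np.asarray(lengths)
        n_max = lengths.max()
        counts = np.array([(lengths >= n).sum()
                           for n in range(min_frames, n_max + 1)])
    else:
        counts = np.zeros(0, dtype=int)
    return SurvivalData(tau_c=scheme.cycle_time, counts=counts,
                        n_censored=n_censored, scheme_name=scheme.name,
                        population=population, max_frames=scheme.n_frames,
                        n_start=min_frames, exposure=scheme.exposure)


# ---------------------------------------------------------------------------
# dissociation-rate spectrum (inverse Laplace on a fixed grid)


@dataclass
class RateSpectrum:
    """Non-negative dissociation-rate amplitudes over a log-spaced grid.

    ``event_amplitudes`` weight each rate by binding events and sum to 1;
    ``state_amplitudes`` re-weight by residence time (amplitude / rate) and
    describe the instantaneous occupancy of each bound state.  ``a_b`` is
    the shared per-illuminated-frame photobleaching number.
    """

    rates: np.ndarray               # 1/s
    event_amplitudes: np.ndarray
    a_b: float
    sse: float = float("nan")
    event_amplitude_sd: np.ndarray | None = None
    a_b_sd: float | None = None
    bootstrap_amplitudes: np.ndarray | None = None   # (n_boot, K) resampled spectra
    horizon_s: float = float("inf")  # longest observable survival span, s

    @property
    def state_amplitudes(self) -> np.ndarray:
        return state_spectrum(self)

    def to_frame(self) -> pd.DataFrame:
        """Tabular spectrum: rate, event amplitude, state amplitude, s.d."""
        return pd.DataFrame({
            "rate_per_s": self.rates,
            "event_amplitude": self.event_amplitudes,
            "state_amplitude": self.state_amplitudes,
            "event_amplitude_sd": (self.event_amplitude_sd
                                   if self.event_amplitude_sd is not None
                                   else np.full(len(self.rates), np.nan)),
        })

    def mean_residence_time(self, mask=None) -> float:
        """Residence time of the (masked) states: 1 / state-weighted mean rate.

        For a sharp component this equals the state-weighted mean of 1/k;
        for the smeared peaks a grid inversion returns it is far more
        stable, because a mean of 1/k would be dominated by whatever small
        amplitude lands on the slowest grid rates.
        """
        s = self.state_amplitudes
        if mask is not None:
            s = np.where(mask, s, 0.0)
        tot = s.sum()
        if tot == 0:
            return float("nan")
        return float(tot / np.sum(s * self.rates))


def default_rate_grid(k_min: float = 1e-4, k_max: float = 1e1,
                      n: int = 200) -> np.ndarray:
    return np.geomspace(k_min, k_max, n)


def _survival_counts(sd: SurvivalData, n_zero_tail: int = 60):
    """Frame numbers n and counts N(n), including the observed-empty tail.

    Bins just beyond the longest surviving track were observed to be empty;
    keeping them (capped at the movie length) penalizes spectra that
    predict longer-lived tracks than the data contain, which anchors the
    slow end of the rate grid against the bleaching number.
    """
    counts = sd.counts.astype(float)
    if n_zero_tail > 0:
        last = sd.n_start + len(counts)           # first frame count with N = 0
        n_extra = min(n_zero_tail, max(sd.max_frames + 1 - last, 0))
        counts = np.concatenate([counts, np.zeros(n_extra)])
    n_frames = np.arange(sd.n_start, sd.n_start + len(counts))
    return n_frames, counts


class _Curve:
    """One survival curve prepared for the global spectrum fit.

    The model for curve c is ``gamma_{g(c)} * B_c(a_b) @ S`` where S holds
    the shared event amplitudes and ``B_c[n, k] = w_ck * d_ck(n)``:

    - decay ``d_ck(n) = exp(-k ((n-1) tau_c + exposure_c) - a_b (n-1))``,
      the exact probability that a binding event spans the n illuminated
      frames of the track and the fluorophore survives the n-1 bleaching
      checks after the first frame;
    - amplitude weight ``w_ck``: 1/k for tracks already bound at movie
      start (a length-biased, occupancy-weighted sample of events),
      ``(1 - exp(-k tau_c)) / (k tau_c)`` for events initiated during the
      movie (start time uniform within a cycle), 1 when each track is
      taken as one event.

    Scale groups g(c): all "initial" curves share one scale, because the
    same molecule ensemble is observed under every scheme and the relative
    track counts across schemes then pin the bound-state mixture; other
    curves get free individual scales.
    """

    def __init__(self, nf, y, tau_c, exposure, population, share_scale=True):
        self.nf = nf
        self.y = y
        self.tau_c = tau_c
        self.exposure = exposure
        self.population = population
        self.share_scale = share_scale

    def basis(self, rates, a_b):
        nf = self.nf[:, None]
        k = rates[None, :]
        if self.population == "event":
            # one track per event, conditioned on reaching the two-frame
            # minimum: survival decays from the first tallied point
            decay = np.exp(-(k * self.tau_c + a_b) * (nf - float(self.nf[0])))
            w = np.ones_like(rates)
        else:
            decay = np.exp(-k * ((nf - 1.0) * self.tau_c + self.exposure)
                           - a_b * (nf - 1.0))
            if self.population == "initial":
                w = 1.0 / rates
            else:
                x = rates * self.tau_c
                w = -np.expm1(-x) / x
        return decay * w[None, :]


def _group_ids(curves):
    # Slow-scheme "initial" curves share scale 0: the same molecule ensemble
    # is observed under each scheme, so their relative track counts pin the
    # bound-state mixture.  Curves whose tracks went through an extra
    # selection (share_scale=False, e.g. immobile prefixes of fast movies)
    # contribute shape only, through a free scale.
    ids = []
    next_free = 1
    for c in curves:
        if c.population == "initial" and c.share_scale:
            ids.append(0)
        else:
            ids.append(next_free)
            next_free += 1
    return np.asarray(ids), next_free


def _scan_sse(curves, rates, a_b, n_als=12):
    """Non-negative least-squares fit of the shared spectrum at one a_b.

    Counts carry Poisson weights 1/sqrt(max(N, 1)); group scales and the
    NNLS amplitudes are optimized alternately, which decreases the
    weighted residual sum of squares monotonically.
    """
    groups, n_groups = _group_ids(curves)
    bases = [c.basis(rates, a_b) for c in curves]
    weights = [1.0 / np.sqrt(np.maximum(c.y, 1.0)) for c in curves]
    gammas = np.ones(n_groups)
    for g in range(n_groups):
        tot = sum(float(c.y.sum()) for c, gi in zip(curves, groups) if gi == g)
        gammas[g] = max(tot, 1.0)
    s = None
    for _ in range(n_als):
        a_stack = np.vstack([(gammas[gi] * b) * w[:, None]
                             for b, w, gi in zip(bases, weights, groups)])
        y_stack = np.concatenate([c.y * w for c, w in zip(curves, weights)])
        s, _ = nnls(a_stack, y_stack)
        for g in range(n_groups):
            num = den = 0.0
            for c, b, w, gi in zip(curves, bases, weights, groups):
                if gi != g:
                    continue
                m = b @ s
                num += float((w * m) @ (w * c.y))
                den += float((w * m) @ (w * m))
            gammas[g] = num / den if den > 0 else 1.0
    sse = 0.0
    for c, b, w, gi in zip(curves, bases, weights, groups):
        r = w * (c.y - gammas[gi] * (b @ s))
        sse += float(r @ r)
    return s, gammas, sse


def _scan_poisson(curves, rates, a_b, n_iter=400, tol=1e-10):
    """Non-negative Poisson fit of the shared spectrum at one a_b.

    Survival counts are treated as Poisson observations and the
    non-negative amplitudes are found by multiplicative (Richardson-Lucy
    type) updates, which monotonically decrease the Poisson deviance.
    Count noise in the sparse survival tail — where the slow rates live —
    is thereby modeled at its actual scale, where a least-squares
    objective would either ignore or overweight it.
    """
    groups, n_groups = _group_ids(curves)
    bases = [c.basis(rates, a_b) for c in curves]
    s = np.full(len(rates), 1.0 / len(rates))
    gammas = np.ones(n_groups)
    for g in range(n_groups):
        tot = sum(float(c.y.sum()) for c, gi in zip(curves, groups) if gi == g)
        gammas[g] = max(tot, 1.0)
    prev = np.inf
    for it in range(n_iter):
        num = np.zeros_like(s)
        den = np.zeros_like(s)
        for c, b, gi in zip(curves, bases, groups):
            mu = np.maximum(gammas[gi] * (b @ s), 1e-300)
            num += gammas[gi] * (b.T @ (c.y / mu))
            den += gammas[gi] * b.sum(axis=0)
        s = s * num / np.maximum(den, 1e-300)
        for g in range(n_groups):
            ytot = mtot = 0.0
            for c, b, gi in zip(curves, bases, groups):
                if gi != g:
                    continue
                ytot += float(c.y.sum())
                mtot += float((b @ s).sum())
            gammas[g] = ytot / mtot if mtot > 0 else 1.0
        if it % 25 == 24:
            dev = _poisson_deviance(curves, bases, gammas, groups, s)
            if prev - dev < tol * max(prev, 1.0):
                break
            prev = dev
    # multiplicative updates approach zero only asymptotically; clear the
    # residual dust, which the 1/k state weighting would otherwise amplify
    s = np.where(s < 1e-6 * s.sum(), 0.0, s)
    dev = _poisson_deviance(curves, bases, gammas, groups, s)
    return s, gammas, dev


def _poisson_deviance(curves, bases, gammas, groups, s):
    dev = 0.0
    for c, b, gi in zip(curves, bases, groups):
        mu = np.maximum(gammas[gi] * (b @ s), 1e-300)
        y = c.y
        pos = y > 0
        dev += 2.0 * float(np.sum(mu - y)
                           + np.sum(y[pos] * np.log(y[pos] / mu[pos])))
    return dev


def _subsample_survival(sd: SurvivalData, frac: float, rng) -> SurvivalData:
    times = sd.survival_times()
    lengths = np.round(times / sd.tau_c).astype(int) + 1
    m = max(int(round(frac * len(lengths))), 2)
    pick = rng.choice(len(lengths), size=m, replace=False)
    lengths = lengths[pick]
    n_max = lengths.max()
    counts = np.array([(lengths >= n).sum()
                       for n in range(sd.n_start, n_max + 1)])
    return SurvivalData(tau_c=sd.tau_c, counts=counts, scheme_name=sd.scheme_name,
                        population=sd.population, max_frames=sd.max_frames,
                        n_start=sd.n_start, exposure=sd.exposure,
                        share_scale=sd.share_scale)


def fit_grid_spectrum(
    survival_sets: list,
    rate_grid: np.ndarray | None = None,
    n_boot: int = 500,
    boot_frac: float = 0.8,
    seed: int = 0,
    a_b_grid: np.ndarray | None = None,
    objective: str = "ls",
) -> RateSpectrum:
    """Invert survival distributions into a dissociation-rate spectrum.

    Survival fractions from at least two illumination schemes with distinct
    cycle times are fitted jointly with
    ``P_c(>= n frames) ∝ sum_k S_k exp(-(k_k tau_c + a_b) n)``:
    for each candidate photobleaching number ``a_b`` on a scan grid the
    non-negative amplitudes ``S`` are obtained by least squares, and the
    ``a_b`` with the smallest total residual wins.  Amplitudes are then
    normalized to sum 1.  Uncertainties are the s.d. over ``n_boot``
    refits, each on a fraction ``boot_frac`` of tracks drawn without
    replacement (the bleach scan is narrowed around the point estimate for
    the resamples).
    """
    if len(survival_sets) < 2:
        raise FitError("need >= 2 illumination schemes to separate bleaching "
                       "from dissociation")
    taus = [sd.tau_c for sd in survival_sets]
    if len(set(np.round(taus, 9))) < 2:
        raise FitError("schemes must have distinct cycle times")
    for sd in survival_sets:
        if sd.n_tracks < 2:
            raise FitError(f"scheme '{sd.scheme_name}' has too few tracks")
    rates = default_rate_grid() if rate_grid is None else np.asarray(rate_grid, float)
    if len(rates) == 0:
        raise FitError("empty rate grid")
    if a_b_grid is None:
        a_b_grid = np.linspace(0.0, 1.5, 60)

    if objective not in ("poisson", "ls"):
        raise ValueError(f"unknown objective {objective!r}")
    solver = _scan_poisson if objective == "poisson" else _scan_sse

    def point_fit(sds, ab_values):
        curves = []
        for sd in sds:
            nf, y = _survival_counts(sd)
            curves.append(_Curve(nf, y, sd.tau_c, sd.exposure,
                                 sd.population, sd.share_scale))
        best = None
        for ab in ab_values:
            s, gam, sse = solver(curves, rates, ab)
            if best is None or sse < best[2]:
                best = (s, ab, sse)
        return best

    s, a_b, sse = point_fit(survival_sets, a_b_grid)
    if s.sum() <= 0:
        raise FitError("all-zero spectrum: survival data uninformative")
    event_amps = s / s.sum()
    horizon = max((sd.max_frames - 1) * sd.tau_c for sd in survival_sets)

    amp_sd = None
    ab_sd = None
    boot_amps = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        step = a_b_grid[1] - a_b_grid[0] if len(a_b_grid) > 1 else 0.0
        narrow = a_b + step * np.arange(-5, 6)
        narrow = narrow[narrow >= 0.0]
        boots = np.empty((n_boot, len(rates)))
        ab_boot = np.empty(n_boot)
        for b in range(n_boot):
            sub = [_subsample_survival(sd, boot_frac, rng) for sd in survival_sets]
            sb, abb, _ = point_fit(sub, narrow)
            tot = sb.sum()
            boots[b] = sb / tot if tot > 0 else 0.0
            ab_boot[b] = abb
        amp_sd = boots.std(axis=0, ddof=1)
        ab_sd = float(ab_boot.std(ddof=1))
        boot_amps = boots

    return RateSpectrum(rates=rates, event_amplitudes=event_amps, a_b=float(a_b),
                        sse=sse, event_amplitude_sd=amp_sd, a_b_sd=ab_sd,
                        bootstrap_amplitudes=boot_amps, horizon_s=float(horizon))


def state_spectrum(spectrum: RateSpectrum) -> np.ndarray:
    """Residence-time-weighted amplitudes s_k = (S_k / k_k) / sum_j (S_j / k_j).

    Rates slower than 1/horizon — residence times longer than the assay
    could possibly observe — are excluded before weighting: their fitted
    amplitudes are boundary noise of the grid inversion, yet the 1/k
    weight would let a sub-percent artifact dominate the state spectrum.
    """
    if spectrum.event_amplitudes.sum() <= 0:
        raise FitError("cannot normalize an all-zero spectrum")
    ev = spectrum.event_amplitudes
    if np.isfinite(spectrum.horizon_s) and spectrum.horizon_s > 0:
        identifiable = spectrum.rates >= 1.0 / spectrum.horizon_s
        if ev[identifiable].sum() > 0:
            ev = np.where(identifiable, ev, 0.0)
    s_over_k = ev / spectrum.rates
    tot = s_over_k.sum()
    if tot <= 0:
        raise FitError("cannot normalize an all-zero spectrum")
    return s_over_k / tot


# ---------------------------------------------------------------------------
# long-bound fraction and binding frequency


@dataclass
class KineticsResult:
    """End products of the kinetic chain, with propagated uncertainties."""

    f_bound: float
    f_long: float
    tau_long: float           # mean long residence time, s
    tau_search: float         # s; inf when f_long = 0
    nu: float                 # binding frequency, 1/s
    threshold_s: float = 50.0
    f_bound_sd: float | None = None
    f_long_sd: float | None = None
    nu_sd: float | None = None

    def to_dict(self) -> dict:
        """JSON-ready summary of the kinetic chain's end products."""
        return {k: (None if v is None or (isinstance(v, float) and math.isnan(v))
                    else float(v))
                for k, v in self.__dict__.items()}


def long_state_mask(spectrum: RateSpectrum, threshold: float = 50.0) -> np.ndarray:
    """Rates belonging to the long-lived component of the spectrum.

    A grid inversion returns each physical dissociation rate as a cluster
    of adjacent grid rates rather than a single spike, and a cluster
    centred near the threshold would otherwise be cut in half.  A
    contiguous run of nonzero amplitudes is therefore included as a whole
    when its state-weighted mean residence time reaches ``threshold``
    (rates faster than a third of the threshold are never included, so a
    pathologically wide run cannot sweep in short-lived states).  Isolated
    spikes reduce to the plain ``1/k >= threshold`` rule.
    """
    s = spectrum.state_amplitudes
    res = 1.0 / spectrum.rates
    mask = np.zeros(len(s), dtype=bool)
    active = s > 0
    i = 0
    while i < len(s):
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(s) and active[j + 1]:
            j += 1
        run = slice(i, j + 1)
        tau_run = float(np.sum(s[run] * res[run]) / s[run].sum())
        if tau_run >= threshold:
            mask[run] = res[run] >= threshold / 3.0
        i = j + 1
    # states at or beyond the threshold always qualify, whatever run they sit in
    mask |= (res >= threshold) & active
    return mask


def long_bound_fraction(fit: DiffusionFit, spectrum: RateSpectrum,
                        threshold: float = 50.0) -> float:
    """Absolute fraction of molecules bound at least ``threshold`` seconds.

    The product of the overall bound fraction (slowest jump-distance
    amplitude) with the summed state-spectrum amplitude of the long-lived
    spectral component (see :func:`long_state_mask`).
    """
    s = spectrum.state_amplitudes
    return float(fit.bound_fraction * s[long_state_mask(spectrum, threshold)].sum())


def binding_frequency(f_long: float, spectrum: RateSpectrum,
                      threshold: float = 50.0) -> KineticsResult:
    """Search time and binding frequency from the three-state flux balance.

    At steady state a molecule alternates between searching (free or
    transiently bound) and stable binding, so occupancies satisfy
    ``f_long / (1 - f_long) = tau_long / tau_search``.  Hence
    ``tau_search = (1 - f_long) * tau_long / f_long`` and the binding
    frequency is ``nu = 1 / tau_search``; ``f_long = 0`` yields ``nu = 0``
    with an infinite search time.
    """
    if not 0.0 <= f_long < 1.0:
        raise FitError("f_long must lie in [0, 1); f_long = 1 leaves no "
                       "search phase")
    tau_long = spectrum.mean_residence_time(mask=long_state_mask(spectrum, threshold))
    if f_long == 0.0 or not math.isfinite(tau_long):
        return KineticsResult(f_bound=float("nan"), f_long=f_long,
                              tau_long=tau_long, tau_search=float("inf"),
                              nu=0.0, threshold_s=threshold)
    tau_search = (1.0 - f_long) * tau_long / f_long
    return KineticsResult(f_bound=float("nan"), f_long=f_long,
                          tau_long=tau_long, tau_search=tau_search,
                          nu=1.0 / tau_search, threshold_s=threshold)


def immobile_prefixes(tracks: list, cut: float = 0.12) -> list:
    """Truncate each track at its first frame-to-frame jump above ``cut``.

    The surviving prefix is the immobile (chromatin-bound) portion of the
    track: it ends when the molecule unbinds and moves, or bleaches.  Used
    to harvest bound-molecule survival information from fast movies, whose
    short cycle time makes their decay an almost pure photobleaching
    readout that anchors the bleach number in the global spectrum fit.
    """
    out = []
    for tr in tracks:
        jumps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        big = np.flatnonzero(jumps > cut)
        end = int(big[0]) + 1 if len(big) else len(tr)
        if end < 2:
            continue
        out.append(Track(
            track_id=tr.track_id, cell_id=tr.cell_id,
            frames=tr.frames[:end], times=tr.times[:end],
            x=tr.x[:end], y=tr.y[:end],
            true_state=None if tr.true_state is None else tr.true_state[:end],
            touches_movie_end=tr.touches_movie_end and end == len(tr),
        ))
    return out


def infer_kinetics(
    fast_tracks: list,
    fast_scheme: IlluminationScheme,
    slow_track_sets: list,
    slow_schemes: list,
    threshold: float = 50.0,
    rate_grid: np.ndarray | None = None,
    n_boot_jumps: int = 100,
    n_boot_grid: int = 100,
    seed: int = 0,
    use_fast_survival: bool = True,
) -> tuple[KineticsResult, DiffusionFit, RateSpectrum]:
    """Run the full chain: jumps -> bound fraction; survivals -> spectrum;
    combine into long-bound fraction, search time and binding frequency."""
    jumps = jumps_from_tracks(fast_tracks, fast_scheme)
    fit = fit_jump_cdf(jumps, n_boot=n_boot_jumps, seed=seed)
    track_sets = list(slow_track_sets)
    schemes = list(slow_schemes)
    survs = []
    for trs, sch in zip(track_sets, schemes):
        for pop in ("initial", "later"):
            sd = build_survival(trs, sch, population=pop)
            if sd.n_tracks >= 5:
                survs.append(sd)
    if use_fast_survival:
        # immobile prefixes of fast tracks pin the bleaching number; the
        # tally starts at four frames because shorter prefixes still
        # contain free molecules that happened to take small jumps
        fast_imm = immobile_prefixes(fast_tracks)
        for pop in ("initial", "later"):
            sd = build_survival(fast_imm, fast_scheme, population=pop,
                                min_frames=4)
            sd.share_scale = False      # prefix selection changes the count
            if sd.n_tracks >= 5:
                survs.append(sd)
    spectrum = fit_grid_spectrum(survs, rate_grid=rate_grid,
                                 n_boot=n_boot_grid, seed=seed + 1,
                                 objective="poisson")
    f_long = long_bound_fraction(fit, spectrum, threshold)
    res = binding_frequency(f_long, spectrum, threshold)
    res.f_bound = fit.bound_fraction
    if fit.amplitude_sd is not None:
        res.f_bound_sd = float(fit.amplitude_sd[0])
    return res, fit, spectrum
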