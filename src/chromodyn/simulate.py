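"""Stochastic simulator for single-molecule tracking experiments.

Molecules switch between three states — freely diffusing, transiently
chromatin-bound and stably chromatin-bound — as a continuous-time Markov
chain.  Free molecules diffuse inside a reflecting nuclear disk; bound
molecules are immobile up to localization error.  A localization is emitted
once per illuminated camera frame and the fluorophore bleaches with a fixed
probability per illuminated frame, so the same kinetic ground truth can be
observed under fast, continuous and time-lapse illumination schemes.

The emitted localizations are linked into tracks with a nearest-neighbour
radius, mimicking how trackers lose fast movers between long exposures:
under slow illumination only bound molecules yield multi-frame tracks, which
is what residence-time analysis consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KineticParams",
    "IlluminationScheme",
    "Track",
    "SimulationResult",
    "params_from_occupancies",
    "stationary_distribution",
    "simulate_tracks",
    "write_tracks",
    "read_tracks",
]

STATES = ("free", "transient", "stable")
_FREE, _TRANSIENT, _STABLE = 0, 1, 2


class ParameterError(ValueError):
    """Raised for non-finite, negative or otherwise invalid kinetic parameters."""


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetic parameters of the three-state model.

    Rates are in 1/s, lengths in micrometres.  ``p_bleach`` is the
    probability that the fluorophore photobleaches during one illuminated
    frame.  ``sigma_loc`` is the localization error s.d. per axis; it is
    shared by transiently and stably bound molecules (slow chromatin motion
    is folded into it).
    """

    D_free: float = 3.0
    k_bind_T: float = 0.3
    k_bind_S: float = 0.01
    k_off_T: float = 1.0
    k_off_S: float = 0.01
    p_bleach: float = 0.1
    sigma_loc: float = 0.025
    nucleus_radius: float = 5.0

    def __post_init__(self) -> None:
        for name in ("D_free", "k_bind_T", "k_bind_S", "k_off_T", "k_off_S",
                     "p_bleach", "sigma_loc", "nucleus_radius"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v!r}")
        if self.D_free <= 0:
            raise ParameterError("D_free must be > 0")
        if not 0.0 <= self.p_bleach <= 1.0:
            raise ParameterError("p_bleach must lie in [0, 1]")
        if self.nucleus_radius <= 0:
            raise ParameterError("nucleus_radius must be > 0")

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q of the CTMC over (free, transient, stable)."""
        q = np.zeros((3, 3))
        q[_FREE, _TRANSIENT] = self.k_bind_T
        q[_FREE, _STABLE] = self.k_bind_S
        q[_TRANSIENT, _FREE] = self.k_off_T
        q[_STABLE, _FREE] = self.k_off_S
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class IlluminationScheme:
    """Camera illumination pattern: exposure, dark gap and frame count.

    The three named constructors reproduce the standard experimental
    settings: 10 ms continuous acquisition for diffusion analysis, 500 ms
    continuous and 500 ms + 10 s time-lapse for residence-time analysis.
    """

    name: str
    exposure: float
    dark_time: float
    n_frames: int
    track_radius: float = 0.52  # linking radius in µm

    def __post_init__(self) -> None:
        if self.exposure <= 0:
            raise ParameterError("exposure must be > 0")
        if self.dark_time < 0:
            raise ParameterError("dark_time must be >= 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")

    @property
    def cycle_time(self) -> float:
        return self.exposure + self.dark_time

    @classmethod
    def fast(cls, n_frames: int = 1000) -> "IlluminationScheme":
        # 10 ms exposure, no dark time; 4 px * 130 nm linking radius
        return cls("fast", 0.010, 0.0, n_frames, track_radius=0.52)

    @classmethod
    def continuous(cls, n_frames: int = 600) -> "IlluminationScheme":
        # 500 ms exposure, no dark time; 3 px linking radius
        return cls("continuous", 0.500, 0.0, n_frames, track_radius=0.39)

    @classmethod
    def timelapse(cls, n_frames: int = 60) -> "IlluminationScheme":
        # 500 ms exposure alternating with a fixed 10 s dark time
        return cls("timelapse", 0.500, 10.0, n_frames, track_radius=0.65)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cycle_time"] = self.cycle_time
        return d


@dataclass
class Track:
    """One linked trajectory: time-ordered 2-D localizations of a molecule."""

    track_id: int
    cell_id: int
    frames: np.ndarray          # illuminated-frame indices, strictly increasing
    times: np.ndarray           # seconds
    x: np.ndarray               # µm
    y: np.ndarray               # µm
    true_state: np.ndarray | None = None   # hidden labels, synthetic data only
    touches_movie_end: bool = False

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SimulationResult:
    """Tracks plus the exact ground truth of the generating process."""

    tracks: list
    scheme: IlluminationScheme
    params: KineticParams
    occupancy: dict = field(default_factory=dict)       # time-weighted state fractions
    sojourn_means: dict = field(default_factory=dict)   # mean sojourn per state (s)
    sojourn_counts: dict = field(default_factory=dict)
    n_stable_entries: int = 0
    total_time: float = 0.0
    nonstable_time: float = 0.0

    @property
    def bound_fraction(self) -> float:
        return self.occupancy.get("transient", 0.0) + self.occupancy.get("stable", 0.0)

    @property
    def stable_event_rate(self) -> float:
        """Realized entries into the stable state per molecule-second of search.

        The denominator counts time spent outside the stable state, so this
        rate is directly comparable with the binding frequency ν inferred by
        the kinetics pipeline (ν = 1 / mean search time).
        """
        if self.nonstable_time == 0:
            return 0.0
        return self.n_stable_entries / self.nonstable_time


def stationary_distribution(params: KineticParams) -> np.ndarray:
    """Stationary distribution π of the three-state CTMC (solves πQ = 0)."""
    q = params.rate_matrix()
    a = np.vstack([q.T, np.ones(3)])
    b = np.zeros(4)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def params_from_occupancies(
    f_transient: float,
    f_stable: float,
    tau_transient: float,
    tau_stable: float,
    **kwargs,
) -> KineticParams:
    """Build kinetic parameters whose stationary occupancies match targets.

    ``f_transient`` and ``f_stable`` are the desired steady-state fractions
    of time in the transient and stable bound states; the residence times
    (s) set the off-rates and the binding rates follow from detailed
    balance on the star-shaped state graph.
    """
    f_free = 1.0 - f_transient - f_stable
    if f_free <= 0:
        raise ParameterError("bound fractions must sum to < 1")
    k_off_T = 1.0 / tau_transient
    k_off_S = 1.0 / tau_stable
    return KineticParams(
        k_bind_T=f_transient * k_off_T / f_free,
        k_bind_S=f_stable * k_off_S / f_free,
        k_off_T=k_off_T,
        k_off_S=k_off_S,
        **kwargs,
    )


def _sample_ctmc_path(params, t_end, rng, initial_state):
    """Exact CTMC trajectory: list of (state, t_start, t_end) covering [0, t_end]."""
    out_rates = np.array([
        params.k_bind_T + params.k_bind_S,
        params.k_off_T,
        params.k_off_S,
    ])
    path = []
    t = 0.0
    s = initial_state
    while t < t_end:
        rate = out_rates[s]
        dwell = rng.exponential(1.0 / rate) if rate > 0 else t_end - t
        t_next = min(t + dwell, t_end)
        path.append((s, t, t_next))
        t = t_next
        if t >= t_end:
            break
        if s == _FREE:
            p_t = params.k_bind_T / rate
            s = _TRANSIENT if rng.random() < p_t else _STABLE
        else:
            s = _FREE
    return path


def _uniform_disk(radius: float, rng) -> np.ndarray:
    r = radius * math.sqrt(rng.random())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([r * math.cos(phi), r * math.sin(phi)])


def _diffuse(pos: np.ndarray, dt: float, D: float, radius: float, rng) -> np.ndarray:
    """Propagate reflected Brownian motion in a disk over time dt.

    Steps small against the nucleus use a Gaussian displacement with a
    radial fold-back at the boundary; once the step s.d. reaches half the
    nucleus radius the position has effectively equilibrated and is redrawn
    uniformly (the stationary law of reflected Brownian motion).
    """
    if dt <= 0:
        return pos
    sigma = math.sqrt(2.0 * D * dt)
    if sigma >= 0.5 * radius:
        return _uniform_disk(radius, rng)
    pos = pos + rng.normal(0.0, sigma, size=2)
    r = math.hypot(pos[0], pos[1])
    if r > radius:
        pos = pos * (max(2.0 * radius - r, 0.0) / r)
    return pos


def simulate_tracks(
    params: KineticParams,
    scheme: IlluminationScheme,
    n_molecules: int,
    seed: int,
    initial_state: str | None = None,
    blur_radius: float = 0.3,
) -> SimulationResult:
    """Simulate ``n_molecules`` molecules under one illumination scheme.

    Each molecule evolves as a CTMC over (free, transient, stable); free
    molecules diffuse with ``D_free`` inside a reflecting disk, bound
    molecules are frozen at their binding position.  One localization is
    emitted per illuminated frame (evaluated at mid-exposure) with Gaussian
    error ``sigma_loc``; after each illuminated frame the fluorophore
    bleaches with probability ``p_bleach``.  Localizations are linked into
    tracks by the scheme's linking radius; tracks shorter than two frames
    are discarded.  By default the initial state is drawn from the CTMC's
    stationary distribution.

    ``blur_radius`` emulates motion blur: a frame in which the molecule
    accumulated a diffusional r.m.s. displacement above this value during
    the exposure yields no detection.  At 10 ms exposures free molecules
    stay below it and are tracked; at 500 ms exposures they blur out, so
    slow movies only contain bound-molecule tracks, as in the experiment.

    Ground truth in the returned :class:`SimulationResult` is computed from
    the exact state paths, independent of detection or bleaching.
    """
    if n_molecules < 1:
        raise ParameterError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    pi = stationary_distribution(params)
    t_movie = (scheme.n_frames - 1) * scheme.cycle_time + scheme.exposure
    obs_times = np.arange(scheme.n_frames) * scheme.cycle_time + scheme.exposure / 2.0

    tracks: list[Track] = []
    occ_time = np.zeros(3)
    sojourn_sum = np.zeros(3)
    sojourn_n = np.zeros(3, dtype=int)
    n_stable_entries = 0
    track_id = 0

    for mol in range(n_molecules):
        if initial_state is None:
            s0 = int(rng.choice(3, p=pi))
        else:
            s0 = STATES.index(initial_state)
        path = _sample_ctmc_path(params, t_movie, rng, s0)

        for s, t0, t1 in path:
            occ_time[s] += t1 - t0
            sojourn_sum[s] += t1 - t0
            sojourn_n[s] += 1
            # an entry at t=0 is an initial condition, not a binding event
            if s == _STABLE and t0 > 0.0:
                n_stable_entries += 1

        # frames imaged before bleaching: the bleach check runs at the end of
        # each illuminated frame, so a molecule bleaching on frame g-1 still
        # yields g localizations and P(>= n frames) = (1 - p_bleach)^(n-1)
        if params.p_bleach > 0:
            n_obs = min(int(rng.geometric(params.p_bleach)), scheme.n_frames)
        else:
            n_obs = scheme.n_frames
        if n_obs < 1:
            continue

        # propagate position through the state path, emitting one
        # localization per illuminated frame (position at mid-exposure);
        # frames in which the molecule diffused more than blur_radius
        # during the exposure are motion-blurred and yield no detection
        pos = _uniform_disk(params.nucleus_radius, rng)
        frames_emit = []
        locs = []
        states_emit = []
        seg = 0
        t_cur = 0.0
        for j in range(n_obs):
            t_start = j * scheme.cycle_time
            t_mid = obs_times[j]
            t_end = t_start + scheme.exposure
            pos_mid = None
            free_in_exposure = 0.0
            while True:
                s, t0, t1 = path[seg]
                t_stop = min(t1, t_end)
                if t_stop > t_cur:
                    if s == _FREE:
                        if t_cur < t_mid <= t_stop:
                            pos = _diffuse(pos, t_mid - t_cur, params.D_free,
                                           params.nucleus_radius, rng)
                            pos_mid = pos.copy()
                            pos = _diffuse(pos, t_stop - t_mid, params.D_free,
                                           params.nucleus_radius, rng)
                        else:
                            pos = _diffuse(pos, t_stop - t_cur, params.D_free,
                                           params.nucleus_radius, rng)
                        free_in_exposure += max(t_stop - max(t_cur, t_start), 0.0)
                    elif t_cur < t_mid <= t_stop:
                        pos_mid = pos.copy()
                    t_cur = t_stop
                if t_end <= t1 or seg == len(path) - 1:
                    break
                seg += 1
            if pos_mid is None:
                pos_mid = pos.copy()
            blur = math.sqrt(2.0 * params.D_free * free_in_exposure)
            if blur <= blur_radius:
                frames_emit.append(j)
                locs.append((pos_mid[0] + rng.normal(0.0, params.sigma_loc),
                             pos_mid[1] + rng.normal(0.0, params.sigma_loc)))
                # state at mid-exposure
                k = seg
                while k > 0 and path[k][1] > t_mid:
                    k -= 1
                states_emit.append(path[k][0])

        # link localizations into tracks: consecutive detections connect if
        # at most one frame is missing and the jump is within the radius
        n_emit = len(frames_emit)
        if n_emit >= 2:
            fr = np.asarray(frames_emit)
            xy = np.asarray(locs)
            gaps = np.diff(fr)
            jumps = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
            link = (gaps <= 2) & (jumps <= scheme.track_radius)
            breaks = np.flatnonzero(~link)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [n_emit]])
            for a, b in zip(starts, ends):
                if b - a < 2:
                    continue
                tracks.append(Track(
                    track_id=track_id,
                    cell_id=mol,
                    frames=fr[a:b].copy(),
                    times=obs_times[fr[a:b]].copy(),
                    x=xy[a:b, 0].copy(),
                    y=xy[a:b, 1].copy(),
                    true_state=np.array([STATES[k] for k in states_emit[a:b]]),
                    touches_movie_end=(fr[b - 1] == scheme.n_frames - 1),
                ))
                track_id += 1

    total_time = n_molecules * t_movie
    with np.errstate(invalid="ignore"):
        means = np.divide(sojourn_sum, sojourn_n,
                          out=np.zeros(3), where=sojourn_n > 0)
    return SimulationResult(
        tracks=tracks,
        scheme=scheme,
        params=params,
        occupancy={STATES[i]: occ_time[i] / total_time for i in range(3)},
        sojourn_means={STATES[i]: means[i] for i in range(3)},
        sojourn_counts={STATES[i]: int(sojourn_n[i]) for i in range(3)},
        n_stable_entries=n_stable_entries,
        total_time=total_time,
        nonstable_time=total_time - occ_time[_STABLE],
    )


# ---------------------------------------------------------------------------
# track table I/O: TSV of localizations plus a YAML scheme sidecar


def tracks_to_frame(tracks: list) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        n = len(tr)
        rows.append(pd.DataFrame({
            "track_id": np.full(n, tr.track_id),
            "cell_id": np.full(n, tr.cell_id),
            "frame": tr.frames,
            "time_s": tr.times,
            "x_um": tr.x,
            "y_um": tr.y,
            "true_state": tr.true_state if tr.true_state is not None else [""] * n,
            "touches_movie_end": np.full(n, tr.touches_movie_end),
        }))
    if not rows:
        return pd.DataFrame(columns=["track_id", "cell_id", "frame", "time_s",
                                     "x_um", "y_um", "true_state", "touches_movie_end"])
    return pd.concat(rows, ignore_index=True)


def write_tracks(tracks: list, scheme: IlluminationScheme, path) -> None:
    """Write tracks as TSV with a YAML illumination-scheme sidecar."""
    df = tracks_to_frame(tracks)
    df.to_csv(path, sep="\t", index=False)
    with open(str(path) + ".scheme.yaml", "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh)


def read_tracks(path) -> tuple[list, IlluminationScheme]:
    df = pd.read_csv(path, sep="\t")
    with open(str(path) + ".scheme.yaml") as fh:
        d = yaml.safe_load(fh)
    d.pop("cycle_time", None)
    scheme = IlluminationScheme(**d)
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        has_state = "true_state" in grp and grp["true_state"].notna().all()
        tracks.append(Track(
            track_id=int(tid),
            cell_id=int(grp["cell_id"].iloc[0]),
            frames=grp["frame"].to_numpy(),
            times=grp["time_s"].to_numpy(),
            x=grp["x_um"].to_numpy(),
            y=grp["y_um"].to_numpy(),
            true_state=grp["true_state"].to_numpy() if has_state else None,
            touches_movie_end=bool(grp["touches_movie_end"].iloc[0]),
        ))
    return tracks, scheme
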