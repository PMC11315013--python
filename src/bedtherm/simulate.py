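"""Synthetic multi-subject, multi-night bed thermodata.

The simulator produces the signals a smart-bed distal skin temperature (DST)
estimator consumes: a five-sensor mattress temperature strip (T1..T5, ~1 Hz,
0.1 degC resolution), a wrist reference channel (4 Hz, 0.02 degC), and
optional foot/proximal channels (1 sample / 30 s, 0.0625 degC).  The latent
physiology is the classic sleep-onset vasodilation response: distal skin
temperature rises by about 1 degC (proximal by about 0.5 degC) after sleep
onset, modelled as a saturating exponential with a configurable time
constant.  Strip sensors read a contact-weighted mixture of skin and ambient
temperature; contact weights are redrawn at position-change events so that
which sensors touch the body varies within and across nights.

Everything is deterministic given ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhysioParams",
    "ArtifactSpec",
    "RawStream",
    "SessionRecording",
    "StudyFixture",
    "Participant",
    "DemographicSummary",
    "ArtifactCounts",
    "STRIP_CHANNELS",
    "CHANNEL_SPECS",
    "simulate_subject_night",
    "inject_artifacts",
    "simulate_study",
    "summarize_demographics",
]

STRIP_CHANNELS = ("T1", "T2", "T3", "T4", "T5")

#: nominal sampling rate (samples/s) and quantisation step (degC) per channel
CHANNEL_SPECS = {
    "T1": (1.0, 0.1),
    "T2": (1.0, 0.1),
    "T3": (1.0, 0.1),
    "T4": (1.0, 0.1),
    "T5": (1.0, 0.1),
    "wrist": (4.0, 0.02),
    "foot": (1.0 / 30.0, 0.0625),
    "proximal": (1.0 / 30.0, 0.0625),
}


@dataclass(frozen=True)
class PhysioParams:
    """Latent thermophysiology of one sleeper-night.

    Parameters
    ----------
    baseline_dst
        Pre-sleep distal skin temperature, degC.
    distal_rise, proximal_rise
        Magnitude of the post-onset rise at distal and proximal sites, degC.
    rise_timescale
        Time constant of the saturating-exponential rise, minutes.
    sleep_onset_latency
        Minutes from bed entry (or lights-off, in the lab) to sleep onset.
    noise_sd
        Per-sample measurement noise, degC, applied before quantisation.
    fluctuation_amplitude
        Standard deviation (degC) of the slow within-night skin-temperature
        fluctuation (sleep-cycle-scale drifts shared by all skin sites).
        ``None`` ties it to twice ``noise_sd``, so the noise-free limit is
        also fluctuation-free.
    fluctuation_periods
        Periods (minutes) of the two sinusoids composing the fluctuation.
    ambient_temp
        Micro-environment temperature seen by uncovered strip sensors, degC.
    contact_coupling
        Initial weight in [0, 1] per strip sensor: 1 = full skin contact,
        0 = reads ambient only.
    foot_offset
        Constant offset of foot relative to wrist distal temperature, degC.
    proximal_baseline
        Pre-sleep proximal (chest) temperature, degC.
    """

    baseline_dst: float = 31.0
    distal_rise: float = 1.0
    proximal_rise: float = 0.5
    rise_timescale: float = 15.0
    sleep_onset_latency: float = 20.0
    noise_sd: float = 0.15
    fluctuation_amplitude: Optional[float] = None
    fluctuation_periods: tuple = (90.0, 40.0)
    ambient_temp: float = 24.0
    contact_coupling: tuple = (0.95, 0.92, 0.90, 0.45, 0.25)
    foot_offset: float = 0.4
    proximal_baseline: float = 34.0

    def __post_init__(self) -> None:
        if self.distal_rise < 0:
            raise ValueError("distal_rise must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cc = tuple(float(c) for c in self.contact_coupling)
        if len(cc) != 5 or any(not 0.0 <= c <= 1.0 for c in cc):
            raise ValueError("contact_coupling needs exactly 5 weights in [0, 1]")
        object.__setattr__(self, "contact_coupling", cc)

    @property
    def effective_fluctuation(self) -> float:
        if self.fluctuation_amplitude is None:
            return 2.0 * self.noise_sd
        return self.fluctuation_amplitude


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates of the artifact classes injected into a clean recording.

    ``p_null`` and ``p_negative`` are per-sample probabilities; null samples
    are stored as NaN, negative samples as implausible sub-zero readings
    (both indicate electronic issues).  ``p_oscillation_minute`` is the
    per-minute probability that one randomly chosen strip sensor oscillates
    with amplitude ``oscillation_amplitude`` for that minute.  Bed absence is
    injected as ``n_absence_segments`` holes in the presence intervals, each
    lasting uniformly within ``absence_duration_range`` minutes; strip
    sensors relax to ambient while the bed is empty.
    """

    p_null: float = 1e-4
    p_negative: float = 5e-5
    p_oscillation_minute: float = 0.005
    oscillation_amplitude: float = 3.0
    n_absence_segments: int = 1
    absence_duration_range: tuple = (2.0, 8.0)

    def __post_init__(self) -> None:
        for name in ("p_null", "p_negative", "p_oscillation_minute"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.oscillation_amplitude <= 0:
            raise ValueError("oscillation_amplitude must be > 0")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        """A spec that injects nothing (clean recordings)."""
        return cls(p_null=0.0, p_negative=0.0, p_oscillation_minute=0.0,
                   n_absence_segments=0)


@dataclass
class RawStream:
    """One channel of timestamped temperature samples for one session."""

    channel: str
    timestamps: np.ndarray  # seconds from session start, strictly increasing
    values: np.ndarray      # degC; NaN encodes a null sample
    nominal_rate: float     # samples/s
    resolution: float       # degC quantum

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(f"{self.channel}: timestamps must be strictly increasing")

    def copy(self) -> "RawStream":
        return RawStream(self.channel, self.timestamps.copy(), self.values.copy(),
                         self.nominal_rate, self.resolution)


@dataclass
class SessionRecording:
    """All streams and events for one subject-night."""

    subject_id: str
    session_id: str
    setting: str  # "home" | "lab"
    streams: dict  # channel -> RawStream
    presence_intervals: list  # [start, end) seconds in bed
    lights_off: Optional[float] = None  # seconds from session start (lab only)
    duration_minutes: float = 0.0

    def __post_init__(self) -> None:
        if self.setting not in ("home", "lab"):
            raise ValueError(f"setting must be 'home' or 'lab', got {self.setting!r}")
        missing = [c for c in STRIP_CHANNELS if c not in self.streams]
        if missing:
            raise ValueError(f"strip channels missing from recording: {missing}")
        if self.setting == "home" and "wrist" not in self.streams:
            raise ValueError("home sessions require a wrist reference stream")

    def copy(self) -> "SessionRecording":
        return SessionRecording(
            self.subject_id, self.session_id, self.setting,
            {c: s.copy() for c, s in self.streams.items()},
            [list(iv) for iv in self.presence_intervals],
            self.lights_off, self.duration_minutes)


@dataclass(frozen=True)
class Participant:
    subject_id: str
    gender: str
    age: float          # years
    height: float       # m
    weight: float       # kg


@dataclass
class StudyFixture:
    """A whole simulated study: participants plus all their recordings."""

    participants: list  # of Participant
    sessions: list      # of SessionRecording
    seed: int

    def sessions_for(self, setting: str) -> list:
        return [s for s in self.sessions if s.setting == setting]


@dataclass(frozen=True)
class ArtifactCounts:
    """Bookkeeping of what :func:`inject_artifacts` actually modified."""

    null_samples: int = 0
    negative_samples: int = 0
    oscillation_minutes: int = 0
    absence_minutes: float = 0.0


@dataclass(frozen=True)
class DemographicSummary:
    mean_age: float
    sd_age: float
    gender_counts: dict
    n: int


# ---------------------------------------------------------------------------
# latent physiology
# ---------------------------------------------------------------------------

def _quantize(values: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(values / resolution) * resolution


def vasodilation_response(t_seconds: np.ndarray, onset_seconds: float,
                          timescale_minutes: float) -> np.ndarray:
    """Shared sleep-onset vasodilation latent: 0 before onset, then a
    saturating exponential approach to 1 with the given time constant."""
    dt = np.asarray(t_seconds, dtype=float) - onset_seconds
    out = 1.0 - np.exp(-np.maximum(dt, 0.0) / (timescale_minutes * 60.0))
    return np.where(dt > 0.0, out, 0.0)


def latent_dst(t_seconds: np.ndarray, params: PhysioParams,
               onset_seconds: float) -> np.ndarray:
    """Noise-free wrist distal skin temperature trajectory, degC."""
    r = vasodilation_response(t_seconds, onset_seconds, params.rise_timescale)
    return params.baseline_dst + params.distal_rise * r


def _jittered_clock(duration_s: float, rate: float, rng: np.random.Generator,
                    jitter: float = 0.05) -> np.ndarray:
    """Sample times for a nominal-rate clock with +/-5 % uniform interval
    jitter ('approximately 1 sample/s')."""
    dt = 1.0 / rate
    n = int(np.ceil(duration_s / dt)) + 8
    steps = dt * (1.0 + rng.uniform(-jitter, jitter, size=n))
    t = np.cumsum(steps)
    return t[t < duration_s]


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def simulate_subject_night(params: PhysioParams, setting: str, duration: float,
                           seed: int, *, subject_id: str = "S01",
                           session_id: str = "S01_N01",
                           lights_off_minute: float = 10.0,
                           include_foot: Optional[bool] = None,
                           position_change_rate_per_hour: float = 1.0,
                           ) -> SessionRecording:
    """Simulate one clean subject-night of bed thermodata.

    Parameters
    ----------
    params
        Latent physiology for this night.
    setting
        ``"home"`` (strip + wrist reference) or ``"lab"`` (strip + foot +
        proximal channels and a lights-off event; no wrist, mirroring
        reference devices not worn under a polysomnography setup).
    duration
        Session length in minutes (>= 60).
    seed
        Seeds every random draw; identical ``(params, seed)`` reproduce
        bitwise-identical streams.
    lights_off_minute
        Lab only: minutes from session start to lights-off.
    include_foot
        Force the foot channel on/off (default: lab only).
    position_change_rate_per_hour
        Poisson rate of posture shifts that redraw strip contact weights.
    """
    if duration < 60:
        raise ValueError(f"duration must be >= 60 minutes, got {duration}")
    rng = np.random.default_rng(seed)
    duration_s = float(duration) * 60.0

    if setting == "lab":
        lights_off = lights_off_minute * 60.0
        onset = lights_off + params.sleep_onset_latency * 60.0
    else:
        lights_off = None
        onset = params.sleep_onset_latency * 60.0
    if include_foot is None:
        include_foot = setting == "lab"

    # slow within-night skin-temperature fluctuation, shared by all skin
    # sites (phases drawn per night); unit-SD sinusoid mixture scaled to
    # params.effective_fluctuation
    amp = params.effective_fluctuation
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)

    def slow_drift(t_sec: np.ndarray) -> np.ndarray:
        if amp == 0.0:
            return np.zeros_like(np.asarray(t_sec, dtype=float))
        p1, p2 = params.fluctuation_periods
        u = (0.8 * np.sin(2 * np.pi * t_sec / (p1 * 60.0) + phases[0])
             + 0.6 * np.sin(2 * np.pi * t_sec / (p2 * 60.0) + phases[1]))
        return amp * u / 0.7071  # mixture SD is 0.7071, rescale to amp

    streams: dict = {}

    # wrist reference (home sessions)
    if setting == "home":
        rate, res = CHANNEL_SPECS["wrist"]
        t = np.arange(0.0, duration_s, 1.0 / rate)
        v = latent_dst(t, params, onset) + slow_drift(t)
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=t.size)
        streams["wrist"] = RawStream("wrist", t, _quantize(v, res), rate, res)

    # strip: contact-weighted skin/ambient mixture, piecewise-constant
    # couplings redrawn at position-change events
    n_events = rng.poisson(position_change_rate_per_hour * duration / 60.0)
    event_times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    couplings = [np.asarray(params.contact_coupling, dtype=float)]
    for _ in range(n_events):
        c = rng.permutation(couplings[-1])
        c = np.clip(c + rng.normal(0.0, 0.02, size=5), 0.0, 1.0)
        couplings.append(c)
    coupling_by_segment = np.stack(couplings)  # (n_events + 1, 5)

    for i, channel in enumerate(STRIP_CHANNELS):
        rate, res = CHANNEL_SPECS[channel]
        t = _jittered_clock(duration_s, rate, rng)
        seg = np.searchsorted(event_times, t, side="right")
        c = coupling_by_segment[seg, i]
        skin = latent_dst(t, params, onset) + slow_drift(t)
        v = c * skin + (1.0 - c) * params.ambient_temp
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=t.size)
        streams[channel] = RawStream(channel, t, _quantize(v, res), rate, res)

    # foot / proximal iButton-style channels
    rate, res = CHANNEL_SPECS["foot"]
    t_slow = np.arange(0.0, duration_s, 30.0)
    if include_foot:
        r = vasodilation_response(t_slow, onset, params.rise_timescale)
        v = (params.baseline_dst + params.foot_offset
             + params.distal_rise * r + slow_drift(t_slow))
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=t_slow.size)
        streams["foot"] = RawStream("foot", t_slow.copy(), _quantize(v, res), rate, res)
    if setting == "lab":
        r = vasodilation_response(t_slow, onset, params.rise_timescale)
        v = (params.proximal_baseline + params.proximal_rise * r
             + 0.5 * slow_drift(t_slow))
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=t_slow.size)
        streams["proximal"] = RawStream("proximal", t_slow.copy(),
                                        _quantize(v, res), rate, res)

    return SessionRecording(
        subject_id=subject_id, session_id=session_id, setting=setting,
        streams=streams, presence_intervals=[[0.0, duration_s]],
        lights_off=lights_off, duration_minutes=float(duration))


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(rec: SessionRecording, spec: ArtifactSpec, seed: int):
    """Contaminate a recording with nulls, negatives, intra-minute
    oscillations and bed-absence gaps at the rates in ``spec``.

    Returns ``(recording, counts)`` where ``counts`` is an
    :class:`ArtifactCounts` tallying exactly what was modified.  The input is
    not mutated.
    """
    rng = np.random.default_rng(seed)
    out = rec.copy()
    n_null = n_neg = n_osc = 0
    absence_minutes = 0.0

    # bed-absence holes first (they overwrite strip values), so the later
    # per-sample artifact counts stay exact
    for _ in range(spec.n_absence_segments):
        lo_d, hi_d = spec.absence_duration_range
        dur_s = rng.uniform(lo_d, hi_d) * 60.0
        span = out.duration_minutes * 60.0
        if dur_s >= span:
            continue
        start = rng.uniform(0.0, span - dur_s)
        end = start + dur_s
        out.presence_intervals = _subtract_interval(out.presence_intervals, start, end)
        for channel in STRIP_CHANNELS:
            s = out.streams[channel]
            inside = (s.timestamps >= start) & (s.timestamps < end)
            ambient = rng.normal(24.0, 0.1)
            s.values[inside] = _quantize(
                np.full(int(inside.sum()), ambient), s.resolution)
        absence_minutes += dur_s / 60.0

    # per-minute oscillation bursts on one randomly chosen strip sensor
    if spec.p_oscillation_minute > 0:
        n_minutes = int(np.floor(out.duration_minutes))
        for m in range(n_minutes):
            if rng.random() >= spec.p_oscillation_minute:
                continue
            channel = STRIP_CHANNELS[rng.integers(5)]
            s = out.streams[channel]
            lo, hi = 60.0 * m, 60.0 * (m + 1)
            idx = np.nonzero((s.timestamps >= lo) & (s.timestamps < hi))[0]
            if idx.size == 0:
                continue
            signs = np.where(np.arange(idx.size) % 2 == 0, 1.0, -1.0)
            s.values[idx] = s.values[idx] + signs * spec.oscillation_amplitude
            n_osc += 1

    for channel in out.streams:
        s = out.streams[channel]
        if spec.p_null > 0:
            hit = rng.random(s.values.size) < spec.p_null
            hit &= ~np.isnan(s.values)
            s.values[hit] = np.nan
            n_null += int(hit.sum())
        if spec.p_negative > 0:
            hit = rng.random(s.values.size) < spec.p_negative
            hit &= ~np.isnan(s.values) & (s.values >= 0)
            s.values[hit] = -rng.uniform(1.0, 10.0, size=int(hit.sum()))
            n_neg += int(hit.sum())

    counts = ArtifactCounts(null_samples=n_null, negative_samples=n_neg,
                            oscillation_minutes=n_osc,
                            absence_minutes=absence_minutes)
    return out, counts


def _subtract_interval(intervals, start, end):
    out = []
    for a, b in intervals:
        if end <= a or start >= b:
            out.append([a, b])
            continue
        if a < start:
            out.append([a, start])
        if end < b:
            out.append([end, b])
    return out


# ---------------------------------------------------------------------------
# study-level simulation
# ---------------------------------------------------------------------------

def _draw_participants(n: int, rng: np.random.Generator) -> list:
    """Demographics drawn uniformly over realistic adult spans."""
    out = []
    for i in range(n):
        gender = "Male" if i % 2 == 0 else "Female"
        out.append(Participant(
            subject_id=f"S{i + 1:02d}", gender=gender,
            age=float(rng.integers(31, 58)),
            height=float(np.round(rng.uniform(1.55, 1.95), 2)),
            weight=float(np.round(rng.uniform(61.0, 118.0), 1))))
    return out


def simulate_study(n_home_subjects: int, home_nights: int,
                   n_lab_subjects: int, lab_nights: int,
                   params: Optional[PhysioParams] = None,
                   spec: Optional[ArtifactSpec] = None,
                   seed: int = 0, *, duration: float = 420.0,
                   position_change_rate_per_hour: float = 1.0) -> StudyFixture:
    """Simulate a whole study: ``n_home_subjects`` x ``home_nights`` home
    sessions plus ``n_lab_subjects`` x ``lab_nights`` lab sessions.

    The participant pool has ``max(n_home_subjects, n_lab_subjects)``
    members; the first ``n_home_subjects`` sleep at home, the first
    ``n_lab_subjects`` also visit the lab.  Each subject gets a stable
    baseline offset and habitual sleep-onset latency; each night adds
    night-to-night latency variation and its own strip-contact profile.
    Artifacts are injected per session when ``spec`` is given.
    """
    if n_home_subjects < 0 or n_lab_subjects < 0:
        raise ValueError("subject counts must be >= 0")
    n_subjects = max(n_home_subjects, n_lab_subjects)
    if n_subjects < 1:
        raise ValueError("at least one subject is required")
    if params is None:
        params = PhysioParams()

    rng = np.random.default_rng(seed)
    participants = _draw_participants(n_subjects, rng)

    # stable per-subject physiology
    base_off = rng.normal(0.0, 0.3, size=n_subjects)
    habit_lat = np.maximum(
        5.0, params.sleep_onset_latency + rng.normal(0.0, 5.0, size=n_subjects))

    sessions = []
    session_seed = rng.integers(0, 2**31 - 1)

    def night_params(si: int, nrng: np.random.Generator) -> PhysioParams:
        lat = max(5.0, habit_lat[si] + nrng.normal(0.0, 3.0))
        cc = np.clip(np.concatenate([
            nrng.uniform(0.93, 1.0, size=3), nrng.uniform(0.15, 0.55, size=2)]),
            0.0, 1.0)
        return replace(params,
                       baseline_dst=params.baseline_dst + base_off[si],
                       sleep_onset_latency=lat,
                       contact_coupling=tuple(nrng.permutation(cc)))

    counter = 0
    for setting, n_subj, n_nights in (("home", n_home_subjects, home_nights),
                                      ("lab", n_lab_subjects, lab_nights)):
        for si in range(n_subj):
            for night in range(n_nights):
                counter += 1
                nseed = int((session_seed + counter * 9973) % (2**31 - 1))
                nrng = np.random.default_rng(nseed)
                p = night_params(si, nrng)
                sid = participants[si].subject_id
                rec = simulate_subject_night(
                    p, setting, duration, seed=int(nrng.integers(2**31 - 1)),
                    subject_id=sid,
                    session_id=f"{sid}_{setting}_N{night + 1:02d}",
                    position_change_rate_per_hour=position_change_rate_per_hour)
                if spec is not None:
                    rec, _ = inject_artifacts(
                        rec, spec, seed=int(nrng.integers(2**31 - 1)))
                sessions.append(rec)

    return StudyFixture(participants=participants, sessions=sessions, seed=seed)


def default_study(seed: int = 0, *, n_home_subjects: int = 20,
                  home_nights: int = 5, n_lab_subjects: int = 18,
                  lab_nights: int = 2, duration: float = 240.0) -> StudyFixture:
    """The package's reference synthetic study: 20 home subjects x 5 nights
    plus 18 lab subjects x 2 nights of 240-minute sessions at the calibrated
    default physiology and artifact rates."""
    return simulate_study(n_home_subjects, home_nights, n_lab_subjects,
                          lab_nights, PhysioParams(), ArtifactSpec(),
                          seed=seed, duration=duration)


def summarize_demographics(participants: Sequence) -> DemographicSummary:
    """Mean/SD of age (n-1 denominator) and gender counts for a roster.

    Accepts :class:`Participant` objects or any records with ``age`` and
    ``gender`` attributes/keys.  Rounding is left to the caller.
    """
    parts = list(participants)
    if len(parts) < 2:
        raise ValueError("need at least 2 participants to summarise")

    def get(p, name):
        return getattr(p, name) if hasattr(p, name) else p[name]

    ages = np.array([float(get(p, "age")) for p in parts])
    genders = [str(get(p, "gender")) for p in parts]
    counts: dict = {}
    for g in genders:
        counts[g] = counts.get(g, 0) + 1
    return DemographicSummary(mean_age=float(ages.mean()),
                              sd_age=float(ages.std(ddof=1)),
                              gender_counts=counts, n=len(parts))
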