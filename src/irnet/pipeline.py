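"""Incident-centred dyadic pipeline for multichannel wearable recordings.

The empirical workflow: two people (a client and their caregiver) wear
multi-sensor wristbands recording acceleration (ACC), blood volume pressure
(BVP), electrodermal activity (EDA), heart rate (HR) and skin temperature
(TEMP) at heterogeneous native rates. Around each logged incident, the 35
minutes of data before the incident time are clipped, every channel is
resampled to a shared 1 Hz grid (2,100 samples), incidents with two or more
short channels are excluded, and each variable's client/caregiver pair is
run through the inter-system recurrence analysis; the per-variable results
aggregate into a direction-frequency table and a multiplex network per
incident.

A synthetic fixture generator stands in for real device exports: it
produces per-channel CSVs at wearable-like native rates from stochastic
limit-cycle (Stuart-Landau) oscillators with configurable ground-truth
coupling direction per channel, slow drifts, measurement noise and an
incident timestamp.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .embedding import EmbeddingSpec
from .network import (
    NO_DIRECTION,
    X_LEADS,
    Y_LEADS,
    CouplingSummary,
    analyze_pair,
    build_multiplex,
)

__all__ = [
    "CHANNELS",
    "NATIVE_RATES",
    "PERSONS",
    "ChannelSeries",
    "DyadRecording",
    "IncidentWindow",
    "ChannelCoupling",
    "resample_1hz",
    "extract_window",
    "qc_filter",
    "analyze_incident",
    "summarize_directions",
    "generate_fixture",
    "synthetic_channel_pair",
    "write_cohort",
    "read_cohort",
]

PERSONS = ("client", "caregiver")
CHANNELS = ("ACC", "BVP", "EDA", "HR", "TEMP")

#: Native sampling rates (Hz) typical of consumer research wristbands.
NATIVE_RATES = {"ACC": 32.0, "BVP": 64.0, "EDA": 4.0, "HR": 1.0, "TEMP": 4.0}

#: Intrinsic oscillation periods (s) of the fixture's latent dynamics,
#: loosely matching each channel's characteristic time scale.
_FIXTURE_PERIODS = {"ACC": 110.0, "BVP": 125.0, "EDA": 150.0, "HR": 100.0, "TEMP": 140.0}

_MAX_GAP_S = 5.0  # longest gap bridged by interpolation on the 1 Hz grid


@dataclass
class ChannelSeries:
    """Timestamped samples of one person's channel at its native rate."""

    times: np.ndarray  # seconds (unix or session-relative)
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) and not (np.diff(t) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.times, self.values = t, v


@dataclass
class DyadRecording:
    """One incident's recording: channels for both people plus the incident time."""

    incident_id: str
    incident_time: float
    channels: dict = field(default_factory=dict)  # (person, channel) -> ChannelSeries
    truth: dict = field(default_factory=dict)  # channel -> planted direction (fixtures)

    def span(self) -> tuple[float, float]:
        starts = [c.times[0] for c in self.channels.values() if len(c.times)]
        ends = [c.times[-1] for c in self.channels.values() if len(c.times)]
        return (min(starts), max(ends)) if starts else (np.nan, np.nan)


@dataclass
class IncidentWindow:
    """Pre-incident series on the shared 1 Hz grid, with per-channel QC flags."""

    incident_id: str
    window_minutes: int
    series: dict = field(default_factory=dict)  # (person, channel) -> np.ndarray
    qc_flags: dict = field(default_factory=dict)  # (person, channel) -> str ("ok", ...)
    truth: dict = field(default_factory=dict)

    def n_short(self, min_minutes: int) -> int:
        need = 60 * min_minutes
        count = 0
        for key in self.series:
            flagged = self.qc_flags.get(key, "ok") != "ok"
            if flagged or len(self.series[key]) < need:
                count += 1
        return count


def resample_1hz(
    channel: ChannelSeries, t_start: float, t_end: float
) -> tuple[np.ndarray, str]:
    """One value per second of [t_start, t_end): second k covers
    [t_start + k, t_start + k + 1).

    Rates above 1 Hz are averaged within each second; 1 Hz and below are
    linearly interpolated onto the second marks (small holes up to 5 s are
    bridged the same way). Returns ``(values, flag)``; when the source
    leaves a gap longer than 5 s inside the window, the series is truncated
    at the first such gap and flagged ``"gap"`` — a source that starts more
    than 5 s late therefore yields an empty, flagged series.
    """
    if len(channel.times) == 0:
        raise ValueError("cannot resample an empty channel")
    n = int(round(t_end - t_start))
    if n <= 0:
        raise ValueError("window contains no whole seconds")
    t, v = channel.times, channel.values
    inside = (t >= t_start - 1.0) & (t <= t_end + 1.0)
    t, v = t[inside], v[inside]
    if len(t) == 0 or t[0] - t_start > _MAX_GAP_S:
        return np.empty(0), "gap"

    # Truncate at the first >5 s hole; the usable window is [t_start, cut).
    holes = np.nonzero(np.diff(t) > _MAX_GAP_S)[0]
    if len(holes):
        cut = t[holes[0]]
    elif t_end - t[-1] > _MAX_GAP_S:
        cut = t[-1]
    else:
        cut = t_end
    n_keep = min(n, int(np.floor(cut - t_start)))
    flag = "ok" if n_keep == n else "gap"
    if n_keep <= 0:
        return np.empty(0), "gap"

    if channel.rate > 1.0:
        idx = np.floor(t - t_start).astype(int)
        keep = (idx >= 0) & (idx < n_keep)
        sums = np.bincount(idx[keep], weights=v[keep], minlength=n_keep)
        counts = np.bincount(idx[keep], minlength=n_keep)
        empty = counts == 0
        counts[empty] = 1
        out = sums / counts
        if empty.any():  # isolated empty seconds inside a bridged <=5 s hole
            marks = np.arange(n_keep, dtype=float)
            out[empty] = np.interp(marks[empty], marks[~empty], out[~empty])
        return out, flag
    marks = t_start + np.arange(n_keep, dtype=float)
    return np.interp(marks, t, v), flag


def extract_window(rec: DyadRecording, minutes: int = 35) -> IncidentWindow:
    """Clip [incident - minutes, incident) and resample every channel to 1 Hz.

    Channels that are absent or unusable are flagged rather than fatal;
    an incident time at or before the start of all data raises.
    """
    t_end = rec.incident_time
    t_start = t_end - 60 * minutes
    start_span, _ = rec.span()
    if not np.isfinite(start_span) or t_end <= start_span:
        raise ValueError(
            f"incident {rec.incident_id}: no data before the incident time"
        )
    win = IncidentWindow(rec.incident_id, minutes, truth=dict(rec.truth))
    for person in PERSONS:
        for channel in CHANNELS:
            key = (person, channel)
            if key not in rec.channels:
                win.series[key] = np.empty(0)
                win.qc_flags[key] = "missing"
                continue
            try:
                values, flag = resample_1hz(rec.channels[key], t_start, t_end)
            except ValueError:
                values, flag = np.empty(0), "missing"
            win.series[key] = values
            win.qc_flags[key] = flag
    return win


def qc_filter(
    windows: list[IncidentWindow], min_minutes: int = 25
) -> tuple[list[IncidentWindow], list[dict]]:
    """Drop incidents with two or more series shorter than ``min_minutes``.

    Returns the retained windows and a machine-readable exclusion log
    (one entry per dropped incident, naming the offending channels).
    """
    retained, log = [], []
    need = 60 * min_minutes
    for win in windows:
        short = [
            f"{person}/{channel}"
            for (person, channel) in win.series
            if len(win.series[(person, channel)]) < need
        ]
        if len(short) >= 2:
            log.append(
                {
                    "incident_id": win.incident_id,
                    "reason": f"{len(short)} series shorter than {min_minutes} min",
                    "channels": short,
                }
            )
        else:
            retained.append(win)
    return retained, log


def analyze_incident(
    window: IncidentWindow, config: AnalysisConfig | None = None
) -> tuple[dict, object]:
    """Per-variable coupling summaries plus the multiplex network of one incident.

    Each of the five variables is analyzed with the client stream as system
    X and the caregiver stream as system Y; a variable whose client or
    caregiver series does not cover the full window (flagged or short) is
    recorded as ``None`` instead of aborting the incident — truncated
    series would not share the window's time axis. The multiplex network
    is built across the variables that analyzed cleanly.
    """
    cfg = config or AnalysisConfig()
    spec = EmbeddingSpec(lag=cfg.lag, dim=cfg.dim)
    need = 60 * window.window_minutes
    summaries: dict[str, CouplingSummary | None] = {}
    usable: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for channel in CHANNELS:
        cx = window.series.get(("client", channel), np.empty(0))
        cy = window.series.get(("caregiver", channel), np.empty(0))
        if len(cx) < need or len(cy) < need:
            summaries[channel] = None
            continue
        try:
            summaries[channel] = analyze_pair(
                cx,
                cy,
                embedding=spec,
                rr_auto=cfg.rr_auto,
                rr_cross=cfg.rr_cross,
                norm=cfg.norm,
                convention=cfg.convention,
                direction_threshold=cfg.direction_threshold,
            )
            usable[channel] = (cx, cy)
        except ValueError:
            summaries[channel] = None
    multiplex = None
    if len(usable) >= 2:
        multiplex = build_multiplex(
            usable,
            embedding=spec,
            rr_auto=cfg.rr_auto,
            rr_cross=cfg.rr_cross,
            norm=cfg.norm,
            convention=cfg.convention,
            direction_threshold=cfg.direction_threshold,
            mode=cfg.multiplex_mode,
        )
    return summaries, multiplex


_LABELS = {
    X_LEADS: "client_leading",
    Y_LEADS: "caregiver_leading",
    NO_DIRECTION: "bidirectional_uncoupled",
}


def summarize_directions(per_incident: list[dict]) -> pd.DataFrame:
    """Direction frequencies (%) per variable across incidents.

    ``per_incident`` holds the per-variable summary dicts returned by
    :func:`analyze_incident`. The output has one row per variable plus an
    overall mean row; each row's percentages sum to 100 up to rounding, and
    the result does not depend on incident order.
    """
    if not per_incident:
        raise ValueError("need at least one incident")
    counts = {
        ch: dict.fromkeys(_LABELS.values(), 0) for ch in CHANNELS
    }
    for summaries in per_incident:
        for ch, s in summaries.items():
            if s is not None:
                counts[ch][_LABELS[s.direction]] += 1
    rows = []
    for ch in CHANNELS:
        total = sum(counts[ch].values())
        row = {"variable": ch, "n": total}
        for label in _LABELS.values():
            row[label] = 100.0 * counts[ch][label] / total if total else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"variable": "Mean", "n": int(df["n"].sum())}
    for label in _LABELS.values():
        mean_row[label] = float(df[label].mean())
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelCoupling:
    """Planted ground truth for one channel of a fixture dyad.

    ``direction`` is ``"client"`` (client drives caregiver), ``"caregiver"``,
    ``"none"`` or ``"bidirectional"``; it may also be a mapping of those
    labels to weights, in which case each incident samples a direction with
    the given odds (e.g. ``{"client": 2, "caregiver": 1}``). ``strength``
    is the diffusive coupling rate kappa (1/s) pulling the driven
    oscillator toward the driver.
    """

    direction: object = "none"
    strength: float = 0.012

    def draw(self, rng: np.random.Generator) -> str:
        if isinstance(self.direction, str):
            if self.direction not in ("client", "caregiver", "none", "bidirectional"):
                raise ValueError(f"invalid direction {self.direction!r}")
            return self.direction
        labels = list(self.direction)
        weights = np.array([self.direction[k] for k in labels], dtype=float)
        return str(rng.choice(labels, p=weights / weights.sum()))


def _stuart_landau_pair(
    rng: np.random.Generator,
    n_seconds: int,
    period_s: float,
    direction: str,
    kappa: float,
    relax: float = 0.1,
    process_noise: float = 0.005,
    coupling_delay_s: int = 10,
    amp_coupling: float = 0.4,
    substeps: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent coupled limit-cycle pair sampled at 1 Hz.

    Each person's channel is the real part of a noisy Stuart-Landau
    oscillator (stationary unit amplitude, phase speed 2*pi/period). The
    driven oscillator feels the driver's state from ``coupling_delay_s``
    seconds earlier in two ways: a diffusive phase pull
    ``kappa * (z_driver(t - d) - z_own)`` and an arousal-like modulation of
    its target amplitude, ``1 + amp_coupling * Re z_driver(t - d)``. The
    stationary amplitude keeps the uncoupled null tightly symmetric (a
    free-running envelope would not); the reaction delay gives the
    follower a persistent phase lag instead of a symmetric zero-lag lock,
    and the amplitude response reproduces the driven-system envelope
    variation that makes the cross-clustering pair asymmetric.
    """
    w = 2 * np.pi / period_s
    h = 1.0 / substeps
    sn = process_noise * np.sqrt(h)
    zc = complex(rng.normal(), rng.normal())
    zg = complex(rng.normal(), rng.normal())
    k_cl = kappa if direction in ("caregiver", "bidirectional") else 0.0
    k_cg = kappa if direction in ("client", "bidirectional") else 0.0
    b_cl = amp_coupling if k_cl else 0.0
    b_cg = amp_coupling if k_cg else 0.0
    d = int(coupling_delay_s)
    hist_c = [zc] * (d + 1)  # 1 Hz delay line
    hist_g = [zg] * (d + 1)
    out = np.empty((n_seconds, 2))
    for i in range(n_seconds):
        zc_delayed, zg_delayed = hist_c[0], hist_g[0]
        for _ in range(substeps):
            r_cl = 1.0 + b_cl * zg_delayed.real
            r_cg = 1.0 + b_cg * zc_delayed.real
            fc = k_cl * (zg_delayed - zc)
            fg = k_cg * (zc_delayed - zg)
            zc = (
                zc
                + h * (((r_cl**2 - abs(zc) ** 2) * relax + 1j * w) * zc + fc)
                + sn * complex(rng.normal(), rng.normal())
            )
            zg = (
                zg
                + h * (((r_cg**2 - abs(zg) ** 2) * relax + 1j * w) * zg + fg)
                + sn * complex(rng.normal(), rng.normal())
            )
        hist_c.append(zc)
        hist_g.append(zg)
        hist_c.pop(0)
        hist_g.pop(0)
        out[i] = zc.real, zg.real
    return out[:, 0], out[:, 1]


def _to_native(
    latent: np.ndarray,
    rate: float,
    t0: float,
    rng: np.random.Generator,
    noise_sd: float = 0.03,
    drift_sd: float = 0.02,
) -> ChannelSeries:
    """Render a 1 Hz latent signal at a channel's native rate.

    Adds white measurement noise and a slow random drift (a smoothed random
    walk with ~10-minute correlation), emulating baseline wander.
    """
    n_s = len(latent)
    t_lat = np.arange(n_s, dtype=float)
    times = t0 + np.arange(int(n_s * rate)) / rate
    values = np.interp(times - t0, t_lat, latent)
    drift_coarse = np.cumsum(rng.normal(0, 1, max(n_s // 600 + 2, 2)))
    drift_coarse *= drift_sd / (np.std(drift_coarse) + 1e-12)
    drift = np.interp(
        times - t0, np.linspace(0, n_s, len(drift_coarse)), drift_coarse
    )
    values = values + drift + noise_sd * rng.normal(size=len(times))
    return ChannelSeries(times=times, values=values, rate=rate)


def generate_fixture(
    n_incidents: int,
    coupling_spec: dict | None = None,
    seed: int = 0,
    n_short: int = 0,
    recording_minutes: float = 40.0,
    noise_sd: float = 0.03,
) -> list[DyadRecording]:
    """Seed-reproducible synthetic dyad cohort.

    ``coupling_spec`` maps channel names to :class:`ChannelCoupling` (or to
    plain direction strings); unlisted channels are uncoupled. Each
    incident's recording spans ``recording_minutes`` with the incident
     36-38 minutes after the start, so a full 35-minute pre-incident window
    exists. ``n_short`` incidents (spread over the cohort) have two
    channels starting only ~20 minutes before the incident, to exercise the
    quality-control rule. The planted per-channel direction is stored in
    ``DyadRecording.truth``.
    """
    if n_short > n_incidents:
        raise ValueError("n_short cannot exceed n_incidents")
    spec = {}
    for ch in CHANNELS:
        raw = (coupling_spec or {}).get(ch, ChannelCoupling())
        if isinstance(raw, str):
            raw = ChannelCoupling(direction=raw)
        elif isinstance(raw, dict):
            if set(raw) <= {"direction", "strength"}:
                raw = ChannelCoupling(**raw)
            else:  # a mapping of direction labels to odds
                raw = ChannelCoupling(direction=raw)
        spec[ch] = raw
    rng = np.random.default_rng(seed)
    short_ids = set(
        rng.choice(n_incidents, size=n_short, replace=False)
    ) if n_short else set()

    cohort = []
    for i in range(n_incidents):
        n_seconds = int(60 * recording_minutes)
        incident_time = float(rng.uniform(36 * 60, min(38 * 60, n_seconds - 1)))
        rec = DyadRecording(incident_id=f"incident_{i:03d}", incident_time=incident_time)
        for ch in CHANNELS:
            direction = spec[ch].draw(rng)
            rec.truth[ch] = direction
            latent_c, latent_g = _stuart_landau_pair(
                rng,
                n_seconds,
                _FIXTURE_PERIODS[ch],
                direction,
                spec[ch].strength,
            )
            for person, latent in (("client", latent_c), ("caregiver", latent_g)):
                series = _to_native(
                    latent, NATIVE_RATES[ch], 0.0, rng, noise_sd=noise_sd
                )
                rec.channels[(person, ch)] = series
        if i in short_ids:
            # two late-starting channels -> both shorter than 25 min
            cut = incident_time - 20 * 60
            for key in (("client", "EDA"), ("caregiver", "HR")):
                s = rec.channels[key]
                keep = s.times >= cut
                rec.channels[key] = ChannelSeries(
                    s.times[keep], s.values[keep], s.rate
                )
        cohort.append(rec)
    return cohort


def synthetic_channel_pair(
    direction: str,
    seed: int,
    channel: str = "EDA",
    strength: float = 0.012,
    minutes: int = 35,
    noise_sd: float = 0.03,
) -> tuple[np.ndarray, np.ndarray]:
    """One channel of a synthetic dyad, rendered at its native rate and
    resampled back to the shared 1 Hz grid.

    Convenience wrapper around the fixture machinery for single-channel
    studies (direction-recovery calibration, worked examples). Returns the
    client and caregiver series, each ``60 * minutes`` samples at 1 Hz.
    """
    rng = np.random.default_rng(seed)
    n_seconds = 60 * minutes + 60
    latent_c, latent_g = _stuart_landau_pair(
        rng, n_seconds, _FIXTURE_PERIODS[channel], direction, strength
    )
    out = []
    for latent in (latent_c, latent_g):
        native = _to_native(latent, NATIVE_RATES[channel], 0.0, rng, noise_sd=noise_sd)
        values, flag = resample_1hz(native, 30.0, 30.0 + 60 * minutes)
        if flag != "ok":
            raise RuntimeError("synthetic channel unexpectedly gapped")
        out.append(values)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Cohort CSV input/output
# ---------------------------------------------------------------------------


def write_cohort(cohort: list[DyadRecording], out_dir) -> None:
    """Write per-channel CSVs (unix_time_s, value) plus incidents.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "incidents.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["incident_id", "incident_time"])
        for rec in cohort:
            writer.writerow([rec.incident_id, f"{rec.incident_time:.3f}"])
    for rec in cohort:
        d = out / rec.incident_id
        d.mkdir(exist_ok=True)
        for (person, channel), series in rec.channels.items():
            path = d / f"{person}_{channel}.csv"
            arr = np.column_stack([series.times, series.values])
            np.savetxt(
                path,
                arr,
                delimiter=",",
                header="unix_time_s,value",
                comments="",
                fmt="%.6f",
            )


def read_cohort(data_dir) -> list[DyadRecording]:
    """Read a cohort directory produced by :func:`write_cohort`."""
    root = Path(data_dir)
    incidents = pd.read_csv(root / "incidents.csv")
    cohort = []
    for _, row in incidents.iterrows():
        rec = DyadRecording(
            incident_id=str(row["incident_id"]),
            incident_time=float(row["incident_time"]),
        )
        d = root / rec.incident_id
        for path in sorted(d.glob("*_*.csv")):
            person, channel = path.stem.split("_", 1)
            df = pd.read_csv(path)
            times = df["unix_time_s"].to_numpy(dtype=float)
            rate = NATIVE_RATES.get(channel, 1.0)
            if len(times) > 1:
                rate = float(round(1.0 / np.median(np.diff(times)), 3))
            rec.channels[(person, channel)] = ChannelSeries(
                times=times, values=df["value"].to_numpy(dtype=float), rate=rate
            )
        cohort.append(rec)
    return cohort
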