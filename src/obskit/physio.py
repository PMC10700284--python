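"""Wrist-sensor channel recordings, session alignment, and signal features.

Models fixed-rate recordings of the four wearable measures — electrodermal
activity (EDA, µS), blood volume pulse from photoplethysmography (BVP,
arbitrary units), 3-axis accelerometry (ACC3) and skin temperature (TEMP)
— aligns them to a session's wall-clock window, and computes the summary
features reported for EDA and PPG:

* EDA: mean/sd/min/max/median, least-squares slope per second, and a count
  of skin conductance responses (SCRs) — local maxima of the smoothed
  series whose prominence exceeds a configurable threshold.
* BVP: the same generic statistics plus heart rate.  Pulse peaks are
  located by prominence-based peak detection with a minimum separation of
  one beat at the configured maximum heart rate; heart rate is 60 over the
  mean inter-beat interval (IBI), with IBI mean/sd and RMSSD alongside.

ACC3 and TEMP receive only the generic statistics (ACC3 on the vector
magnitude).  Default fixture sampling rates follow wrist-device convention
(EDA 4 Hz, BVP 64 Hz, ACC 32 Hz, TEMP 4 Hz) but are always read from the
recording, never assumed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .errors import NoBeatsError, PhysioError
from .session import PauseInterval, SessionRecord

CHANNELS = ("EDA", "BVP", "ACC3", "TEMP")

#: Conventional wrist-device sampling rates used by the fixture generator (Hz).
DEFAULT_RATES = {"EDA": 4.0, "BVP": 64.0, "ACC3": 32.0, "TEMP": 4.0}

#: SCR detection defaults: prominence threshold (µS) and smoothing window (s).
DEFAULT_SCR_PROMINENCE_US = 0.01
DEFAULT_SMOOTH_S = 0.5

#: Maximum physiological heart rate used to set minimum peak separation.
DEFAULT_HR_MAX_BPM = 180.0


@dataclass(frozen=True)
class ChannelRecording:
    """One fixed-rate channel: samples starting at ``start_wall_time``.

    Sample ``i`` is taken at wall time ``start_wall_time + i / sampling_rate``.
    ACC3 samples are (x, y, z) triples; all other channels are scalars.
    """

    channel: str
    sampling_rate: float
    start_wall_time: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise PhysioError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if self.sampling_rate <= 0:
            raise PhysioError("sampling_rate must be positive")
        arr = np.asarray(self.samples, dtype=float)
        if self.channel == "ACC3":
            if arr.size and (arr.ndim != 2 or arr.shape[1] != 3):
                raise PhysioError("ACC3 samples must be (n, 3) triples")
            if not arr.size:
                arr = arr.reshape(0, 3)
        else:
            if arr.ndim != 1:
                raise PhysioError(f"{self.channel} samples must be one-dimensional")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.shape[0]

    def sample_times(self) -> np.ndarray:
        """Wall times of every sample."""
        n = len(self)
        return self.start_wall_time + np.arange(n) / self.sampling_rate


@dataclass(frozen=True)
class PhysioRecording:
    """A device's set of channels, at most one recording per channel type."""

    device_id: str
    channels: dict[str, ChannelRecording] = field(default_factory=dict)
    pauses: tuple[PauseInterval, ...] = ()

    def __post_init__(self) -> None:
        for name, rec in self.channels.items():
            if name != rec.channel:
                raise PhysioError(
                    f"channel map key {name!r} disagrees with recording "
                    f"channel {rec.channel!r}"
                )


class PhysioRecordingBuilder:
    """Ingestion contract for streamed samples.

    Any source that yields ``(channel, wall_time, value)`` tuples can feed
    the builder; per-channel sampling rates are fixed up front and the
    first sample's wall time anchors each channel.
    """

    def __init__(self, device_id: str, rates: dict[str, float] | None = None):
        self.device_id = device_id
        self.rates = dict(DEFAULT_RATES if rates is None else rates)
        self._start: dict[str, float] = {}
        self._buf: dict[str, list] = {}

    def add(self, channel: str, wall_time: float, value) -> None:
        if channel not in CHANNELS:
            raise PhysioError(f"unknown channel {channel!r}")
        if channel not in self._start:
            self._start[channel] = wall_time
            self._buf[channel] = []
        self._buf[channel].append(value)

    def build(self) -> PhysioRecording:
        channels = {
            ch: ChannelRecording(
                channel=ch,
                sampling_rate=self.rates[ch],
                start_wall_time=self._start[ch],
                samples=np.asarray(self._buf[ch], dtype=float),
            )
            for ch in self._buf
        }
        return PhysioRecording(self.device_id, channels)


# ---------------------------------------------------------------------------
# Channel CSV I/O
# ---------------------------------------------------------------------------

def write_channel_csv(rec: ChannelRecording, path: str | Path) -> Path:
    """Write one channel as commented-header CSV (one sample per row)."""
    p = Path(path)
    with open(p, "w", encoding="utf-8") as fh:
        fh.write(f"# channel={rec.channel}\n")
        fh.write(f"# start_wall_time={rec.start_wall_time!r}\n")
        fh.write(f"# rate={rec.sampling_rate!r}\n")
        for row in rec.samples:
            if rec.channel == "ACC3":
                fh.write(",".join(repr(float(v)) for v in row) + "\n")
            else:
                fh.write(f"{float(row)!r}\n")
    return p


def read_channel_csv(path: str | Path) -> ChannelRecording:
    p = Path(path)
    if not p.is_file():
        raise PhysioError(f"channel file not found: {p}")
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(p, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            else:
                rows.append([float(x) for x in line.split(",")])
    for required in ("channel", "start_wall_time", "rate"):
        if required not in meta:
            raise PhysioError(f"channel CSV {p} missing header line '# {required}=...'")
    channel = meta["channel"]
    arr = np.asarray(rows, dtype=float)
    if channel != "ACC3" and arr.size:
        arr = arr.reshape(-1)
    elif channel == "ACC3" and not arr.size:
        arr = arr.reshape(0, 3)
    return ChannelRecording(
        channel=channel,
        sampling_rate=float(meta["rate"]),
        start_wall_time=float(meta["start_wall_time"]),
        samples=arr,
    )


# ---------------------------------------------------------------------------
# Session alignment
# ---------------------------------------------------------------------------

def align_to_session(
    rec: PhysioRecording,
    session: SessionRecord,
    session_start_wall: float,
) -> PhysioRecording:
    """Crop every channel to the session's wall-clock window.

    The window is the half-open span ``[start, start + duration + pauses)``
    — the full wall span of the session, paused time included.  Paused
    spans are retained in the cropped channels but carried as annotations
    on the returned recording so downstream feature code can mask them.
    A channel with no overlap is retained empty, with a warning.
    """
    span = session.info.duration + session.total_pause_s
    lo, hi = session_start_wall, session_start_wall + span
    out: dict[str, ChannelRecording] = {}
    for name, ch in rec.channels.items():
        times = ch.sample_times()
        keep = (times >= lo) & (times < hi)
        if len(ch) and not keep.any():
            warnings.warn(
                f"channel {name} has no overlap with the session window "
                f"[{lo}, {hi})", stacklevel=2,
            )
            out[name] = replace(ch, samples=ch.samples[:0])
            continue
        if not len(ch):
            warnings.warn(f"channel {name} is empty", stacklevel=2)
            out[name] = ch
            continue
        idx = np.flatnonzero(keep)
        new_start = times[idx[0]]
        out[name] = replace(
            ch, start_wall_time=float(new_start), samples=ch.samples[idx]
        )
    pauses = tuple(
        PauseInterval(max(p.wall_start, lo), min(p.wall_end, hi))
        for p in session.pauses
        if p.wall_start < hi and p.wall_end > lo
    )
    return PhysioRecording(rec.device_id, out, pauses=pauses)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _basic_stats(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
    }


def _slope_per_second(x: np.ndarray, rate: float) -> float:
    t = np.arange(x.size) / rate
    res = _stats.linregress(t, x)
    return float(res.slope)


def _smooth(x: np.ndarray, rate: float, smooth_s: float) -> np.ndarray:
    w = max(1, int(round(smooth_s * rate)))
    if w <= 1 or x.size < w:
        return x
    kernel = np.ones(w) / w
    # reflect-pad so the moving average keeps length and avoids edge dips
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")
    return sm[pad:pad + x.size]


def eda_features(
    samples: np.ndarray,
    rate: float,
    scr_prominence: float = DEFAULT_SCR_PROMINENCE_US,
    smooth_s: float = DEFAULT_SMOOTH_S,
) -> dict[str, float | None]:
    """Summary features of an electrodermal-activity series (µS).

    ``peak_count`` counts SCR-like local maxima of the moving-average
    smoothed series whose prominence exceeds *scr_prominence*.  ``slope``
    is the least-squares linear trend in µS per second; it is reported as
    ``None`` for series of fewer than two samples.
    """
    if rate <= 0:
        raise PhysioError("rate must be positive")
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise PhysioError("cannot compute EDA features of an empty series")
    feats: dict[str, float | None] = dict(_basic_stats(x))
    feats["slope"] = _slope_per_second(x, rate) if x.size >= 2 else None
    sm = _smooth(x, rate, smooth_s)
    peaks, _ = _signal.find_peaks(sm, prominence=scr_prominence)
    feats["peak_count"] = int(peaks.size)
    return feats


def _find_beats(x: np.ndarray, rate: float, hr_max_bpm: float) -> np.ndarray:
    min_dist = max(1, int(round(rate * 60.0 / hr_max_bpm)))
    ptp = float(np.ptp(x))
    if ptp == 0.0:
        return np.empty(0, dtype=int)
    peaks, _ = _signal.find_peaks(x, distance=min_dist, prominence=0.3 * ptp)
    return peaks


def ppg_heart_rate(
    samples: np.ndarray,
    rate: float,
    hr_max_bpm: float = DEFAULT_HR_MAX_BPM,
) -> dict[str, float]:
    """Heart rate and inter-beat-interval statistics from a PPG/BVP series.

    Beats are prominence-detected peaks separated by at least one beat
    period at *hr_max_bpm*.  Returns ``hr_bpm`` (60 / mean IBI),
    ``ibi_mean_s``, ``ibi_sd_s`` and ``rmssd_s``; the latter two are NaN
    when too few beats exist to define them.

    Raises :class:`NoBeatsError` when fewer than two beats are found.
    """
    if rate <= 0:
        raise PhysioError("rate must be positive")
    x = np.asarray(samples, dtype=float)
    peaks = _find_beats(x, rate, hr_max_bpm)
    if peaks.size < 2:
        raise NoBeatsError(
            f"found {peaks.size} pulse peak(s); at least 2 are needed"
        )
    ibi = np.diff(peaks) / rate
    succ = np.diff(ibi)
    return {
        "hr_bpm": float(60.0 / np.mean(ibi)),
        "ibi_mean_s": float(np.mean(ibi)),
        "ibi_sd_s": float(np.std(ibi, ddof=1)) if ibi.size > 1 else float("nan"),
        "rmssd_s": float(np.sqrt(np.mean(succ**2))) if succ.size else float("nan"),
    }


@dataclass(frozen=True)
class PhysioFeatureReport:
    """Per-channel feature maps for one recording."""

    device_id: str
    features: dict[str, dict[str, float | None]]


def compute_features(
    rec: PhysioRecording,
    scr_prominence: float = DEFAULT_SCR_PROMINENCE_US,
    smooth_s: float = DEFAULT_SMOOTH_S,
    hr_max_bpm: float = DEFAULT_HR_MAX_BPM,
) -> PhysioFeatureReport:
    """Compute the per-channel feature report for a recording.

    EDA gets the SCR-aware feature set; BVP gets generic statistics plus
    heart-rate metrics (omitted with a warning if no beats are found);
    ACC3 (vector magnitude) and TEMP get generic statistics only.
    """
    out: dict[str, dict[str, float | None]] = {}
    for name, ch in rec.channels.items():
        if not len(ch):
            warnings.warn(f"channel {name} is empty; skipped", stacklevel=2)
            continue
        if name == "EDA":
            out[name] = eda_features(
                ch.samples, ch.sampling_rate, scr_prominence, smooth_s
            )
        elif name == "BVP":
            feats: dict[str, float | None] = dict(_basic_stats(ch.samples))
            feats["slope"] = (
                _slope_per_second(ch.samples, ch.sampling_rate)
                if len(ch) >= 2 else None
            )
            peaks = _find_beats(ch.samples, ch.sampling_rate, hr_max_bpm)
            feats["peak_count"] = int(peaks.size)
            try:
                feats.update(ppg_heart_rate(ch.samples, ch.sampling_rate, hr_max_bpm))
            except NoBeatsError:
                warnings.warn("no pulse beats found in BVP channel", stacklevel=2)
            out[name] = feats
        else:
            x = ch.samples
            if name == "ACC3":
                x = np.linalg.norm(x, axis=1)
            feats = dict(_basic_stats(x))
            feats["slope"] = (
                _slope_per_second(x, ch.sampling_rate) if x.size >= 2 else None
            )
            out[name] = feats
    return PhysioFeatureReport(rec.device_id, out)
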