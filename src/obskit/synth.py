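"""Seeded synthetic inputs: keypress logs, physiological channels, and
paired-observer sessions with a controlled disagreement model.

Every generator is a pure function of its arguments including the seed —
no global random state — so fixtures are reproducible and the detection
and agreement code stays falsifiable:

* keypress logs draw per-key event times from homogeneous Poisson
  processes, so expected counts are known in closed form;
* physiological channels embed known ground truth (pulse frequency, SCR
  times), so feature extraction can be checked by parameter recovery;
* observer pairs apply independent event drops, Gaussian timing jitter
  and spurious insertions to a base session, emulating an imperfect human
  reliability observer.

The SCR bump shape (1 s linear rise, exponential decay with a 4 s time
constant, 0.2 µS amplitude) is a fixture convention chosen to look like a
skin conductance response, not a physiological model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

from .errors import ObskitError, PhysioError, SchemaError
from .ksf import KeystrokeSchema
from .physio import CHANNELS, ChannelRecording, DEFAULT_RATES, PhysioRecording
from .recorder import ESC, KeyPressToken
from .session import (
    DurationEvent,
    FrequencyEvent,
    SessionInfo,
    SessionRecord,
)

#: SCR bump fixture constants (rise seconds, decay time constant, amplitude µS).
SCR_RISE_S = 1.0
SCR_TAU_S = 4.0
SCR_AMPLITUDE_US = 0.2

#: Mean synthetic duration-episode length in seconds.
EPISODE_MEAN_S = 5.0


@dataclass(frozen=True)
class ObserverErrorModel:
    """How an imperfect second observer distorts the base session.

    ``drop_prob`` — probability each base event is missed;
    ``add_rate`` — spurious events per second of session;
    ``jitter_sd`` — SD of Gaussian timing error applied per event, seconds.
    """

    drop_prob: float = 0.0
    add_rate: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_prob <= 1.0:
            raise ObskitError("drop_prob must lie in [0, 1]")
        if self.add_rate < 0:
            raise ObskitError("add_rate must be non-negative")
        if self.jitter_sd < 0:
            raise ObskitError("jitter_sd must be non-negative")


# ---------------------------------------------------------------------------
# Keypress logs
# ---------------------------------------------------------------------------

def gen_keypress_log(
    schema: KeystrokeSchema,
    rates: dict[str, float],
    duration_s: float,
    seed: int,
    start_wall: float = 0.0,
) -> list[KeyPressToken]:
    """Poisson keypress stream: ESC at *start_wall*, then per-key events.

    ``rates`` maps bound keys to events per second.  Event times are drawn
    from independent homogeneous Poisson processes over the session span
    and merged in wall-time order.
    """
    if duration_s <= 0:
        raise ObskitError("duration must be positive")
    for key, rate in rates.items():
        if schema.binding_for_key(key) is None:
            raise SchemaError(f"rate given for key {key!r} not bound in schema")
        if rate < 0:
            raise ObskitError(f"negative rate for key {key!r}")
    rng = np.random.default_rng(seed)
    presses: list[tuple[float, str]] = []
    for key in sorted(rates):
        n = rng.poisson(rates[key] * duration_s)
        times = np.sort(rng.uniform(0.0, duration_s, size=n))
        presses.extend((float(t), key) for t in times)
    presses.sort()
    tokens = [KeyPressToken(ESC, start_wall)]
    tokens.extend(KeyPressToken(key, start_wall + t) for t, key in presses)
    return tokens


# ---------------------------------------------------------------------------
# Physiological channels with known ground truth
# ---------------------------------------------------------------------------

def _scr_bump(t_rel: np.ndarray) -> np.ndarray:
    """SCR fixture waveform at times since onset (µS)."""
    out = np.zeros_like(t_rel)
    rising = (t_rel >= 0) & (t_rel < SCR_RISE_S)
    out[rising] = SCR_AMPLITUDE_US * t_rel[rising] / SCR_RISE_S
    decaying = t_rel >= SCR_RISE_S
    out[decaying] = SCR_AMPLITUDE_US * np.exp(-(t_rel[decaying] - SCR_RISE_S) / SCR_TAU_S)
    return out


def gen_physio(
    hr_bpm: float,
    scr_times: Sequence[float],
    duration_s: float,
    seed: int,
    rates: dict[str, float] | None = None,
    start_wall: float = 0.0,
    bvp_noise_sd: float = 0.02,
    eda_noise_sd: float = 0.001,
    device_id: str = "SYNTH-E4",
) -> PhysioRecording:
    """Synthesize a four-channel wearable recording with known ground truth.

    The BVP channel is a pulse train at ``hr_bpm / 60`` Hz (narrow
    Gaussian bumps at each beat) plus seeded noise; the EDA channel is a
    0.5 µS baseline with one SCR-shaped bump at each of *scr_times*.  ACC3
    is resting gravity plus noise and TEMP a steady skin temperature —
    enough to exercise the generic statistics.
    """
    if not 30.0 < hr_bpm < 220.0:
        raise PhysioError(f"heart rate {hr_bpm} bpm outside the supported range")
    for s in scr_times:
        if not 0.0 <= s <= duration_s:
            raise PhysioError(f"SCR time {s} outside session duration {duration_s}")
    rate_map = dict(DEFAULT_RATES if rates is None else rates)
    rng = np.random.default_rng(seed)

    # BVP: distance to nearest beat → narrow Gaussian pulse.
    period = 60.0 / hr_bpm
    fs = rate_map["BVP"]
    t = np.arange(int(round(duration_s * fs))) / fs
    d = (t + period / 2.0) % period - period / 2.0
    sigma = 0.05 * period
    bvp = np.exp(-(d**2) / (2.0 * sigma**2))
    bvp += rng.normal(0.0, bvp_noise_sd, size=bvp.size)

    fs_eda = rate_map["EDA"]
    t_eda = np.arange(int(round(duration_s * fs_eda))) / fs_eda
    eda = np.full(t_eda.size, 0.5)
    for s in scr_times:
        eda += _scr_bump(t_eda - s)
    eda += rng.normal(0.0, eda_noise_sd, size=eda.size)

    fs_acc = rate_map["ACC3"]
    n_acc = int(round(duration_s * fs_acc))
    acc = np.tile([0.0, 0.0, 9.81], (n_acc, 1))
    acc += rng.normal(0.0, 0.05, size=acc.shape)

    fs_temp = rate_map["TEMP"]
    n_temp = int(round(duration_s * fs_temp))
    temp = 33.0 + rng.normal(0.0, 0.01, size=n_temp)

    channels = {
        "BVP": ChannelRecording("BVP", fs, start_wall, bvp),
        "EDA": ChannelRecording("EDA", fs_eda, start_wall, eda),
        "ACC3": ChannelRecording("ACC3", fs_acc, start_wall, acc),
        "TEMP": ChannelRecording("TEMP", fs_temp, start_wall, temp),
    }
    return PhysioRecording(device_id, channels)


# ---------------------------------------------------------------------------
# Whole sessions and observer pairs
# ---------------------------------------------------------------------------

def default_info(
    schema: KeystrokeSchema,
    duration_s: float,
    session_number: str = "1",
    is_reliability: bool = False,
) -> SessionInfo:
    """A filled-in SessionInfo consistent with *schema* for fixture use."""
    condition = schema.conditions[0] if schema.conditions else "baseline"
    return SessionInfo(
        mrn="000000",
        assessment="Functional Analysis",
        condition=condition,
        therapist="Therapist A",
        data_recorder="Recorder B",
        concern="Self-injury",
        phase="Assessment",
        session_number=session_number,
        is_reliability=is_reliability,
        start_datetime=datetime(2023, 3, 5, 9, 0, 0),
        duration=duration_s,
    )


def gen_session_record(
    schema: KeystrokeSchema,
    rates: dict[str, float],
    duration_s: float,
    seed: int,
    info: Optional[SessionInfo] = None,
) -> SessionRecord:
    """Generate a valid session directly (bypassing the recorder).

    ``rates`` maps behavior *tags* to events per second: frequency tags
    get Poisson-timed instances; duration tags get Poisson-started
    episodes with exponential lengths (mean 5 s) clipped to the session.
    """
    if duration_s <= 0:
        raise ObskitError("duration must be positive")
    rng = np.random.default_rng(seed)
    freq: list[FrequencyEvent] = []
    dur: list[DurationEvent] = []
    for tag in sorted(rates):
        if not schema.has_behavior(tag):
            raise SchemaError(f"rate given for tag {tag!r} not in schema")
        n = rng.poisson(rates[tag] * duration_s)
        times = np.sort(rng.uniform(0.0, duration_s, size=n))
        if schema.kind_of(tag) == "frequency":
            freq.extend(FrequencyEvent(tag, float(t)) for t in times)
        else:
            lengths = rng.exponential(EPISODE_MEAN_S, size=n)
            spans = []
            last_end = 0.0
            for t, L in zip(times, lengths):
                start = max(float(t), last_end)
                end = min(start + float(L), duration_s)
                if end > start:
                    spans.append((start, end))
                    last_end = end
            dur.extend(DurationEvent(tag, s, e) for s, e in spans)
    freq.sort(key=lambda e: e.t)
    dur.sort(key=lambda e: e.start)
    info = info if info is not None else default_info(schema, duration_s)
    info = replace(info, duration=duration_s)
    return SessionRecord(
        info=info, freq_events=tuple(freq), dur_events=tuple(dur), schema=schema
    )


def gen_observer_pair(
    base: SessionRecord, model: ObserverErrorModel
) -> tuple[SessionRecord, SessionRecord]:
    """Derive a (primary, reliability) pair from a base session.

    The primary is the base itself.  The reliability record drops each
    base event independently with ``drop_prob``, jitters surviving event
    times by Gaussian noise clamped to the session span, and inserts
    spurious frequency events at ``add_rate`` per second with uniformly
    chosen tags.  Deterministic given the model's seed.
    """
    rng = np.random.default_rng(model.seed)
    duration = base.info.duration

    def _jitter(t: float) -> float:
        if model.jitter_sd == 0.0:
            return t
        return float(np.clip(t + rng.normal(0.0, model.jitter_sd), 0.0, duration))

    freq: list[FrequencyEvent] = []
    for ev in base.freq_events:
        if model.drop_prob > 0.0 and rng.random() < model.drop_prob:
            continue
        freq.append(FrequencyEvent(ev.tag, _jitter(ev.t)))

    dur: list[DurationEvent] = []
    for ev in base.dur_events:
        if model.drop_prob > 0.0 and rng.random() < model.drop_prob:
            continue
        a, b = sorted((_jitter(ev.start), _jitter(ev.end)))
        dur.append(DurationEvent(ev.tag, a, b))

    freq_tags = tuple(b.behavior for b in base.schema.frequency_bindings)
    if model.add_rate > 0.0 and freq_tags:
        n_add = rng.poisson(model.add_rate * duration)
        for _ in range(int(n_add)):
            tag = freq_tags[rng.integers(len(freq_tags))]
            freq.append(FrequencyEvent(tag, float(rng.uniform(0.0, duration))))

    freq.sort(key=lambda e: e.t)
    dur.sort(key=lambda e: e.start)
    rel_info = replace(base.info, is_reliability=True)
    reliability = SessionRecord(
        info=rel_info,
        freq_events=tuple(freq),
        dur_events=tuple(dur),
        pauses=base.pauses,
        schema=base.schema,
    )
    return base, reliability


def demo_schema() -> KeystrokeSchema:
    """A small schema used across fixtures: two frequency keys, one duration."""
    from .ksf import KeyBinding

    return KeystrokeSchema(
        name="demo",
        bindings=(
            KeyBinding("a", "hitting", "frequency"),
            KeyBinding("s", "kicking", "frequency"),
            KeyBinding("z", "aggression", "duration"),
        ),
        conditions=("baseline", "treatment", "tangible", "toy play"),
    )
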