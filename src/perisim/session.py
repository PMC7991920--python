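"""Session orchestration: a complete (binocular) visual-field test.

A session maps the blind spot per eye, then runs the test plan with
eye/location interleaving randomized by a seeded generator, injecting
catch trials on configurable cadences.  Every presentation — threshold,
blind-spot-mapping, fixation-loss, false-positive, false-negative or
suprathreshold — is logged as an event, and the full result (thresholds,
reliability indices, durations) is a pure function of that log, which
:func:`replay` verifies by recomputing everything from the log alone.

Simulated durations accumulate stimulus time, response latency (the
drawn response time when seen, the full response window otherwise) and
the inter-stimulus interval.  Per-eye duration is total time divided by
the number of eyes tested, matching how mean test duration per eye is
reported for simultaneous binocular testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np

from .calibration import (
    CalibrationCurve,
    db_from_luminance,
    gray_for_luminance,
    luminance_from_db,
)
from .errors import (
    DomainError,
    LogIntegrityError,
    RunawaySessionError,
    UnsupportedStimulusError,
)
from .observer import Observer, respond
from .patterns import Eye, TestPattern, blind_spot_spec, build_pattern
from .reliability import (
    CatchTrialRecord,
    ReliabilityIndices,
    fl_probe,
    fn_probe,
    fp_probe,
    map_blind_spot,
    summarize_reliability,
)
from .strategy import (
    SuprathresholdTrial,
    TestPlan,
    estimate,
    init_staircase,
    make_plan,
    next_level,
    record_response,
)

GOLDMANN_DIAMETERS_DEG = {"III": 0.43}

EVENT_KINDS = ("threshold", "FL", "FP", "FN", "suprathreshold", "blindspot-mapping")


def goldmann_size(spec: str = "III") -> float:
    """Stimulus diameter in degrees for a Goldmann size label (III: 0.43°)."""
    try:
        return GOLDMANN_DIAMETERS_DEG[spec]
    except KeyError:
        raise UnsupportedStimulusError(f"unsupported Goldmann size {spec!r}") from None


@dataclass(frozen=True)
class SessionConfig:
    protocol: str = "T-24"
    eyes: tuple[Eye, ...] = ("OD", "OS")
    seed: int = 0
    start_level: int = 25
    suprathreshold_level: int = 28
    stimulus_duration_ms: float = 200.0
    response_window_ms: float = 1500.0
    inter_stimulus_ms: float = 400.0
    fl_cadence: int = 10
    fp_cadence: int = 10
    fn_cadence: int = 20
    fn_offset_cd_m2: float = 0.5
    fn_offset_mode: str = "easier"
    stimulus_size: str = "III"

    def __post_init__(self) -> None:
        for name in ("stimulus_duration_ms", "response_window_ms", "inter_stimulus_ms"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


@dataclass(frozen=True)
class PresentationEvent:
    seq: int
    sim_time_ms: float
    eye: Eye
    kind: str
    location_id: int | None
    x: float | None
    y: float | None
    nominal_db: float | None
    achieved_gray: int | None
    achieved_luminance_cd_m2: float | None
    seen: bool | None
    response_time_ms: float | None
    elapsed_ms: float
    stimulus_diameter_deg: float
    background_cd_m2: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EventLog:
    """Header (protocol/eyes/config echo) plus the ordered event list."""

    protocol: str
    eyes: tuple[Eye, ...]
    n_eyes: int
    events: tuple[PresentationEvent, ...]

    def to_jsonl(self) -> str:
        header = {"record": "session-start", "protocol": self.protocol,
                  "eyes": list(self.eyes), "n_eyes": self.n_eyes}
        lines = [json.dumps(header, sort_keys=True)]
        lines += [json.dumps(e.to_dict(), sort_keys=True) for e in self.events]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "EventLog":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise LogIntegrityError("empty event log")
        header = json.loads(lines[0])
        if header.get("record") != "session-start":
            raise LogIntegrityError("log must start with a session-start header")
        events = tuple(PresentationEvent(**json.loads(ln)) for ln in lines[1:])
        return cls(protocol=header["protocol"], eyes=tuple(header["eyes"]),
                   n_eyes=header["n_eyes"], events=events)


@dataclass(frozen=True)
class SessionResult:
    protocol: str
    eyes: tuple[Eye, ...]
    thresholds: dict[Eye, dict[int, int]]
    floored: dict[Eye, tuple[int, ...]]
    ceilinged: dict[Eye, tuple[int, ...]]
    reliability: dict[Eye, ReliabilityIndices]
    blind_spot_centers: dict[Eye, tuple[float, float]]
    blind_spot_mapping_failed: dict[Eye, bool]
    supra: dict[Eye, dict[int, tuple[bool, float | None]]]
    total_duration_s: float
    per_eye_duration_s: float
    n_events: int
    log: EventLog | None = None

    def to_dict(self) -> dict:
        def rel(r: ReliabilityIndices) -> dict:
            return {
                "fl_probes": r.fl_probes, "fl_triggers": r.fl_triggers,
                "fp_probes": r.fp_probes, "fp_triggers": r.fp_triggers,
                "fn_probes": r.fn_probes, "fn_triggers": r.fn_triggers,
                "fixation_loss_ratio": r.fixation_loss_ratio,
                "false_positive_rate": r.false_positive_rate,
                "false_negative_rate": r.false_negative_rate,
            }
        return {
            "protocol": self.protocol,
            "eyes": list(self.eyes),
            "thresholds": {e: {str(k): v for k, v in sorted(m.items())}
                           for e, m in self.thresholds.items()},
            "floored": {e: sorted(v) for e, v in self.floored.items()},
            "ceilinged": {e: sorted(v) for e, v in self.ceilinged.items()},
            "reliability": {e: rel(r) for e, r in self.reliability.items()},
            "blind_spot_centers": {e: list(c) for e, c in self.blind_spot_centers.items()},
            "blind_spot_mapping_failed": dict(self.blind_spot_mapping_failed),
            "supra": {e: {str(k): list(v) for k, v in sorted(m.items())}
                      for e, m in self.supra.items()},
            "total_duration_s": self.total_duration_s,
            "per_eye_duration_s": self.per_eye_duration_s,
            "n_events": self.n_events,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))


class _SessionRecorder:
    """Accumulates events with monotone sim time and strict sequencing."""

    def __init__(self, config: SessionConfig) -> None:
        self.config = config
        self.events: list[PresentationEvent] = []
        self.sim_time_ms = 0.0
        self.diameter = goldmann_size(config.stimulus_size)

    def log(self, *, eye: Eye, kind: str, location_id: int | None,
            x: float | None, y: float | None, nominal_db: float | None,
            achieved_gray: int | None, achieved_lum: float | None,
            seen: bool | None, rt: float | None,
            background: float) -> PresentationEvent:
        c = self.config
        latency = rt if (seen and rt is not None) else c.response_window_ms
        elapsed = c.stimulus_duration_ms + latency + c.inter_stimulus_ms
        ev = PresentationEvent(
            seq=len(self.events), sim_time_ms=self.sim_time_ms, eye=eye, kind=kind,
            location_id=location_id, x=x, y=y, nominal_db=nominal_db,
            achieved_gray=achieved_gray, achieved_luminance_cd_m2=achieved_lum,
            seen=seen, response_time_ms=rt, elapsed_ms=elapsed,
            stimulus_diameter_deg=self.diameter, background_cd_m2=background,
        )
        self.events.append(ev)
        self.sim_time_ms += elapsed
        return ev


def _render(curve: CalibrationCurve, level_db: float) -> tuple[float, int, float]:
    """Nominal luminance plus the gray-quantized (achieved) rendering."""
    nominal_lum = luminance_from_db(curve, level_db)
    gray, achieved = gray_for_luminance(curve, nominal_lum)
    return nominal_lum, gray, achieved


def run_session(
    config: SessionConfig,
    observers: Mapping[Eye, Observer],
    calibration: CalibrationCurve,
) -> SessionResult:
    """Execute a full test for the configured eyes.

    Observers are supplied per eye (``{"OD": ..., "OS": ...}``); the
    test pattern is built per eye so the blind-spot exclusions sit on
    each eye's temporal side.  Returns the result with the attached
    event log.
    """
    for eye in config.eyes:
        if eye not in observers:
            raise DomainError(f"no observer supplied for eye {eye}")
    rng = np.random.default_rng(config.seed)
    rec = _SessionRecorder(config)
    bg = calibration.background_luminance
    patterns: dict[Eye, TestPattern] = {
        eye: build_pattern(config.protocol, eye) for eye in config.eyes
    }

    # --- blind-spot mapping per eye (Heijl-Krakau setup) ---
    bs_centers: dict[Eye, tuple[float, float]] = {}
    bs_failed: dict[Eye, bool] = {}
    for eye in config.eyes:
        mapping = map_blind_spot(blind_spot_spec(eye), observers[eye], rng)
        bs_centers[eye] = mapping.center
        bs_failed[eye] = mapping.mapping_failed
        for (x, y, seen) in mapping.probes:
            _, gray, achieved = _render(calibration, 0.0)
            rec.log(eye=eye, kind="blindspot-mapping", location_id=None, x=x, y=y,
                    nominal_db=0.0, achieved_gray=gray, achieved_lum=achieved,
                    seen=seen, rt=None, background=bg)

    catch_records: dict[Eye, list[CatchTrialRecord]] = {e: [] for e in config.eyes}
    trial_count: dict[Eye, int] = {e: 0 for e in config.eyes}
    last_seen_lum: dict[tuple[Eye, int], float] = {}

    def _catch_trials(eye: Eye, plan: TestPlan | None) -> None:
        n = trial_count[eye]
        obs = observers[eye]
        if n % config.fl_cadence == 0:
            r = fl_probe(bs_centers[eye], obs, rng, time_ms=rec.sim_time_ms)
            catch_records[eye].append(r)
            _, gray, achieved = _render(calibration, 0.0)
            rec.log(eye=eye, kind="FL", location_id=None,
                    x=bs_centers[eye][0], y=bs_centers[eye][1], nominal_db=0.0,
                    achieved_gray=gray, achieved_lum=achieved,
                    seen=r.triggered, rt=r.response_time_ms, background=bg)
        if n % config.fp_cadence == 0:
            r = fp_probe(obs, rng, time_ms=rec.sim_time_ms)
            catch_records[eye].append(r)
            rec.log(eye=eye, kind="FP", location_id=None, x=None, y=None,
                    nominal_db=None, achieved_gray=None, achieved_lum=None,
                    seen=r.triggered, rt=r.response_time_ms, background=bg)
        if plan is not None and n % config.fn_cadence == 0:
            eligible = [
                lid for (e, lid), st in plan.states.items()
                if e == eye and st.finished and st.last_seen_level is not None
            ]
            if eligible:
                lid = int(rng.choice(np.array(sorted(eligible))))
                loc = patterns[eye].location(lid)
                r = fn_probe(loc, estimate(plan.states[(eye, lid)]),
                             last_seen_lum[(eye, lid)], obs, rng, calibration,
                             offset_cd_m2=config.fn_offset_cd_m2,
                             mode=config.fn_offset_mode, time_ms=rec.sim_time_ms)
                catch_records[eye].append(r)
                _, gray, achieved = _render(calibration, r.level_db)
                rec.log(eye=eye, kind="FN", location_id=lid, x=loc.x, y=loc.y,
                        nominal_db=r.level_db, achieved_gray=gray,
                        achieved_lum=achieved, seen=not r.triggered,
                        rt=r.response_time_ms, background=bg)

    thresholds: dict[Eye, dict[int, int]] = {e: {} for e in config.eyes}
    floored: dict[Eye, list[int]] = {e: [] for e in config.eyes}
    ceilinged: dict[Eye, list[int]] = {e: [] for e in config.eyes}
    supra: dict[Eye, dict[int, tuple[bool, float | None]]] = {e: {} for e in config.eyes}

    if config.protocol == "S-24":
        # single-presentation suprathreshold screening
        for eye in config.eyes:
            obs = observers[eye]
            for loc in patterns[eye].locations:
                level = float(config.suprathreshold_level)
                seen, rt = respond(obs.surface, obs.params, loc.x, loc.y, level, rng)
                _, gray, achieved = _render(calibration, level)
                rec.log(eye=eye, kind="suprathreshold", location_id=loc.id,
                        x=loc.x, y=loc.y, nominal_db=level, achieved_gray=gray,
                        achieved_lum=achieved, seen=seen, rt=rt, background=bg)
                supra[eye][loc.id] = (seen, rt)
                trial_count[eye] += 1
                _catch_trials(eye, None)
    else:
        plan = make_plan(patterns, eyes=config.eyes, seeding_default=config.start_level)
        cap = 10 * 6 * len(plan.pairs)
        presented = 0
        while not plan.complete:
            ready = plan.ready_pairs()
            if not ready:
                raise RunawaySessionError("no ready pairs but plan incomplete")
            eye, lid = ready[int(rng.integers(len(ready)))]
            st = plan.staircase(eye, lid)
            level = next_level(st)
            loc = patterns[eye].location(lid)
            nominal_lum, gray, achieved = _render(calibration, level)
            obs = observers[eye]
            seen, rt = respond(obs.surface, obs.params, loc.x, loc.y, float(level), rng)
            record_response(st, seen)
            if seen:
                last_seen_lum[(eye, lid)] = nominal_lum
            rec.log(eye=eye, kind="threshold", location_id=lid, x=loc.x, y=loc.y,
                    nominal_db=float(level), achieved_gray=gray, achieved_lum=achieved,
                    seen=seen, rt=rt, background=bg)
            presented += 1
            trial_count[eye] += 1
            if presented > cap:
                raise RunawaySessionError(f"exceeded safety cap of {cap} presentations")
            _catch_trials(eye, plan)
        for (eye, lid), st in plan.states.items():
            thresholds[eye][lid] = estimate(st)
            if st.floored:
                floored[eye].append(lid)
            if st.ceilinged:
                ceilinged[eye].append(lid)

    reliability = {e: summarize_reliability(catch_records[e]) for e in config.eyes}
    total_s = rec.sim_time_ms / 1000.0
    log = EventLog(protocol=config.protocol, eyes=tuple(config.eyes),
                   n_eyes=len(config.eyes), events=tuple(rec.events))
    return SessionResult(
        protocol=config.protocol, eyes=tuple(config.eyes),
        thresholds=thresholds,
        floored={e: tuple(sorted(v)) for e, v in floored.items()},
        ceilinged={e: tuple(sorted(v)) for e, v in ceilinged.items()},
        reliability=reliability,
        blind_spot_centers=bs_centers, blind_spot_mapping_failed=bs_failed,
        supra=supra,
        total_duration_s=total_s,
        per_eye_duration_s=total_s / len(config.eyes),
        n_events=len(rec.events), log=log,
    )


def replay(log: EventLog) -> SessionResult:
    """Recompute a :class:`SessionResult` purely from an event log.

    Re-runs the staircase rule over each location's logged responses and
    verifies the logged levels match; recounts catch trials; re-derives
    blind-spot centers and durations.  Raises
    :class:`LogIntegrityError` on sequence gaps, non-monotone times, or
    levels inconsistent with the staircase rule.
    """
    events = log.events
    for i, ev in enumerate(events):
        if ev.seq != i:
            raise LogIntegrityError(f"sequence gap at index {i} (seq {ev.seq})")
        if ev.kind not in EVENT_KINDS:
            raise LogIntegrityError(f"unknown event kind {ev.kind!r}")
        if i and ev.sim_time_ms < events[i - 1].sim_time_ms:
            raise LogIntegrityError(f"sim_time decreases at seq {i}")

    eyes = tuple(log.eyes)
    thresholds: dict[Eye, dict[int, int]] = {e: {} for e in eyes}
    floored: dict[Eye, list[int]] = {e: [] for e in eyes}
    ceilinged: dict[Eye, list[int]] = {e: [] for e in eyes}
    supra: dict[Eye, dict[int, tuple[bool, float | None]]] = {e: {} for e in eyes}
    staircases: dict[tuple[Eye, int], object] = {}
    catch: dict[Eye, list[CatchTrialRecord]] = {e: [] for e in eyes}
    bs_unseen: dict[Eye, list[tuple[float, float]]] = {e: [] for e in eyes}
    bs_probes: dict[Eye, int] = {e: 0 for e in eyes}

    for ev in events:
        if ev.kind == "threshold":
            key = (ev.eye, ev.location_id)
            st = staircases.get(key)
            if st is None:
                st = init_staircase(ev.location_id, int(ev.nominal_db))
                staircases[key] = st
            if next_level(st) != int(ev.nominal_db):
                raise LogIntegrityError(
                    f"level {ev.nominal_db} at seq {ev.seq} inconsistent with staircase"
                )
            record_response(st, bool(ev.seen))
        elif ev.kind == "suprathreshold":
            supra[ev.eye][ev.location_id] = (bool(ev.seen), ev.response_time_ms)
        elif ev.kind == "blindspot-mapping":
            bs_probes[ev.eye] += 1
            if not ev.seen:
                bs_unseen[ev.eye].append((ev.x, ev.y))
        elif ev.kind == "FL":
            catch[ev.eye].append(CatchTrialRecord(
                kind="FL", eye=ev.eye, triggered=bool(ev.seen),
                level_db=ev.nominal_db, time_ms=ev.sim_time_ms))
        elif ev.kind == "FP":
            catch[ev.eye].append(CatchTrialRecord(
                kind="FP", eye=ev.eye, triggered=bool(ev.seen),
                time_ms=ev.sim_time_ms))
        elif ev.kind == "FN":
            catch[ev.eye].append(CatchTrialRecord(
                kind="FN", eye=ev.eye, triggered=not ev.seen,
                level_db=ev.nominal_db, time_ms=ev.sim_time_ms,
                location_id=ev.location_id))

    for (eye, lid), st in staircases.items():
        thresholds[eye][lid] = estimate(st)
        if st.floored:
            floored[eye].append(lid)
        if st.ceilinged:
            ceilinged[eye].append(lid)

    bs_centers: dict[Eye, tuple[float, float]] = {}
    bs_failed: dict[Eye, bool] = {}
    for eye in eyes:
        if bs_unseen[eye]:
            arr = np.array(bs_unseen[eye])
            bs_centers[eye] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
            bs_failed[eye] = False
        else:
            bs_centers[eye] = blind_spot_spec(eye).expected_center
            bs_failed[eye] = True

    total_s = sum(ev.elapsed_ms for ev in events) / 1000.0
    return SessionResult(
        protocol=log.protocol, eyes=eyes, thresholds=thresholds,
        floored={e: tuple(sorted(v)) for e, v in floored.items()},
        ceilinged={e: tuple(sorted(v)) for e, v in ceilinged.items()},
        reliability={e: summarize_reliability(catch[e]) for e in eyes},
        blind_spot_centers=bs_centers, blind_spot_mapping_failed=bs_failed,
        supra=supra, total_duration_s=total_s,
        per_eye_duration_s=total_s / log.n_eyes,
        n_events=len(events), log=log,
    )
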