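"""Catch-trial machinery: fixation losses, false positives, false negatives.

Fixation is monitored with the Heijl-Krakau method: the physiologic
blind spot is mapped at the start of the test by probing a grid around
its expected center with the brightest (0 dB) stimulus, and the mapped
center is re-probed periodically as the test progresses.  A response to
a blind-spot probe implies the eye was not fixating and is recorded as a
fixation loss.

False-positive probes open a response window with no stimulus; any
response is a false positive.  False-negative probes re-present a
stimulus at a location whose threshold is already established, offset in
luminance from the last stimulus the observer reported seeing; a missed
response is a false negative.  The luminance offset defaults to +0.5
cd/m^2 (a brighter, *easier* stimulus — a dimmer one could be missed
legitimately and would not indicate inattention); a ``literal`` mode
presenting 0.5 cd/m^2 *dimmer* is selectable for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationCurve, db_from_luminance, luminance_from_db
from .errors import DomainError, IneligibleLocationError
from .observer import Observer, false_response, respond
from .patterns import BlindSpotSpec, FieldLocation

FN_OFFSET_CD_M2 = 0.5
MAPPING_GRID_HALF = 3  # 7x7 grid at 1 degree spacing
MAPPING_STIMULUS_DB = 0


@dataclass(frozen=True)
class CatchTrialRecord:
    kind: str  # FL | FP | FN
    eye: str
    triggered: bool
    level_db: float | None = None  # None for FP (no stimulus)
    time_ms: float | None = None
    location_id: int | None = None
    response_time_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("FL", "FP", "FN"):
            raise DomainError(f"unknown catch-trial kind {self.kind!r}")
        if self.kind == "FP" and self.level_db is not None:
            raise DomainError("FP records carry no stimulus level")


@dataclass(frozen=True)
class BlindSpotMapping:
    """Outcome of the initial blind-spot search."""

    center: tuple[float, float]
    mapping_failed: bool
    n_unseen: int
    probes: tuple[tuple[float, float, bool], ...] = ()  # (x, y, seen)


@dataclass(frozen=True)
class ReliabilityIndices:
    """Session reliability summary; rates are None when no probes ran."""

    fl_probes: int
    fl_triggers: int
    fp_probes: int
    fp_triggers: int
    fn_probes: int
    fn_triggers: int

    @property
    def fixation_loss_ratio(self) -> float | None:
        return self.fl_triggers / self.fl_probes if self.fl_probes else None

    @property
    def false_positive_rate(self) -> float | None:
        """Percent of FP windows with a response."""
        return 100.0 * self.fp_triggers / self.fp_probes if self.fp_probes else None

    @property
    def false_negative_rate(self) -> float | None:
        """Percent of FN probes with no response."""
        return 100.0 * self.fn_triggers / self.fn_probes if self.fn_probes else None


def map_blind_spot(
    spec: BlindSpotSpec, observer: Observer, rng: np.random.Generator
) -> BlindSpotMapping:
    """Locate the blind spot by probing a 7x7 1°-spaced grid at 0 dB.

    The mapped center is the centroid of non-responses; if every probe is
    seen the expected center is kept and the mapping is flagged failed.
    """
    cx, cy = spec.expected_center
    probes = []
    unseen = []
    for dy in range(MAPPING_GRID_HALF, -MAPPING_GRID_HALF - 1, -1):
        for dx in range(-MAPPING_GRID_HALF, MAPPING_GRID_HALF + 1):
            x, y = cx + dx, cy + dy
            seen, _ = respond(observer.surface, observer.params, x, y,
                              MAPPING_STIMULUS_DB, rng)
            probes.append((x, y, seen))
            if not seen:
                unseen.append((x, y))
    if not unseen:
        return BlindSpotMapping(center=(cx, cy), mapping_failed=True,
                                n_unseen=0, probes=tuple(probes))
    arr = np.array(unseen)
    center = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
    return BlindSpotMapping(center=center, mapping_failed=False,
                            n_unseen=len(unseen), probes=tuple(probes))


def fl_probe(
    mapped_center: tuple[float, float],
    observer: Observer,
    rng: np.random.Generator,
    time_ms: float | None = None,
) -> CatchTrialRecord:
    """Heijl-Krakau probe: 0 dB stimulus at the mapped blind-spot center."""
    seen, rt = respond(observer.surface, observer.params,
                       mapped_center[0], mapped_center[1], MAPPING_STIMULUS_DB, rng)
    return CatchTrialRecord(kind="FL", eye=observer.eye, triggered=seen,
                            level_db=float(MAPPING_STIMULUS_DB), time_ms=time_ms,
                            response_time_ms=rt)


def fp_probe(
    observer: Observer, rng: np.random.Generator, time_ms: float | None = None
) -> CatchTrialRecord:
    """Stimulus-free response window; any response is a false positive."""
    responded, rt = false_response(observer.params, rng)
    return CatchTrialRecord(kind="FP", eye=observer.eye, triggered=responded,
                            time_ms=time_ms, response_time_ms=rt)


def fn_probe(
    location: FieldLocation,
    established_threshold: int,
    last_seen_luminance: float,
    observer: Observer,
    rng: np.random.Generator,
    curve: CalibrationCurve,
    offset_cd_m2: float = FN_OFFSET_CD_M2,
    mode: str = "easier",
    time_ms: float | None = None,
) -> CatchTrialRecord:
    """Re-probe an established location near its last seen luminance.

    ``easier`` mode adds ``offset_cd_m2`` (brighter); ``literal`` mode
    subtracts it.  A missed response is a false negative.
    """
    if last_seen_luminance <= 0:
        raise IneligibleLocationError(
            f"location {location.id} has no seen stimulus to offset from"
        )
    if mode == "easier":
        target = last_seen_luminance + offset_cd_m2
    elif mode == "literal":
        target = last_seen_luminance - offset_cd_m2
    else:
        raise DomainError(f"unknown FN offset mode {mode!r}")
    target = min(max(target, luminance_from_db(curve, 49)), curve.max_luminance)
    level = db_from_luminance(curve, target).db
    seen, rt = respond(observer.surface, observer.params,
                       location.x, location.y, level, rng)
    return CatchTrialRecord(kind="FN", eye=observer.eye, triggered=not seen,
                            level_db=float(level), time_ms=time_ms,
                            location_id=location.id, response_time_ms=rt)


def summarize_reliability(records: list[CatchTrialRecord]) -> ReliabilityIndices:
    """Pure recount of catch-trial outcomes from the record list."""
    def count(kind: str) -> tuple[int, int]:
        probes = [r for r in records if r.kind == kind]
        return len(probes), sum(r.triggered for r in probes)

    fl_n, fl_t = count("FL")
    fp_n, fp_t = count("FP")
    fn_n, fn_t = count("FN")
    return ReliabilityIndices(fl_probes=fl_n, fl_triggers=fl_t,
                              fp_probes=fp_n, fp_triggers=fp_t,
                              fn_probes=fn_n, fn_triggers=fn_t)
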