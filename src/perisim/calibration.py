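"""Display calibration and the decibel attenuation scale.

A perimeter presents stimuli on a display whose gray levels (0-255) map
nonlinearly to luminance.  The engine consumes a measured table of
(gray level, luminance cd/m^2) knots, linearly interpolates between them,
and anchors the decibel scale to the display maximum: 0 dB is the
brightest renderable stimulus (120 cd/m^2 on the reference device) and

    dB(L) = 10 * log10(L_max / L),

clamped to the reportable range [0, 49].  Higher dB therefore means a
dimmer stimulus, and a higher threshold in dB means better sensitivity.

The background luminance (1 cd/m^2 by default, the device's scotopic
black background) is carried as metadata only; the dB reference is the
maximum stimulus luminance, not a Weber increment over background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationIntegrityError,
    DomainError,
    DuplicateKnotError,
    IncompleteCurveError,
    OutOfGamutError,
)

GRAY_MIN = 0
GRAY_MAX = 255
DB_MIN = 0.0
DB_MAX = 49.0
DEFAULT_BACKGROUND_CD_M2 = 1.0

#: Identity-gamma two-knot curve used as the test fixture: black at 0,
#: 120 cd/m^2 at gray 255. Real displays are nonlinear and are loaded
#: from measured CSV tables.
DEFAULT_TABLE: tuple[tuple[int, float], ...] = ((0, 0.0), (255, 120.0))


@dataclass(frozen=True)
class CalibrationKnot:
    """One measured (gray level, luminance) point."""

    gray_level: int
    luminance: float

    def __post_init__(self) -> None:
        if not (GRAY_MIN <= self.gray_level <= GRAY_MAX):
            raise DomainError(f"gray_level {self.gray_level} outside [0, 255]")
        if not np.isfinite(self.luminance) or self.luminance < 0:
            raise DomainError(f"luminance {self.luminance} must be finite and >= 0")


@dataclass(frozen=True)
class DecibelValue:
    """A dB attenuation value, with flags recording any clamping."""

    db: float
    floored: bool = False
    ceilinged: bool = False

    def __float__(self) -> float:
        return self.db


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear gray-level -> luminance map anchoring the dB scale."""

    knots: tuple[CalibrationKnot, ...]
    background_luminance: float = DEFAULT_BACKGROUND_CD_M2

    # cached interpolation vectors
    _grays: np.ndarray = field(init=False, repr=False, compare=False)
    _lums: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.knots) < 2:
            raise IncompleteCurveError("need at least 2 calibration knots")
        grays = np.array([k.gray_level for k in self.knots], dtype=float)
        lums = np.array([k.luminance for k in self.knots], dtype=float)
        if np.any(np.diff(grays) <= 0):
            raise DuplicateKnotError("gray levels must be strictly increasing")
        if np.any(np.diff(lums) < 0):
            raise CalibrationIntegrityError("luminance must be non-decreasing in gray level")
        if self.knots[0].gray_level != GRAY_MIN or self.knots[-1].gray_level != GRAY_MAX:
            raise IncompleteCurveError("curve must include knots at gray 0 and gray 255")
        object.__setattr__(self, "_grays", grays)
        object.__setattr__(self, "_lums", lums)

    @property
    def max_luminance(self) -> float:
        """Luminance at gray 255; the 0 dB reference."""
        return self.knots[-1].luminance


def load_calibration(
    table: Iterable[Sequence[float]],
    background_luminance: float = DEFAULT_BACKGROUND_CD_M2,
) -> CalibrationCurve:
    """Build a :class:`CalibrationCurve` from (gray, luminance) pairs.

    Pairs may arrive in any order; they are sorted by gray level.  Raises
    :class:`DuplicateKnotError` for repeated gray levels,
    :class:`IncompleteCurveError` if the 0/255 endpoints are missing, and
    :class:`CalibrationIntegrityError` if luminance decreases.
    """
    rows = [(int(g), float(l)) for g, l in table]
    if len(rows) < 2:
        raise IncompleteCurveError("need at least 2 calibration rows")
    grays = [g for g, _ in rows]
    if len(set(grays)) != len(grays):
        dupes = sorted({g for g in grays if grays.count(g) > 1})
        raise DuplicateKnotError(f"duplicate gray level(s): {dupes}")
    rows.sort(key=lambda r: r[0])
    knots = tuple(CalibrationKnot(g, l) for g, l in rows)
    return CalibrationCurve(knots=knots, background_luminance=background_luminance)


def load_calibration_csv(path, background_luminance: float = DEFAULT_BACKGROUND_CD_M2) -> CalibrationCurve:
    """Load a calibration CSV with header ``gray_level,luminance_cd_m2``.

    Comment lines starting with ``#`` are ignored.
    """
    df = pd.read_csv(path, comment="#")
    expected = {"gray_level", "luminance_cd_m2"}
    if not expected.issubset(df.columns):
        raise IncompleteCurveError(
            f"calibration CSV must have columns {sorted(expected)}, got {list(df.columns)}"
        )
    pairs = list(zip(df["gray_level"].tolist(), df["luminance_cd_m2"].tolist()))
    return load_calibration(pairs, background_luminance=background_luminance)


def luminance_at_gray(curve: CalibrationCurve, gray: float) -> float:
    """Interpolated luminance (cd/m^2) at a (possibly fractional) gray level."""
    if not (GRAY_MIN <= gray <= GRAY_MAX):
        raise DomainError(f"gray {gray} outside [0, 255]")
    return float(np.interp(gray, curve._grays, curve._lums))


def gray_for_luminance(curve: CalibrationCurve, target: float) -> tuple[int, float]:
    """Integer gray level whose luminance is nearest ``target``.

    Returns ``(gray_level, achieved_luminance)``.  Ties go to the lower
    gray level.  Only integer gray levels are renderable, so the achieved
    luminance can differ from the target by up to half the local
    per-gray-step luminance difference.
    """
    if target < 0:
        raise DomainError(f"target luminance {target} < 0")
    if target > curve.max_luminance:
        raise OutOfGamutError(
            f"target {target} cd/m^2 exceeds display maximum {curve.max_luminance}"
        )
    all_grays = np.arange(GRAY_MIN, GRAY_MAX + 1)
    lums = np.interp(all_grays, curve._grays, curve._lums)
    idx = int(np.argmin(np.abs(lums - target)))  # argmin takes the first = lowest gray
    return int(all_grays[idx]), float(lums[idx])


def db_from_luminance(curve: CalibrationCurve, luminance: float) -> DecibelValue:
    """Attenuation in dB of a stimulus luminance, clamped to [0, 49]."""
    if luminance <= 0:
        raise DomainError(f"luminance must be > 0 for a dB value, got {luminance}")
    db = 10.0 * np.log10(curve.max_luminance / luminance)
    if db < DB_MIN:
        return DecibelValue(DB_MIN, floored=True)
    if db > DB_MAX:
        return DecibelValue(DB_MAX, ceilinged=True)
    return DecibelValue(float(db))


def luminance_from_db(curve: CalibrationCurve, db: float) -> float:
    """Stimulus luminance (cd/m^2) at a commanded attenuation in [0, 49] dB."""
    if not (DB_MIN <= db <= DB_MAX):
        raise DomainError(f"db {db} outside [{DB_MIN}, {DB_MAX}]")
    return float(curve.max_luminance / 10.0 ** (db / 10.0))


def default_curve(background_luminance: float = DEFAULT_BACKGROUND_CD_M2) -> CalibrationCurve:
    """The two-knot identity-gamma fixture curve {(0,0),(255,120)}."""
    return load_calibration(DEFAULT_TABLE, background_luminance=background_luminance)
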