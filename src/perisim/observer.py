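"""Synthetic observers: sensitivity surfaces and a frequency-of-seeing model.

The simulated patient stands in for human subjects.  Its true sensitivity
is a surface over the visual field — flat, a "hill of vision" declining
linearly with eccentricity, or an explicit per-point map — optionally
carved by circular scotomas and containing an absolute physiologic blind
spot.  Responses follow a cumulative-Gaussian frequency-of-seeing curve

    p(seen | stimulus s dB at true sensitivity t) =
        guess + (1 - guess - lapse) * Phi((t - s) / sigma),

with ``guess`` the probability of responding to an invisible stimulus,
``lapse`` the probability of missing a visible one, and ``sigma`` the
psychometric slope in dB.  Fixation jitter displaces the effective
stimulus location by a per-trial bivariate-normal gaze offset; it is the
mechanism that makes Heijl-Krakau fixation-loss probes nontrivial.
Response times, used by suprathreshold summaries and duration
accounting, are lognormal.

Healthy cohorts are generated near the regime of real healthy fields:
global mean sensitivity around 32 dB with central values above
pericentral ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.stats import norm

from .calibration import DB_MAX, DB_MIN
from .errors import DomainError
from .patterns import BLIND_SPOT_CENTER_OD, Eye

#: Sentinel sensitivity for absolute (blind-spot) regions: the stimulus is
#: never seen there apart from guesses.  -inf flows through the Gaussian
#: CDF naturally (Phi(-inf) = 0 -> p = guess).
ABSOLUTE = -math.inf

BLIND_SPOT_RADIUS_DEG = 2.5


@dataclass(frozen=True)
class Scotoma:
    """Circular sensitivity loss: ``depth`` dB subtracted inside ``radius``."""

    x: float
    y: float
    radius: float
    depth: float


@dataclass(frozen=True)
class SensitivitySurface:
    """True sensitivity as a function of field position.

    ``kind`` is ``flat`` (constant ``peak``), ``hill`` (peak minus
    ``slope`` dB per degree of eccentricity) or ``map`` (explicit values
    keyed by (x, y), nearest-point lookup).  Values clamp to [0, 49];
    scotoma depths subtract after the base surface, floored at 0.
    """

    kind: str = "hill"
    peak: float = 34.0
    slope: float = 0.2
    scotomas: tuple[Scotoma, ...] = ()
    blind_spot: tuple[tuple[float, float], float] | None = (BLIND_SPOT_CENTER_OD, BLIND_SPOT_RADIUS_DEG)
    value_map: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "hill", "map"):
            raise DomainError(f"unknown surface kind {self.kind!r}")
        if self.kind == "map" and not self.value_map:
            raise DomainError("map surface requires value_map entries")


def sensitivity_at(surface: SensitivitySurface, x: float, y: float) -> float:
    """True sensitivity in dB at (x, y); :data:`ABSOLUTE` inside the blind spot."""
    if surface.blind_spot is not None:
        (bx, by), br = surface.blind_spot
        if math.hypot(x - bx, y - by) <= br:
            return ABSOLUTE
    if surface.kind == "flat":
        t = surface.peak
    elif surface.kind == "hill":
        t = surface.peak - surface.slope * math.hypot(x, y)
    else:
        t = min(surface.value_map, key=lambda e: math.hypot(e[0] - x, e[1] - y))[2]
    t = min(max(t, DB_MIN), DB_MAX)
    for s in surface.scotomas:
        if math.hypot(x - s.x, y - s.y) <= s.radius:
            t = max(t - s.depth, 0.0)
    return t


@dataclass(frozen=True)
class PsychometricParams:
    """Frequency-of-seeing, fixation, and response-time parameters."""

    sigma: float = 1.0          # FoS slope, dB
    guess_rate: float = 0.0     # P(respond | invisible stimulus)
    lapse_rate: float = 0.0     # P(miss | clearly visible stimulus)
    fixation_sigma: float = 0.0  # per-trial gaze offset SD, degrees
    rt_log_mean: float = math.log(450.0)  # lognormal response time, ms
    rt_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError("sigma must be > 0")
        if not (0 <= self.guess_rate and 0 <= self.lapse_rate
                and self.guess_rate + self.lapse_rate < 1):
            raise DomainError("need 0 <= guess_rate + lapse_rate < 1")
        if self.fixation_sigma < 0:
            raise DomainError("fixation_sigma must be >= 0")


@dataclass(frozen=True)
class Observer:
    """A synthetic patient: one eye's surface plus response model."""

    surface: SensitivitySurface
    params: PsychometricParams = field(default_factory=PsychometricParams)
    eye: Eye = "OD"


def p_seen(
    surface: SensitivitySurface,
    params: PsychometricParams,
    x: float,
    y: float,
    stimulus_db: float,
) -> float:
    """Detection probability for a stimulus of ``stimulus_db`` at (x, y).

    No gaze offset is applied here; :func:`respond` perturbs the location
    before evaluating this curve.
    """
    if not (DB_MIN <= stimulus_db <= DB_MAX):
        raise DomainError(f"stimulus_db {stimulus_db} outside [{DB_MIN}, {DB_MAX}]")
    t = sensitivity_at(surface, x, y)
    if t == ABSOLUTE:
        return params.guess_rate
    core = norm.cdf((t - stimulus_db) / params.sigma)
    return params.guess_rate + (1.0 - params.guess_rate - params.lapse_rate) * float(core)


def respond(
    surface: SensitivitySurface,
    params: PsychometricParams,
    x: float,
    y: float,
    stimulus_db: float,
    rng: np.random.Generator,
) -> tuple[bool, float | None]:
    """One Bernoulli trial: (seen, response_time_ms or None).

    Samples the trial's gaze offset, evaluates the frequency-of-seeing
    curve at the perturbed location, and draws the response.  Fully
    reproducible given the generator state.
    """
    if params.fixation_sigma > 0:
        dx, dy = rng.normal(0.0, params.fixation_sigma, size=2)
    else:
        dx = dy = 0.0
    p = p_seen(surface, params, x - dx, y - dy, stimulus_db)
    seen = bool(rng.random() < p)
    rt = float(rng.lognormal(params.rt_log_mean, params.rt_log_sd)) if seen else None
    return seen, rt


def false_response(params: PsychometricParams, rng: np.random.Generator) -> tuple[bool, float | None]:
    """Response in an empty window (no stimulus): Bernoulli(guess_rate)."""
    seen = bool(rng.random() < params.guess_rate)
    rt = float(rng.lognormal(params.rt_log_mean, params.rt_log_sd)) if seen else None
    return seen, rt


def make_cohort(
    n: int,
    regime: str,
    rng: np.random.Generator,
    eye: Eye = "OD",
    params: PsychometricParams | None = None,
) -> list[Observer]:
    """Generate ``n`` synthetic observers for one eye.

    ``healthy``: hill surfaces with peak ~ Normal(34, 1) dB and slope ~
    Normal(0.2, 0.05) dB/deg (slope floored at 0.05 so central values
    stay above pericentral), no scotomas.  ``glaucoma``: a healthy base
    plus 1-3 circular scotomas of depth 5-30 dB and radius 2-6 deg,
    centered within 21 deg of fixation.  Reproducible per generator state.
    """
    if n < 1:
        raise DomainError("cohort size must be >= 1")
    if regime not in ("healthy", "glaucoma"):
        raise DomainError(f"unknown regime {regime!r}")
    if params is None:
        params = PsychometricParams(sigma=1.0, guess_rate=0.01, lapse_rate=0.01,
                                    fixation_sigma=0.5)
    bs_center = (BLIND_SPOT_CENTER_OD if eye == "OD"
                 else (-BLIND_SPOT_CENTER_OD[0], BLIND_SPOT_CENTER_OD[1]))
    out: list[Observer] = []
    for _ in range(n):
        peak = float(rng.normal(34.0, 1.0))
        slope = max(float(rng.normal(0.2, 0.05)), 0.05)
        scotomas: list[Scotoma] = []
        if regime == "glaucoma":
            for _ in range(int(rng.integers(1, 4))):
                ecc = float(rng.uniform(3.0, 21.0))
                theta = float(rng.uniform(0.0, 2.0 * math.pi))
                scotomas.append(Scotoma(
                    x=ecc * math.cos(theta),
                    y=ecc * math.sin(theta),
                    radius=float(rng.uniform(2.0, 6.0)),
                    depth=float(rng.uniform(5.0, 30.0)),
                ))
        surface = SensitivitySurface(
            kind="hill", peak=peak, slope=slope, scotomas=tuple(scotomas),
            blind_spot=(bs_center, BLIND_SPOT_RADIUS_DEG),
        )
        out.append(Observer(surface=surface, params=params, eye=eye))
    return out


# ---------------------------------------------------------------------------
# Observer spec (YAML/JSON) I/O

def observer_from_dict(doc: dict) -> Observer:
    s = doc.get("surface", {})
    bs = s.get("blind_spot")
    blind_spot = None
    if bs is not None:
        blind_spot = ((float(bs["x"]), float(bs["y"])), float(bs.get("radius", BLIND_SPOT_RADIUS_DEG)))
    surface = SensitivitySurface(
        kind=s.get("kind", "hill"),
        peak=float(s.get("peak", 34.0)),
        slope=float(s.get("slope", 0.2)),
        scotomas=tuple(
            Scotoma(x=sc["x"], y=sc["y"], radius=sc["radius"], depth=sc["depth"])
            for sc in s.get("scotomas", [])
        ),
        blind_spot=blind_spot,
        value_map=tuple(tuple(e) for e in s.get("value_map", [])),
    )
    p = doc.get("psychometric", {})
    r = doc.get("rt", {})
    params = PsychometricParams(
        sigma=float(p.get("sigma", 1.0)),
        guess_rate=float(p.get("guess", 0.0)),
        lapse_rate=float(p.get("lapse", 0.0)),
        fixation_sigma=float(p.get("fixation_sigma", 0.0)),
        rt_log_mean=float(r.get("log_mean", math.log(450.0))),
        rt_log_sd=float(r.get("log_sd", 0.25)),
    )
    return Observer(surface=surface, params=params, eye=doc.get("eye", "OD"))


def load_observer(path) -> Observer:
    """Load an observer spec from a YAML or JSON file."""
    with open(path) as fh:
        text = fh.read()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    return observer_from_dict(doc)


def mirror_observer(obs: Observer) -> Observer:
    """The fellow-eye observer: surface mirrored in x, opposite eye label."""
    s = obs.surface
    bs = None
    if s.blind_spot is not None:
        (bx, by), br = s.blind_spot
        bs = ((-bx, by), br)
    surface = replace(
        s,
        scotomas=tuple(replace(sc, x=-sc.x) for sc in s.scotomas),
        blind_spot=bs,
        value_map=tuple((-x, y, v) for x, y, v in s.value_map),
    )
    return Observer(surface=surface, params=obs.params,
                    eye="OS" if obs.eye == "OD" else "OD")
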