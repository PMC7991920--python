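"""Clinical report statistics: sector means, MD/PSD, deviation maps.

Given a completed threshold map and a normative model (per-location
normal means and standard deviations, here built from simulated
cohorts), the report computes:

* **Sector means** — mean ± SD of thresholds per quadrant (ST/SN/IN/IT),
  per region (central: eccentricity <= 12°; pericentral: 12-24°), and
  globally.
* **Total deviation (TD)** — measured threshold minus the normal mean at
  each location; **general height** — the k-th best TD with
  k = max(1, floor(0.15 n)) (the 7th-best location on the 50-point
  grid), capturing diffuse loss; **pattern deviation (PD)** — TD minus
  general height, isolating focal defects.
* **Probability grades** — one-sided normal tail of TD against the
  normative SD at the 5 / 2 / 1 / 0.5 % cutoffs.
* **MD** (mean deviation) — the variance-weighted mean of TD,
  MD = sum(w_i TD_i) / sum(w_i) with w_i = 1 / SD_i^2; **PSD** — the
  matching weighted dispersion sqrt(sum(w_i (TD_i - MD)^2) / sum(w_i)).
  A uniformly depressed field therefore has MD equal to the depression
  and PSD zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .errors import (
    DegenerateCohortError,
    IncompleteResultError,
    PatternMismatchError,
    ReportSchemaError,
)
from .patterns import SectorAssignment, TestPattern

PROBABILITY_CUTOFFS = (0.05, 0.02, 0.01, 0.005)
GENERAL_HEIGHT_FRACTION = 0.15
GRAYSCALE_BIN_WIDTH_DB = 5
GRAYSCALE_N_BINS = 10

SECTORS = ("ST", "SN", "IN", "IT", "global", "central", "pericentral")


@dataclass(frozen=True)
class SectorSummary:
    """Mean ± population SD of thresholds per sector."""

    means: dict[str, float]
    sds: dict[str, float]
    counts: dict[str, int]


@dataclass(frozen=True)
class NormativeModel:
    """Per-location normal mean/SD on a named pattern, with provenance."""

    pattern_name: str
    means: dict[int, float]
    sds: dict[int, float]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sds):
            raise PatternMismatchError("means and sds cover different locations")
        if any(sd <= 0 for sd in self.sds.values()):
            raise DegenerateCohortError("normative SDs must be > 0")

    def to_json(self) -> str:
        return json.dumps({
            "pattern": self.pattern_name,
            "locations": {str(k): {"mean": self.means[k], "sd": self.sds[k]}
                          for k in sorted(self.means)},
            "provenance": self.provenance,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        doc = json.loads(text)
        means = {int(k): v["mean"] for k, v in doc["locations"].items()}
        sds = {int(k): v["sd"] for k, v in doc["locations"].items()}
        return cls(pattern_name=doc["pattern"], means=means, sds=sds,
                   provenance=doc.get("provenance"))


@dataclass(frozen=True)
class DeviationMaps:
    total_deviation: dict[int, float]
    pattern_deviation: dict[int, float]
    general_height: float
    grades: dict[int, str]  # ">=5%", "<5%", "<2%", "<1%", "<0.5%"


@dataclass(frozen=True)
class GlobalIndices:
    md: float
    psd: float


def sector_means(
    thresholds: Mapping[int, float],
    sectors: Mapping[int, SectorAssignment],
) -> SectorSummary:
    """Mean and population SD of thresholds per quadrant/region/global."""
    missing = set(sectors) - set(thresholds)
    if missing:
        raise IncompleteResultError(f"thresholds missing for locations {sorted(missing)}")
    groups: dict[str, list[float]] = {s: [] for s in SECTORS}
    for lid, assign in sectors.items():
        t = float(thresholds[lid])
        groups[assign.quadrant].append(t)
        groups[assign.region].append(t)
        groups["global"].append(t)
    means, sds, counts = {}, {}, {}
    for s, vals in groups.items():
        counts[s] = len(vals)
        if vals:
            means[s] = float(np.mean(vals))
            sds[s] = float(np.std(vals))  # population SD
        else:
            means[s] = math.nan
            sds[s] = math.nan
    return SectorSummary(means=means, sds=sds, counts=counts)


NORMATIVE_SD_FLOOR_DB = 1.0


def build_normative(
    cohort_thresholds: list[Mapping[int, float]],
    pattern: TestPattern,
    provenance: dict | None = None,
    sd_floor: float = NORMATIVE_SD_FLOOR_DB,
) -> NormativeModel:
    """Per-location mean/SD across a cohort of threshold maps (population SD).

    Per-location SDs are floored at ``sd_floor`` (integer-dB thresholds can
    collide by chance in small cohorts, and a zero SD would make the
    probability maps infinitely confident).  A cohort with zero variance
    everywhere — identical members — is rejected as degenerate.
    """
    if len(cohort_thresholds) < 2:
        raise DegenerateCohortError("need >= 2 cohort members")
    ids = {loc.id for loc in pattern.locations}
    for i, th in enumerate(cohort_thresholds):
        if set(th) != ids:
            raise PatternMismatchError(f"cohort member {i} does not cover pattern "
                                       f"{pattern.name}")
    means, sds = {}, {}
    raw_sds = []
    for lid in sorted(ids):
        vals = np.array([th[lid] for th in cohort_thresholds], dtype=float)
        means[lid] = float(vals.mean())
        sd = float(vals.std(ddof=0))
        raw_sds.append(sd)
        sds[lid] = max(sd, sd_floor)
    if max(raw_sds) <= 0:
        raise DegenerateCohortError("cohort members are identical (zero variance)")
    return NormativeModel(pattern_name=pattern.name, means=means, sds=sds,
                          provenance=provenance)


def _grade(td: float, sd: float) -> str:
    p = float(norm.cdf(td / sd))
    if p < 0.005:
        return "<0.5%"
    if p < 0.01:
        return "<1%"
    if p < 0.02:
        return "<2%"
    if p < 0.05:
        return "<5%"
    return ">=5%"


def deviation_maps(
    thresholds: Mapping[int, float], norm_model: NormativeModel
) -> DeviationMaps:
    """Total/pattern deviation and probability grades against the norm."""
    if set(norm_model.means) != set(thresholds):
        raise PatternMismatchError("normative model does not cover the result's locations")
    td = {lid: float(thresholds[lid]) - norm_model.means[lid] for lid in thresholds}
    n = len(td)
    k = max(1, int(math.floor(GENERAL_HEIGHT_FRACTION * n)))
    general_height = sorted(td.values(), reverse=True)[k - 1]
    pd = {lid: v - general_height for lid, v in td.items()}
    grades = {lid: _grade(td[lid], norm_model.sds[lid]) for lid in td}
    return DeviationMaps(total_deviation=td, pattern_deviation=pd,
                         general_height=general_height, grades=grades)


def global_indices(maps: DeviationMaps, norm_model: NormativeModel) -> GlobalIndices:
    """Variance-weighted MD and PSD from the total-deviation map."""
    ids = sorted(maps.total_deviation)
    td = np.array([maps.total_deviation[i] for i in ids])
    w = np.array([1.0 / norm_model.sds[i] ** 2 for i in ids])
    md = float(np.sum(w * td) / np.sum(w))
    psd = float(math.sqrt(np.sum(w * (td - md) ** 2) / np.sum(w)))
    return GlobalIndices(md=md, psd=psd)


def grayscale_map(thresholds: Mapping[int, float]) -> dict[int, int]:
    """Ten 5-dB bins: 0 = darkest (0-4 dB) ... 9 = lightest (45-49 dB)."""
    return {
        lid: min(int(float(t) // GRAYSCALE_BIN_WIDTH_DB), GRAYSCALE_N_BINS - 1)
        for lid, t in thresholds.items()
    }


# ---------------------------------------------------------------------------
# Report document

REQUIRED_REPORT_FIELDS = {
    "name": str, "dob": str, "gender": str, "test_id": str, "exam_date": str,
    "test_time": str, "strategy": str,
}
_EYE_REQUIRED = {"fixation_losses", "false_positives", "false_negatives",
                 "thresholds", "grayscale", "md", "psd"}


def _load_schema() -> dict:
    with resources.files("perisim.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(doc: dict) -> None:
    """Check the report against the shipped schema; raise on violation."""
    schema = _load_schema()
    for field_name, type_name in schema["required"].items():
        if field_name not in doc:
            raise ReportSchemaError(f"missing report field {field_name!r}")
        expected = {"string": str, "object": dict}[type_name]
        if not isinstance(doc[field_name], expected):
            raise ReportSchemaError(f"field {field_name!r} must be {type_name}")
    if not doc["per_eye"]:
        raise ReportSchemaError("report must cover >= 1 eye")
    for eye, section in doc["per_eye"].items():
        missing = set(schema["per_eye_required"]) - set(section)
        if missing:
            raise ReportSchemaError(f"eye {eye} section missing {sorted(missing)}")
        if doc["normative"] != "none" and "total_deviation" not in section:
            raise ReportSchemaError("normative model supplied but TD section absent")


def render_report(
    result,
    metadata: Mapping[str, str],
    norm_model: NormativeModel | None = None,
    sectors_by_eye: Mapping[str, Mapping[int, SectorAssignment]] | None = None,
) -> dict:
    """Assemble and validate the clinical report document.

    ``result`` is a completed :class:`~perisim.session.SessionResult`.
    Deviation sections are included only when a normative model is
    supplied; otherwise the report is flagged ``normative: none``.
    """
    doc: dict = {k: str(metadata.get(k, "")) for k in REQUIRED_REPORT_FIELDS}
    doc["strategy"] = doc["strategy"] or result.protocol
    doc["normative"] = "none" if norm_model is None else "simulated"
    if norm_model is not None and norm_model.provenance:
        doc["normative_provenance"] = norm_model.provenance
    doc["protocol"] = result.protocol
    doc["total_duration_s"] = result.total_duration_s
    doc["per_eye_duration_s"] = result.per_eye_duration_s
    doc["per_eye"] = {}
    for eye in result.eyes:
        rel = result.reliability[eye]
        th = result.thresholds[eye]
        section: dict = {
            "fixation_losses": f"{rel.fl_triggers}/{rel.fl_probes}",
            "false_positives": rel.false_positive_rate,
            "false_negatives": rel.false_negative_rate,
            "thresholds": {str(k): v for k, v in sorted(th.items())},
            "grayscale": {str(k): v for k, v in sorted(grayscale_map(th).items())}
            if th else {},
            "md": None,
            "psd": None,
        }
        if norm_model is not None and th:
            maps = deviation_maps(th, norm_model)
            idx = global_indices(maps, norm_model)
            section["md"] = idx.md
            section["psd"] = idx.psd
            section["total_deviation"] = {str(k): round(v, 3)
                                          for k, v in sorted(maps.total_deviation.items())}
            section["pattern_deviation"] = {str(k): round(v, 3)
                                            for k, v in sorted(maps.pattern_deviation.items())}
            section["probability_grades"] = {str(k): v
                                             for k, v in sorted(maps.grades.items())}
        if sectors_by_eye is not None and th:
            summary = sector_means(th, sectors_by_eye[eye])
            section["sector_means"] = {s: {"mean": round(summary.means[s], 2),
                                           "sd": round(summary.sds[s], 2),
                                           "n": summary.counts[s]}
                                       for s in SECTORS}
        doc["per_eye"][eye] = section
    validate_report(doc)
    return doc


def report_csv(result, norm_model: NormativeModel | None, patterns) -> str:
    """CSV export of threshold and deviation grids.

    Columns: ``location_id,x,y,eye,threshold_db,td,pd,grade``.
    """
    lines = ["location_id,x,y,eye,threshold_db,td,pd,grade"]
    for eye in result.eyes:
        th = result.thresholds[eye]
        maps = deviation_maps(th, norm_model) if (norm_model and th) else None
        pat = patterns[eye]
        for lid in sorted(th):
            loc = pat.location(lid)
            td = f"{maps.total_deviation[lid]:.3f}" if maps else ""
            pd = f"{maps.pattern_deviation[lid]:.3f}" if maps else ""
            grade = maps.grades[lid] if maps else ""
            lines.append(f"{lid},{loc.x},{loc.y},{eye},{th[lid]},{td},{pd},{grade}")
    return "\n".join(lines) + "\n"
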