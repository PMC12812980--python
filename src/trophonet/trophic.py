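"""Trophic State Index (TSI) scoring and classification.

Implements the modified Carlson TSI used for Chinese rivers: four component
indices computed from chlorophyll-a (μg/L), total nitrogen (mg/L), total
phosphorus (mg/L) and Secchi disk depth (m), combined into a weighted
composite on the 0–100 scale and classified from oligotrophic to
hyper-eutrophic.  All logarithms are natural logarithms; the printed
component constants are only consistent with ln.

Units are enforced, never converted: Chl-a in μg/L, TN and TP in mg/L,
Secchi depth in m.  Non-positive measurements are rejected rather than
clamped (no detection-limit substitution rule is defined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TSI_COEFFICIENTS",
    "COMPOSITE_WEIGHTS",
    "TROPHIC_LABELS",
    "WaterChemistryRecord",
    "TrophicAssessment",
    "TrophicSummary",
    "tsi_component",
    "composite_tsi",
    "classify_trophic_state",
    "is_eutrophic",
    "assess_record",
    "assess_sites",
]

# Component score = 10 * (a + b * ln(value)); (a, b) per measured quantity.
TSI_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "chl_a": (2.5, 1.086),   # chlorophyll-a, μg/L
    "tn": (5.453, 1.694),    # total nitrogen, mg/L
    "tp": (9.436, 1.624),    # total phosphorus, mg/L
    "sd": (5.118, -1.94),    # Secchi depth, m (transparency falls as TSI rises)
}

# Composite weights in the order (Chl-a, TN, TP, SD); they sum to 1.
COMPOSITE_WEIGHTS: dict[str, float] = {
    "chl_a": 0.326,
    "tn": 0.219,
    "tp": 0.230,
    "sd": 0.225,
}

TROPHIC_LABELS = (
    "oligotrophic",
    "mesotrophic",
    "slightly_eutrophic",
    "moderately_eutrophic",
    "hyper_eutrophic",
)


class ChemistryDomainError(ValueError):
    """A chemistry measurement is outside the domain of its TSI component."""


def tsi_component(kind: str, value: float, *, site_id: str | None = None) -> float:
    """Return one component TSI score, ``10 * (a + b * ln(value))``.

    Parameters
    ----------
    kind:
        One of ``chl_a``, ``tn``, ``tp``, ``sd``.
    value:
        The measurement in the component's unit (μg/L, mg/L, mg/L, m).
    site_id:
        Optional label used in error messages.
    """
    try:
        a, b = TSI_COEFFICIENTS[kind]
    except KeyError:
        raise ValueError(
            f"unknown TSI component {kind!r}; expected one of {sorted(TSI_COEFFICIENTS)}"
        ) from None
    if not np.isfinite(value) or value <= 0:
        where = f" at site {site_id!r}" if site_id else ""
        raise ChemistryDomainError(
            f"{kind} must be a positive finite number{where}; got {value!r}"
        )
    return 10.0 * (a + b * math.log(value))


def composite_tsi(tsi_chl: float, tsi_tn: float, tsi_tp: float, tsi_sd: float) -> float:
    """Weighted composite TSI from the four component scores.

    All four components are required; there is no missing-component
    reweighting by default (see :func:`assess_record` for the opt-in).
    """
    parts = {"chl_a": tsi_chl, "tn": tsi_tn, "tp": tsi_tp, "sd": tsi_sd}
    for name, score in parts.items():
        if score is None or not np.isfinite(score):
            raise ValueError(f"component TSI({name}) is missing or non-finite: {score!r}")
    return sum(COMPOSITE_WEIGHTS[k] * parts[k] for k in parts)


def classify_trophic_state(tsi: float) -> str:
    """Map a composite TSI to its trophic class label.

    Boundaries follow the printed intervals verbatim: ``TSI < 30``
    oligotrophic; ``30 ≤ TSI ≤ 50`` mesotrophic; ``50 < TSI ≤ 60`` slightly
    eutrophic; ``60 < TSI ≤ 70`` moderately eutrophic; ``TSI > 70``
    hyper-eutrophic.
    """
    if not np.isfinite(tsi):
        raise ValueError(f"TSI must be finite, got {tsi!r}")
    if tsi < 30:
        return "oligotrophic"
    if tsi <= 50:
        return "mesotrophic"
    if tsi <= 60:
        return "slightly_eutrophic"
    if tsi <= 70:
        return "moderately_eutrophic"
    return "hyper_eutrophic"


def is_eutrophic(tsi: float) -> bool:
    """Eutrophic predicate: composite TSI strictly above 50."""
    return tsi > 50


@dataclass(frozen=True)
class WaterChemistryRecord:
    """One site's measured water chemistry.

    ``extras`` holds optional covariates (wt °C, do mg/L, cod mg/L, ph,
    nh4 mg/L, no3 mg/L, po4 mg/L, cond μS/cm, orp mV, flow m/s) that are
    carried through but not used in TSI scoring.
    """

    site_id: str
    tn: float
    tp: float
    chl_a: float
    secchi: float
    extras: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be a non-empty string")


@dataclass(frozen=True)
class TrophicAssessment:
    """Per-site component and composite TSI scores with class label."""

    site_id: str
    tsi_chl: float
    tsi_tn: float
    tsi_tp: float
    tsi_sd: float
    tsi: float
    label: str


@dataclass(frozen=True)
class TrophicSummary:
    """Summary of composite TSI over a set of assessed units.

    ``sd`` is the sample standard deviation (n−1 denominator); for a single
    unit it is reported as 0.0 with ``sd_defined`` False.  One input row is
    one classified unit; any replicate aggregation is left to the caller.
    """

    n_samples: int
    counts: Mapping[str, int]
    fraction_eutrophic: float  # percent of units with TSI > 50
    tsi_min: float
    tsi_max: float
    tsi_median: float
    tsi_mean: float
    tsi_sd: float
    sd_defined: bool


def assess_record(
    record: WaterChemistryRecord, *, allow_missing: bool = False
) -> TrophicAssessment:
    """Score and classify one site.

    With ``allow_missing=True`` (an extension, never the default), absent
    components (None) are dropped and the remaining weights renormalized.
    """
    raw = {"chl_a": record.chl_a, "tn": record.tn, "tp": record.tp, "sd": record.secchi}
    present = {k: v for k, v in raw.items() if v is not None}
    if len(present) < 4 and not allow_missing:
        missing = sorted(set(raw) - set(present))
        raise ValueError(
            f"site {record.site_id!r} is missing components {missing}; "
            "pass allow_missing=True to renormalize remaining weights"
        )
    if not present:
        raise ValueError(f"site {record.site_id!r} has no usable components")
    scores = {k: tsi_component(k, v, site_id=record.site_id) for k, v in present.items()}
    wsum = sum(COMPOSITE_WEIGHTS[k] for k in scores)
    tsi = sum(COMPOSITE_WEIGHTS[k] * s for k, s in scores.items()) / wsum
    return TrophicAssessment(
        site_id=record.site_id,
        tsi_chl=scores.get("chl_a", math.nan),
        tsi_tn=scores.get("tn", math.nan),
        tsi_tp=scores.get("tp", math.nan),
        tsi_sd=scores.get("sd", math.nan),
        tsi=tsi,
        label=classify_trophic_state(tsi),
    )


def summarize(assessments: Sequence[TrophicAssessment]) -> TrophicSummary:
    """Descriptive statistics of composite TSI over assessed units."""
    if not assessments:
        raise ValueError("cannot summarize an empty assessment list")
    tsi = np.asarray([a.tsi for a in assessments], dtype=float)
    counts = {label: 0 for label in TROPHIC_LABELS}
    for a in assessments:
        counts[a.label] += 1
    n = len(tsi)
    sd_defined = n > 1
    return TrophicSummary(
        n_samples=n,
        counts=counts,
        fraction_eutrophic=100.0 * float(np.mean(tsi > 50)),
        tsi_min=float(tsi.min()),
        tsi_max=float(tsi.max()),
        tsi_median=float(np.median(tsi)),
        tsi_mean=float(tsi.mean()),
        tsi_sd=float(tsi.std(ddof=1)) if sd_defined else 0.0,
        sd_defined=sd_defined,
    )


def assess_sites(
    records: Iterable[WaterChemistryRecord], *, allow_missing: bool = False
) -> tuple[list[TrophicAssessment], TrophicSummary]:
    """Assess every record and summarize the composite TSI distribution.

    site_ids must be unique; any invalid record aborts with its site_id.
    """
    records = list(records)
    if not records:
        raise ValueError("no water chemistry records supplied")
    seen: set[str] = set()
    for r in records:
        if r.site_id in seen:
            raise ValueError(f"duplicate site_id {r.site_id!r}")
        seen.add(r.site_id)
    assessments = [assess_record(r, allow_missing=allow_missing) for r in records]
    return assessments, summarize(assessments)
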