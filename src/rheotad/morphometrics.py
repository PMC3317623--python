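"""Measurement data model and ratio descriptors for tadpole morphometrics.

Measurements follow the standard larval-morphology abbreviation schema (BL body
length, TL total length, ODW oral-disc width, DG dorsal-gap size, JW jaw-sheath
width, A1len length of the first upper keratodont row, MP/SMP marginal and
submarginal papilla counts, ...), all lengths in mm, all counts dimensionless.
Ratios are carried as percentages (100 = the two measurements are equal), and
a coarse verbal descriptor scale classifies them: a ratio of 97-103% is
"equal", 95-96% or 104-105% "almost equal", 47-53% "in the middle", and
45-46% or 54-55% "almost in the middle".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ABBREVIATIONS",
    "COUNT_FIELDS",
    "STANDARD_RATIOS",
    "MeasurementRecord",
    "RatioDescriptor",
    "MissingFieldError",
    "ZeroDenominatorError",
    "compute_ratio",
    "describe_ratio",
    "derive_standard_ratios",
    "validate_record",
]

#: Continuous measurement fields (mm unless noted).
_LENGTH_FIELDS = (
    "BL TL TAL BH BW DF DMTH ED EH HAB IND IOD JW MCL MTH ND NH NP ODW RN "
    "SBH SBW SE SH SL SS SV TH THM TMH TMHM TMW VF VL".split()
    + [f"A{i}len" for i in range(1, 9)]
    + [f"P{i}len" for i in range(1, 4)]
)

#: Integer count fields.
COUNT_FIELDS = frozenset(
    [f"A{i}num" for i in range(1, 9)]
    + [f"P{i}num" for i in range(1, 4)]
    + ["MP", "SMP", "UR", "LR"]
)

#: Keratodont densities (keratodonts per unit row length).
_DENSITY_FIELDS = [f"A{i}den" for i in range(1, 9)] + [f"P{i}den" for i in range(1, 4)]

#: Gap sizes (rows or mm depending on usage).
_GAP_FIELDS = ["DG", "VG"]

ABBREVIATIONS = frozenset(_LENGTH_FIELDS) | COUNT_FIELDS | frozenset(
    _DENSITY_FIELDS
) | frozenset(_GAP_FIELDS)

ORAL_DISC_MARGINS = ("continuous_with_snout", "shallow_crevice", "free")
LATERAL_TRANSPARENT_STATES = ("recognizable", "poorly_recognizable", "absent")

#: Ratio panel batched for the cluster rules (numerator, denominator).
STANDARD_RATIOS = (
    ("ODW", "BW"),
    ("DG", "ODW"),
    ("JW", "ODW"),
    ("A1len", "ODW"),
    ("TAL", "BL"),
    ("EH", "BH"),
    ("NH", "BH"),
    ("NH", "EH"),
    ("RN", "NP"),
    ("SE", "BL"),
    ("MCL", "JW"),
)

GOSNER_RANGE = (21, 46)


class MissingFieldError(KeyError):
    """A required measurement abbreviation is absent from the record."""


class ZeroDenominatorError(ZeroDivisionError):
    """Ratio denominator is zero."""


@dataclass
class MeasurementRecord:
    """One voucher tadpole: identity, stage, measurements and oral-disc traits.

    ``measurements`` maps abbreviations (see :data:`ABBREVIATIONS`) to values;
    missing measurements are first-class and simply absent from the mapping.
    """

    voucher_id: str = ""
    field_number: str = ""
    species_label: str = ""
    gosner_stage: Optional[int] = None
    measurements: dict[str, float] = field(default_factory=dict)
    # qualitative oral-disc and body-wall traits (None = not scored)
    has_dorsal_gap: Optional[bool] = None
    has_upper_jaw_sheath: Optional[bool] = None
    has_medial_convexity: Optional[bool] = None
    oral_disc_margin: Optional[str] = None
    lower_sheath_shape: Optional[str] = None  # "U" or "V"
    lower_sheath_ribbed: Optional[bool] = None
    lateral_bulge: Optional[bool] = None
    lateral_emargination: Optional[bool] = None
    has_dorsolateral_glands: Optional[bool] = None
    lateral_transparent_area: Optional[str] = None
    ltrf: Optional[str] = None

    def get(self, abbreviation: str) -> Optional[float]:
        return self.measurements.get(abbreviation)


def compute_ratio(
    record: MeasurementRecord, numerator: str, denominator: str
) -> float:
    """Percentage ratio of two measurement fields (numerator/denominator x 100).

    Raises :class:`MissingFieldError` naming the absent abbreviation, or
    :class:`ZeroDenominatorError` if the denominator is zero.
    """
    for name in (numerator, denominator):
        if record.get(name) is None:
            raise MissingFieldError(name)
    den = record.measurements[denominator]
    if den == 0:
        raise ZeroDenominatorError(f"{denominator} is zero")
    return record.measurements[numerator] / den * 100.0


@dataclass(frozen=True)
class RatioDescriptor:
    term: str
    rounded_percentage: int


def _round_half_away(value: float) -> int:
    # round-half-away-from-zero so 96.5 -> 97 deterministically
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def describe_ratio(value: float) -> RatioDescriptor:
    """Classify a percentage ratio on the verbal descriptor scale.

    The value is rounded to the nearest integer percent (half away from zero)
    before range lookup, so ``describe_ratio(x) == describe_ratio(round(x))``.
    """
    if value < 0:
        raise ValueError(f"ratio percentage must be non-negative, got {value}")
    r = _round_half_away(value)
    if 97 <= r <= 103:
        term = "equal"
    elif r in (95, 96, 104, 105):
        term = "almost_equal"
    elif 47 <= r <= 53:
        term = "in_the_middle"
    elif r in (45, 46, 54, 55):
        term = "almost_in_the_middle"
    else:
        term = "unclassified"
    return RatioDescriptor(term=term, rounded_percentage=r)


def derive_standard_ratios(record: MeasurementRecord) -> dict[str, float]:
    """Batch the standard ratio panel; present only where both operands are.

    Ratios whose operands are missing or whose denominator is zero are simply
    omitted — partial panels are normal, and :func:`validate_record` is the
    place that reports data problems.
    """
    panel: dict[str, float] = {}
    for num, den in STANDARD_RATIOS:
        try:
            panel[f"{num}/{den}"] = compute_ratio(record, num, den)
        except (MissingFieldError, ZeroDenominatorError):
            continue
    return panel


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str


def validate_record(
    record: MeasurementRecord, tl_tolerance: float = 0.05
) -> list[ValidationIssue]:
    """Report every invariant violation; an empty list means the record is valid.

    ``tl_tolerance`` is the allowed relative mismatch of TL vs BL + TAL (as a
    fraction of TL); a mismatch is a warning, not an error, because total
    length is measured independently of its parts.
    """
    issues: list[ValidationIssue] = []
    st = record.gosner_stage
    if st is not None and not GOSNER_RANGE[0] <= st <= GOSNER_RANGE[1]:
        issues.append(
            ValidationIssue(
                "error",
                f"gosner_stage {st} outside {GOSNER_RANGE[0]}..{GOSNER_RANGE[1]}",
            )
        )
    for name, value in record.measurements.items():
        if name not in ABBREVIATIONS:
            issues.append(ValidationIssue("warning", f"unknown abbreviation {name}"))
            continue
        if value < 0:
            issues.append(ValidationIssue("error", f"{name} is negative ({value})"))
        if name in COUNT_FIELDS and value != int(value):
            issues.append(
                ValidationIssue("error", f"count field {name} not an integer ({value})")
            )
    tl, bl, tal = (record.get(k) for k in ("TL", "BL", "TAL"))
    if None not in (tl, bl, tal) and tl > 0:
        if abs(tl - (bl + tal)) > tl_tolerance * tl:
            issues.append(
                ValidationIssue(
                    "warning",
                    f"TL {tl} inconsistent with BL+TAL {bl + tal:.2f} "
                    f"(tolerance {tl_tolerance:.0%} of TL)",
                )
            )
    dg = record.get("DG")
    if record.has_dorsal_gap is False and dg not in (None, 0):
        issues.append(
            ValidationIssue(
                "error", f"has_dorsal_gap is False but DG = {dg}"
            )
        )
    if (
        record.oral_disc_margin is not None
        and record.oral_disc_margin not in ORAL_DISC_MARGINS
    ):
        issues.append(
            ValidationIssue(
                "error", f"oral_disc_margin {record.oral_disc_margin!r} unknown"
            )
        )
    return issues
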