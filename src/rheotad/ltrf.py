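"""Labial tooth row formulas (LTRF).

An LTRF such as ``"8(5-8)/3"`` or ``"6(3-6)/3(1)"`` summarises the keratodont
(labial tooth) rows on a tadpole's oral disc: the number of upper rows, a slash,
the number of lower rows, each optionally followed by a parenthesised list of
the rows that bear a medial gap ("interrupted" rows).  Rows are indexed 1-based
from the jaw outward, so A1 is the first upper row and P1 the first lower row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Ltrf", "LtrfError", "parse_ltrf", "format_ltrf", "ltrf_summary"]

EN_DASH = "–"
_DASHES = "-–—"  # hyphen, en dash, em dash


class LtrfError(ValueError):
    """Raised for malformed or internally inconsistent formulas."""


@dataclass(frozen=True)
class Ltrf:
    """Structured keratodont-row formula.

    ``upper_gaps``/``lower_gaps`` hold the 1-based indices of interrupted rows.
    """

    upper_rows: int
    lower_rows: int
    upper_gaps: frozenset[int] = field(default_factory=frozenset)
    lower_gaps: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.upper_rows < 1:
            raise LtrfError("at least one upper keratodont row is required")
        if self.lower_rows < 0:
            raise LtrfError("lower row count must be non-negative")
        for label, gaps, n in (
            ("upper", self.upper_gaps, self.upper_rows),
            ("lower", self.lower_gaps, self.lower_rows),
        ):
            bad = [i for i in gaps if not 1 <= i <= n]
            if bad:
                raise LtrfError(
                    f"{label} gap index {min(bad)} outside row range 1..{n}"
                )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_ltrf(self)


_SIDE_RE = re.compile(r"^(\d+)\s*(?:\(\s*([\d,\s\-–—]+?)\s*\))?$")


def _parse_range_list(text: str) -> frozenset[int]:
    indices: set[int] = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            raise LtrfError(f"empty element in gap list {text!r}")
        m = re.match(rf"^(\d+)\s*[{_DASHES}]\s*(\d+)$", part)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise LtrfError(f"descending gap range {part!r}")
            indices.update(range(lo, hi + 1))
        elif part.isdigit():
            indices.add(int(part))
        else:
            raise LtrfError(f"cannot parse gap element {part!r}")
    return frozenset(indices)


def _parse_side(text: str, label: str) -> tuple[int, frozenset[int]]:
    m = _SIDE_RE.match(text.strip())
    if not m:
        raise LtrfError(f"malformed {label} labium {text!r}")
    n = int(m.group(1))
    gaps = _parse_range_list(m.group(2)) if m.group(2) else frozenset()
    return n, gaps


def parse_ltrf(text: str) -> Ltrf:
    """Parse a formula string into an :class:`Ltrf`.

    Accepts hyphen, en dash or em dash inside gap ranges, e.g. both
    ``"7(5-7)/3"`` and ``"7(5–7)/3"``.  Raises :class:`LtrfError` for malformed
    strings or gap indices exceeding the row count.
    """
    if not isinstance(text, str) or "/" not in text:
        raise LtrfError(f"not an LTRF string: {text!r}")
    upper_text, lower_text = text.split("/", 1)
    upper, upper_gaps = _parse_side(upper_text, "upper")
    lower, lower_gaps = _parse_side(lower_text, "lower")
    return Ltrf(upper, lower, upper_gaps, lower_gaps)


def _format_gaps(gaps: frozenset[int], dash: str) -> str:
    """Collapse contiguous runs to ranges; keep isolated indices as-is."""
    if not gaps:
        return ""
    items = sorted(gaps)
    runs: list[list[int]] = [[items[0], items[0]]]
    for i in items[1:]:
        if i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    parts = [
        f"{lo}{dash}{hi}" if hi > lo else str(lo) for lo, hi in runs
    ]
    return f"({','.join(parts)})"


def format_ltrf(ltrf: Ltrf, dash: str = EN_DASH) -> str:
    """Render the canonical formula string; inverse of :func:`parse_ltrf`.

    The dash used inside ranges defaults to the en dash; pass ``dash="-"`` for
    ASCII-only pipelines.
    """
    upper = f"{ltrf.upper_rows}{_format_gaps(ltrf.upper_gaps, dash)}"
    lower = f"{ltrf.lower_rows}{_format_gaps(ltrf.lower_gaps, dash)}"
    return f"{upper}/{lower}"


def ltrf_summary(ltrf: Ltrf) -> dict[str, int]:
    """Row statistics: totals and interrupted/uninterrupted counts per labium."""
    iu = len(ltrf.upper_gaps)
    il = len(ltrf.lower_gaps)
    return {
        "UR": ltrf.upper_rows,
        "LR": ltrf.lower_rows,
        "uninterrupted_upper": ltrf.upper_rows - iu,
        "interrupted_upper": iu,
        "uninterrupted_lower": ltrf.lower_rows - il,
        "interrupted_lower": il,
        "total_rows": ltrf.upper_rows + ltrf.lower_rows,
    }
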