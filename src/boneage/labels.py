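"""Ambiguous-label codec: report text -> Gaussian label distributions over monthly bins.

Radiology reports rarely state skeletal age to the month.  Typical statements
are a rounded point estimate ("approximately 9 years old") or an interval
("12-13 years old", "aged between 13 and 14").  This module parses such
statements, maps them to a mean age ``mu`` in months, and encodes ``mu`` as a
discrete Gaussian probability distribution over the ordered label set
``L = [1, 2, ..., 240]`` months:

    y_i = phi(l_i; mu, sigma) / sum_c phi(l_c; mu, sigma)

with ``phi`` the normal density.  The renormalisation over the 240 bins makes
the distribution exact on the label range (an implicit truncation).  A
predicted distribution is decoded back to months by its expectation (default)
or its argmax.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np

#: number of monthly bins; bin i (1-based) is l_i = i months, 0 < age <= 240
N_BINS = 240

#: bin centers in months, MONTHS[k] = k + 1
MONTHS = np.arange(1, N_BINS + 1, dtype=float)


class LabelKind(str, Enum):
    POINT = "point"
    INTERVAL = "interval"


class LabelParseError(ValueError):
    """Raised when report text contains no recognisable age statement."""

    def __init__(self, text: str):
        self.text = text
        super().__init__(f"could not extract an age label from report text: {text!r}")


@dataclass(frozen=True)
class AmbiguousLabel:
    """An age statement extracted from a report.

    ``low_months == high_months`` for point labels.  Bounds are in months and
    must satisfy ``0 < low <= high <= 240``.
    """

    kind: LabelKind
    low_months: float
    high_months: float
    raw_text: str = ""

    def __post_init__(self):
        if not (0 < self.low_months <= self.high_months <= N_BINS):
            raise ValueError(
                f"label bounds out of range (0, {N_BINS}]: "
                f"[{self.low_months}, {self.high_months}]"
            )
        if self.kind is LabelKind.POINT and self.low_months != self.high_months:
            raise ValueError("point label must have equal bounds")


@dataclass(frozen=True)
class LabelDistribution:
    """A probability vector over the 240 monthly bins, with its (mu, sigma)."""

    probs: np.ndarray
    mu: float
    sigma: float

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_BINS,):
            raise ValueError(f"probs must have shape ({N_BINS},), got {p.shape}")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("probs must sum to 1")
        object.__setattr__(self, "probs", p)

    def prob_at_month(self, month: int) -> float:
        """Probability of bin ``l = month`` (1-based months)."""
        return float(self.probs[month - 1])


_NUM = r"(\d+(?:\.\d+)?)"

# interval patterns, tried before point patterns ("12-13 years" contains "13 years")
_INTERVAL_PATTERNS = [
    # "12-13 years (old)", "12 – 13 years", "12 to 13 years"
    re.compile(_NUM + r"\s*(?:[-–—~]|to)\s*" + _NUM + r"\s*(years?|months?)",
               re.IGNORECASE),
    # "between 13 and 14 (years)", "aged between 13 and 14"
    re.compile(r"between\s+" + _NUM + r"\s+and\s+" + _NUM + r"(?:\s*(years?|months?))?",
               re.IGNORECASE),
]

_POINT_PATTERNS = [
    # "approximately 9 years (old)", "about 9 years", "around 9 years", "9 years old"
    re.compile(r"(?:approximately|about|around|roughly|~)?\s*" + _NUM
               + r"\s*(years?|months?)(?:\s*old)?", re.IGNORECASE),
]

_BARE_NUMBER = re.compile(r"^\s*" + _NUM + r"\s*$")


def _to_months(value: float, unit: str | None) -> float:
    if unit is None or unit.lower().startswith("year"):
        return value * 12.0
    return value


def parse_report_label(text: str) -> AmbiguousLabel:
    """Extract an :class:`AmbiguousLabel` from report text.

    Recognises point statements ("approximately 9 years old", "108 months"),
    interval statements ("12-13 years old", "aged between 13 and 14",
    "10 to 11 years"), and bare numeric labels, read as months.  Years are
    converted to months (x12).

    Raises
    ------
    LabelParseError
        If no age pattern is present.  Parsing never falls back to a default.
    """
    if not text or not text.strip():
        raise LabelParseError(text)

    m = _BARE_NUMBER.match(text)
    if m:
        months = float(m.group(1))
        return AmbiguousLabel(LabelKind.POINT, months, months, raw_text=text)

    for pat in _INTERVAL_PATTERNS:
        m = pat.search(text)
        if m:
            unit = m.group(3) if m.lastindex >= 3 else None
            low = _to_months(float(m.group(1)), unit)
            high = _to_months(float(m.group(2)), unit)
            if low > high:
                low, high = high, low
            return AmbiguousLabel(LabelKind.INTERVAL, low, high, raw_text=text)

    for pat in _POINT_PATTERNS:
        m = pat.search(text)
        if m:
            months = _to_months(float(m.group(1)), m.group(2))
            return AmbiguousLabel(LabelKind.POINT, months, months, raw_text=text)

    raise LabelParseError(text)


def label_to_mu(label: AmbiguousLabel) -> float:
    """Mean age in months for a parsed label.

    A point label maps to itself; an interval maps to its midpoint, so
    "12-13 years old" (144-156 months) maps to 150 months.
    """
    if label.kind is LabelKind.POINT:
        return label.low_months
    return 0.5 * (label.low_months + label.high_months)


def make_distribution(mu: float, sigma: float) -> LabelDistribution:
    """Encode ``mu`` as a Gaussian distribution over the 240 monthly bins.

    ``probs[i] = phi(l_i; mu, sigma) / sum_c phi(l_c; mu, sigma)`` with
    ``l_i = i+1`` months; the normalisation truncates the Gaussian to the
    label range exactly.

    Raises
    ------
    ValueError
        If ``mu`` lies outside ``(0, 240]`` or ``sigma <= 0``.
    """
    if not (0 < mu <= N_BINS):
        raise ValueError(f"mu must be in (0, {N_BINS}], got {mu}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    # unnormalised log-density; constant factors cancel in the normalisation
    z = (MONTHS - mu) / sigma
    logp = -0.5 * z * z
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return LabelDistribution(probs=p, mu=float(mu), sigma=float(sigma))


def encode_label(label: AmbiguousLabel, sigma: float) -> LabelDistribution:
    """Parse-result -> distribution shortcut: ``make_distribution(label_to_mu(.))``."""
    return make_distribution(label_to_mu(label), sigma)


def decode_age(probs: np.ndarray, readout: str = "expectation") -> float:
    """Scalar age in months from a predicted distribution.

    ``readout='expectation'`` returns ``sum_i probs[i] * l_i`` (default);
    ``readout='argmax'`` returns the modal bin in months.

    Raises
    ------
    ValueError
        If the input does not sum to 1 within 1e-6, or readout is unknown.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (N_BINS,):
        raise ValueError(f"expected shape ({N_BINS},), got {p.shape}")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"distribution not normalised: sum = {p.sum()!r}")
    if readout == "expectation":
        return float(p @ MONTHS)
    if readout == "argmax":
        return float(MONTHS[int(np.argmax(p))])
    raise ValueError(f"unknown readout {readout!r}")
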