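"""Response functions mapping signal levels to behavior-parameter values.

A single rule "signal S increases/decreases behavior B" is represented by a
saturating response curve R(s) in [0, 1); the modulated behavior value is

    b(s) = b0 + (bM - b0) * R(s)

where ``b0`` is the base value with no signal and ``bM`` the saturation
value at large signal.  When several rules act on the same behavior, the
up-regulating and down-regulating terms are each pooled into a multivariate
Hill response

    U = sum_i (u_i/u_i*)^p_i / (1 + sum_i (u_i/u_i*)^p_i)

(and likewise D for the down terms), and the behavior value is the bilinear
combination

    b(u, d) = (1 - D) * [(1 - U) * b0 + U * bM] + D * bm

which reduces to the single-rule Hill form when only one term is present.
All evaluation functions accept scalars or numpy arrays for signal values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurveForm",
    "ResponseCurve",
    "RuleTerm",
    "BehaviorResponse",
    "evaluate_curve",
    "aggregate_response",
    "evaluate_behavior",
    "hill",
]

#: cap keeping the capped-linear form strictly below 1
_LINEAR_CAP = 1.0 - 1e-9
#: numerator contributed by a saturated step term inside a multivariate sum
_STEP_NUMERATOR = 1e6
#: threshold above which (s/h)^p is computed in log space
_LOG_OVERFLOW = 300.0 * math.log(10.0)


class CurveForm(str, enum.Enum):
    HILL = "hill"
    LINEAR_CAPPED = "linear_capped"
    STEP = "step"


def _check_signal(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("signal value must be nonnegative")
    return s


def _pow_ratio(s: np.ndarray, half_max: float, power: float) -> np.ndarray:
    """(s / half_max) ** power, evaluated in log space when it would overflow."""
    ratio = s / half_max
    with np.errstate(divide="ignore", over="ignore"):
        logterm = power * np.log(np.where(ratio > 0, ratio, 1.0))
    out = np.where(
        logterm > _LOG_OVERFLOW,
        np.exp(_LOG_OVERFLOW),
        np.where(ratio > 0, np.exp(np.minimum(logterm, _LOG_OVERFLOW)), 0.0),
    )
    return out


def hill(s, half_max: float, power: float):
    """Classic Hill response (s/h)^p / (1 + (s/h)^p), in [0, 1)."""
    s = _check_signal(s)
    if half_max <= 0:
        raise ValueError("half_max must be positive")
    if power <= 0:
        raise ValueError("hill_power must be positive")
    x = _pow_ratio(s, half_max, power)
    # cap at the largest double below 1 so the open upper bound survives
    # floating-point rounding at saturating signals
    out = np.minimum(x / (1.0 + x), np.nextafter(1.0, 0.0))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ResponseCurve:
    """A single-signal response curve R(s) with values in [0, 1)."""

    form: CurveForm = CurveForm.HILL
    half_max: float = 1.0
    hill_power: float = 1.0

    def __post_init__(self):
        if self.half_max <= 0:
            raise ValueError("half_max must be positive")
        if self.hill_power <= 0:
            raise ValueError("hill_power must be positive")

    def __call__(self, s):
        return evaluate_curve(self, s)


def evaluate_curve(curve: ResponseCurve, s):
    """Evaluate a response curve at signal level(s) ``s``.

    The hill form is (s/h)^p / (1+(s/h)^p); the capped-linear form is
    min(s / (2h), cap) so that R(h) = 0.5 and the value stays below 1; the
    step form is 0 below the half-max and 1 at or above it.
    """
    s = _check_signal(s)
    form = CurveForm(curve.form)
    if form is CurveForm.HILL:
        return hill(s, curve.half_max, curve.hill_power)
    if form is CurveForm.LINEAR_CAPPED:
        out = np.minimum(s / (2.0 * curve.half_max), _LINEAR_CAP)
        return out if out.ndim else float(out)
    # step
    out = np.where(s >= curve.half_max, 1.0, 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RuleTerm:
    """One signal's contribution to a pooled up- or down-response."""

    signal: str
    half_max: float
    hill_power: float
    applies_to_dead: bool = False
    form: CurveForm = CurveForm.HILL

    def __post_init__(self):
        if self.half_max <= 0:
            raise ValueError(f"half_max must be positive for signal {self.signal!r}")
        if self.hill_power <= 0:
            raise ValueError(f"hill_power must be positive for signal {self.signal!r}")

    def numerator(self, s):
        """This term's contribution to the pooled Hill numerator."""
        s = _check_signal(s)
        form = CurveForm(self.form)
        if form is CurveForm.HILL:
            return _pow_ratio(s, self.half_max, self.hill_power)
        if form is CurveForm.STEP:
            # a saturated step contributes a large fixed numerator, else nothing
            return np.where(s >= self.half_max, _STEP_NUMERATOR, 0.0)
        # linear term pooled via x/(1-x) so a lone term reproduces the curve
        x = np.minimum(s / (2.0 * self.half_max), _LINEAR_CAP)
        return x / (1.0 - x)


def _lookup(signals, name):
    try:
        return signals[name]
    except KeyError:
        raise KeyError(f"no value provided for signal {name!r}") from None


def aggregate_response(terms, signals, *, dead: bool = False):
    """Pooled multivariate response of a collection of terms, in [0, 1).

    ``signals`` maps signal identifier -> value (scalar or array).  Terms
    whose ``applies_to_dead`` flag excludes a dead cell are skipped when
    ``dead`` is true.  An empty collection returns 0.
    """
    total = 0.0
    any_term = False
    for term in terms:
        if dead and not term.applies_to_dead:
            continue
        s = _lookup(signals, term.signal)
        total = total + term.numerator(s)
        any_term = True
    if not any_term:
        return 0.0
    out = total / (1.0 + total)
    return out if np.ndim(out) else float(out)


@dataclass
class BehaviorResponse:
    """All rules acting on one behavior of one cell type, pooled per Eq-style
    bilinear combination of total up and down responses."""

    behavior: str
    base_value: float
    max_value: float | None = None
    min_value: float | None = None
    up_terms: list[RuleTerm] = field(default_factory=list)
    down_terms: list[RuleTerm] = field(default_factory=list)
    #: source rows (provenance), parallel to up_terms then down_terms
    sources: list = field(default_factory=list)

    def __post_init__(self):
        if self.up_terms and self.max_value is None:
            raise ValueError(f"{self.behavior}: up rules present but no saturation (max) value")
        if self.down_terms and self.min_value is None:
            raise ValueError(f"{self.behavior}: down rules present but no saturation (min) value")

    def __call__(self, signals, *, dead: bool = False):
        return evaluate_behavior(self, signals, dead=dead)


def evaluate_behavior(resp: BehaviorResponse, signals, *, dead: bool = False):
    """Behavior value under the pooled up/down responses.

    Returns (1-D)*[(1-U)*b0 + U*bM] + D*bm with U, D the pooled up and down
    responses.  The result always lies in the interval spanned by
    {b0, bm, bM}.  Dead cells only feel rules flagged applies_to_dead.
    """
    U = aggregate_response(resp.up_terms, signals, dead=dead)
    D = aggregate_response(resp.down_terms, signals, dead=dead)
    b0 = resp.base_value
    bM = resp.max_value if resp.max_value is not None else b0
    bm = resp.min_value if resp.min_value is not None else b0
    out = (1.0 - D) * ((1.0 - U) * b0 + U * bM) + D * bm
    return out if np.ndim(out) else float(out)
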