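"""Monotherapy efficacy summaries: IC50, relative inhibition (RI), and
response distribution statistics.

These reference implementations make synthetic datasets self-contained.
When an input table already carries IC50/RI columns (as DrugComb exports
do), the table values take precedence over recomputation — see
:func:`drcbridge.data_model.summarize_curve`.
"""

from __future__ import annotations

import numpy as np

from .data_model import DoseResponseCurve

#: Factor replacing a zero dose with 0.1 × the smallest positive dose
#: before log10 transformation (log10(0) is undefined but the untreated
#: control carries signal worth keeping on the curve).
DEFAULT_PSEUDO_DOSE_FACTOR = 0.1


def log_doses(
    curve: DoseResponseCurve,
    zero_dose_policy: str = "pseudo_dose",
    pseudo_dose_factor: float = DEFAULT_PSEUDO_DOSE_FACTOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (log10 doses, responses) after applying the zero-dose policy."""
    doses = np.asarray(curve.doses, dtype=float)
    responses = np.asarray(curve.responses, dtype=float)
    if doses[0] == 0.0:
        if zero_dose_policy == "pseudo_dose":
            positive = doses[doses > 0]
            if positive.size == 0:
                raise ValueError("curve has no positive dose")
            doses = doses.copy()
            doses[0] = pseudo_dose_factor * positive.min()
        elif zero_dose_policy == "drop":
            responses = responses[doses > 0]
            doses = doses[doses > 0]
        else:
            raise ValueError(f"unknown zero_dose_policy {zero_dose_policy!r}")
    if doses.size < 2:
        raise ValueError("fewer than 2 usable knots after zero-dose policy")
    return np.log10(doses), responses


def estimate_ic50(
    curve: DoseResponseCurve, absolute_midpoint: bool = False
) -> float | None:
    """Dose (µM) at which the piecewise-linear curve first reaches half of
    its maximal response.

    The half level is 0.5 × max(responses) by default (the curve's own
    maximum), or an absolute 50% inhibition with ``absolute_midpoint``.
    Returns None when the curve never crosses the half level.
    """
    x, y = log_doses(curve)
    half = 50.0 if absolute_midpoint else 0.5 * float(np.max(y))
    if absolute_midpoint is False and np.max(y) <= 0:
        return None
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        lo, hi = min(y0, y1), max(y0, y1)
        if lo <= half <= hi:
            if y1 == y0:
                return float(10 ** x[i])
            t = (half - y0) / (y1 - y0)
            if 0.0 <= t <= 1.0:
                return float(10 ** (x[i] + t * (x[i + 1] - x[i])))
    if y[0] >= half:  # already above half at the lowest dose
        return float(10 ** x[0])
    return None


def compute_ri(curve: DoseResponseCurve) -> float | None:
    """Relative inhibition: normalized area under the log10-dose response
    curve.

    Trapezoidal area of % inhibition over log10-dose, divided by
    (log-dose span × 100): the mean inhibition over the tested range,
    rescaled so responses in [0, 100] map to RI in roughly [0, 1].
    Returns None for a degenerate (zero-span) curve.
    """
    x, y = log_doses(curve)
    span = x[-1] - x[0]
    if span <= 0:
        return None
    area = float(np.trapezoid(y, x))
    return area / (span * 100.0)


def curve_statistics(curve: DoseResponseCurve) -> dict[str, float]:
    """Max, min, mean and median of the measured % inhibition values."""
    responses = np.asarray(curve.responses, dtype=float)
    return {
        "max": float(np.max(responses)),
        "min": float(np.min(responses)),
        "mean": float(np.mean(responses)),
        "median": float(np.median(responses)),
    }
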