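"""Dose–response curve harmonization across heterogeneous screening designs.

High-throughput screening studies measure monotherapy dose–response
matrices on anywhere from 2 to 10 doses, over different concentration
ranges. Two encodings of a curve are provided:

* a **baseline** encoding — raw doses and responses right-padded with a
  sentinel to a fixed width, which preserves the study's dose design and
  therefore transfers poorly across studies; and
* an **imputation** encoding — responses interpolated onto a common
  fixed-length grid in log10-dose space by three operators (piecewise
  linear, Lagrange polynomial, and an anchored four-parameter log-logistic
  curve), concatenated, which is design-independent.

The imputation grid is per-curve: ``target_length`` points equally spaced
between the curve's own smallest and largest usable log10-dose. Only the
interpolated responses enter the feature vector, never the doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_model import DoseResponseCurve, MonotherapySummary
from .monotherapy import DEFAULT_PSEUDO_DOSE_FACTOR, log_doses

INTERPOLATION_METHODS = ("linear", "lagrange", "ll4")


class DegenerateCurveError(ValueError):
    """Raised when a curve has < 2 usable knots under the active policy."""


@dataclass(frozen=True)
class HarmonizationConfig:
    """Settings for curve encoding.

    target_length
        Number of grid points every curve is interpolated to (N_max);
        matches the widest dose design supported (10).
    pad_value / pad_cap
        Sentinel and fixed width for the baseline encoding: doses and
        responses are each right-padded with ``pad_value`` to ``pad_cap``.
    methods
        Ordered subset of interpolation operators for the imputation
        encoding.
    zero_dose_policy / pseudo_dose_factor
        How a zero (control) dose is made log-transformable: replaced by
        ``pseudo_dose_factor`` × the smallest positive dose, or dropped.
    ll4_natural_log
        Evaluate the log-logistic exponent in natural-log dose units
        instead of log10 (the slope anchor is always computed in log10).
    """

    target_length: int = 10
    pad_value: float = -1.0
    pad_cap: int = 10
    methods: tuple[str, ...] = INTERPOLATION_METHODS
    zero_dose_policy: str = "pseudo_dose"
    pseudo_dose_factor: float = DEFAULT_PSEUDO_DOSE_FACTOR
    ll4_natural_log: bool = False

    def __post_init__(self) -> None:
        if self.target_length < 2:
            raise ValueError("target_length must be >= 2")
        if not self.methods:
            raise ValueError("at least one interpolation method required")
        unknown = set(self.methods) - set(INTERPOLATION_METHODS)
        if unknown:
            raise ValueError(f"unknown interpolation method(s): {sorted(unknown)}")
        if not 0 < self.pseudo_dose_factor < 1:
            raise ValueError("pseudo_dose_factor must be in (0, 1)")


@dataclass(frozen=True)
class LL4Params:
    """Anchored four-parameter log-logistic curve parameters.

    a: slope, (y_n − y_1) / (x_n − x_1) in response units per log10-dose;
    b: upper anchor, the curve's maximum response;
    c: lower anchor, the curve's minimum response;
    d: IC50 in µM.
    ``ic50_fallback`` flags that d came from the geometric mean of the
    dose range because no IC50 was available.
    """

    a: float
    b: float
    c: float
    d: float
    ic50_fallback: bool = False

    def __post_init__(self) -> None:
        if self.c > self.b:
            raise ValueError("lower anchor c must not exceed upper anchor b")
        if not self.d > 0:
            raise ValueError("IC50 anchor d must be positive")


def _usable_knots(curve: DoseResponseCurve, config: HarmonizationConfig):
    try:
        return log_doses(curve, config.zero_dose_policy, config.pseudo_dose_factor)
    except ValueError as exc:
        raise DegenerateCurveError(str(exc)) from exc


def log10_grid(curve: DoseResponseCurve, config: HarmonizationConfig) -> np.ndarray:
    """Common query grid: ``target_length`` equally spaced log10-doses from
    the curve's smallest to largest usable dose, endpoints included."""
    x, _ = _usable_knots(curve, config)
    return np.linspace(x[0], x[-1], config.target_length)


def interp_linear(curve: DoseResponseCurve, grid: np.ndarray,
                  config: HarmonizationConfig | None = None) -> np.ndarray:
    """Piecewise-linear interpolation in log10-dose coordinates.

    Reproduces every measured response exactly at its own log-dose; query
    points outside the knot range are clamped to the endpoint responses.
    """
    config = config or HarmonizationConfig()
    x, y = _usable_knots(curve, config)
    return np.interp(np.asarray(grid, dtype=float), x, y)


def interp_lagrange(curve: DoseResponseCurve, grid: np.ndarray,
                    config: HarmonizationConfig | None = None) -> np.ndarray:
    """Lagrange polynomial interpolation in log10-dose coordinates.

    Evaluates the unique degree-(n−1) polynomial through all n knots,
    P(x) = Σ_j y_j Π_{k≠j} (x − x_k)/(x_j − x_k). High-degree polynomials
    oscillate between knots (Runge), so the output is clipped to the
    observed response range extended by 50% of its span on each side.
    """
    config = config or HarmonizationConfig()
    x, y = _usable_knots(curve, config)
    if len(np.unique(x)) != len(x):
        dupes = [v for v in x if list(x).count(v) > 1]
        raise ValueError(f"duplicate log-doses at knots: {sorted(set(dupes))}")
    grid = np.asarray(grid, dtype=float)
    result = np.zeros_like(grid)
    for j in range(len(x)):
        basis = np.ones_like(grid)
        for k in range(len(x)):
            if k != j:
                basis *= (grid - x[k]) / (x[j] - x[k])
        result += y[j] * basis
    span = float(np.max(y) - np.min(y))
    lo = float(np.min(y)) - 0.5 * span
    hi = float(np.max(y)) + 0.5 * span
    return np.clip(result, lo, hi)


def build_ll4_params(
    curve: DoseResponseCurve,
    ic50: float | None = None,
    config: HarmonizationConfig | None = None,
) -> LL4Params:
    """Anchor log-logistic parameters from the curve itself (no fitting).

    a is the end-to-end slope in log10-dose units, b/c the observed
    max/min response, d the supplied IC50. When no IC50 is supplied the
    midpoint-crossing estimate is used, and failing that the geometric
    mean of the dose range (flagged)."""
    from .monotherapy import estimate_ic50

    config = config or HarmonizationConfig()
    x, y = _usable_knots(curve, config)
    a = float((y[-1] - y[0]) / (x[-1] - x[0]))
    b = float(np.max(y))
    c = float(np.min(y))
    fallback = False
    if ic50 is None:
        ic50 = estimate_ic50(curve)
    if ic50 is None:
        ic50 = float(10 ** ((x[0] + x[-1]) / 2.0))  # geometric mean of dose range
        fallback = True
    return LL4Params(a=a, b=b, c=c, d=float(ic50), ic50_fallback=fallback)


def interp_ll4(
    curve: DoseResponseCurve,
    grid: np.ndarray,
    params: LL4Params,
    config: HarmonizationConfig | None = None,
) -> np.ndarray:
    """Evaluate the anchored log-logistic curve on the query grid.

    y(x) = b + (c − b) / (1 + exp(a·(x − log10 d))) with x in log10-dose
    space; the slope anchor and the exponent share the log10 coordinate
    system so that y(log10 d) = (b + c)/2 exactly. Overflow saturates to
    the asymptotes via the logistic sigmoid.
    """
    config = config or HarmonizationConfig()
    grid = np.asarray(grid, dtype=float)
    delta = grid - np.log10(params.d)
    if config.ll4_natural_log:
        delta = delta * np.log(10.0)
    # (c-b)/(1+exp(a*delta)) == (c-b)*expit(-a*delta); expit saturates
    # instead of overflowing, so large |a*delta| hits the asymptotes cleanly
    return params.b + (params.c - params.b) * expit(-params.a * delta)


def encode_drc_baseline(
    curve: DoseResponseCurve, config: HarmonizationConfig | None = None
) -> np.ndarray:
    """Baseline encoding: raw doses then responses, each right-padded with
    the sentinel to ``pad_cap``; output length is always 2 × pad_cap."""
    config = config or HarmonizationConfig()
    n = curve.n_doses
    if n > config.pad_cap:
        raise ValueError(f"curve has {n} doses, exceeding pad_cap={config.pad_cap}")
    pad = [config.pad_value] * (config.pad_cap - n)
    return np.asarray(list(curve.doses) + pad + list(curve.responses) + pad, dtype=float)


def encode_drc_imputation(
    curve: DoseResponseCurve,
    summary: MonotherapySummary | None = None,
    config: HarmonizationConfig | None = None,
) -> np.ndarray:
    """Imputation encoding: each configured method's responses on the
    common grid, concatenated in method order (length |methods| × target_length).

    Doses are not included, which is what makes the encoding independent
    of the study's dose design. A degenerate curve yields a sentinel-filled
    vector rather than failing the whole record.
    """
    config = config or HarmonizationConfig()
    width = len(config.methods) * config.target_length
    try:
        grid = log10_grid(curve, config)
    except DegenerateCurveError:
        return np.full(width, config.pad_value)
    pieces = []
    for method in config.methods:
        if method == "linear":
            pieces.append(interp_linear(curve, grid, config))
        elif method == "lagrange":
            pieces.append(interp_lagrange(curve, grid, config))
        elif method == "ll4":
            ic50 = summary.ic50 if summary is not None else None
            params = build_ll4_params(curve, ic50, config)
            pieces.append(interp_ll4(curve, grid, params, config))
    return np.concatenate(pieces)
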