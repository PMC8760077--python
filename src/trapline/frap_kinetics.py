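"""Photobleaching-recovery normalization, one-site binding fits and the
extra-sum-of-squares F-test.

The recovery model is the hyperbolic one-site specific-binding curve applied
to post-bleach time,

    Y(t) = ymax * t / (t_half + t),

so Y(t_half) = ymax / 2 by construction.  Fitting profiles the sum of squared
residuals over ``t_half`` — the per-trace plateau ``ymax`` has a closed-form
least-squares solution given ``t_half`` — starting from a fixed grid, which
makes every fit deterministic.  Half-times of two groups of traces are
compared by nesting a shared-``t_half`` model (per-trace ``ymax`` free in
both models) inside a per-group-``t_half`` model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError
from .tables_io import FrapTrace

#: Deterministic multi-start grid for the half-time profile.
THALF_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)

YMAX_MAX = 1.5
_YMAX_MIN = 1e-9
MIN_POINTS = 6


@dataclass(frozen=True)
class FrapFit:
    """Least-squares estimates for one trace."""

    ymax: float
    t_half: float
    ssr: float
    n_points: int

    def predict(self, t):
        return model(np.asarray(t, dtype=float), self.ymax, self.t_half)


@dataclass(frozen=True)
class FTestResult:
    """Nested-model comparison of shared vs per-group half-time."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    t_half_shared: float
    t_half_a: float
    t_half_b: float
    ssr_null: float
    ssr_alt: float


def model(t, ymax: float, t_half: float):
    """One-site binding recovery curve."""
    t = np.asarray(t, dtype=float)
    return ymax * t / (t_half + t)


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Map intensities so the pre-bleach reference is 1 and the first
    post-bleach frame is 0."""
    span = trace.prebleach_value - trace.postbleach_value
    if span == 0:
        raise ValidationError(
            f"trace {trace.trace_id}: pre- and post-bleach values are equal; "
            "cannot normalize a degenerate trace"
        )
    intensities = tuple(
        (i - trace.postbleach_value) / span for i in trace.intensities
    )
    return FrapTrace(
        trace_id=trace.trace_id,
        times=trace.times,
        intensities=intensities,
        prebleach_value=1.0,
        postbleach_value=0.0,
    )


# ---------------------------------------------------------------------------
# profile machinery
# ---------------------------------------------------------------------------


def _arrays(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.asarray(trace.times, dtype=float),
        np.asarray(trace.intensities, dtype=float),
    )


def _profile_ymax(t: np.ndarray, y: np.ndarray, t_half: float) -> float:
    """Closed-form least-squares plateau for a fixed half-time, clipped to
    the admissible range."""
    g = t / (t_half + t)
    denom = float(g @ g)
    if denom <= 0:
        return _YMAX_MIN
    return float(np.clip((y @ g) / denom, _YMAX_MIN, YMAX_MAX))


def _profile_ssr(groups: Sequence[tuple[np.ndarray, np.ndarray]], t_half: float) -> float:
    ssr = 0.0
    for t, y in groups:
        g = t / (t_half + t)
        ymax = _profile_ymax(t, y, t_half)
        r = y - ymax * g
        ssr += float(r @ r)
    return ssr


def _fit_shared_t_half(
    groups: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float]:
    """Minimize the pooled SSR over a shared half-time (per-trace plateau
    profiled out).  Returns (t_half, ssr)."""
    grid_ssr = [_profile_ssr(groups, th) for th in THALF_GRID]
    best = int(np.argmin(grid_ssr))
    lo = THALF_GRID[best - 1] if best > 0 else THALF_GRID[0] / 10.0
    hi = THALF_GRID[best + 1] if best < len(THALF_GRID) - 1 else THALF_GRID[-1] * 10.0
    result = optimize.minimize_scalar(
        lambda th: _profile_ssr(groups, th),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    candidates = [(float(result.fun), float(result.x))]
    candidates += [(s, th) for s, th in zip(grid_ssr, THALF_GRID)]
    ssr, t_half = min(candidates)
    return t_half, ssr


def fit_one_site(trace: FrapTrace) -> FrapFit:
    """Fit (ymax, t_half) to a normalized trace by profiled least squares."""
    if not trace.is_normalized:
        raise ValidationError(
            f"trace {trace.trace_id}: normalize before fitting "
            "(prebleach must be 1 and postbleach 0)"
        )
    if trace.n_points < MIN_POINTS:
        raise ValidationError(
            f"trace {trace.trace_id}: need >= {MIN_POINTS} post-bleach points, "
            f"got {trace.n_points}"
        )
    t, y = _arrays(trace)
    try:
        t_half, ssr = _fit_shared_t_half([(t, y)])
    except Exception as exc:  # pragma: no cover - defensive
        raise FitError(f"trace {trace.trace_id}: fit failed: {exc}") from exc
    ymax = _profile_ymax(t, y, t_half)
    if not (t_half > 0) or not np.isfinite(ssr):
        raise FitError(
            f"trace {trace.trace_id}: fit did not converge",
            best_candidate=(ymax, t_half),
        )
    return FrapFit(ymax=ymax, t_half=t_half, ssr=ssr, n_points=trace.n_points)


def compare_t_half(
    group_a: Sequence[FrapTrace],
    group_b: Sequence[FrapTrace],
) -> FTestResult:
    """Extra-sum-of-squares F-test for a common vs per-group half-time.

    Null model: one half-time shared by every trace in both groups (plateaus
    free per trace).  Alternative: one half-time per group.  F compares the
    SSR drop against the alternative model's residual variance.
    """
    for label, group in (("a", group_a), ("b", group_b)):
        if len(group) < 3:
            raise ValidationError(
                f"group {label}: need >= 3 traces, got {len(group)}"
            )
    failures = []
    for trace in (*group_a, *group_b):
        try:
            fit_one_site(trace)
        except (ValidationError, FitError) as exc:
            failures.append(f"{trace.trace_id}: {exc}")
    if failures:
        raise FitError(
            "unfittable trace(s): " + "; ".join(failures)
        )

    arrays_a = [_arrays(tr) for tr in group_a]
    arrays_b = [_arrays(tr) for tr in group_b]
    n_points = sum(t.size for t, _ in arrays_a + arrays_b)
    n_traces = len(arrays_a) + len(arrays_b)

    t_half_shared, ssr_null = _fit_shared_t_half(arrays_a + arrays_b)
    t_half_a, ssr_a = _fit_shared_t_half(arrays_a)
    t_half_b, ssr_b = _fit_shared_t_half(arrays_b)
    ssr_alt = ssr_a + ssr_b

    df_null = n_points - (1 + n_traces)
    df_alt = n_points - (2 + n_traces)
    if df_alt <= 0:
        raise ValidationError("not enough points for the nested comparison")
    delta = max(ssr_null - ssr_alt, 0.0)
    df_num = df_null - df_alt  # = 1
    if ssr_null < 1e-12:
        # the shared-half-time model already fits to machine precision;
        # any SSR difference is floating-point dust, not evidence
        f_stat, p_value = 0.0, 1.0
    elif ssr_alt > 0:
        f_stat = (delta / df_num) / (ssr_alt / df_alt)
        p_value = float(stats.f.sf(f_stat, df_num, df_alt))
    elif delta > 0:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat, p_value = 0.0, 1.0
    return FTestResult(
        f_stat=float(f_stat),
        df_num=df_num,
        df_den=df_alt,
        p_value=p_value,
        t_half_shared=t_half_shared,
        t_half_a=t_half_a,
        t_half_b=t_half_b,
        ssr_null=ssr_null,
        ssr_alt=ssr_alt,
    )
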