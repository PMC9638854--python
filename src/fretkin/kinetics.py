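"""Constrained four-parameter-logistic (4PL) decay fitting.

After acute inhibition of ATP production, the FRET efficiency of the
AT1.03NL sensor declines sigmoidally from its resting plateau toward the
sensor floor.  The decline is summarised by

    f(t) = base + (max - base) / (1 + (t_half / t)^n)

with ``base`` fixed at the empirically calibrated sensor floor (0.2827,
the mean minus two SD of the ATP-insensitive AT1.03RK construct), ``max``
a fitted plateau bounded above by 0.7 (the highest reliable efficiency
observed in healthy tissue), ``t_half`` the half-life in minutes (time at
which f = (base + max)/2) and ``n`` the Hill coefficient.  For a decaying
trace n is negative; a more negative n means a steeper transition at the
half-life.

Only ``max``, ``t_half`` and ``n`` are free; time is measured in minutes
since drug addition, with the first post-drug frame at one frame interval
so the t = 0 singularity of the formula never enters the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .roi_regions import RegionTrace

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "LogisticFit", "four_pl", "fit_decay", "fit_cohort"]

#: Sensor floor: mean - 2 SD of the ATP-insensitive control construct.
DEFAULT_BASE = 0.2827
#: Highest reliable mean FRET efficiency recorded in healthy tissue.
DEFAULT_MAX_UPPER = 0.7


def four_pl(t, base, max_eta, t_half, hill):
    """Evaluate the four-parameter logistic f(t) = base + (max-base)/(1+(t_half/t)^n).

    ``t`` may be a scalar or array of minutes since drug addition.  At
    t = 0 the continuous limit is returned: ``max_eta`` for hill < 0
    (a decaying curve starts at its plateau), ``base`` for hill > 0.

    Raises
    ------
    ValueError
        If ``t_half <= 0``, ``hill == 0`` (degenerate flat curve) or any
        t < 0.
    """
    if t_half <= 0:
        raise ValueError(f"t_half must be positive, got {t_half}")
    if hill == 0:
        raise ValueError("hill = 0 gives a degenerate (constant) curve")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("four_pl is defined for t >= 0 (minutes since drug)")
    limit = max_eta if hill < 0 else base
    with np.errstate(divide="ignore"):
        out = np.where(
            t > 0,
            base + (max_eta - base) / (1.0 + (t_half / np.where(t > 0, t, 1.0)) ** hill),
            limit,
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the constrained 4PL fit.

    Parameters
    ----------
    base_fixed:
        Sensor floor, held fixed during fitting (default 0.2827).
    max_upper_bound:
        Upper bound for the fitted plateau (default 0.7).
    drug_time_min:
        Time of drug addition on the trace's own clock; frames at or
        before this time are excluded and the fit clock starts there.
    cost_tol, max_nfev:
        Trust-region least-squares termination controls.
    """

    base_fixed: float = DEFAULT_BASE
    max_upper_bound: float = DEFAULT_MAX_UPPER
    drug_time_min: float = 0.0
    cost_tol: float = 1e-10
    max_nfev: int = 2000
    hill_bound: float = 50.0
    min_points: int = 8
    #: restart grid on the initial Hill guess used when the first attempt fails
    hill_restarts: tuple[float, ...] = (-1.0, -2.0, -5.0)

    def __post_init__(self):
        if not 0 < self.base_fixed < self.max_upper_bound <= 1:
            raise ValueError(
                "require 0 < base_fixed < max_upper_bound <= 1, got "
                f"base={self.base_fixed}, max_upper={self.max_upper_bound}"
            )


@dataclass
class LogisticFit:
    """Result of one constrained 4PL fit."""

    region: str
    disc_id: str
    base: float
    max_eta: float
    t_half: float
    hill: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""
    #: diagnostic flags: "t_half_exceeds_window" when the fitted half-life
    #: lies beyond the last observed timepoint (its CI is unbounded above),
    #: "increasing_trace" when the fitted Hill coefficient is positive.
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __call__(self, t):
        return four_pl(t, self.base, self.max_eta, self.t_half, self.hill)


def _initial_guess(t, y, cfg: FitConfig, hill0: float):
    max0 = float(np.mean(y[:5])) if y.size >= 5 else float(np.mean(y))
    max0 = min(max(max0, cfg.base_fixed + 1e-3), cfg.max_upper_bound)
    mid = 0.5 * (cfg.base_fixed + max0)
    below = np.nonzero(y <= mid)[0]
    duration = float(t[-1])
    t_half0 = float(t[below[0]]) if below.size else duration / 2.0
    t_half0 = max(t_half0, float(t[0]))
    return max0, t_half0, hill0


def fit_decay(trace: RegionTrace, cfg: FitConfig | None = None) -> LogisticFit:
    """Fit the constrained 4PL to the post-drug part of one region trace.

    Frames with t > drug_time enter the residual, re-expressed in minutes
    since drug addition; missing values (NaN frames) are dropped, not
    interpolated.  ``base`` is fixed; free parameters are bounded by
    base < max_eta <= max_upper_bound, 0 < t_half <= 10 x duration and
    |hill| <= 50.  The fit is a deterministic bounded trust-region least
    squares; if the first attempt does not converge, a small restart grid
    on the initial Hill guess is tried.

    Raises
    ------
    ValueError
        Fewer than ``cfg.min_points`` usable post-drug points, values
        outside [0, 1], or a trace already at the sensor floor.
    """
    cfg = cfg or FitConfig()
    times = np.asarray(trace.times_min, dtype=float)
    values = np.asarray(trace.mean_eta, dtype=float)
    post = times > cfg.drug_time_min
    t = times[post] - cfg.drug_time_min
    y = values[post]
    keep = np.isfinite(y)
    t, y = t[keep], y[keep]

    if t.size < cfg.min_points:
        raise ValueError(
            f"need >= {cfg.min_points} post-drug points, got {t.size} "
            f"(region {trace.region!r}, disc {trace.disc_id!r})"
        )
    if np.any((y < 0) | (y > 1)):
        raise ValueError("trace values must lie within [0, 1]")
    if np.all(y < cfg.base_fixed + 0.01):
        raise ValueError(
            f"trace already at floor (all values < {cfg.base_fixed + 0.01:.4f}); "
            "nothing to fit"
        )

    base = cfg.base_fixed
    duration = float(t[-1])
    lower = np.array([base + 1e-9, 1e-9, -cfg.hill_bound])
    upper = np.array([cfg.max_upper_bound, 10.0 * duration, cfg.hill_bound])

    def residual(p):
        return four_pl(t, base, p[0], p[1], p[2]) - y

    best = None
    for hill0 in (-2.0,) + tuple(cfg.hill_restarts):
        x0 = np.clip(_initial_guess(t, y, cfg, hill0), lower, upper)
        res = least_squares(
            residual, x0, bounds=(lower, upper), method="trf",
            ftol=cfg.cost_tol, xtol=cfg.cost_tol, gtol=cfg.cost_tol,
            max_nfev=cfg.max_nfev,
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.status > 0 and res.cost < 1e-6 * max(1, t.size):
            best = res
            break

    max_eta, t_half, hill = (float(v) for v in best.x)
    converged = bool(best.status > 0)
    message = best.message
    flags: list[str] = []
    # half-life pinned at its bound means the optimiser could not find a
    # genuine transition (e.g. a constant trace): not a usable fit
    if t_half >= 0.99 * upper[1]:
        converged = False
        message = "t_half at upper bound (no decay within a plausible window)"
    elif hill < 0 and four_pl(t[0], base, max_eta, t_half, hill) - four_pl(
            duration, base, max_eta, t_half, hill) < 0.01 * (max_eta - base):
        converged = False
        message = "no appreciable decay within the observation window"
    if t_half > duration:
        flags.append("t_half_exceeds_window")
    if hill > 0:
        flags.append("increasing_trace")

    return LogisticFit(
        region=trace.region, disc_id=trace.disc_id, base=base,
        max_eta=max_eta, t_half=t_half, hill=hill,
        rss=float(2 * best.cost), n_points=int(t.size),
        converged=converged, message=message, flags=tuple(flags),
    )


FIT_COLUMNS = [
    "disc_id", "region", "base", "max_eta", "t_half_min", "hill",
    "rss", "n_points", "converged", "flags",
]


def _fit_row(fit: LogisticFit) -> dict:
    return {
        "disc_id": fit.disc_id, "region": fit.region, "base": fit.base,
        "max_eta": fit.max_eta, "t_half_min": fit.t_half, "hill": fit.hill,
        "rss": fit.rss, "n_points": fit.n_points, "converged": fit.converged,
        "flags": ";".join(fit.flags),
    }


def fit_cohort(traces: list[RegionTrace], cfg: FitConfig | None = None) -> pd.DataFrame:
    """Fit every disc x region trace plus each region's mean trace.

    The mean trace of a region is the unweighted mean over discs at each
    timepoint (disc_id "mean" in the output).  Per-trace failures are
    recorded as non-converged rows with NaN parameters and do not abort
    the cohort.
    """
    cfg = cfg or FitConfig()
    rows = []
    by_region: dict[str, list[RegionTrace]] = {}
    for trace in traces:
        by_region.setdefault(trace.region, []).append(trace)
        try:
            rows.append(_fit_row(fit_decay(trace, cfg)))
        except ValueError as exc:
            logger.warning("fit failed for disc %s region %s: %s",
                           trace.disc_id, trace.region, exc)
            rows.append({
                "disc_id": trace.disc_id, "region": trace.region,
                "base": cfg.base_fixed, "max_eta": np.nan, "t_half_min": np.nan,
                "hill": np.nan, "rss": np.nan, "n_points": 0,
                "converged": False, "flags": "error",
            })

    for region, group in by_region.items():
        times = np.asarray(group[0].times_min, dtype=float)
        for tr in group[1:]:
            if not np.array_equal(np.asarray(tr.times_min, dtype=float), times):
                raise ValueError(
                    f"discs of region {region!r} have mismatched time axes; "
                    "mean trace undefined"
                )
        stack = np.vstack([tr.mean_eta for tr in group])
        mean_trace = RegionTrace(
            region=region, disc_id="mean", times_min=times,
            mean_eta=np.nanmean(stack, axis=0),
            n_valid=np.sum(np.isfinite(stack), axis=0),
        )
        try:
            rows.append(_fit_row(fit_decay(mean_trace, cfg)))
        except ValueError as exc:
            logger.warning("mean-trace fit failed for region %s: %s", region, exc)

    return pd.DataFrame(rows, columns=FIT_COLUMNS)
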