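"""Structure detectors: fit five parametric curve families to a short series.

This is the core of structural temporal pattern detection.  A series
``Y(t)`` is approximated by each member of a small family of shapes

====== ============ ==========================================
index  family       approximation function
====== ============ ==========================================
1      constant     ``f(t) = a``
2      straight     ``f(t) = a*t + b``
3      exponential  ``f(t) = a*exp(b*t) + c``
4      sinusoidal   ``f(t) = a*sin(b*t) + c``
5      triangular   ``f(t) = a - b*|t - c|`` (clamped below at
                    the series minimum)
====== ============ ==========================================

and scored by the error function ``E = sum((Y - Yhat)**2)`` (sum of squared
residuals).  The best fit is the family with minimal ``E``; ties break
toward the lower index (simpler shape).  Constant and straight fits use the
closed-form least-squares solutions; the three nonlinear families are fitted
by Nelder-Mead simplex search from several heuristic, moment-based starting
points, which guards against the families' non-convex error surfaces.

The fitted output is four numbers per series — ``a``, ``b``, ``c`` and the
winning family ``index`` — exactly the quantities used downstream as
classifier features; unused parameters are fixed at 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

FAMILY_NAMES = {
    1: "constant",
    2: "straight",
    3: "exponential",
    4: "sinusoidal",
    5: "triangular",
}
FAMILY_INDEX = {v: k for k, v in FAMILY_NAMES.items()}
SEARCHED_FAMILIES = ("exponential", "sinusoidal", "triangular")


class FitError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    """Simplex search hit the iteration cap; best-seen parameters returned."""


@dataclass(frozen=True)
class DetectorConfig:
    """Numerical settings for the simplex-searched families.

    ``n_starts`` heuristic starting points are generated per family (points
    beyond the 5 built-in heuristics are seeded random perturbations);
    Nelder-Mead polishing runs from the ``polish_top`` best of them.  The
    returned error never exceeds the error of any starting point.
    """

    max_iter: int = 150
    tol: float = 1e-8
    n_starts: int = 5
    polish_top: int = 1
    seed: int = 0


DEFAULT_CONFIG = DetectorConfig()


@dataclass
class FitSeries:
    """Input to a structure fit: strictly increasing times and their values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 1:
            raise FitError("times/values must be equal-length 1-D arrays, length >= 1")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise FitError("non-finite input to structure fit")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise FitError("times must be strictly increasing")
        self.times = t
        self.values = v

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class StructureFit:
    """Result of fitting one family: parameters, family index and error E."""

    index: int
    a: float
    b: float
    c: float
    error: float

    @property
    def family(self) -> str:
        return FAMILY_NAMES[self.index]

    def as_tuple(self) -> tuple[float, float, float, int]:
        return (self.a, self.b, self.c, self.index)


def error(values: np.ndarray, predicted: np.ndarray) -> float:
    """Sum of squared residuals between a series and its approximation."""
    y = np.asarray(values, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise FitError(f"length mismatch: {y.shape} vs {yhat.shape}")
    r = y - yhat
    return float(r @ r)


def predict(fit: StructureFit, times: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Evaluate a fitted structure at given times (triangular needs its floor)."""
    t = np.asarray(times, dtype=float)
    if fit.index == 1:
        return np.full_like(t, fit.a)
    if fit.index == 2:
        return fit.a * t + fit.b
    if fit.index == 3:
        return fit.a * np.exp(fit.b * t) + fit.c
    if fit.index == 4:
        return fit.a * np.sin(fit.b * t) + fit.c
    if fit.index == 5:
        out = fit.a - fit.b * np.abs(t - fit.c)
        return out if floor is None else np.maximum(out, floor)
    raise FitError(f"unknown family index {fit.index}")


# ---------------------------------------------------------------------------
# Closed-form fits
# ---------------------------------------------------------------------------


def fit_constant(fs: FitSeries) -> StructureFit:
    """Least-squares constant: ``a`` is the mean of the values."""
    a = float(fs.values.mean())
    return StructureFit(1, a, 0.0, 0.0, error(fs.values, np.full(len(fs), a)))


def fit_straight(fs: FitSeries) -> StructureFit:
    """Ordinary least-squares line ``f(t) = a*t + b`` (a slope, b intercept).

    Degenerate inputs (all times equal) fall back to slope 0 through the mean.
    """
    t, y = fs.times, fs.values
    if len(fs) < 2 or np.ptp(t) == 0:
        b = float(y.mean())
        return StructureFit(2, 0.0, b, 0.0, error(y, np.full_like(y, b)))
    tbar = t.mean()
    ybar = y.mean()
    tc = t - tbar
    a = float((tc @ (y - ybar)) / (tc @ tc))
    b = float(ybar - a * tbar)
    return StructureFit(2, a, b, 0.0, error(y, a * t + b))


# ---------------------------------------------------------------------------
# Simplex-searched fits
# ---------------------------------------------------------------------------


def _profiled_starts(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (scale, offset) and SSE for ``scale*F[g] + offset ~ y``.

    ``F`` holds one basis row per grid value of the profiled nonlinear
    parameter; the two linear parameters are solved by normal equations,
    vectorized over the whole grid.
    """
    n = y.size
    s_f = F.sum(axis=1)
    s_ff = (F * F).sum(axis=1)
    s_fy = F @ y
    s_y = y.sum()
    det = n * s_ff - s_f**2
    safe = np.abs(det) > 1e-12 * max(n * np.abs(s_ff).max(), 1.0)
    det = np.where(safe, det, 1.0)
    scale = np.where(safe, (n * s_fy - s_f * s_y) / det, 0.0)
    offset = np.where(safe, (s_y * s_ff - s_f * s_fy) / det, y.mean())
    sse = np.maximum(y @ y - scale * s_fy - offset * s_y, 0.0)
    return scale, offset, sse


def _starts_exponential(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    # profile the nonlinear rate b on a signed log-spaced grid; (a, c) are
    # linear given b and solved in closed form
    span = max(t[-1] - t[0], 1e-9)
    g = np.geomspace(0.05, 8.0, 8) / span
    rates = np.concatenate([g, -g])
    F = np.exp(np.clip(rates[:, None] * t[None, :], -700, 700))
    a, c, sse = _profiled_starts(F, y)
    order = np.argsort(sse, kind="stable")
    return [(float(a[i]), float(rates[i]), float(c[i])) for i in order]


def _starts_sinusoidal(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    # profile the frequency b (grid up to Nyquist plus the dominant FFT bin
    # for uniform sampling); amplitude and offset are linear given b
    span = max(t[-1] - t[0], 1e-9)
    n = t.size
    dt = np.diff(t)
    nyquist = np.pi / max(dt.min(), 1e-9)
    bs = list(np.geomspace(np.pi / span, max(nyquist, 1.1 * np.pi / span), 24))
    if n >= 4 and np.allclose(dt, dt[0]):
        spectrum = np.abs(np.fft.rfft(y - y.mean()))
        if spectrum[1:].size:
            k = int(np.argmax(spectrum[1:])) + 1
            bs.append(2 * np.pi * k / (n * dt[0]))
    bs = np.asarray(bs)
    F = np.sin(bs[:, None] * t[None, :])
    a, c, sse = _profiled_starts(F, y)
    order = np.argsort(sse, kind="stable")
    return [(float(a[i]), float(bs[i]), float(c[i])) for i in order]


def _starts_triangular(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    # profile the peak location c over the sample positions (plus midpoints);
    # peak height a and slope b are linear given c (clamp ignored at start)
    cs = np.unique(np.concatenate([t, (t[:-1] + t[1:]) / 2.0]))
    F = -np.abs(t[None, :] - cs[:, None])
    b, a, sse = _profiled_starts(F, y)  # scale multiplies -|t-c|, offset is a
    order = np.argsort(sse, kind="stable")
    return [(float(a[i]), float(b[i]), float(cs[i])) for i in order]


_START_HEURISTICS = {
    "exponential": _starts_exponential,
    "sinusoidal": _starts_sinusoidal,
    "triangular": _starts_triangular,
}


def _objective(family: str, t: np.ndarray, y: np.ndarray, floor: float):
    if family == "exponential":

        def f(p):
            r = p[0] * np.exp(np.clip(p[1] * t, -700, 700)) + p[2] - y
            return r @ r

    elif family == "sinusoidal":

        def f(p):
            r = p[0] * np.sin(p[1] * t) + p[2] - y
            return r @ r

    else:  # triangular

        def f(p):
            r = np.maximum(p[0] - p[1] * np.abs(t - p[2]), floor) - y
            return r @ r

    return f


def _nelder_mead(
    obj, x0: np.ndarray, max_iter: int, xatol: float, fatol: float
) -> tuple[np.ndarray, float, bool]:
    """Minimal Nelder-Mead simplex (standard coefficients, scipy-style
    initial simplex and termination).  Returns (x, f(x), converged)."""
    ndim = x0.size
    sim = np.repeat(x0[None, :], ndim + 1, axis=0)
    for k in range(ndim):
        if sim[k + 1, k] != 0.0:
            sim[k + 1, k] *= 1.05
        else:
            sim[k + 1, k] = 0.00025
    fsim = np.array([obj(x) for x in sim])
    order = np.argsort(fsim, kind="stable")
    sim, fsim = sim[order], fsim[order]
    converged = False
    for _ in range(max_iter):
        if (
            np.max(np.abs(sim[1:] - sim[0])) <= xatol
            and np.max(np.abs(fsim[1:] - fsim[0])) <= fatol
        ):
            converged = True
            break
        centroid = sim[:-1].mean(axis=0)
        xr = centroid + (centroid - sim[-1])
        fr = obj(xr)
        if fr < fsim[0]:
            xe = centroid + 2.0 * (centroid - sim[-1])
            fe = obj(xe)
            if fe < fr:
                sim[-1], fsim[-1] = xe, fe
            else:
                sim[-1], fsim[-1] = xr, fr
        elif fr < fsim[-2]:
            sim[-1], fsim[-1] = xr, fr
        else:
            if fr < fsim[-1]:  # outside contraction
                xc = centroid + 0.5 * (centroid - sim[-1])
                fc = obj(xc)
                if fc <= fr:
                    sim[-1], fsim[-1] = xc, fc
                else:
                    sim[1:] = sim[0] + 0.5 * (sim[1:] - sim[0])
                    fsim[1:] = [obj(x) for x in sim[1:]]
            else:  # inside contraction
                xc = centroid - 0.5 * (centroid - sim[-1])
                fc = obj(xc)
                if fc < fsim[-1]:
                    sim[-1], fsim[-1] = xc, fc
                else:
                    sim[1:] = sim[0] + 0.5 * (sim[1:] - sim[0])
                    fsim[1:] = [obj(x) for x in sim[1:]]
        order = np.argsort(fsim, kind="stable")
        sim, fsim = sim[order], fsim[order]
    return sim[0], float(fsim[0]), converged


def fit_searched(
    fs: FitSeries, family: str, config: DetectorConfig = DEFAULT_CONFIG
) -> StructureFit:
    """Fit a nonlinear family by multi-start Nelder-Mead simplex search.

    All starting points are evaluated; simplex polishing runs from the best
    ``config.polish_top`` of them, so the returned error is never worse than
    any start's error.
    """
    if family not in SEARCHED_FAMILIES:
        raise FitError(f"unknown searched family {family!r}")
    if len(fs) < 3:
        raise FitError(f"{family} fit needs >= 3 points, got {len(fs)}")
    t, y = fs.times, fs.values
    floor = float(y.min())
    obj = _objective(family, t, y, floor)

    starts = _START_HEURISTICS[family](t, y)
    if config.n_starts < len(starts):
        starts = starts[: config.n_starts]
    elif config.n_starts > len(starts):
        rng = np.random.default_rng(config.seed)
        base = np.asarray(starts)
        scale = np.maximum(np.abs(base).max(axis=0), 1e-3)
        for _ in range(config.n_starts - len(starts)):
            starts.append(tuple(base[0] + rng.normal(0, 0.5, 3) * scale))

    evals = [(obj(np.asarray(s)), np.asarray(s, dtype=float)) for s in starts]
    evals.sort(key=lambda e: e[0])
    best_e, best_p = evals[0]

    converged = False
    for e0, p0 in evals[: max(1, config.polish_top)]:
        x, fx, conv = _nelder_mead(obj, p0, config.max_iter, config.tol, config.tol)
        converged = converged or conv
        if fx < best_e:
            best_e, best_p = fx, x
    if not converged:
        warnings.warn(
            f"{family} simplex search hit the iteration cap; returning best-seen fit",
            ConvergenceWarning,
            stacklevel=2,
        )
    a, b, c = (float(x) for x in best_p)
    return StructureFit(FAMILY_INDEX[family], a, b, c, float(best_e))


def best_fit(fs: FitSeries, config: DetectorConfig = DEFAULT_CONFIG) -> StructureFit:
    """Evaluate all applicable families and return the minimum-error fit.

    Single-point series always use the constant detector.  Two-point series
    admit only the closed-form families.  Equal errors break toward the
    lower (simpler) index.
    """
    candidates = [fit_constant(fs)]
    if len(fs) >= 2:
        candidates.append(fit_straight(fs))
    if len(fs) >= 3:
        candidates.extend(fit_searched(fs, fam, config) for fam in SEARCHED_FAMILIES)
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.error < best.error:
            best = cand
    return best


__all__ = [
    "FAMILY_NAMES",
    "FAMILY_INDEX",
    "SEARCHED_FAMILIES",
    "DetectorConfig",
    "DEFAULT_CONFIG",
    "FitSeries",
    "StructureFit",
    "FitError",
    "ConvergenceWarning",
    "error",
    "predict",
    "fit_constant",
    "fit_straight",
    "fit_searched",
    "best_fit",
]
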