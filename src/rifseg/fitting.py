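"""Nonlinear least-squares fitting of decay models to per-bin time series.

Each bin is fitted across all replicates simultaneously: the replicate
series are stacked into one residual vector with equal weights.  Before
fitting, the series is normalized to the maximum of the across-replicate
mean series so that amplitudes are comparable between bins.

Three models are fitted, all parameterized by the *delay* rather than
the (unknown) TSS distance:

CO
    ``amp`` for ``t < delay``; ``amp * exp(-lam*(t - delay))`` after.
CO_BG
    CO plus a constant background (microarray probes).
RST
    the rifampicin-sensitive-termination model in the
    ``(amp, beta, lam, delay, delay_increase)`` parameterization, where
    ``delay_increase = (n - n_term)/v`` is the arrival time of the
    post-termination polymerase wave; identifiable without knowing the
    elongation rate.

The objective is continuous but non-differentiable at the delay
breakpoints, so optimization is multi-start: a coarse grid over the
nonlinear parameters (delay on the observed time points, decay constant
log-spaced) with closed-form amplitudes — every model is linear in its
amplitude(s) once the nonlinear parameters are fixed — followed by a
bounded trust-region least-squares polish from the best grid cells.

The RST model has two extra free parameters and will happily fit a
spurious small increase.  :func:`fit_rst` therefore collects all
converged fits within a residual range of the best fit (default 20%) and
returns the one with the *smallest* termination proportion; a plain
``beta = 0`` fit is always among the candidates, so it wins whenever it
explains the data nearly as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from rifseg.preprocess import BinSeries

__all__ = ["DecayFit", "normalize_series", "fit_bin", "fit_rst"]

_LAM_MIN, _LAM_MAX = 1e-4, 1e3  # 1/min


@dataclass
class DecayFit:
    """Fitted decay parameters of one bin (normalized units)."""

    model: str
    amplitude: float            # steady-state abundance at t=0 (normalized)
    lam: float                  # 1/min
    delay: float                # min
    bg: float = 0.0             # CO_BG only
    beta: float = 0.0           # RST only
    delay_increase: float = 0.0  # RST only, (n - n_term)/v in min
    rss: float = float("nan")
    norm_factor: float = 1.0
    converged: bool = True

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.lam

    @property
    def intensity(self) -> float:
        """Back-transformed RNA abundance at t = 0."""
        base = self.amplitude * (1.0 - self.beta) if self.model == "RST" else self.amplitude
        return (base + self.bg) * self.norm_factor


def normalize_series(b: BinSeries) -> tuple[np.ndarray, float]:
    """Divide all replicate values by the peak of the mean series.

    Returns the normalized abundance matrix and the factor; multiplying
    back by the factor recovers the original values exactly.
    """
    factor = float(b.mean_series.max())
    if factor <= 0:
        raise ValueError("series has no positive signal")
    return b.abundance / factor, factor


# --- model evaluation in stacked form --------------------------------------

def _co_curve(t, amp, lam, delay, bg=0.0):
    g = np.where(t < delay, 1.0, np.exp(-lam * np.maximum(t - delay, 0.0)))
    return amp * g + bg


def _rst_basis(t, lam, delay, di):
    """Basis (f1, f2) with model = amp*f1 - (amp*beta)*f2."""
    tail = np.exp(-lam * np.maximum(t - delay, 0.0))
    f1 = np.where(t < delay, 1.0, tail)
    f2 = np.where(
        t < di,
        1.0,
        np.where(t < delay,
                 np.exp(-lam * np.maximum(t - di, 0.0)),
                 math.exp(-lam * max(delay - di, 0.0)) * tail),
    )
    return f1, f2


def _rst_curve(t, amp, beta, lam, delay, di):
    f1, f2 = _rst_basis(t, lam, delay, di)
    return amp * f1 - amp * beta * f2


def _grids(times: np.ndarray):
    t_max = float(times[-1])
    delays = np.unique(np.concatenate([times, (times[:-1] + times[1:]) / 2.0]))
    delays = delays[(delays >= 0) & (delays <= t_max)]
    half_lives = np.geomspace(0.25, 30.0, 10)
    lams = math.log(2.0) / half_lives
    return delays, lams


def _stack(b: BinSeries):
    y, factor = normalize_series(b)
    reps, nt = y.shape
    t = np.tile(b.times, reps)
    return t, y.reshape(-1), factor


def fit_bin(b: BinSeries, model: str | None = None) -> DecayFit:
    """Fit the assigned decay model to one bin across all replicates.

    ``model`` is one of ``CO``, ``CO_BG``, ``RST``; when None it is taken
    from the bin flags (RST candidate -> RST, background tag -> CO_BG,
    else CO).  A failed fit is returned with ``converged=False`` rather
    than raised, and is excluded from segmentation downstream.
    """
    if model is None:
        model = "RST" if b.rst_candidate else ("CO_BG" if b.bg_model else "CO")
    min_pts = 5 if model == "RST" else 4
    if b.times.size < min_pts:
        return DecayFit(model=model, amplitude=np.nan, lam=np.nan, delay=np.nan,
                        converged=False)
    try:
        if model == "RST":
            return fit_rst(b)
        return _fit_co(b, with_bg=(model == "CO_BG"))
    except Exception:
        return DecayFit(model=model, amplitude=np.nan, lam=np.nan, delay=np.nan,
                        converged=False)


def _fit_co(b: BinSeries, with_bg: bool) -> DecayFit:
    t, y, factor = _stack(b)
    delays, lams = _grids(b.times)
    t_max = float(b.times[-1])
    best = None
    for d in delays:
        for lam in lams:
            g = np.where(t < d, 1.0, np.exp(-lam * np.maximum(t - d, 0.0)))
            if with_bg:
                A = np.column_stack([g, np.ones_like(g)])
                coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
                amp, bg = max(coef[0], 0.0), max(coef[1], 0.0)
            else:
                denom = float(g @ g)
                amp = max(float(g @ y) / denom, 0.0) if denom > 0 else 0.0
                bg = 0.0
            rss = float(np.sum((amp * g + bg - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, amp, bg, lam, d)
    _, amp0, bg0, lam0, d0 = best

    if with_bg:
        def resid(p):
            return _co_curve(t, p[0], p[1], p[2], p[3]) - y
        x0 = [max(amp0, 1e-6), max(lam0, _LAM_MIN), d0, bg0]
        lb = [0.0, _LAM_MIN, 0.0, 0.0]
        ub = [np.inf, _LAM_MAX, t_max, np.inf]
    else:
        def resid(p):
            return _co_curve(t, p[0], p[1], p[2]) - y
        x0 = [max(amp0, 1e-6), max(lam0, _LAM_MIN), d0]
        lb = [0.0, _LAM_MIN, 0.0]
        ub = [np.inf, _LAM_MAX, t_max]
    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    p = sol.x
    return DecayFit(model="CO_BG" if with_bg else "CO",
                    amplitude=float(p[0]), lam=float(p[1]), delay=float(p[2]),
                    bg=float(p[3]) if with_bg else 0.0,
                    rss=float(np.sum(sol.fun ** 2)), norm_factor=factor,
                    converged=bool(sol.success))


def fit_rst(b: BinSeries, residual_range: float = 0.20) -> DecayFit:
    """Fit the RST model with the minimal-beta selection rule.

    All converged multi-start fits whose residual sum of squares lies
    within ``residual_range`` of the best one are collected; among them
    the fit with the smallest termination proportion is returned.  With
    ``residual_range=0`` this degenerates to the plain best fit.
    """
    t, y, factor = _stack(b)
    delays, lams = _grids(b.times)
    t_max = float(b.times[-1])

    # coarse grid with closed-form amplitudes
    cells = []
    for d in delays:
        di_grid = np.unique(np.clip(delays[delays <= d], 0.0, d))
        for di in di_grid:
            for lam in lams:
                f1, f2 = _rst_basis(t, lam, d, di)
                A = np.column_stack([f1, -f2])
                coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
                amp = max(coef[0], 1e-9)
                beta = min(max(coef[1] / amp, 0.0), 1.0)
                rss = float(np.sum((_rst_curve(t, amp, beta, lam, d, di) - y) ** 2))
                cells.append((rss, amp, beta, lam, d, di))
    cells.sort(key=lambda c: c[0])

    # polish the best grid cells; parameterize di = frac * delay so the
    # constraint delay_increase <= delay is a simple box bound
    candidates: list[DecayFit] = []

    def polish(amp0, beta0, lam0, d0, di0):
        frac0 = di0 / d0 if d0 > 0 else 0.0

        def resid(p):
            amp, beta, lam, d, frac = p
            return _rst_curve(t, amp, beta, lam, d, frac * d) - y

        sol = least_squares(resid, [max(amp0, 1e-6), beta0, max(lam0, _LAM_MIN),
                                    max(d0, 1e-9), min(max(frac0, 0.0), 1.0)],
                            bounds=([0.0, 0.0, _LAM_MIN, 0.0, 0.0],
                                    [np.inf, 1.0, _LAM_MAX, t_max, 1.0]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        amp, beta, lam, d, frac = sol.x
        return DecayFit(model="RST", amplitude=float(amp), lam=float(lam),
                        delay=float(d), beta=float(beta),
                        delay_increase=float(frac * d),
                        rss=float(np.sum(sol.fun ** 2)), norm_factor=factor,
                        converged=bool(sol.success))

    for rss, amp, beta, lam, d, di in cells[:8]:
        fit = polish(amp, beta, lam, d, di)
        if fit.converged:
            candidates.append(fit)

    # the beta = 0 fit (plain CO) is always a candidate
    co = _fit_co(b, with_bg=False)
    if co.converged:
        candidates.append(DecayFit(model="RST", amplitude=co.amplitude, lam=co.lam,
                                   delay=co.delay, beta=0.0, delay_increase=0.0,
                                   rss=co.rss, norm_factor=factor, converged=True))
    if not candidates:
        return DecayFit(model="RST", amplitude=np.nan, lam=np.nan, delay=np.nan,
                        converged=False)
    best_rss = min(c.rss for c in candidates)
    admissible = [c for c in candidates if c.rss <= (1.0 + residual_range) * best_rss]
    return min(admissible, key=lambda c: (c.beta, c.rss))
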