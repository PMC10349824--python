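"""Closed-form positional RNA-concentration models for rifampicin time series.

All models describe the expected number of RNA molecules covering a
position ``n`` nucleotides downstream of a transcription start site (TSS)
at time ``t`` after rifampicin addition, under steady-state synthesis with
rate ``alpha``, first-order decay with constant ``lam`` and constant
elongation rate ``v``.  The key shared feature is the *delay* ``n / v``:
abundance at a position only starts to fall once the last polymerase that
initiated before rifampicin has passed it.

Internal unit system: minutes and nucleotides.  Rates quoted per second
(the common laboratory convention for elongation and decay rates) are
converted on ingestion via :meth:`ModelParams.from_per_second` or the
``per_minute`` helper.

Several variants extend the basic delayed exponential:

* a constant-background variant for microarray intensities,
* a post-transcriptional-decay variant in which only full-length
  transcripts are degraded, so steady-state abundance declines linearly
  toward the 3' end,
* a pre-steady-state variant for transcripts whose expression started
  shortly before rifampicin addition,
* a rifampicin-sensitive-termination (RST) variant in which a partial
  terminator upstream of ``n`` is relieved by rifampicin, producing a
  transient abundance *increase* before the decay,
* a two-promoter variant summing transcripts initiated at two TSSs.

The piecewise forms are written in their continuity-consistent version:
every branch boundary matches exactly, and the final branch of the
post-transcriptional, pre-steady-state and RST models decays as a pure
exponential from the value attained when the last polymerase passes the
position (the physically meaningful "frozen peak").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "per_minute",
    "conc_co",
    "conc_co_bg",
    "conc_post",
    "conc_pre_steady",
    "conc_rst",
    "conc_two_promoter",
    "half_life",
    "decay_constant",
    "termination_percent",
    "synthesis_ratio_from_tp",
    "rst_min_distance",
    "fraction_full_length",
]


def per_minute(rate_per_second: float) -> float:
    """Convert a per-second rate (1/s or nt/s) to the internal per-minute unit."""
    return rate_per_second * 60.0


class ParameterDomainError(ValueError):
    """Raised when model parameters violate their physical domain."""


@dataclass
class ModelParams:
    """Parameters of the positional concentration models.

    Attributes
    ----------
    alpha : float
        Synthesis (initiation) rate in molecules/min.
    lam : float
        First-order decay constant in 1/min.
    v : float
        Elongation rate in nt/min.
    n : float
        Position downstream of the TSS in nt.
    bg : float
        Constant background level (abundance units, >= 0).
    L : float or None
        Total transcript length in nt (post-transcriptional model).
    n_term : float or None
        Position of the rifampicin-sensitive termination site in nt
        (RST model); must satisfy ``n_term <= n``.
    beta : float
        Termination proportion at ``n_term``, in [0, 1].
    t_rif : float or None
        Time of rifampicin addition relative to the first initiation, in
        minutes (pre-steady-state model).
    alpha2 : float
        Synthesis rate of a second, downstream promoter (molecules/min).
    n2 : float or None
        Distance from the second promoter in nt; ``n2 < n``.
    """

    alpha: float
    lam: float
    v: float
    n: float = 0.0
    bg: float = 0.0
    L: float | None = None
    n_term: float | None = None
    beta: float = 0.0
    t_rif: float | None = None
    alpha2: float = 0.0
    n2: float | None = None

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.lam > 0 and self.v > 0):
            raise ParameterDomainError(
                "alpha, lam and v must be strictly positive "
                f"(got alpha={self.alpha}, lam={self.lam}, v={self.v})"
            )
        if self.n < 0:
            raise ParameterDomainError("position n must be >= 0")
        if self.bg < 0:
            raise ParameterDomainError("background bg must be >= 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ParameterDomainError("termination proportion beta must lie in [0, 1]")
        if self.L is not None and not (0 <= self.n <= self.L):
            raise ParameterDomainError("need 0 <= n <= L for the post-transcriptional model")
        if self.n_term is not None and not (0 <= self.n_term <= self.n):
            raise ParameterDomainError("need 0 <= n_term <= n for the RST model")
        if self.n2 is not None and not (self.n2 < self.n):
            raise ParameterDomainError("second promoter must be downstream: n2 < n")
        if self.alpha2 < 0:
            raise ParameterDomainError("alpha2 must be >= 0")

    @classmethod
    def from_per_second(cls, alpha: float, lam: float, v: float, **kwargs) -> "ModelParams":
        """Build params from per-second rates (alpha [1/s], lam [1/s], v [nt/s])."""
        if "t_rif" in kwargs and kwargs["t_rif"] is not None:
            kwargs["t_rif"] = kwargs["t_rif"] / 60.0
        return cls(alpha=per_minute(alpha), lam=per_minute(lam), v=per_minute(v), **kwargs)

    @property
    def delay(self) -> float:
        """Time (min) the last polymerase needs to reach position ``n``."""
        return self.n / self.v


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterDomainError("time t must be >= 0")
    return t


def conc_co(t, p: ModelParams):
    """Co-transcriptional decay: steady plateau, then delayed exponential.

    ``alpha/lam`` for ``t < n/v``; ``(alpha/lam) * exp(-lam*(t - n/v))``
    afterwards.  Continuous at the breakpoint.
    """
    t = _check_t(t)
    ss = p.alpha / p.lam
    d = p.delay
    out = np.where(t < d, ss, ss * np.exp(-p.lam * np.maximum(t - d, 0.0)))
    return out if out.shape else float(out)


def conc_co_bg(t, p: ModelParams):
    """Co-transcriptional decay plus a constant background ``bg``."""
    t = _check_t(t)
    out = np.asarray(conc_co(t, p)) + p.bg
    return out if out.shape else float(out)


def conc_post(t, p: ModelParams):
    """Post-transcriptional decay (only full-length transcripts degrade).

    Steady state carries the elongating polymerases on top of the
    full-length pool, hence the positional surplus ``alpha*(L - n)/v``:

    * ``t <  n/v``:            ``alpha/lam + alpha*(L - n)/v``
    * ``n/v <= t < L/v``:      ``alpha/lam + alpha*(L/v - t)``
    * ``t >= L/v``:            ``(alpha/lam) * exp(-lam*(t - L/v))``

    The final branch is the pure exponential from the steady-state value
    reached when the last polymerase terminates, which makes the function
    continuous at ``t = L/v``.
    """
    t = _check_t(t)
    if p.L is None:
        raise ParameterDomainError("post-transcriptional model requires L")
    ss = p.alpha / p.lam
    nv = p.n / p.v
    Lv = p.L / p.v
    out = np.where(
        t < nv,
        ss + p.alpha * (p.L - p.n) / p.v,
        np.where(
            t < Lv,
            ss + p.alpha * (Lv - t),
            ss * np.exp(-p.lam * np.maximum(t - Lv, 0.0)),
        ),
    )
    return out if out.shape else float(out)


def conc_pre_steady(t, p: ModelParams):
    """Pre-steady-state expression: rifampicin added ``t_rif`` min after the
    first initiation; times are measured relative to the first initiation.

    * ``t < n/v``:                       0 (no polymerase has arrived yet)
    * ``n/v <= t < n/v + t_rif``:        ``(alpha/lam)*(1 - exp(-lam*(t - n/v)))``
    * ``t >= n/v + t_rif``:              exponential decay with rate ``lam``
      from the frozen peak ``(alpha/lam)*(1 - exp(-lam*t_rif))``.

    As ``t_rif -> inf`` the curve converges to the co-transcriptional model
    (time-shifted so that decay starts at ``n/v + t_rif``).
    """
    t = _check_t(t)
    if p.t_rif is None or p.t_rif <= 0:
        raise ParameterDomainError("pre-steady-state model requires t_rif > 0")
    ss = p.alpha / p.lam
    nv = p.n / p.v
    t_end = nv + p.t_rif
    peak = ss * (1.0 - math.exp(-p.lam * p.t_rif))
    out = np.where(
        t < nv,
        0.0,
        np.where(
            t < t_end,
            ss * (1.0 - np.exp(-p.lam * np.maximum(t - nv, 0.0))),
            peak * np.exp(-p.lam * np.maximum(t - t_end, 0.0)),
        ),
    )
    return out if out.shape else float(out)


def conc_rst(t, p: ModelParams):
    """Rifampicin-sensitive termination at ``n_term`` with proportion ``beta``.

    Before rifampicin only ``(1 - beta)`` of the polymerases pass the
    terminator, so the plateau is lowered.  After rifampicin the
    termination is relieved and a wave of higher polymerase density needs
    ``(n - n_term)/v`` minutes to arrive, raising the abundance toward the
    unterminated steady state for at most ``n_term/v`` minutes:

    * ``t <  (n - n_term)/v``:   ``alpha*(1 - beta)/lam``
    * ``...  <= t < n/v``:       ``alpha/lam - (alpha*beta/lam)*exp(-lam*(t - (n-n_term)/v))``
    * ``t >= n/v``:              exponential decay with rate ``lam`` from
      the frozen peak ``alpha/lam - (alpha*beta/lam)*exp(-lam*n_term/v)``.

    With ``beta = 0`` the model reduces exactly to :func:`conc_co`.
    """
    t = _check_t(t)
    if p.n_term is None:
        raise ParameterDomainError("RST model requires n_term")
    ss = p.alpha / p.lam
    amp = p.alpha * p.beta / p.lam
    t_rise = (p.n - p.n_term) / p.v
    t_dec = p.n / p.v
    peak = ss - amp * math.exp(-p.lam * p.n_term / p.v)
    out = np.where(
        t < t_rise,
        ss - amp,
        np.where(
            t < t_dec,
            ss - amp * np.exp(-p.lam * np.maximum(t - t_rise, 0.0)),
            peak * np.exp(-p.lam * np.maximum(t - t_dec, 0.0)),
        ),
    )
    return out if out.shape else float(out)


def conc_two_promoter(t, p: ModelParams):
    """Superposition of transcripts from two TSSs at distances ``n`` and ``n2``.

    The upstream promoter (distance ``n``, rate ``alpha``) and the
    downstream promoter (distance ``n2 < n``, rate ``alpha2``) share the
    elongation rate and decay constant; each contributes its own delayed
    exponential and the contributions add.  ``alpha2 = 0`` reduces to
    :func:`conc_co`.
    """
    t = _check_t(t)
    if p.alpha2 and p.n2 is None:
        raise ParameterDomainError("two-promoter model requires n2")
    c1 = np.asarray(conc_co(t, p), dtype=float)
    if p.alpha2 == 0.0 or p.n2 is None:
        return c1 if c1.shape else float(c1)
    d2 = p.n2 / p.v
    ss2 = p.alpha2 / p.lam
    c2 = np.where(t < d2, ss2, ss2 * np.exp(-p.lam * np.maximum(t - d2, 0.0)))
    out = c1 + c2
    return out if out.shape else float(out)


def half_life(lam: float) -> float:
    """Half-life (min) from a decay constant in 1/min: ``ln(2)/lam``."""
    if lam <= 0:
        raise ParameterDomainError("decay constant must be > 0")
    return math.log(2.0) / lam


def decay_constant(hl: float) -> float:
    """Decay constant (1/min) from a half-life in minutes."""
    if hl <= 0:
        raise ParameterDomainError("half-life must be > 0")
    return math.log(2.0) / hl


def termination_percent(r_synt: float) -> float:
    """Partial termination percentage from a log2 synthesis-rate ratio.

    ``t_p = (1 - 2**r_synt) * 100``.  Negative ratios (lower downstream
    synthesis) map to positive percentages; positive ratios give negative
    values, which are reported unclamped so that downstream display code
    may clamp them without losing information here.
    """
    return (1.0 - 2.0 ** r_synt) * 100.0


def synthesis_ratio_from_tp(t_p: float) -> float:
    """Inverse of :func:`termination_percent` for ``t_p < 100``."""
    if t_p >= 100.0:
        raise ParameterDomainError("termination percentage must be < 100")
    return math.log2(1.0 - t_p / 100.0)


def rst_min_distance(v: float, half_life_min: float, beta: float, threshold: float = 0.075):
    """Minimal TSS distance of an RST site giving a detectable increase.

    The maximal relative abundance increase over the pre-rifampicin
    plateau in the RST model is ``beta*(1 - exp(-lam*n_term/v))/(1 - beta)``.
    Solving for the smallest ``n_term`` at which this reaches ``threshold``
    gives ``-(v/lam) * ln(1 - threshold*(1 - beta)/beta)``.

    Parameters use the laboratory units: ``v`` in nt/s, ``half_life_min``
    in minutes; the result is in nt.  Returns ``math.inf`` when the
    threshold exceeds the largest possible increase ``beta/(1 - beta)``
    (the event is undetectable at any distance).
    """
    if not (0 < beta <= 1):
        raise ParameterDomainError("beta must lie in (0, 1]")
    if threshold < 0:
        raise ParameterDomainError("threshold must be >= 0")
    if threshold == 0:
        return 0.0
    lam = decay_constant(half_life_min)  # 1/min
    v_min = per_minute(v)  # nt/min
    arg = 1.0 - threshold * (1.0 - beta) / beta
    if arg <= 0:
        return math.inf
    return -(v_min / lam) * math.log(arg)


def fraction_full_length(L: float, lam: float, v: float) -> float:
    """Steady-state fraction of transcripts finished before any decay hit.

    Under co-transcriptional decay a nascent transcript survives the
    ``L/v`` minutes of synthesis with probability ``exp(-lam*L/v)``.
    ``lam`` in 1/min, ``v`` in nt/min, ``L`` in nt.
    """
    if L < 0 or lam <= 0 or v <= 0:
        raise ParameterDomainError("need L >= 0, lam > 0, v > 0")
    return math.exp(-lam * L / v)
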