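"""Classification of fragment boundaries into transcriptional events.

Between consecutive fragments within one coverage segment the pipeline
evaluates:

* **iTSS_I** — an internal TSS indicated by a drop of the fitted delay
  between two delay fragments (Welch t-test on the projected-delay
  distributions at the comparison position),
* **velocity change** — a significant difference of the delay slopes
  (ANCOVA interaction of position with fragment membership),
* **HL_FC** — a fold change of the mean half-life between half-life
  fragments (Welch t-test),
* **iTSS_II / term / processing site** — classified from the log2
  synthesis-rate ratio ``R_synt`` between consecutive abundance
  fragments of the same transcriptional unit, with a MANOVA p-value over
  the joint (half-life, abundance) response,
* **TI** — a fold change of the mean fitted termination factor between
  TI fragments (Welch t-test).

The synthesis-rate ratio is ``R_synt = log2(int3'/int5') -
log2(HL3'/HL5')``; a negative ratio converts to the partial termination
percentage ``t_p = (1 - 2**R_synt) * 100``.  p-values are adjusted for
multiple testing by Benjamini-Hochberg, separately within each event
type.

The module also provides the binomial enrichment assessment of observed
RST segments against the background probability of an isolated bin being
flagged by chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rifseg.models import termination_percent
from rifseg.segmentation import Fragment, fragment_boundary_delays

__all__ = [
    "EventRecord",
    "RSTSegmentStats",
    "synthesis_ratio",
    "classify_boundary",
    "itss_delay_event",
    "velocity_change_event",
    "hl_event",
    "ti_event",
    "adjust_events",
    "rst_enrichment",
]


@dataclass
class EventRecord:
    """One classified boundary between two fragments."""

    type: str
    strand: str
    position: float
    magnitude: float
    p_value: float
    p_adjusted: float = float("nan")
    r_synt: float = float("nan")
    t_p: float = float("nan")
    tu_id: int | None = None
    frag5: int | None = None
    frag3: int | None = None


@dataclass
class RSTSegmentStats:
    """Filter outcome and noise probability of one observed RST segment."""

    length: int
    frac_indicator: float
    mean_rate: float
    n_high_rate: int
    prop_bg: float
    binom_tail: float

    @property
    def passes_filters(self) -> bool:
        return (self.length >= 5 and self.mean_rate >= 0.15
                and self.n_high_rate >= math.ceil(0.75 * self.length))


# ---------------------------------------------------------------------------
# synthesis-rate ratio and boundary classification
# ---------------------------------------------------------------------------

def synthesis_ratio(hl5, int5, hl3, int3) -> tuple[float, float, float]:
    """Log2 synthesis-rate ratio between consecutive abundance fragments.

    ``hl*`` and ``int*`` are the member half-lives and t=0 abundances of
    the 5' and 3' fragments (the half-life values trimmed to the
    abundance fragment's bins).  Returns ``(R_synt, t_p, p)`` where the
    p-value comes from a one-way MANOVA (Pillai's trace) with fragment
    membership as the factor and (half-life, log2 abundance) as the joint
    response.
    """
    hl5, int5 = np.asarray(hl5, float), np.asarray(int5, float)
    hl3, int3 = np.asarray(hl3, float), np.asarray(int3, float)
    r_synt = (math.log2(int3.mean() / int5.mean())
              - math.log2(hl3.mean() / hl5.mean()))
    t_p = termination_percent(r_synt)
    p = _manova_p(hl5, int5, hl3, int3)
    return r_synt, t_p, p


def _manova_p(hl5, int5, hl3, int3) -> float:
    from statsmodels.multivariate.manova import MANOVA

    df = pd.DataFrame({
        "hl": np.concatenate([hl5, hl3]),
        "logint": np.log2(np.concatenate([int5, int3])),
        "grp": ["five"] * hl5.size + ["three"] * hl3.size,
    })
    if min(hl5.size, hl3.size) < 2:
        return float("nan")
    # degenerate case: identical group means on both responses carry no
    # evidence of a difference (statsmodels rejects the zero hypothesis matrix)
    if (abs(hl5.mean() - hl3.mean()) < 1e-12
            and abs(np.log2(int5).mean() - np.log2(int3).mean()) < 1e-12):
        return 1.0
    try:
        mv = MANOVA.from_formula("hl + logint ~ grp", data=df)
        tab = mv.mv_test().results["grp"]["stat"]
        return float(tab.loc["Pillai's trace", "Pr > F"])
    except Exception:
        return float("nan")


def classify_boundary(r_synt: float, log2_hl_fc: float, p_value: float,
                      r_synt_window: tuple[float, float] = (-0.5, 0.2),
                      hl_fc_min: float = 1.0, alpha: float = 0.05) -> str | None:
    """Classify an abundance-fragment boundary from its synthesis ratio.

    Above the window -> new internal TSS (iTSS_II); below -> (partial)
    termination; inside the window a significant |log2 half-life fold
    change| >= ``hl_fc_min`` marks a processing/stabilization site
    (differential operon decay); otherwise no event.
    """
    lo, hi = r_synt_window
    if r_synt > hi:
        return "iTSS_II"
    if r_synt < lo:
        return "term"
    if abs(log2_hl_fc) >= hl_fc_min and p_value <= alpha:
        return "processing_site"
    return None


# ---------------------------------------------------------------------------
# delay-track events
# ---------------------------------------------------------------------------

def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value; degenerate zero-variance inputs compare means."""
    if a.size < 2 or b.size < 2:
        return float("nan")
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if math.isnan(p):
        return 1.0 if abs(a.mean() - b.mean()) < 1e-12 else 0.0
    return p


def _projected_distribution(frag: Fragment, positions, delays, comp_pos: float):
    """Fitted delay at the comparison position plus the fragment residuals."""
    u, b = frag.params["slope"], frag.params["intercept"]
    proj = u * comp_pos + b
    member = [i for i in range(frag.start, frag.stop) if i not in frag.outliers]
    resid = np.asarray(delays)[member] - (u * np.asarray(positions)[member] + b)
    return proj, proj + resid


def itss_delay_event(frag5: Fragment, frag3: Fragment, positions, delays,
                     strand: str = "+") -> EventRecord:
    """Internal TSS candidate from a delay drop between adjacent fragments.

    The comparison position is the midpoint between the fragments'
    adjacent bins.  Each fragment contributes the distribution of its
    fitted delay at that position plus its fit residuals; a Welch t-test
    compares the two.  The magnitude is the delay drop (5' projection
    minus 3' projection, positive for a drop).
    """
    positions = np.asarray(positions, float)
    comp = 0.5 * (positions[frag5.stop - 1] + positions[frag3.start])
    proj5, dist5 = _projected_distribution(frag5, positions, delays, comp)
    proj3, dist3 = _projected_distribution(frag3, positions, delays, comp)
    p = _welch_p(dist5, dist3)
    return EventRecord(type="iTSS_I", strand=strand, position=comp,
                       magnitude=float(proj5 - proj3), p_value=p)


def velocity_change_event(frag5: Fragment, frag3: Fragment, positions, delays,
                          strand: str = "+") -> EventRecord:
    """Elongation-rate change between adjacent delay fragments (ANCOVA).

    Fits ``delay ~ position * fragment`` and takes the p-value of the
    interaction term; the magnitude is the difference of velocities
    ``1/slope`` in nt/s (infinite slopes from flat fragments yield nan).
    """
    import statsmodels.formula.api as smf

    positions = np.asarray(positions, float)
    delays = np.asarray(delays, float)
    idx5 = list(range(frag5.start, frag5.stop))
    idx3 = list(range(frag3.start, frag3.stop))
    df = pd.DataFrame({
        "pos": np.concatenate([positions[idx5], positions[idx3]]),
        "delay": np.concatenate([delays[idx5], delays[idx3]]),
        "grp": ["five"] * len(idx5) + ["three"] * len(idx3),
    })
    comp = 0.5 * (positions[frag5.stop - 1] + positions[frag3.start])
    try:
        fit = smf.ols("delay ~ pos * C(grp)", data=df).fit()
        p = float(fit.pvalues.get("pos:C(grp)[T.three]", float("nan")))
    except Exception:
        p = float("nan")

    def vel(frag):
        u = frag.params["slope"]
        return 1.0 / u / 60.0 if u > 0 else float("inf")

    v5, v3 = vel(frag5), vel(frag3)
    mag = v3 - v5 if np.isfinite(v5) and np.isfinite(v3) else float("nan")
    return EventRecord(type="velocity_change", strand=strand, position=comp,
                       magnitude=mag, p_value=p)


# ---------------------------------------------------------------------------
# mean-track events
# ---------------------------------------------------------------------------

def _mean_track_event(kind: str, frag5: Fragment, frag3: Fragment, positions,
                      values, strand: str) -> EventRecord:
    positions = np.asarray(positions, float)
    a = frag5.members(values)
    b = frag3.members(values)
    comp = 0.5 * (positions[frag5.stop - 1] + positions[frag3.start])
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = float(np.log2(b.mean() / a.mean())) if a.mean() > 0 and b.mean() > 0 \
            else float(b.mean() - a.mean())
    p = _welch_p(a, b)
    return EventRecord(type=kind, strand=strand, position=comp,
                       magnitude=mag, p_value=p)


def hl_event(frag5, frag3, positions, halflives, strand: str = "+") -> EventRecord:
    """Half-life fold-change event between adjacent half-life fragments."""
    return _mean_track_event("HL_FC", frag5, frag3, positions, halflives, strand)


def ti_event(frag5, frag3, positions, ti_rates, strand: str = "+") -> EventRecord:
    """Transcriptional-interference event: change of the mean fitted
    termination factor between adjacent TI fragments."""
    ev = _mean_track_event("TI", frag5, frag3, positions, ti_rates, strand)
    a = frag5.members(ti_rates)
    b = frag3.members(ti_rates)
    ev.magnitude = float(b.mean() - a.mean())  # termination rates may be 0
    return ev


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def adjust_events(records: list[EventRecord]) -> list[EventRecord]:
    """Benjamini-Hochberg adjustment, separately within each event type."""
    from statsmodels.stats.multitest import multipletests

    by_type: dict[str, list[EventRecord]] = {}
    for r in records:
        by_type.setdefault(r.type, []).append(r)
    for recs in by_type.values():
        pvals = np.array([r.p_value for r in recs])
        ok = np.isfinite(pvals)
        if ok.any():
            adj = np.full(pvals.shape, np.nan)
            adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
            for r, a in zip(recs, adj):
                r.p_adjusted = float(a)
    return records


# ---------------------------------------------------------------------------
# RST segment enrichment
# ---------------------------------------------------------------------------

def rst_enrichment(n_total_bins: int, n_flagged_bins: int,
                   segments: list[dict] | None = None,
                   max_length: int | None = None):
    """Binomial assessment of observed RST segments against random noise.

    ``prop_bg`` is the chance that an isolated bin carries the
    post-rifampicin-increase indicator; under pure noise the probability
    that a run of ``n`` bins contains at least ``ceil(0.75 n)`` flagged
    bins follows the binomial tail.  For every observed segment (a dict
    with keys ``length``, ``frac_indicator``, ``mean_rate``,
    ``n_high_rate``) an :class:`RSTSegmentStats` is produced, applying
    the three filters: length >= 5 bins, mean fitted termination rate
    >= 0.15, and >= 75% of bins with rate >= 0.15.

    Returns ``(prop_bg, stats_list, table)`` where ``table`` lists, for
    each segment length from 5 to the longest observed (or
    ``max_length``), the binomial tail probability and the expected
    number of chance segments among ``n_total_bins`` bins.
    """
    if not (0 < n_flagged_bins <= n_total_bins):
        raise ValueError("need 0 < flagged <= total bins")
    prop_bg = n_flagged_bins / n_total_bins
    segments = segments or []
    stats_list = []
    for seg in segments:
        n = int(seg["length"])
        k = math.ceil(0.75 * n)
        tail = float(stats_binom_tail(n, k, prop_bg))
        stats_list.append(RSTSegmentStats(
            length=n,
            frac_indicator=float(seg.get("frac_indicator", float("nan"))),
            mean_rate=float(seg.get("mean_rate", float("nan"))),
            n_high_rate=int(seg.get("n_high_rate", 0)),
            prop_bg=prop_bg,
            binom_tail=tail,
        ))
    top = max_length or max((s.length for s in stats_list), default=5)
    rows = []
    for n in range(5, max(top, 5) + 1):
        k = math.ceil(0.75 * n)
        tail = float(stats_binom_tail(n, k, prop_bg))
        rows.append({"length": n, "p_tail": tail,
                     "expected_segments": tail * n_total_bins})
    return prop_bg, stats_list, pd.DataFrame(rows)


def stats_binom_tail(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    return float(stats.binom.sf(k - 1, n, p))
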