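"""Exact penalized dynamic-programming segmentation and transcription-unit assembly.

A coverage segment is an ordered run of bins.  Segmentation chooses split
points so that the total of per-fragment scores plus a penalty per split
is optimal; the recursion over prefixes is solved exactly in O(n^2)
scorer evaluations, with no heuristic pruning.  Four scorers are used:

* ``indicator`` — sum of absolute deviations from the fragment mean of a
  +/-1 indicator sequence (RST-candidate detection),
* ``delay`` — L1 residuals of a linear fit of delay against genome
  position, slope clipped to the physiologically meaningful band
  [0, 1/60] min/nt (elongation rate >= 1 nt/s), with penalized outlier
  removal,
* ``mean`` — L1 deviations from the fragment mean (half-life, TI
  termination factor) with the same outlier scheme; the RNA-abundance
  track is scored on log2 values to stabilize the spread,
* the transcription-unit junction score, which is maximized rather than
  minimized.

Outlier removal is iterative: the point with the largest absolute
residual is dropped and the fit recomputed, each removal adding a fixed
outlier penalty; at most ``min(ceil(0.4 n), 10)`` outliers per fragment.

Transcriptional units (TUs) chain consecutive delay fragments that are
consistent with one uninterrupted transcription process.  A junction
between fragments is kept inside a TU when its score
``(s - e) + ln(s) + 0.5`` — ``e`` the fitted delay at the end of the 5'
fragment, ``s`` at the start of the 3' fragment — beats the (negative)
split penalty; a fragment starting at delay ~0 always opens a new TU
(the ``ln`` term diverges).  Because the total TU score decomposes over
junctions, the maximizing DP reduces to an exact per-junction choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Fragment",
    "TranscriptionalUnit",
    "dp_segment",
    "score_indicator",
    "score_delay",
    "score_mean",
    "indicator_scorer",
    "delay_scorer",
    "mean_scorer",
    "hierarchical_segment",
    "assemble_tus",
    "estimate_penalties",
    "SLOPE_MAX",
]

SLOPE_MAX = 1.0 / 60.0  # min/nt; slope above this means elongation < 1 nt/s


@dataclass
class Fragment:
    """A run of bins judged homogeneous in one track.

    ``start``/``stop`` are half-open indices into the scored array;
    ``params`` holds the fitted slope/intercept (delay track) or the mean
    (other tracks); ``outliers`` are absolute indices excluded from the
    fit; ``sd``/``se`` summarize the member values without outliers.
    """

    track: str
    start: int
    stop: int
    score: float
    params: dict = field(default_factory=dict)
    outliers: tuple = ()
    sd: float = float("nan")
    se: float = float("nan")

    def __len__(self) -> int:
        return self.stop - self.start

    def members(self, values: np.ndarray) -> np.ndarray:
        """Member values excluding outliers."""
        idx = [i for i in range(self.start, self.stop) if i not in self.outliers]
        return np.asarray(values)[idx]


def max_outliers(n: int, cap: int = 10) -> int:
    return min(math.ceil(0.4 * n), cap)


# ---------------------------------------------------------------------------
# scoring functions
# ---------------------------------------------------------------------------

def score_indicator(values) -> float:
    """Sum of absolute deviations from the mean of a +/-1 sequence."""
    y = np.asarray(values, dtype=float)
    return float(np.abs(y - y.mean()).sum())


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line with slope clipped to [0, SLOPE_MAX]."""
    if x.size < 2 or np.ptp(x) == 0:
        return 0.0, float(np.mean(y))
    xm, ym = x.mean(), y.mean()
    denom = float(np.sum((x - xm) ** 2))
    u = float(np.sum((x - xm) * (y - ym)) / denom)
    u = min(max(u, 0.0), SLOPE_MAX)
    return u, ym - u * xm


def score_delay(x, y, outlier_penalty: float, cap: int = 10):
    """Score a delay fragment: L1 residuals of the clipped linear fit with
    iterative penalized outlier removal.

    Returns ``(score, slope, intercept, outliers)`` where ``outliers``
    are indices into the fragment-local arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    keep = np.ones(n, dtype=bool)
    removed: list[int] = []
    best = None
    for j in range(max_outliers(n, cap) + 1):
        u, b = _fit_line(x[keep], y[keep])
        resid = np.abs(y - (u * x + b))
        score = float(resid[keep].sum()) + outlier_penalty * j
        cand = (score, u, b, tuple(removed))
        if best is None or score < best[0]:
            best = cand
        if keep.sum() <= 2:
            break
        worst = int(np.flatnonzero(keep)[np.argmax(resid[keep])])
        keep[worst] = False
        removed = removed + [worst]
    return best


def score_mean(y, outlier_penalty: float, log2: bool = False, cap: int = 10):
    """Score a mean-level fragment: L1 deviations from the mean with
    iterative penalized outlier removal.

    Returns ``(score, mean, outliers)``; with ``log2=True`` the values are
    scored on the log2 scale (RNA-abundance track).
    """
    y = np.asarray(y, dtype=float)
    if log2:
        y = np.log2(y)
    n = y.size
    keep = np.ones(n, dtype=bool)
    removed: list[int] = []
    best = None
    for j in range(max_outliers(n, cap) + 1):
        m = float(y[keep].mean())
        resid = np.abs(y - m)
        score = float(resid[keep].sum()) + outlier_penalty * j
        cand = (score, m, tuple(removed))
        if best is None or score < best[0]:
            best = cand
        if keep.sum() <= 1:
            break
        worst = int(np.flatnonzero(keep)[np.argmax(resid[keep])])
        keep[worst] = False
        removed = removed + [worst]
    return best


# scorer factories: each returns f(values, start, stop) -> (score, params, outliers)

def indicator_scorer():
    def f(values, start, stop):
        y = np.asarray(values, dtype=float)[start:stop]
        return score_indicator(y), {"mean": float(y.mean())}, ()
    f.track = "rst_indicator"
    return f


def delay_scorer(positions, outlier_penalty: float = 2.5, cap: int = 10):
    positions = np.asarray(positions, dtype=float)

    def f(values, start, stop):
        score, u, b, out = score_delay(positions[start:stop],
                                       np.asarray(values, dtype=float)[start:stop],
                                       outlier_penalty, cap)
        return score, {"slope": u, "intercept": b}, tuple(start + o for o in out)
    f.track = "delay"
    return f


def mean_scorer(outlier_penalty: float = 1.5, log2: bool = False,
                track: str = "halflife", cap: int = 10):
    def f(values, start, stop):
        score, m, out = score_mean(np.asarray(values, dtype=float)[start:stop],
                                   outlier_penalty, log2=log2, cap=cap)
        return score, {"mean": m}, tuple(start + o for o in out)
    f.track = track
    return f


# ---------------------------------------------------------------------------
# exact DP over one coverage segment
# ---------------------------------------------------------------------------

def dp_segment(values, score_fn, penalty: float, min_len: int = 3,
               mode: str = "minimize") -> list[Fragment]:
    """Exact penalized segmentation of ``values`` into fragments.

    Every fragment of length >= ``min_len`` is scored by ``score_fn``;
    each split adds ``penalty`` to the total, which is minimized (or
    maximized with ``mode='maximize'``).  Ties are broken toward fewer
    fragments, then toward leftmost boundaries.  Sequences shorter than
    ``min_len`` are returned as a single fragment.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        return []
    track = getattr(score_fn, "track", "track")
    if n < min_len:
        score, params, out = score_fn(values, 0, n)
        return [_make_fragment(track, 0, n, score, params, out, values)]

    sign = -1.0 if mode == "maximize" else 1.0
    cache: dict[tuple[int, int], tuple] = {}

    def scored(i, j):
        if (i, j) not in cache:
            cache[(i, j)] = score_fn(values, i, j)
        return cache[(i, j)]

    INF = float("inf")
    best = [INF] * (n + 1)       # best signed score of prefix [0, j)
    splits = [0] * (n + 1)
    back = [0] * (n + 1)
    best[0] = 0.0
    for j in range(min_len, n + 1):
        for i in range(0, j - min_len + 1):
            if i != 0 and best[i] == INF:
                continue
            s = scored(i, j)[0] * sign
            cand = best[i] + s + (0.0 if i == 0 else sign * penalty)
            nspl = splits[i] + (0 if i == 0 else 1)
            if (cand < best[j] - 1e-12
                    or (abs(cand - best[j]) <= 1e-12
                        and (nspl < splits[j]
                             or (nspl == splits[j] and i < back[j])))):
                best[j] = cand
                splits[j] = nspl
                back[j] = i
    # reconstruct
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j))
        j = i
    bounds.reverse()
    frags = []
    for i, j in bounds:
        score, params, out = scored(i, j)
        frags.append(_make_fragment(track, i, j, score, params, out, values))
    return frags


def _make_fragment(track, start, stop, score, params, outliers, values) -> Fragment:
    member = np.asarray([values[i] for i in range(start, stop) if i not in outliers])
    sd = float(np.std(member, ddof=1)) if member.size > 1 else float("nan")
    se = sd / math.sqrt(member.size) if member.size > 1 else float("nan")
    return Fragment(track=track, start=start, stop=stop, score=score,
                    params=params, outliers=tuple(outliers), sd=sd, se=se)


# ---------------------------------------------------------------------------
# hierarchical segmentation
# ---------------------------------------------------------------------------

DEFAULT_PENALTIES = {
    "delay": 3.5,
    "halflife": 2.0,
    "intensity": 2.0,
    "ti": 1.0,
}
DEFAULT_OUTLIER_PENALTIES = {
    "delay": 2.5,
    "halflife": 1.5,
    "intensity": 1.5,
    "ti": 0.75,
}


def hierarchical_segment(positions, delay, halflife, intensity, ti=None,
                         penalties: dict | None = None,
                         outlier_penalties: dict | None = None,
                         min_len: int = 3) -> dict[str, list[Fragment]]:
    """Hierarchical fragmentation of one coverage segment.

    The delay track is segmented first; each delay fragment is segmented
    into half-life fragments, which in turn are segmented into
    RNA-abundance (intensity, scored on log2) fragments, so that a child
    fragment never crosses a parent boundary.  Where the TI termination
    factor ``ti`` is available (RST candidate regions), contiguous finite
    runs inside each delay fragment are segmented as a fourth track.
    """
    pen = dict(DEFAULT_PENALTIES)
    pen.update(penalties or {})
    npen = dict(DEFAULT_OUTLIER_PENALTIES)
    npen.update(outlier_penalties or {})
    positions = np.asarray(positions, dtype=float)
    delay = np.asarray(delay, dtype=float)
    halflife = np.asarray(halflife, dtype=float)
    intensity = np.asarray(intensity, dtype=float)

    out: dict[str, list[Fragment]] = {"delay": [], "halflife": [], "intensity": [], "ti": []}
    out["delay"] = dp_segment(delay, delay_scorer(positions, npen["delay"]),
                              penalty=pen["delay"], min_len=min_len)
    for dfrag in out["delay"]:
        sub = dp_segment(halflife[dfrag.start:dfrag.stop],
                         mean_scorer(npen["halflife"], track="halflife"),
                         penalty=pen["halflife"], min_len=min_len)
        for hf in sub:
            hf = _shift(hf, dfrag.start)
            out["halflife"].append(hf)
            isub = dp_segment(intensity[hf.start:hf.stop],
                              mean_scorer(npen["intensity"], log2=True, track="intensity"),
                              penalty=pen["intensity"], min_len=min_len)
            out["intensity"].extend(_shift(f, hf.start) for f in isub)
        if ti is not None:
            tiv = np.asarray(ti, dtype=float)
            for lo, hi in _finite_runs(tiv, dfrag.start, dfrag.stop):
                tsub = dp_segment(tiv[lo:hi], mean_scorer(npen["ti"], track="ti"),
                                  penalty=pen["ti"], min_len=min_len)
                out["ti"].extend(_shift(f, lo) for f in tsub)
    return out


def _shift(frag: Fragment, offset: int) -> Fragment:
    frag.start += offset
    frag.stop += offset
    frag.outliers = tuple(o + offset for o in frag.outliers)
    return frag


def _finite_runs(values: np.ndarray, start: int, stop: int):
    runs = []
    i = start
    while i < stop:
        if np.isfinite(values[i]):
            j = i
            while j < stop and np.isfinite(values[j]):
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# transcription units
# ---------------------------------------------------------------------------

@dataclass
class TranscriptionalUnit:
    """An ordered chain of delay fragments sharing one transcription process."""

    fragments: list[Fragment]
    junctions: list[dict] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.fragments[0].start

    @property
    def stop(self) -> int:
        return self.fragments[-1].stop


def fragment_boundary_delays(frag: Fragment, positions) -> tuple[float, float]:
    """Fitted delay at the first (s) and last (e) bin of a delay fragment."""
    u = frag.params["slope"]
    b = frag.params["intercept"]
    positions = np.asarray(positions, dtype=float)
    return u * positions[frag.start] + b, u * positions[frag.stop - 1] + b


def tu_junction_score(e_prev: float, s_next: float) -> float:
    """Score of keeping a fragment junction inside one TU.

    ``(s - e) + ln(s) + 0.5``; the log term penalizes 3' fragments whose
    fitted start delay is near zero (a fresh TSS) and is ~0 at the 0.6-min
    delay where a continuing transcript becomes more plausible.
    """
    if s_next <= 0:
        return -math.inf
    return (s_next - e_prev) + math.log(s_next) + 0.5


def assemble_tus(delay_fragments: list[Fragment], positions,
                 penalty: float = -0.75) -> list[TranscriptionalUnit]:
    """Chain consecutive delay fragments into transcriptional units.

    The total score of an assembly is the sum, per junction, of either
    the junction score (kept inside a TU) or the split penalty (default
    -0.75, a TU break).  The score is maximized; because it decomposes
    over junctions the exact optimum keeps a junction iff its score
    exceeds the penalty.  Fragments whose fitted start delay is <= 0
    always open a new TU.
    """
    if not delay_fragments:
        return []
    tus = [TranscriptionalUnit(fragments=[delay_fragments[0]])]
    for prev, nxt in zip(delay_fragments, delay_fragments[1:]):
        _, e_prev = fragment_boundary_delays(prev, positions)
        s_next, _ = fragment_boundary_delays(nxt, positions)
        score = tu_junction_score(e_prev, s_next)
        keep = score > penalty and s_next > 0
        info = {"score": score, "e_prev": e_prev, "s_next": s_next,
                "delay_gap": s_next - e_prev, "kept": keep}
        if keep:
            tus[-1].fragments.append(nxt)
            tus[-1].junctions.append(info)
        else:
            tus.append(TranscriptionalUnit(fragments=[nxt]))
    return tus


# ---------------------------------------------------------------------------
# automatic penalty estimation
# ---------------------------------------------------------------------------

def _split_significant_delay(positions, values, f1: Fragment, f2: Fragment,
                             alpha: float) -> bool | None:
    """ANCOVA: does the delay slope/level differ between adjacent fragments?"""
    import pandas as pd
    import statsmodels.formula.api as smf

    x = np.concatenate([positions[f1.start:f1.stop], positions[f2.start:f2.stop]])
    y = np.concatenate([values[f1.start:f1.stop], values[f2.start:f2.stop]])
    g = np.array([0] * len(f1) + [1] * len(f2))
    if len(f1) < 3 or len(f2) < 3:
        return None
    df = pd.DataFrame({"pos": x, "delay": y, "grp": g})
    try:
        fit = smf.ols("delay ~ pos * C(grp)", data=df).fit()
        pvals = [fit.pvalues.get("pos:C(grp)[T.1]", np.nan),
                 fit.pvalues.get("C(grp)[T.1]", np.nan)]
        p = np.nanmin(pvals)
    except Exception:
        return None
    return bool(p <= alpha) if np.isfinite(p) else None


def _split_significant_mean(values, f1: Fragment, f2: Fragment, alpha: float,
                            log2: bool = False) -> bool | None:
    # all member bins enter the test; outliers are only excluded from the
    # fragment parameter estimates, not from the split assessment
    values = np.asarray(values, dtype=float)
    a = values[f1.start:f1.stop]
    b = values[f2.start:f2.stop]
    if log2:
        a, b = np.log2(a), np.log2(b)
    if a.size < 2 or b.size < 2:
        return None
    t = stats.ttest_ind(a, b, equal_var=False)
    return bool(t.pvalue <= alpha) if np.isfinite(t.pvalue) else None


def estimate_penalties(samples: list[dict], penalty_grid, track: str,
                       alpha: float = 0.05, min_len: int = 3,
                       outlier_penalty: float | None = None) -> float:
    """Select the split penalty maximizing (#significant - #non-significant)
    adjacent-fragment splits over a sample of coverage segments.

    ``samples`` is a list of dicts with keys ``positions`` and ``values``.
    Delay splits are tested by ANCOVA (slope/level difference), all other
    tracks by Welch's t-test at level ``alpha``.  Ties resolve to the
    largest penalty (fewest splits).
    """
    penalty_grid = list(penalty_grid)
    if len(penalty_grid) == 1:
        return penalty_grid[0]
    if outlier_penalty is None:
        outlier_penalty = DEFAULT_OUTLIER_PENALTIES.get(track, 1.5)
    best_pen, best_diff = None, -math.inf
    for pen in sorted(penalty_grid):
        sig = nonsig = 0
        for sample in samples:
            pos = np.asarray(sample["positions"], dtype=float)
            vals = np.asarray(sample["values"], dtype=float)
            if track == "delay":
                scorer = delay_scorer(pos, outlier_penalty)
            else:
                scorer = mean_scorer(outlier_penalty, log2=(track == "intensity"),
                                     track=track)
            frags = dp_segment(vals, scorer, penalty=pen, min_len=min_len)
            for f1, f2 in zip(frags, frags[1:]):
                if track == "delay":
                    res = _split_significant_delay(pos, vals, f1, f2, alpha)
                else:
                    res = _split_significant_mean(vals, f1, f2, alpha,
                                                  log2=(track == "intensity"))
                if res is True:
                    sig += 1
                elif res is False:
                    nonsig += 1
        diff = sig - nonsig
        if diff >= best_diff:
            best_diff, best_pen = diff, pen
    return best_pen
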