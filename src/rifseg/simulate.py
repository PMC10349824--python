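"""Stochastic per-second simulation of transcription, elongation and decay.

Each transcript is a contiguous run of genome positions, represented by
its 5' and 3' end coordinates.  Sense transcripts grow from their TSS
toward higher coordinates; the optional single antisense transcript
grows from its TSS toward position 1.  Growing, paused and terminated
(full-length) transcripts are kept in separate pools, sense and
antisense independently.

Every simulated second applies, in this order: transcription initiation
(Bernoulli per TSS, suppressed after rifampicin addition), antisense
initiation, an optional initiation-rate switch, release from a
transcriptional pause, elongation by the integer step ``elongation_rate``,
entry into a pause at the pause site, decay, termination, and finally
counting of the transcripts covering each requested position.

Decay modes
-----------
co
    Degradation may start on nascent transcripts: a growing (or paused)
    transcript hit by decay is truncated to its single 3'-most position;
    full-length transcripts are deleted.
post
    Only full-length transcripts are degraded (deleted).
endo_exo
    Transcripts containing a predefined endonuclease site lose everything
    5' of their rightmost contained site (instantaneous 3'->5'
    exonucleolytic removal of the upstream cleavage product).

Termination modes (besides reaching ``total_length``)
----------------------------------------------------
* a fixed random per-step termination probability,
* partial termination at a given site tested for every transcript whose
  3' end crosses the site within one elongation step,
* termination by collision with the antisense transcript: sense/antisense
  pairs whose 3' ends lie within a window (default 30 nt) collide; the
  sense transcript terminates with probability ``ti_prob_sense``,
  otherwise the antisense transcript terminates.

Counting includes paused and full-length transcripts.  The same seed
yields a bit-identical result; each replicate uses an independent RNG
stream spawned from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from rifseg.preprocess import BinSeries

__all__ = ["SimConfig", "SimResult", "simulate", "make_timeseries",
           "velocity_accuracy_experiment"]


@dataclass
class SimConfig:
    """Configuration of one stochastic transcription/decay simulation.

    Rates that act per 1-s step (initiation, decay, termination and pause
    probabilities) must lie in [0, 1]; ``elongation_rate`` is an integer
    number of nt per step.
    """

    total_length: int
    tss_positions: tuple = (1,)
    initiation_rates: tuple = (0.5,)
    rifampicin_time: int = 600
    max_time: int = 1500
    elongation_rate: int = 20
    decay_constant: float = 0.01
    decay_mode: str = "co"              # co | post | endo_exo
    endo_sites: tuple = ()
    secondary_rates: tuple | None = None
    switch_time: int | None = None
    as_tss: int | None = None           # antisense 5' end; elongates toward 1
    as_initiation_rate: float = 0.0
    term_fixed_prob: float = 0.0
    term_site: int | None = None
    term_site_prob: float = 0.0
    ti_prob_sense: float | None = None  # collision termination when not None
    collision_window: int = 30
    pause_site: int | None = None
    pause_start_prob: float = 1.0
    pause_off_rate: float = 0.0
    count_positions: tuple = (1,)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [*self.initiation_rates, self.decay_constant, self.as_initiation_rate,
                 self.term_fixed_prob, self.term_site_prob, self.pause_start_prob,
                 self.pause_off_rate]
        if self.ti_prob_sense is not None:
            probs.append(self.ti_prob_sense)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("per-step probabilities must lie in [0, 1]")
        if self.rifampicin_time > self.max_time:
            raise ValueError("rifampicin_time must be <= max_time")
        if self.as_tss is not None and self.as_tss <= 1:
            raise ValueError("antisense TSS must be > 1")
        if self.elongation_rate < 1:
            raise ValueError("elongation_rate must be a positive integer nt/step")
        if self.decay_mode not in ("co", "post", "endo_exo"):
            raise ValueError("decay_mode must be co, post or endo_exo")


@dataclass
class SimResult:
    """Positional transcript counts per replicate, time step and species.

    ``counts`` has shape ``(replicates, max_time + 1, len(count_positions), 2)``
    with species 0 = sense, 1 = antisense; ``counts[:, t]`` is the state
    after all actions of step ``t`` (step 0 is the initial empty state).
    """

    counts: np.ndarray
    config: SimConfig


class _Pool:
    """A pool of transcripts as parallel 5'/3' coordinate arrays."""

    def __init__(self):
        self.five: np.ndarray = np.empty(0, dtype=np.int64)
        self.three: np.ndarray = np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return self.five.size

    def add(self, five, three):
        self.five = np.concatenate([self.five, np.atleast_1d(np.asarray(five, dtype=np.int64))])
        self.three = np.concatenate([self.three, np.atleast_1d(np.asarray(three, dtype=np.int64))])

    def take(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Remove transcripts selected by ``mask`` and return their ends."""
        f, t = self.five[mask], self.three[mask]
        self.five, self.three = self.five[~mask], self.three[~mask]
        return f, t

    def count_covering(self, pos: int, sense: bool) -> int:
        if sense:
            return int(np.count_nonzero((self.five <= pos) & (pos <= self.three)))
        return int(np.count_nonzero((self.three <= pos) & (pos <= self.five)))


def _simulate_replicate(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    v = cfg.elongation_rate
    pos = np.asarray(cfg.count_positions, dtype=np.int64)
    counts = np.zeros((cfg.max_time + 1, pos.size, 2), dtype=np.int64)

    growing, paused, full = _Pool(), _Pool(), _Pool()
    as_growing, as_full = _Pool(), _Pool()
    rates = list(cfg.initiation_rates)
    endo = np.sort(np.asarray(cfg.endo_sites, dtype=np.int64))

    for step in range(1, cfg.max_time + 1):
        before_rif = step <= cfg.rifampicin_time
        # --- initiation -----------------------------------------------------
        if before_rif:
            for tss, rate in zip(cfg.tss_positions, rates):
                if rate > 0 and rng.random() <= rate:
                    growing.add(tss, tss)
            if cfg.as_tss is not None and cfg.as_initiation_rate > 0 \
                    and rng.random() <= cfg.as_initiation_rate:
                as_growing.add(cfg.as_tss, cfg.as_tss)
        # --- initiation-rate switch (sense only) ----------------------------
        if cfg.switch_time is not None and step == cfg.switch_time \
                and cfg.secondary_rates is not None:
            rates = list(cfg.secondary_rates)
        # --- pause release ---------------------------------------------------
        if len(paused) and cfg.pause_off_rate > 0:
            release = rng.random(len(paused)) <= cfg.pause_off_rate
            if release.any():
                growing.add(*paused.take(release))
        # --- elongation ------------------------------------------------------
        prev_three = growing.three.copy()
        growing.three = growing.three + v
        as_growing.three = as_growing.three - v
        # --- pause entry (sense, 3' end crossed the pause site this step) ----
        if cfg.pause_site is not None and cfg.pause_start_prob > 0 and len(growing):
            crossed = (prev_three < cfg.pause_site) & (growing.three >= cfg.pause_site)
            if crossed.any():
                enter = crossed & (rng.random(len(growing)) <= cfg.pause_start_prob)
                if enter.any():
                    f, _ = growing.take(enter)
                    paused.add(f, np.full(f.size, cfg.pause_site, dtype=np.int64))
        # --- decay -----------------------------------------------------------
        lam = cfg.decay_constant
        if lam > 0:
            if cfg.decay_mode == "co":
                for pool in (growing, paused, as_growing):
                    if len(pool):
                        hit = rng.random(len(pool)) <= lam
                        pool.five[hit] = pool.three[hit]  # keep 3'-most position
                for pool in (full, as_full):
                    if len(pool):
                        pool.take(rng.random(len(pool)) <= lam)
            elif cfg.decay_mode == "post":
                for pool in (full, as_full):
                    if len(pool):
                        pool.take(rng.random(len(pool)) <= lam)
            else:  # endo_exo
                for pool in (growing, paused, full):
                    if len(pool) and endo.size:
                        contains = np.zeros(len(pool), dtype=bool)
                        newfive = pool.five.copy()
                        for site in endo:  # rightmost contained site wins
                            inside = (pool.five <= site) & (site <= pool.three)
                            contains |= inside
                            newfive[inside] = site
                        hit = contains & (rng.random(len(pool)) <= lam)
                        pool.five[hit] = newfive[hit]
        # --- termination -----------------------------------------------------
        if len(growing):
            done = growing.three >= cfg.total_length
            if done.any():
                f, t = growing.take(done)
                full.add(f, np.minimum(t, cfg.total_length))
        if len(as_growing):
            done = as_growing.three <= 1
            if done.any():
                f, t = as_growing.take(done)
                as_full.add(f, np.maximum(t, 1))
        if cfg.term_fixed_prob > 0 and len(growing):
            hit = rng.random(len(growing)) <= cfg.term_fixed_prob
            if hit.any():
                full.add(*growing.take(hit))
        if cfg.term_site is not None and cfg.term_site_prob > 0 and len(growing):
            # window = one elongation step, so no transcript skips the test
            window = (cfg.term_site <= growing.three) & (growing.three < cfg.term_site + v)
            if window.any():
                hit = window & (rng.random(len(growing)) <= cfg.term_site_prob)
                if hit.any():
                    f, t = growing.take(hit)
                    full.add(f, np.full(f.size, cfg.term_site, dtype=np.int64))
        if cfg.ti_prob_sense is not None and len(growing) and len(as_growing):
            _collide(growing, full, as_growing, as_full,
                     cfg.ti_prob_sense, cfg.collision_window, rng)
        # --- counting --------------------------------------------------------
        for k, p in enumerate(pos):
            counts[step, k, 0] = (growing.count_covering(p, True)
                                  + paused.count_covering(p, True)
                                  + full.count_covering(p, True))
            counts[step, k, 1] = (as_growing.count_covering(p, False)
                                  + as_full.count_covering(p, False))
    return counts


def _collide(growing: _Pool, full: _Pool, as_growing: _Pool, as_full: _Pool,
             ti_prob_sense: float, window: int, rng: np.random.Generator) -> None:
    """Pair colliding sense/antisense polymerases and terminate one of each pair.

    Each antisense transcript pairs with at most one sense transcript (the
    nearest 3' end within the window), and each sense transcript is used
    at most once per step.
    """
    sense_used = np.zeros(len(growing), dtype=bool)
    sense_term = np.zeros(len(growing), dtype=bool)
    as_term = np.zeros(len(as_growing), dtype=bool)
    order = np.argsort(as_growing.three)
    for ai in order:
        d = np.abs(growing.three - as_growing.three[ai]).astype(float)
        d[sense_used | sense_term] = np.inf
        si = int(np.argmin(d)) if d.size else -1
        if si < 0 or d[si] > window:
            continue
        sense_used[si] = True
        if rng.random() <= ti_prob_sense:
            sense_term[si] = True
        else:
            as_term[ai] = True
    if sense_term.any():
        full.add(*growing.take(sense_term))
    if as_term.any():
        as_full.add(*as_growing.take(as_term))


def simulate(config: SimConfig) -> SimResult:
    """Run the simulation for all replicates; deterministic given the seed."""
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    counts = np.zeros((config.replicates, config.max_time + 1,
                       len(config.count_positions), 2), dtype=np.int64)
    for r, ss in enumerate(streams):
        counts[r] = _simulate_replicate(config, np.random.default_rng(ss))
    return SimResult(counts=counts, config=config)


def make_timeseries(result: SimResult, sampling_times, noise: str = "none",
                    species: str = "sense", strand: str = "+",
                    rng: np.random.Generator | None = None) -> list[BinSeries]:
    """Extract a bin-series collection at the given sampling times.

    ``sampling_times`` are minutes relative to rifampicin addition and
    must map onto simulated steps.  With ``noise='poisson'`` every count
    is replaced by a Poisson draw with the count as mean, mimicking
    technical sequencing noise.
    """
    cfg = result.config
    times = np.asarray(sampling_times, dtype=float)
    steps = cfg.rifampicin_time + np.round(times * 60.0).astype(int)
    if steps.max() > cfg.max_time or steps.min() < 0:
        raise ValueError("sampling times fall outside the simulated window")
    sp = 0 if species == "sense" else 1
    data = result.counts[..., sp][:, steps, :].astype(float)  # (reps, times, positions)
    if noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(cfg.seed + 1)
        data = rng.poisson(data).astype(float)
    elif noise != "none":
        raise ValueError("noise must be 'none' or 'poisson'")
    bins = []
    for k, p in enumerate(cfg.count_positions):
        bins.append(BinSeries(position=int(p), strand=strand,
                              abundance=data[:, :, k], times=times))
    return bins


# ---------------------------------------------------------------------------
# elongation-rate accuracy experiment
# ---------------------------------------------------------------------------

DECAY_CONSTANTS = (0.003465736, 0.01155, 0.00578)       # 1/s; t1/2 = 3.33, 1, 2 min
INITIATION_RATES = (0.2, 0.4, 0.8)                       # 1/s
VELOCITIES = (15, 30, 45, 60)                            # nt/s


def velocity_accuracy_experiment(seed: int = 0, n_repeats: int = 5,
                                 sampling_times=(0, 1, 2, 3, 4, 5, 6, 8, 10, 15),
                                 delay_penalty: float = 3.5,
                                 outlier_penalty: float = 2.5,
                                 max_velocity: float = 120.0,
                                 transcript_length: int = 1000,
                                 verbose: bool = False):
    """Input vs. fitted elongation rate over a grid of simulation settings.

    For every combination of decay constant, initiation rate and
    elongation rate a 1000-nt transcript is simulated (3 replicates,
    co-transcriptional decay), Poisson noise is added, every 50-nt bin is
    fitted with the delayed-exponential model, the delay track is
    segmented (split penalty 3.5, outlier penalty 2.5) and each fragment's
    slope is converted to a velocity (v = 1/slope).  Fragments with
    velocity above ``max_velocity`` nt/s are excluded, mirroring the
    physiological upper bound.  Returns a DataFrame with one row per
    retained fragment.
    """
    import pandas as pd

    from rifseg import fitting
    from rifseg import segmentation as sg

    positions = tuple(range(50, transcript_length + 1, 50))
    rows = []
    master = np.random.SeedSequence(seed)
    for rep_idx in range(n_repeats):
        for lam in DECAY_CONSTANTS:
            for alpha in INITIATION_RATES:
                for v in VELOCITIES:
                    sub_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                    # steady state needs arrival (L/v) plus several half-lives
                    settle = int(transcript_length / v + 4 * math.log(2) / lam)
                    cfg = SimConfig(
                        total_length=transcript_length,
                        initiation_rates=(alpha,),
                        rifampicin_time=settle,
                        max_time=settle + int(60 * max(sampling_times)),
                        elongation_rate=v,
                        decay_constant=lam,
                        decay_mode="co",
                        count_positions=positions,
                        replicates=3,
                        seed=sub_seed,
                    )
                    bins = make_timeseries(simulate(cfg), sampling_times,
                                           noise="poisson")
                    fits = [fitting.fit_bin(b, "CO") for b in bins]
                    ok = [(b, f) for b, f in zip(bins, fits) if f.converged]
                    if len(ok) < 3:
                        continue
                    xs = np.array([b.position for b, _ in ok], dtype=float)
                    ds = np.array([f.delay for _, f in ok])
                    frags = sg.dp_segment(ds, sg.delay_scorer(xs, outlier_penalty),
                                          penalty=delay_penalty, min_len=3)
                    for fr in frags:
                        u = fr.params["slope"]  # min/nt
                        if u <= 0:
                            continue
                        v_fit = 1.0 / u / 60.0  # nt/s
                        if v_fit > max_velocity:
                            continue
                        rows.append({"repeat": rep_idx, "lam": lam, "alpha": alpha,
                                     "input_velocity": float(v),
                                     "fitted_velocity": v_fit,
                                     "n_bins": len(fr)})
                    if verbose:
                        print(f"repeat={rep_idx} lam={lam} alpha={alpha} v={v}: "
                              f"{len(frags)} fragment(s)")
    return pd.DataFrame(rows)
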