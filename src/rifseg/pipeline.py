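"""End-to-end orchestration: preprocess -> fit -> segment -> TUs -> events.

The pipeline is a pure function of its inputs, configuration and seed;
rerunning with the same arguments yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from rifseg import events as ev
from rifseg import fitting, preprocess
from rifseg import segmentation as sg
from rifseg.preprocess import BinSeries

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class RunConfig:
    """Thresholds and penalties of one analysis run."""

    platform: str = "rnaseq"            # rnaseq | microarray
    bin_width: int = 50
    min_mean: float = 10.0
    max_gap: float = 300.0
    bg_threshold: float = 4000.0
    increase_threshold: float = 0.075
    rst_penalty: float = 10.0
    rst_min_frac: float = 0.75
    upstream_extension: float = 1000.0
    residual_range: float = 0.20
    penalties: dict = field(default_factory=dict)
    outlier_penalties: dict = field(default_factory=dict)
    tu_penalty: float = -0.75
    min_len: int = 3
    r_synt_window: tuple = (-0.5, 0.2)
    hl_fc_min: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "r_synt_window" in data:
            data["r_synt_window"] = tuple(data["r_synt_window"])
        return cls(**data)


@dataclass
class PipelineResult:
    bins: list
    fits: list
    fits_df: pd.DataFrame
    fragments_df: pd.DataFrame
    tus_df: pd.DataFrame
    events: list
    events_df: pd.DataFrame
    synthesis_df: pd.DataFrame
    rst_stats: list
    prop_bg: float | None


def run_pipeline(bins: list[BinSeries], config: RunConfig | None = None) -> PipelineResult:
    """Run the full analysis on a prepared BinSeries collection."""
    cfg = config or RunConfig()
    bins = preprocess.filter_low(bins, cfg.min_mean, platform=cfg.platform)
    bins = preprocess.split_by_gaps(bins, cfg.max_gap)
    bins = preprocess.tag_bg_model(bins, cfg.bg_threshold, platform=cfg.platform)
    bins = preprocess.flag_rst_candidates(
        bins, cfg.increase_threshold, cfg.rst_penalty, cfg.rst_min_frac,
        cfg.upstream_extension)

    fits = []
    for b in bins:
        if b.rst_candidate:
            f = fitting.fit_rst(b, cfg.residual_range)
        else:
            f = fitting.fit_bin(b, "CO_BG" if b.bg_model else "CO")
        fits.append(f)
    fits_df = _fits_table(bins, fits)

    fragments_rows: list[dict] = []
    tu_rows: list[dict] = []
    records: list[ev.EventRecord] = []
    synth_rows: list[dict] = []
    rst_stats: list[ev.RSTSegmentStats] = []
    tu_counter = 0

    n_flagged = sum(preprocess.rst_indicator(b, cfg.increase_threshold) == 1 for b in bins)
    prop_bg = n_flagged / len(bins) if bins else None

    ok = fits_df[fits_df["converged"]].copy()
    for (strand, seg_id), sub in ok.groupby(["strand", "segment_id"], sort=True):
        sub = sub.sort_values("position").reset_index(drop=True)
        if len(sub) == 0:
            continue
        pos = sub["position"].to_numpy(float)
        delay = sub["delay"].to_numpy(float)
        hl = sub["half_life"].to_numpy(float)
        inten = sub["intensity"].to_numpy(float)
        ti = np.where(sub["model"].to_numpy() == "RST",
                      sub["beta"].to_numpy(float), np.nan)
        frames = sg.hierarchical_segment(pos, delay, hl, inten, ti=ti,
                                         penalties=cfg.penalties,
                                         outlier_penalties=cfg.outlier_penalties,
                                         min_len=cfg.min_len)
        tus = sg.assemble_tus(frames["delay"], pos, penalty=cfg.tu_penalty)
        delay_tu: dict[int, int] = {}
        for tu in tus:
            tu_rows.append({"tu_id": tu_counter, "strand": strand,
                            "segment_id": seg_id,
                            "start_pos": pos[tu.start], "end_pos": pos[tu.stop - 1],
                            "n_fragments": len(tu.fragments)})
            for fr in tu.fragments:
                delay_tu[fr.start] = tu_counter
            tu_counter += 1

        def tu_of(index: int) -> int | None:
            for tu in tus:
                if tu.start <= index < tu.stop:
                    return delay_tu[tu.fragments[0].start]
            return None

        track_values = {"delay": delay, "halflife": hl, "intensity": inten, "ti": ti}
        for track, frs in frames.items():
            for fr in frs:
                row = {"track": track, "strand": strand, "segment_id": seg_id,
                       "start_pos": pos[fr.start], "end_pos": pos[fr.stop - 1],
                       "start_idx": fr.start, "stop_idx": fr.stop,
                       "score": fr.score, "sd": fr.sd, "se": fr.se,
                       "outliers": ",".join(map(str, fr.outliers))}
                row.update(fr.params)
                if track == "delay":
                    row["tu_id"] = tu_of(fr.start)
                    u = fr.params["slope"]
                    row["velocity_nt_s"] = (1.0 / u / 60.0) if u > 0 else float("inf")
                fragments_rows.append(row)

        # --- delay-track events --------------------------------------------
        dfr = frames["delay"]
        for f5, f3 in zip(dfr, dfr[1:]):
            vc = ev.velocity_change_event(f5, f3, pos, delay, strand)
            vc.tu_id = tu_of(f5.start)
            records.append(vc)
            _, e_prev = sg.fragment_boundary_delays(f5, pos)
            s_next, _ = sg.fragment_boundary_delays(f3, pos)
            same_tu = tu_of(f5.start) == tu_of(f3.start)
            if same_tu and e_prev - s_next > 0:
                it = ev.itss_delay_event(f5, f3, pos, delay, strand)
                it.tu_id = tu_of(f5.start)
                records.append(it)
        # --- half-life events ----------------------------------------------
        hfr = frames["halflife"]
        for f5, f3 in zip(hfr, hfr[1:]):
            records.append(ev.hl_event(f5, f3, pos, hl, strand))
        # --- synthesis-ratio events within one TU ---------------------------
        ifr = frames["intensity"]
        for f5, f3 in zip(ifr, ifr[1:]):
            tu5, tu3 = tu_of(f5.start), tu_of(f3.start)
            if tu5 is None or tu5 != tu3:
                continue
            hl5 = hl[f5.start:f5.stop]
            hl3 = hl[f3.start:f3.stop]
            in5 = inten[f5.start:f5.stop]
            in3 = inten[f3.start:f3.stop]
            r_synt, t_p, p = ev.synthesis_ratio(hl5, in5, hl3, in3)
            hl_fc = math.log2(hl3.mean() / hl5.mean())
            kind = ev.classify_boundary(r_synt, hl_fc, p, cfg.r_synt_window,
                                        cfg.hl_fc_min, cfg.alpha)
            comp = 0.5 * (pos[f5.stop - 1] + pos[f3.start])
            synth_rows.append({"strand": strand, "segment_id": seg_id,
                               "position": comp, "r_synt": r_synt, "t_p": t_p,
                               "log2_hl_fc": hl_fc, "p_value": p,
                               "classification": kind or ""})
            if kind is not None:
                records.append(ev.EventRecord(
                    type=kind, strand=strand, position=comp, magnitude=r_synt,
                    p_value=p, r_synt=r_synt, t_p=t_p, tu_id=tu5))
        # --- TI events -------------------------------------------------------
        tfr = frames["ti"]
        for f5, f3 in zip(tfr, tfr[1:]):
            if f3.start == f5.stop:  # only adjacent runs
                records.append(ev.ti_event(f5, f3, pos, ti, strand))
        # --- observed RST segments -------------------------------------------
        if prop_bg and 0 < prop_bg < 1:
            for lo, hi in sg._finite_runs(ti, 0, len(ti)):
                rates = ti[lo:hi]
                seg = {"length": hi - lo,
                       "frac_indicator": float("nan"),
                       "mean_rate": float(np.mean(rates)),
                       "n_high_rate": int(np.sum(rates >= 0.15))}
                _, stats_list, _ = ev.rst_enrichment(len(bins), n_flagged, [seg])
                st = stats_list[0]
                rst_stats.append(st)
                if st.passes_filters:
                    records.append(ev.EventRecord(
                        type="RST_segment", strand=strand,
                        position=0.5 * (pos[lo] + pos[hi - 1]),
                        magnitude=st.mean_rate, p_value=st.binom_tail))

    records = ev.adjust_events(records)
    event_columns = list(ev.EventRecord.__dataclass_fields__)
    events_df = pd.DataFrame([asdict(r) for r in records], columns=event_columns)
    return PipelineResult(
        bins=bins, fits=fits, fits_df=fits_df,
        fragments_df=pd.DataFrame(fragments_rows),
        tus_df=pd.DataFrame(tu_rows),
        events=records, events_df=events_df,
        synthesis_df=pd.DataFrame(synth_rows),
        rst_stats=rst_stats, prop_bg=prop_bg,
    )


def _fits_table(bins, fits) -> pd.DataFrame:
    rows = []
    for b, f in zip(bins, fits):
        rows.append({
            "position": b.position, "strand": b.strand,
            "segment_id": b.segment_id, "bg_model": b.bg_model,
            "rst_candidate": b.rst_candidate, "model": f.model,
            "amplitude": f.amplitude, "lam": f.lam,
            "half_life": f.half_life if f.converged else float("nan"),
            "delay": f.delay, "bg": f.bg, "beta": f.beta,
            "delay_increase": f.delay_increase, "rss": f.rss,
            "norm_factor": f.norm_factor,
            "intensity": f.intensity if f.converged else float("nan"),
            "converged": f.converged,
        })
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every stage's table as TSV plus BED/GFF exports."""
    from pathlib import Path

    from rifseg import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_probe_table(result.bins, outdir / "bins.tsv")
    result.fits_df.to_csv(outdir / "fits.tsv", sep="\t", index=False)
    result.fragments_df.to_csv(outdir / "fragments.tsv", sep="\t", index=False)
    result.tus_df.to_csv(outdir / "tus.tsv", sep="\t", index=False)
    result.events_df.to_csv(outdir / "events.tsv", sep="\t", index=False)
    result.synthesis_df.to_csv(outdir / "synthesis_ratios.tsv", sep="\t", index=False)
    if len(result.fragments_df):
        rio.write_fragments_bed(result.fragments_df, outdir / "fragments.bed")
    if len(result.events_df):
        rio.write_events_gff(result.events_df, outdir / "events.gff3")
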