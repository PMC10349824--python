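"""File formats: coverage readers, the canonical bin-series TSV, and exports.

Coordinates are 1-based and inclusive internally; bedGraph's 0-based
half-open intervals are converted on read, so the interval ``[0, 50)``
covers nucleotides 1..50 and contributes to the bin addressed 50.

The canonical bin-series TSV has columns ``position`` (1-based last
nucleotide of the bin), ``strand``, ``width``, the flag columns
``segment_id``, ``bg_model``, ``rst_candidate``, and one abundance
column per time point x replicate labeled ``t<minutes>.rep<k>``.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from rifseg.preprocess import BinSeries

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_bedgraph",
    "read_wiggle",
    "coverage_to_array",
    "write_fragments_bed",
    "write_events_gff",
]

_COLUMN_RE = re.compile(r"^t([0-9.]+)\.rep(\d+)$")


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_probe_table(path) -> list[BinSeries]:
    """Read the canonical probe/bin TSV into a BinSeries collection."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "strand"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: header must contain {sorted(required)}")
    layout = []
    for col in df.columns:
        m = _COLUMN_RE.match(col)
        if m:
            layout.append((float(m.group(1)), int(m.group(2)), col))
    if not layout:
        raise FormatError(f"{path}: no tX.repY abundance columns found")
    times = sorted({t for t, _, _ in layout})
    reps = sorted({r for _, r, _ in layout})
    bins = []
    for _, row in df.iterrows():
        ab = np.full((len(reps), len(times)), np.nan)
        for t, r, col in layout:
            ab[reps.index(r), times.index(t)] = row[col]
        b = BinSeries(position=int(row["position"]), strand=str(row["strand"]),
                      abundance=ab, times=np.asarray(times, float),
                      width=int(row.get("width", 50)))
        if "segment_id" in df.columns and not pd.isna(row["segment_id"]):
            b.segment_id = int(row["segment_id"])
        if "bg_model" in df.columns:
            b.bg_model = bool(row["bg_model"])
        if "rst_candidate" in df.columns:
            b.rst_candidate = bool(row["rst_candidate"])
        bins.append(b)
    return bins


def write_probe_table(bins: list[BinSeries], path) -> None:
    """Write a BinSeries collection to the canonical TSV (lossless round trip)."""
    rows = []
    for b in bins:
        row = {"position": b.position, "strand": b.strand, "width": b.width,
               "segment_id": b.segment_id if b.segment_id is not None else "",
               "bg_model": b.bg_model, "rst_candidate": b.rst_candidate}
        for r in range(b.abundance.shape[0]):
            for j, t in enumerate(b.times):
                row[f"t{_fmt_time(t)}.rep{r + 1}"] = b.abundance[r, j]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt_time(t: float) -> str:
    return f"{t:g}"


def read_bedgraph(path) -> np.ndarray:
    """Read a bedGraph track into a 1-based per-nucleotide coverage array.

    Index 0 of the returned array is nucleotide 1; the 0-based half-open
    interval ``start end`` covers nucleotides ``start+1 .. end``.
    """
    intervals = []
    max_end = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.append((start, end, value))
            max_end = max(max_end, end)
    cov = np.zeros(max_end)
    for start, end, value in intervals:
        cov[start:end] = value
    return cov


def read_wiggle(path) -> np.ndarray:
    """Read a fixedStep wiggle track into a 1-based coverage array."""
    values: dict[int, float] = {}
    pos = step = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                try:
                    pos = int(fields["start"])
                    step = int(fields.get("step", 1))
                except (KeyError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad fixedStep header") from exc
                continue
            if pos is None:
                raise FormatError(f"{path}:{lineno}: data before fixedStep header")
            try:
                values[pos] = float(line)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            pos += step
    if not values:
        return np.zeros(0)
    cov = np.zeros(max(values))
    for p, v in values.items():
        cov[p - 1] = v
    return cov


def coverage_to_array(file_map: dict, reader=read_bedgraph) -> np.ndarray:
    """Stack per-(replicate, time) coverage files into one tensor.

    ``file_map`` maps ``(replicate_index, time_minutes)`` to a path; the
    result has shape (n_replicates, n_times, genome_length).
    """
    reps = sorted({r for r, _ in file_map})
    times = sorted({t for _, t in file_map})
    tracks = {key: reader(p) for key, p in file_map.items()}
    glen = max(v.size for v in tracks.values())
    out = np.zeros((len(reps), len(times), glen))
    for (r, t), cov in tracks.items():
        out[reps.index(r), times.index(t), :cov.size] = cov
    return out


def write_fragments_bed(frag_df: pd.DataFrame, path, name_prefix: str = "frag") -> None:
    """Export a fragment table as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for i, row in frag_df.iterrows():
            fh.write("\t".join([
                str(row.get("chrom", "genome")),
                str(int(row["start_pos"]) - 1),
                str(int(row["end_pos"])),
                f"{name_prefix}_{row['track']}_{i}",
                "0",
                str(row["strand"]),
            ]) + "\n")


def write_events_gff(events_df: pd.DataFrame, path, source: str = "rifseg") -> None:
    """Export an events table as GFF3 point features with attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in events_df.iterrows():
            pos = int(round(row["position"]))
            attrs = (f"ID=event{i};event_type={row['type']};"
                     f"magnitude={row['magnitude']:.4g};"
                     f"p_value={row['p_value']:.3g};"
                     f"p_adjusted={row['p_adjusted']:.3g}")
            fh.write("\t".join([
                "genome", source, str(row["type"]), str(pos), str(pos),
                ".", str(row["strand"]), ".", attrs,
            ]) + "\n")
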