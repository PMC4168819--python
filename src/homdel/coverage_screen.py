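"""Per-exon read-depth screening of a case exome against a control panel.

A homozygous exon deletion leaves an exome essentially read-free over the
deleted exon while unrelated control exomes, processed identically, show
full depth there. The screen computes mean reads/base per exon for the
case and for each panel sample, summarizes the panel (mean, min, max), and
calls an exon a homozygous-deletion candidate when the case/panel depth
ratio is at or below ``max_ratio`` and the panel itself is deep enough to
judge (``min_panel_depth``). Exons the panel cannot vouch for are reported
``low_confidence`` rather than called either way. Raw means are compared
by default (no between-sample normalization); an optional per-sample
median scaling handles unequal library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_model import TranscriptModel

EXON_KEY = ["gene", "exon_index", "chrom", "start", "end"]


class CoverageError(ValueError):
    pass


@dataclass
class CoverageParams:
    """Calling thresholds: ratio at/below ``max_ratio`` with panel mean at
    least ``min_panel_depth`` reads/base is a homozygous-deletion candidate."""

    max_ratio: float = 0.1
    min_panel_depth: float = 10.0

    def __post_init__(self) -> None:
        if self.max_ratio < 0:
            raise ValueError("max_ratio must be >= 0")
        if self.min_panel_depth < 0:
            raise ValueError("min_panel_depth must be >= 0")


@dataclass(frozen=True)
class DeletionCall:
    gene: str
    exon_index: int
    chrom: str
    start: int
    end: int
    case_depth: float
    panel_mean: float
    depth_ratio: float | None  # None when the panel mean is 0 (undefined)
    verdict: str  # homozygous_deletion_candidate | normal | low_confidence


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Read a per-base depth track.

    Accepts a 3-column TSV (chrom, pos, depth; 1-based positions) or a
    bedGraph (chrom, start, end, depth; 0-based half-open intervals).
    Returns a normalized interval frame (chrom, start, end, depth) with
    1-based inclusive bounds. Bases absent from the track count as depth 0.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] == 3:
        df.columns = ["chrom", "pos", "depth"]
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"].astype(int),
                "end": df["pos"].astype(int),
                "depth": df["depth"].astype(float),
            }
        )
    elif df.shape[1] == 4:
        df.columns = ["chrom", "start", "end", "depth"]
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"].astype(int) + 1,  # bedGraph is 0-based
                "end": df["end"].astype(int),
                "depth": df["depth"].astype(float),
            }
        )
    else:
        raise CoverageError(
            f"depth track must have 3 (TSV) or 4 (bedGraph) columns, got {df.shape[1]}"
        )
    return out


def model_exon_frame(model: TranscriptModel) -> pd.DataFrame:
    """Exon intervals of a transcript as the screen's key frame."""
    gene = model.gene_id or model.transcript_id or "gene"
    rows = [
        {"gene": gene, "exon_index": i, "chrom": model.chrom, "start": s, "end": e}
        for i, (s, e) in enumerate(model.exons, start=1)
    ]
    return pd.DataFrame(rows)


def exon_mean_depth(depth_track: pd.DataFrame, exons: pd.DataFrame) -> pd.Series:
    """Mean reads/base per exon (inclusive bounds; uncovered bases are 0).

    ``depth_track`` is an interval frame as returned by
    :func:`read_depth_track`; ``exons`` carries the EXON_KEY columns.
    """
    track_chroms = set(depth_track["chrom"])
    means = []
    for row in exons.itertuples():
        if row.chrom not in track_chroms:
            raise CoverageError(
                f"exon {row.gene}:{row.exon_index} on {row.chrom!r} has no "
                f"depth track for its chromosome"
            )
        sub = depth_track[depth_track["chrom"] == row.chrom]
        ov_start = np.maximum(sub["start"].to_numpy(), row.start)
        ov_end = np.minimum(sub["end"].to_numpy(), row.end)
        ov_len = np.clip(ov_end - ov_start + 1, 0, None)
        total = float((ov_len * sub["depth"].to_numpy()).sum())
        means.append(total / (row.end - row.start + 1))
    return pd.Series(means, index=exons.index, dtype=float)


@dataclass
class ExonDepthTable:
    """Mean reads/base per exon per sample, with panel summaries.

    ``df`` holds the EXON_KEY columns, one column per sample, and after
    :func:`compare_to_panel` the columns ``panel_mean``, ``panel_min``,
    ``panel_max`` and ``depth_ratio``.
    """

    df: pd.DataFrame
    case_sample: str | None = None
    panel_samples: list[str] | None = None

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def build_depth_table(
    exons: pd.DataFrame, columns: dict[str, pd.Series]
) -> ExonDepthTable:
    df = exons.copy()
    for name, col in columns.items():
        df[name] = col.to_numpy()
    return ExonDepthTable(df=df)


def compare_to_panel(
    table: ExonDepthTable,
    case: str,
    panel: list[str],
    normalize: bool = False,
) -> ExonDepthTable:
    """Summarize the control panel per exon and compute the case ratio.

    Requires >= 2 panel samples with exon keys identical to the case.
    A panel mean of 0 leaves the ratio undefined (low confidence downstream).
    With ``normalize=True`` every sample is first scaled to equal per-sample
    median exon depth.
    """
    if len(panel) < 2:
        raise CoverageError("control panel needs at least 2 samples")
    missing = [s for s in [case, *panel] if s not in table.df.columns]
    if missing:
        raise CoverageError(f"samples missing from depth table: {missing}")
    df = table.df.copy()
    if normalize:
        medians = {s: float(df[s].median()) for s in [case, *panel]}
        target = float(np.median([m for m in medians.values() if m > 0]))
        for s, m in medians.items():
            if m > 0:
                df[s] = df[s] * (target / m)
    panel_vals = df[panel].to_numpy(dtype=float)
    df["panel_mean"] = panel_vals.mean(axis=1)
    df["panel_min"] = panel_vals.min(axis=1)
    df["panel_max"] = panel_vals.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            df["panel_mean"].to_numpy() > 0,
            df[case].to_numpy(dtype=float) / df["panel_mean"].to_numpy(),
            np.nan,
        )
    df["depth_ratio"] = ratio
    return ExonDepthTable(df=df, case_sample=case, panel_samples=list(panel))


def call_deletions(
    table: ExonDepthTable, params: CoverageParams | None = None
) -> list[DeletionCall]:
    """Call candidate homozygously deleted exons from a panel-summarized table.

    Verdicts are computed on unrounded values; the reported ratio is rounded
    to 4 decimals.
    """
    params = params or CoverageParams()
    if "panel_mean" not in table.df.columns:
        raise CoverageError("table lacks panel summaries; run compare_to_panel first")
    calls = []
    case = table.case_sample
    for _, row in table.df.iterrows():
        case_depth = float(row[case])
        panel_mean = float(row["panel_mean"])
        ratio = None if np.isnan(row["depth_ratio"]) else float(row["depth_ratio"])
        if panel_mean < params.min_panel_depth or ratio is None:
            verdict = "low_confidence"
        elif ratio <= params.max_ratio:
            verdict = "homozygous_deletion_candidate"
        else:
            verdict = "normal"
        calls.append(
            DeletionCall(
                gene=row["gene"],
                exon_index=int(row["exon_index"]),
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                case_depth=round(case_depth, 4),
                panel_mean=round(panel_mean, 4),
                depth_ratio=None if ratio is None else round(ratio, 4),
                verdict=verdict,
            )
        )
    return calls


def write_calls_tsv(calls: list[DeletionCall], path: str | Path) -> None:
    header = (
        "gene\texon_index\tchrom\tstart\tend\tcase_depth\tpanel_mean"
        "\tdepth_ratio\tverdict"
    )
    lines = [header]
    for c in calls:
        ratio = "NA" if c.depth_ratio is None else f"{c.depth_ratio}"
        lines.append(
            f"{c.gene}\t{c.exon_index}\t{c.chrom}\t{c.start}\t{c.end}"
            f"\t{c.case_depth}\t{c.panel_mean}\t{ratio}\t{c.verdict}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_candidates_bed(calls: list[DeletionCall], path: str | Path) -> None:
    lines = [
        f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.gene}_exon{c.exon_index}"
        for c in calls
        if c.verdict == "homozygous_deletion_candidate"
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
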