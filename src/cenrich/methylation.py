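"""Per-CpG methylation frequency, change classification and family summaries.

Input tables carry one row per CpG site: chromosome, 0-based position, the
number of reads with any valid methylation call at the site (``n_valid``) and
the number of those calls that were methylated (``n_meth``).  The site's
methylation frequency is ``100 * n_meth / n_valid`` percent; reads without a
call at the site are already excluded from both counts.

The change classifier compares a knockout (or treated) sample against its
wild-type control site by site, using strict threshold rules on percentage
points: only sites with WT frequency > 40% and coverage > 10 in both samples
enter the comparison; a difference above +10 points is *increased*, below
-10 points *decreased*, anything in the closed band [-10, +10] *unchanged*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import RegionSet

__all__ = [
    "site_frequency",
    "load_meth_table",
    "write_meth_table",
    "classify_changes",
    "aggregate_by_family",
    "find_dip_regions",
]

MPL_COLUMNS = ["chrom", "pos", "n_valid", "n_meth"]
CLASSES = ["increased", "decreased", "unchanged", "excluded"]


def site_frequency(n_meth: int, n_valid: int) -> float:
    """Methylation frequency in percent; NaN when the site has no valid call."""
    if n_valid < 0 or n_meth < 0:
        raise ValueError("counts must be non-negative")
    if n_meth > n_valid:
        raise ValueError(f"n_meth ({n_meth}) exceeds n_valid ({n_valid})")
    if n_valid == 0:
        return float("nan")
    return 100.0 * n_meth / n_valid


def _with_freq(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if (df["n_meth"] > df["n_valid"]).any():
        bad = df[df["n_meth"] > df["n_valid"]].iloc[0]
        raise ValueError(
            f"n_meth > n_valid at {bad['chrom']}:{bad['pos']}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["freq"] = np.where(
            df["n_valid"] > 0, 100.0 * df["n_meth"] / df["n_valid"], np.nan
        )
    return df


def load_meth_table(path) -> pd.DataFrame:
    """Read a site table (TSV with header chrom, pos, n_valid, n_meth)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MPL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return _with_freq(df[MPL_COLUMNS])


def write_meth_table(df: pd.DataFrame, path) -> None:
    df[MPL_COLUMNS].to_csv(path, sep="\t", index=False)


def classify_changes(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    min_wt_freq: float = 40.0,
    min_cov: int = 10,
    delta: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify per-site methylation changes of KO relative to WT.

    Only sites present (called) in both tables are considered; every joined
    site receives exactly one class.  Sites failing the WT-level filter
    (WT frequency strictly > ``min_wt_freq``) or the coverage filter
    (strictly > ``min_cov`` valid calls in *both* samples) are ``excluded``.
    Among the rest, the difference KO - WT in percentage points is compared
    against ``delta`` with strict inequalities; the boundary values land in
    ``unchanged``.

    Returns (per-site table with ``change_class``, summary table with counts
    and, for the three change classes, proportions among non-excluded sites).
    """
    wt = _with_freq(wt[MPL_COLUMNS]) if "freq" not in wt.columns else wt
    ko = _with_freq(ko[MPL_COLUMNS]) if "freq" not in ko.columns else ko
    joined = wt.merge(ko, on=["chrom", "pos"], suffixes=("_wt", "_ko"), how="inner")
    # A site with zero valid calls in a sample was not called there.
    joined = joined[(joined["n_valid_wt"] > 0) & (joined["n_valid_ko"] > 0)].copy()

    delta_freq = joined["freq_ko"] - joined["freq_wt"]
    included = (
        (joined["freq_wt"] > min_wt_freq)
        & (joined["n_valid_wt"] > min_cov)
        & (joined["n_valid_ko"] > min_cov)
    )
    cls = np.where(
        ~included,
        "excluded",
        np.where(delta_freq > delta, "increased",
                 np.where(delta_freq < -delta, "decreased", "unchanged")),
    )
    joined["delta"] = delta_freq
    joined["change_class"] = cls

    counts = joined["change_class"].value_counts().reindex(CLASSES, fill_value=0)
    n_included = int(counts[["increased", "decreased", "unchanged"]].sum())
    rows = []
    for c in CLASSES:
        prop = (
            counts[c] / n_included
            if c != "excluded" and n_included > 0
            else (np.nan if c != "excluded" else np.nan)
        )
        rows.append((c, int(counts[c]), prop))
    summary = pd.DataFrame(rows, columns=["change_class", "count", "proportion"])
    return joined, summary


def aggregate_by_family(
    sites: pd.DataFrame, regions: RegionSet, other_label: str = "other"
) -> pd.Series:
    """Unweighted mean site frequency per repeat-family label, plus overall.

    Sites are assigned to families by position lookup in ``regions``; a site
    inside overlapping regions of different labels contributes to each of
    those family means (but once to the overall mean).  Sites outside all
    regions are summarized under ``other``.  Families with no site are absent
    from the output.
    """
    sites = _with_freq(sites[MPL_COLUMNS]) if "freq" not in sites.columns else sites
    sites = sites[sites["freq"].notna()]
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for row in sites.itertuples(index=False):
        labels = regions.labels_at(row.chrom, row.pos) or {other_label}
        for label in labels:
            sums[label] = sums.get(label, 0.0) + row.freq
            counts[label] = counts.get(label, 0) + 1
    out = {label: sums[label] / counts[label] for label in sorted(sums)}
    if len(sites):
        out["overall"] = float(sites["freq"].mean())
    return pd.Series(out, dtype=float)


def find_dip_regions(
    positions: Sequence[int],
    freqs: Sequence[float],
    window_bp: int = 5000,
    low_threshold: float = 50.0,
    min_len_bp: int = 10000,
) -> list[tuple[int, int]]:
    """Locally hypomethylated intervals within a frequency track.

    The track extent is tiled into ``window_bp`` windows; windows with at
    least one site get the mean frequency of their sites.  A dip is a maximal
    run of consecutive informative windows whose means are all below
    ``low_threshold``, spanning at least ``min_len_bp``, and flanked on both
    sides by an informative window at or above the threshold — a uniformly
    low track therefore yields no dip.  Returns (start, end) intervals in
    track coordinates.
    """
    positions = np.asarray(positions)
    freqs = np.asarray(freqs, dtype=float)
    if positions.size == 0:
        return []
    order = np.argsort(positions)
    positions, freqs = positions[order], freqs[order]
    lo = int(positions[0]) // window_bp * window_bp
    hi = int(positions[-1]) + 1
    window_means: list[tuple[int, float]] = []
    for w_start in range(lo, hi, window_bp):
        mask = (positions >= w_start) & (positions < w_start + window_bp)
        if mask.any():
            window_means.append((w_start, float(freqs[mask].mean())))

    dips: list[tuple[int, int]] = []
    run: list[int] = []
    prev_high = False  # was the window before the run at/above threshold?
    for i, (w_start, mean) in enumerate(window_means):
        if mean < low_threshold:
            if not run:
                run_flanked_left = prev_high
            run.append(w_start)
        else:
            if run:
                span = run[-1] + window_bp - run[0]
                if run_flanked_left and span >= min_len_bp:
                    dips.append((run[0], run[-1] + window_bp))
                run = []
            prev_high = True
    # A run still open at the end of the track lacks a right flank: no dip.
    return dips
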