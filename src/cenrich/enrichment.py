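"""Predict size-selection enrichment from an in silico digestion.

The workflow: partition the genome into target (e.g. centromeric) and
non-target sequence, digest both with a multi-enzyme plan, bin every fragment
by length, and ask what share of each length bin is of target origin.  The
per-bin base-pair share divided by the genome-wide target share (the
*baseline*) is the predicted fold enrichment a size selection at that bin
would deliver.  ``screen_combinations`` repeats this for every enzyme
combination of a panel to find combinations that cut the background often but
the target rarely.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome_io import RegionSet, SequenceRecord, region_sequences
from .restriction import (
    DigestionPlan,
    Enzyme,
    Fragment,
    _gap_breaks,
    candidate_sites,
    digest,
    resolve_greedy,
)

__all__ = [
    "SizeBinning",
    "EnrichmentTable",
    "ComboScore",
    "default_binning",
    "baseline_fraction",
    "digest_partitions",
    "predict_enrichment",
    "screen_combinations",
]

TARGET = "target"
NON_TARGET = "non_target"


class SizeBinning:
    """Half-open fragment length bins; the last bin is open-ended.

    ``edges = [0, 5000, ..., 55000]`` yields bins [0,5k), [5k,10k), ...,
    [50k,55k), [55k,inf).
    """

    def __init__(self, edges: Sequence[int]):
        edges = list(edges)
        if not edges:
            raise ValueError("need at least one bin edge")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] != 0:
            edges = [0] + edges
        self.edges = edges

    @property
    def n_bins(self) -> int:
        return len(self.edges)

    def bounds(self, i: int) -> tuple[int, float]:
        lo = self.edges[i]
        hi = self.edges[i + 1] if i + 1 < len(self.edges) else math.inf
        return lo, hi

    def label(self, i: int) -> str:
        lo, hi = self.bounds(i)
        return f"[{lo},{int(hi)})" if math.isfinite(hi) else f">={lo}"

    def bin_index(self, length: int) -> int:
        # Rightmost edge <= length.
        return int(np.searchsorted(self.edges, length, side="right")) - 1

    def __repr__(self) -> str:
        return f"SizeBinning({self.edges})"


def default_binning(step: int = 5000, top: int = 55000) -> SizeBinning:
    """5-kb bins up to 55 kb, then a single open-ended high-molecular-weight bin."""
    return SizeBinning(list(range(0, top + step, step)))


@dataclass
class EnrichmentTable:
    """Per-size-bin fragment and base-pair composition of a digest.

    ``fold_bp`` of a bin is ``pct_bp_target / baseline_pct``: how much richer
    in target base-pairs a selection of that bin is than the undigested
    genome.
    """

    table: pd.DataFrame
    baseline_pct: float
    binning: SizeBinning

    def aggregate_pct_bp_target(self, min_length: int = 0) -> float:
        """Pooled target bp percentage over bins whose lower edge >= min_length."""
        sub = self.table[self.table["bin_lo"] >= min_length]
        total = sub["bp_total"].sum()
        if total == 0:
            return float("nan")
        return 100.0 * sub["bp_target"].sum() / total

    def aggregate_fold(self, min_length: int = 0) -> float:
        """Pooled fold enrichment over bins whose lower edge >= min_length."""
        if self.baseline_pct == 0:
            return float("nan")
        return self.aggregate_pct_bp_target(min_length) / self.baseline_pct

    def max_fold(self, min_length: int = 0) -> float:
        sub = self.table[(self.table["bin_lo"] >= min_length) & (self.table["bp_total"] > 0)]
        if sub.empty or sub["fold_bp"].isna().all():
            return float("nan")
        return float(sub["fold_bp"].max())

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["baseline_pct"] = self.baseline_pct
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ComboScore:
    enzymes: tuple[str, ...]
    score: float
    table: EnrichmentTable


def baseline_fraction(
    regions: RegionSet,
    genome: Sequence[SequenceRecord],
    target_labels: Sequence[str] = ("cen_region",),
) -> float:
    """Fraction (0-1) of genome base-pairs lying in target-labeled regions."""
    genome_bp = sum(len(rec) for rec in genome)
    if genome_bp == 0:
        raise ValueError("empty genome")
    target = regions.select(list(target_labels))
    if len(target) == 0:
        return 0.0
    return target.total_bp() / genome_bp


def digest_partitions(
    genome: Sequence[SequenceRecord],
    regions: RegionSet,
    plan: DigestionPlan,
    target_labels: Sequence[str] = ("cen_region",),
    mode: str = "per_region",
) -> list[Fragment]:
    """Digest the genome and label each fragment target / non-target.

    ``per_region``: target regions and their per-chromosome complement are
    digested as separate substrates (restriction sites spanning a partition
    boundary never cut).  ``whole_chromosome``: each chromosome is digested
    intact and fragments are labeled target when >= 50% of their length
    overlaps target regions.
    """
    target_regions = regions.select(list(target_labels))
    if mode == "per_region":
        chrom_lengths = {rec.id: len(rec) for rec in genome}
        background = target_regions.complement(chrom_lengths)
        fragments: list[Fragment] = []
        for labeled, part in (
            (region_sequences(genome, target_regions), TARGET),
            (region_sequences(genome, background), NON_TARGET),
        ):
            for ls in labeled:
                for f in digest(ls.sequence, plan, seq_id=ls.region.chrom, source_label=part):
                    # Lift fragment coordinates back to chromosome space.
                    fragments.append(
                        Fragment(
                            f.seq_id,
                            ls.region.start + f.start,
                            ls.region.start + f.end,
                            part,
                        )
                    )
        return fragments
    if mode == "whole_chromosome":
        fragments = []
        for rec in genome:
            for f in digest(rec.sequence, plan, seq_id=rec.id):
                # Merged overlap: bases under >1 target label count once.
                covered = target_regions.overlap_length(rec.id, f.start, f.end)
                label = TARGET if 2 * covered >= f.length else NON_TARGET
                fragments.append(Fragment(f.seq_id, f.start, f.end, label))
        return fragments
    raise ValueError(f"unknown partition mode {mode!r}")


def _bin_fragments(
    fragments: Sequence[Fragment], binning: SizeBinning
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = binning.n_bins
    n_frag_target = np.zeros(n, dtype=np.int64)
    n_frag_total = np.zeros(n, dtype=np.int64)
    bp_target = np.zeros(n, dtype=np.int64)
    bp_total = np.zeros(n, dtype=np.int64)
    for f in fragments:
        i = binning.bin_index(f.length)
        n_frag_total[i] += 1
        bp_total[i] += f.length
        if f.source_label == TARGET:
            n_frag_target[i] += 1
            bp_target[i] += f.length
    return n_frag_target, n_frag_total, bp_target, bp_total


def _table_from_counts(
    counts: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    binning: SizeBinning,
    baseline_pct: float,
) -> EnrichmentTable:
    n_frag_target, n_frag_total, bp_target, bp_total = counts
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_frag = np.where(n_frag_total > 0, 100.0 * n_frag_target / n_frag_total, np.nan)
        pct_bp = np.where(bp_total > 0, 100.0 * bp_target / bp_total, np.nan)
        fold = pct_bp / baseline_pct if baseline_pct > 0 else np.full(len(bp_total), np.nan)
    df = pd.DataFrame(
        {
            "bin": [binning.label(i) for i in range(binning.n_bins)],
            "bin_lo": [binning.bounds(i)[0] for i in range(binning.n_bins)],
            "n_frag_target": n_frag_target,
            "n_frag_total": n_frag_total,
            "bp_target": bp_target,
            "bp_total": bp_total,
            "pct_frag_target": pct_frag,
            "pct_bp_target": pct_bp,
            "fold_bp": fold,
        }
    )
    return EnrichmentTable(df, baseline_pct, binning)


def predict_enrichment(
    genome: Sequence[SequenceRecord],
    regions: RegionSet,
    plan: DigestionPlan,
    binning: Optional[SizeBinning] = None,
    target_labels: Sequence[str] = ("cen_region",),
    mode: str = "per_region",
) -> EnrichmentTable:
    """Predict per-size-bin target enrichment for one digestion plan.

    The baseline percentage is the undigested genome's target bp share;
    a bin's ``fold_bp`` is its target bp percentage over that baseline.
    When the target set is empty the baseline is 0 and folds are reported
    as NaN (absent), never infinity.
    """
    binning = binning or default_binning()
    baseline_pct = 100.0 * baseline_fraction(regions, genome, target_labels)
    fragments = digest_partitions(genome, regions, plan, target_labels, mode)
    return _table_from_counts(_bin_fragments(fragments, binning), binning, baseline_pct)


Objective = Union[str, Callable[[EnrichmentTable], float]]


def _make_objective(objective: Objective) -> Callable[[EnrichmentTable], float]:
    if callable(objective):
        return objective
    if objective.startswith("max_fold@"):
        cutoff = int(objective.split("@", 1)[1])
        return lambda t: t.max_fold(cutoff)
    if objective.startswith("agg_fold@"):
        cutoff = int(objective.split("@", 1)[1])
        return lambda t: t.aggregate_fold(cutoff)
    if objective == "top_bin_pct_bp":
        return lambda t: float(t.table["pct_bp_target"].iloc[-1])
    raise ValueError(f"unknown objective {objective!r}")


def screen_combinations(
    genome: Sequence[SequenceRecord],
    regions: RegionSet,
    panel: Sequence[Enzyme],
    max_size: int,
    objective: Objective = "max_fold@15000",
    binning: Optional[SizeBinning] = None,
    target_labels: Sequence[str] = ("cen_region",),
    min_solo_target_pct: Optional[float] = None,
) -> list[ComboScore]:
    """Score every enzyme combination of size <= max_size.

    Candidate site positions are computed once per enzyme per substrate and
    re-used across combinations, so the screen costs one scan per enzyme plus
    one greedy merge per combination.  Results are sorted by objective
    descending; ties go to the smaller combination, then lexicographic names.

    ``min_solo_target_pct`` optionally prunes enzymes whose *solo* digestion
    already drops the aggregate target bp percentage below the floor (an
    enzyme that shreds the target cannot be rescued by partners).
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if not panel:
        raise ValueError("empty enzyme panel")
    binning = binning or default_binning()
    baseline_pct = 100.0 * baseline_fraction(regions, genome, target_labels)
    score_of = _make_objective(objective)

    # Build substrates once: (length, partition label) plus per-enzyme candidates.
    target_regions = regions.select(list(target_labels))
    chrom_lengths = {rec.id: len(rec) for rec in genome}
    background = target_regions.complement(chrom_lengths)
    substrates: list[tuple[str, str]] = []  # (sequence, partition)
    for ls in region_sequences(genome, target_regions):
        substrates.append((ls.sequence.upper(), TARGET))
    for ls in region_sequences(genome, background):
        substrates.append((ls.sequence.upper(), NON_TARGET))

    cand: dict[str, list[list]] = {e.name: [] for e in panel}
    for enzyme in panel:
        for seq, _part in substrates:
            cand[enzyme.name].append(candidate_sites(seq, [enzyme]))
    # Assembly-gap breaks depend only on the shortest recognition length;
    # recompute lazily per plan minimum and cache.
    gap_cache: dict[int, list[list[tuple[int, int]]]] = {}

    def gaps_for(min_len: int) -> list[list[tuple[int, int]]]:
        if min_len not in gap_cache:
            gap_cache[min_len] = [_gap_breaks(seq, min_len) for seq, _ in substrates]
        return gap_cache[min_len]

    def table_for(combo: Sequence[Enzyme]) -> EnrichmentTable:
        min_len = min(len(e) for e in combo)
        gaps = gaps_for(min_len)
        fragments: list[Fragment] = []
        for i, (seq, part) in enumerate(substrates):
            hits = resolve_greedy(
                h for enzyme in combo for h in cand[enzyme.name][i]
            )
            removed = sorted([(h.start, h.end) for h in hits] + gaps[i])
            # site_removal sweep over the pre-resolved hits
            pos = 0
            for start, end in removed:
                if start > pos:
                    fragments.append(Fragment("s", pos, start, part))
                pos = max(pos, end)
            if pos < len(seq):
                fragments.append(Fragment("s", pos, len(seq), part))
        return _table_from_counts(_bin_fragments(fragments, binning), binning, baseline_pct)

    kept_panel = list(panel)
    if min_solo_target_pct is not None:
        kept_panel = [
            e
            for e in panel
            if table_for([e]).aggregate_pct_bp_target(0) >= min_solo_target_pct
        ]

    scores: list[ComboScore] = []
    for size in range(1, min(max_size, len(kept_panel)) + 1):
        for combo in itertools.combinations(sorted(kept_panel, key=lambda e: e.name), size):
            table = table_for(combo)
            s = score_of(table)
            scores.append(ComboScore(tuple(e.name for e in combo), s, table))
    scores.sort(
        key=lambda c: (
            -(c.score if not math.isnan(c.score) else -math.inf),
            len(c.enzymes),
            c.enzymes,
        )
    )
    return scores
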