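"""Sequencing-derived quantification of realized enrichment.

Everything here consumes outputs of external alignment/basecalling pipelines
as plain read sets or count tables: k-mer based classification of satellite
reads, binned log2 enrichment profiles vs. a whole-genome control, calling of
enrichment domains (runs of bins above a fold cutoff), residual uncut
restriction sites in reads, read-count based length proxies, and coverage
threshold tables.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genome_io import Region, RegionSet
from .restriction import Enzyme, compile_pattern

__all__ = [
    "KmerSet",
    "BinnedCounts",
    "EnrichmentDomain",
    "iter_reads",
    "count_kmer_positive_reads",
    "binned_log2_profile",
    "call_domains",
    "domain_region_coverage",
    "uncut_site_fraction",
    "length_change",
    "coverage_threshold_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = _revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerSet:
    """A set of canonical k-mers used to classify satellite-derived reads."""

    def __init__(self, kmers: Iterable[str], k: Optional[int] = None):
        canon = {canonical_kmer(km.upper()) for km in kmers}
        if not canon:
            raise ValueError("empty k-mer set")
        lengths = {len(km) for km in canon}
        if len(lengths) != 1:
            raise ValueError(f"k-mers of mixed lengths: {sorted(lengths)}")
        length = lengths.pop()
        if k is not None and k != length:
            raise ValueError(f"k={k} does not match k-mer length {length}")
        self.k = length
        for km in canon:
            if set(km) - set("ACGT"):
                raise ValueError(f"k-mer {km!r} contains non-ACGT characters")
        self.kmers = frozenset(canon)

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return canonical_kmer(kmer) in self.kmers

    @classmethod
    def from_file(cls, path, k: Optional[int] = None) -> "KmerSet":
        """One k-mer per line, '#' comments allowed."""
        kmers = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    kmers.append(line)
        return cls(kmers, k)

    @classmethod
    def from_monomer(cls, monomer: str, k: int = 18) -> "KmerSet":
        """All k-mers of a tandemly repeated monomer, junctions included.

        The monomer is virtually doubled so k-mers spanning the head-to-tail
        junction of the repeat array are represented.
        """
        monomer = monomer.upper()
        if len(monomer) < k:
            raise ValueError(f"monomer shorter than k={k}")
        doubled = monomer + monomer[: k - 1]
        return cls((doubled[i : i + k] for i in range(len(monomer))), k)


def iter_reads(source) -> Iterable[str]:
    """Yield read sequences (uppercase strings) from FASTA/FASTQ[.gz] or iterables."""
    if isinstance(source, (str, Path)):
        path = str(source)
        stem = path[:-3] if path.endswith(".gz") else path
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield str(rec.seq).upper()
    else:
        for item in source:
            if isinstance(item, str):
                yield item.upper()
            else:  # SeqRecord or Seq
                yield str(getattr(item, "seq", item)).upper()


def count_kmer_positive_reads(
    reads, kmerset: KmerSet, min_hits: int = 2, distinct: bool = False
) -> tuple[int, int, float]:
    """Count reads carrying at least ``min_hits`` set k-mers.

    A read is positive when at least ``min_hits`` of its k-mer windows
    (canonicalized, so orientation is irrelevant) are members of ``kmerset``;
    with ``distinct=True`` repeated occurrences of the same k-mer count once.
    Windows containing ``N`` never match.  Reads shorter than k count in the
    total but can never be positive.  Returns (n_positive, n_total, fraction).
    """
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    k = kmerset.k
    n_positive = 0
    n_total = 0
    for read in iter_reads(reads):
        n_total += 1
        hits = 0
        seen: set[str] = set()
        for i in range(len(read) - k + 1):
            window = read[i : i + k]
            if "N" in window:
                continue
            canon = canonical_kmer(window)
            if canon in kmerset.kmers:
                if distinct:
                    seen.add(canon)
                else:
                    hits += 1
                    if hits >= min_hits:
                        break
        if distinct:
            hits = len(seen)
        if hits >= min_hits:
            n_positive += 1
    fraction = n_positive / n_total if n_total else float("nan")
    return n_positive, n_total, fraction


class BinnedCounts:
    """Per-(chrom, bin_start) counts on a fixed-width genomic grid."""

    def __init__(self, counts: Mapping[tuple[str, int], float], bin_width: int = 2000):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for (chrom, start), value in counts.items():
            if start % bin_width:
                raise ValueError(f"bin_start {start} not a multiple of bin_width {bin_width}")
            if value < 0:
                raise ValueError(f"negative count at {chrom}:{start}")
        self.counts = dict(counts)
        self.bin_width = bin_width

    @classmethod
    def from_tsv(cls, path, bin_width: int = 2000) -> "BinnedCounts":
        """Read bedGraph (chrom, start, end, value) or 3-column chrom/start/value."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] >= 4:
            counts = {(r[0], int(r[1])): float(r[3]) for r in df.itertuples(index=False)}
        else:
            counts = {(r[0], int(r[1])): float(r[2]) for r in df.itertuples(index=False)}
        return cls(counts, bin_width)

    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass(frozen=True)
class EnrichmentDomain:
    chrom: str
    start: int
    end: int
    mean_fold: float


def binned_log2_profile(
    sample: BinnedCounts, reference: BinnedCounts, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-bin log2 ratio of sample over reference after depth equalization.

    Both tracks are scaled to the same total (the mean of the two totals);
    the log2 ratio of a bin is ``log2((s*S + p) / (r*R + p))`` with S, R the
    scale factors and p the pseudocount in scaled-count units.  Bins present
    in only one track are treated as zero in the other.
    """
    if sample.bin_width != reference.bin_width:
        raise ValueError(
            f"bin widths differ: {sample.bin_width} vs {reference.bin_width}"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    ts, tr = sample.total(), reference.total()
    common = (ts + tr) / 2.0
    s_scale = common / ts if ts > 0 else 0.0
    r_scale = common / tr if tr > 0 else 0.0
    bins = sorted(set(sample.counts) | set(reference.counts))
    rows = []
    for chrom, start in bins:
        s = sample.counts.get((chrom, start), 0.0) * s_scale
        r = reference.counts.get((chrom, start), 0.0) * r_scale
        log2_ratio = math.log2((s + pseudocount) / (r + pseudocount))
        rows.append((chrom, start, log2_ratio, 2.0 ** log2_ratio))
    df = pd.DataFrame(rows, columns=["chrom", "bin_start", "log2_ratio", "fold"])
    df.attrs["bin_width"] = sample.bin_width
    return df


def call_domains(
    profile: pd.DataFrame,
    bin_width: Optional[int] = None,
    min_fold: float = 5.0,
    max_gap_bins: int = 0,
    min_bins: int = 1,
) -> list[EnrichmentDomain]:
    """Maximal runs of bins with fold strictly above ``min_fold``.

    Within a chromosome, runs separated by at most ``max_gap_bins``
    consecutive sub-threshold bins are merged; runs of fewer than ``min_bins``
    qualifying bins are dropped.  The reported mean fold averages the
    qualifying bins of the domain.
    """
    if min_fold <= 0:
        raise ValueError("min_fold must be > 0")
    bin_width = bin_width or profile.attrs.get("bin_width")
    if not bin_width:
        raise ValueError("bin_width not given and absent from profile metadata")
    domains: list[EnrichmentDomain] = []
    for chrom, sub in profile.groupby("chrom", sort=True):
        sub = sub.sort_values("bin_start")
        starts = sub["bin_start"].to_numpy()
        folds = sub["fold"].to_numpy()
        run: list[tuple[int, float]] = []  # (bin_start, fold) of qualifying bins
        last_hit_index: Optional[int] = None
        for idx, (start, fold) in enumerate(zip(starts, folds)):
            if fold > min_fold:
                gap_bins = 0
                if run and last_hit_index is not None:
                    # Gap measured on the genomic grid, robust to missing bins.
                    gap_bins = (start - run[-1][0]) // bin_width - 1
                if run and gap_bins > max_gap_bins:
                    domains.extend(_flush_run(chrom, run, bin_width, min_bins))
                    run = []
                run.append((int(start), float(fold)))
                last_hit_index = idx
        domains.extend(_flush_run(chrom, run, bin_width, min_bins))
    return domains


def _flush_run(
    chrom: str, run: list[tuple[int, float]], bin_width: int, min_bins: int
) -> list[EnrichmentDomain]:
    if not run or len(run) < min_bins:
        return []
    folds = [f for _, f in run]
    return [
        EnrichmentDomain(chrom, run[0][0], run[-1][0] + bin_width, float(np.mean(folds)))
    ]


def domain_region_coverage(
    domains: Sequence[EnrichmentDomain],
    regions: RegionSet,
    label: Optional[str] = None,
) -> pd.DataFrame:
    """Per labeled region: base-pairs covered by domains and the proportion."""
    domain_set = RegionSet(
        Region(d.chrom, d.start, d.end, "domain") for d in domains
    )
    rows = []
    for r in regions:
        if label is not None and r.label != label:
            continue
        covered = domain_set.overlap_length(r.chrom, r.start, r.end)
        rows.append((r.chrom, r.start, r.end, r.label, covered, covered / r.length))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "covered_bp", "proportion"]
    )


def _count_site_occurrences(reads, enzymes: Sequence[Enzyme]) -> dict[str, int]:
    """Occurrences of each recognition site in a read set, overlaps allowed.

    Reads are observations, not substrates, so no non-overlapping resolution
    is applied; each position matching the site (either orientation, forward
    coordinates, deduplicated) counts once.
    """
    matchers = {e.name: compile_pattern(e.recognition) for e in enzymes}
    totals = {e.name: 0 for e in enzymes}
    for read in iter_reads(reads):
        for name, matcher in matchers.items():
            totals[name] += sum(1 for _ in matcher.finditer(read))
    return totals


def uncut_site_fraction(
    sample_reads, reference_reads, enzymes: Sequence[Enzyme]
) -> dict[str, Optional[float]]:
    """Residual intact restriction sites in reads, as percent of a control.

    Both read sets are assumed depth-normalized (downsampled to equal total
    base count).  Returns per-enzyme percentages plus a ``pooled`` entry;
    an enzyme with zero occurrences in the reference is reported as None.
    """
    sample_counts = _count_site_occurrences(sample_reads, enzymes)
    reference_counts = _count_site_occurrences(reference_reads, enzymes)
    out: dict[str, Optional[float]] = {}
    for e in enzymes:
        ref = reference_counts[e.name]
        out[e.name] = 100.0 * sample_counts[e.name] / ref if ref > 0 else None
    pooled_ref = sum(reference_counts.values())
    pooled_sample = sum(sample_counts.values())
    out["pooled"] = 100.0 * pooled_sample / pooled_ref if pooled_ref > 0 else None
    return out


def length_change(
    counts_a: Mapping[str, float], counts_b: Mapping[str, float]
) -> dict[str, Optional[float]]:
    """Per-region percent variation of A over B: (A/B - 1) * 100.

    Used as a proxy for satellite array length when counts are reads mapping
    to each region at equal sequencing depth.  Regions with a zero or missing
    B count are reported as None.
    """
    out: dict[str, Optional[float]] = {}
    for region in counts_a:
        b = counts_b.get(region, 0.0)
        out[region] = (counts_a[region] / b - 1.0) * 100.0 if b > 0 else None
    return out


def coverage_threshold_table(
    bin_coverages: Sequence[float], thresholds: Sequence[float]
) -> pd.DataFrame:
    """Percent of bins with coverage >= t for each threshold t (ascending)."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    cov = np.asarray(bin_coverages, dtype=float)
    rows = []
    for t in thresholds:
        pct = 100.0 * float((cov >= t).mean()) if cov.size else float("nan")
        rows.append((t, pct))
    return pd.DataFrame(rows, columns=["min_coverage", "pct_bins"])
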