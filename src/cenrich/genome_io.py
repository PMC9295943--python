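"""Genome and region I/O plus the interval arithmetic shared by all modules.

Coordinates are 0-based half-open (BED convention) everywhere.  Regions carry
a family label (``cen_region``, ``HOR``, ``HSat1``..``HSat5``, or anything
else the annotation provides); overlapping intervals with the same label are
merged on load.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "SequenceRecord",
    "Region",
    "RegionSet",
    "LabeledSequence",
    "load_genome",
    "load_regions",
    "write_regions",
    "region_sequences",
    "overlap_length",
    "write_fragments_bed",
]

DEFAULT_LABEL = "cen_region"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Region:
    chrom: str
    start: int
    end: int
    label: str = DEFAULT_LABEL

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LabeledSequence:
    region: Region
    sequence: str


class RegionSet:
    """Labeled genomic intervals with fast overlap queries.

    Intervals are kept sorted per chromosome; same-label overlaps are merged
    at construction so the per-label sets are disjoint.
    """

    def __init__(self, regions: Iterable[Region] = ()):
        self.regions: list[Region] = self._merge_same_label(regions)
        self._trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.label)

    @staticmethod
    def _merge_same_label(regions: Iterable[Region]) -> list[Region]:
        merged: list[Region] = []
        by_key: dict[tuple[str, str], list[Region]] = {}
        for r in regions:
            by_key.setdefault((r.chrom, r.label), []).append(r)
        for (chrom, label), group in by_key.items():
            group.sort()
            cur_start, cur_end = group[0].start, group[0].end
            for r in group[1:]:
                if r.start <= cur_end:
                    cur_end = max(cur_end, r.end)
                else:
                    merged.append(Region(chrom, cur_start, cur_end, label))
                    cur_start, cur_end = r.start, r.end
            merged.append(Region(chrom, cur_start, cur_end, label))
        merged.sort()
        return merged

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def labels(self) -> set[str]:
        return {r.label for r in self.regions}

    def select(self, labels: Optional[Sequence[str]] = None) -> "RegionSet":
        if labels is None:
            return self
        wanted = set(labels)
        return RegionSet(r for r in self.regions if r.label in wanted)

    def total_bp(self, labels: Optional[Sequence[str]] = None) -> int:
        """Total base-pairs covered, counting bases under >1 label once."""
        chosen = self.select(labels).regions
        total = 0
        by_chrom: dict[str, list[Region]] = {}
        for r in chosen:
            by_chrom.setdefault(r.chrom, []).append(r)
        for group in by_chrom.values():
            group.sort()
            cur_start, cur_end = group[0].start, group[0].end
            for r in group[1:]:
                if r.start <= cur_end:
                    cur_end = max(cur_end, r.end)
                else:
                    total += cur_end - cur_start
                    cur_start, cur_end = r.start, r.end
            total += cur_end - cur_start
        return total

    def overlap_length(
        self, chrom: str, start: int, end: int, label: Optional[str] = None
    ) -> int:
        """Base-pairs of (chrom,start,end) covered by regions (of one label)."""
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return 0
        pieces = [
            (max(start, iv.begin), min(end, iv.end))
            for iv in tree.overlap(start, end)
            if label is None or iv.data == label
        ]
        if not pieces:
            return 0
        # Merge so double-labeled bases are counted once.
        pieces.sort()
        covered = 0
        cur_start, cur_end = pieces[0]
        for s, e in pieces[1:]:
            if s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                covered += cur_end - cur_start
                cur_start, cur_end = s, e
        covered += cur_end - cur_start
        return covered

    def labels_at(self, chrom: str, pos: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}

    def complement(
        self,
        chrom_lengths: dict[str, int],
        labels: Optional[Sequence[str]] = None,
        complement_label: str = "other",
    ) -> "RegionSet":
        """Per-chromosome complement of the (selected) regions."""
        chosen = self.select(labels)
        out: list[Region] = []
        for chrom, length in chrom_lengths.items():
            pos = 0
            for r in (x for x in chosen.regions if x.chrom == chrom):
                if r.start > pos:
                    out.append(Region(chrom, pos, min(r.start, length), complement_label))
                pos = max(pos, r.end)
            if pos < length:
                out.append(Region(chrom, pos, length, complement_label))
        return RegionSet(out)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_genome(path) -> list[SequenceRecord]:
    """Read a FASTA (optionally gzip) into uppercased in-memory records."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def load_regions(path, min_length: int = 0, default_label: str = DEFAULT_LABEL) -> RegionSet:
    """Read BED3+/BED4+ regions; column 4, when present, is the family label.

    Intervals shorter than ``min_length`` are dropped *before* merging, the
    same order of operations as filtering an annotation table by array length
    and then digesting what remains.
    """
    regions: list[Region] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else default_label
            if end - start >= max(min_length, 1):
                regions.append(Region(chrom, start, end, label))
    return RegionSet(regions)


def write_regions(regions: RegionSet, path) -> None:
    """Write a RegionSet as canonical BED4 (tab-separated, sorted)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def region_sequences(
    genome: Sequence[SequenceRecord], regions: RegionSet
) -> list[LabeledSequence]:
    """Extract each region's sequence (0-based half-open slices)."""
    by_id = {rec.id: rec.sequence for rec in genome}
    out: list[LabeledSequence] = []
    for r in regions:
        if r.chrom not in by_id:
            raise KeyError(f"region chrom {r.chrom!r} not present in genome")
        seq = by_id[r.chrom]
        if r.end > len(seq):
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} exceeds sequence length {len(seq)}"
            )
        out.append(LabeledSequence(r, seq[r.start : r.end]))
    return out


def overlap_length(
    interval: tuple[str, int, int], regions: RegionSet, label: Optional[str] = None
) -> int:
    """Total base-pairs of ``interval`` covered by ``regions`` (optionally one label)."""
    chrom, start, end = interval
    return regions.overlap_length(chrom, start, end, label)


def write_fragments_bed(fragments, path) -> None:
    """Write digestion fragments as BED6: chrom, start, end, label, length, '.'"""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{f.source_label}\t{f.length}\t.\n")
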