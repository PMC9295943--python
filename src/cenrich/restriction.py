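"""Restriction enzymes with degenerate recognition sites and in silico digestion.

Recognition sequences are given in the IUPAC nucleotide alphabet
(``ACGTRYSWKMBDHVN``).  Digestion follows a *site-removal* semantic by
default: every retained recognition-site occurrence is excised from the
substrate and the remaining runs of sequence become the predicted digestion
products.  This mirrors the common string-level shortcut of replacing each
site occurrence with a break and measuring the lengths of the resulting
pieces.  A mass-conserving ``site_retained`` mode (cut at the start of each
site, all bases kept on the downstream fragment boundary) is provided for
comparison with physical digests.

Overlapping candidate sites — which arise with degenerate patterns and with
multi-enzyme panels — are resolved to a non-overlapping set by greedy
left-most selection; ties at the same start position are broken in favour of
the longer recognition sequence, then by enzyme name.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "IUPAC_CODES",
    "Enzyme",
    "DigestionPlan",
    "SiteHit",
    "Fragment",
    "compile_pattern",
    "find_sites",
    "digest",
    "reverse_complement_iupac",
    "load_enzyme_panel",
    "default_panel",
]

#: IUPAC code -> set of concrete bases it stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def reverse_complement_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC string, degenerate codes included."""
    try:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol {exc.args[0]!r} in {pattern!r}") from exc


def _validate_iupac(pattern: str) -> str:
    pattern = pattern.upper()
    if not pattern:
        raise ValueError("recognition sequence must be non-empty")
    for c in pattern:
        if c not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC symbol {c!r} in recognition {pattern!r}")
    return pattern


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: a name and an IUPAC recognition sequence."""

    name: str
    recognition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", _validate_iupac(self.recognition))
        if not self.name:
            raise ValueError("enzyme name must be non-empty")

    @property
    def palindromic(self) -> bool:
        """True when the recognition set equals its own reverse complement."""
        return self.recognition == reverse_complement_iupac(self.recognition)

    def __len__(self) -> int:
        return len(self.recognition)


@dataclass(frozen=True)
class SiteHit:
    """One retained recognition-site occurrence, forward coordinates."""

    seq_id: str
    start: int
    end: int
    enzyme: str


@dataclass(frozen=True)
class Fragment:
    """A digestion product located on its source sequence."""

    seq_id: str
    start: int
    end: int
    source_label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(f"fragment ({self.start},{self.end}) has length <= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DigestionPlan:
    """One or more enzymes plus the digestion semantics to apply."""

    enzymes: tuple[Enzyme, ...]
    mode: str = "site_removal"
    match_policy: str = "greedy_leftmost_nonoverlapping"

    def __post_init__(self) -> None:
        enzymes = tuple(self.enzymes)
        object.__setattr__(self, "enzymes", enzymes)
        if not enzymes:
            raise ValueError("a digestion plan needs at least one enzyme")
        names = [e.name for e in enzymes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate enzyme names in plan: {names}")
        if self.mode not in ("site_removal", "site_retained"):
            raise ValueError(f"unknown digestion mode {self.mode!r}")
        if self.match_policy != "greedy_leftmost_nonoverlapping":
            raise ValueError(f"unknown match policy {self.match_policy!r}")

    @property
    def min_recognition_length(self) -> int:
        return min(len(e) for e in self.enzymes)


class CompiledPattern:
    """Matcher for one IUPAC recognition sequence over ACGT(N) text.

    ``N`` in the *text* matches nothing (assembly gaps and ambiguous calls are
    not substrate).  Non-palindromic patterns are also scanned in the
    reverse-complement orientation, with hits reported as forward-strand
    coordinates and duplicates removed.  Candidate matches may overlap.
    """

    def __init__(self, recognition: str):
        self.recognition = _validate_iupac(recognition)
        self._regexes = [self._to_regex(self.recognition)]
        rc = reverse_complement_iupac(self.recognition)
        if rc != self.recognition:
            self._regexes.append(self._to_regex(rc))

    @staticmethod
    def _to_regex(pattern: str) -> re.Pattern[str]:
        # Lookahead so overlapping candidates are all reported.
        parts = []
        for c in pattern:
            bases = IUPAC_CODES[c]
            parts.append(next(iter(bases)) if len(bases) == 1 else f"[{''.join(sorted(bases))}]")
        return re.compile(f"(?=({''.join(parts)}))")

    def __len__(self) -> int:
        return len(self.recognition)

    def finditer(self, text: str) -> Iterator[int]:
        """Yield sorted, deduplicated start offsets of all candidate matches."""
        starts: set[int] = set()
        for rx in self._regexes:
            starts.update(m.start() for m in rx.finditer(text))
        yield from sorted(starts)

    def matches_at(self, text: str, offset: int) -> bool:
        window = text[offset : offset + len(self.recognition)]
        if len(window) < len(self.recognition):
            return False
        return any(rx.match(text, offset) for rx in self._regexes)


def compile_pattern(recognition: str) -> CompiledPattern:
    """Compile an IUPAC recognition sequence into a reusable matcher."""
    return CompiledPattern(recognition)


def candidate_sites(
    seq: str, enzymes: Sequence[Enzyme], *, seq_id: str = "seq"
) -> list[SiteHit]:
    """All (possibly overlapping) candidate occurrences for every enzyme."""
    text = seq.upper()
    hits: list[SiteHit] = []
    for enzyme in enzymes:
        matcher = compile_pattern(enzyme.recognition)
        hits.extend(
            SiteHit(seq_id, s, s + len(enzyme), enzyme.name) for s in matcher.finditer(text)
        )
    return hits


def resolve_greedy(hits: Iterable[SiteHit]) -> list[SiteHit]:
    """Greedy left-most non-overlapping selection with deterministic tie-break.

    Ties at equal start go to the longer recognition site, then to the
    lexicographically smaller enzyme name.
    """
    ordered = sorted(hits, key=lambda h: (h.start, -(h.end - h.start), h.enzyme))
    kept: list[SiteHit] = []
    last_end = -1
    for hit in ordered:
        if hit.start >= last_end:
            kept.append(hit)
            last_end = hit.end
    return kept


def find_sites(seq: str, plan: DigestionPlan, *, seq_id: str = "seq") -> list[SiteHit]:
    """Retained recognition-site occurrences for a multi-enzyme plan.

    Candidates from all enzymes are pooled and resolved jointly, so the result
    does not depend on the order enzymes are listed in the plan.
    """
    if not seq:
        return []
    return resolve_greedy(candidate_sites(seq, plan.enzymes, seq_id=seq_id))


_N_RUN = re.compile("N+")


def _gap_breaks(text: str, min_len: int) -> list[tuple[int, int]]:
    """Runs of N at least ``min_len`` long, treated as hard fragment breaks."""
    return [
        (m.start(), m.end()) for m in _N_RUN.finditer(text) if m.end() - m.start() >= min_len
    ]


def digest(
    seq: str,
    plan: DigestionPlan,
    *,
    seq_id: str = "seq",
    source_label: str = "unlabeled",
) -> list[Fragment]:
    """Digest one sequence, returning its predicted fragments.

    ``site_removal`` excises retained sites: fragments are the maximal runs
    between them and zero-length pieces (adjacent sites) are dropped, so
    ``sum(fragment lengths) + sum(retained site lengths) == len(seq)`` on
    gap-free sequences.  ``site_retained`` cuts at each retained hit's start
    and conserves every base.  In both modes, runs of ``N`` at least as long
    as the plan's shortest recognition sequence act as hard breaks (assembly
    gaps are not contiguous DNA) and are never part of a fragment.
    """
    text = seq.upper()
    if not text:
        return []
    hits = find_sites(text, plan, seq_id=seq_id)
    gaps = _gap_breaks(text, plan.min_recognition_length)

    if plan.mode == "site_removal":
        removed = sorted([(h.start, h.end) for h in hits] + gaps)
    else:  # site_retained: cut at each hit start; gaps still removed
        cuts = sorted({h.start for h in hits})
        removed = sorted(gaps)
        # Translate cut positions into zero-width removals for uniform sweep.
        removed = sorted(removed + [(c, c) for c in cuts])

    fragments: list[Fragment] = []
    pos = 0
    for start, end in removed:
        if start > pos:
            fragments.append(Fragment(seq_id, pos, start, source_label))
        pos = max(pos, end)
    if pos < len(text):
        fragments.append(Fragment(seq_id, pos, len(text), source_label))
    return fragments


def load_enzyme_panel(path) -> list[Enzyme]:
    """Read a two-column ``name<TAB>recognition`` TSV (header optional)."""
    enzymes: list[Enzyme] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>recognition'")
            name, recognition = fields[0].strip(), fields[1].strip()
            if lineno == 1 and name.lower() in ("name", "enzyme"):
                continue
            enzymes.append(Enzyme(name, recognition))
    return enzymes


def default_panel() -> list[Enzyme]:
    """The six enzymes shipped with the package.

    ScrFI, NlaIV and EcoO109I form the SNE combination; ScrFI, EcoO109I and
    BstUI form SEB; MscI + AseI is the alternative two-enzyme combination.
    """
    from importlib import resources

    path = resources.files("cenrich").joinpath("data/enzymes_default.tsv")
    with resources.as_file(path) as p:
        return load_enzyme_panel(p)
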