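"""Independent brute-force reference for site finding and digestion.

Deliberately naive: O(n*m) window-by-window comparison against the IUPAC
code table, checking both orientations explicitly, then the same greedy
left-most selection rule applied literally.  Used only as the oracle in
tests; shares no code path with the package implementation.
"""

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def revcomp_pattern(pattern):
    return "".join(COMP[c] for c in reversed(pattern))


def window_matches(text, offset, pattern):
    if offset + len(pattern) > len(text):
        return False
    for i, code in enumerate(pattern):
        if text[offset + i] not in IUPAC[code]:  # genome N is in no code's set
            return False
    return True


def naive_candidates(text, enzymes):
    """All candidate (start, end, name), both orientations, deduplicated."""
    text = text.upper()
    out = []
    for name, pattern in enzymes:
        patterns = {pattern, revcomp_pattern(pattern)}
        starts = set()
        for p in patterns:
            for offset in range(len(text)):
                if window_matches(text, offset, p):
                    starts.add(offset)
        out.extend((s, s + len(pattern), name) for s in sorted(starts))
    return out


def naive_find_sites(text, enzymes):
    """Greedy left-most non-overlapping; ties: longer site, then name."""
    candidates = sorted(
        naive_candidates(text, enzymes), key=lambda h: (h[0], -(h[1] - h[0]), h[2])
    )
    kept = []
    last_end = -1
    for start, end, name in candidates:
        if start >= last_end:
            kept.append((start, end, name))
            last_end = end
    return kept


def naive_digest_lengths(text, enzymes):
    """Fragment lengths after excising every retained site."""
    hits = naive_find_sites(text, enzymes)
    lengths = []
    pos = 0
    for start, end, _ in hits:
        if start > pos:
            lengths.append(start - pos)
        pos = end
    if pos < len(text):
        lengths.append(len(text) - pos)
    return lengths
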