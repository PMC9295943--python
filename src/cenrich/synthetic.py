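"""Synthetic genomes, size-selected read pools and methylation tables.

Generators with exact, recomputable ground truth so the digestion,
enrichment-prediction, read-classification and methylation modules can be
exercised without any external download.  The toy genome mimics the
architecture that makes restriction-based centromere enrichment work: AT-rich
171-bp monomers repeated head-to-tail into homogeneous satellite arrays that
are depleted of chosen recognition sites, embedded in background DNA that
carries those sites at a controllable spacing.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import Region, RegionSet, SequenceRecord
from .restriction import DigestionPlan, Enzyme, Fragment, IUPAC_CODES, find_sites

__all__ = [
    "SyntheticGenomeSpec",
    "make_monomer",
    "make_toy_genome",
    "simulate_size_selected_reads",
    "simulate_methylation",
    "DEFAULT_FAMILY_PARAMS",
]

BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _site_free(seq: str, enzymes: Sequence[Enzyme]) -> bool:
    if not enzymes:
        return True
    plan = DigestionPlan(tuple(enzymes))
    return not find_sites(seq, plan)


def _scrub_sites(
    seq: str, enzymes: Sequence[Enzyme], rng: np.random.Generator, max_rounds: int = 100
) -> str:
    """Destroy every recognition site by point substitutions until clean."""
    if not enzymes:
        return seq
    plan = DigestionPlan(tuple(enzymes))
    chars = list(seq)
    for _ in range(max_rounds):
        hits = find_sites("".join(chars), plan)
        if not hits:
            return "".join(chars)
        for h in hits:
            pos = int(rng.integers(h.start, h.end))
            current = chars[pos]
            choices = [b for b in "ACGT" if b != current]
            chars[pos] = choices[int(rng.integers(0, 3))]
    raise RuntimeError("could not scrub all recognition sites; loosen constraints")


def make_monomer(
    length: int = 171,
    gc: float = 0.35,
    forbidden_enzymes: Sequence[Enzyme] = (),
    seed: int = 0,
    max_attempts: int = 200,
) -> str:
    """A random monomer whose tandem repetition contains no forbidden site.

    The monomer is validated on its own doubling, so sites spanning the
    head-to-tail junction of a tandem array are excluded as well.  Rejection
    sampling is followed by targeted point-substitution repair; an error is
    raised after ``max_attempts`` full restarts.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        candidate = _random_seq(rng, length, gc)
        try:
            repaired = _scrub_sites_tandem(candidate, forbidden_enzymes, rng)
        except RuntimeError:
            continue
        return repaired
    raise RuntimeError(
        f"no site-free monomer found in {max_attempts} attempts; "
        "loosen constraints (fewer enzymes, longer monomer, lower gc)"
    )


def _scrub_sites_tandem(
    monomer: str, enzymes: Sequence[Enzyme], rng: np.random.Generator, max_rounds: int = 100
) -> str:
    """Scrub sites from a monomer judged on its doubled (tandem) form."""
    if not enzymes:
        return monomer
    plan = DigestionPlan(tuple(enzymes))
    chars = list(monomer)
    n = len(monomer)
    for _ in range(max_rounds):
        doubled = "".join(chars) * 2
        hits = find_sites(doubled, plan)
        if not hits:
            return "".join(chars)
        for h in hits:
            pos = int(rng.integers(h.start, h.end)) % n
            current = chars[pos]
            choices = [b for b in "ACGT" if b != current]
            chars[pos] = choices[int(rng.integers(0, 3))]
    raise RuntimeError("tandem scrub failed")


def _concrete_site(enzyme: Enzyme, rng: np.random.Generator) -> str:
    """One concrete ACGT realization of a degenerate recognition sequence."""
    out = []
    for code in enzyme.recognition:
        bases = sorted(IUPAC_CODES[code])
        out.append(bases[int(rng.integers(0, len(bases)))])
    return "".join(out)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Layout of a toy genome: satellite arrays embedded in cuttable background.

    ``background_site_spacing`` is the target distance between injected
    recognition sites in the background; actual spacing is jittered uniformly
    by +-20% so fragment lengths vary but stay controllable.
    ``divergence_rate`` applies per-base substitutions to each monomer copy,
    emulating divergent flanks (0 = perfectly homogeneous array).
    """

    monomer_length: int = 171
    hor_unit: int = 4
    array_copies: int = 50
    n_arrays: int = 1
    background_length: int = 307_800
    background_site_spacing: int = 500
    forbidden_enzymes: tuple[Enzyme, ...] = ()
    divergence_rate: float = 0.0
    gc: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("monomer_length", "hor_unit", "array_copies", "n_arrays",
                     "background_length", "background_site_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.divergence_rate <= 1:
            raise ValueError("divergence_rate must be in [0, 1]")

    @property
    def array_length(self) -> int:
        return self.monomer_length * self.hor_unit * self.array_copies


def _background(
    rng: np.random.Generator, spec: SyntheticGenomeSpec, length: int
) -> str:
    """Background DNA: scrubbed filler with exact sites injected at ~spacing."""
    enzymes = list(spec.forbidden_enzymes)
    filler = _random_seq(rng, length, 0.5)
    filler = _scrub_sites(filler, enzymes, rng)
    if not enzymes:
        return filler
    chars = list(filler)
    pos = spec.background_site_spacing
    i = 0
    while pos < length:
        enzyme = enzymes[i % len(enzymes)]
        site = _concrete_site(enzyme, rng)
        if pos + len(site) <= length:
            chars[pos : pos + len(site)] = site
        jitter = rng.uniform(0.8, 1.2)
        pos += max(len(site) + 1, int(spec.background_site_spacing * jitter))
        i += 1
    return "".join(chars)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    n_mut = rng.binomial(len(chars), rate)
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        current = chars[pos]
        choices = [b for b in "ACGT" if b != current]
        chars[pos] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def make_toy_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[list[SequenceRecord], RegionSet, dict]:
    """Build one synthetic chromosome: background | arrays | background.

    Returns (genome records, region annotations, truth record).  Arrays are
    labeled both ``cen_region`` and ``HOR`` in the annotation.  The truth
    record stores the monomer, exact array coordinates and the exact target
    base-pair fraction, recomputable from the outputs.
    """
    rng = np.random.default_rng(spec.seed)
    monomer = make_monomer(
        spec.monomer_length, spec.gc, spec.forbidden_enzymes, seed=int(rng.integers(2**31))
    )
    hor = monomer * spec.hor_unit

    n_bg_segments = spec.n_arrays + 1
    seg_len = spec.background_length // n_bg_segments
    seg_lens = [seg_len] * n_bg_segments
    seg_lens[-1] += spec.background_length - seg_len * n_bg_segments

    parts: list[str] = []
    regions: list[Region] = []
    arrays: list[tuple[int, int]] = []
    pos = 0
    for i in range(spec.n_arrays):
        bg = _background(rng, spec, seg_lens[i])
        parts.append(bg)
        pos += len(bg)
        array_seq = "".join(
            _mutate(hor, spec.divergence_rate, rng) for _ in range(spec.array_copies)
        )
        if spec.divergence_rate > 0:
            array_seq = _scrub_sites(array_seq, list(spec.forbidden_enzymes), rng)
        parts.append(array_seq)
        regions.append(Region("chrS", pos, pos + len(array_seq), "cen_region"))
        regions.append(Region("chrS", pos, pos + len(array_seq), "HOR"))
        arrays.append((pos, pos + len(array_seq)))
        pos += len(array_seq)
    parts.append(_background(rng, spec, seg_lens[-1]))

    sequence = "".join(parts)
    genome = [SequenceRecord("chrS", sequence)]
    region_set = RegionSet(regions)
    target_bp = sum(e - s for s, e in arrays)
    truth = {
        "monomer": monomer,
        "chrom_length": len(sequence),
        "arrays": arrays,
        "target_bp": target_bp,
        "target_fraction": target_bp / len(sequence),
        "seed": spec.seed,
    }
    return genome, region_set, truth


def simulate_size_selected_reads(
    fragments: Sequence[Fragment],
    sequences: dict[str, str],
    min_length: int,
    n_reads: int,
    read_length: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[tuple[str, str]]:
    """Reads drawn from the pool of fragments passing a size cutoff.

    Fragments shorter than ``min_length`` are discarded (the in silico
    counterpart of selecting high-molecular-weight material); reads start
    uniformly per base across the surviving pool, half of them on the reverse
    strand.  Returns (read_id, sequence) pairs; read ids carry the source
    fragment's label so origin is recoverable.  ``error_rate`` applies
    uniform substitution errors (off by default).
    """
    eligible = [f for f in fragments if f.length >= max(min_length, read_length)]
    if not eligible:
        raise ValueError(f"no fragment of length >= {max(min_length, read_length)}")
    rng = np.random.default_rng(seed)
    lengths = np.array([f.length for f in eligible], dtype=float)
    probs = lengths / lengths.sum()
    choices = rng.choice(len(eligible), size=n_reads, p=probs)
    reads: list[tuple[str, str]] = []
    for i, idx in enumerate(choices):
        frag = eligible[int(idx)]
        start = int(rng.integers(0, frag.length - read_length + 1))
        seq = sequences[frag.seq_id][frag.start + start : frag.start + start + read_length]
        if rng.random() < 0.5:
            seq = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        seq = _mutate(seq, error_rate, rng) if error_rate else seq
        reads.append((f"read_{i}|source={frag.source_label}", seq))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")


@dataclass(frozen=True)
class FamilyParams:
    """Methylation behaviour of one repeat family.

    ``mean_wt`` is the family's mean wild-type methylation frequency in
    percent; ``relative_drop`` the knockout's relative decrease of that mean
    (0.73 means the KO family mean is 27% of the WT mean); ``dispersion``
    the concentration of the per-site beta distribution around the family
    mean (larger = tighter).
    """

    mean_wt: float
    relative_drop: float
    dispersion: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.mean_wt <= 100:
            raise ValueError("mean_wt must be a percentage in [0, 100]")
        if not 0 <= self.relative_drop <= 1:
            raise ValueError("relative_drop must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


#: Default family effects: the pericentromeric HSATII family loses ~73% of its
#: wild-type methylation upon DNMT1/DNMT3B knockout while alpha-satellite
#: loses only ~9.8%.
DEFAULT_FAMILY_PARAMS: dict[str, FamilyParams] = {
    "HSat2": FamilyParams(mean_wt=70.0, relative_drop=0.73),
    "alpha_sat": FamilyParams(mean_wt=60.0, relative_drop=0.098),
}


def _beta_mean(rng: np.random.Generator, mean_pct: float, concentration: float, size: int):
    m = min(max(mean_pct / 100.0, 1e-6), 1 - 1e-6)
    return rng.beta(m * concentration, (1 - m) * concentration, size=size)


def simulate_methylation(
    family_params: Optional[dict[str, FamilyParams]] = None,
    n_sites: int = 5000,
    mean_coverage: float = 30.0,
    region_length: int = 1_000_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, RegionSet, dict]:
    """Paired WT/KO methylation tables with known family-level effects.

    ``n_sites`` CpG sites are split evenly across the families; each family
    occupies its own region on a synthetic chromosome (so family assignment
    by position lookup is exact).  Per site, a WT methylation level is drawn
    from a beta distribution around the family WT mean, the KO level is the
    WT level scaled by ``1 - relative_drop``, and methylated-call counts are
    binomial draws at Poisson coverage (minimum 1).

    Returns (wt table, ko table, regions, truth).  The truth record stores
    the realized per-family relative drops and their Monte-Carlo standard
    errors, computed from the simulated site-level means.
    """
    family_params = DEFAULT_FAMILY_PARAMS if family_params is None else family_params
    if not family_params:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)
    families = sorted(family_params)
    per_family = n_sites // len(families)

    regions = []
    wt_rows, ko_rows = [], []
    truth: dict = {"families": {}, "seed": seed}
    for fi, fam in enumerate(families):
        params = family_params[fam]
        start = fi * region_length
        end = start + region_length
        regions.append(Region("chrM", start, end, fam))
        pos = np.sort(rng.choice(np.arange(start, end), size=per_family, replace=False))
        wt_level = _beta_mean(rng, params.mean_wt, params.dispersion, per_family)
        ko_level = wt_level * (1.0 - params.relative_drop)
        cov_wt = np.maximum(rng.poisson(mean_coverage, per_family), 1)
        cov_ko = np.maximum(rng.poisson(mean_coverage, per_family), 1)
        meth_wt = rng.binomial(cov_wt, wt_level)
        meth_ko = rng.binomial(cov_ko, ko_level)
        for p, nv, nm in zip(pos, cov_wt, meth_wt):
            wt_rows.append(("chrM", int(p), int(nv), int(nm)))
        for p, nv, nm in zip(pos, cov_ko, meth_ko):
            ko_rows.append(("chrM", int(p), int(nv), int(nm)))
        realized_drop = 1.0 - ko_level.mean() / wt_level.mean()
        # SE of the relative drop via the delta method on the two means.
        se = (
            ko_level.std(ddof=1)
            / wt_level.mean()
            / np.sqrt(per_family)
        )
        truth["families"][fam] = {
            "mean_wt": params.mean_wt,
            "relative_drop": params.relative_drop,
            "realized_drop": float(realized_drop),
            "se_drop": float(se),
            "n_sites": per_family,
        }

    columns = ["chrom", "pos", "n_valid", "n_meth"]
    wt = pd.DataFrame(wt_rows, columns=columns)
    ko = pd.DataFrame(ko_rows, columns=columns)
    return wt, ko, RegionSet(regions), truth
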