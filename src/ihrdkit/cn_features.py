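"""Structural-genomic features from allele-specific copy-number segments.

The central quantity is the LOH score: the fraction of the assessable genome
covered by loss-of-heterozygosity events.  An LOH event is a maximal run of
segments with total copy number > 0 and minor-allele copy number 0 whose
combined LOH length strictly exceeds 15 Mb (homozygous deletions, total copy
number 0, do not qualify).  Chromosomes in which such events cover at least
75% of the chromosome's length are excluded from both numerator and
denominator — near-whole-chromosome LOH typically arises through mechanisms
other than defective homology-directed repair.

Runs are merged before the 15 Mb test: adjacent LOH segments, optionally
separated by short unassessed gaps (default bridge 3 Mb), form one event;
any intervening assessed non-LOH segment breaks the run.  Event length and
the numerator count LOH-segment bases only, never bridged gap bases.

Coordinates are 1-based inclusive, matching Sequenza segment output.  Sex
chromosomes are excluded by default (an all-male cohort renders chrX
hemizygosity spurious LOH).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .signatures import SignatureExposure

__all__ = [
    "CNSegment",
    "CNSegmentProfile",
    "GenomicFeatureVector",
    "FEATURE_NAMES",
    "loh_score",
    "mutation_burden",
    "extract_features",
    "HYPERMUTATION_MUT_PER_MB",
    "LOH_MIN_EVENT_BP",
    "LOH_CHROM_EXCLUSION_FRACTION",
    "DEFAULT_CALLABLE_MB",
]

#: tumors at or above this mutation rate are flagged hypermutated
HYPERMUTATION_MUT_PER_MB = 20.0
#: an LOH run must strictly exceed this length (bp) to count as an event
LOH_MIN_EVENT_BP = 15_000_000
#: chromosomes with LOH events covering at least this fraction are excluded
LOH_CHROM_EXCLUSION_FRACTION = 0.75
#: default callable exome footprint used for the mut/Mb denominator
DEFAULT_CALLABLE_MB = 30.0

_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "x", "y"}

FEATURE_NAMES = (
    "csig3_weight",
    "csig8_weight",
    "loh_score",
    "n_somatic_mutations",
    "ploidy",
    "n_segments",
)


@dataclass(frozen=True)
class CNSegment:
    """One allele-specific copy-number segment (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds major allele of total {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_loh(self) -> bool:
        return self.total_cn > 0 and self.minor_cn == 0


@dataclass
class CNSegmentProfile:
    """All segments for one tumor plus ploidy/cellularity and the genome frame."""

    sample_id: str
    segments: list[CNSegment]
    ploidy: float
    cellularity: float
    chromosome_lengths: Mapping[str, int]

    def __post_init__(self):
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if not 0 < self.cellularity <= 1:
            raise ValueError("cellularity must be in (0, 1]")
        by_chrom: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            if seg.chrom not in self.chromosome_lengths:
                raise ValueError(f"segment chromosome {seg.chrom!r} has no length entry")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segments_by_chrom(self) -> dict[str, list[CNSegment]]:
        out: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        for segs in out.values():
            segs.sort(key=lambda s: s.start)
        return out


def _loh_runs(segs: list[CNSegment], bridge_gap_bp: int) -> list[int]:
    """LOH-base totals of maximal runs on one (sorted) chromosome.

    A run extends across an unassessed gap of at most ``bridge_gap_bp``;
    an assessed non-LOH segment always terminates the run.
    """
    runs: list[int] = []
    run_bases = 0
    run_end = None  # end coordinate of the last LOH segment in the open run
    for seg in segs:
        if seg.is_loh:
            if run_end is not None and seg.start - run_end - 1 <= bridge_gap_bp:
                run_bases += seg.length
            else:
                if run_bases:
                    runs.append(run_bases)
                run_bases = seg.length
            run_end = seg.end
        else:
            if run_bases:
                runs.append(run_bases)
            run_bases = 0
            run_end = None
    if run_bases:
        runs.append(run_bases)
    return runs


def loh_score(
    profile: CNSegmentProfile,
    *,
    min_event_bp: int = LOH_MIN_EVENT_BP,
    chrom_exclusion_fraction: float = LOH_CHROM_EXCLUSION_FRACTION,
    bridge_gap_bp: int = 3_000_000,
    exclusion_basis: str = "assembly",
    include_sex_chromosomes: bool = False,
) -> float:
    """Fraction of the assessable genome covered by LOH events.

    Parameters
    ----------
    profile : CNSegmentProfile
    min_event_bp : int
        A merged LOH run qualifies as an event only when its LOH bases
        strictly exceed this length.
    chrom_exclusion_fraction : float
        Chromosomes whose event bases reach this fraction of the chromosome
        are dropped from numerator and denominator.
    bridge_gap_bp : int
        Maximum unassessed gap bridged when merging adjacent LOH segments.
    exclusion_basis : {"assembly", "assessable"}
        Denominator of the exclusion fraction: the assembly chromosome
        length (default; the rule speaks of the chromosome's entire length)
        or the chromosome's assessed bases.
    include_sex_chromosomes : bool
        Off by default; chrX/chrY segments are ignored.

    Raises
    ------
    ValueError
        If the profile holds no usable segments, or every chromosome is
        excluded (denominator zero).
    """
    if exclusion_basis not in ("assembly", "assessable"):
        raise ValueError("exclusion_basis must be 'assembly' or 'assessable'")
    by_chrom = profile.segments_by_chrom()
    if not include_sex_chromosomes:
        by_chrom = {c: s for c, s in by_chrom.items() if c not in _SEX_CHROMS}
    if not by_chrom:
        raise ValueError(f"profile {profile.sample_id} has no assessable segments")

    numerator = 0
    denominator = 0
    for chrom, segs in by_chrom.items():
        assessed = sum(s.length for s in segs)
        event_bases = sum(
            r for r in _loh_runs(segs, bridge_gap_bp) if r > min_event_bp
        )
        basis = (
            profile.chromosome_lengths[chrom]
            if exclusion_basis == "assembly"
            else assessed
        )
        if basis > 0 and event_bases / basis >= chrom_exclusion_fraction:
            continue  # near-whole-chromosome LOH: drop entirely
        numerator += event_bases
        denominator += assessed
    if denominator == 0:
        raise ValueError(
            f"profile {profile.sample_id}: no assessable bases remain after "
            "chromosome exclusions"
        )
    return numerator / denominator


def mutation_burden(
    n_snvs: int, callable_mb: float = DEFAULT_CALLABLE_MB
) -> tuple[float, bool]:
    """Mutations per megabase and the hypermutation flag (>= 20 mut/Mb)."""
    if n_snvs < 0:
        raise ValueError("n_snvs must be non-negative")
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    rate = n_snvs / callable_mb
    return rate, rate >= HYPERMUTATION_MUT_PER_MB


@dataclass(frozen=True)
class GenomicFeatureVector:
    """The six iHRD input features for one tumor (order: FEATURE_NAMES)."""

    sample_id: str
    csig3_weight: float
    csig8_weight: float
    loh_score: float
    n_somatic_mutations: int
    ploidy: float
    n_segments: int

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite feature for {self.sample_id}")
        if not 0 <= self.loh_score <= 1:
            raise ValueError("loh_score must lie in [0, 1]")
        if not 0 <= self.csig3_weight <= 1 or not 0 <= self.csig8_weight <= 1:
            raise ValueError("signature weights must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.csig3_weight,
            self.csig8_weight,
            self.loh_score,
            float(self.n_somatic_mutations),
            self.ploidy,
            float(self.n_segments),
        ])


def extract_features(
    exposure: SignatureExposure,
    profile: CNSegmentProfile,
    n_snvs: int | None = None,
    **loh_kwargs,
) -> GenomicFeatureVector:
    """Assemble the six iHRD features for one tumor.

    ``exposure`` and ``profile`` must describe the same sample.  ``n_snvs``
    defaults to the exposure's SNV count.
    """
    if exposure.sample_id != profile.sample_id:
        raise ValueError(
            f"sample mismatch: exposure {exposure.sample_id!r} vs "
            f"profile {profile.sample_id!r}"
        )
    return GenomicFeatureVector(
        sample_id=exposure.sample_id,
        csig3_weight=exposure.weight("CSig3"),
        csig8_weight=exposure.weight("CSig8"),
        loh_score=loh_score(profile, **loh_kwargs),
        n_somatic_mutations=int(exposure.n_snvs if n_snvs is None else n_snvs),
        ploidy=profile.ploidy,
        n_segments=profile.n_segments,
    )
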