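"""Seeded synthetic tumor cohorts with the statistical structure the
pipeline assumes.

Every tumor is drawn from one of five truth classes — biallelic core-gene
loss (``HRRd_BAL``), multiple monoallelic loss (``HRRd_MML``), cryptic HRR
deficiency without a core-gene event (``HRRd_cryptic``), HRR-``proficient``,
and ``hypermutated`` — and receives a mutation catalog (multinomial draw
from its true signature mixture), an allele-specific copy-number segment
profile realising a drawn LOH fraction, gene-alteration events consistent
with its class, panel-gene expression values, and a clinical outcome linked
to true HRRd status.

Default calibration
-------------------
The class-level defaults encode the group statistics the analysis is built
around: HRRd-class LOH scores average 0.133 (SD 0.07) against 0.116
(SD 0.06) for proficient tumors; CSig3-positive tumors average 5.94 mut/Mb
against 3.47 mut/Mb for negative tumors (hypermutated tumors, >= 20 mut/Mb,
excluded); and roughly 19.6% of a default cohort is called CSig3-positive
end-to-end.  Because the CSig3 call conditions on the *fitted* weight and an
attributed-count floor, the latent burden means that reproduce the called-
group averages differ slightly from the averages themselves; they were fixed
once by simulation (see docs/methods.md) and are frozen below.

Mutation counts are negative-binomial (NB2, variance mu + alpha*mu^2) with a
class-conditional dispersion alpha = 0.12 — cohort-level burden remains
overdispersed through the class mixture, while within-class spread stays
compatible with the attributed-count gate of the signature call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cn_features import CNSegment, CNSegmentProfile
from .cohort_stats import ClinicalOutcome
from .hrg_annotation import AlterationType, GeneAlterationEvent
from .signatures import SignatureMatrix, TrinucleotideCatalog, synthetic_signature_matrix

__all__ = [
    "HG19_AUTOSOMES",
    "ClassParams",
    "CohortConfig",
    "SyntheticTumor",
    "default_config",
    "generate_cohort",
    "generate_loh_profile",
    "TRUTH_CLASSES",
    "HRRD_CLASSES",
]

#: hg19 autosome assembly lengths (bp)
HG19_AUTOSOMES: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566,
}

TRUTH_CLASSES = ("HRRd_BAL", "HRRd_MML", "HRRd_cryptic", "proficient", "hypermutated")
HRRD_CLASSES = frozenset({"HRRd_BAL", "HRRd_MML", "HRRd_cryptic"})

# beta parameters with mean 0.133, SD 0.07 (HRRd) and mean 0.116, SD 0.06
_LOH_BETA_HRRD = (3.000, 19.543)
_LOH_BETA_PROFICIENT = (3.187, 24.288)
# CSig3 weight regime of HRRd tumors: mean 0.50, SD 0.08
_CSIG3_BETA_HRRD = (19.03, 19.03)


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one truth class."""

    csig3_beta: tuple[float, float] | None  # None -> true CSig3 weight 0
    mut_per_mb_mean: float
    nb_dispersion: float
    loh_beta: tuple[float, float]
    ploidy: tuple[float, float, float, float]  # mean, sd, lower, upper
    n_segments: tuple[float, float]  # mean, sd
    psa50_prob: float
    days_on_treatment_mean: float
    csig8_high_prob: float = 0.07  # chance of an elevated CSig8 component


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort design; identical config + seed reproduce a cohort exactly."""

    n_tumors: int = 418
    proportions: Mapping[str, float] = field(default_factory=lambda: {
        "HRRd_BAL": 0.139,
        "HRRd_MML": 0.056,
        "HRRd_cryptic": 0.077,
        "proficient": 0.680,
        "hypermutated": 0.048,
    })
    class_params: Mapping[str, ClassParams] = field(default_factory=dict)
    callable_mb: float = 30.0
    chrom_loh_cap: float = 0.70
    split_event_prob: float = 0.30
    treatment_probs: tuple[float, float, float] = (0.25, 0.15, 0.60)  # parpi, carbo, other
    signature_matrix: SignatureMatrix | None = None

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"class proportions must sum to 1 (got {total}): "
                f"{dict(self.proportions)}"
            )
        unknown = set(self.proportions) - set(TRUTH_CLASSES)
        if unknown:
            raise ValueError(f"unknown truth classes: {sorted(unknown)}")
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be positive")
        if not 0 < self.chrom_loh_cap < LOHCAP_MAX:
            raise ValueError(
                f"chrom_loh_cap must lie in (0, {LOHCAP_MAX}) to respect the "
                "whole-chromosome exclusion rule"
            )


LOHCAP_MAX = 0.75  # per-chromosome LOH above this triggers the exclusion rule


def _default_class_params() -> dict[str, ClassParams]:
    hrrd_common = dict(
        csig3_beta=_CSIG3_BETA_HRRD,
        nb_dispersion=0.12,
        loh_beta=_LOH_BETA_HRRD,
        ploidy=(2.6, 0.5, 1.5, 5.5),
        n_segments=(210.0, 40.0),
        psa50_prob=0.75,
        days_on_treatment_mean=440.0,
    )
    # Latent burden means, frozen after a one-off calibration run (see
    # docs/methods.md): chosen so the *pipeline-called* CSig3(+)/(-) group
    # means land on 5.94 / 3.47 mut/Mb under default conditions.
    return {
        "HRRd_BAL": ClassParams(mut_per_mb_mean=5.25, **hrrd_common),
        "HRRd_MML": ClassParams(mut_per_mb_mean=5.25, **hrrd_common),
        "HRRd_cryptic": ClassParams(mut_per_mb_mean=5.25, **hrrd_common),
        "proficient": ClassParams(
            csig3_beta=None,
            mut_per_mb_mean=3.42,
            nb_dispersion=0.12,
            loh_beta=_LOH_BETA_PROFICIENT,
            ploidy=(2.1, 0.4, 1.5, 5.5),
            n_segments=(140.0, 35.0),
            psa50_prob=0.12,
            days_on_treatment_mean=141.0,
        ),
        "hypermutated": ClassParams(
            csig3_beta=None,
            mut_per_mb_mean=35.0,
            nb_dispersion=0.30,
            loh_beta=_LOH_BETA_PROFICIENT,
            ploidy=(2.1, 0.4, 1.5, 5.5),
            n_segments=(150.0, 35.0),
            psa50_prob=0.12,
            days_on_treatment_mean=141.0,
        ),
    }


def default_config(**overrides) -> CohortConfig:
    """The default-calibrated cohort design (418 tumors)."""
    cfg = CohortConfig(class_params=_default_class_params())
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SyntheticTumor:
    """One simulated tumor with raw inputs for every pipeline stage."""

    sample_id: str
    truth_class: str
    true_weights: dict[str, float]
    target_loh: float
    mut_per_mb: float
    catalog: TrinucleotideCatalog
    profile: CNSegmentProfile
    events: list[GeneAlterationEvent]
    expression: dict[str, float]
    outcome: ClinicalOutcome

    @property
    def is_hrrd(self) -> bool:
        return self.truth_class in HRRD_CLASSES


# --------------------------------------------------------------- LOH profiles


_EVENT_STATES = ((1, 0), (2, 0))  # copy-loss LOH, copy-neutral LOH
_BACKGROUND_STATES = ((2, 1), (3, 1), (4, 2), (4, 1), (5, 2))
_BACKGROUND_PROBS = (0.55, 0.20, 0.10, 0.10, 0.05)
_MIN_EVENT_BP = 16_000_000  # strictly above the 15 Mb event threshold
_MAX_EVENT_BP = 80_000_000


def generate_loh_profile(
    sample_id: str,
    target_fraction: float,
    rng: np.random.Generator,
    genome: Mapping[str, int] | None = None,
    ploidy: float = 2.0,
    cellularity: float | None = None,
    n_segments_target: int | None = None,
    chrom_loh_cap: float = 0.70,
    split_event_prob: float = 0.30,
) -> CNSegmentProfile:
    """Construct a fully-assessed segment profile whose LOH score approximates
    ``target_fraction`` (within +/- 0.02; typically much closer).

    LOH events strictly longer than 15 Mb are placed on random autosomes,
    capped per chromosome below the whole-chromosome exclusion threshold so
    no chromosome is dropped by the scorer.  The rest of the genome is tiled
    with heterozygous segments.  Raises when the target is infeasible for
    the genome under the per-chromosome cap.
    """
    if not 0 <= target_fraction < 0.9:
        raise ValueError("target_fraction must lie in [0, 0.9)")
    if not 0 < chrom_loh_cap < LOHCAP_MAX:
        raise ValueError(f"chrom_loh_cap must lie in (0, {LOHCAP_MAX})")
    genome = dict(genome or HG19_AUTOSOMES)
    total = sum(genome.values())
    capacity = {c: int(chrom_loh_cap * n) for c, n in genome.items()}
    if target_fraction * total > sum(capacity.values()):
        raise ValueError(
            f"target LOH fraction {target_fraction} infeasible: exceeds the "
            f"per-chromosome cap of {chrom_loh_cap}"
        )

    # --- draw event lengths and assign them to chromosomes
    events_by_chrom: dict[str, list[int]] = {c: [] for c in genome}
    used = {c: 0 for c in genome}
    needed = target_fraction * total
    while needed > _MIN_EVENT_BP / 2:
        open_chroms = [c for c in genome if capacity[c] - used[c] >= _MIN_EVENT_BP]
        if not open_chroms:
            break
        chrom = open_chroms[rng.integers(len(open_chroms))]
        cap_left = capacity[chrom] - used[chrom]
        upper = min(cap_left, _MAX_EVENT_BP, max(int(needed), _MIN_EVENT_BP))
        length = int(rng.integers(_MIN_EVENT_BP, max(upper, _MIN_EVENT_BP) + 1))
        events_by_chrom[chrom].append(length)
        used[chrom] += length
        needed -= length

    n_events = sum(len(v) for v in events_by_chrom.values())
    n_background = max(
        (n_segments_target or 0) - n_events, len(genome)
    )

    # --- lay out each chromosome: alternating heterozygous gaps and events
    segments: list[CNSegment] = []
    # distribute background segment counts over chromosomes by length
    chroms = list(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    bg_counts = rng.multinomial(max(n_background, len(chroms)), weights / weights.sum())
    for chrom, n_bg in zip(chroms, bg_counts):
        length = genome[chrom]
        ev_lengths = events_by_chrom[chrom]
        free = length - sum(ev_lengths)
        n_gaps = len(ev_lengths) + 1
        n_pieces = max(int(n_bg), n_gaps)
        # split the free sequence into n_pieces, allocated across the gaps
        cuts = (np.sort(rng.uniform(1, free, size=n_pieces - 1).astype(np.int64))
                if n_pieces > 1 else np.array([], dtype=np.int64))
        piece_lengths = np.diff(np.concatenate([[0], cuts, [free]])).astype(int)
        # assign pieces to gap slots round-robin so every gap gets >= 1 piece
        gap_pieces: list[list[int]] = [[] for _ in range(n_gaps)]
        for i, piece in enumerate(piece_lengths):
            gap_pieces[i % n_gaps].append(int(piece))
        pos = 1
        for gi in range(n_gaps):
            for piece in gap_pieces[gi]:
                if piece <= 0:
                    continue
                total_cn, minor_cn = _BACKGROUND_STATES[
                    rng.choice(len(_BACKGROUND_STATES), p=_BACKGROUND_PROBS)
                ]
                segments.append(CNSegment(chrom, pos, pos + piece - 1, total_cn, minor_cn))
                pos += piece
            if gi < len(ev_lengths):
                ev_len = ev_lengths[gi]
                total_cn, minor_cn = _EVENT_STATES[int(rng.random() < 0.4)]
                if ev_len >= 2 * _MIN_EVENT_BP and rng.random() < split_event_prob:
                    # emit the event as adjacent sub-segments (scorer must merge)
                    cut = int(rng.integers(ev_len // 4, 3 * ev_len // 4))
                    other_cn = _EVENT_STATES[int(rng.random() < 0.5)][0]
                    segments.append(CNSegment(chrom, pos, pos + cut - 1, total_cn, minor_cn))
                    segments.append(CNSegment(chrom, pos + cut, pos + ev_len - 1, other_cn, 0))
                else:
                    segments.append(CNSegment(chrom, pos, pos + ev_len - 1, total_cn, minor_cn))
                pos += ev_len

    return CNSegmentProfile(
        sample_id=sample_id,
        segments=segments,
        ploidy=float(ploidy),
        cellularity=float(cellularity if cellularity is not None
                          else rng.uniform(0.3, 0.95)),
        chromosome_lengths=genome,
    )


# ---------------------------------------------------------------- gene events


_BAL_GENE_WEIGHTS = {
    "BRCA2": 0.60, "BRCA1": 0.08, "PALB2": 0.08, "RAD51C": 0.06,
    "RAD51": 0.04, "GEN1": 0.04, "BRIP1": 0.04, "RAD51B": 0.03,
    "RAD51D": 0.03,
}
_CORE_FOR_MML = ("BRCA2", "BRCA1", "RAD51B", "RAD51C", "PALB2", "BARD1", "BRIP1")
_EXPRESSION_GENES = (
    "BRCA1", "BRCA2", "PALB2", "RAD51B", "RAD51C", "RAD51D",
    "RAD54L2", "BARD1", "GEN1", "BRIP1", "RAD51", "CHD1", "CDK12", "ATM",
)
_GERMLINE_FRACTION_OF_BAL = 0.36


def _draw_events(sample_id: str, truth_class: str, rng: np.random.Generator
                 ) -> list[GeneAlterationEvent]:
    ev: list[tuple[str, AlterationType]] = []
    if truth_class == "HRRd_BAL":
        genes = list(_BAL_GENE_WEIGHTS)
        probs = np.array(list(_BAL_GENE_WEIGHTS.values()))
        gene = genes[rng.choice(len(genes), p=probs / probs.sum())]
        if rng.random() < _GERMLINE_FRACTION_OF_BAL:
            ev += [(gene, AlterationType.GERMLINE_PATHOGENIC), (gene, AlterationType.LOH)]
        else:
            pattern = rng.random()
            if pattern < 0.15:
                ev.append((gene, AlterationType.DEEP_DELETION))
            elif pattern < 0.75:
                ev += [(gene, AlterationType.SOMATIC_PATHOGENIC),
                       (gene, AlterationType.COPY_LOSS)]
            else:
                ev += [(gene, AlterationType.SOMATIC_PATHOGENIC),
                       (gene, AlterationType.SOMATIC_PATHOGENIC)]
    elif truth_class == "HRRd_MML":
        k = 2 + int(rng.random() < 0.3)
        for gene in rng.choice(_CORE_FOR_MML, size=k, replace=False):
            ev.append((str(gene), AlterationType.COPY_LOSS))
    elif truth_class == "HRRd_cryptic":
        # no core-gene event; CHD1 loss in a subset, otherwise genomically silent
        if rng.random() < 0.5:
            ev.append(("CHD1", AlterationType.COPY_LOSS))
            if rng.random() < 0.5:
                ev.append(("CHD1", AlterationType.LOH))
    elif truth_class == "proficient":
        r = rng.random()
        if r < 0.08:
            ev.append(("ATM", AlterationType.COPY_LOSS))
        elif r < 0.11:
            ev.append(("ATM", AlterationType.DEEP_DELETION))
        elif r < 0.13:
            ev.append(("CHEK2", AlterationType.DEEP_DELETION))
        elif r < 0.20:
            ev.append(("TP53", AlterationType.COPY_LOSS))
    elif truth_class == "hypermutated":
        for gene in ("MSH2", "MSH6"):
            if rng.random() < 0.5:
                ev.append((gene, AlterationType.SOMATIC_PATHOGENIC))
    return [GeneAlterationEvent(sample_id, g, e) for g, e in ev]


def _draw_expression(events: Sequence[GeneAlterationEvent],
                     rng: np.random.Generator) -> dict[str, float]:
    """log2 expression for the panel genes; copy loss shifts down ~1 unit,
    deep deletion ~2.5 units."""
    lost = {e.gene for e in events
            if e.event in (AlterationType.COPY_LOSS, AlterationType.LOH)}
    deleted = {e.gene for e in events if e.event is AlterationType.DEEP_DELETION}
    expr = {}
    for gene in _EXPRESSION_GENES:
        base = rng.normal(5.0, 0.6)
        if gene in deleted:
            base -= 2.5
        elif gene in lost:
            base -= 1.0
        expr[gene] = float(base)
    return expr


# --------------------------------------------------------------- full cohort


def _draw_signature_weights(params: ClassParams, sigs: SignatureMatrix,
                            rng: np.random.Generator) -> dict[str, float]:
    w3 = float(rng.beta(*params.csig3_beta)) if params.csig3_beta else 0.0
    if rng.random() < params.csig8_high_prob:
        w8 = float(rng.beta(5.0, 15.0))       # elevated, mean 0.25
    else:
        w8 = float(rng.beta(1.5, 40.0))       # background, mean ~0.036
    rest = max(1.0 - w3 - w8, 0.0)
    weights = {"CSig3": w3, "CSig8": w8}
    # aging signature takes most of the remainder; a couple of minor others
    others = [s for s in sigs.signature_ids if s not in ("CSig1", "CSig3", "CSig8")]
    share_csig1 = rng.beta(6.0, 2.0)
    weights["CSig1"] = rest * float(share_csig1)
    minor = rng.dirichlet(np.full(3, 1.0)) * rest * (1.0 - float(share_csig1))
    for name, value in zip(rng.choice(others, size=3, replace=False), minor):
        weights[str(name)] = float(value)
    return weights


def _draw_count(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    r = 1.0 / dispersion
    p = r / (r + mean)
    return max(int(rng.negative_binomial(r, p)), 1)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    class_override: str | None = None,
    n_tumors: int | None = None,
) -> list[SyntheticTumor]:
    """Draw a full synthetic cohort.

    ``class_override`` forces every tumor into one truth class (used for
    per-class calibration checks); ``n_tumors`` overrides the config size.
    Identical arguments always return an identical cohort.
    """
    config = config or default_config()
    params_map = dict(config.class_params) or _default_class_params()
    rng = np.random.default_rng(seed)
    sigs = config.signature_matrix or synthetic_signature_matrix()
    n = n_tumors or config.n_tumors

    classes = list(config.proportions)
    probs = np.array([config.proportions[c] for c in classes])
    tumors: list[SyntheticTumor] = []
    for i in range(n):
        truth = class_override or classes[rng.choice(len(classes), p=probs)]
        params = params_map[truth]
        sample_id = f"SYN-{i:04d}"

        # mutation catalog
        mean_count = params.mut_per_mb_mean * config.callable_mb
        n_snvs = _draw_count(mean_count, params.nb_dispersion, rng)
        if truth == "hypermutated":
            floor = int(20.0 * config.callable_mb)
            while n_snvs < floor:
                n_snvs = _draw_count(mean_count, params.nb_dispersion, rng)
        weights = _draw_signature_weights(params, sigs, rng)
        catalog = TrinucleotideCatalog(
            sample_id, rng.multinomial(n_snvs, sigs.mixture_profile(weights))
        )

        # copy-number profile
        target_loh = float(np.clip(rng.beta(*params.loh_beta), 0.0, 0.6))
        mu, sd, lo, hi = params.ploidy
        ploidy = float(np.clip(rng.normal(mu, sd), lo, hi))
        seg_mu, seg_sd = params.n_segments
        seg_target = max(int(rng.normal(seg_mu, seg_sd)), 30)
        profile = generate_loh_profile(
            sample_id, target_loh, rng,
            ploidy=ploidy, n_segments_target=seg_target,
            chrom_loh_cap=config.chrom_loh_cap,
            split_event_prob=config.split_event_prob,
        )

        # annotations, expression, outcome
        events = _draw_events(sample_id, truth, rng)
        expression = _draw_expression(events, rng)
        t = rng.choice(3, p=np.array(config.treatment_probs))
        treatment = ("parpi", "carboplatin", "other")[t]
        psa50 = (bool(rng.random() < params.psa50_prob)
                 if treatment == "carboplatin" else None)
        days = None
        if treatment == "parpi":
            shape = 2.2
            days = int(rng.gamma(shape, params.days_on_treatment_mean / shape))
        outcome = ClinicalOutcome(sample_id, treatment, psa50, days)

        tumors.append(SyntheticTumor(
            sample_id=sample_id,
            truth_class=truth,
            true_weights=weights,
            target_loh=target_loh,
            mut_per_mb=n_snvs / config.callable_mb,
            catalog=catalog,
            profile=profile,
            events=events,
            expression=expression,
            outcome=outcome,
        ))
    return tumors
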