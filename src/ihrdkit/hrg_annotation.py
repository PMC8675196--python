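"""Gene-level zygosity calls and tumor cohort grouping for HRR genes.

Per-gene alteration events (pathogenic mutations, copy loss, deep deletion,
LOH) are consumed as pre-curated annotations and collapsed into a zygosity
call per (tumor, gene): biallelic loss (BAL), monoallelic loss (MAL), or
intact.  Tumors are then assigned to mutually exclusive cohort groups by a
fixed precedence, the olaparib-panel biomarker status (O-HRGmut) is derived,
and an HRR-Reference comparator set — tumors with no alteration in any
HRR-associated gene and no confounders — is constructed for frequency
comparisons.

Zygosity rules
--------------
BAL: a deep (homozygous) deletion; or two or more pathogenic mutations
(germline and/or somatic); or one pathogenic mutation combined with copy
loss or LOH.  MAL: exactly one hit — a single pathogenic mutation or a
monoallelic copy loss with no second event.  LOH without a mutation does not
count as a hit (it may be copy-neutral).  Anything else is intact.

Group precedence (first match wins)
-----------------------------------
HRG-Germ (germline pathogenic mutation in a core HRR gene) > HRG-BAL
(somatic biallelic core-gene loss) > FANC-BAL (Fanconi-anemia gene biallelic
loss) > HRG-MML (monoallelic loss of two or more core genes) > HRG-MAL
(exactly one) > ATM/CHEK2 (biallelic ATM or CHEK2, no core-gene events) >
HRG-Intact.  The ordering is a design choice: core-gene events dominate
sensor-gene events, and germline carriers are labelled as carriers whether or
not a somatic second hit is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlterationType",
    "Zygosity",
    "CohortGroup",
    "GeneAlterationEvent",
    "GenePanels",
    "TumorAnnotation",
    "classify_gene_zygosity",
    "assign_group",
    "o_hrg_status",
    "annotate_tumor",
    "build_hrr_reference",
]


class AlterationType(str, Enum):
    GERMLINE_PATHOGENIC = "germline_pathogenic_mutation"
    SOMATIC_PATHOGENIC = "somatic_pathogenic_mutation"
    COPY_LOSS = "monoallelic_copy_loss"
    DEEP_DELETION = "homozygous_deletion"
    LOH = "loh"


class Zygosity(str, Enum):
    BAL = "BAL"
    MAL = "MAL"
    INTACT = "intact"


class CohortGroup(str, Enum):
    HRG_GERM = "HRG-Germ"
    HRG_BAL = "HRG-BAL"
    FANC_BAL = "FANC-BAL"
    HRG_MML = "HRG-MML"
    HRG_MAL = "HRG-MAL"
    ATM_CHEK2 = "ATM-CHEK2"
    HRG_INTACT = "HRG-Intact"


@dataclass(frozen=True)
class GeneAlterationEvent:
    sample_id: str
    gene: str
    event: AlterationType

    def __post_init__(self):
        object.__setattr__(self, "event", AlterationType(self.event))


_CORE_HRG = (
    "BRCA1", "BRCA2", "RAD51", "RAD51B", "RAD51C", "RAD51D",
    "RAD54L2", "BARD1", "GEN1", "PALB2", "BRIP1",
)
_FANCONI = (
    "FANCA", "FANCB", "FANCC", "FANCD2", "FANCE", "FANCF",
    "FANCG", "FANCI", "FANCL", "FANCM",
)
_SENSORS = ("ATM", "ATR", "CHEK2", "MRE11", "RAD50", "NBN")
_OLAPARIB = (
    "ATM", "BRCA1", "BRCA2", "BARD1", "BRIP1", "CDK12", "CHEK1",
    "CHEK2", "FANCL", "PALB2", "RAD51B", "RAD51C", "RAD51D", "RAD54L",
)
_NHEJ = ("PRKDC", "XRCC4", "XRCC5", "XRCC6", "LIG4", "NHEJ1")
_OTHER_INTEREST = ("CHD1", "SPOP", "CDK12", "RNASEH2B", "TP53", "XRCC2") + _NHEJ


@dataclass(frozen=True)
class GenePanels:
    """Gene panels driving grouping, biomarker status and the HRR-Reference.

    Panels may overlap (the olaparib panel shares genes with the core list).
    ``nhej`` defaults to the canonical NHEJ factors; the published analysis
    names the gene class without enumerating it.
    """

    core_hrg: tuple[str, ...] = _CORE_HRG
    fanconi: tuple[str, ...] = _FANCONI
    sensors: tuple[str, ...] = _SENSORS
    olaparib_panel: tuple[str, ...] = _OLAPARIB
    other_interest: tuple[str, ...] = _OTHER_INTEREST
    nhej: tuple[str, ...] = _NHEJ

    def __post_init__(self):
        for name in ("core_hrg", "fanconi", "sensors", "olaparib_panel",
                     "other_interest", "nhej"):
            if not getattr(self, name):
                raise ValueError(f"panel {name!r} must be non-empty")

    @property
    def hrr_associated(self) -> frozenset[str]:
        """Union of all panels with an established HRR association."""
        return frozenset(
            self.core_hrg + self.fanconi + self.sensors + self.other_interest
        )


def classify_gene_zygosity(events: Iterable[AlterationType | str]) -> Zygosity:
    """Collapse one (sample, gene)'s events into a BAL/MAL/intact call."""
    events = [AlterationType(e) for e in events]
    n_mut = sum(
        e in (AlterationType.GERMLINE_PATHOGENIC, AlterationType.SOMATIC_PATHOGENIC)
        for e in events
    )
    has_loss = AlterationType.COPY_LOSS in events
    has_loh = AlterationType.LOH in events
    if AlterationType.DEEP_DELETION in events:
        return Zygosity.BAL
    if n_mut >= 2:
        return Zygosity.BAL
    if n_mut >= 1 and (has_loss or has_loh):
        return Zygosity.BAL
    if n_mut == 1 or has_loss:
        return Zygosity.MAL
    return Zygosity.INTACT


def assign_group(
    zygosity: Mapping[str, Zygosity],
    germline_genes: Iterable[str],
    panels: GenePanels | None = None,
) -> CohortGroup:
    """Assign one tumor to a cohort group by the documented precedence."""
    panels = panels or GenePanels()
    germline = set(germline_genes)
    core = set(panels.core_hrg)

    if germline & core:
        return CohortGroup.HRG_GERM
    core_zyg = {g: z for g, z in zygosity.items() if g in core}
    if any(z == Zygosity.BAL for z in core_zyg.values()):
        return CohortGroup.HRG_BAL
    if any(
        zygosity.get(g) == Zygosity.BAL for g in panels.fanconi
    ):
        return CohortGroup.FANC_BAL
    n_core_mal = sum(z == Zygosity.MAL for z in core_zyg.values())
    if n_core_mal >= 2:
        return CohortGroup.HRG_MML
    if n_core_mal == 1:
        return CohortGroup.HRG_MAL
    if zygosity.get("ATM") == Zygosity.BAL or zygosity.get("CHEK2") == Zygosity.BAL:
        return CohortGroup.ATM_CHEK2
    return CohortGroup.HRG_INTACT


def o_hrg_status(
    zygosity: Mapping[str, Zygosity],
    germline_genes: Iterable[str],
    panels: GenePanels | None = None,
) -> bool:
    """Olaparib-panel biomarker: biallelic loss or a germline pathogenic
    mutation in any of the 14 approved genes."""
    panels = panels or GenePanels()
    germline = set(germline_genes)
    return any(
        zygosity.get(g) == Zygosity.BAL or g in germline
        for g in panels.olaparib_panel
    )


@dataclass
class TumorAnnotation:
    """Per-tumor gene zygosity, group label and biomarker statuses."""

    sample_id: str
    zygosity: dict[str, Zygosity]
    germline_genes: frozenset[str]
    event_genes: frozenset[str]
    group: CohortGroup
    o_hrg_positive: bool
    hypermutated: bool = False
    in_hrr_reference: bool = False
    csig3_positive: bool | None = None
    ihrd_positive: bool | None = None


def annotate_tumor(
    sample_id: str,
    events: Sequence[GeneAlterationEvent],
    hypermutated: bool = False,
    panels: GenePanels | None = None,
) -> TumorAnnotation:
    """Compute zygosity per gene and derive group / O-HRGmut for one tumor."""
    panels = panels or GenePanels()
    by_gene: dict[str, list[AlterationType]] = {}
    germline: set[str] = set()
    for ev in events:
        if ev.sample_id != sample_id:
            raise ValueError(
                f"event sample {ev.sample_id!r} does not match {sample_id!r}"
            )
        by_gene.setdefault(ev.gene, []).append(ev.event)
        if ev.event is AlterationType.GERMLINE_PATHOGENIC:
            germline.add(ev.gene)
    zygosity = {g: classify_gene_zygosity(evs) for g, evs in by_gene.items()}
    return TumorAnnotation(
        sample_id=sample_id,
        zygosity=zygosity,
        germline_genes=frozenset(germline),
        event_genes=frozenset(by_gene),
        group=assign_group(zygosity, germline, panels),
        o_hrg_positive=o_hrg_status(zygosity, germline, panels),
        hypermutated=hypermutated,
    )


def build_hrr_reference(
    annotations: Sequence[TumorAnnotation],
    panels: GenePanels | None = None,
) -> set[str]:
    """Select the HRR-Reference comparator tumors.

    Criteria: no alteration event of any kind (including LOH-only records) in
    any HRR-associated gene (core, Fanconi, sensor, or other-interest
    panels), not hypermutated, no XRCC2 loss and no NHEJ-gene alteration.
    The ``in_hrr_reference`` flag is set in place on every annotation.
    """
    panels = panels or GenePanels()
    excluded_genes = panels.hrr_associated | set(panels.nhej) | {"XRCC2"}
    reference: set[str] = set()
    for ann in annotations:
        clean = not ann.hypermutated and not (ann.event_genes & excluded_genes)
        ann.in_hrr_reference = clean
        if clean:
            reference.add(ann.sample_id)
    return reference
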