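"""End-to-end orchestration: catalogs + segments + annotations -> per-tumor
report and cohort summary.

This is the in-memory engine behind the command-line interface; it consumes
objects, never files, so synthetic and file-loaded cohorts run identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cn_features import (
    CNSegmentProfile,
    extract_features,
    loh_score,
    mutation_burden,
)
from .hrg_annotation import (
    GeneAlterationEvent,
    GenePanels,
    annotate_tumor,
    build_hrr_reference,
)
from .ihrd import IHRDClassifier, TrainingSpec, features_to_matrix, train_ihrd
from .signatures import SignatureMatrix, TrinucleotideCatalog, fit_signatures

__all__ = ["classify_cohort", "train_from_cohort", "CohortReport"]


@dataclass
class CohortReport:
    """Per-tumor table plus the feature vectors and annotations behind it."""

    table: pd.DataFrame
    features: list
    annotations: list

    def summary(self) -> dict:
        t = self.table
        out = {
            "n_tumors": int(len(t)),
            "csig3_positive": int(t["csig3_positive"].sum()),
            "hypermutated": int(t["hypermutated"].sum()),
            "group_counts": t["group"].value_counts().to_dict(),
        }
        if "ihrd_positive" in t:
            out["ihrd_positive"] = int(t["ihrd_positive"].sum())
        if "o_hrg_positive" in t:
            out["o_hrg_positive"] = int(t["o_hrg_positive"].sum())
        return out


def classify_cohort(
    catalogs: Sequence[TrinucleotideCatalog],
    profiles: Sequence[CNSegmentProfile],
    sigs: SignatureMatrix,
    events: Mapping[str, Sequence[GeneAlterationEvent]] | None = None,
    classifier: IHRDClassifier | None = None,
    weight_cutoff: float = 0.06,
    callable_mb: float = 30.0,
    panels: GenePanels | None = None,
) -> CohortReport:
    """Run signature fitting, structural features, annotation and (optionally)
    iHRD prediction over a cohort.  Catalogs and profiles are matched by
    sample id; a missing profile is an error."""
    profile_by_id = {p.sample_id: p for p in profiles}
    missing = [c.sample_id for c in catalogs if c.sample_id not in profile_by_id]
    if missing:
        raise ValueError(f"no segment profile for samples: {missing[:5]}")

    rows = []
    features = []
    annotations = []
    for catalog in catalogs:
        profile = profile_by_id[catalog.sample_id]
        exposure = fit_signatures(catalog, sigs, weight_cutoff=weight_cutoff)
        fv = extract_features(exposure, profile)
        mut_mb, hyper = mutation_burden(catalog.n_snvs, callable_mb)
        ann = annotate_tumor(
            catalog.sample_id,
            list(events.get(catalog.sample_id, [])) if events else [],
            hypermutated=hyper,
            panels=panels,
        )
        ann.csig3_positive = exposure.csig3_positive
        features.append(fv)
        annotations.append(ann)
        rows.append({
            "sample_id": catalog.sample_id,
            "group": ann.group.value,
            "csig3_weight": fv.csig3_weight,
            "csig3_positive": exposure.csig3_positive,
            "csig8_weight": fv.csig8_weight,
            "csig8_positive": exposure.csig8_positive,
            "loh_score": fv.loh_score,
            "n_snvs": catalog.n_snvs,
            "mut_per_mb": mut_mb,
            "hypermutated": hyper,
            "ploidy": fv.ploidy,
            "n_segments": fv.n_segments,
            "o_hrg_positive": ann.o_hrg_positive,
        })
    build_hrr_reference(annotations, panels)
    table = pd.DataFrame(rows)
    table["in_hrr_reference"] = [a.in_hrr_reference for a in annotations]

    if classifier is not None:
        X, ids = features_to_matrix(features)
        decision = classifier.decision_function(X)
        positive = decision > classifier.decision_threshold_
        table["ihrd_decision_value"] = decision
        table["ihrd_positive"] = positive
        for ann, flag in zip(annotations, positive):
            ann.ihrd_positive = bool(flag)
    return CohortReport(table=table, features=features, annotations=annotations)


def train_from_cohort(
    report: CohortReport,
    cv_folds: int = 5,
    seed: int | None = None,
) -> "TrainedClassifier":
    """Train the iHRD model on a classified cohort using the canonical
    design: biallelic core-gene tumors against HRR-Reference tumors."""
    from .hrg_annotation import CohortGroup
    from .ihrd import DEFAULT_SEED, TrainedClassifier  # noqa: F401

    positives = [
        a.sample_id for a in report.annotations
        if a.group in (CohortGroup.HRG_BAL, CohortGroup.HRG_GERM)
    ]
    negatives = [a.sample_id for a in report.annotations if a.in_hrr_reference]
    spec = TrainingSpec(
        positive_ids=tuple(positives),
        negative_ids=tuple(negatives),
        cv_folds=cv_folds,
        seed=DEFAULT_SEED if seed is None else seed,
    )
    return train_ihrd(report.features, spec)
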