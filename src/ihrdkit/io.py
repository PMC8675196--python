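"""Plain-text I/O for every pipeline input and output format.

All tables are tab-separated.  Segment files follow the Sequenza column
convention (``chromosome  start.pos  end.pos  CNt  A  B``) with a leading
``sample_id`` column so one file can carry a cohort; ploidy/cellularity live
in a companion summary table.  Catalogs and signature matrices are 96-row
tables keyed by context in the canonical ordering.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .cn_features import CNSegment, CNSegmentProfile
from .cohort_stats import ClinicalOutcome
from .contexts import CONTEXTS_96
from .hrg_annotation import GeneAlterationEvent
from .signatures import SignatureMatrix, TrinucleotideCatalog

__all__ = [
    "read_signature_matrix", "write_signature_matrix",
    "read_catalogs", "write_catalogs",
    "read_snv_table", "write_snv_table", "read_snv_vcf",
    "read_segment_table", "write_segment_table",
    "read_sample_summary", "write_sample_summary",
    "read_chromosome_lengths", "write_chromosome_lengths",
    "read_gene_events", "write_gene_events",
    "read_expression", "write_expression",
    "read_clinical", "write_clinical",
    "write_cohort", "load_cohort_inputs",
]


def _check_context_order(index: Sequence[str], what: str) -> None:
    if list(index) != list(CONTEXTS_96):
        raise ValueError(
            f"{what} must list the 96 contexts in canonical order "
            f"(C>A..T>G blocks, 5' then 3' base alphabetical)"
        )


# ------------------------------------------------------------- signatures


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_context_order(df.index, "signature matrix")
    return SignatureMatrix(tuple(df.columns), df.to_numpy(dtype=float))


def write_signature_matrix(sigs: SignatureMatrix, path: str | Path) -> None:
    pd.DataFrame(
        sigs.profiles, index=pd.Index(CONTEXTS_96, name="context"),
        columns=list(sigs.signature_ids),
    ).to_csv(path, sep="\t", float_format="%.8g")


# --------------------------------------------------------------- catalogs


def read_catalogs(path: str | Path) -> list[TrinucleotideCatalog]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_context_order(df.index, "catalog table")
    return [TrinucleotideCatalog(str(c), df[c].to_numpy(dtype=float))
            for c in df.columns]


def write_catalogs(catalogs: Sequence[TrinucleotideCatalog], path: str | Path) -> None:
    pd.DataFrame(
        {c.sample_id: c.counts.astype(int) for c in catalogs},
        index=pd.Index(CONTEXTS_96, name="context"),
    ).to_csv(path, sep="\t")


# ------------------------------------------------------------------- SNVs


def read_snv_table(path: str | Path) -> dict[str, list[tuple]]:
    """MAF-like TSV (sample_id, chrom, pos, ref, alt[, context]) grouped by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, list[tuple]] = {}
    has_context = "context" in df.columns
    for row in df.itertuples(index=False):
        rec = (row.chrom, int(row.pos), row.ref, row.alt)
        if has_context:
            rec = rec + (row.context,)
        out.setdefault(str(row.sample_id), []).append(rec)
    return out


def write_snv_table(snvs_by_sample: Mapping[str, Sequence[tuple]],
                    path: str | Path) -> None:
    rows = []
    for sample_id, records in snvs_by_sample.items():
        for rec in records:
            chrom, pos, ref, alt = rec[:4]
            context = rec[4] if len(rec) > 4 else ""
            rows.append((sample_id, chrom, pos, ref, alt, context))
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "context"]
    ).to_csv(path, sep="\t", index=False)


def read_snv_vcf(
    path: str | Path,
    context_source: Callable[[str, int], str] | None = None,
) -> list[tuple]:
    """SNV records from a standard VCF (non-SNVs are skipped).

    Requires pysam (install the ``vcf`` extra).  Returns ``(chrom, pos, ref,
    alt, context-or-None)`` tuples ready for catalog building.
    """
    import pysam  # optional dependency

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue
                tri = context_source(rec.chrom, rec.pos) if context_source else None
                records.append((rec.chrom, rec.pos, rec.ref, alt, tri))
    return records


# --------------------------------------------------------------- segments


def write_segment_table(profiles: Sequence[CNSegmentProfile], path: str | Path) -> None:
    rows = [
        (p.sample_id, s.chrom, s.start, s.end, s.total_cn,
         s.total_cn - s.minor_cn, s.minor_cn)
        for p in profiles for s in p.segments
    ]
    pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "start.pos", "end.pos", "CNt", "A", "B"],
    ).to_csv(path, sep="\t", index=False)


def read_segment_table(
    path: str | Path,
    summary: pd.DataFrame | None = None,
    chromosome_lengths: Mapping[str, int] | None = None,
) -> list[CNSegmentProfile]:
    """Sequenza-style segments plus a per-sample ploidy/cellularity summary."""
    from .synthetic_data import HG19_AUTOSOMES

    lengths = dict(chromosome_lengths or HG19_AUTOSOMES)
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if summary is not None:
        summary = summary.set_index("sample_id") if "sample_id" in summary else summary
    profiles = []
    for sample_id, group in df.groupby("sample_id", sort=True):
        segments = [
            CNSegment(str(r.chromosome), int(getattr(r, "_2")), int(getattr(r, "_3")),
                      int(r.CNt), int(r.B))
            for r in group.itertuples(index=False)
        ]
        ploidy, cellularity = 2.0, 1.0
        if summary is not None and sample_id in summary.index:
            ploidy = float(summary.loc[sample_id, "ploidy"])
            cellularity = float(summary.loc[sample_id, "cellularity"])
        profiles.append(CNSegmentProfile(
            str(sample_id), segments, ploidy, cellularity, lengths
        ))
    return profiles


def write_sample_summary(profiles: Sequence[CNSegmentProfile], path: str | Path) -> None:
    pd.DataFrame(
        [(p.sample_id, p.ploidy, p.cellularity) for p in profiles],
        columns=["sample_id", "ploidy", "cellularity"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_chromosome_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(lengths.items()), columns=["chromosome", "length"]
    ).to_csv(path, sep="\t", index=False)


def read_chromosome_lengths(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return dict(zip(df["chromosome"], df["length"].astype(int)))


# ------------------------------------------------------------- annotations


def write_gene_events(events: Sequence[GeneAlterationEvent], path: str | Path) -> None:
    pd.DataFrame(
        [(e.sample_id, e.gene, e.event.value) for e in events],
        columns=["sample_id", "gene", "event"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_events(path: str | Path) -> dict[str, list[GeneAlterationEvent]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[GeneAlterationEvent]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.sample_id), []).append(
            GeneAlterationEvent(str(r.sample_id), str(r.gene), r.event)
        )
    return out


def write_expression(expression: Mapping[str, Mapping[str, float]],
                     path: str | Path) -> None:
    """``expression[sample][gene]`` -> genes x samples TSV of log2 values."""
    pd.DataFrame(expression).rename_axis("gene").to_csv(
        path, sep="\t", float_format="%.5g"
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical(outcomes: Sequence[ClinicalOutcome], path: str | Path) -> None:
    pd.DataFrame(
        [(o.sample_id, o.treatment,
          "" if o.psa50_response is None else int(o.psa50_response),
          "" if o.days_on_treatment is None else o.days_on_treatment)
         for o in outcomes],
        columns=["sample_id", "treatment", "psa50_response", "days_on_treatment"],
    ).to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> list[ClinicalOutcome]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        psa = None if pd.isna(r.psa50_response) else bool(int(r.psa50_response))
        days = None if pd.isna(r.days_on_treatment) else int(r.days_on_treatment)
        out.append(ClinicalOutcome(str(r.sample_id), str(r.treatment), psa, days))
    return out


# ------------------------------------------------------------ whole cohorts


def write_cohort(tumors, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort in every pipeline input format plus a truth
    table; returns the path of each written file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalogs": outdir / "catalogs.tsv",
        "segments": outdir / "segments.tsv",
        "summary": outdir / "sample_summary.tsv",
        "chromosomes": outdir / "chromosome_lengths.tsv",
        "events": outdir / "gene_events.tsv",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_catalogs([t.catalog for t in tumors], paths["catalogs"])
    write_segment_table([t.profile for t in tumors], paths["segments"])
    write_sample_summary([t.profile for t in tumors], paths["summary"])
    write_chromosome_lengths(tumors[0].profile.chromosome_lengths,
                             paths["chromosomes"])
    write_gene_events([e for t in tumors for e in t.events], paths["events"])
    write_expression({t.sample_id: t.expression for t in tumors},
                     paths["expression"])
    write_clinical([t.outcome for t in tumors], paths["clinical"])
    pd.DataFrame(
        [(t.sample_id, t.truth_class, t.true_weights.get("CSig3", 0.0),
          t.target_loh, t.mut_per_mb) for t in tumors],
        columns=["sample_id", "truth_class", "true_csig3_weight",
                 "target_loh", "mut_per_mb"],
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def load_cohort_inputs(indir: str | Path) -> dict:
    """Load a directory written by :func:`write_cohort`."""
    indir = Path(indir)
    lengths = read_chromosome_lengths(indir / "chromosome_lengths.tsv")
    return {
        "catalogs": read_catalogs(indir / "catalogs.tsv"),
        "profiles": read_segment_table(
            indir / "segments.tsv",
            summary=read_sample_summary(indir / "sample_summary.tsv"),
            chromosome_lengths=lengths,
        ),
        "events": read_gene_events(indir / "gene_events.tsv"),
        "expression": read_expression(indir / "expression.tsv"),
        "clinical": read_clinical(indir / "clinical.tsv"),
    }
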