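"""Readers and writers for all pipeline inputs and outputs.

Supported inputs: annotated variant TSV (ANNOVAR-output style), minimal
multi-sample VCF 4.x (read via pysam; per-sample AD preferred, DP+AF
fallback), sample-sheet CSV, catalog TSV (chrom pos ref alt) and
transcript/domain YAML configs.  Outputs are TSV and JSON only, with
deterministic column order; every writer round-trips through its reader.
"""
from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pysam
import yaml

from .annotate import TranscriptModel
from .model import (
    Catalog,
    CnvLohEvent,
    DataValidationError,
    DEFAULT_GENE_REGIONS,
    FunctionalClass,
    GENE_CHROMOSOMES,
    SampleMeta,
    Tissue,
    VariantKey,
    VariantObservation,
    Zygosity,
    parse_functional_class,
)
from .scan import CohortSummary
from .zygosity import FrequencyTable, GROUP_ORDER

logger = logging.getLogger(__name__)

VARIANT_TABLE_COLUMNS = [
    "sample_id", "chromosome", "position", "ref", "alt", "gene",
    "functional_class", "exon", "ref_reads", "var_reads", "novel", "zygosity",
]

EVENT_COLUMNS = [
    "patient_id", "sample_id", "gene", "label", "start", "end",
    "n_variants", "contains_novel",
]


def _resolve_gene(chromosome: str, position: int) -> Optional[str]:
    for gene, (chrom, start, end) in DEFAULT_GENE_REGIONS.items():
        if chromosome == chrom and start <= position <= end:
            return gene
    return None


def _resolve_chromosome(gene: str) -> Optional[str]:
    return GENE_CHROMOSOMES.get(gene)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def read_variant_table(
    path: Union[str, Path], dialect: str = "annovar_tsv"
) -> tuple[list[VariantObservation], list[SampleMeta]]:
    """Read per-sample variant observations.

    Returns the observations plus stub SampleMeta records (one per distinct
    sample id; tissue/pairing come from the sample sheet, not from here).
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"variant table not found: {path}")
    if dialect == "annovar_tsv":
        observations = _read_annovar_tsv(path)
    elif dialect == "vcf":
        observations = _read_vcf(path)
    else:
        raise DataValidationError(f"unknown dialect {dialect!r} (expected vcf or annovar_tsv)")
    sample_ids = sorted({o.sample_id for o in observations})
    stubs = [SampleMeta(sample_id=sid, patient_id=sid) for sid in sample_ids]
    return observations, stubs


def _read_annovar_tsv(path: Path) -> list[VariantObservation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    aliases = {
        "sample": "sample_id", "chr": "chromosome", "chrom": "chromosome",
        "pos": "position", "start": "position", "ref_allele": "ref",
        "alt_allele": "alt", "var": "alt", "func": "functional_class",
        "type": "functional_class",
    }
    df = df.rename(columns=aliases)
    required = ["sample_id", "position", "ref", "alt", "ref_reads", "var_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing mandatory column(s) {missing}")

    observations: list[VariantObservation] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        record = dict(zip(df.columns, row))
        try:
            position = int(record["position"])
            gene = record.get("gene", "").strip()
            chromosome = record.get("chromosome", "").strip()
            if not chromosome:
                chromosome = _resolve_chromosome(gene) or ""
            if not chromosome:
                raise DataValidationError(f"cannot map chromosome for gene {gene!r}")
            if not gene:
                gene = _resolve_gene(chromosome, position) or ""
            if not gene:
                raise DataValidationError("record has no resolvable gene")
            func = record.get("functional_class", "").strip()
            exon = record.get("exon", "").strip()
            novel = record.get("novel", "").strip()
            zyg = record.get("zygosity", "").strip()
            observations.append(
                VariantObservation(
                    key=VariantKey(chromosome, position, record["ref"].strip(), record["alt"].strip()),
                    sample_id=record["sample_id"].strip(),
                    gene=gene,
                    ref_reads=int(record["ref_reads"]),
                    var_reads=int(record["var_reads"]),
                    functional_class=parse_functional_class(func) if func else None,
                    exon=int(exon) if exon else None,
                    novel={"true": True, "1": True, "false": False, "0": False}.get(novel.lower())
                    if novel else None,
                    zygosity=Zygosity(zyg) if zyg else None,
                )
            )
        except (ValueError, DataValidationError) as exc:
            errors.append(f"{path}:{line_no}: {exc}")
    if errors:
        raise DataValidationError("malformed rows:\n" + "\n".join(errors))
    return observations


def _read_vcf(path: Path) -> list[VariantObservation]:
    observations: list[VariantObservation] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            chromosome = rec.chrom if str(rec.chrom).startswith("chr") else f"chr{rec.chrom}"
            gene = rec.info.get("GENE") if "GENE" in rec.info else None
            if isinstance(gene, tuple):
                gene = gene[0]
            if gene is None:
                gene = _resolve_gene(chromosome, rec.pos)
            if gene is None:
                raise DataValidationError(
                    f"{path}: no resolvable gene at {chromosome}:{rec.pos}"
                )
            alts = rec.alts or ()
            for sample_name, call in rec.samples.items():
                ad = call.get("AD")
                for alt_idx, alt in enumerate(alts):
                    if ad is not None and ad[0] is not None:
                        ref_reads, var_reads = int(ad[0]), int(ad[alt_idx + 1])
                    else:
                        dp, af = call.get("DP"), call.get("AF")
                        if dp is None or af is None:
                            raise DataValidationError(
                                f"{path}: sample {sample_name} at {chromosome}:{rec.pos} "
                                "has neither AD nor DP+AF"
                            )
                        if isinstance(af, tuple):
                            af = af[alt_idx]
                        var_reads = int(round(float(dp) * float(af)))
                        ref_reads = int(dp) - var_reads
                        logger.warning(
                            "inferred read counts from DP and AF for %s at %s:%d",
                            sample_name, chromosome, rec.pos,
                        )
                    if var_reads <= 0:
                        continue  # sample does not carry this alt allele
                    observations.append(
                        VariantObservation(
                            key=VariantKey(chromosome, rec.pos, rec.ref, str(alt)),
                            sample_id=sample_name,
                            gene=str(gene),
                            ref_reads=ref_reads,
                            var_reads=var_reads,
                        )
                    )
    return observations


def write_variant_table(
    observations: Sequence[VariantObservation], path: Union[str, Path]
) -> None:
    """Write observations as the canonical annovar_tsv dialect."""
    rows = []
    for o in observations:
        rows.append({
            "sample_id": o.sample_id,
            "chromosome": o.key.chromosome,
            "position": o.key.position,
            "ref": o.key.ref,
            "alt": o.key.alt,
            "gene": o.gene,
            "functional_class": o.functional_class.value if o.functional_class else "",
            "exon": o.exon if o.exon is not None else "",
            "ref_reads": o.ref_reads,
            "var_reads": o.var_reads,
            "novel": "" if o.novel is None else str(o.novel).lower(),
            "zygosity": o.zygosity.value if o.zygosity else "",
        })
    pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: Union[str, Path]) -> list[SampleMeta]:
    """Read the sample sheet CSV (sample_id, patient_id, tissue,
    paired_sample_id, stage); applies the trailing-"N" pairing heuristic
    when no explicit pairing column is filled in."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise DataValidationError(f"{path}: missing mandatory column 'sample_id'")
    samples = []
    for i, record in enumerate(df.to_dict("records")):
        line_no = i + 2
        tissue_raw = record.get("tissue", "").strip().lower().replace(" ", "_")
        try:
            tissue = Tissue(tissue_raw) if tissue_raw else None
        except ValueError:
            raise DataValidationError(f"{path}:{line_no}: unknown tissue {tissue_raw!r}")
        samples.append(
            SampleMeta(
                sample_id=record["sample_id"].strip(),
                patient_id=record.get("patient_id", "").strip() or record["sample_id"].strip(),
                tissue=tissue,
                paired_sample_id=record.get("paired_sample_id", "").strip() or None,
                stage=record.get("stage", "").strip() or None,
            )
        )
    return resolve_pairs(samples)


def resolve_pairs(samples: list[SampleMeta]) -> list[SampleMeta]:
    """Fill in missing pairing from the trailing-"N" naming convention
    (tumor CC1018 <-> normal CC1018N); explicit pairing wins."""
    by_id = {s.sample_id: s for s in samples}
    for s in samples:
        if s.paired_sample_id is not None or s.tissue != Tissue.NORMAL:
            continue
        if s.sample_id.endswith("N"):
            candidate = s.sample_id[:-1]
            other = by_id.get(candidate)
            if other is not None and other.is_lesion and other.paired_sample_id is None \
                    and other.patient_id == s.patient_id:
                s.paired_sample_id = candidate
                other.paired_sample_id = s.sample_id
                logger.info(
                    "paired %s with %s via trailing-N naming heuristic",
                    s.sample_id, candidate,
                )
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: Union[str, Path]) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "tissue": s.tissue.value if s.tissue else "",
            "paired_sample_id": s.paired_sample_id or "",
            "stage": s.stage or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue", "paired_sample_id", "stage"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# catalogs and transcripts
# ---------------------------------------------------------------------------

def read_catalog(path: Union[str, Path], name: str = "catalog") -> Catalog:
    """Read a catalog TSV with columns chrom, pos, ref, alt."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"catalog not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns={"chromosome": "chrom", "position": "pos"})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing catalog column {col!r}")
    entries = frozenset(
        VariantKey(r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
    )
    return Catalog(name=name, entries=entries)


def write_catalog(catalog: Catalog, path: Union[str, Path]) -> None:
    rows = sorted(
        ({"chrom": k.chromosome, "pos": k.position, "ref": k.ref, "alt": k.alt}
         for k in catalog.entries),
        key=lambda r: (r["chrom"], r["pos"], r["ref"], r["alt"]),
    )
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(path, sep="\t", index=False)


def load_transcripts(path: Union[str, Path]) -> dict[str, TranscriptModel]:
    """Read transcript models from YAML/JSON: {gene: {strand, ref_start,
    reference, cds: [[start, end], ...], span: [start, end]}}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for gene, spec in raw.items():
        out[gene] = TranscriptModel(
            gene=gene,
            strand=spec["strand"],
            cds_intervals=tuple((int(s), int(e)) for s, e in spec["cds"]),
            reference=spec["reference"],
            ref_start=int(spec["ref_start"]),
            span=tuple(spec["span"]) if "span" in spec else None,
        )
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(obj, path: Union[str, Path], format: str = "tsv") -> None:
    """Write an analysis object (event list, FrequencyTable, CohortSummary
    or plain dict) to TSV or JSON with deterministic layout."""
    if format not in {"tsv", "json"}:
        raise DataValidationError(f"unknown report format {format!r}")
    path = Path(path)
    if isinstance(obj, FrequencyTable):
        if format == "tsv":
            _write_frequency_tsv(obj, path)
        else:
            payload = {
                "group_sizes": {g.value: n for g, n in obj.group_sizes.items()},
                "rows": obj.df.to_dict("records"),
            }
            path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return
    if isinstance(obj, CohortSummary):
        path.write_text(json.dumps(obj.to_dict(), indent=2) + "\n")
        return
    if isinstance(obj, dict):
        path.write_text(json.dumps(obj, indent=2, default=str) + "\n")
        return
    # sequence of events (possibly empty)
    events = list(obj)
    if all(isinstance(e, CnvLohEvent) for e in events):
        rows = [
            {
                "patient_id": e.patient_id,
                "sample_id": e.sample_id,
                "gene": e.gene,
                "label": e.label.value,
                "start": e.start,
                "end": e.end,
                "n_variants": e.n_variants,
                "contains_novel": str(e.contains_novel).lower(),
            }
            for e in events
        ]
        df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        if format == "tsv":
            df.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(json.dumps(rows, indent=2) + "\n")
        return
    raise DataValidationError(f"do not know how to report a {type(obj).__name__}")


def read_events(path: Union[str, Path]) -> pd.DataFrame:
    """Events come back as a DataFrame (the run members are not persisted)."""
    return pd.read_csv(path, sep="\t")


def _write_frequency_tsv(table: FrequencyTable, path: Path) -> None:
    df = table.df.copy()
    header_sizes = {f"{z}_{g.value}": table.group_sizes.get(g, 0)
                    for g in GROUP_ORDER for z in ("het", "hom")}
    renames = {col: f"{col} ({n})" for col, n in header_sizes.items() if col in df.columns}
    df = df.rename(columns=renames)
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path: Union[str, Path]) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t")
    group_sizes: dict[Tissue, int] = {}
    renames = {}
    for col in df.columns:
        if col.startswith(("het_", "hom_")) and "(" in col:
            base, size = col.rsplit(" (", 1)
            renames[col] = base
            group = Tissue(base.split("_", 1)[1])
            group_sizes[group] = int(size.rstrip(")"))
    df = df.rename(columns=renames)
    if "novel" in df.columns:
        df["novel"] = df["novel"].astype(bool)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return FrequencyTable(df=df, group_sizes=group_sizes)
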