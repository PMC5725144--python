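"""End-to-end pipeline: (simulate) -> annotate -> frequency table -> CNV/LOH
scan -> domain mapping -> combined report.

Every stage writes its outputs to disk, and those outputs are sufficient to
re-run any downstream stage in isolation; the combined ``report.json``
echoes all parameters (seed, tau, k, thresholds) for provenance.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as asio
from .annotate import annotate_consequences, annotate_novelty, depth_filter, DEFAULT_MIN_READS
from .domains import DEFAULT_DOMAIN_MODELS, ProteinVariant, genomic_to_protein, load_domain_config, tally_domains
from .model import DataValidationError, FunctionalClass, ScanParams, ZygosityThresholds
from .scan import scan_cohort
from .simulate import SimConfig, simulate_catalog, simulate_cohort
from .zygosity import annotate_zygosity, build_frequency_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path
    variants: Optional[Path] = None
    dialect: str = "annovar_tsv"
    sample_sheet: Optional[Path] = None
    catalogs: dict[str, Path] = field(default_factory=dict)
    transcripts: Optional[Path] = None
    domains: Optional[Path] = None
    min_reads: int = DEFAULT_MIN_READS
    scan_params: ScanParams = field(default_factory=ScanParams)
    thresholds: ZygosityThresholds = field(default_factory=ZygosityThresholds)
    sim: Optional[SimConfig] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _p(key):
            return (base / raw[key]).resolve() if key in raw and raw[key] else None

        scan_raw = raw.get("scan", {})
        thr_raw = raw.get("zygosity", {})
        sim = SimConfig(**raw["simulate"]) if "simulate" in raw else None
        return cls(
            outdir=(base / raw.get("outdir", "out")).resolve(),
            variants=_p("variants"),
            dialect=raw.get("dialect", "annovar_tsv"),
            sample_sheet=_p("sample_sheet"),
            catalogs={name: (base / p).resolve() for name, p in raw.get("catalogs", {}).items()},
            transcripts=_p("transcripts"),
            domains=_p("domains"),
            min_reads=int(raw.get("min_reads", DEFAULT_MIN_READS)),
            scan_params=ScanParams(**scan_raw),
            thresholds=ZygosityThresholds(**thr_raw),
            sim=sim,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages in order; returns the combined report
    (also written to <outdir>/report.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            "min_reads": config.min_reads,
            "tau": config.scan_params.tau,
            "k": config.scan_params.k,
            "symmetric": config.scan_params.symmetric,
            "max_vaf": config.scan_params.max_vaf,
            "het_low": config.thresholds.het_low,
            "hom_low": config.thresholds.hom_low,
            "seed": config.sim.seed if config.sim else None,
        }
    }

    # -- simulate ----------------------------------------------------------
    catalogs = []
    if config.sim is not None:
        try:
            observations, samples, truth = simulate_cohort(config.sim)
            asio.write_variant_table(observations, out / "variants.tsv")
            asio.write_sample_sheet(samples, out / "samples.csv")
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            catalog = simulate_catalog(config.sim)
            asio.write_catalog(catalog, out / "catalog.tsv")
            catalogs.append(catalog)
        except Exception as exc:
            raise StageError("simulate", exc) from exc
    else:
        try:
            if config.variants is None or config.sample_sheet is None:
                missing = "variants" if config.variants is None else "sample_sheet"
                raise DataValidationError(f"config missing required input path: {missing}")
            for p in [config.variants, config.sample_sheet, *config.catalogs.values()]:
                if not Path(p).exists():
                    raise DataValidationError(f"input path does not exist: {p}")
            observations, _ = asio.read_variant_table(config.variants, config.dialect)
            samples = asio.read_sample_sheet(config.sample_sheet)
            catalogs = [asio.read_catalog(p, name) for name, p in config.catalogs.items()]
        except StageError:
            raise
        except Exception as exc:
            raise StageError("load", exc) from exc

    # -- annotate ----------------------------------------------------------
    try:
        n_raw = len(observations)
        observations = depth_filter(observations, config.min_reads)
        if catalogs:
            annotate_novelty(observations, catalogs)
        transcripts = asio.load_transcripts(config.transcripts) if config.transcripts else {}
        if transcripts:
            annotate_consequences(observations, transcripts)
        annotate_zygosity(observations, config.thresholds)
        asio.write_variant_table(observations, out / "annotated.tsv")
        by_class: dict[str, int] = {}
        for o in observations:
            label = (o.functional_class or FunctionalClass.OTHER).value
            by_class[label] = by_class.get(label, 0) + 1
        report["variants"] = {
            "n_input": n_raw,
            "n_after_depth_filter": len(observations),
            "n_novel": sum(1 for o in observations if o.novel),
            "n_known": sum(1 for o in observations if o.novel is False),
            "by_class": dict(sorted(by_class.items())),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # -- frequency table ---------------------------------------------------
    try:
        table = build_frequency_table(observations, samples, config.thresholds)
        asio.write_report(table, out / "frequency_table.tsv", "tsv")
        report["frequency_table"] = {"n_rows": len(table)}
    except Exception as exc:
        raise StageError("freq-table", exc) from exc

    # -- CNV/LOH scan ------------------------------------------------------
    try:
        events, summary = scan_cohort(observations, samples, config.scan_params, config.thresholds)
        asio.write_report(events, out / "events.tsv", "tsv")
        asio.write_report(summary, out / "cnv_loh_summary.json", "json")
        report["cnv_loh"] = summary.to_dict()
    except Exception as exc:
        raise StageError("scan-cnv", exc) from exc

    # -- domain mapping ----------------------------------------------------
    if config.transcripts:
        try:
            transcripts = asio.load_transcripts(config.transcripts)
            models = load_domain_config(config.domains) if config.domains else DEFAULT_DOMAIN_MODELS
            tallies: dict[str, dict[str, int]] = {}
            rows = []
            for gene, tx in sorted(transcripts.items()):
                if gene not in models:
                    continue
                pvs = []
                for o in observations:
                    if o.gene != gene:
                        continue
                    aa = genomic_to_protein(o.key, tx)
                    if aa is None:
                        continue
                    pv = ProteinVariant(o.key, gene, aa, o.functional_class)
                    pvs.append(pv)
                    rows.append({
                        "gene": gene,
                        "chromosome": o.key.chromosome,
                        "position": o.key.position,
                        "ref": o.key.ref,
                        "alt": o.key.alt,
                        "protein_position": aa,
                        "domain": None,  # filled below
                    })
                tally = tally_domains(pvs, models[gene])
                tallies[gene] = {k: v for k, v in tally.items() if v}
                from .domains import map_to_domain
                for row, pv in zip(rows[-len(pvs):], pvs):
                    row["domain"] = map_to_domain(pv, models[gene])
            import pandas as pd
            pd.DataFrame(
                rows,
                columns=["gene", "chromosome", "position", "ref", "alt", "protein_position", "domain"],
            ).to_csv(out / "domain_map.tsv", sep="\t", index=False)
            report["domain_tallies"] = tallies
        except Exception as exc:
            raise StageError("map-domains", exc) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
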