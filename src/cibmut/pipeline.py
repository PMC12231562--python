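"""End-to-end orchestration: filter → classify → microhomology → impact →
SV → summarize, with report emission and a self-check against the embedded
reference tables."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import reference_tables as ref
from .errors import ConfigurationError
from .genomic_io import read_gene_models, read_genome, read_variant_table, normalize_indel
from .impact_annotate import DEFAULT_FLANK, annotate_all, impact_proportions
from .microhomology import MHConfig, classify_dependency, signatures_to_table
from .mutation_classify import DEFAULT_COMPLEX_WINDOW, classify_events, events_to_table
from .spectrum_stats import (
    LineMeta,
    frequency_table,
    mutation_frequency,
    per_plant_summary,
    tss_profile,
)
from .sv_analysis import read_sv_table, summarize_svs, sv_size, sv_table
from .variant_filter import FilterConfig, filter_variants

logger = logging.getLogger(__name__)


def read_line_metadata(path: str | Path) -> list[LineMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "genotype": str})
    required = {"line_id", "genotype", "dose"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"{path}: line metadata needs columns {sorted(required)}"
        )
    return [
        LineMeta(
            r.line_id, r.genotype, float(r.dose),
            getattr(r, "generation", "M2"),
        )
        for r in df.itertuples()
    ]


@dataclass
class PipelineConfig:
    genome_fasta: Path
    gff3: Path
    vcf: Path
    line_metadata: Path
    out_dir: Path
    sv_calls: Path | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    mh_config: MHConfig = field(default_factory=MHConfig)
    impact_flank: int = DEFAULT_FLANK
    complex_window: int = DEFAULT_COMPLEX_WINDOW
    genome_length_override: int | None = None
    report_precision: int = 2
    seed: int = 0


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle.

    Outputs (all TSV unless noted): retained/removed calls, classified
    events, microhomology signatures, impact annotations and tier summary,
    SV summary, the frequency table, the per-genotype spectrum table, the
    TSS profile, and a JSON run log with stage counts and parameters.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"parameters": _params_dict(cfg), "stages": {}}

    genome = read_genome(cfg.genome_fasta)
    models = read_gene_models(cfg.gff3)
    lines = read_line_metadata(cfg.line_metadata)
    genotype_of_line = {m.line_id: m.genotype for m in lines}
    genome_length = cfg.genome_length_override or genome.total_length

    calls = read_variant_table(cfg.vcf)
    log["stages"]["input_calls"] = len(calls)

    calls = [normalize_indel(c, genome) for c in calls]
    retained, removed = filter_variants(
        calls, [m.line_id for m in lines], cfg.filter_config
    )
    log["stages"]["retained"] = len(retained)
    log["stages"]["removed"] = len(removed)
    pd.DataFrame(
        [
            {"contig": c.contig, "pos": c.pos, "ref": c.ref_allele,
             "alt": c.alt_allele, "line_id": c.line_id, "reason": reason}
            for c, reason in removed
        ]
    ).to_csv(out / "removed_calls.tsv", sep="\t", index=False)

    events = classify_events(retained, window=cfg.complex_window)
    log["stages"]["events"] = len(events)
    events_to_table(events).to_csv(out / "events.tsv", sep="\t", index=False)

    indel_events = [e for e in events if e.is_indel]
    signatures = [
        classify_dependency(e, genome, cfg.mh_config) for e in indel_events
    ]
    signatures_to_table(indel_events, signatures).to_csv(
        out / "microhomology.tsv", sep="\t", index=False
    )

    annotations = annotate_all(events, models, genome, cfg.impact_flank)
    pd.DataFrame(
        [
            {"line_id": a.event.line_id, "contig": a.event.contig,
             "start": a.event.start, "category": a.event.category,
             "gene_id": a.gene_id or ".", "subclass": a.subclass,
             "tier": a.tier}
            for a in annotations
        ]
    ).to_csv(out / "impact.tsv", sep="\t", index=False)
    impact_proportions(annotations, genotype_of_line).to_csv(
        out / "impact_summary.tsv", sep="\t", index=False
    )

    summaries = per_plant_summary(events, lines, genome_length)
    frequency_table(summaries, cfg.report_precision).to_csv(
        out / "frequency_table.tsv", sep="\t", index=False
    )
    _spectrum_table(summaries).to_csv(
        out / "spectrum_summary.tsv", sep="\t", index=False
    )
    tss_profile(annotations, models, genotype_of_line).to_csv(
        out / "tss_profile.tsv", sep="\t"
    )

    if cfg.sv_calls is not None:
        svs = read_sv_table(cfg.sv_calls)
        summarize_svs(svs, genotype_of_line).to_csv(
            out / "sv_summary.tsv", sep="\t", index=False
        )
        sv_table(svs, genotype_of_line).to_csv(
            out / "sv_table.tsv", sep="\t", index=False
        )
        log["stages"]["svs"] = len(svs)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return {p.stem: p for p in out.glob("*.tsv")} | {"run_log": out / "run_log.json"}


def _params_dict(cfg: PipelineConfig) -> dict:
    def conv(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return dataclasses.asdict(v)
        if isinstance(v, Path):
            return str(v)
        return v

    return {f.name: conv(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}


def _spectrum_table(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries.values():
        row = {
            "genotype": s.genotype, "n_lines": s.n_lines, "dose": s.dose,
            "total_events": sum(s.counts.values()),
            "ts_tv": round(s.ts_tv, 3) if s.ts_tv == s.ts_tv else "",
            "ins_dels": round(s.ins_dels, 3) if s.ins_dels == s.ins_dels else "",
            "sbs_indel": round(s.sbs_indel, 3) if s.sbs_indel == s.sbs_indel else "",
        }
        for c, v in s.proportion_mean.items():
            row[f"prop_{c}"] = round(v, 4) if v == v else ""
        rows.append(row)
    return pd.DataFrame(rows)


def verify_reference_tables() -> pd.DataFrame:
    """Recompute every derived cell of the embedded reference tables.

    Checks: (1) the three total mutation frequencies from the printed
    counts, line numbers and doses; (2) end − start against the printed
    size for all SV rows.  Returns a per-cell pass/fail report.
    """
    rows = []
    for geno, (total, n_lines, dose) in ref.MUTATION_TOTALS.items():
        computed = mutation_frequency(
            total, n_lines, ref.REFERENCE_GENOME_LENGTH, dose
        ) * 1e10
        printed = ref.PRINTED_TOTAL_FREQUENCY[geno]
        ndec = len(str(printed).split(".")[1])
        rows.append(
            {
                "table": "frequency", "cell": f"{geno}/total",
                "printed": printed, "computed": round(computed, ndec),
                "pass": round(computed, ndec) == printed,
            }
        )
    for group, sample, chrom, start, end, svtype, printed_size in ref.SV_TABLE_ROWS:
        rec = next(
            r for r in ref.sv_records()
            if (r.line_id, r.contig, r.start) == (sample, chrom, start)
        )
        rows.append(
            {
                "table": "sv", "cell": f"{sample}@{chrom}:{start}",
                "printed": printed_size, "computed": sv_size(rec),
                "pass": sv_size(rec) == printed_size,
            }
        )
    return pd.DataFrame(rows)
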