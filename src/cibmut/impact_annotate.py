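"""Lightweight variant-effect annotation with four impact tiers.

Each mutation event is assigned one functional subclass by overlap with the
gene models, then a fixed severity tier:

* HIGH — frameshift, stop_gained, stop_lost, start_lost, splice_donor,
  splice_acceptor
* MODERATE — missense, inframe_indel, utr5, utr3
* LOW — synonymous, intron
* MODIFIER — upstream, downstream, intergenic

Note the tier map places UTR variants in MODERATE and intron variants in
LOW; this is the tiering used throughout the reports here, deliberately
different from stock variant-effect-predictor defaults.

Severity resolution: when an event touches several features or genes, the
most severe subclass wins; a complex event takes the most severe subclass
among its member calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .errors import ReferenceMismatchError
from .genomic_io import GeneModel, Genome, VariantCall
from .mutation_classify import MutationEvent

TIER_OF = {
    "frameshift": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_donor": "HIGH",
    "splice_acceptor": "HIGH",
    "missense": "MODERATE",
    "inframe_indel": "MODERATE",
    "utr5": "MODERATE",
    "utr3": "MODERATE",
    "synonymous": "LOW",
    "intron": "LOW",
    "upstream": "MODIFIER",
    "downstream": "MODIFIER",
    "intergenic": "MODIFIER",
}

TIERS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

# most severe first; index = severity rank
_SEVERITY_ORDER = (
    "frameshift", "stop_gained", "stop_lost", "start_lost",
    "splice_donor", "splice_acceptor", "missense", "inframe_indel",
    "utr5", "utr3", "synonymous", "intron", "upstream", "downstream",
    "intergenic",
)
_RANK = {s: i for i, s in enumerate(_SEVERITY_ORDER)}

DEFAULT_FLANK = 5000
SPLICE_SITE_SIZE = 2  # first/last bases of an intron


@dataclass
class ImpactAnnotation:
    event: MutationEvent
    gene_id: str | None
    subclass: str
    tier: str


def _complement(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _cds_positions(model: GeneModel) -> list[int]:
    """Genomic positions of coding bases in translation order (5'->3' of
    the mRNA)."""
    pos: list[int] = []
    for s, e, _ in model.cds:
        span = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
        pos.extend(span)
    return pos


def _splice_sites(model: GeneModel) -> tuple[set[int], set[int]]:
    """(donor positions, acceptor positions): the first/last two bases of
    each intron, in transcription order."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    exons = list(model.exons)  # already transcription-ordered
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if model.strand == "+":
            intron = (e1 + 1, s2 - 1)
            if intron[1] >= intron[0]:
                donors.update(range(intron[0], min(intron[0] + SPLICE_SITE_SIZE, intron[1] + 1)))
                acceptors.update(range(max(intron[1] - SPLICE_SITE_SIZE + 1, intron[0]), intron[1] + 1))
        else:
            intron = (e2 + 1, s1 - 1)
            if intron[1] >= intron[0]:
                donors.update(range(max(intron[1] - SPLICE_SITE_SIZE + 1, intron[0]), intron[1] + 1))
                acceptors.update(range(intron[0], min(intron[0] + SPLICE_SITE_SIZE, intron[1] + 1)))
    return donors, acceptors


def _sbs_coding_subclass(
    call: VariantCall, model: GeneModel, genome: Genome
) -> str:
    """Translate the affected codon (standard genetic code) for a CDS SBS."""
    cds_pos = _cds_positions(model)
    idx = cds_pos.index(call.pos)
    codon_i = idx // 3
    codon_pos = cds_pos[codon_i * 3 : codon_i * 3 + 3]
    if len(codon_pos) < 3:  # trailing partial codon in a malformed model
        return "synonymous"

    def base_at(p: int, substitute: bool) -> str:
        b = genome.fetch(call.contig, p, p)
        if substitute and p == call.pos:
            b = call.alt_allele
        return b if model.strand == "+" else _complement(b)

    ref_codon = "".join(base_at(p, False) for p in codon_pos)
    alt_codon = "".join(base_at(p, True) for p in codon_pos)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def _call_subclass_for_gene(
    call: VariantCall, model: GeneModel, genome: Genome, flank: int
) -> str | None:
    """Subclass of one call against one gene model, or None if out of range."""
    lo, hi = call.pos, call.end
    g_lo, g_hi = model.gene_start, model.gene_end

    if hi < g_lo - flank or lo > g_hi + flank:
        return None
    if hi < g_lo or lo > g_hi:  # flanking region
        before = hi < g_lo
        if model.strand == "+":
            return "upstream" if before else "downstream"
        return "downstream" if before else "upstream"

    donors, acceptors = _splice_sites(model)
    footprint = set(range(lo, hi + 1))
    if footprint & donors:
        return "splice_donor"
    if footprint & acceptors:
        return "splice_acceptor"

    cds_set = set()
    for s, e, _ in model.cds:
        cds_set.update(range(s, e + 1))
    in_cds = bool(footprint & cds_set)
    # a deletion's footprint includes the anchor base; test the changed bases
    if call.indel_len < 0:
        changed = set(range(call.pos + len(call.alt_allele), call.end + 1))
        in_cds = bool(changed & cds_set)
    if in_cds:
        if call.is_sbs:
            return _sbs_coding_subclass(call, model, genome)
        return "frameshift" if abs(call.indel_len) % 3 else "inframe_indel"

    exon_set = set()
    for s, e in model.exons:
        exon_set.update(range(s, e + 1))
    if footprint & exon_set:  # exonic, non-coding -> UTR
        if not cds_set:
            return "intron"  # non-coding gene: treat as LOW-impact genic
        cds_min, cds_max = min(cds_set), max(cds_set)
        mid = (lo + hi) / 2
        if model.strand == "+":
            return "utr5" if mid < cds_min else "utr3"
        return "utr5" if mid > cds_max else "utr3"
    return "intron"


def annotate_impact(
    event: MutationEvent,
    models: list[GeneModel],
    genome: Genome,
    flank: int = DEFAULT_FLANK,
) -> ImpactAnnotation:
    """Annotate one event: most severe subclass over all member calls and
    all gene models within range, then the fixed tier map."""
    for call in event.members:
        observed = genome.fetch(call.contig, call.pos, call.end)
        if observed != call.ref_allele:
            raise ReferenceMismatchError(
                f"{call.contig}:{call.pos} REF {call.ref_allele!r} vs "
                f"genome {observed!r}"
            )
    best: tuple[int, str, str | None] | None = None
    for model in models:
        if model.contig != event.contig:
            continue
        for call in event.members:
            sub = _call_subclass_for_gene(call, model, genome, flank)
            if sub is None:
                continue
            cand = (_RANK[sub], sub, model.gene_id)
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        return ImpactAnnotation(event, None, "intergenic", "MODIFIER")
    _, subclass, gene_id = best
    return ImpactAnnotation(event, gene_id, subclass, TIER_OF[subclass])


def annotate_all(
    events: list[MutationEvent],
    models: list[GeneModel],
    genome: Genome,
    flank: int = DEFAULT_FLANK,
) -> list[ImpactAnnotation]:
    return [annotate_impact(e, models, genome, flank) for e in events]


def impact_proportions(
    annotations: list[ImpactAnnotation],
    genotype_of_line: dict[str, str],
) -> pd.DataFrame:
    """Per-genotype mean tier proportions with per-plant averaging.

    Proportions of the four tiers are computed per line first, then averaged
    across the lines of a genotype (each sequenced plant contributes equally
    regardless of its mutation count).  Also reports the mean number of
    frameshift events per plant.
    """
    rows = []
    by_line: dict[str, list[ImpactAnnotation]] = {}
    for a in annotations:
        by_line.setdefault(a.event.line_id, []).append(a)
    for line_id, anns in by_line.items():
        n = len(anns)
        row = {"line_id": line_id, "genotype": genotype_of_line[line_id]}
        for tier in TIERS:
            row[tier] = sum(a.tier == tier for a in anns) / n
        row["frameshift_count"] = sum(a.subclass == "frameshift" for a in anns)
        rows.append(row)
    per_line = pd.DataFrame(rows)
    if per_line.empty:
        return per_line
    agg = per_line.groupby("genotype").agg(
        n_lines=("line_id", "count"),
        **{tier: (tier, "mean") for tier in TIERS},
        frameshift_per_plant=("frameshift_count", "mean"),
    )
    return agg.reset_index()


def subclass_counts(annotations: list[ImpactAnnotation]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "genotype_line": [a.event.line_id for a in annotations],
            "subclass": [a.subclass for a in annotations],
            "tier": [a.tier for a in annotations],
        }
    )
    return (
        df.groupby(["subclass", "tier"]).size().rename("count").reset_index()
    )
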