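"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Externally everything is 1-based inclusive (the VCF/GFF3 dialect); internal
arithmetic converts to 0-based offsets only inside function bodies, never in
the stored records.  ``VariantCall.pos`` is the 1-based position of the first
REF base, as in VCF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import FormatError, ReferenceMismatchError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig, uppercased, alphabet {A,C,G,T,N}."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"contig {self.contig_name!r} contains non-nucleotide "
                f"characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


class Genome:
    """A set of contigs with unique names; behaves like a read-only mapping."""

    def __init__(self, contigs: Iterable[GenomeSequence]):
        self._contigs: dict[str, GenomeSequence] = {}
        for c in contigs:
            if c.contig_name in self._contigs:
                raise FormatError(f"duplicate contig name {c.contig_name!r}")
            self._contigs[c.contig_name] = c

    def __getitem__(self, name: str) -> GenomeSequence:
        return self._contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self):
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self._contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice, truncated at contig bounds."""
        seq = self._contigs[contig].sequence
        return seq[max(0, start - 1) : min(len(seq), end)]


@dataclass(frozen=True)
class GeneModel:
    """A gene with a single retained isoform.

    All coordinates 1-based inclusive.  ``exons`` are sorted by transcription
    order (5'→3' of the mRNA); ``cds`` intervals carry the frame phase of
    their first base.  The TSS is the first transcribed base: ``gene_start``
    on the + strand, ``gene_end`` on the − strand.
    """

    gene_id: str
    contig: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        spans = sorted((s, e) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
        for s, e, _ in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValidationError(
                    f"{self.gene_id}: CDS {s}-{e} not contained in any exon"
                )

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end


@dataclass(frozen=True)
class VariantCall:
    """One raw small-variant call at a locus, owned by one sequenced line.

    ``af_by_line`` maps every genotyped line to the fraction of reads
    supporting the variant allele; an absent line means fraction 0.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    line_id: str
    af_by_line: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.contig}:{self.pos} ref equals alt ({self.ref_allele})"
            )
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for line, af in self.af_by_line.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(
                    f"{self.contig}:{self.pos} af for {line} outside [0,1]: {af}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity used for sharing checks across lines."""
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)

    @property
    def is_sbs(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def indel_len(self) -> int:
        """Signed length change (negative for deletions, 0 for balanced)."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference footprint."""
        return self.pos + len(self.ref_allele) - 1


def read_genome(path: str | Path) -> Genome:
    """Read a (multi-contig) FASTA into a :class:`Genome`, uppercasing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no sequences found, returning empty genome")
    return Genome(records)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in genome:
            fh.write(f">{contig.contig_name}\n")
            for i in range(0, contig.length, width):
                fh.write(contig.sequence[i : i + width] + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file (via gffutils).

    One :class:`GeneModel` per gene; when a gene carries several mRNA
    isoforms the first in file order defines the exon/CDS structure and the
    choice is logged.  CDS intervals outside every exon raise
    :class:`ValidationError`.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        isoforms = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not isoforms:
            continue
        if len(isoforms) > 1:
            logger.info(
                "gene %s has %d isoforms; keeping first (%s)",
                gene.id, len(isoforms), isoforms[0].id,
            )
        mrna = isoforms[0]
        exon_raw = sorted(
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon")
        )
        cds_raw = sorted(
            (f.start, f.end, int(f.frame) if str(f.frame).isdigit() else 0)
            for f in db.children(mrna, featuretype="CDS")
        )
        if gene.strand == "-":
            exon_raw = exon_raw[::-1]
            cds_raw = cds_raw[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                gene_start=gene.start,
                gene_end=gene.end,
                exons=tuple(exon_raw),
                cds=tuple(cds_raw),
            )
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS GFF3 for the retained isoform of each gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = (m.contig, "cibmut")
            fh.write(
                "\t".join(map(str, (*base, "gene", m.gene_start, m.gene_end,
                                    ".", m.strand, ".", f"ID={m.gene_id}"))) + "\n"
            )
            mid = f"{m.gene_id}.1"
            fh.write(
                "\t".join(map(str, (*base, "mRNA", m.gene_start, m.gene_end,
                                    ".", m.strand, ".",
                                    f"ID={mid};Parent={m.gene_id}"))) + "\n"
            )
            for s, e in m.exons:
                fh.write(
                    "\t".join(map(str, (*base, "exon", s, e, ".", m.strand,
                                        ".", f"Parent={mid}"))) + "\n"
                )
            for s, e, ph in m.cds:
                fh.write(
                    "\t".join(map(str, (*base, "CDS", s, e, ".", m.strand,
                                        ph, f"Parent={mid}"))) + "\n"
                )


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_TAB_COLUMNS = ("contig", "pos", "ref", "alt", "line_id", "af")


def _af_from_sample(sample, alt_i: int) -> float | None:
    """Variant-supporting read fraction of ALT allele ``alt_i`` (0-based)
    from a VCF per-sample record.

    Accepts an AD field (ref,alt,... depths; the fraction is the allele's
    depth over the total), an alt-only AD with VarScan-style RD for the
    reference depth, or a FREQ percentage; any per-line fraction in [0,1]
    is usable.
    """
    ad = sample.get("AD")
    if ad is not None and not all(v is None for v in ad):
        vals = [v or 0 for v in ad]
        if len(vals) >= alt_i + 2:
            total = sum(vals)
            return vals[alt_i + 1] / total if total else 0.0
        # Some callers emit alt-only AD plus RD for the reference depth.
        rd = sample.get("RD")
        if rd is not None:
            total = rd + vals[0]
            return vals[0] / total if total else 0.0
    freq = sample.get("FREQ")
    if freq is not None:
        if isinstance(freq, (tuple, list)):
            freq = freq[0]
        if isinstance(freq, (bytes, str)):
            freq = str(freq).rstrip("%")
            return float(freq) / 100.0
        return float(freq)
    return None


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read small-variant calls from a VCF (v4.2) or a tab-separated table.

    VCF records are split per ALT allele and per carrier line (a carrier is a
    sample with non-zero supporting-read fraction); symbolic ALTs (``<DEL>``
    and friends) are skipped here and belong to the SV reader.  The
    tab-separated fallback has columns contig, pos, ref, alt, line_id, af.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_vcf(path)
    return _read_tabular(path)


def _read_vcf(path: Path) -> list[VariantCall]:
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for alt_i, alt in enumerate(rec.alts or ()):
                if alt.startswith("<") or "[" in alt or "]" in alt:
                    logger.info(
                        "skipping symbolic ALT %s at %s:%d (SV reader territory)",
                        alt, rec.chrom, rec.pos,
                    )
                    continue
                af_by_line: dict[str, float] = {}
                for sname in samples:
                    af = _af_from_sample(rec.samples[sname], alt_i)
                    if af is None:
                        raise FormatError(
                            f"{path}: record {rec.chrom}:{rec.pos} sample "
                            f"{sname} carries neither AD nor FREQ; a "
                            "per-sample variant-supporting read fraction "
                            "is required"
                        )
                    af_by_line[sname] = af
                for sname, af in af_by_line.items():
                    if af > 0:
                        calls.append(
                            VariantCall(
                                contig=rec.chrom,
                                pos=rec.pos,
                                ref_allele=rec.ref.upper(),
                                alt_allele=alt.upper(),
                                line_id=sname,
                                af_by_line=dict(af_by_line),
                            )
                        )
    return calls


def _read_tabular(path: Path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TAB_COLUMNS)] != list(_TAB_COLUMNS):
            raise FormatError(
                f"{path}: expected header columns {_TAB_COLUMNS}, got {header}"
            )
        rows = []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 columns")
            rows.append(cols)
    # First pass: collect af per line for each variant key.
    af_map: dict[tuple, dict[str, float]] = {}
    for cols in rows:
        key = (cols[0], int(cols[1]), cols[2].upper(), cols[3].upper())
        af_map.setdefault(key, {})[cols[4]] = float(cols[5])
    for cols in rows:
        key = (cols[0], int(cols[1]), cols[2].upper(), cols[3].upper())
        calls.append(
            VariantCall(
                contig=key[0], pos=key[1], ref_allele=key[2],
                alt_allele=key[3], line_id=cols[4],
                af_by_line=dict(af_map[key]),
            )
        )
    return calls


def write_variant_table(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Write calls to the tab-separated call-table format (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TAB_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.pos}\t{c.ref_allele}\t{c.alt_allele}\t"
                f"{c.line_id}\t{c.af_by_line.get(c.line_id, 0.0):.6g}\n"
            )


# ---------------------------------------------------------------------------
# InDel normalization
# ---------------------------------------------------------------------------

def _check_ref(call: VariantCall, genome: Genome) -> None:
    observed = genome.fetch(call.contig, call.pos, call.end)
    if observed != call.ref_allele:
        raise ReferenceMismatchError(
            f"{call.contig}:{call.pos} REF {call.ref_allele!r} disagrees "
            f"with genome {observed!r}"
        )


def normalize_indel(call: VariantCall, genome: Genome) -> VariantCall:
    """Canonicalize a variant: trim shared flanking bases, left-align InDels.

    Follows the standard VCF normalization algorithm: trim identical trailing
    bases, then identical leading bases, then shift a pure insertion/deletion
    left one base at a time while the trailing base of the longer allele
    matches the reference base before the locus.  The alternate haplotype is
    preserved exactly; the operation is idempotent.  SBSs pass through
    unchanged.
    """
    _check_ref(call, genome)
    if call.is_sbs:
        return call

    seq = genome[call.contig].sequence
    pos, ref, alt = call.pos, call.ref_allele, call.alt_allele

    # Trim shared trailing bases; when an allele empties, extend both alleles
    # one reference base to the left (this is what shifts an InDel left).
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if ref and alt:
            continue
        if pos > 1:
            prev = seq[pos - 2]
            ref, alt = prev + ref, prev + alt
            pos -= 1
        else:  # contig start: re-anchor on the base after the footprint
            nxt = seq[pos - 1 + len(ref)]
            ref, alt = ref + nxt, alt + nxt
            break
    # trim shared leading bases, keeping the anchor base for indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(call, pos=pos, ref_allele=ref, alt_allele=alt)
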