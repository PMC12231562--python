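"""Structural-variant representation, multi-caller consensus and summaries.

SVs here are interval-scale records (>= ~50 bp) from breakpoint callers
(Lumpy, Delly, Manta).  Running the callers is upstream of this package;
this module ingests their call sets, merges per-line same-type calls with
high reciprocal overlap into consensus records, and emits per-genotype
summary tables (counts by type, size ranges, deletion fraction).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

SV_TYPES = ("DEL", "DUP", "INV", "INS", "BND")
KNOWN_CALLERS = ("lumpy", "delly", "manta", "other")

DEFAULT_MIN_SV_SIZE = 50  # boundary between small-InDel and SV accounting


@dataclass(frozen=True)
class SVRecord:
    line_id: str
    contig: str
    start: int
    end: int
    sv_type: str
    callers: frozenset[str] = frozenset({"other"})
    validated: bool = False

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type != "BND" and self.start >= self.end:
            raise ValidationError(
                f"{self.contig}:{self.start}-{self.end}: start must be < end"
            )
        if not self.callers:
            raise ValidationError("callers must be non-empty")

    @property
    def size(self) -> int:
        return sv_size(self)


def sv_size(record: SVRecord) -> int:
    """SV size in bp, defined as end - start (interval types only)."""
    if record.sv_type == "BND":
        raise ValidationError("size undefined for BND records")
    if record.start >= record.end:
        raise ValidationError(
            f"invalid record {record.contig}:{record.start}-{record.end}"
        )
    return record.end - record.start


def _reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start), inter / (b.end - b.start))


def merge_consensus(
    callsets: list[list[SVRecord]],
    reciprocal_overlap: float = 0.8,
    min_callers: int = 2,
) -> list[SVRecord]:
    """Merge per-caller call sets into consensus records.

    Same-line, same-type, same-contig records whose reciprocal overlap
    reaches the threshold are merged (single-linkage): consensus coordinates
    are the member medians and the caller set is the union.  Consensus
    records supported by fewer than ``min_callers`` callers are dropped
    unless flagged validated.  The result is independent of caller order
    and idempotent.
    """
    records = [r for cs in callsets for r in cs]
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i], records[j]
            if (a.line_id, a.contig, a.sv_type) != (b.line_id, b.contig, b.sv_type):
                continue
            if _reciprocal_overlap(a, b) >= reciprocal_overlap:
                union(i, j)

    groups: dict[int, list[SVRecord]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(records[i])

    merged: list[SVRecord] = []
    for members in groups.values():
        callers = frozenset().union(*(m.callers for m in members))
        rec = SVRecord(
            line_id=members[0].line_id,
            contig=members[0].contig,
            start=int(statistics.median(m.start for m in members)),
            end=int(statistics.median(m.end for m in members)),
            sv_type=members[0].sv_type,
            callers=callers,
            validated=any(m.validated for m in members),
        )
        if len(callers) >= min_callers or rec.validated:
            merged.append(rec)
    merged.sort(key=lambda r: (r.line_id, r.contig, r.start))
    return merged


def summarize_svs(
    records: list[SVRecord], genotype_of_line: dict[str, str]
) -> pd.DataFrame:
    """Per-genotype SV summary: counts by type, size min/max, deletion
    fraction.  Genotypes present in the mapping but without records get a
    zero row."""
    rows = []
    by_geno: dict[str, list[SVRecord]] = {
        g: [] for g in dict.fromkeys(genotype_of_line.values())
    }
    for r in records:
        by_geno.setdefault(genotype_of_line.get(r.line_id, "unknown"), []).append(r)
    for geno, recs in by_geno.items():
        sizes = [sv_size(r) for r in recs if r.sv_type != "BND"]
        row = {
            "genotype": geno,
            "n_svs": len(recs),
            "size_min": min(sizes) if sizes else 0,
            "size_max": max(sizes) if sizes else 0,
            "deletion_fraction": (
                sum(r.sv_type == "DEL" for r in recs) / len(recs) if recs else 0.0
            ),
        }
        for t in SV_TYPES:
            row[f"n_{t}"] = sum(r.sv_type == t for r in recs)
        rows.append(row)
    return pd.DataFrame(rows)


def sv_table(records: list[SVRecord], genotype_of_line: dict[str, str]) -> pd.DataFrame:
    """Per-record report shaped like the published SV tables: group, sample,
    chromosome, start, end, type, size, validation flag."""
    rows = [
        {
            "group": genotype_of_line.get(r.line_id, "unknown"),
            "sample": r.line_id,
            "chromosome": r.contig,
            "start": r.start,
            "end": r.end,
            "sv_type": r.sv_type,
            "size_bp": sv_size(r) if r.sv_type != "BND" else 0,
            "callers": ",".join(sorted(r.callers)),
            "validated": r.validated,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: TSV (published-table shape) and symbolic-ALT VCF
# ---------------------------------------------------------------------------

_TSV_COLS = ("line_id", "contig", "start", "end", "sv_type", "callers", "validated")

_TYPE_ALIASES = {
    "DELETION": "DEL", "DUPLICATION": "DUP", "INVERSION": "INV",
    "INSERTION": "INS",
}


def read_sv_table(path: str | Path) -> list[SVRecord]:
    """Read SVs from a TSV with columns line_id, contig, start, end,
    sv_type, callers (comma-separated, optional), validated (optional)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for req in _TSV_COLS[:5]:
            if req not in idx:
                raise FormatError(f"{path}: missing column {req!r}")
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            svt = cols[idx["sv_type"]].upper()
            svt = _TYPE_ALIASES.get(svt, svt)
            callers = frozenset(
                cols[idx["callers"]].split(",")
            ) if "callers" in idx and cols[idx["callers"]] else frozenset({"other"})
            validated = (
                cols[idx["validated"]].lower() in ("1", "true", "yes", "✓")
                if "validated" in idx and len(cols) > idx["validated"]
                else False
            )
            records.append(
                SVRecord(
                    line_id=cols[idx["line_id"]],
                    contig=cols[idx["contig"]],
                    start=int(cols[idx["start"]]),
                    end=int(cols[idx["end"]]),
                    sv_type=svt,
                    callers=callers,
                    validated=validated,
                )
            )
    return records


def write_sv_table(records: list[SVRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLS) + "\n")
        for r in records:
            fh.write(
                f"{r.line_id}\t{r.contig}\t{r.start}\t{r.end}\t{r.sv_type}\t"
                f"{','.join(sorted(r.callers))}\t{int(r.validated)}\n"
            )
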