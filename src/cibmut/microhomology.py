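"""Junction-microhomology analysis of InDels.

During double-strand-break repair, alternative end joining (Alt-EJ / MMEJ)
anneals short identical sequences (microhomologies, here 1–20 bp) flanking
the break, leaving a characteristic signature at the rejoined site: the
deleted (or tandem-duplicated) segment shares its terminal bases with the
immediately adjacent reference sequence.  This module measures that
signature for every InDel and classifies its flanking-sequence context into
three mutually exclusive dependency classes:

``homopoly``
    the InDel allele is a single repeated base lying in a homopolymer run
    (classic replication-slippage / polymerase-stutter context);
``polynucleotide_repeat``
    the junction sits in a perfect tandem repeat of unit length >= 2, or the
    InDel (>= 2 bp) carries junction microhomology of >= 1 bp;
``independent``
    neither feature is present — a blunt, microhomology-independent joint.

All scans operate on the left-aligned (normalized) representation, so the
reported quantities do not depend on how the caller chose to place the
InDel.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidVariantError
from .genomic_io import Genome
from .mutation_classify import MutationEvent

HOMOPOLY = "homopoly"
POLY_REPEAT = "polynucleotide_repeat"
INDEPENDENT = "independent"
DEPENDENCY_CLASSES = (HOMOPOLY, POLY_REPEAT, INDEPENDENT)


@dataclass(frozen=True)
class MHConfig:
    """Thresholds for the microhomology scans.

    ``flank_window``/``mh_cap`` default to 20 bp, the upper end of the
    microhomology lengths Alt-EJ typically uses (2–20 bp).
    """

    flank_window: int = 20
    mh_cap: int = 20
    homopoly_min_run: int = 3
    repeat_unit_min: int = 2
    repeat_unit_max: int = 10
    repeat_min_copies: int = 2

    def __post_init__(self) -> None:
        if min(
            self.flank_window, self.mh_cap, self.homopoly_min_run,
            self.repeat_unit_min, self.repeat_unit_max, self.repeat_min_copies,
        ) <= 0:
            raise ValueError("all MHConfig fields must be positive")
        if self.repeat_unit_min < 2:
            raise ValueError("repeat_unit_min must be >= 2")


@dataclass
class MicrohomologySignature:
    """Per-InDel junction signature with all intermediate quantities."""

    mh_len: int
    mh_side: str  # left / right / both / none
    homopolymer_run: int
    repeat_unit: str | None
    dependency_class: str
    ambiguous_context: bool = False


def _indel_allele(event: MutationEvent) -> tuple[str, int, int, bool]:
    """(allele bases, junction start, junction end, is_deletion).

    For a deletion the junction interval is the deleted reference bases
    (anchor excluded); for an insertion it is the two reference bases
    flanking the insertion point.  1-based inclusive.
    """
    if not event.is_indel:
        raise InvalidVariantError(
            f"microhomology analysis requires an InDel event, got "
            f"{event.category}"
        )
    call = event.members[0]
    if event.indel_len < 0:
        allele = call.ref_allele[len(call.alt_allele):]
        start = call.pos + len(call.alt_allele)
        return allele, start, call.end, True
    allele = call.alt_allele[len(call.ref_allele):]
    return allele, call.pos, call.pos + 1, False


def _bases_match(a: str, b: str) -> bool:
    """Equality with N treated as never matching."""
    return len(a) == len(b) and all(
        x == y and x != "N" for x, y in zip(a, b)
    )


def junction_microhomology(
    event: MutationEvent, genome: Genome, cfg: MHConfig = MHConfig()
) -> tuple[int, str]:
    """Maximum junction microhomology length and the side attaining it.

    Let A be the deleted (or inserted) bases.  The microhomology length is
    the largest k <= min(|A|, mh_cap) such that the k-prefix of A equals the
    k reference bases immediately 3' of the event, or the k-suffix of A
    equals the k bases immediately 5' of it.  Flanks truncated at contig
    ends contribute what they can.
    """
    allele, start, end, is_del = _indel_allele(event)
    if is_del:
        left_end = start - 1      # last base 5' of the junction
        right_start = end + 1     # first base 3' of the junction
    else:
        call = event.members[0]
        left_end = call.pos
        right_start = call.pos + 1

    cap = min(len(allele), cfg.mh_cap)
    right_flank = genome.fetch(event.contig, right_start, right_start + cap - 1)
    left_flank = genome.fetch(event.contig, max(1, left_end - cap + 1), left_end)

    best_right = 0
    for k in range(1, min(cap, len(right_flank)) + 1):
        if _bases_match(allele[:k], right_flank[:k]):
            best_right = k
    best_left = 0
    for k in range(1, min(cap, len(left_flank)) + 1):
        if _bases_match(allele[-k:], left_flank[len(left_flank) - k:]):
            best_left = k

    mh_len = max(best_left, best_right)
    if mh_len == 0:
        side = "none"
    elif best_left == best_right:
        side = "both"
    elif best_right > best_left:
        side = "right"
    else:
        side = "left"
    return mh_len, side


def homopolymer_run(
    event: MutationEvent, genome: Genome, cfg: MHConfig = MHConfig()
) -> int:
    """Length of the longest single-base reference run overlapping the
    junction interval (deleted bases included for deletions; the two bases
    adjacent to the insertion point for insertions)."""
    _, start, end, _ = _indel_allele(event)
    seq = genome[event.contig].sequence
    n = len(seq)
    best = 0
    for pos in range(start, end + 1):
        i = pos - 1
        if i < 0 or i >= n:
            continue
        base = seq[i]
        if base == "N":
            continue
        lo = i
        while lo > 0 and seq[lo - 1] == base:
            lo -= 1
        hi = i
        while hi < n - 1 and seq[hi + 1] == base:
            hi += 1
        best = max(best, hi - lo + 1)
    return best


def _is_homopolymer(unit: str) -> bool:
    return len(set(unit)) == 1


def tandem_repeat_context(
    event: MutationEvent, genome: Genome, cfg: MHConfig = MHConfig()
) -> str | None:
    """Shortest tandem-repeat unit whose perfect array covers the junction.

    Scans units of length 2..repeat_unit_max within +/- flank_window of the
    junction for perfect arrays of >= repeat_min_copies copies.  A deletion
    junction must be entirely contained in the array; an insertion point
    must touch it.  Mononucleotide units are the homopolymer feature, not a
    polynucleotide repeat, and are excluded.
    """
    _, start, end, is_del = _indel_allele(event)
    seq = genome[event.contig].sequence
    lo = max(1, start - cfg.flank_window)   # 1-based window bounds
    hi = min(len(seq), end + cfg.flank_window)
    region = seq[lo - 1 : hi]

    for unit_len in range(cfg.repeat_unit_min, cfg.repeat_unit_max + 1):
        for i in range(len(region) - unit_len * cfg.repeat_min_copies + 1):
            unit = region[i : i + unit_len]
            if "N" in unit or _is_homopolymer(unit):
                continue
            copies = 1
            j = i + unit_len
            while region[j : j + unit_len] == unit:
                copies += 1
                j += unit_len
            if copies < cfg.repeat_min_copies:
                continue
            arr_start = lo + i                   # 1-based genome coords
            arr_end = lo + i + unit_len * copies - 1
            if is_del:
                covered = arr_start <= start and end <= arr_end
            else:
                covered = not (arr_end < start or arr_start > end)
            if covered:
                return unit
    return None


def classify_dependency(
    event: MutationEvent, genome: Genome, cfg: MHConfig = MHConfig()
) -> MicrohomologySignature:
    """Full signature and three-class dependency call for one InDel.

    Priority when several features fire: homopoly > polynucleotide_repeat >
    independent, mirroring a mutually exclusive three-class accounting.
    Junctions whose flanking window contains N are reported as independent
    with ``ambiguous_context`` set.
    """
    allele, start, end, _ = _indel_allele(event)
    mh_len, mh_side = junction_microhomology(event, genome, cfg)
    run = homopolymer_run(event, genome, cfg)
    unit = tandem_repeat_context(event, genome, cfg)

    window_seq = genome.fetch(
        event.contig, start - cfg.flank_window, end + cfg.flank_window
    )
    ambiguous = "N" in window_seq or "N" in allele
    if ambiguous:
        cls = INDEPENDENT
    elif _is_homopolymer(allele) and run >= cfg.homopoly_min_run:
        cls = HOMOPOLY
    elif unit is not None or (len(allele) >= 2 and mh_len >= 1):
        cls = POLY_REPEAT
    else:
        cls = INDEPENDENT
    return MicrohomologySignature(
        mh_len=mh_len,
        mh_side=mh_side,
        homopolymer_run=run,
        repeat_unit=unit,
        dependency_class=cls,
        ambiguous_context=ambiguous,
    )


def signatures_to_table(events, signatures):
    """Signature table (one row per InDel) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for e, s in zip(events, signatures):
        rows.append(
            {
                "line_id": e.line_id, "contig": e.contig, "start": e.start,
                "end": e.end, "indel_len": e.indel_len, "mh_len": s.mh_len,
                "mh_side": s.mh_side, "homopolymer_run": s.homopolymer_run,
                "repeat_unit": s.repeat_unit or ".",
                "dependency_class": s.dependency_class,
                "ambiguous_context": s.ambiguous_context,
            }
        )
    return pd.DataFrame(rows)
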