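"""Seven-category mutation taxonomy and strand-collapsed SBS classes.

Categories: SBS, single-base insertion (``ins1``), single-base deletion
(``del1``), deletions >= 2 bp (``del_ge2``), insertions >= 2 bp
(``ins_ge2``), complex mutations (two or more calls within 10 bp, counted as
one event), and SV.  The SV category is assigned only by the SV module;
small-variant classification never produces it.

SBS classes are strand-collapsed into the usual six: a G>A on one strand is
the same biological event as C>T on the other, so both report ``G/C>A/T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import InvalidVariantError
from .genomic_io import VariantCall

logger = logging.getLogger(__name__)

CATEGORIES = ("SBS", "del1", "ins1", "del_ge2", "ins_ge2", "complex", "SV")

SBS_CLASSES = (
    "A/T>G/C", "G/C>A/T", "A/T>T/A", "A/T>C/G", "G/C>T/A", "G/C>C/G",
)
TRANSITION_CLASSES = frozenset({"A/T>G/C", "G/C>A/T"})

LENGTH_BINS = ("1", "2-10", "11-30", ">30")

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# all 12 ordered base pairs, collapsed so reverse-complement pairs share a class
_SBS_CLASS_OF = {
    ("A", "G"): "A/T>G/C", ("T", "C"): "A/T>G/C",
    ("G", "A"): "G/C>A/T", ("C", "T"): "G/C>A/T",
    ("A", "T"): "A/T>T/A", ("T", "A"): "A/T>T/A",
    ("A", "C"): "A/T>C/G", ("T", "G"): "A/T>C/G",
    ("G", "T"): "G/C>T/A", ("C", "A"): "G/C>T/A",
    ("G", "C"): "G/C>C/G", ("C", "G"): "G/C>C/G",
}

DEFAULT_COMPLEX_WINDOW = 10


def length_bin(indel_len: int) -> str:
    """Fragment-length bin of an InDel: 1, 2-10, 11-30 or >30 bp."""
    n = abs(indel_len)
    if n < 1:
        raise InvalidVariantError("length bin undefined for length 0")
    if n == 1:
        return "1"
    if n <= 10:
        return "2-10"
    if n <= 30:
        return "11-30"
    return ">30"


def classify_sbs(ref_base: str, alt_base: str) -> str:
    """Strand-collapsed 6-class label for a single-base substitution."""
    if ref_base not in _COMPLEMENT or alt_base not in _COMPLEMENT:
        raise InvalidVariantError(
            f"SBS bases must be A/C/G/T, got {ref_base!r}>{alt_base!r}"
        )
    if ref_base == alt_base:
        raise InvalidVariantError(f"ref equals alt ({ref_base})")
    return _SBS_CLASS_OF[(ref_base, alt_base)]


def is_transition(sbs_class: str) -> bool:
    return sbs_class in TRANSITION_CLASSES


@dataclass
class MutationEvent:
    """A filtered, normalized, classified mutation owned by one line.

    ``start``/``end`` delimit the 1-based inclusive reference footprint; for
    an insertion ``end == start``.  ``members`` lists constituent calls and
    has length >= 2 exactly when the category is complex.
    """

    line_id: str
    contig: str
    start: int
    end: int
    category: str
    sbs_class: str | None = None
    indel_len: int = 0
    members: list[VariantCall] = field(default_factory=list)
    length_bin: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidVariantError(f"unknown category {self.category!r}")

    @property
    def is_indel(self) -> bool:
        return self.category in ("del1", "ins1", "del_ge2", "ins_ge2")

    @property
    def n_calls(self) -> int:
        """Number of constituent raw calls this event accounts for."""
        return len(self.members) if self.category == "complex" else 1


def _footprint(call: VariantCall) -> tuple[int, int]:
    return call.pos, call.end


def _event_from_call(call: VariantCall) -> MutationEvent:
    """Classify one isolated (non-complex) normalized call."""
    if call.is_sbs:
        return MutationEvent(
            line_id=call.line_id, contig=call.contig,
            start=call.pos, end=call.pos, category="SBS",
            sbs_class=classify_sbs(call.ref_allele, call.alt_allele),
            members=[call],
        )
    delta = call.indel_len
    if delta < 0:
        category = "del1" if delta == -1 else "del_ge2"
    else:
        category = "ins1" if delta == 1 else "ins_ge2"
    return MutationEvent(
        line_id=call.line_id, contig=call.contig,
        start=call.pos, end=call.end, category=category,
        indel_len=delta, length_bin=length_bin(delta), members=[call],
    )


def _decompose_mnv(call: VariantCall) -> list[VariantCall]:
    """Split a balanced multi-base substitution into per-base SBS calls.

    The seven-category taxonomy has no MNV class; the per-base calls fall
    within the complex-mutation window of each other and are re-joined as
    one complex event downstream.
    """
    from dataclasses import replace

    out = []
    for i, (r, a) in enumerate(zip(call.ref_allele, call.alt_allele)):
        if r != a:
            out.append(
                replace(call, pos=call.pos + i, ref_allele=r, alt_allele=a)
            )
    return out


def cluster_complex(
    calls: list[VariantCall],
    window: int = DEFAULT_COMPLEX_WINDOW,
) -> list[MutationEvent]:
    """Chain nearby same-line calls into complex events.

    Two successive calls on the same contig join one event when the gap from
    the end of the previous reference footprint to the start of the next is
    at most ``window`` bases; chaining is transitive.  Singleton chains pass
    through as ordinary events.
    """
    ordered = sorted(calls, key=lambda c: (c.contig, c.pos, c.ref_allele, c.alt_allele))
    if [c.key for c in ordered] != [c.key for c in calls]:
        logger.warning("cluster_complex input unsorted; sorting internally")

    events: list[MutationEvent] = []
    chain: list[VariantCall] = []

    def flush() -> None:
        if not chain:
            return
        if len(chain) == 1:
            events.append(_event_from_call(chain[0]))
        else:
            events.append(
                MutationEvent(
                    line_id=chain[0].line_id,
                    contig=chain[0].contig,
                    start=min(c.pos for c in chain),
                    end=max(c.end for c in chain),
                    category="complex",
                    members=list(chain),
                )
            )
        chain.clear()

    for call in ordered:
        if chain and call.contig == chain[-1].contig:
            gap = call.pos - max(c.end for c in chain)
            if gap <= window:
                chain.append(call)
                continue
        flush()
        chain.append(call)
    flush()
    return events


def classify_events(
    calls: list[VariantCall],
    window: int = DEFAULT_COMPLEX_WINDOW,
) -> list[MutationEvent]:
    """Classify retained, normalized calls into the seven-category events.

    Balanced multi-base substitutions are decomposed into per-base SBS calls
    first (they re-join as complex events when within the window).  Calls are
    grouped per line; every input call appears in exactly one output event.
    """
    expanded: list[VariantCall] = []
    for c in calls:
        if len(c.ref_allele) == len(c.alt_allele) and len(c.ref_allele) > 1:
            expanded.extend(_decompose_mnv(c))
        else:
            expanded.append(c)

    by_line: dict[str, list[VariantCall]] = {}
    for c in expanded:
        by_line.setdefault(c.line_id, []).append(c)

    events: list[MutationEvent] = []
    for line_id in sorted(by_line):
        line_calls = sorted(
            by_line[line_id],
            key=lambda c: (c.contig, c.pos, c.ref_allele, c.alt_allele),
        )
        events.extend(cluster_complex(line_calls, window=window))
    return events


def events_to_table(events: list[MutationEvent]):
    """Events as a pandas DataFrame in the tab-separated report shape."""
    import pandas as pd

    rows = [
        {
            "line_id": e.line_id,
            "contig": e.contig,
            "start": e.start,
            "end": e.end,
            "category": e.category,
            "sbs_class": e.sbs_class or ".",
            "indel_len": e.indel_len,
            "length_bin": e.length_bin or ".",
            "member_count": len(e.members),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "line_id", "contig", "start", "end", "category", "sbs_class",
            "indel_len", "length_bin", "member_count",
        ],
    )
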