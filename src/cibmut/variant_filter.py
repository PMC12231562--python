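"""Retention filtering of raw calls: keep line-private, well-supported
mutations; remove shared/background variants.

A call is retained when the variant-supporting read fraction is at least
``af_target_min`` (default 25%) in its own line, stays below ``af_other_max``
(default 5%) in every other sequenced line, and the variant is not carried by
``shared_line_min`` (default 2) or more lines.  Variants shared by two or
more individuals predate the mutagenic treatment (standing variation or a
systematic calling artifact) and are removed; the identity used for the
sharing test is the exact normalized (contig, pos, ref, alt) tuple.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import ConfigurationError
from .genomic_io import VariantCall

REASON_LOW_AF = "low_af_target"
REASON_OTHER = "present_in_other"
REASON_SHARED = "shared"


@dataclass(frozen=True)
class FilterConfig:
    af_target_min: float = 0.25
    af_other_max: float = 0.05
    shared_line_min: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.af_other_max < self.af_target_min <= 1:
            raise ConfigurationError(
                "need 0 <= af_other_max < af_target_min <= 1, got "
                f"{self.af_other_max} / {self.af_target_min}"
            )
        if self.shared_line_min < 2:
            raise ConfigurationError("shared_line_min must be >= 2")


def filter_variants(
    calls: list[VariantCall],
    lines: list[str],
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Partition ``calls`` into (retained, removed-with-reason).

    Reasons: ``low_af_target`` (support below threshold in the owning line),
    ``shared`` (carried at >= af_other_max by >= shared_line_min lines),
    ``present_in_other`` (detectable in some other line but below the
    sharing count).  Every input call lands in exactly one of the two lists.
    """
    line_set = set(lines)
    for c in calls:
        if c.line_id not in line_set:
            raise ConfigurationError(
                f"call at {c.contig}:{c.pos} owned by unknown line "
                f"{c.line_id!r}; known lines: {sorted(line_set)}"
            )

    # carriers per variant identity: lines whose support reaches af_other_max
    carrier_count: Counter = Counter()
    seen: set[tuple] = set()
    for c in calls:
        if c.key in seen:
            continue
        seen.add(c.key)
        carriers = {
            line for line, af in c.af_by_line.items() if af >= cfg.af_other_max
        }
        carrier_count[c.key] = len(carriers)

    retained: list[VariantCall] = []
    removed: list[tuple[VariantCall, str]] = []
    for c in calls:
        af_target = c.af_by_line.get(c.line_id, 0.0)
        if af_target < cfg.af_target_min:
            removed.append((c, REASON_LOW_AF))
            continue
        if carrier_count[c.key] >= cfg.shared_line_min:
            removed.append((c, REASON_SHARED))
            continue
        others_clean = all(
            af < cfg.af_other_max
            for line, af in c.af_by_line.items()
            if line != c.line_id
        )
        if not others_clean:
            removed.append((c, REASON_OTHER))
            continue
        retained.append(c)
    return retained, removed
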