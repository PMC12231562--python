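"""Frequencies, ratios, per-plant averaging, TSS profiles and group letters.

The central reporting conventions:

* **Per-plant averaging** — because the number of sequenced lines differs
  between genotypes, proportions and ratios are computed per line (plant)
  first and then averaged across the lines of a genotype, each plant
  weighted equally.  SEM uses n = number of lines.
* **Mutation frequency** — events per plant divided by the reference genome
  length and by the absorbed dose:
  ``f = (total_events / n_lines) / L_ref / dose``  [per bp per Gy].
  Reports scale this by 1e10.  Controls (dose 0) are reported as counts
  only; the frequency is undefined there.
* **Group comparison** — one-way ANOVA followed by Duncan's multiple-range
  test at alpha = 0.05, reported as a compact letter display.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .genomic_io import GeneModel
from .mutation_classify import (
    CATEGORIES,
    MutationEvent,
    is_transition,
)

logger = logging.getLogger(__name__)

# Total length of the five nuclear chromosomes of the TAIR10 A. thaliana
# reference assembly; default L_ref for the packaged profiles.
TAIR10_NUCLEAR_LENGTH = 119_146_348

FREQ_SCALE = 1e10  # report unit: 1e-10 per bp per Gy


@dataclass(frozen=True)
class LineMeta:
    line_id: str
    genotype: str
    dose: float  # Gy; 0 for unirradiated controls
    generation: str = "M2"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ConfigurationError(f"{self.line_id}: dose must be >= 0")


@dataclass
class SpectrumSummary:
    genotype: str
    n_lines: int
    dose: float
    counts: dict[str, int]              # total per category
    mean_per_plant: dict[str, float]    # counts / n_lines
    frequency: dict[str, float]         # per bp per Gy (unscaled); {} if dose 0
    proportion_mean: dict[str, float]   # mean of per-plant proportions
    proportion_sem: dict[str, float]
    ts_tv: float                        # mean of per-plant Ts/Tv
    ins_dels: float
    sbs_indel: float


def mutation_frequency(
    event_count_total: int, n_lines: int, genome_length: int, dose: float
) -> float:
    """Mutation frequency per bp per Gy.

    (events per plant) / genome length / dose.  Undefined at dose 0.
    """
    if n_lines < 1 or genome_length < 1:
        raise ConfigurationError("n_lines and genome_length must be >= 1")
    if dose <= 0:
        raise ConfigurationError(
            "frequency undefined at dose 0; report controls as counts"
        )
    return (event_count_total / n_lines) / genome_length / dose


def fold_change(freq_a: float, freq_b: float) -> float:
    """Ratio of two frequencies (undefined when the denominator is 0)."""
    if freq_b <= 0:
        raise ConfigurationError("fold change undefined for freq_b <= 0")
    return freq_a / freq_b


def _safe_mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def per_plant_summary(
    events: list[MutationEvent],
    lines: list[LineMeta],
    genome_length: int = TAIR10_NUCLEAR_LENGTH,
) -> dict[str, SpectrumSummary]:
    """Per-genotype spectrum summaries with per-plant averaging.

    Ratios (Ts/Tv, Ins/Dels, SBS/InDels) are computed per line and averaged
    over lines with a non-zero denominator; frequencies are computed on
    genotype totals.  Genotypes with zero lines are omitted with a warning.
    """
    meta = {m.line_id: m for m in lines}
    for e in events:
        if e.line_id not in meta:
            raise ConfigurationError(f"event owned by unknown line {e.line_id!r}")

    genotypes: dict[str, list[LineMeta]] = {}
    for m in lines:
        genotypes.setdefault(m.genotype, []).append(m)

    by_line: dict[str, list[MutationEvent]] = {m.line_id: [] for m in lines}
    for e in events:
        by_line[e.line_id].append(e)

    out: dict[str, SpectrumSummary] = {}
    for geno, members in genotypes.items():
        if not members:
            warnings.warn(f"genotype {geno} has no lines; omitted")
            continue
        n_lines = len(members)
        doses = {m.dose for m in members}
        dose = doses.pop() if len(doses) == 1 else float("nan")

        counts = {c: 0 for c in CATEGORIES}
        prop_rows: list[dict[str, float]] = []
        ts_tv_vals, ins_dels_vals, sbs_indel_vals = [], [], []
        for m in members:
            evs = by_line[m.line_id]
            line_counts = {c: sum(e.category == c for e in evs) for c in CATEGORIES}
            for c in CATEGORIES:
                counts[c] += line_counts[c]
            total = sum(line_counts.values())
            if total:
                prop_rows.append({c: line_counts[c] / total for c in CATEGORIES})
            ts = sum(
                1 for e in evs if e.category == "SBS" and is_transition(e.sbs_class)
            )
            tv = line_counts["SBS"] - ts
            if tv:
                ts_tv_vals.append(ts / tv)
            ins = line_counts["ins1"] + line_counts["ins_ge2"]
            dels = line_counts["del1"] + line_counts["del_ge2"]
            if dels:
                ins_dels_vals.append(ins / dels)
            if ins + dels:
                sbs_indel_vals.append(line_counts["SBS"] / (ins + dels))

        prop_mean = {
            c: _safe_mean([r[c] for r in prop_rows]) for c in CATEGORIES
        }
        prop_sem = {
            c: (
                float(np.std([r[c] for r in prop_rows], ddof=1) / math.sqrt(len(prop_rows)))
                if len(prop_rows) > 1 else float("nan")
            )
            for c in CATEGORIES
        }
        freq = {}
        if dose and dose > 0:
            freq = {
                c: mutation_frequency(counts[c], n_lines, genome_length, dose)
                for c in CATEGORIES
            }
            freq["total"] = mutation_frequency(
                sum(counts.values()), n_lines, genome_length, dose
            )
        out[geno] = SpectrumSummary(
            genotype=geno,
            n_lines=n_lines,
            dose=dose,
            counts=counts,
            mean_per_plant={c: counts[c] / n_lines for c in CATEGORIES},
            frequency=freq,
            proportion_mean=prop_mean,
            proportion_sem=prop_sem,
            ts_tv=_safe_mean(ts_tv_vals),
            ins_dels=_safe_mean(ins_dels_vals),
            sbs_indel=_safe_mean(sbs_indel_vals),
        )
    return out


def frequency_table(
    summaries: dict[str, SpectrumSummary], precision: int = 2
) -> pd.DataFrame:
    """Frequencies scaled to 1e-10/bp/Gy, one genotype per row.

    The total keeps an extra decimal, matching the convention of reporting
    totals at finer precision than per-category cells.
    """
    rows = []
    for s in summaries.values():
        if not s.frequency:
            continue
        row = {"genotype": s.genotype}
        for c in CATEGORIES:
            row[c] = round(s.frequency[c] * FREQ_SCALE, precision)
        row["total"] = round(s.frequency["total"] * FREQ_SCALE, precision + 1)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSS-relative profile
# ---------------------------------------------------------------------------

def tss_distance(event_start: int, model: GeneModel) -> int:
    """Signed distance from the TSS along the direction of transcription
    (negative = upstream of the TSS)."""
    if model.strand == "+":
        return event_start - model.tss
    return model.tss - event_start


def tss_profile(
    annotations,
    models: list[GeneModel],
    genotype_of_line: dict[str, str],
    window: int = 10_000,
    bin_size: int = 1_000,
    nearest: bool = False,
) -> pd.DataFrame:
    """Binned counts of signed TSS distance for non-intergenic events.

    Distances are measured to the annotated gene's TSS by default, or to
    the nearest TSS on the contig with ``nearest=True``.  Events farther
    than ``window`` from the TSS are dropped.
    """
    model_of = {m.gene_id: m for m in models}
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)

    edges = np.arange(-window, window + bin_size, bin_size)
    labels = [f"{edges[i]}..{edges[i+1]}" for i in range(len(edges) - 1)]
    counts: dict[str, np.ndarray] = {}
    for a in annotations:
        if a.subclass == "intergenic":
            continue
        if nearest:
            cands = by_contig.get(a.event.contig, [])
            if not cands:
                continue
            model = min(cands, key=lambda m: abs(a.event.start - m.tss))
        else:
            if a.gene_id is None or a.gene_id not in model_of:
                continue
            model = model_of[a.gene_id]
        d = tss_distance(a.event.start, model)
        if not -window <= d <= window:
            continue
        idx = min(int((d + window) // bin_size), len(labels) - 1)
        geno = genotype_of_line.get(a.event.line_id, "unknown")
        counts.setdefault(geno, np.zeros(len(labels), dtype=int))[idx] += 1

    df = pd.DataFrame(counts, index=labels).T
    df.index.name = "genotype"
    return df


# ---------------------------------------------------------------------------
# One-way ANOVA + Duncan's multiple-range test
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=4096)
def _duncan_q(span: int, df_err: int, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protection level
    1-(1-alpha)^(span-1).  Cached: the quantile is expensive and depends
    only on (span, df, alpha)."""
    protection = 1 - (1 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1 - protection, span, df_err))

def anova_duncan(
    groups: list[tuple[str, list[float]]], alpha: float = 0.05
) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA followed by Duncan's multiple-range letters.

    Means are sorted descending; the critical range for a span of p means
    uses the studentized range at protection level 1-(1-alpha)^(p-1) with
    the ANOVA error df, and the harmonic mean of group sizes for unequal n.
    Labels sharing a letter are not significantly different.  With zero
    within-group variance everywhere, letters follow exact mean equality.
    """
    if len(groups) < 2:
        raise ConfigurationError("need >= 2 groups")
    for label, vals in groups:
        if len(vals) < 2:
            raise ConfigurationError(f"group {label!r} needs n >= 2")

    labels = [g[0] for g in groups]
    data = [np.asarray(g[1], dtype=float) for g in groups]
    k = len(groups)
    n_total = sum(len(d) for d in data)
    df_err = n_total - k
    grand = np.concatenate(data)
    means = np.array([d.mean() for d in data])
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    mse = ss_within / df_err
    ss_between = sum(len(d) * (d.mean() - grand.mean()) ** 2 for d in data)

    if mse == 0:
        f_stat = math.inf if ss_between > 0 else 0.0
        p_value = 0.0 if ss_between > 0 else 1.0
        # letters by exact equality of means
        letters: dict[str, str] = {}
        seen: dict[float, str] = {}
        next_letter = 0
        for label, mean in sorted(zip(labels, means), key=lambda t: -t[1]):
            if mean not in seen:
                seen[mean] = chr(ord("a") + next_letter)
                next_letter += 1
            letters[label] = seen[mean]
        return f_stat, p_value, letters

    f_stat, p_value = stats.f_oneway(*data)
    f_stat, p_value = float(f_stat), float(p_value)

    n_h = k / sum(1 / len(d) for d in data)  # harmonic mean group size
    order = np.argsort(-means)  # descending
    sorted_means = means[order]
    sorted_labels = [labels[i] for i in order]

    def critical_range(span: int) -> float:
        q = _duncan_q(span, df_err, alpha)
        return q * math.sqrt(mse / n_h)

    # Stepwise range testing with the containment (protection) rule: a range
    # inside an already non-significant range is never declared significant.
    nonsig_spans: list[tuple[int, int]] = []
    sig = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        r_crit = critical_range(span)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(lo <= i and j <= hi for lo, hi in nonsig_spans):
                continue
            if sorted_means[i] - sorted_means[j] >= r_crit:
                sig[i, j] = sig[j, i] = True
            else:
                nonsig_spans.append((i, j))

    # Compact letter display from maximal non-significant runs.  The
    # containment rule makes non-significance interval-shaped on the sorted
    # means, so maximal runs suffice.
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        runs.append((i, j))
    maximal = [
        (lo, hi)
        for lo, hi in set(runs)
        if not any((lo2 <= lo and hi <= hi2) and (lo2, hi2) != (lo, hi)
                   for lo2, hi2 in runs)
    ]
    maximal.sort()
    letter_map: dict[str, list[str]] = {lab: [] for lab in labels}
    for letter_i, (lo, hi) in enumerate(maximal):
        letter = chr(ord("a") + letter_i)
        for idx in range(lo, hi + 1):
            letter_map[sorted_labels[idx]].append(letter)
    letters = {lab: "".join(sorted(ls)) for lab, ls in letter_map.items()}
    return f_stat, p_value, letters
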