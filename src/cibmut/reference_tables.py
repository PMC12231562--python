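"""Published reference summary values for self-checks.

These constants reproduce the printed summary tables of the carbon-ion-beam
mutagenesis resequencing study the packaged genotype profiles are calibrated
to: per-genotype mutation totals with line counts and doses, the per-category
mutation frequencies (in 1e-10 / bp / Gy), and the validated SV coordinate
table.  They serve as arithmetic fixtures: the verify step recomputes every
derived cell (frequencies from counts, SV sizes from coordinates) and flags
any disagreement.
"""

from __future__ import annotations

# total nuclear reference length used by the frequency arithmetic (bp)
REFERENCE_GENOME_LENGTH = 119_146_348

# genotype -> (total mutation events, n sequenced lines, dose in Gy)
MUTATION_TOTALS = {
    "WT-200Gy": (318, 10, 200.0),
    "teb-8-100Gy": (224, 11, 100.0),
    "lig4-4-100Gy": (192, 14, 100.0),
}

# printed total mutation frequencies, 1e-10 per bp per Gy
PRINTED_TOTAL_FREQUENCY = {
    "WT-200Gy": 13.345,
    "teb-8-100Gy": 17.09,
    "lig4-4-100Gy": 11.51,
}

# printed per-category frequencies, 1e-10 per bp per Gy
PRINTED_CATEGORY_FREQUENCY = {
    "WT-200Gy": {
        "SBS": 9.78, "del1": 1.39, "ins1": 0.51, "del_ge2": 1.35,
        "ins_ge2": 0.30, "complex": 0.09,
    },
    "teb-8-100Gy": {
        "SBS": 11.14, "del1": 2.82, "ins1": 0.69, "del_ge2": 1.37,
        "ins_ge2": 0.31, "complex": 0.76,
    },
    "lig4-4-100Gy": {
        "SBS": 6.36, "del1": 0.24, "ins1": 0.30, "del_ge2": 4.02,
        "ins_ge2": 0.24, "complex": 0.36,
    },
}

# validated SV call set: (group, sample, chromosome, start, end, type, size)
SV_TABLE_ROWS = [
    ("lig4-4-100Gy", "L1-2", "1", 6992317, 6992386, "DEL", 69),
    ("lig4-4-100Gy", "L1-4", "1", 10993642, 10993984, "DEL", 342),
    ("lig4-4-100Gy", "L1-11", "1", 16939998, 16940064, "DEL", 66),
    ("lig4-4-100Gy", "L1-12", "1", 25618829, 25618891, "DEL", 62),
    ("lig4-4-100Gy", "L1-14", "1", 27307872, 27308242, "DEL", 370),
    ("lig4-4-100Gy", "L1-4", "1", 28491172, 28491229, "DEL", 57),
    ("lig4-4-100Gy", "L1-2", "1", 30164546, 30165031, "DEL", 485),
    ("lig4-4-100Gy", "L1-12", "2", 10395128, 10395225, "DUP", 97),
    ("lig4-4-100Gy", "L1-15", "3", 19928674, 19928724, "DEL", 50),
    ("lig4-4-100Gy", "L1-11", "3", 21916848, 21916914, "DEL", 66),
    ("lig4-4-100Gy", "L1-8", "4", 195851, 195942, "DEL", 86),
    ("lig4-4-100Gy", "L1-12", "4", 16040504, 16040567, "DEL", 63),
    ("lig4-4-100Gy", "L1-7", "4", 18179116, 18179773, "DEL", 657),
    ("lig4-4-100Gy", "L1-6", "4", 18289363, 18289512, "DEL", 149),
    ("lig4-4-100Gy", "L1-9", "5", 1745827, 1745882, "DEL", 55),
    ("lig4-4-100Gy", "L1-13", "5", 5531895, 5531960, "DEL", 65),
    ("lig4-4-100Gy", "L1-7", "5", 17879971, 17880025, "DEL", 54),
    ("lig4-4-100Gy", "L1-7", "5", 20646146, 20646201, "DEL", 55),
    ("WT-200Gy", "3-4", "1", 21677471, 21677532, "DEL", 61),
    ("WT-200Gy", "3-1", "3", 307505, 326093, "DEL", 18588),
]


def sv_records():
    """The reference SV table as SVRecord objects (validated flag set)."""
    from .sv_analysis import SVRecord

    return [
        SVRecord(
            line_id=sample, contig=chrom, start=start, end=end,
            sv_type=svtype, callers=frozenset({"lumpy", "delly", "manta"}),
            validated=True,
        )
        for _, sample, chrom, start, end, svtype, _ in SV_TABLE_ROWS
    ]


def sv_genotype_of_line() -> dict[str, str]:
    return {sample: group for group, sample, *_ in SV_TABLE_ROWS}
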