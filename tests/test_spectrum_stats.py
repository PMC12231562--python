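"""Frequency arithmetic, per-plant averaging, TSS profiles and
ANOVA + Duncan letters."""

import numpy as np
import pytest
from scipy import stats

from cibmut.errors import ConfigurationError
from cibmut.genomic_io import GeneModel, VariantCall
from cibmut.impact_annotate import ImpactAnnotation
from cibmut.mutation_classify import MutationEvent
from cibmut.spectrum_stats import (
    TAIR10_NUCLEAR_LENGTH,
    LineMeta,
    anova_duncan,
    fold_change,
    mutation_frequency,
    per_plant_summary,
    tss_distance,
    tss_profile,
)

L = TAIR10_NUCLEAR_LENGTH


class TestMutationFrequency:
    @pytest.mark.parametrize(
        "count,n,dose,expected,ndigits",
        [(318, 10, 200, 13.345, 3), (224, 11, 100, 17.09, 2),
         (192, 14, 100, 11.51, 2)],
    )
    def test_published_totals(self, count, n, dose, expected, ndigits):
        f = mutation_frequency(count, n, L, dose) * 1e10
        assert round(f, ndigits) == expected

    def test_zero_events(self):
        assert mutation_frequency(0, 5, L, 100) == 0

    def test_dose_zero_undefined(self):
        with pytest.raises(ConfigurationError):
            mutation_frequency(10, 5, L, 0)


class TestFoldChange:
    @pytest.mark.parametrize(
        "a,b,expected", [(2.82, 1.39, 2.03), (2.82, 0.24, 11.75), (0.76, 0.09, 8.44)]
    )
    def test_published_ratios(self, a, b, expected):
        assert round(fold_change(a, b), 2) == expected

    def test_identity(self):
        assert fold_change(3.7, 3.7) == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.raises(ConfigurationError):
            fold_change(1.0, 0.0)


def make_event(line, category, pos=100, sbs_class=None, indel_len=0):
    ref, alt = ("A", "T") if category == "SBS" else ("CA", "C")
    return MutationEvent(
        line_id=line, contig="chr1", start=pos, end=pos, category=category,
        sbs_class=sbs_class, indel_len=indel_len,
        members=[VariantCall("chr1", pos, ref, alt, line)],
    )


class TestPerPlantSummary:
    def test_mean_of_per_plant_proportions(self):
        lines = [LineMeta("L1", "WT", 100), LineMeta("L2", "WT", 100)]
        events = (
            # L1: 3 SBS of 5 events (0.6); L2: 4 of 5 (0.8)
            [make_event("L1", "SBS", 10 * (i + 1), "A/T>G/C") for i in range(3)]
            + [make_event("L1", "del1", 200 + 20 * i, indel_len=-1) for i in range(2)]
            + [make_event("L2", "SBS", 10 * (i + 1), "A/T>G/C") for i in range(4)]
            + [make_event("L2", "del1", 500, indel_len=-1)]
        )
        s = per_plant_summary(events, lines)["WT"]
        assert s.proportion_mean["SBS"] == pytest.approx(0.7)

    def test_ts_tv_per_line(self):
        lines = [LineMeta("L1", "WT", 100)]
        events = (
            [make_event("L1", "SBS", 10 * (i + 1), "G/C>A/T") for i in range(4)]
            + [make_event("L1", "SBS", 300 + 10 * i, "A/T>T/A") for i in range(2)]
        )
        s = per_plant_summary(events, lines)["WT"]
        assert s.ts_tv == pytest.approx(2.0)

    def test_frequency_uses_totals(self):
        lines = [LineMeta(f"L{i}", "WT", 200) for i in range(10)]
        events = [
            make_event(f"L{i}", "SBS", 100 + 31 * j, "A/T>G/C")
            for i in range(10)
            for j in range(3)
        ]
        s = per_plant_summary(events, lines, genome_length=L)["WT"]
        assert s.frequency["total"] == pytest.approx((30 / 10) / L / 200)


class TestTssProfile:
    def test_signed_distance_conventions(self):
        plus = GeneModel("g1", "chr1", "+", 1000, 2000, ((1000, 2000),))
        minus = GeneModel("g2", "chr1", "-", 1000, 2000, ((1000, 2000),))
        assert tss_distance(1500, plus) == 500
        assert tss_distance(1500, minus) == 500
        assert tss_distance(500, plus) == -500

    def test_decaying_placement_gives_decaying_bins(self, rng):
        """Events placed with exponential decay from the TSS produce bin
        counts that decrease away from the TSS (within sampling noise)."""
        model = GeneModel("g1", "chr1", "+", 50_000, 60_000, ((50_000, 60_000),))
        anns = []
        for _ in range(2000):
            d = int(rng.exponential(1500)) * (1 if rng.random() < 0.5 else -1)
            ev = make_event("L1", "SBS", 50_000 + d, "A/T>G/C")
            anns.append(ImpactAnnotation(ev, "g1", "missense", "MODERATE"))
        df = tss_profile(anns, [model], {"L1": "WT"}, window=8000, bin_size=2000)
        row = df.loc["WT"].to_numpy()
        mid = len(row) // 2
        # inner bins hold more events than outer bins on both sides
        assert row[mid] > row[0]
        assert row[mid - 1] > row[0]
        assert row[mid] > row[-1]
        assert df.loc["WT"].sum() == sum(
            1 for a in anns if abs(a.event.start - 50_000) <= 8000
        )

    def test_intergenic_excluded(self):
        model = GeneModel("g1", "chr1", "+", 1000, 2000, ((1000, 2000),))
        ev = make_event("L1", "SBS", 1200, "A/T>G/C")
        anns = [
            ImpactAnnotation(ev, "g1", "missense", "MODERATE"),
            ImpactAnnotation(make_event("L1", "SBS", 1300, "A/T>G/C"),
                             None, "intergenic", "MODIFIER"),
        ]
        df = tss_profile(anns, [model], {"L1": "WT"})
        assert df.loc["WT"].sum() == 1


class TestAnovaDuncan:
    def test_identical_groups_share_letter(self):
        groups = [(g, [5.0, 5.0, 5.0]) for g in "ABC"]
        _, _, letters = anova_duncan(groups)
        assert len(set(letters.values())) == 1

    def test_separated_groups_differ(self, rng):
        a = list(rng.normal(0, 1, 10))
        b = list(rng.normal(10, 1, 10))
        f, p, letters = anova_duncan([("a", a), ("b", b)])
        assert p < 1e-6
        assert letters["a"] != letters["b"]

    def test_letters_shift_invariant(self, rng):
        groups = [
            ("a", list(rng.normal(0, 1, 8))),
            ("b", list(rng.normal(1, 1, 8))),
            ("c", list(rng.normal(5, 1, 8))),
        ]
        _, _, letters = anova_duncan(groups)
        shifted = [(g, [v + 100 for v in vals]) for g, vals in groups]
        _, _, letters2 = anova_duncan(shifted)
        assert letters == letters2

    def test_compact_letter_display_valid(self, rng):
        """Groups sharing no letter must differ by at least the pairwise
        critical range; groups sharing a letter must not."""
        for trial in range(20):
            k = int(rng.integers(3, 6))
            groups = [
                (f"g{i}", list(rng.normal(rng.uniform(0, 4), 1, 6)))
                for i in range(k)
            ]
            f, p, letters = anova_duncan(groups)
            means = {g: np.mean(v) for g, v in groups}
            n = 6
            mse = np.mean([np.var(v, ddof=1) for _, v in groups])
            df_err = k * (n - 1)
            for i in range(k):
                for j in range(i + 1, k):
                    gi, gj = groups[i][0], groups[j][0]
                    shared = set(letters[gi]) & set(letters[gj])
                    if not shared:
                        # separated: difference exceeds the 2-span range
                        r2 = stats.studentized_range.ppf(0.95, 2, df_err) * (
                            mse / n
                        ) ** 0.5
                        assert abs(means[gi] - means[gj]) >= r2 * 0.999

    def test_null_false_separation_rate(self, rng):
        """Under the null (k=3 equal means), the fraction of simulations
        separating the extreme pair stays in the vicinity of alpha."""
        n_sim, k, n = 800, 3, 5
        hits = 0
        for _ in range(n_sim):
            groups = [(f"g{i}", list(rng.normal(0, 1, n))) for i in range(k)]
            _, _, letters = anova_duncan(groups)
            sets = [set(letters[f"g{i}"]) for i in range(k)]
            if any(
                not (sets[i] & sets[j])
                for i in range(k)
                for j in range(i + 1, k)
            ):
                hits += 1
        rate = hits / n_sim
        # Duncan's protection keeps the familywise rate near alpha; allow
        # generous Monte-Carlo slack
        assert 0.01 < rate < 0.15

    def test_zero_variance_letters_by_equality(self):
        groups = [("a", [3.0, 3.0]), ("b", [3.0, 3.0]), ("c", [5.0, 5.0])]
        f, p, letters = anova_duncan(groups)
        assert letters["a"] == letters["b"] != letters["c"]
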