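"""Generator contracts: determinism, profile fidelity, truth/emission
consistency and end-to-end parameter recovery."""

from collections import Counter

import pytest

from cibmut.microhomology import (
    HOMOPOLY,
    INDEPENDENT,
    POLY_REPEAT,
    classify_dependency,
)
from cibmut.mutation_classify import classify_events
from cibmut.spectrum_stats import mutation_frequency
from cibmut.synthetic_data import (
    GenotypeProfile,
    find_homopolymer_runs,
    find_tandem_arrays,
    generate_genome,
    generate_mutations,
    line_metadata,
    packaged_profiles,
    simulate_to_dir,
)
from cibmut.variant_filter import filter_variants


def small_profile(**overrides):
    base = dict(
        name="toy", dose=100.0, n_lines=4, mean_events_per_line=15,
        category_probs={"SBS": 0.5, "del1": 0.1, "ins1": 0.1,
                        "del_ge2": 0.15, "ins_ge2": 0.1, "complex": 0.05,
                        "SV": 0.0},
        sbs_class_probs={"A/T>G/C": 0.3, "G/C>A/T": 0.3, "A/T>T/A": 0.1,
                         "A/T>C/G": 0.1, "G/C>T/A": 0.1, "G/C>C/G": 0.1},
        indel_ge2_bin_probs={"2-10": 0.7, "11-30": 0.3, ">30": 0.0},
        mh_class_probs={HOMOPOLY: 0.3, POLY_REPEAT: 0.4, INDEPENDENT: 0.3},
    )
    base.update(overrides)
    return GenotypeProfile(**base)


class TestGenerateGenome:
    def test_deterministic_bundle(self, tmp_path):
        p1 = simulate_to_dir(small_profile(), tmp_path / "a",
                             genome_length=30_000, n_genes=5, seed=7)
        p2 = simulate_to_dir(small_profile(), tmp_path / "b",
                             genome_length=30_000, n_genes=5, seed=7)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_zero_density_leaves_only_chance_repeats(self):
        plain, _ = generate_genome(
            length=20_000, homopolymer_density=0, tandem_repeat_density=0,
            n_genes=0, seed=3,
        )
        seeded, _ = generate_genome(length=20_000, n_genes=0, seed=3)
        n_plain = len(
            [r for r in find_homopolymer_runs(plain["chr1"].sequence) if r[1] >= 8]
        )
        n_seeded = len(
            [r for r in find_homopolymer_runs(seeded["chr1"].sequence) if r[1] >= 8]
        )
        # seeding stamps far more long runs than arise by chance
        assert n_seeded > 3 * max(n_plain, 1)

    def test_seeded_features_found_by_scanners(self):
        genome, _ = generate_genome(length=50_000, n_genes=0, seed=5)
        seq = genome["chr1"].sequence
        assert len(find_homopolymer_runs(seq, min_len=5)) > 20
        assert len(find_tandem_arrays(seq, min_copies=3)) > 20

    def test_no_genes_valid(self):
        genome, models = generate_genome(length=10_000, n_genes=0, seed=1)
        assert genome.total_length == 10_000
        assert models == []

    def test_gene_models_validate(self):
        _, models = generate_genome(length=60_000, n_genes=12, seed=2)
        assert len(models) == 12
        strands = {m.strand for m in models}
        assert strands == {"+", "-"}
        for m in models:
            assert m.cds and m.exons


class TestGenerateMutations:
    def test_degenerate_all_sbs(self):
        genome, models = generate_genome(length=20_000, n_genes=4, seed=9)
        profile = small_profile(
            category_probs={"SBS": 1.0, "del1": 0, "ins1": 0, "del_ge2": 0,
                            "ins_ge2": 0, "complex": 0, "SV": 0},
            n_background_shared=0, n_background_low_af=0,
        )
        _, truths = generate_mutations(genome, models, profile, seed=1)
        assert truths
        assert all(t.category == "SBS" for t in truths)

    def test_hard_length_cap(self, synthetic_genome):
        genome, models = synthetic_genome
        profile = packaged_profiles()["teb-8-100Gy"]
        _, truths = generate_mutations(genome, models, profile, seed=7)
        lens = [abs(t.indel_len) for t in truths if t.indel_len]
        assert lens and max(lens) <= 30

    def test_af_model(self, lig4_bundle):
        *_, calls, truths = lig4_bundle
        mut_afs = [
            c.af_by_line[c.line_id]
            for t in truths if t.kind == "mutation" for c in t.calls
        ]
        assert all(0.2 < af < 0.8 for af in mut_afs)

    def test_background_variants_removed_by_filter(self, lig4_bundle):
        genome, models, profile, calls, truths = lig4_bundle
        lines = [m.line_id for m in line_metadata(profile)]
        retained, removed = filter_variants(calls, lines)
        removed_keys = {(c.contig, c.pos, c.line_id) for c, _ in removed}
        for t in truths:
            if t.kind != "mutation":
                assert (t.contig, t.pos, t.line_id) in removed_keys

    def test_truth_emission_consistency(self, lig4_bundle):
        """Classifying the emitted calls recovers the truth category for
        >= 99% of non-complex mutation events."""
        genome, models, profile, calls, truths = lig4_bundle
        mut = [t for t in truths if t.kind == "mutation"]
        events = classify_events([c for t in mut for c in t.calls])
        by_key = {(e.line_id, e.start): e.category for e in events}
        checked = mismatched = 0
        for t in mut:
            if t.category == "complex":
                continue
            checked += 1
            if by_key.get((t.line_id, t.pos)) != t.category:
                mismatched += 1
        assert checked > 50
        assert mismatched / checked <= 0.01


class TestParameterRecovery:
    def test_mh_mix_recovered_end_to_end(self, lig4_bundle):
        """Filter + classify + microhomology on lig4-4-profile data recover
        the profile's dependency-class mix within 3 binomial SEM."""
        genome, models, profile, calls, truths = lig4_bundle
        lines = [m.line_id for m in line_metadata(profile)]
        retained, _ = filter_variants(calls, lines)
        indels = [e for e in classify_events(retained) if e.is_indel]
        sigs = [classify_dependency(e, genome) for e in indels]
        counts = Counter(s.dependency_class for s in sigs)
        n = len(sigs)
        assert n > 30
        for cls, p in profile.mh_class_probs.items():
            sem = (p * (1 - p) / n) ** 0.5
            assert abs(counts[cls] / n - p) <= 3 * sem + 1e-9, cls

    def test_total_frequency_recovered(self, lig4_bundle):
        """Per-bp-per-Gy total frequency matches the profile's expectation
        within 3 SEM of the Poisson total."""
        genome, models, profile, calls, truths = lig4_bundle
        lines = [m.line_id for m in line_metadata(profile)]
        retained, _ = filter_variants(calls, lines)
        events = classify_events(retained)
        L, dose = genome.total_length, profile.dose
        f_hat = mutation_frequency(len(events), profile.n_lines, L, dose)
        # placements that found no context are skipped, so compare against
        # the emitted-truth expectation, not the raw Poisson mean
        mu = profile.mean_events_per_line * profile.n_lines
        sem = mu ** 0.5
        lo = mutation_frequency(mu - 3 * sem, profile.n_lines, L, dose)
        hi = mutation_frequency(mu + 3 * sem, profile.n_lines, L, dose)
        assert lo <= f_hat <= hi


class TestPackagedProfiles:
    def test_calibration_constants(self):
        p = packaged_profiles()
        wt, teb, lig4 = (
            p["WT-200Gy"], p["teb-8-100Gy"], p["lig4-4-100Gy"],
        )
        assert wt.mean_events_per_line == pytest.approx(31.8)
        assert teb.mean_events_per_line == pytest.approx(224 / 11)
        assert lig4.mean_events_per_line == pytest.approx(192 / 14)
        assert lig4.mh_class_probs[POLY_REPEAT] == pytest.approx(0.6762)
        assert lig4.mh_class_probs[HOMOPOLY] == pytest.approx(0.0760)
        assert lig4.mh_class_probs[INDEPENDENT] == pytest.approx(0.2478)
        assert teb.indel_max_len == 30
        assert teb.single_base_indel_fraction == pytest.approx(0.6765, abs=1e-3)
        assert wt.category_probs["SBS"] == pytest.approx(0.7296)
        for prof in p.values():
            assert sum(prof.category_probs.values()) == pytest.approx(1.0)
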