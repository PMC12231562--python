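"""Junction microhomology, repeat-context features and dependency classes,
checked against naive brute-force string scanners."""

import os.path

import pytest

from cibmut.errors import InvalidVariantError
from cibmut.genomic_io import VariantCall, normalize_indel
from cibmut.microhomology import (
    HOMOPOLY,
    INDEPENDENT,
    POLY_REPEAT,
    MHConfig,
    classify_dependency,
    homopolymer_run,
    junction_microhomology,
    tandem_repeat_context,
)
from cibmut.mutation_classify import MutationEvent

from conftest import make_genome

CFG = MHConfig()


def indel_event(genome, pos, ref, alt, line="L1"):
    call = normalize_indel(VariantCall("chr1", pos, ref, alt, line), genome)
    delta = call.indel_len
    cat = ("del1" if delta == -1 else "del_ge2") if delta < 0 else (
        "ins1" if delta == 1 else "ins_ge2"
    )
    return MutationEvent(
        line_id=line, contig="chr1", start=call.pos, end=call.end,
        category=cat, indel_len=delta, members=[call],
    )


# -- independent brute-force oracles ---------------------------------------

def oracle_mh(genome, event, cap=20):
    """Naive microhomology: common prefix with the 3' flank, common suffix
    with the 5' flank, via os.path.commonprefix."""
    seq = genome["chr1"].sequence
    call = event.members[0]
    if event.indel_len < 0:
        allele = call.ref_allele[1:]
        left = seq[: call.pos]          # up to and incl. anchor (0-based slice)
        right = seq[call.end:]
    else:
        allele = call.alt_allele[1:]
        left = seq[: call.pos]
        right = seq[call.pos:]
    k = min(len(allele), cap)
    pre = len(os.path.commonprefix([allele[:k], right[:k]]))
    suf = len(os.path.commonprefix([allele[::-1][:k], left[::-1][:k]]))
    return max(pre, suf)


def oracle_repeat(genome, event, cfg=CFG):
    """Exhaustive O(window^2) scan for a covering perfect tandem array."""
    seq = genome["chr1"].sequence
    call = event.members[0]
    if event.indel_len < 0:
        j_lo, j_hi = call.pos + 1, call.end  # 1-based deleted bases
        need_containment = True
    else:
        j_lo, j_hi = call.pos, call.pos + 1
        need_containment = False
    best = None
    for unit_len in range(2, cfg.repeat_unit_max + 1):
        for arr_start in range(
            max(1, j_lo - cfg.flank_window), j_hi + cfg.flank_window
        ):
            unit = seq[arr_start - 1 : arr_start - 1 + unit_len]
            if len(unit) < unit_len or len(set(unit)) == 1 or "N" in unit:
                continue
            copies = 1
            while (
                seq[arr_start - 1 + copies * unit_len :
                    arr_start - 1 + (copies + 1) * unit_len] == unit
            ):
                copies += 1
            if copies < cfg.repeat_min_copies:
                continue
            arr_end = arr_start + unit_len * copies - 1
            if need_containment:
                ok = arr_start <= j_lo and j_hi <= arr_end
            else:
                ok = not (arr_end < j_lo or arr_start > j_hi)
            if ok and (best is None or unit_len < len(best)):
                best = unit
    return best


class TestJunctionMicrohomology:
    def test_deletion_with_right_microhomology(self):
        # delete "AT" from C[AT]ATG: prefix of allele matches 3' flank
        genome = make_genome("GGGGGC" + "ATATG" + "GGGGG")
        ev = indel_event(genome, 6, "CAT", "C")
        mh, side = junction_microhomology(ev, genome, CFG)
        assert (mh, side) == (2, "right")

    def test_no_shared_bases(self):
        genome = make_genome("GGGGG" + "TCA" + "CCCCC")
        ev = indel_event(genome, 5, "GTCA", "G")
        mh, side = junction_microhomology(ev, genome, CFG)
        assert (mh, side) == (0, "none")

    def test_tandem_duplication_insertion(self):
        # insert CAG immediately 5' of reference CAGT...
        genome = make_genome("GGGGT" + "CAGT" + "GGGG")
        ev = indel_event(genome, 5, "T", "TCAG")
        mh, side = junction_microhomology(ev, genome, CFG)
        assert mh == 3

    def test_oracle_equivalence_fuzz(self, rng):
        """>= 1000 random junctions agree with the naive scanner."""
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.2, 0.1, 0.3])
                          for _ in range(80))
            genome = make_genome(seq)
            pos = int(rng.integers(5, 50))
            if rng.random() < 0.5:
                length = int(rng.integers(1, 8))
                ref = seq[pos - 1 : pos + length]
                ev = indel_event(genome, pos, ref, ref[0])
            else:
                ins = "".join(rng.choice(list("ACGT")) for _ in range(int(rng.integers(1, 8))))
                ev = indel_event(genome, pos, seq[pos - 1], seq[pos - 1] + ins)
            mh, _ = junction_microhomology(ev, genome, CFG)
            assert mh == oracle_mh(genome, ev)


class TestHomopolymerRun:
    def test_single_base_deletion_in_run(self):
        genome = make_genome("GGGGC" + "AAA" + "TGGGG")
        ev = indel_event(genome, 5, "CA", "C")
        assert homopolymer_run(ev, genome, CFG) == 3

    def test_two_base_deletion_in_longer_run(self):
        genome = make_genome("GGGG" + "GAAAAC" + "GGGG")
        ev = indel_event(genome, 5, "GAA", "G")
        assert homopolymer_run(ev, genome, CFG) == 4

    def test_sbs_rejected(self):
        genome = make_genome("ACGTACGT")
        ev = MutationEvent(
            line_id="L1", contig="chr1", start=3, end=3, category="SBS",
            sbs_class="G/C>A/T",
            members=[VariantCall("chr1", 3, "G", "A", "L1")],
        )
        with pytest.raises(InvalidVariantError):
            homopolymer_run(ev, genome, CFG)


class TestTandemRepeatContext:
    def test_single_base_deletion_in_dinucleotide_array(self):
        genome = make_genome("GGGGC" + "ATATATAT" + "CGGGG")
        ev = indel_event(genome, 6, "AT", "A")  # deletes the first T
        assert tandem_repeat_context(ev, genome, CFG) == "AT"

    def test_unit_deletion_from_cag_array(self):
        genome = make_genome("GGGGT" + "CAGCAGCAG" + "TGGGG")
        ev = indel_event(genome, 5, "TCAG", "T")
        assert tandem_repeat_context(ev, genome, CFG) == "CAG"

    def test_unique_context_returns_none(self):
        genome = make_genome("GATCCGTAGCTTACGGATCGTACG")
        ev = indel_event(genome, 8, "AGC", "A")
        assert tandem_repeat_context(ev, genome, CFG) is None

    def test_oracle_equivalence_fuzz(self, rng):
        """Random repeat-rich junctions agree with the exhaustive scan."""
        for _ in range(1000):
            # repeat-rich alphabet to exercise arrays frequently
            seq = "".join(rng.choice(list("ATAC")) for _ in range(70))
            genome = make_genome(seq)
            pos = int(rng.integers(5, 45))
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5:
                ref = seq[pos - 1 : pos + length]
                ev = indel_event(genome, pos, ref, ref[0])
            else:
                ins = "".join(rng.choice(list("ATAC")) for _ in range(length))
                ev = indel_event(genome, pos, seq[pos - 1], seq[pos - 1] + ins)
            got = tandem_repeat_context(ev, genome, CFG)
            expected = oracle_repeat(genome, ev)
            if expected is None:
                assert got is None
            else:
                assert got is not None and len(got) == len(expected)


class TestClassifyDependency:
    def test_homopoly(self):
        genome = make_genome("GGGGC" + "AAA" + "TGGGG")
        sig = classify_dependency(indel_event(genome, 5, "CA", "C"), genome, CFG)
        assert sig.dependency_class == HOMOPOLY
        assert sig.homopolymer_run == 3

    def test_polynucleotide_repeat_via_microhomology(self):
        genome = make_genome("GGGGGC" + "ATATG" + "GGGGG")
        sig = classify_dependency(indel_event(genome, 6, "CAT", "C"), genome, CFG)
        assert sig.dependency_class == POLY_REPEAT
        assert sig.mh_len == 2

    def test_independent(self):
        genome = make_genome("GGGGG" + "TCA" + "CCCCC")
        sig = classify_dependency(indel_event(genome, 5, "GTCA", "G"), genome, CFG)
        assert sig.dependency_class == INDEPENDENT
        assert sig.mh_len == 0

    def test_ambiguous_context_flagged(self):
        genome = make_genome("GGNGG" + "TCA" + "CCCCC")
        sig = classify_dependency(indel_event(genome, 5, "GTCA", "G"), genome, CFG)
        assert sig.ambiguous_context
        assert sig.dependency_class == INDEPENDENT


class TestInvariants:
    def test_tandem_unit_deletion_mh_equals_unit_length(self, rng):
        """Deleting one unit of a perfect 2-copy tandem repeat leaves
        junction microhomology of exactly the unit length."""
        for _ in range(100):
            unit_len = int(rng.integers(2, 7))
            unit = "".join(rng.choice(list("ACGT")) for _ in range(unit_len))
            if len(set(unit)) == 1:
                continue
            flank_l = "".join(rng.choice(list("G")) for _ in range(10))
            flank_r = "".join(rng.choice(list("C")) for _ in range(10))
            # guard against the unit blending into the flanks
            if unit[0] == flank_l[-1] or unit[-1] == flank_r[0] or unit[-1] == flank_l[-1]:
                continue
            seq = flank_l + unit * 2 + flank_r
            genome = make_genome(seq)
            ev = indel_event(genome, 10, flank_l[-1] + unit, flank_l[-1])
            mh, _ = junction_microhomology(ev, genome, CFG)
            assert mh == unit_len

    def test_representation_invariance(self):
        """A right-shifted InDel yields the same signature after
        normalization as its left-aligned form."""
        genome = make_genome("GGGGC" + "ATATATAT" + "CGGGG")
        left = indel_event(genome, 5, "CAT", "C")
        right = indel_event(genome, 9, "TAT", "T")  # same haplotype, shifted
        sig_l = classify_dependency(left, genome, CFG)
        sig_r = classify_dependency(right, genome, CFG)
        assert sig_l == sig_r
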