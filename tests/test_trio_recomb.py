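"""Maternal origin calling: allele tracing, segment voting, region verdicts,
junction pairs and pair fractions — with a brute-force consistency oracle and
the haplotype-relabeling symmetry property."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xstrlink.iohub import FEMALE, MALE, Genotype, MarkerLocus, SnpRecord, TrioRecord
from xstrlink.trio_recomb import (
    MaternalAllele,
    SegmentOriginCall,
    Verdict,
    call_region_origin,
    call_segment_origin,
    junction_pairs,
    maternal_allele_of_child,
    pair_recombination,
    select_informative_snps,
)

from conftest import gt, make_snp


class TestSelectInformativeSnps:
    def _snps(self):
        return [
            make_snp(pos, {"M": gt(0, 1)}, maf=maf)
            for pos, maf in [
                (100, 0.5), (200, 0.1), (300, 0.25), (400, 0.05),
                (500, 0.3), (600, 0.15), (700, 0.2), (800, 0.19),
                (900, 0.01), (1000, 0.45),
            ]
        ]

    def test_maf_and_window_filter(self):
        kept = select_informative_snps(self._snps(), (100, 1000), maf_min=0.25)
        assert [s.pos for s in kept] == [100, 300, 500, 1000]

    def test_empty_window(self):
        assert select_informative_snps(self._snps(), (2000, 3000), 0.0) == []

    def test_maf_zero_keeps_all_in_window(self):
        assert len(select_informative_snps(self._snps(), (100, 1000), 0.0)) == 10

    def test_raising_maf_min_never_adds_snps(self):
        snps = self._snps()
        prev = len(select_informative_snps(snps, (100, 1000), 0.0))
        for maf_min in (0.05, 0.1, 0.2, 0.3, 0.5):
            cur = len(select_informative_snps(snps, (100, 1000), maf_min))
            assert cur <= prev
            prev = cur


class TestMaternalAllele:
    def test_son_passthrough(self, son_trio):
        snp = make_snp(1, {"M1": gt(0, 1), "C1": gt(0)})
        assert maternal_allele_of_child(snp, son_trio) == 0

    def test_daughter_subtraction(self, daughter_trio):
        # daughter 0/1, father carries 1 -> maternal allele is 0
        snp = make_snp(1, {"M2": gt(0, 1), "P2": gt(1), "C2": gt(0, 1)})
        assert maternal_allele_of_child(snp, daughter_trio) == 0

    def test_daughter_homozygous(self, daughter_trio):
        snp = make_snp(1, {"M2": gt(0, 1), "P2": gt(1), "C2": gt(1, 1)})
        assert maternal_allele_of_child(snp, daughter_trio) == 1

    def test_daughter_homozygous_against_father_is_error(self, daughter_trio):
        # daughter 0/0 but father carries 1: no consistent assignment
        snp = make_snp(1, {"M2": gt(0, 1), "P2": gt(1), "C2": gt(0, 0)})
        assert (
            maternal_allele_of_child(snp, daughter_trio)
            is MaternalAllele.MENDELIAN_ERROR
        )

    def test_daughter_het_without_father_undetermined(self, daughter_trio):
        snp = make_snp(1, {"M2": gt(0, 1), "P2": gt(None), "C2": gt(0, 1)})
        assert (
            maternal_allele_of_child(snp, daughter_trio)
            is MaternalAllele.UNDETERMINED
        )

    def test_male_het_site_is_error(self, son_trio):
        snp = make_snp(1, {"M1": gt(0, 1), "C1": gt(0, 1, flag="male_het")})
        assert (
            maternal_allele_of_child(snp, son_trio)
            is MaternalAllele.MENDELIAN_ERROR
        )


class TestSegmentAndRegion:
    def test_single_snp_hap1(self, son_trio):
        snps = [make_snp(1, {"M1": gt(0, 1), "C1": gt(0)})]
        call = call_segment_origin(snps, son_trio)
        assert call.verdict == Verdict.HAP1
        assert call.n_informative_snps == 1

    def test_unanimous_hap2(self, son_trio):
        snps = [make_snp(p, {"M1": gt(0, 1), "C1": gt(1)}) for p in (1, 2, 3)]
        assert call_segment_origin(snps, son_trio).verdict == Verdict.HAP2

    def test_split_votes_discordant(self, son_trio):
        snps = [
            make_snp(1, {"M1": gt(0, 1), "C1": gt(0)}),
            make_snp(2, {"M1": gt(0, 1), "C1": gt(1)}),
        ]
        call = call_segment_origin(snps, son_trio)
        assert call.verdict == Verdict.DISCORDANT
        assert call.n_conflicting_snps == 1

    def test_homozygous_mother_uninformative(self, son_trio):
        snps = [make_snp(1, {"M1": gt(1, 1), "C1": gt(1)})]
        call = call_segment_origin(snps, son_trio)
        assert call.verdict == Verdict.UNINFORMATIVE
        assert call.n_informative_snps == 0

    def test_unphased_mother_cannot_vote(self, son_trio):
        snps = [make_snp(1, {"M1": gt(0, 1, phased=False, flag="unphased_het"),
                             "C1": gt(0)})]
        assert call_segment_origin(snps, son_trio).verdict == Verdict.UNINFORMATIVE

    def test_mendel_error_dropped_and_counted(self, daughter_trio):
        snps = [
            make_snp(1, {"M2": gt(0, 1), "P2": gt(1), "C2": gt(0, 0)}),  # error
            make_snp(2, {"M2": gt(0, 1), "P2": gt(1), "C2": gt(0, 1)}),  # HAP1
        ]
        call = call_segment_origin(snps, daughter_trio)
        assert call.verdict == Verdict.HAP1
        assert call.n_mendel_errors == 1

    def test_region_truth_table_exhaustive(self):
        """All 16 (up, down) verdict pairs against independently stated rules."""
        segment_verdicts = [
            Verdict.HAP1, Verdict.HAP2, Verdict.UNINFORMATIVE, Verdict.DISCORDANT
        ]
        hap = {Verdict.HAP1, Verdict.HAP2}
        for u in segment_verdicts:
            for d in segment_verdicts:
                got = call_region_origin(
                    SegmentOriginCall(u, 1 if u in hap else 0),
                    SegmentOriginCall(d, 1 if d in hap else 0),
                )
                if u == Verdict.DISCORDANT or d == Verdict.DISCORDANT:
                    want = Verdict.EXCLUDED
                elif u in hap and d in hap:
                    want = u if u == d else Verdict.EXCLUDED
                else:
                    want = Verdict.UNINFORMATIVE
                assert got == want, (u, d)


class TestJunctionPairs:
    def _panel(self, sizes):
        loci = []
        pos = 1000
        for g, size in enumerate(sizes):
            for i in range(size):
                loci.append(
                    MarkerLocus(f"G{g}L{i}", "chrX", pos, pos + 10, f"G{g}",
                                window_bp=100)
                )
                pos += 10_000
        return loci

    def test_between_group_boundary_markers(self):
        pairs = junction_pairs(self._panel([3, 3, 4]))
        assert pairs == [("G0L2", "G1L0"), ("G1L2", "G2L0")]

    def test_panel_group_sizes(self):
        loci = self._panel([3, 3, 4, 4, 3, 4, 4])
        assert len(junction_pairs(loci)) == 6
        assert len(junction_pairs(loci, intra_group=True)) == 18

    def test_single_group_no_pairs(self):
        assert junction_pairs(self._panel([5])) == []

    def test_interleaved_groups_rejected(self):
        loci = self._panel([2, 2])
        # move a G0 locus beyond G1
        bad = loci[:1] + loci[2:] + [
            MarkerLocus("G0Lx", "chrX", 10**6, 10**6 + 10, "G0", window_bp=100)
        ]
        with pytest.raises(ValueError, match="interleaved"):
            junction_pairs(bad)


class TestPairRecombination:
    def test_manual_count(self):
        va = {"t1": Verdict.HAP1, "t2": Verdict.HAP1, "t3": Verdict.HAP2,
              "t4": Verdict.HAP1}
        vb = {"t1": Verdict.HAP1, "t2": Verdict.HAP2, "t3": Verdict.HAP2,
              "t4": Verdict.UNINFORMATIVE}
        r = pair_recombination(va, vb)
        assert (r.k_recomb, r.n_informative) == (1, 3)
        assert r.n_uninformative == 1

    def test_identical_vectors_no_recombinants(self):
        v = {f"t{i}": Verdict.HAP1 if i % 2 else Verdict.HAP2 for i in range(20)}
        r = pair_recombination(v, dict(v))
        assert r.k_recomb == 0 and r.fraction == 0.0
        assert r.ci_low == 0.0

    def test_empty_is_nan_not_exception(self):
        r = pair_recombination({"t": Verdict.UNINFORMATIVE},
                               {"t": Verdict.HAP1})
        assert r.n_informative == 0 and math.isnan(r.fraction)

    def test_conservation_of_trios(self):
        rng = np.random.default_rng(5)
        opts = [Verdict.HAP1, Verdict.HAP2, Verdict.UNINFORMATIVE,
                Verdict.EXCLUDED]
        va = {f"t{i}": opts[rng.integers(4)] for i in range(100)}
        vb = {f"t{i}": opts[rng.integers(4)] for i in range(100)}
        r = pair_recombination(va, vb)
        assert r.n_informative + r.n_uninformative + r.n_excluded == 100


# ---------------------------------------------------------------------------
# brute-force oracle and symmetry property


def _oracle_segment_verdict(snps, trio):
    """Enumerate which maternal haplotypes are consistent with every
    informative site; the verdict follows from the consistent set alone."""
    consistent = {0, 1}
    any_informative = False
    for snp in snps:
        mother = snp.genotypes.get(trio.mother_id)
        if mother is None or not mother.is_het or mother.flag or not mother.phased:
            continue
        allele = maternal_allele_of_child(snp, trio)
        if allele is MaternalAllele.UNDETERMINED:
            continue
        if allele is MaternalAllele.MENDELIAN_ERROR:
            continue
        if allele not in mother.alleles:
            continue
        any_informative = True
        consistent &= {h for h in (0, 1) if mother.alleles[h] == allele}
    if not any_informative:
        return Verdict.UNINFORMATIVE
    if not consistent:
        return Verdict.DISCORDANT
    return Verdict.HAP1 if consistent == {0} else Verdict.HAP2


def _random_trio_segment(rng, n_snps):
    trio = TrioRecord("F", "C", "M", None, MALE)
    snps = []
    for pos in range(1, n_snps + 1):
        m = (int(rng.integers(2)), int(rng.integers(2)))
        mat = m[rng.integers(2)]
        # occasional undetermined / error-free mix
        child = mat if rng.random() < 0.9 else int(rng.integers(2))
        snps.append(
            make_snp(pos, {"M": Genotype((m[0], m[1])), "C": Genotype((child,))})
        )
    return snps, trio


def test_segment_verdicts_match_bruteforce_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(200):
        snps, trio = _random_trio_segment(rng, int(rng.integers(1, 6)))
        got = call_segment_origin(snps, trio).verdict
        assert got == _oracle_segment_verdict(snps, trio)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_haplotype_relabeling_flips_verdicts_keeps_fractions(seed):
    """Swapping the mother's phased allele order flips HAP1<->HAP2 everywhere
    but leaves k_recomb and n_informative unchanged."""
    rng = np.random.default_rng(seed)
    flip_map = {Verdict.HAP1: Verdict.HAP2, Verdict.HAP2: Verdict.HAP1}

    def build(swap):
        verdicts = {}
        for t in range(8):
            trio = TrioRecord("F", f"C{t}", f"M{t}", None, MALE)
            rng_t = np.random.default_rng(seed * 131 + t)
            snps = []
            for pos in range(1, 5):
                m = (int(rng_t.integers(2)), int(rng_t.integers(2)))
                child = m[rng_t.integers(2)]
                mm = (m[1], m[0]) if swap else m
                snps.append(
                    make_snp(pos, {f"M{t}": Genotype(mm),
                                   f"C{t}": Genotype((child,))})
                )
            verdicts[f"C{t}"] = call_segment_origin(snps, trio).verdict
        return verdicts

    orig = build(swap=False)
    flipped = build(swap=True)
    for tid in orig:
        assert flipped[tid] == flip_map.get(orig[tid], orig[tid])
    ra = pair_recombination(orig, orig)
    rb = pair_recombination(flipped, flipped)
    assert (ra.k_recomb, ra.n_informative) == (rb.k_recomb, rb.n_informative)
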