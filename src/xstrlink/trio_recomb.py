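"""Maternal haplotype-of-origin calling and trio-based recombination fractions.

The method traces, for each target STR locus and each mother/child trio,
which of the mother's two phased X haplotypes carried the chromosomal region
around the locus into the child. Sons reveal the transmitted maternal allele
directly (they carry a single maternal X); daughters reveal it by subtracting
the father's hemizygous allele from their genotype. Each SNP at which the
mother is heterozygous and the child's maternal allele is determined casts a
vote for maternal haplotype 1 or 2; the upstream and downstream flanking
windows are called separately and must agree for the region to be assigned.

The calling is deliberately conservative:

* a segment with zero informative SNPs is UNINFORMATIVE (a mother homozygous
  across the window gives no signal);
* conflicting votes within one segment make it DISCORDANT;
* upstream/downstream segments naming different haplotypes — a crossover
  landing inside the searched span, which leaves the STR's own phase
  ambiguous — EXCLUDE the trio for that locus instead of guessing.

A recombination between two loci is scored when a trio's region verdicts at
the two loci name different maternal haplotypes; the recombination fraction
is the recombinant share of informative trios with an exact binomial CI.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import iohub, statkit
from .iohub import Genotype, MarkerLocus, SnpRecord, TrioRecord

__all__ = [
    "Verdict",
    "MaternalAllele",
    "SegmentOriginCall",
    "RegionOriginCall",
    "PairRecombResult",
    "select_informative_snps",
    "maternal_allele_of_child",
    "call_segment_origin",
    "call_region_origin",
    "call_trio_region",
    "junction_pairs",
    "pair_recombination",
    "analyze_cohort",
]


class Verdict(str, enum.Enum):
    HAP1 = "HAP1"
    HAP2 = "HAP2"
    UNINFORMATIVE = "UNINFORMATIVE"
    DISCORDANT = "DISCORDANT"  # segment-level only
    EXCLUDED = "EXCLUDED"  # region-level only

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class MaternalAllele(enum.Enum):
    """Sentinel outcomes of maternal-allele tracing at one SNP."""

    UNDETERMINED = enum.auto()
    MENDELIAN_ERROR = enum.auto()


@dataclass(frozen=True)
class SegmentOriginCall:
    """Verdict for one flanking segment of one trio.

    A HAP1/HAP2 verdict requires at least one informative SNP and unanimity
    (``n_conflicting_snps == 0``); UNINFORMATIVE means zero informative SNPs.
    """

    verdict: Verdict
    n_informative_snps: int = 0
    n_conflicting_snps: int = 0
    n_mendel_errors: int = 0


@dataclass(frozen=True)
class RegionOriginCall:
    """Combined verdict for the region harboring one locus in one trio."""

    locus: str
    trio: str
    upstream: SegmentOriginCall
    downstream: SegmentOriginCall
    verdict: Verdict


@dataclass
class PairRecombResult:
    """Recombination fraction between two loci over a trio cohort."""

    locus_a: str
    locus_b: str
    k_recomb: int
    n_informative: int
    fraction: float  # NaN when n_informative == 0
    ci_low: float
    ci_high: float
    n_uninformative: int = 0
    n_excluded: int = 0

    @property
    def pair(self) -> str:
        return f"{self.locus_a}-{self.locus_b}"


def select_informative_snps(
    snps: Sequence[SnpRecord],
    window: tuple[int, int],
    maf_min: float = 0.2,
) -> list[SnpRecord]:
    """Retain biallelic SNPs inside ``window`` with cohort MAF >= ``maf_min``.

    ``window`` is 1-based inclusive; input order is preserved. The 0.2
    default keeps the expected maternal heterozygosity per retained site
    above 2*0.2*0.8 = 0.32, so a 10 kb window at typical SNP density almost
    always contains an informative site.
    """
    lo, hi = window
    return [s for s in snps if lo <= s.pos <= hi and s.maf >= maf_min]


def maternal_allele_of_child(
    snp: SnpRecord, trio: TrioRecord
) -> int | MaternalAllele:
    """Trace the maternal allele transmitted to the child at one SNP.

    Sons pass through their hemizygous allele. A homozygous daughter's
    maternal allele is her single allele (her genotype must also contain the
    father's allele, else the site is a Mendelian error). A heterozygous
    daughter's maternal allele is the one *not* carried by her hemizygous
    father; with the father missing it stays UNDETERMINED.
    """
    child = snp.genotypes.get(trio.child_id)
    if child is None or child.is_missing or child.flag == "male_het":
        return (
            MaternalAllele.MENDELIAN_ERROR
            if child is not None and child.flag == "male_het"
            else MaternalAllele.UNDETERMINED
        )
    if trio.child_sex == iohub.MALE:
        a = child.single_allele
        if a is None:  # diploid-coded male not normalized upstream
            return MaternalAllele.UNDETERMINED
        return a
    # daughter
    if len(child.alleles) != 2:
        return MaternalAllele.UNDETERMINED
    c1, c2 = child.alleles
    father = snp.genotypes.get(trio.father_id) if trio.father_id else None
    f = None
    if father is not None and not father.is_missing and father.flag != "male_het":
        f = father.single_allele
        if f is None and len(set(father.alleles)) == 1:
            f = father.alleles[0]
    if c1 == c2:
        if f is not None and f != c1:
            return MaternalAllele.MENDELIAN_ERROR
        return c1
    if child.flag == "unphased_het" and f is None:
        return MaternalAllele.UNDETERMINED
    if f is None:
        return MaternalAllele.UNDETERMINED
    if f == c1:
        return c2
    if f == c2:
        return c1
    return MaternalAllele.MENDELIAN_ERROR


def call_segment_origin(
    snps: Sequence[SnpRecord], trio: TrioRecord
) -> SegmentOriginCall:
    """Vote the maternal haplotype-of-origin of one flanking segment.

    Each SNP with a heterozygous *phased* mother and a determined child
    maternal allele votes HAP1 if the allele matches the mother's first
    phased allele, HAP2 otherwise. Unanimous votes give that verdict; zero
    votes UNINFORMATIVE; any split DISCORDANT. Mendelian-error sites are
    dropped from voting and tallied.
    """
    votes1 = votes2 = 0
    n_mendel = 0
    for snp in snps:
        mother = snp.genotypes.get(trio.mother_id)
        if mother is None or not mother.is_het:
            continue
        if mother.flag is not None or not mother.phased:
            continue
        allele = maternal_allele_of_child(snp, trio)
        if allele is MaternalAllele.UNDETERMINED:
            continue
        if allele is MaternalAllele.MENDELIAN_ERROR:
            n_mendel += 1
            continue
        if allele not in mother.alleles:
            n_mendel += 1
            continue
        if allele == mother.alleles[0]:
            votes1 += 1
        else:
            votes2 += 1
    n_inf = votes1 + votes2
    if n_inf == 0:
        verdict = Verdict.UNINFORMATIVE
    elif votes1 and votes2:
        verdict = Verdict.DISCORDANT
    else:
        verdict = Verdict.HAP1 if votes1 else Verdict.HAP2
    return SegmentOriginCall(
        verdict=verdict,
        n_informative_snps=n_inf,
        n_conflicting_snps=min(votes1, votes2),
        n_mendel_errors=n_mendel,
    )


def call_region_origin(
    up: SegmentOriginCall, down: SegmentOriginCall
) -> Verdict:
    """Combine the two flanking-segment verdicts into a region verdict.

    Agreeing haplotype calls assign the region; opposite calls (a crossover
    inside the span) or any discordant segment EXCLUDE the trio for this
    locus; everything else is UNINFORMATIVE.
    """
    u, d = up.verdict, down.verdict
    hap = {Verdict.HAP1, Verdict.HAP2}
    if Verdict.DISCORDANT in (u, d):
        return Verdict.EXCLUDED
    if u in hap and d in hap:
        return u if u == d else Verdict.EXCLUDED
    if u in hap or d in hap:
        return Verdict.UNINFORMATIVE
    return Verdict.UNINFORMATIVE


def call_trio_region(
    snps: Sequence[SnpRecord],
    trio: TrioRecord,
    locus: MarkerLocus,
    maf_min: float = 0.2,
) -> RegionOriginCall:
    """Call the maternal origin of the region around ``locus`` for one trio."""
    up_snps = select_informative_snps(snps, locus.upstream_window, maf_min)
    down_snps = select_informative_snps(snps, locus.downstream_window, maf_min)
    up = call_segment_origin(up_snps, trio)
    down = call_segment_origin(down_snps, trio)
    return RegionOriginCall(
        locus=locus.name,
        trio=trio.child_id,
        upstream=up,
        downstream=down,
        verdict=call_region_origin(up, down),
    )


def junction_pairs(
    markers: Sequence[MarkerLocus], intra_group: bool = False
) -> list[tuple[str, str]]:
    """Boundary-marker pairs between adjacent linkage groups.

    For each adjacent pair of groups along the chromosome the junction is
    (last locus of the left group, first locus of the right group). With
    ``intra_group`` set, all within-group adjacent pairs are returned
    instead. Loci of one group must be contiguous along the chromosome.
    """
    ordered = sorted(markers, key=lambda m: (m.chrom, m.start, m.end))
    groups: list[tuple[str, list[MarkerLocus]]] = []
    for m in ordered:
        if not groups or groups[-1][0] != m.linkage_group:
            groups.append((m.linkage_group, []))
        groups[-1][1].append(m)
    seen = [g for g, _ in groups]
    if len(set(seen)) != len(seen):
        raise ValueError(
            "linkage groups are interleaved along the chromosome: "
            + " -> ".join(seen)
        )
    pairs: list[tuple[str, str]] = []
    if intra_group:
        for _, loci in groups:
            pairs.extend(
                (loci[i].name, loci[i + 1].name) for i in range(len(loci) - 1)
            )
    else:
        for left, right in zip(groups, groups[1:]):
            pairs.append((left[1][-1].name, right[1][0].name))
    return pairs


def pair_recombination(
    calls_a: Mapping[str, Verdict],
    calls_b: Mapping[str, Verdict],
    alpha: float = 0.05,
    locus_a: str = "A",
    locus_b: str = "B",
) -> PairRecombResult:
    """Recombination fraction between two loci from per-trio region verdicts.

    A trio is informative when both verdicts are haplotype assignments;
    it is recombinant when they name different maternal haplotypes. The CI
    is exact binomial. ``n_informative == 0`` yields NaN fraction/CI.
    """
    hap = {Verdict.HAP1, Verdict.HAP2}
    k = n = n_unf = n_exc = 0
    for trio_id, va in calls_a.items():
        vb = calls_b.get(trio_id)
        if vb is None:
            continue
        if va in hap and vb in hap:
            n += 1
            if va != vb:
                k += 1
        elif Verdict.EXCLUDED in (va, vb):
            n_exc += 1
        else:
            n_unf += 1
    if n == 0:
        return PairRecombResult(
            locus_a, locus_b, 0, 0, float("nan"), float("nan"), float("nan"),
            n_uninformative=n_unf, n_excluded=n_exc,
        )
    ci = statkit.clopper_pearson(k, n, alpha)
    return PairRecombResult(
        locus_a, locus_b, k, n, k / n, ci.low, ci.high,
        n_uninformative=n_unf, n_excluded=n_exc,
    )


# ---------------------------------------------------------------------------
# cohort orchestration


@dataclass
class CohortResult:
    """Full output of a trio-cohort analysis."""

    pair_results: list[PairRecombResult]
    region_calls: pd.DataFrame  # trio, locus, up/down verdicts + counts
    qc: dict = field(default_factory=dict)

    def pair_report_rows(self) -> list[dict]:
        rows = []
        for r in self.pair_results:
            rows.append(
                {
                    "pair": r.pair,
                    "k_recomb": r.k_recomb,
                    "n_informative": r.n_informative,
                    "fraction_pct": 100.0 * r.fraction,
                    "ci_low_pct": 100.0 * r.ci_low,
                    "ci_high_pct": 100.0 * r.ci_high,
                }
            )
        return rows


def analyze_cohort(
    vcf_path: str | Path,
    ped_path: str | Path,
    markers: Sequence[MarkerLocus] | str | Path,
    window_bp: int | None = None,
    maf_min: float = 0.2,
    alpha: float = 0.05,
    intra_group: bool = False,
    mendel_error_max: float = 0.10,
) -> CohortResult:
    """Run the full trio pipeline: VCF + pedigree + markers -> pair fractions.

    ``mendel_error_max`` is a whole-trio QC gate: a trio whose share of
    Mendelian-error sites (across all segments) exceeds it has every region
    call EXCLUDED — such trios indicate sample swaps or systematic genotyping
    problems rather than isolated mutations.
    """
    if not isinstance(markers, (list, tuple)):
        markers = iohub.read_marker_table(markers)
    if window_bp is not None:
        markers = [
            MarkerLocus(m.name, m.chrom, m.start, m.end, m.linkage_group, window_bp)
            for m in markers
        ]
    ped = iohub.read_pedigree(ped_path)
    sex = ped.sex_by_sample()
    trios = iohub.trios_from_pedigree(ped)
    sample_ids = sorted({s for t in trios for s in t.sample_ids})

    chroms = {m.chrom for m in markers}
    if len(chroms) != 1:
        raise ValueError("all markers must lie on one chromosome")
    chrom = chroms.pop()
    lo = min(m.searched_span[0] for m in markers)
    hi = max(m.searched_span[1] for m in markers)
    snps = iohub.read_phased_vcf(
        vcf_path, region=(chrom, lo, hi), sample_ids=sample_ids, sex_by_sample=sex
    )

    calls: dict[str, dict[str, RegionOriginCall]] = defaultdict(dict)
    mendel_by_trio: dict[str, int] = defaultdict(int)
    voted_by_trio: dict[str, int] = defaultdict(int)
    for locus in markers:
        span = locus.searched_span
        local = [s for s in snps if span[0] <= s.pos <= span[1]]
        for trio in trios:
            call = call_trio_region(local, trio, locus, maf_min)
            calls[locus.name][trio.child_id] = call
            errs = call.upstream.n_mendel_errors + call.downstream.n_mendel_errors
            inf = call.upstream.n_informative_snps + call.downstream.n_informative_snps
            mendel_by_trio[trio.child_id] += errs
            voted_by_trio[trio.child_id] += inf + errs

    flagged = {
        tid
        for tid in mendel_by_trio
        if voted_by_trio[tid] > 0
        and mendel_by_trio[tid] / voted_by_trio[tid] > mendel_error_max
    }
    verdicts: dict[str, dict[str, Verdict]] = {
        ln: {
            tid: (Verdict.EXCLUDED if tid in flagged else c.verdict)
            for tid, c in per_trio.items()
        }
        for ln, per_trio in calls.items()
    }

    pairs = junction_pairs(markers, intra_group=intra_group)
    by_name = {m.name: m for m in markers}
    results = [
        pair_recombination(
            verdicts[a], verdicts[b], alpha, locus_a=a, locus_b=b
        )
        for a, b in pairs
    ]

    rows = []
    for ln, per_trio in calls.items():
        for tid, c in per_trio.items():
            rows.append(
                {
                    "trio": tid,
                    "locus": ln,
                    "pos": by_name[ln].start,
                    "up_verdict": str(c.upstream.verdict),
                    "down_verdict": str(c.downstream.verdict),
                    "verdict": "EXCLUDED" if tid in flagged else str(c.verdict),
                    "n_snps_up": c.upstream.n_informative_snps,
                    "n_snps_down": c.downstream.n_informative_snps,
                }
            )
    region_df = pd.DataFrame(rows).sort_values(["pos", "trio"]).drop(columns="pos")
    qc = {
        "n_trios": len(trios),
        "n_snps_loaded": len(snps),
        "n_mendel_error_sites": int(sum(mendel_by_trio.values())),
        "n_trios_flagged_mendel": len(flagged),
        "window_bp": markers[0].window_bp if markers else None,
        "maf_min": maf_min,
        "alpha": alpha,
    }
    return CohortResult(pair_results=results, region_calls=region_df, qc=qc)
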