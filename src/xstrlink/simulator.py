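"""Synthetic phased trio cohorts and STR family data with known crossover truth.

The generator mirrors the study design the analysis modules expect:

* a cohort of mother/child trios (father included only for daughters) with
  phased SNPs in the flanking windows of each target locus, written as
  VCF 4.2 + 5-column pedigree + marker table;
* two-generation X-STR families whose composition follows the observed
  family table (22 of mother+father+2 daughters, 21 of mother+2 sons, ...).

Meioses use a no-interference crossover process: the transmitted maternal
haplotype starts from a fair coin and switches between adjacent locus
segments independently with the per-interval recombination probability
theta_i. Interference is irrelevant here because every downstream quantity
is a between-locus switch indicator. Founder haplotypes are drawn under
linkage equilibrium by default; a two-ancestor mosaic mode creates genuine
LD for decay-curve testing. Every draw flows from one seed, so identical
configurations produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import iohub
from .iohub import FEMALE, MALE, MarkerLocus, PedigreeRecord, PedigreeTable
from .markers import CHROM_X_LENGTH, default_panel

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "SimulatedFamilies",
    "simulate_maternal_haplotypes",
    "simulate_mosaic_haplotype_sample",
    "simulate_meiosis",
    "simulate_trio_cohort",
    "simulate_str_families",
    "default_genetic_map",
    "DEFAULT_FAMILY_STRUCTURES",
]

# (fathers, mothers, daughters, sons, n_families) — the observed composition
# of the 66 genotyped two-generation families.
DEFAULT_FAMILY_STRUCTURES: list[tuple[int, int, int, int, int]] = [
    (1, 1, 2, 0, 22),
    (0, 1, 0, 2, 21),
    (1, 1, 1, 1, 20),
    (0, 1, 0, 3, 1),
    (1, 1, 1, 2, 1),
    (1, 1, 2, 1, 1),
]

_DEFAULT_STR_FREQS = {
    "10": 0.05, "11": 0.10, "12": 0.20, "13": 0.30,
    "14": 0.20, "15": 0.10, "16": 0.05,
}


def default_genetic_map(
    loci: Sequence[MarkerLocus],
    theta_between: float = 0.5,
    theta_within: float = 0.01,
) -> list[float]:
    """Per-interval switch probabilities for consecutive loci: ``theta_within``
    inside a linkage group, ``theta_between`` across group boundaries."""
    thetas = []
    for a, b in zip(loci, loci[1:]):
        thetas.append(
            theta_within if a.linkage_group == b.linkage_group else theta_between
        )
    return thetas


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults reproduce the analysed designs: 602 SNP trios over the
    25-locus / 7-group panel with free recombination between groups, and 66
    STR families with the observed composition. ``maf_range`` spans common
    variation (uniform 0.05–0.5); the trio pipeline then applies its own
    0.2 informativeness cutoff, as on real data. ``snp_density`` of
    1 SNP/kb in the flanking windows matches the high-coverage call rate of
    common variants at the 0.2 MAF threshold closely enough to leave every
    10 kb segment informative for most mothers.
    """

    n_trios: int = 602
    child_sex_ratio: float = 0.5  # probability a trio child is male
    loci: list[MarkerLocus] = field(default_factory=default_panel)
    snp_density: float = 1.0  # SNPs per kb inside flanking windows
    maf_range: tuple[float, float] = (0.05, 0.5)
    genetic_map: list[float] | None = None  # per adjacent-locus interval
    theta_between: float = 0.5
    theta_within: float = 0.01
    gene_conversion_rate: float = 0.0  # per locus per meiosis; <=1 kb tract
    # STR families
    family_structures: list[tuple[int, int, int, int, int]] = field(
        default_factory=lambda: [t for t in DEFAULT_FAMILY_STRUCTURES]
    )
    str_loci: list[str] = field(default_factory=lambda: ["A", "B"])
    str_thetas: list[float] = field(default_factory=lambda: [0.05])
    str_allele_freqs: dict[str, dict[str, float]] | None = None
    mutation_rate: float = 0.0  # per locus per meiosis, +/- one repeat
    seed: int = 0

    def resolved_map(self) -> list[float]:
        gm = (
            self.genetic_map
            if self.genetic_map is not None
            else default_genetic_map(self.loci, self.theta_between, self.theta_within)
        )
        if len(gm) != len(self.loci) - 1:
            raise ValueError("genetic_map must have one theta per locus interval")
        if any(not 0.0 <= t <= 0.5 for t in gm):
            raise ValueError("all interval thetas must lie in [0, 0.5]")
        return list(gm)


# ---------------------------------------------------------------------------
# site layout and haplotypes


@dataclass
class SiteLayout:
    """SNP positions, population frequencies and locus-segment assignment."""

    positions: np.ndarray  # (n_sites,) bp, ascending
    freqs: np.ndarray  # (n_sites,) ALT allele frequency
    segment_ids: np.ndarray  # (n_sites,) index of the harboring locus


def _build_layout(config: SimConfig, rng: np.random.Generator) -> SiteLayout:
    positions: list[int] = []
    segments: list[int] = []
    lo_maf, hi_maf = config.maf_range
    for idx, locus in enumerate(sorted(config.loci, key=lambda m: m.start)):
        for win in (locus.upstream_window, locus.downstream_window):
            lo, hi = win
            hi = min(hi, CHROM_X_LENGTH)
            if hi < lo:
                continue
            span = hi - lo + 1
            n = rng.poisson(config.snp_density * span / 1000.0)
            pos = np.unique(rng.integers(lo, hi + 1, size=n))
            positions.extend(int(p) for p in pos)
            segments.extend([idx] * len(pos))
    order = np.argsort(positions, kind="stable")
    positions_arr = np.asarray(positions, dtype=np.int64)[order]
    segments_arr = np.asarray(segments, dtype=np.int64)[order]
    freqs = rng.uniform(lo_maf, hi_maf, size=positions_arr.size)
    # random side of the frequency spectrum so REF is not always major
    flip = rng.random(positions_arr.size) < 0.5
    freqs = np.where(flip, 1.0 - freqs, freqs)
    return SiteLayout(positions=positions_arr, freqs=freqs, segment_ids=segments_arr)


def simulate_maternal_haplotypes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    layout: SiteLayout | None = None,
    ancestors: np.ndarray | None = None,
    mosaic_switch_per_bp: float = 0.0,
) -> tuple[SiteLayout, np.ndarray]:
    """Draw one mother's phased haplotype pair over the configured layout.

    Default mode draws alleles independently per site from the population
    frequency (linkage equilibrium). Mosaic mode instead copies each
    haplotype from a shared panel of ``ancestors`` (rows = ancestral
    haplotypes) with switch probability ``mosaic_switch_per_bp`` per base
    pair; because the whole cohort copies from the same few founders, this
    creates genuine distance-dependent LD for decay analyses.

    Returns the layout and a (2, n_sites) 0/1 array; row 0 is haplotype 1.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    layout = _build_layout(config, rng) if layout is None else layout
    n = layout.positions.size
    if ancestors is not None and mosaic_switch_per_bp > 0:
        n_anc = ancestors.shape[0]
        haps = np.empty((2, n), dtype=np.int8)
        gaps = np.diff(layout.positions)
        for h in range(2):
            src = int(rng.integers(n_anc))
            idxs = np.empty(n, dtype=np.int64)
            if n:
                idxs[0] = src
            switch = rng.random(n - 1) < (1 - np.exp(-mosaic_switch_per_bp * gaps))
            for i, sw in enumerate(switch, start=1):
                if sw:
                    src = int(rng.integers(n_anc))
                idxs[i] = src
            haps[h] = ancestors[idxs, np.arange(n)]
        return layout, haps
    haps = (rng.random((2, n)) < layout.freqs).astype(np.int8)
    return layout, haps


def simulate_mosaic_haplotype_sample(
    config: SimConfig,
    n_haplotypes: int,
    n_ancestors: int = 4,
    switch_per_bp: float = 1e-4,
) -> tuple[SiteLayout, np.ndarray]:
    """A sample of haplotypes copied from a common founder panel.

    Every haplotype is an ancestral mosaic over the same ``n_ancestors``
    founders, so allelic association decays with distance at a rate set by
    ``switch_per_bp``. Returns the layout and an (n_haplotypes, n_sites)
    matrix, ready for :func:`xstrlink.ld_analysis.ld_decay`.
    """
    rng = np.random.default_rng(config.seed)
    layout = _build_layout(config, rng)
    anc = (rng.random((n_ancestors, layout.positions.size)) < layout.freqs).astype(
        np.int8
    )
    rows = []
    for _ in range((n_haplotypes + 1) // 2):
        _, pair = simulate_maternal_haplotypes(
            config, rng, layout=layout, ancestors=anc,
            mosaic_switch_per_bp=switch_per_bp,
        )
        rows.extend(pair)
    return layout, np.asarray(rows[:n_haplotypes], dtype=np.int8)


# ---------------------------------------------------------------------------
# meiosis engine


@dataclass(frozen=True)
class Meiosis:
    """One simulated maternal gamete."""

    alleles: np.ndarray  # (n_sites,) transmitted alleles
    segment_hap: np.ndarray  # (n_segments,) transmitted haplotype index (0/1)
    crossovers: tuple[int, ...]  # bp positions, one per switch


def simulate_meiosis(
    hap1: np.ndarray,
    hap2: np.ndarray,
    segment_ids: np.ndarray,
    thetas: Sequence[float],
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> Meiosis:
    """Transmit one maternal gamete under the no-interference model.

    The starting haplotype is a fair coin; each of the ``len(thetas)``
    inter-segment intervals switches haplotype independently with
    probability ``thetas[i]``. When ``positions`` is given, each crossover
    is placed uniformly between the bounding segments' nearest sites.
    """
    n_seg = int(segment_ids.max()) + 1 if segment_ids.size else 0
    if len(thetas) != max(n_seg - 1, 0):
        raise ValueError("need one theta per interval between segments")
    start = int(rng.integers(2))
    switches = rng.random(len(thetas)) < np.asarray(thetas)
    seg_hap = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
    seg_hap = seg_hap.astype(np.int8)
    alleles = np.where(seg_hap[segment_ids] == 0, hap1, hap2)
    crossovers: list[int] = []
    if positions is not None:
        for i, sw in enumerate(switches):
            if not sw:
                continue
            left = positions[segment_ids == i]
            right = positions[segment_ids == i + 1]
            lo = int(left.max()) if left.size else 0
            hi = int(right.min()) if right.size else lo + 1
            crossovers.append(int(rng.integers(lo, max(hi, lo + 1))))
    elif switches.any():
        crossovers = [i for i, sw in enumerate(switches) if sw]
    return Meiosis(
        alleles=alleles.astype(np.int8),
        segment_hap=seg_hap,
        crossovers=tuple(crossovers),
    )


# ---------------------------------------------------------------------------
# trio cohort


@dataclass
class SimulatedCohort:
    """An in-memory phased trio cohort plus its crossover truth."""

    config: SimConfig
    layout: SiteLayout
    loci: list[MarkerLocus]
    samples: list[str]  # VCF column order
    sample_sex: dict[str, str]
    genotypes: dict[str, np.ndarray]  # sample -> (ploidy, n_sites) int8
    pedigree: PedigreeTable
    truth: pd.DataFrame  # trio, locus, hap_index

    def truth_recombinants(self, locus_a: str, locus_b: str) -> tuple[int, int]:
        """(recombinant, total) meioses between two loci from the truth table."""
        t = self.truth.pivot(index="trio", columns="locus", values="hap_index")
        sub = t[[locus_a, locus_b]].dropna()
        k = int((sub[locus_a] != sub[locus_b]).sum())
        return k, len(sub)

    # -- writers ----------------------------------------------------------

    def write_vcf(self, path: str | Path) -> None:
        chrom = self.loci[0].chrom
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={CHROM_X_LENGTH}>\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
            if self.samples:
                header += "\tFORMAT\t" + "\t".join(self.samples)
            fh.write(header + "\n")
            for i, pos in enumerate(self.layout.positions):
                cols = [chrom, str(int(pos)), ".", "A", "G", ".", "PASS", "."]
                if self.samples:
                    cols.append("GT")
                for s in self.samples:
                    g = self.genotypes[s]
                    if g.shape[0] == 1:
                        cols.append(str(int(g[0, i])))
                    else:
                        cols.append(f"{int(g[0, i])}|{int(g[1, i])}")
                fh.write("\t".join(cols) + "\n")

    def write_ped(self, path: str | Path) -> None:
        iohub.write_pedigree(self.pedigree, path)

    def write_markers(self, path: str | Path) -> None:
        iohub.write_marker_table(self.loci, path)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_trio_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a phased trio cohort with recorded crossover truth.

    Mothers receive two phased haplotypes; fathers an independent single
    haplotype; sons the maternal gamete alone (no father sample is emitted
    for them); daughters the maternal gamete phased against the full
    paternal haplotype (maternal first). The truth table records the
    transmitted maternal haplotype index at every locus of every trio.
    """
    rng = np.random.default_rng(config.seed)
    loci = sorted(config.loci, key=lambda m: m.start)
    thetas = config.resolved_map()
    if config.n_trios > 0:
        layout = _build_layout(config, rng)
    else:
        layout = SiteLayout(
            positions=np.empty(0, dtype=np.int64),
            freqs=np.empty(0),
            segment_ids=np.empty(0, dtype=np.int64),
        )
    n_sites = layout.positions.size

    samples: list[str] = []
    sample_sex: dict[str, str] = {}
    genotypes: dict[str, np.ndarray] = {}
    ped_records: list[PedigreeRecord] = []
    truth_rows: list[dict] = []

    for t in range(config.n_trios):
        fam = f"F{t:04d}"
        mid, pid, cid = f"M{t:04d}", f"P{t:04d}", f"C{t:04d}"
        _, mother = simulate_maternal_haplotypes(config, rng, layout=layout)
        is_son = rng.random() < config.child_sex_ratio
        meiosis = simulate_meiosis(
            mother[0], mother[1], layout.segment_ids, thetas, rng,
            positions=layout.positions,
        )
        gamete = meiosis.alleles.copy()
        seg_hap = meiosis.segment_hap.copy()
        if config.gene_conversion_rate > 0:
            _apply_gene_conversion(
                gamete, mother, layout, loci, config.gene_conversion_rate, rng
            )

        samples.append(mid)
        sample_sex[mid] = FEMALE
        genotypes[mid] = mother
        ped_records.append(PedigreeRecord(fam, mid, None, None, FEMALE))

        if is_son:
            samples.append(cid)
            sample_sex[cid] = MALE
            genotypes[cid] = gamete[None, :]
            ped_records.append(PedigreeRecord(fam, cid, None, mid, MALE))
        else:
            father = (rng.random(n_sites) < layout.freqs).astype(np.int8)
            samples.append(pid)
            sample_sex[pid] = MALE
            genotypes[pid] = father[None, :]
            ped_records.append(PedigreeRecord(fam, pid, None, None, MALE))
            samples.append(cid)
            sample_sex[cid] = FEMALE
            genotypes[cid] = np.stack([gamete, father])
            ped_records.append(PedigreeRecord(fam, cid, pid, mid, FEMALE))

        for idx, locus in enumerate(loci):
            truth_rows.append(
                {"trio": cid, "locus": locus.name, "hap_index": int(seg_hap[idx])}
            )

    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(
        config=config,
        layout=layout,
        loci=loci,
        samples=samples,
        sample_sex=sample_sex,
        genotypes=genotypes,
        pedigree=PedigreeTable(ped_records),
        truth=truth,
    )


def _apply_gene_conversion(
    gamete: np.ndarray,
    mother: np.ndarray,
    layout: SiteLayout,
    loci: Sequence[MarkerLocus],
    rate: float,
    rng: np.random.Generator,
    tract_bp: int = 1000,
) -> None:
    """Overwrite short tracts (<= ``tract_bp``) with the homologous haplotype,
    mimicking non-crossover gene conversion inside a searched span."""
    for idx, locus in enumerate(loci):
        if rng.random() >= rate:
            continue
        sites = np.flatnonzero(layout.segment_ids == idx)
        if not sites.size:
            continue
        center = int(rng.choice(layout.positions[sites]))
        tract = sites[
            np.abs(layout.positions[sites] - center) <= tract_bp // 2
        ]
        cur = gamete[tract]
        swapped = np.where(
            cur == mother[0, tract], mother[1, tract], mother[0, tract]
        )
        gamete[tract] = swapped


# ---------------------------------------------------------------------------
# STR families


@dataclass
class SimulatedFamilies:
    """Simulated two-generation X-STR families plus per-meiosis truth."""

    config: SimConfig
    table: pd.DataFrame  # family_id, member_id, role, sex, <locus columns>
    truth: pd.DataFrame  # family_id, child_id, pair, recombinant

    def write_table(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def families(self):
        """Parsed view through the family-table reader (round-trips IO)."""
        from io import StringIO

        from .pedigree_linkage import read_family_table

        buf = StringIO()
        self.table.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return read_family_table(buf)


def _draw_str_allele(freqs: dict[str, float], rng: np.random.Generator) -> str:
    names = list(freqs)
    probs = np.asarray([freqs[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _mutate(allele: str, rng: np.random.Generator) -> str:
    step = 1 if rng.random() < 0.5 else -1
    try:
        if "." in allele:
            whole, frac = allele.split(".")
            return f"{int(whole) + step}.{frac}"
        return str(int(allele) + step)
    except ValueError:
        return allele


def simulate_str_families(config: SimConfig) -> SimulatedFamilies:
    """Generate X-STR genotypes for two-generation families.

    Maternal two-locus (or multi-locus) haplotypes are drawn under linkage
    equilibrium from the per-locus allele frequencies; each child's
    transmission runs through the same meiosis engine with the configured
    per-interval thetas. Optional mutations perturb a transmitted allele by
    one repeat unit and are recorded in the truth table.
    """
    rng = np.random.default_rng(config.seed + 1)
    loci = list(config.str_loci)
    thetas = list(config.str_thetas)
    if len(thetas) != len(loci) - 1:
        raise ValueError("str_thetas must have one value per locus interval")
    freqs = config.str_allele_freqs or {n: dict(_DEFAULT_STR_FREQS) for n in loci}
    for name, table in freqs.items():
        total = sum(table.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"allele frequencies for {name} sum to {total}")

    seg_ids = np.arange(len(loci))
    rows: list[dict] = []
    truth_rows: list[dict] = []
    fam_no = 0
    for n_f, n_m, n_dau, n_son, count in config.family_structures:
        for _ in range(count):
            fam_no += 1
            fam = f"FAM{fam_no:03d}"
            hap1 = np.array([_draw_str_allele(freqs[n], rng) for n in loci])
            hap2 = np.array([_draw_str_allele(freqs[n], rng) for n in loci])
            father = (
                {n: _draw_str_allele(freqs[n], rng) for n in loci} if n_f else None
            )
            row_m = {
                "family_id": fam, "member_id": f"{fam}_MO", "role": "mother",
                "sex": "female",
            }
            for i, n in enumerate(loci):
                row_m[n] = f"{hap1[i]}/{hap2[i]}"
            rows.append(row_m)
            if father is not None:
                row_f = {
                    "family_id": fam, "member_id": f"{fam}_FA", "role": "father",
                    "sex": "male", **father,
                }
                rows.append(row_f)
            kids = [FEMALE] * n_dau + [MALE] * n_son
            for ci, sex in enumerate(kids, start=1):
                cid = f"{fam}_C{ci}"
                meiosis = simulate_meiosis(hap1, hap2, seg_ids, thetas, rng)
                trans = list(meiosis.alleles)
                mutated = []
                for i in range(len(loci)):
                    if config.mutation_rate > 0 and rng.random() < config.mutation_rate:
                        trans[i] = _mutate(str(trans[i]), rng)
                        mutated.append(loci[i])
                row_c = {
                    "family_id": fam, "member_id": cid, "role": "child",
                    "sex": "female" if sex == FEMALE else "male",
                }
                for i, n in enumerate(loci):
                    if sex == MALE:
                        row_c[n] = str(trans[i])
                    else:
                        row_c[n] = f"{trans[i]}/{father[n]}"
                rows.append(row_c)
                for i in range(len(loci) - 1):
                    truth_rows.append(
                        {
                            "family_id": fam,
                            "child_id": cid,
                            "pair": f"{loci[i]}-{loci[i + 1]}",
                            "recombinant": int(
                                meiosis.segment_hap[i] != meiosis.segment_hap[i + 1]
                            ),
                            "mutated": ",".join(mutated) or ".",
                        }
                    )
    cols = ["family_id", "member_id", "role", "sex", *loci]
    table = pd.DataFrame(rows, columns=cols).fillna(".")
    return SimulatedFamilies(
        config=config, table=table, truth=pd.DataFrame(truth_rows)
    )
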