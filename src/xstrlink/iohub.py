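"""Readers, writers and domain records for the file formats the pipeline touches.

Coordinates follow the VCF convention throughout: 1-based, inclusive at both
ends. A marker's flanking windows are ``[start - w, start - 1]`` upstream and
``[end + 1, end + w]`` downstream, clamped at position 1.

Male X genotypes arrive from public releases in two encodings — true haploid
(``1``) and homozygous-diploid (``1|1``); both are accepted and normalized to
a single allele. A heterozygous diploid call on a male X site is biologically
impossible outside the pseudoautosomal regions and is flagged as a Mendelian
inconsistency rather than silently used.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "MarkerLocus",
    "PedigreeRecord",
    "PedigreeTable",
    "TrioRecord",
    "Genotype",
    "SnpRecord",
    "read_phased_vcf",
    "read_marker_table",
    "write_marker_table",
    "read_pedigree",
    "write_pedigree",
    "trios_from_pedigree",
    "write_pair_report",
    "read_config",
]

MALE = "male"
FEMALE = "female"

_CHROM_RE = re.compile(r"^(chr)?([0-9]{1,2}|[XYM]|MT)$", re.IGNORECASE)


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class MarkerLocus:
    """A target STR locus with its flanking search windows.

    ``start``/``end`` bound the repeat region (1-based inclusive);
    ``window_bp`` is the length of each flanking segment used to trace
    transmission of the surrounding chromosomal region.
    """

    name: str
    chrom: str
    start: int
    end: int
    linkage_group: str
    window_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"locus {self.name}: start ({self.start}) > end ({self.end})"
            )
        if self.window_bp <= 0:
            raise ValueError(f"locus {self.name}: window_bp must be positive")

    @property
    def upstream_window(self) -> tuple[int, int]:
        """1-based inclusive interval immediately 5' of the repeat."""
        return (max(1, self.start - self.window_bp), self.start - 1)

    @property
    def downstream_window(self) -> tuple[int, int]:
        return (self.end + 1, self.end + self.window_bp)

    @property
    def searched_span(self) -> tuple[int, int]:
        """Full searched range: repeat plus both flanking windows."""
        return (max(1, self.start - self.window_bp), self.end + self.window_bp)


@dataclass(frozen=True)
class PedigreeRecord:
    family_id: str
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # MALE or FEMALE


@dataclass
class PedigreeTable:
    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        ids = {r.sample_id for r in self.records}
        self.external_parents: set[str] = set()
        for r in self.records:
            for pid in (r.father_id, r.mother_id):
                if pid is not None and pid not in ids:
                    self.external_parents.add(pid)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def sex_by_sample(self) -> dict[str, str]:
        return {r.sample_id: r.sex for r in self.records}


@dataclass(frozen=True)
class TrioRecord:
    """A mother/child transmission unit; the father is required only to
    resolve a daughter's maternal allele by subtraction."""

    family_id: str
    child_id: str
    mother_id: str
    father_id: str | None
    child_sex: str

    @property
    def sample_ids(self) -> tuple[str, ...]:
        ids = [self.mother_id, self.child_id]
        if self.father_id is not None:
            ids.insert(1, self.father_id)
        return tuple(ids)


@dataclass(frozen=True)
class Genotype:
    """One sample's call at one site.

    ``alleles`` holds allele indices (0 = REF, 1 = ALT), one entry for
    hemizygous calls and two for diploid calls; ``None`` marks a missing
    allele. ``flag`` records per-sample QC problems: ``unphased_het`` (cannot
    be used for origin calling) or ``male_het`` (Mendelian-inconsistent
    heterozygous diploid call on a male X).
    """

    alleles: tuple[int | None, ...]
    phased: bool = True
    flag: str | None = None

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return (
            len(self.alleles) == 2
            and not self.is_missing
            and self.alleles[0] != self.alleles[1]
        )

    @property
    def single_allele(self) -> int | None:
        """The hemizygous allele for haploid calls, else None."""
        if len(self.alleles) == 1:
            return self.alleles[0]
        return None


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with per-sample genotypes and a cohort MAF.

    Phased diploid genotypes carry haplotype order: ``alleles[0]`` sits on
    haplotype 1. The MAF is recomputed over the analysis cohort rather than
    taken from INFO, so filtering behaves identically on real and simulated
    input.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Mapping[str, Genotype]
    maf: float = field(default=0.0, compare=False)


# ---------------------------------------------------------------------------
# VCF reading


def _parse_region(region: str | tuple[str, int, int] | None):
    if region is None:
        return None
    if isinstance(region, tuple):
        return region
    m = re.match(r"^([^:]+):(\d+)-(\d+)$", region)
    if not m:
        raise ValueError(f"cannot parse region {region!r}; expected chrom:start-end")
    return (m.group(1), int(m.group(2)), int(m.group(3)))


def _normalize_genotype(gt, phased: bool, sex: str | None) -> Genotype:
    alleles = tuple(gt)
    if len(alleles) == 2 and sex == MALE:
        a, b = alleles
        if a is not None and a == b:
            return Genotype(alleles=(a,), phased=True)
        if a is not None and b is not None and a != b:
            return Genotype(alleles=alleles, phased=phased, flag="male_het")
        return Genotype(alleles=(None,), phased=True)
    if len(alleles) == 2 and alleles[0] != alleles[1] and not phased:
        if alleles[0] is not None and alleles[1] is not None:
            return Genotype(alleles=alleles, phased=False, flag="unphased_het")
    return Genotype(alleles=alleles, phased=phased)


def read_phased_vcf(
    path: str | Path,
    region: str | tuple[str, int, int] | None = None,
    sample_ids: Sequence[str] | None = None,
    sex_by_sample: Mapping[str, str] | None = None,
) -> list[SnpRecord]:
    """Read biallelic SNPs for a set of samples from a phased VCF.

    Parameters
    ----------
    path
        VCF 4.x file (plain text or bgzipped).
    region
        ``chrom:start-end`` (1-based inclusive) or a tuple; ``None`` keeps
        every site. The file is streamed, so no index is needed.
    sample_ids
        Samples to extract; every id must exist in the header.
    sex_by_sample
        Optional sex map used to normalize male X calls: homozygous-diploid
        male calls collapse to a single allele, heterozygous male calls are
        flagged ``male_het``.

    Returns
    -------
    Records for biallelic SNPs only (multi-allelic sites and indels are
    dropped), each carrying a cohort MAF over the requested samples.
    """
    reg = _parse_region(region)
    sex_by_sample = sex_by_sample or {}
    records: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        if sample_ids is None:
            sample_ids = header_samples
        else:
            missing = [s for s in sample_ids if s not in header_samples]
            if missing:
                raise ValueError(
                    f"sample(s) not present in VCF {path}: {', '.join(missing)}"
                )
        for rec in vf:
            if reg is not None:
                chrom, start, end = reg
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            gts: dict[str, Genotype] = {}
            for sid in sample_ids:
                s = rec.samples[sid]
                gts[sid] = _normalize_genotype(
                    s["GT"], bool(s.phased), sex_by_sample.get(sid)
                )
            records.append(
                SnpRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    genotypes=gts,
                    maf=_cohort_maf(gts.values()),
                )
            )
    return records


def _cohort_maf(genotypes: Iterable[Genotype]) -> float:
    n_alt = 0
    n_tot = 0
    for g in genotypes:
        for a in g.alleles:
            if a is not None:
                n_tot += 1
                n_alt += a
    if n_tot == 0:
        return 0.0
    f = n_alt / n_tot
    return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# marker table


_MARKER_COLUMNS = ["name", "chrom", "start", "end", "linkage_group"]


def read_marker_table(path: str | Path) -> list[MarkerLocus]:
    """Read a tab-separated marker table into loci sorted by (chrom, start).

    Expected header: ``name  chrom  start  end  linkage_group[  window_bp]``.
    Duplicate names and ``start > end`` are rejected; an unusual chromosome
    label only triggers a warning so non-reference assemblies still load.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "name": str})
    missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table {path} lacks column(s): {', '.join(missing)}")
    dup = df["name"][df["name"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate marker name(s): {', '.join(sorted(set(dup)))}")
    loci = []
    for row in df.itertuples(index=False):
        if not _CHROM_RE.match(str(row.chrom)):
            warnings.warn(
                f"unrecognized chromosome label {row.chrom!r} for {row.name}",
                stacklevel=2,
            )
        w = getattr(row, "window_bp", None)
        if w is None or (isinstance(w, float) and w != w):  # absent or NaN
            w = 10_000
        loci.append(
            MarkerLocus(
                name=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                linkage_group=str(row.linkage_group),
                window_bp=int(w),
            )
        )
    loci.sort(key=lambda m: (m.chrom, m.start, m.end))
    return loci


def write_marker_table(loci: Sequence[MarkerLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": [m.name for m in loci],
            "chrom": [m.chrom for m in loci],
            "start": [m.start for m in loci],
            "end": [m.end for m in loci],
            "linkage_group": [m.linkage_group for m in loci],
            "window_bp": [m.window_bp for m in loci],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree


_SEX_CODES = {"1": MALE, "2": FEMALE, "m": MALE, "f": FEMALE,
              "male": MALE, "female": FEMALE}
_MISSING_PARENT = {"0", ".", "", "NA"}


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a 5-column pedigree: family, sample, father, mother, sex.

    Parent fields coded ``0``/``.`` are treated as missing; sex accepts
    ``1``/``2`` or ``male``/``female``.
    """
    records = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"{path} line {line_no}: expected 5 columns")
            fam, sid, fid, mid, sex = fields[:5]
            sex_l = _SEX_CODES.get(sex.lower())
            if sex_l is None:
                raise ValueError(f"{path} line {line_no}: bad sex code {sex!r}")
            records.append(
                PedigreeRecord(
                    family_id=fam,
                    sample_id=sid,
                    father_id=None if fid in _MISSING_PARENT else fid,
                    mother_id=None if mid in _MISSING_PARENT else mid,
                    sex=sex_l,
                )
            )
    return PedigreeTable(records)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(
                "\t".join(
                    [
                        r.family_id,
                        r.sample_id,
                        r.father_id or "0",
                        r.mother_id or "0",
                        "1" if r.sex == MALE else "2",
                    ]
                )
                + "\n"
            )


def trios_from_pedigree(ped: PedigreeTable) -> list[TrioRecord]:
    """Extract mother/child transmission units from a pedigree.

    Every child with a recorded mother forms a trio. Daughters keep their
    father id when present; a daughter without a genotyped father is still
    returned (her sites simply stay undetermined during origin calling).
    """
    trios = []
    for r in ped.records:
        if r.mother_id is None:
            continue
        trios.append(
            TrioRecord(
                family_id=r.family_id,
                child_id=r.sample_id,
                mother_id=r.mother_id,
                father_id=r.father_id,
                child_sex=r.sex,
            )
        )
    return trios


# ---------------------------------------------------------------------------
# reports and config

REPORT_COLUMNS = [
    "pair",
    "k_recomb",
    "n_informative",
    "fraction_pct",
    "ci_low_pct",
    "ci_high_pct",
]


def write_pair_report(
    rows: Iterable[Mapping],
    path: str | Path,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write the per-pair recombination report as TSV.

    Leading ``#`` comment lines record the parameter set (window_bp,
    maf_min, alpha, seed, ...) so a result is reproducible from the report
    alone; the column header is exactly ``pair  k_recomb  n_informative
    fraction_pct  ci_low_pct  ci_high_pct``.
    """
    with open(path, "w") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            out = []
            for col in REPORT_COLUMNS:
                val = row[col]
                if isinstance(val, float):
                    out.append("NA" if val != val else f"{val:.2f}")
                else:
                    out.append(str(val))
            fh.write("\t".join(out) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key=value`` / ``key: value`` configuration file.

    Keys mirror the CLI flags (``window_bp``, ``maf_min``, ``alpha``, ...);
    command-line values override configuration values.
    """
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            elif ":" in line:
                key, _, val = line.partition(":")
            else:
                raise ValueError(f"cannot parse config line {line!r}")
            cfg[key.strip()] = val.strip()
    return cfg
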