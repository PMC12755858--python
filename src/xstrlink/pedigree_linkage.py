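"""Two-point linkage analysis of X-STR pairs from two-generation families.

Maternal meioses are extracted with the same transmission logic used for
SNP trios: a son's X-STR allele is the transmitted maternal allele; a
daughter's maternal allele is found by subtracting her father's hemizygous
allele. A meiosis is informative for a locus pair when the mother is
heterozygous at both loci and both transmitted alleles are determined.

Because the mother's gametic phase is unobserved, the likelihood marginalizes
over her two possible phase configurations, sharing one phase latent variable
per family (children of one mother are not independent given phase):

    L_fam(theta) = sum_phase prior(phase) * prod_meioses p(meiosis | phase)

with p = (1 - theta)/2 for a phase-consistent transmission and theta/2 for an
inconsistent one. Under linkage equilibrium the two phase configurations of a
double-heterozygous mother have identical haplotype-frequency products, so
the LE prior reduces to 1/2 each; explicit haplotype-frequency priors can be
supplied when population phase information exists.

theta_hat maximizes the summed log marginal likelihood on [0, 0.5];
MLOD = log10 L(theta_hat) - log10 L(0.5) is non-negative by construction and
is 0 exactly when free recombination fits best. Map distances use the
Kosambi function d = (1/4) ln((1+2*theta)/(1-2*theta)).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import statkit
from .iohub import FEMALE, MALE
from .trio_recomb import PairRecombResult

__all__ = [
    "FamilyGenotypes",
    "MaternalMeiosis",
    "FamilyMeioses",
    "TwoPointResult",
    "read_family_table",
    "extract_maternal_meioses",
    "two_point_loglik",
    "estimate_theta_mlod",
    "family_recomb_fraction",
    "kosambi_map",
    "kosambi_theta",
]


class Trace(enum.Enum):
    UNDETERMINED = enum.auto()
    MENDELIAN_ERROR = enum.auto()


@dataclass
class FamilyGenotypes:
    """X-STR genotypes of one two-generation family.

    ``mother``/``father`` map locus -> allele pair / single allele; children
    are (child_id, sex, {locus: alleles}) with one allele for sons and two
    for daughters. STR alleles are repeat-count strings ("12", "15.3").
    """

    family_id: str
    mother: dict[str, tuple[str, str]]
    father: dict[str, str] | None
    children: list[tuple[str, str, dict[str, tuple[str, ...]]]]


@dataclass(frozen=True)
class MaternalMeiosis:
    """One maternal transmission scored at a locus pair."""

    child_id: str
    allele_a: str | None
    allele_b: str | None
    informative: bool
    mendel_error: bool = False


@dataclass(frozen=True)
class FamilyMeioses:
    """Informative meioses of one family plus the mother's two-locus genotype
    (needed to enumerate her phase configurations)."""

    family_id: str
    mother_a: tuple[str, str]
    mother_b: tuple[str, str]
    transmissions: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class TwoPointResult:
    """Two-point linkage summary for one marker pair."""

    locus_a: str
    locus_b: str
    theta_hat: float  # NaN when no informative meioses
    mlod: float
    kosambi_cm: float
    n_informative: int


# ---------------------------------------------------------------------------
# family table IO


def read_family_table(path: str | Path) -> list[FamilyGenotypes]:
    """Read a family X-STR genotype TSV.

    Columns: ``family_id  member_id  role  sex`` then one column per locus
    holding ``a`` (hemizygous) or ``a/b`` genotypes; missing data as ``.``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    fixed = ["family_id", "member_id", "role", "sex"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"family table lacks column(s): {', '.join(missing)}")
    loci = [c for c in df.columns if c not in fixed]
    families = []
    for fam_id, sub in df.groupby("family_id", sort=True):
        mother: dict[str, tuple[str, str]] = {}
        father: dict[str, str] | None = None
        children: list[tuple[str, str, dict[str, tuple[str, ...]]]] = []
        for row in sub.itertuples(index=False):
            gts: dict[str, tuple[str, ...]] = {}
            for locus in loci:
                raw = getattr(row, locus)
                if raw is None or raw != raw or raw in (".", ""):
                    continue
                gts[locus] = tuple(str(raw).split("/"))
            role = row.role.lower()
            if role == "mother":
                mother = {
                    k: (v[0], v[1]) for k, v in gts.items() if len(v) == 2
                }
            elif role == "father":
                father = {k: v[0] for k, v in gts.items()}
            elif role == "child":
                sex = MALE if row.sex.lower() in ("1", "m", "male") else FEMALE
                children.append((row.member_id, sex, gts))
            else:
                raise ValueError(f"unknown role {row.role!r} in family {fam_id}")
        if not mother:
            raise ValueError(f"family {fam_id} has no mother record")
        families.append(
            FamilyGenotypes(
                family_id=str(fam_id), mother=mother, father=father,
                children=children,
            )
        )
    return families


# ---------------------------------------------------------------------------
# meiosis extraction


def _transmitted_allele(
    child_alleles: tuple[str, ...],
    sex: str,
    father_allele: str | None,
    mother_pair: tuple[str, str],
):
    """Maternal allele transmitted at one locus, or a Trace sentinel."""
    if sex == MALE:
        if len(child_alleles) != 1:
            return Trace.UNDETERMINED
        allele = child_alleles[0]
    else:
        if len(child_alleles) != 2:
            return Trace.UNDETERMINED
        c1, c2 = child_alleles
        if c1 == c2:
            if father_allele is not None and father_allele != c1:
                return Trace.MENDELIAN_ERROR
            allele = c1
        else:
            if father_allele is None:
                return Trace.UNDETERMINED
            if father_allele == c1:
                allele = c2
            elif father_allele == c2:
                allele = c1
            else:
                return Trace.MENDELIAN_ERROR
    if allele not in mother_pair:
        return Trace.MENDELIAN_ERROR  # possible mutation; excluded from theta
    return allele


def extract_maternal_meioses(
    family: FamilyGenotypes, locus_a: str, locus_b: str
) -> list[MaternalMeiosis]:
    """Score every child of a family as a maternal meiosis at a locus pair.

    Informative requires: mother heterozygous at both loci and both
    transmitted alleles determined without Mendelian inconsistency. Meioses
    carrying an allele absent from the mother (possible mutation) are
    flagged and never enter theta estimation.
    """
    ma = family.mother.get(locus_a)
    mb = family.mother.get(locus_b)
    out = []
    for child_id, sex, gts in family.children:
        ta = tb = None
        err = False
        for locus, mpair, slot in ((locus_a, ma, "a"), (locus_b, mb, "b")):
            if mpair is None or locus not in gts:
                res = Trace.UNDETERMINED
            else:
                f_allele = (
                    family.father.get(locus) if family.father is not None else None
                )
                res = _transmitted_allele(gts[locus], sex, f_allele, mpair)
            if res is Trace.MENDELIAN_ERROR:
                err = True
            elif res is not Trace.UNDETERMINED:
                if slot == "a":
                    ta = res
                else:
                    tb = res
        informative = (
            not err
            and ta is not None
            and tb is not None
            and ma is not None
            and mb is not None
            and ma[0] != ma[1]
            and mb[0] != mb[1]
        )
        out.append(
            MaternalMeiosis(
                child_id=child_id,
                allele_a=ta,
                allele_b=tb,
                informative=informative,
                mendel_error=err,
            )
        )
    return out


def collect_family_meioses(
    families: Sequence[FamilyGenotypes], locus_a: str, locus_b: str
) -> list[FamilyMeioses]:
    """Informative meioses per family, ready for the phase-marginalized
    likelihood; families with none are dropped."""
    out = []
    for fam in families:
        ma = fam.mother.get(locus_a)
        mb = fam.mother.get(locus_b)
        if ma is None or mb is None:
            continue
        meioses = extract_maternal_meioses(fam, locus_a, locus_b)
        trans = tuple(
            (m.allele_a, m.allele_b) for m in meioses if m.informative
        )
        if trans:
            out.append(
                FamilyMeioses(
                    family_id=fam.family_id, mother_a=ma, mother_b=mb,
                    transmissions=trans,
                )
            )
    return out


# ---------------------------------------------------------------------------
# likelihood


def _phase_configs(fam: FamilyMeioses):
    """The mother's two phase configurations as haplotype pairs."""
    (a1, a2), (b1, b2) = fam.mother_a, fam.mother_b
    return (
        ((a1, b1), (a2, b2)),  # cis
        ((a1, b2), (a2, b1)),  # trans
    )


def _family_log_marginal(
    fam: FamilyMeioses, theta: float, prior: tuple[float, float]
) -> float:
    terms = []
    for phase, w in zip(_phase_configs(fam), prior):
        if w <= 0:
            continue
        logp = math.log(w)
        for ta, tb in fam.transmissions:
            consistent = (ta, tb) in phase
            p = (1.0 - theta) / 2.0 if consistent else theta / 2.0
            if p == 0.0:
                logp = -math.inf
                break
            logp += math.log(p)
        terms.append(logp)
    if not terms:
        return -math.inf
    return float(np.logaddexp.reduce(terms))


def two_point_loglik(
    families: Sequence[FamilyMeioses],
    theta: float,
    phase_prior: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Log marginal likelihood of theta over families with shared-phase mothers.

    ``phase_prior`` optionally maps family_id -> (w_cis, w_trans) prior
    weights (e.g. from population haplotype frequencies); the default is the
    linkage-equilibrium uniform prior (1/2, 1/2).
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")
    total = 0.0
    for fam in families:
        prior = (0.5, 0.5)
        if phase_prior is not None and fam.family_id in phase_prior:
            w1, w2 = phase_prior[fam.family_id]
            s = w1 + w2
            prior = (w1 / s, w2 / s)
        total += _family_log_marginal(fam, theta, prior)
    return total


def estimate_theta_mlod(
    families: Sequence[FamilyMeioses],
    phase_prior: Mapping[str, tuple[float, float]] | None = None,
    locus_a: str = "A",
    locus_b: str = "B",
    tol: float = 1e-6,
) -> TwoPointResult:
    """Maximum-likelihood theta and MLOD score for one locus pair.

    The likelihood is maximized over [0, 0.5] by bounded scalar optimization
    with the exact boundary values checked as well; a likelihood tie with
    theta = 0.5 resolves to 0.5 (no-linkage is the conservative verdict, and
    it makes MLOD = 0 exact for flat likelihoods such as a single meiosis).
    """
    n_inf = sum(len(f.transmissions) for f in families)
    if n_inf == 0:
        return TwoPointResult(locus_a, locus_b, float("nan"), 0.0, float("nan"), 0)

    def nll(t: float) -> float:
        return -two_point_loglik(families, t, phase_prior)

    res = minimize_scalar(
        nll, bounds=(0.0, 0.5), method="bounded", options={"xatol": tol * 1e-2}
    )
    candidates = [0.0, float(res.x), 0.5]
    lls = [-nll(t) for t in candidates]
    best = int(np.argmax(lls))
    ll_half = lls[2]
    if lls[best] - ll_half <= 1e-12:
        theta_hat, ll_hat = 0.5, ll_half
    else:
        theta_hat, ll_hat = candidates[best], lls[best]
    mlod = max(0.0, (ll_hat - ll_half) / math.log(10.0))
    return TwoPointResult(
        locus_a=locus_a,
        locus_b=locus_b,
        theta_hat=theta_hat,
        mlod=mlod,
        kosambi_cm=kosambi_map(theta_hat),
        n_informative=n_inf,
    )


def family_recomb_fraction(
    families: Sequence[FamilyGenotypes],
    locus_a: str,
    locus_b: str,
    alpha: float = 0.05,
    phase_prior: Mapping[str, tuple[float, float]] | None = None,
) -> PairRecombResult:
    """Recombination fraction Rc between two X-STRs over a family set.

    Rc is the phase-marginalized ML estimate; the exact binomial CI is
    anchored on (round(Rc * n), n) informative meioses, mirroring how a CI
    is attached to a directly counted recombinant fraction.
    """
    fams = collect_family_meioses(families, locus_a, locus_b)
    res = estimate_theta_mlod(
        fams, phase_prior, locus_a=locus_a, locus_b=locus_b
    )
    n = res.n_informative
    if n == 0:
        return PairRecombResult(
            locus_a, locus_b, 0, 0, float("nan"), float("nan"), float("nan")
        )
    k = int(round(res.theta_hat * n))
    ci = statkit.clopper_pearson(k, n, alpha)
    return PairRecombResult(
        locus_a, locus_b, k, n, res.theta_hat, ci.low, ci.high
    )


# ---------------------------------------------------------------------------
# map functions


def kosambi_map(theta: float) -> float:
    """Kosambi map distance in centiMorgans for a recombination fraction.

    d = (1/4) ln((1+2*theta)/(1-2*theta)) Morgans; theta = 0.5 maps to +inf
    (reported as NA in tables).
    """
    if theta != theta:
        return float("nan")
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")
    if theta == 0.5:
        return math.inf
    return 25.0 * math.log((1.0 + 2.0 * theta) / (1.0 - 2.0 * theta))


def kosambi_theta(cm: float) -> float:
    """Inverse Kosambi: recombination fraction for a map distance in cM."""
    if cm < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * math.tanh(2.0 * cm / 100.0)


def two_point_table(
    families: Sequence[FamilyGenotypes],
    pairs: Sequence[tuple[str, str]],
    phase_prior: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """TwoPointResult rows (pair, theta_hat, mlod, kosambi_cm, n_informative)
    for every requested locus pair."""
    rows = []
    for a, b in pairs:
        fams = collect_family_meioses(families, a, b)
        r = estimate_theta_mlod(fams, phase_prior, locus_a=a, locus_b=b)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "theta_hat": r.theta_hat,
                "mlod": r.mlod,
                "kosambi_cm": r.kosambi_cm,
                "n_informative": r.n_informative,
            }
        )
    return pd.DataFrame(rows)
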