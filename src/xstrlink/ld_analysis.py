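"""Pairwise linkage disequilibrium on phased haplotypes and its decay with
distance.

Estimation is haplotype-based throughout (no EM from unphased genotypes):
the inputs are phased, so D for a site pair is simply the observed gamete
frequency minus the product of allele frequencies. The decay curve bins
pairwise r^2 by inter-site distance and reports the first bin whose mean
drops to a threshold (0.1 by default) — the quantity used to justify sizing
flanking windows at 10 kb, comfortably above the distance at which allelic
association fades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LdPair", "DecayCurve", "pairwise_ld", "ld_decay"]


@dataclass(frozen=True)
class LdPair:
    """LD coefficients for one site pair: raw D, normalized |D'|, and r^2."""

    pos_a: int
    pos_b: int
    distance: int
    d: float
    d_prime: float
    r2: float
    defined: bool = True


@dataclass
class DecayCurve:
    """Distance-binned mean r^2 with per-bin pair counts.

    ``bins`` holds half-open bin edges ``[k*w, (k+1)*w)``;
    ``threshold_crossing`` is the midpoint of the first non-empty bin whose
    mean r^2 <= threshold (NaN when no bin qualifies).
    """

    table: pd.DataFrame  # bin_start, bin_end, mean_r2, n_pairs
    threshold: float
    threshold_crossing: float

    @property
    def n_pairs_total(self) -> int:
        return int(self.table["n_pairs"].sum())


def pairwise_ld(
    hap_a: np.ndarray, hap_b: np.ndarray, pos_a: int = 0, pos_b: int = 0
) -> LdPair:
    """LD between two aligned binary haplotype vectors.

    D = p_AB - p_A p_B; D' = |D| / D_max with the usual sign-dependent
    normalizer; r^2 = D^2 / (p_A q_A p_B q_B). A monomorphic site makes the
    result undefined (``defined=False``) and such pairs never enter decay
    curves.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("haplotype vectors must be equal-length 1-D, size >= 2")
    p_a = a.mean()
    p_b = b.mean()
    dist = abs(pos_b - pos_a)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LdPair(pos_a, pos_b, dist, float("nan"), float("nan"),
                      float("nan"), defined=False)
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdPair(pos_a, pos_b, dist, float(d), float(d_prime), float(r2))


def ld_decay(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    maf_min: float = 0.05,
    max_dist: int = 300_000,
    bin_width: int = 500,
    threshold: float = 0.1,
) -> DecayCurve:
    """Distance-binned LD decay curve over all qualifying site pairs.

    Parameters
    ----------
    haplotypes
        (n_haplotypes, n_sites) 0/1 matrix of phased haplotypes.
    positions
        Site positions (bp), ascending, length n_sites.
    maf_min
        Both sites of a pair must have MAF >= this (0.05 by default, the
        conventional cutoff for LD scans).
    max_dist, bin_width
        Pairs farther apart than ``max_dist`` are skipped; distances fall in
        half-open bins of ``bin_width`` bp.
    threshold
        Level whose first downward crossing (by bin mean) is reported at the
        bin midpoint.
    """
    H = np.asarray(haplotypes, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    if H.ndim != 2 or H.shape[1] != pos.size:
        raise ValueError("haplotypes must be (n_hap, n_sites) matching positions")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")

    freq = H.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    # monomorphic sites have undefined LD and never enter the curve
    keep = (maf >= maf_min) & (freq > 0) & (freq < 1)
    H = H[:, keep]
    pos = pos[keep]
    n_sites = pos.size

    n_bins = int(np.ceil(max_dist / bin_width)) if max_dist > 0 else 0
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    if n_sites >= 2 and n_bins:
        Hc = H - H.mean(axis=0)
        norms = np.sqrt((Hc * Hc).sum(axis=0))
        for i in range(n_sites - 1):
            j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
            if j_hi <= i + 1:
                continue
            js = np.arange(i + 1, j_hi)
            r = (Hc[:, js].T @ Hc[:, i]) / (norms[js] * norms[i])
            r2 = r * r
            bins = (pos[js] - pos[i]) // bin_width
            inside = bins < n_bins
            np.add.at(sums, bins[inside], r2[inside])
            np.add.at(counts, bins[inside], 1)

    starts = np.arange(n_bins, dtype=np.int64) * bin_width
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_start": starts,
            "bin_end": starts + bin_width,
            "mean_r2": means,
            "n_pairs": counts,
        }
    )
    crossing = float("nan")
    hit = np.flatnonzero((counts > 0) & (means <= threshold))
    if hit.size:
        crossing = float(starts[hit[0]] + bin_width / 2.0)
    return DecayCurve(table=table, threshold=threshold, threshold_crossing=crossing)
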