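"""Per-group diversity, inbreeding and relatedness estimators, and
between-group differentiation estimators for microsatellite panels.

Diversity within groups
    A_N     mean number of alleles per locus
    A_R(g)  allelic richness, hypergeometric rarefaction to g gene copies
    A_P(g)  private allelic richness (alleles expected in the focal group's
            subsample and absent from every other group's subsample)
    H_O     observed heterozygosity
    H_E     Nei's unbiased expected heterozygosity, (n/(n-1)) (1 - sum p^2)
            with n gene copies
    F_IS    multilocus 1 - H_O/H_E with components summed over loci
    r_w     mean within-group pairwise Queller-Goodnight relatedness

Differentiation between groups (Nei-Chesser bias-corrected components,
harmonic-mean sample size; multilocus ratios formed from locus-averaged
H_S and H_T):
    G_ST    (H_T - H_S) / H_T
    G''_ST  Hedrick-Meirmans standardized G_ST,
            k (H_T - H_S) / ((k H_T - H_S)(1 - H_S))
    D_EST   Jost's D, (k/(k-1)) (H_T - H_S) / (1 - H_S)

Rarefaction is computed in exact rational arithmetic so that, for small
samples, values agree bit-for-bit with exhaustive enumeration over
gene-copy subsamples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class LocusCounts:
    """Gene-copy counts for one locus in one group."""

    sizes: np.ndarray  # distinct allele sizes (bp), ascending
    counts: np.ndarray  # gene-copy count per size
    n_genes: int  # 2 x typed individuals at this locus

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_genes:
            raise ValueError("allele counts do not sum to n_genes")


AlleleCounts = list[LocusCounts]  # one entry per locus


def allele_counts(ds: GenotypeDataset, ids: list[str] | None = None) -> AlleleCounts:
    """Tabulate gene-copy counts per locus, missing genotypes dropped per locus."""
    sub = ds if ids is None else ds.subset(ids)
    typed = sub.typed_mask()
    out: AlleleCounts = []
    for l in range(sub.n_loci):
        genes = sub.alleles[typed[:, l], l, :].ravel()
        sizes, counts = np.unique(genes, return_counts=True)
        out.append(LocusCounts(sizes=sizes, counts=counts, n_genes=int(genes.size)))
    return out


# ---------------------------------------------------------------------------
# within-group diversity
# ---------------------------------------------------------------------------

def unbiased_expected_het(counts: AlleleCounts) -> tuple[np.ndarray, float]:
    """Nei's unbiased gene diversity per locus and its unweighted mean.

    Loci with fewer than 2 gene copies are excluded (NaN) with a warning.
    """
    per_locus = np.full(len(counts), np.nan)
    for l, lc in enumerate(counts):
        if lc.n_genes < 2:
            logger.warning("locus %d has n_genes=%d < 2; excluded from H_E", l, lc.n_genes)
            continue
        p = lc.counts / lc.n_genes
        per_locus[l] = lc.n_genes / (lc.n_genes - 1) * (1.0 - np.sum(p * p))
    return per_locus, float(np.nanmean(per_locus))


def observed_het(ds: GenotypeDataset, ids: list[str] | None = None) -> tuple[np.ndarray, float]:
    """Fraction of typed individuals heterozygous, per locus and mean."""
    sub = ds if ids is None else ds.subset(ids)
    typed = sub.typed_mask()
    n_typed = typed.sum(axis=0).astype(float)
    het = (sub.alleles[:, :, 0] != sub.alleles[:, :, 1]) & typed
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(n_typed > 0, het.sum(axis=0) / n_typed, np.nan)
    return per_locus, float(np.nanmean(per_locus))


def mean_alleles_per_locus(counts: AlleleCounts) -> float:
    return float(np.mean([len(lc.sizes) for lc in counts if lc.n_genes > 0]))


def _rarefied_locus(counts: np.ndarray, n: int, g: int) -> Fraction:
    """Expected allele count in a subsample of g of n gene copies (exact)."""
    denom = math.comb(n, g)
    total = Fraction(0)
    for c in counts:
        total += 1 - Fraction(math.comb(n - int(c), g), denom)
    return total


def rarefied_allelic_richness(
    counts: AlleleCounts, g: int
) -> tuple[np.ndarray, float]:
    """A_R(g): expected alleles per locus in a g-gene-copy subsample.

    Requires ``g <= n_genes`` at every locus.
    """
    per_locus = np.empty(len(counts))
    for l, lc in enumerate(counts):
        if g > lc.n_genes:
            raise ValueError(
                f"rarefaction size g={g} exceeds n_genes={lc.n_genes} at locus {l}"
            )
        per_locus[l] = float(_rarefied_locus(lc.counts, lc.n_genes, g))
    return per_locus, float(np.mean(per_locus))


def rarefied_private_allelic_richness(
    group_counts: list[AlleleCounts], g: int
) -> tuple[np.ndarray, np.ndarray]:
    """A_P(g) per group: rarefied count of alleles private to each group.

    For allele a and group j, ``Q_aj(g) = 1 - C(n_j - N_aj, g)/C(n_j, g)`` is
    the probability the allele shows up in group j's subsample; a contributes
    ``Q_aj * prod_{j' != j} (1 - Q_aj')`` to group j's private richness.

    Returns ``(per_group_per_locus, per_group_mean)`` with shapes
    ``(n_groups, n_loci)`` and ``(n_groups,)``.
    """
    if len(group_counts) < 2:
        raise ValueError("private allelic richness needs at least 2 groups")
    n_groups = len(group_counts)
    n_loci = len(group_counts[0])
    out = np.zeros((n_groups, n_loci))
    for l in range(n_loci):
        locus = [gc[l] for gc in group_counts]
        for lc in locus:
            if g > lc.n_genes:
                raise ValueError(
                    f"rarefaction size g={g} exceeds n_genes={lc.n_genes} at locus {l}"
                )
        all_sizes = np.unique(np.concatenate([lc.sizes for lc in locus]))
        # Q[j, a]: presence probability of allele a in group j's subsample
        Q = [[Fraction(0)] * len(all_sizes) for _ in range(n_groups)]
        for j, lc in enumerate(locus):
            denom = math.comb(lc.n_genes, g)
            idx = {s: i for i, s in enumerate(all_sizes)}
            for s, c in zip(lc.sizes, lc.counts):
                Q[j][idx[s]] = 1 - Fraction(
                    math.comb(lc.n_genes - int(c), g), denom
                )
        for j in range(n_groups):
            tot = Fraction(0)
            for a in range(len(all_sizes)):
                term = Q[j][a]
                if term == 0:
                    continue
                for j2 in range(n_groups):
                    if j2 != j:
                        term *= 1 - Q[j2][a]
                tot += term
            out[j, l] = float(tot)
    return out, out.mean(axis=1)


def inbreeding_fis(
    ds: GenotypeDataset, ids: list[str] | None = None
) -> tuple[np.ndarray, float]:
    """Multilocus F_IS = 1 - sum_l H_O,l / sum_l H_E,l (per-locus values kept).

    Undefined (NaN, with a warning) when every locus is monomorphic.
    """
    counts = allele_counts(ds, ids)
    he, _ = unbiased_expected_het(counts)
    ho, _ = observed_het(ds, ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = 1.0 - ho / he
    ok = ~np.isnan(he) & ~np.isnan(ho)
    he_sum = np.nansum(he[ok])
    if he_sum <= 0:
        logger.warning("all loci monomorphic; F_IS undefined")
        return per_locus, float("nan")
    return per_locus, float(1.0 - np.nansum(ho[ok]) / he_sum)


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def reference_frequencies(ds: GenotypeDataset, ids: list[str] | None = None) -> AlleleCounts:
    """Allele-frequency reference for relatedness (defaults to whole dataset)."""
    return allele_counts(ds, ids)


def mean_pairwise_relatedness(
    ds: GenotypeDataset,
    ids: list[str],
    reference: AlleleCounts | None = None,
) -> float:
    """Mean Queller-Goodnight relatedness over all within-group dyads (r_w).

    The multilocus estimate for a dyad is the ratio of locus-summed
    numerators to locus-summed denominators, symmetrized over the two
    orderings of the pair; reference allele frequencies come from
    ``reference`` (default: the whole dataset), independent of the dyad.
    """
    sub = ds.subset(ids)
    if sub.n_individuals < 2:
        raise ValueError("relatedness needs at least 2 individuals")
    if reference is None:
        reference = allele_counts(ds)
    n, L = sub.n_individuals, sub.n_loci
    typed = sub.typed_mask()

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    any_poly = False
    for l in range(L):
        ref = reference[l]
        if ref.n_genes == 0 or len(ref.sizes) < 2:
            continue
        any_poly = True
        freq = {int(s): c / ref.n_genes for s, c in zip(ref.sizes, ref.counts)}
        a = sub.alleles[:, l, 0]
        b = sub.alleles[:, l, 1]
        p = np.array([freq.get(int(x), 0.0) for x in a])
        q = np.array([freq.get(int(x), 0.0) for x in b])
        t = typed[:, l]
        # similarity S_xy = mean of the four allele-identity indicators
        S = 0.25 * (
            (a[:, None] == a[None, :]).astype(float)
            + (a[:, None] == b[None, :])
            + (b[:, None] == a[None, :])
            + (b[:, None] == b[None, :])
        )
        px = p + q  # p_a + p_b per individual
        hom = (a == b).astype(float)
        pair_ok = t[:, None] & t[None, :]
        # numerator/denominator of focal individual x paired with y,
        # symmetrized by adding the transpose
        num_l = (2.0 * S - px[:, None]) + (2.0 * S - px[None, :])
        den_l = (1.0 + hom - px)[:, None] + (1.0 + hom - px)[None, :]
        num += np.where(pair_ok, num_l, 0.0)
        den += np.where(pair_ok, den_l, 0.0)
    if not any_poly:
        logger.warning("monomorphic panel; relatedness undefined")
        return float("nan")
    iu = np.triu_indices(n, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num[iu] / den[iu]
    return float(np.nanmean(r))


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _nei_chesser_components(
    group_counts: list[AlleleCounts],
) -> tuple[np.ndarray, np.ndarray]:
    """Locus-wise bias-corrected H_S and H_T over k groups (Nei-Chesser).

    Uses the harmonic mean ntilde of per-group typed-individual counts:
    ``H_S = 2*ntilde/(2*ntilde - 1) * (1 - mean_s sum_a p_sa^2)`` and
    ``H_T = (1 - sum_a pbar_a^2) + H_S / (2*ntilde*k)``.
    Loci unusable in any group (n_genes < 2) are NaN.
    """
    k = len(group_counts)
    n_loci = len(group_counts[0])
    hs = np.full(n_loci, np.nan)
    ht = np.full(n_loci, np.nan)
    for l in range(n_loci):
        locus = [gc[l] for gc in group_counts]
        if any(lc.n_genes < 2 for lc in locus):
            continue
        all_sizes = np.unique(np.concatenate([lc.sizes for lc in locus]))
        P = np.zeros((k, len(all_sizes)))
        for j, lc in enumerate(locus):
            idx = np.searchsorted(all_sizes, lc.sizes)
            P[j, idx] = lc.counts / lc.n_genes
        ntilde = k / np.sum([2.0 / lc.n_genes for lc in locus])  # harmonic, diploids
        h_s = 1.0 - np.mean(np.sum(P * P, axis=1))
        pbar = P.mean(axis=0)
        h_t = 1.0 - np.sum(pbar * pbar)
        hs[l] = 2 * ntilde / (2 * ntilde - 1) * h_s
        ht[l] = h_t + hs[l] / (2 * ntilde * k)
    return hs, ht


def _mean_components(group_counts: list[AlleleCounts]) -> tuple[float, float, int]:
    hs, ht = _nei_chesser_components(group_counts)
    ok = ~np.isnan(hs)
    if not ok.any():
        logger.warning("no usable locus for differentiation")
        return float("nan"), float("nan"), len(group_counts)
    return float(hs[ok].mean()), float(ht[ok].mean()), len(group_counts)


def global_gst_nei_chesser(group_counts: list[AlleleCounts]) -> float:
    """Nei-Chesser G_ST = (H_T - H_S)/H_T over k >= 2 groups (multilocus)."""
    if len(group_counts) < 2:
        raise ValueError("G_ST needs at least 2 groups")
    hs, ht, _ = _mean_components(group_counts)
    if not np.isfinite(ht) or ht <= 0:
        logger.warning("H_T = 0; G_ST undefined")
        return float("nan")
    return (ht - hs) / ht


def pairwise_gst_double_prime(ca: AlleleCounts, cb: AlleleCounts) -> float:
    """Hedrick-Meirmans G''_ST for two groups (k = 2)."""
    return _gst_double_prime([ca, cb])


def _gst_double_prime(group_counts: list[AlleleCounts]) -> float:
    k = len(group_counts)
    hs, ht, _ = _mean_components(group_counts)
    denom = (k * ht - hs) * (1.0 - hs)
    if not np.isfinite(denom) or denom == 0:
        logger.warning("degenerate components; G''_ST undefined")
        return float("nan")
    return k * (ht - hs) / denom


def pairwise_jost_d(ca: AlleleCounts, cb: AlleleCounts) -> float:
    """Jost's D_EST for two groups (k = 2), unbiased components."""
    k = 2
    hs, ht, _ = _mean_components([ca, cb])
    if not np.isfinite(hs) or hs >= 1.0:
        logger.warning("H_S = 1; D undefined")
        return float("nan")
    return (k / (k - 1)) * (ht - hs) / (1.0 - hs)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def diversity_table(
    ds: GenotypeDataset,
    groups: list[tuple[str, str, list[str]]],
    rarefaction_g: int | None = None,
    reference: AlleleCounts | None = None,
) -> pd.DataFrame:
    """Per-group summary: n, A_N, A_R(g), A_P(g), H_O, H_E, F_IS, r_w.

    ``rarefaction_g`` defaults to the smallest per-locus gene-copy count
    across all groups (the largest size every group supports).
    """
    counts = [allele_counts(ds, m) for _, _, m in groups]
    if rarefaction_g is None:
        rarefaction_g = int(min(lc.n_genes for gc in counts for lc in gc))
    # relatedness reference: pooled sample of the same period (dyad-independent)
    period_reference: dict[str, AlleleCounts] = {}
    if reference is None:
        for period in {p for _, p, _ in groups}:
            members = [m for _, p, mm in groups if p == period for m in mm]
            period_reference[period] = allele_counts(ds, members)
    ap_locus, ap_mean = (
        rarefied_private_allelic_richness(counts, rarefaction_g)
        if len(groups) >= 2
        else (np.full((1, ds.n_loci), np.nan), np.array([np.nan]))
    )
    rows = []
    for j, ((area, period, members), gc) in enumerate(zip(groups, counts)):
        _, he = unbiased_expected_het(gc)
        _, ho = observed_het(ds, members)
        _, ar = rarefied_allelic_richness(gc, rarefaction_g)
        _, fis = inbreeding_fis(ds, members)
        ref = reference if reference is not None else period_reference[period]
        rw = mean_pairwise_relatedness(ds, members, reference=ref)
        rows.append(
            {
                "area": area,
                "period": period,
                "n": len(members),
                "AN": mean_alleles_per_locus(gc),
                "AR": ar,
                "AP": float(ap_mean[j]),
                "HO": ho,
                "HE": he,
                "FIS": fis,
                "rw": rw,
                "g": rarefaction_g,
            }
        )
    return pd.DataFrame(rows)


def pairwise_table(
    ds: GenotypeDataset, groups: list[tuple[str, str, list[str]]]
) -> pd.DataFrame:
    """Long-format pairwise G''_ST and D_EST over the given groups."""
    counts = [allele_counts(ds, m) for _, _, m in groups]
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ai, pi, _ = groups[i]
            aj, pj, _ = groups[j]
            rows.append(
                {
                    "area_1": ai,
                    "period_1": pi,
                    "area_2": aj,
                    "period_2": pj,
                    "Gpp": pairwise_gst_double_prime(counts[i], counts[j]),
                    "D": pairwise_jost_d(counts[i], counts[j]),
                }
            )
    return pd.DataFrame(rows)
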