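import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from icedrift import divstats
from icedrift.divstats import (
    LocusCounts,
    allele_counts,
    global_gst_nei_chesser,
    inbreeding_fis,
    mean_pairwise_relatedness,
    observed_het,
    pairwise_gst_double_prime,
    pairwise_jost_d,
    rarefied_allelic_richness,
    rarefied_private_allelic_richness,
    unbiased_expected_het,
)

from conftest import make_dataset


def lc(counts):
    counts = np.asarray(counts, dtype=np.int64)
    sizes = 100 + 2 * np.arange(len(counts))
    keep = counts > 0
    return LocusCounts(sizes=sizes[keep], counts=counts[keep], n_genes=int(counts.sum()))


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def test_unbiased_het_examples():
    assert unbiased_expected_het([lc([4])])[1] == 0.0  # monomorphic
    # 2 diploids with alleles {A,A,B,B}: (4/3)(1 - 0.5)
    assert unbiased_expected_het([lc([2, 2])])[1] == pytest.approx(2 / 3)


def test_unbiased_het_asymptotic(rng):
    genes = rng.choice([100, 102], size=20_000, p=[0.5, 0.5])
    s, c = np.unique(genes, return_counts=True)
    locus = LocusCounts(sizes=s, counts=c, n_genes=genes.size)
    assert unbiased_expected_het([locus])[1] == pytest.approx(0.5, abs=0.01)


def test_observed_het_counts():
    ds = make_dataset(
        [
            [[100, 102]],
            [[100, 104]],
            [[100, 100]],
            [[102, 104]],
        ]
    )
    per_locus, mean = observed_het(ds)
    assert mean == pytest.approx(0.75)
    homo = make_dataset([[[100, 100]], [[102, 102]]])
    assert observed_het(homo)[1] == 0.0
    het = make_dataset([[[100, 102]], [[102, 104]]])
    assert observed_het(het)[1] == 1.0


# ---------------------------------------------------------------------------
# rarefaction vs exhaustive enumeration
# ---------------------------------------------------------------------------

def oracle_ar(counts, g):
    """Mean allele count over every g-subset of the gene copies (exact)."""
    genes = [a for a, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(genes)), g))
    tot = Fraction(0)
    for sub in subsets:
        tot += len({genes[i] for i in sub})
    return tot / len(subsets)


def all_partitions(n):
    """All allele-count configurations (partitions) of n gene copies."""
    def parts(n, mx):
        if n == 0:
            yield ()
            return
        for first in range(min(n, mx), 0, -1):
            for rest in parts(n - first, first):
                yield (first,) + rest

    return list(parts(n, n))


def test_allelic_richness_matches_enumeration_exhaustively():
    """A_R(g) equals subset enumeration for every configuration, n_genes <= 8."""
    for n in range(2, 9):
        for config in all_partitions(n):
            locus = [lc(list(config))]
            for g in range(1, n + 1):
                expected = float(oracle_ar(list(config), g))
                assert rarefied_allelic_richness(locus, g)[1] == expected, (config, g)


def test_allelic_richness_examples():
    assert rarefied_allelic_richness([lc([3, 1])], 2)[1] == pytest.approx(1.5)
    assert rarefied_allelic_richness([lc([5, 2, 1])], 1)[1] == 1.0  # g=1
    # g = n_genes recovers the observed allele count
    assert rarefied_allelic_richness([lc([5, 2, 1])], 8)[1] == 3.0


def test_allelic_richness_g_too_large():
    with pytest.raises(ValueError, match="exceeds"):
        rarefied_allelic_richness([lc([2, 1])], 4)


def oracle_ap(groups, g):
    """Private richness of group 0 by enumerating subsets jointly.

    ``groups``: list of per-group count vectors over a shared allele index.
    """
    gene_lists = [
        [a for a, c in enumerate(counts) for _ in range(c)] for counts in groups
    ]
    subset_lists = [
        list(itertools.combinations(genes, g)) for genes in gene_lists
    ]
    total = Fraction(0)
    n_combo = 0
    for combo in itertools.product(*subset_lists):
        n_combo += 1
        focal = set(combo[0])
        others = set().union(*combo[1:])
        total += len(focal - others)
    return total / n_combo


def test_private_richness_matches_enumeration(rng):
    for _ in range(25):
        n_alleles = int(rng.integers(2, 4))
        n_groups = int(rng.integers(2, 4))
        groups = []
        for _ in range(n_groups):
            counts = rng.multinomial(int(rng.integers(2, 7)), np.ones(n_alleles) / n_alleles)
            while counts.sum() < 2:
                counts = rng.multinomial(3, np.ones(n_alleles) / n_alleles)
            groups.append(counts)
        g = int(rng.integers(1, min(c.sum() for c in groups) + 1))
        loci = [
            [LocusCounts(
                sizes=100 + 2 * np.arange(n_alleles)[c > 0],
                counts=c[c > 0],
                n_genes=int(c.sum()),
            )]
            for c in groups
        ]
        per_locus, _ = rarefied_private_allelic_richness(loci, g)
        expected = float(oracle_ap([list(c) for c in groups], g))
        assert per_locus[0, 0] == pytest.approx(expected, abs=1e-12), (groups, g)


def test_private_richness_examples():
    focal = [lc([3, 1])]
    other = [lc([4, 0])]
    per_locus, mean = rarefied_private_allelic_richness([focal, other], 2)
    # allele B: Q_focal(2) = 1 - C(3,2)/C(4,2) = 1/2, absent elsewhere
    assert mean[0] == pytest.approx(0.5)
    # alleles at high count in every group are essentially never private
    a = [lc([10, 10])]
    b = [lc([10, 10])]
    _, m = rarefied_private_allelic_richness([a, b], 10)
    assert m[0] < 1e-3
    with pytest.raises(ValueError, match="2 groups"):
        rarefied_private_allelic_richness([focal], 2)


def test_richness_monotonicity_properties():
    locus = [lc([6, 3, 2, 1])]
    values = [rarefied_allelic_richness(locus, g)[1] for g in range(1, 13)]
    assert all(b >= a for a, b in zip(values, values[1:]))
    groups = [[lc([5, 3, 1, 0])], [lc([2, 0, 2, 3])]]
    ap, _ = rarefied_private_allelic_richness(groups, 4)
    ar = rarefied_allelic_richness(groups[0], 4)[0]
    assert ap[0, 0] <= ar[0] + 1e-12


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------

def test_fis_all_homozygous_polymorphic():
    ds = make_dataset([[[100, 100]], [[102, 102]], [[104, 104]]])
    assert inbreeding_fis(ds)[1] == pytest.approx(1.0)


def test_fis_zero_under_random_mating(rng):
    p = np.array([0.4, 0.3, 0.2, 0.1])
    sizes = np.array([100, 102, 104, 106])
    fis_vals = []
    for _ in range(40):
        alleles = rng.choice(sizes, size=(60, 10, 2), p=p)
        ds = make_dataset(alleles)
        fis_vals.append(inbreeding_fis(ds)[1])
    se = np.std(fis_vals, ddof=1) / np.sqrt(len(fis_vals))
    assert abs(np.mean(fis_vals)) < 2 * se + 0.01


def test_fis_undefined_when_monomorphic():
    ds = make_dataset([[[100, 100]], [[100, 100]]])
    assert np.isnan(inbreeding_fis(ds)[1])


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def _dyad_sets(rng, kind, n_dyads=150, L=22, K=8):
    sizes = 100 + 2 * np.arange(K)
    a = rng.choice(sizes, size=(n_dyads, L, 2))
    b = np.empty_like(a)
    if kind == "unrelated":
        b = rng.choice(sizes, size=(n_dyads, L, 2))
    elif kind == "parent-offspring":
        pick = rng.integers(0, 2, size=(n_dyads, L))
        b[:, :, 0] = np.take_along_axis(a, pick[:, :, None], axis=2)[:, :, 0]
        b[:, :, 1] = rng.choice(sizes, size=(n_dyads, L))
    elif kind == "full-sib":
        other = rng.choice(sizes, size=(n_dyads, L, 2))  # second parent
        pa = rng.integers(0, 2, size=(n_dyads, L))
        pb = rng.integers(0, 2, size=(n_dyads, L))
        b[:, :, 0] = np.take_along_axis(a, pa[:, :, None], axis=2)[:, :, 0]
        b[:, :, 1] = np.take_along_axis(other, pb[:, :, None], axis=2)[:, :, 0]
        # resample the 'a' side as a sibling from the same parents
        qa = rng.integers(0, 2, size=(n_dyads, L))
        qb = rng.integers(0, 2, size=(n_dyads, L))
        a = np.stack(
            [
                np.take_along_axis(a, qa[:, :, None], axis=2)[:, :, 0],
                np.take_along_axis(other, qb[:, :, None], axis=2)[:, :, 0],
            ],
            axis=2,
        )
    return a, b


@pytest.mark.parametrize(
    "kind,expected",
    [("unrelated", 0.0), ("parent-offspring", 0.5), ("full-sib", 0.5)],
)
def test_queller_goodnight_pedigree_expectations(rng, kind, expected):
    a, b = _dyad_sets(rng, kind)
    n = a.shape[0]
    ds = make_dataset(np.concatenate([a, b]))
    ref = allele_counts(ds)
    rs = [
        mean_pairwise_relatedness(ds, [f"ind{d:03d}", f"ind{d + n:03d}"], reference=ref)
        for d in range(n)
    ]
    se = np.std(rs, ddof=1) / np.sqrt(len(rs))
    assert np.mean(rs) == pytest.approx(expected, abs=2 * se + 0.01)


def test_relatedness_monomorphic_panel_is_nan():
    ds = make_dataset(np.full((4, 3, 2), 100))
    assert np.isnan(mean_pairwise_relatedness(ds, ds.ids))


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _two_samples(rng, n=500, L=22, K=8, same_pool=True):
    p = rng.dirichlet(np.full(K, 2.0), size=L)
    sizes = 100 + 2 * np.arange(K)

    def draw():
        a = np.empty((n, L, 2), dtype=np.int64)
        for l in range(L):
            a[:, l, :] = rng.choice(sizes, size=(n, 2), p=p[l])
        return a

    return draw(), draw()


def test_differentiation_identical_duplicates_near_zero(rng):
    a, _ = _two_samples(rng)
    c = allele_counts(make_dataset(a))
    assert abs(pairwise_gst_double_prime(c, c)) < 0.01
    assert abs(pairwise_jost_d(c, c)) < 0.01
    assert abs(global_gst_nei_chesser([c, c])) < 0.01


def test_differentiation_disjoint_fixed_alleles_is_one():
    c1 = allele_counts(make_dataset(np.full((20, 5, 2), 100)))
    c2 = allele_counts(make_dataset(np.full((20, 5, 2), 104)))
    assert pairwise_gst_double_prime(c1, c2) == pytest.approx(1.0)
    assert pairwise_jost_d(c1, c2) == pytest.approx(1.0)
    assert global_gst_nei_chesser([c1, c2]) == pytest.approx(1.0)
    # k groups each fixed for a unique allele
    cs = [allele_counts(make_dataset(np.full((15, 5, 2), 100 + 2 * j))) for j in range(4)]
    assert global_gst_nei_chesser(cs) == pytest.approx(1.0)


def test_differentiation_panmictic_pool_near_zero(rng):
    a, b = _two_samples(rng)
    ca = allele_counts(make_dataset(a))
    cb = allele_counts(make_dataset(b))
    assert abs(pairwise_gst_double_prime(ca, cb)) < 0.01
    assert abs(pairwise_jost_d(ca, cb)) < 0.01
    assert abs(global_gst_nei_chesser([ca, cb])) < 0.01


def test_differentiation_invariances(rng):
    a, b = _two_samples(rng, n=40, L=6)
    ca = allele_counts(make_dataset(a))
    cb = allele_counts(make_dataset(b))
    base = pairwise_gst_double_prime(ca, cb)
    # relabeling every allele (shared shift) leaves differentiation unchanged
    shifted = pairwise_gst_double_prime(
        allele_counts(make_dataset(a + 10)), allele_counts(make_dataset(b + 10))
    )
    assert shifted == pytest.approx(base)
    # individual order does not matter
    perm = rng.permutation(40)
    reordered = allele_counts(make_dataset(a[perm]))
    assert pairwise_gst_double_prime(reordered, cb) == pytest.approx(base)


def test_gpp_upper_bounds_gst(rng):
    # moderately diverged groups: G''_ST >= G_ST
    sizes = 100 + 2 * np.arange(6)
    p1 = np.array([0.5, 0.2, 0.1, 0.1, 0.05, 0.05])
    p2 = np.array([0.1, 0.1, 0.45, 0.15, 0.1, 0.1])
    a = rng.choice(sizes, size=(80, 10, 2), p=p1)
    b = rng.choice(sizes, size=(80, 10, 2), p=p2)
    ca, cb = allele_counts(make_dataset(a)), allele_counts(make_dataset(b))
    gpp = pairwise_gst_double_prime(ca, cb)
    gst = global_gst_nei_chesser([ca, cb])
    assert gpp >= gst > 0


def test_diversity_table_shapes(structured_dataset):
    from icedrift.genio import assign_periods, filter_min_group_size

    ds, _, spec = structured_dataset
    gt = filter_min_group_size(assign_periods(ds))
    table = divstats.diversity_table(ds, gt.groups)
    assert len(table) == len(gt.groups)
    assert ((table["HE"] >= 0) & (table["HE"] <= 1)).all()
    assert ((table["HO"] >= 0) & (table["HO"] <= 1)).all()
    assert (table["AR"] <= table["AN"] + 1e-9).all()
    assert (table["AP"] <= table["AR"] + 1e-9).all()
    assert table["FIS"].between(-1, 1).all()
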