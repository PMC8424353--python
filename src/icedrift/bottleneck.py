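"""Recent-bottleneck tests for microsatellite panels.

Two classic signals of a recent contraction are implemented:

* The Garza-Williamson M-ratio: the number of observed alleles divided by
  the number of occupied-plus-vacant bins on the size lattice spanned by
  the observed range.  Bottlenecks knock out rare size classes faster
  than they shrink the range, so low M (conventionally < 0.7) flags a
  contraction.

* The heterozygosity-excess test: after a contraction, allele number
  drops faster than gene diversity, so observed H_E exceeds the
  mutation-drift-equilibrium expectation *given the observed allele
  count*.  The equilibrium distribution of H for a sample of n gene
  copies carrying exactly k alleles is obtained by coalescent simulation
  under a stepwise (SMM) or two-phase (TPM) mutation model, with the
  scaled mutation rate theta calibrated by bisection so the expected
  allele count matches k, and conditioning on k by rejection.  Per-locus
  standardized deviations are combined with a one-tailed Wilcoxon
  signed-rank test.

The coalescent sampler uses the Ethier-Griffiths urn: replaying the
time-reversed sequence of coalescence and mutation events forward from
the most recent common ancestor yields an exact stationary sample
without building the genealogy explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .divstats import AlleleCounts

logger = logging.getLogger(__name__)

#: conventional bottleneck flag threshold for the mean M-ratio
M_RATIO_THRESHOLD = 0.7

#: loci up to this count use the exact Wilcoxon null distribution
WILCOXON_EXACT_MAX = 25


@dataclass(frozen=True)
class MutationModel:
    """Microsatellite mutation model for equilibrium simulation.

    ``kind='smm'`` is the strict stepwise model (every mutation moves the
    allele +-1 repeat).  ``kind='tpm'`` mixes single steps with
    multi-step jumps: a mutation is multi-step with probability
    ``p_multistep`` and then jumps a geometrically distributed number of
    repeats with mean ``geometric_mean``.
    """

    kind: str = "tpm"
    p_multistep: float = 0.22
    geometric_mean: float = 3.1

    def __post_init__(self) -> None:
        if self.kind not in ("smm", "tpm"):
            raise ValueError(f"unknown mutation model {self.kind!r}")
        if not 0.0 <= self.p_multistep <= 1.0:
            raise ValueError("p_multistep must be in [0, 1]")
        if self.geometric_mean <= 0:
            raise ValueError("geometric_mean must be positive")

    def effective_p_multistep(self) -> float:
        return 0.0 if self.kind == "smm" else self.p_multistep


SMM = MutationModel(kind="smm")
TPM_DEFAULT = MutationModel(kind="tpm")


@dataclass
class MRatioResult:
    per_locus: pd.DataFrame  # locus, k, min, max, repeat_unit, M
    mean_m: float
    flagged: bool  # mean M strictly below the 0.7 convention


@dataclass
class HetExcessResult:
    per_locus: pd.DataFrame  # locus, n_genes, k, He_obs, He_eq_mean, He_eq_sd, deviation
    p_value: float  # one-tailed Wilcoxon signed-rank, H1: excess
    model: MutationModel
    reps: int


# ---------------------------------------------------------------------------
# M-ratio
# ---------------------------------------------------------------------------

def m_ratio(
    counts: AlleleCounts,
    repeat_units: list[int] | int = 2,
    locus_names: list[str] | None = None,
) -> MRatioResult:
    """Garza-Williamson M = k / (1 + (max - min)/repeat_unit), per locus and mean.

    Allele sizes must sit on the locus's repeat lattice; monomorphic loci
    are excluded with a warning.
    """
    if isinstance(repeat_units, int):
        repeat_units = [repeat_units] * len(counts)
    rows = []
    for l, (lc, unit) in enumerate(zip(counts, repeat_units)):
        name = locus_names[l] if locus_names else f"L{l + 1}"
        if len(lc.sizes) < 2:
            logger.warning("locus %s monomorphic; excluded from M-ratio", name)
            continue
        lo, hi = int(lc.sizes.min()), int(lc.sizes.max())
        off = (lc.sizes - lo) % unit
        if np.any(off != 0):
            bad = int(lc.sizes[np.nonzero(off)[0][0]])
            raise ValueError(
                f"allele size {bad} at locus {name} is off the {unit}-bp lattice"
            )
        bins = 1 + (hi - lo) // unit
        rows.append(
            {
                "locus": name,
                "k": len(lc.sizes),
                "min": lo,
                "max": hi,
                "repeat_unit": unit,
                "M": len(lc.sizes) / bins,
            }
        )
    if not rows:
        raise ValueError("no polymorphic locus; M-ratio undefined")
    df = pd.DataFrame(rows)
    mean_m = float(df["M"].mean())
    return MRatioResult(per_locus=df, mean_m=mean_m, flagged=mean_m < M_RATIO_THRESHOLD)


# ---------------------------------------------------------------------------
# coalescent equilibrium sampler
# ---------------------------------------------------------------------------

def sample_equilibrium_locus(
    n: int, theta: float, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """One stationary sample of n gene copies: allele states in repeat units.

    Backward in time, with j lineages, the number of mutations before the
    next coalescence is geometric with success probability
    (j-1)/(theta + j - 1).  Replayed forward from the common ancestor:
    a lineage splits, then that stage's mutations hit uniform lineages.
    """
    states = np.zeros(n, dtype=np.int64)
    p_mult = model.effective_p_multistep()
    for j in range(2, n + 1):
        # split: copy a uniform lineage
        src = rng.integers(j - 1)
        states[j - 1] = states[src]
        m = rng.geometric((j - 1) / (theta + j - 1)) - 1
        if m:
            targets = rng.integers(j, size=m)
            steps = np.ones(m, dtype=np.int64)
            if p_mult > 0.0:
                multi = rng.random(m) < p_mult
                nm = int(multi.sum())
                if nm:
                    steps[multi] = rng.geometric(1.0 / model.geometric_mean, size=nm)
            signs = rng.integers(0, 2, size=m) * 2 - 1
            np.add.at(states, targets, signs * steps)
    return states


def _unbiased_het_from_states(states: np.ndarray) -> tuple[float, int]:
    n = states.size
    _, c = np.unique(states, return_counts=True)
    p = c / n
    return n / (n - 1) * (1.0 - float(np.sum(p * p))), len(c)


def _mean_allele_count(
    n: int, theta: float, model: MutationModel, rng: np.random.Generator, reps: int
) -> float:
    ks = [
        len(np.unique(sample_equilibrium_locus(n, theta, model, rng)))
        for _ in range(reps)
    ]
    return float(np.mean(ks))


def calibrate_theta(
    n: int,
    k: int,
    model: MutationModel,
    rng: np.random.Generator,
    reps: int = 400,
    iters: int = 14,
) -> float:
    """Bisection on log(theta) so the expected equilibrium allele count is k."""
    if k < 2 or n < k:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    lo, hi = 1e-3, 1.0
    while _mean_allele_count(n, hi, model, rng, reps) < k and hi < 1e4:
        hi *= 4.0
    while _mean_allele_count(n, lo, model, rng, reps) > k and lo > 1e-6:
        lo /= 4.0
    for _ in range(iters):
        mid = float(np.sqrt(lo * hi))
        if _mean_allele_count(n, mid, model, rng, reps) < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


@dataclass
class _EqDist:
    mean: float
    sd: float
    samples: np.ndarray
    theta: float


class EquilibriumCache:
    """Memoized equilibrium H distributions keyed by (n, k, model, reps)."""

    def __init__(self) -> None:
        self._store: dict = {}

    def get(
        self,
        n: int,
        k: int,
        model: MutationModel,
        reps: int,
        rng: np.random.Generator,
        max_attempts: int = 1_000_000,
    ) -> _EqDist:
        key = (n, k, model.kind, model.p_multistep, model.geometric_mean, reps)
        if key not in self._store:
            samples, theta = simulate_equilibrium_het(
                n, k, model, reps, rng, max_attempts=max_attempts
            )
            self._store[key] = _EqDist(
                mean=float(samples.mean()),
                sd=float(samples.std(ddof=1)),
                samples=samples,
                theta=theta,
            )
        return self._store[key]


def simulate_equilibrium_het(
    n: int,
    k: int,
    model: MutationModel,
    reps: int,
    rng: np.random.Generator,
    max_attempts: int = 1_000_000,
    theta: float | None = None,
) -> tuple[np.ndarray, float]:
    """Equilibrium distribution of unbiased H for samples of n gene copies
    carrying exactly k alleles.

    theta is calibrated by bisection (unless given) and the conditioning
    on the observed allele count is by rejection, capped at
    ``max_attempts`` simulations.
    Returns ``(samples, theta)`` with ``len(samples) == reps``.
    """
    if k < 2:
        raise ValueError("heterozygosity-excess needs polymorphic loci (k >= 2)")
    if n < k:
        raise ValueError(f"cannot have k={k} alleles among n={n} gene copies")
    if theta is None:
        theta = calibrate_theta(n, k, model, rng)
    out = np.empty(reps)
    got = 0
    attempts = 0
    while got < reps:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not condition on k={k} (n={n}) after {max_attempts} attempts"
            )
        states = sample_equilibrium_locus(n, theta, model, rng)
        attempts += 1
        he, kk = _unbiased_het_from_states(states)
        if kk == k:
            out[got] = he
            got += 1
    return out, theta


# ---------------------------------------------------------------------------
# heterozygosity-excess test
# ---------------------------------------------------------------------------

def het_excess_test(
    counts: AlleleCounts,
    model: MutationModel = TPM_DEFAULT,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    cache: EquilibriumCache | None = None,
    locus_names: list[str] | None = None,
) -> HetExcessResult:
    """One-tailed heterozygosity-excess test for one group.

    Per polymorphic locus, the observed unbiased H_E is located within
    the simulated equilibrium distribution given (n, k).  Two per-locus
    summaries are computed: the mean/SD-standardized deviation
    (descriptive), and the normal quantile of the conditional mid-p
    value ``P(H_eq < He_obs) + 0.5 P(H_eq = He_obs)``.  The Wilcoxon
    signed-rank test (alternative: excess) runs on the quantile scores,
    which are symmetric around zero at mutation-drift equilibrium —
    the raw standardized deviations are left-skewed under the null,
    which would inflate the one-tailed error rate.  Needs >= 4 usable
    loci.
    """
    rng = np.random.default_rng() if rng is None else rng
    cache = EquilibriumCache() if cache is None else cache
    rows = []
    for l, lc in enumerate(counts):
        name = locus_names[l] if locus_names else f"L{l + 1}"
        if len(lc.sizes) < 2 or lc.n_genes < 4:
            logger.info("locus %s unusable for het-excess (k<2 or n<4)", name)
            continue
        he_obs = lc.n_genes / (lc.n_genes - 1) * (
            1.0 - float(np.sum((lc.counts / lc.n_genes) ** 2))
        )
        dist = cache.get(lc.n_genes, len(lc.sizes), model, reps, rng)
        midp = float(
            np.mean(dist.samples < he_obs) + 0.5 * np.mean(dist.samples == he_obs)
        )
        midp = min(max(midp, 0.5 / reps), 1.0 - 0.5 / reps)
        rows.append(
            {
                "locus": name,
                "n_genes": lc.n_genes,
                "k": len(lc.sizes),
                "He_obs": he_obs,
                "He_eq_mean": dist.mean,
                "He_eq_sd": dist.sd,
                "deviation": (he_obs - dist.mean) / dist.sd,
                "quantile_score": float(st.norm.ppf(midp)),
            }
        )
    if len(rows) < 4:
        raise ValueError(f"only {len(rows)} usable loci; need >= 4 for the Wilcoxon test")
    df = pd.DataFrame(rows)
    method = "exact" if len(df) <= WILCOXON_EXACT_MAX else "approx"
    res = st.wilcoxon(
        df["quantile_score"].to_numpy(), alternative="greater", method=method
    )
    return HetExcessResult(
        per_locus=df, p_value=float(res.pvalue), model=model, reps=reps
    )


def bottleneck_table(
    group_counts: dict[str, AlleleCounts],
    repeat_units: list[int] | int = 2,
    model: MutationModel = TPM_DEFAULT,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    locus_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group bottleneck summary: mean M, flag, Wilcoxon excess p."""
    rng = np.random.default_rng() if rng is None else rng
    cache = EquilibriumCache()
    rows = []
    for label, counts in group_counts.items():
        mres = m_ratio(counts, repeat_units, locus_names)
        hres = het_excess_test(
            counts, model=model, reps=reps, rng=rng, cache=cache, locus_names=locus_names
        )
        rows.append(
            {
                "group": label,
                "mean_M": mres.mean_m,
                "M_flag": mres.flagged,
                "het_excess_p": hres.p_value,
                "reps": reps,
                "model": model.kind,
                "p_multistep": model.effective_p_multistep(),
            }
        )
    return pd.DataFrame(rows)
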