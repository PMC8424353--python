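"""Synthetic microsatellite datasets with known truth for every pipeline stage.

The generator emulates the spatio-temporal monitoring design this
package analyses — four sampling areas crossed with five multi-year
periods, 22 dinucleotide loci, around 600 individuals — without
claiming the real allele-frequency distributions.

Two levels of truth injection are provided:

* genotype level (:func:`generate_panmictic`,
  :func:`generate_structured_series`): area differentiation follows the
  Balding-Nichols model (per-area allele frequencies drawn from a
  Dirichlet centred on the period pool with concentration
  (1 - F)/F), which makes the target F_ST of each period an explicit
  parameter; the period pools themselves are deformed so pool gene
  diversity follows a logit-linear path.  Mother-offspring pairs can be
  injected for kin-robustness checks.

* response level (:func:`generate_trend_series`): group-level statistic
  series drawn directly from the trend-model family (Gaussian or beta)
  with a known slope, for calibrating the trend estimators' confidence
  intervals.  Default noise magnitudes are matched to the uncertainty
  typical of 16-group microsatellite monitoring designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genio import DEFAULT_PERIODS, GenotypeDataset, LocusDef

DEFAULT_AREAS = ("NWS", "NES", "SWS", "SES")


@dataclass
class SynthSpec:
    """Configuration of the synthetic monitoring design."""

    n_areas: int = 4
    n_periods: int = 5
    n_per_group: int = 30
    n_loci: int = 22
    min_alleles: int = 5
    max_alleles: int = 12
    repeat_unit: int = 2
    base_size: int = 100
    #: initial pairwise-level F_ST and its per-period logit slope
    fst0: float = 0.01
    fst_logit_slope: float = 0.0
    #: per-period logit slope of pool gene diversity (negative = erosion)
    he_logit_slope: float = 0.0
    kin_fraction: float = 0.0
    area_labels: tuple[str, ...] = DEFAULT_AREAS
    period_bins: tuple = tuple(DEFAULT_PERIODS)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst0 < 1.0:
            raise ValueError("fst0 must be in [0, 1)")
        if not 0.0 <= self.kin_fraction <= 0.5:
            raise ValueError("kin_fraction must be in [0, 0.5]")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    def areas(self) -> list[str]:
        if len(self.area_labels) >= self.n_areas:
            return list(self.area_labels[: self.n_areas])
        return [f"A{i + 1}" for i in range(self.n_areas)]

    def periods(self) -> list[tuple[str, int, int]]:
        return [tuple(b) for b in self.period_bins[: self.n_periods]]

    def fst_path(self) -> np.ndarray:
        t = np.arange(self.n_periods)
        return expit(logit(self.fst0) + self.fst_logit_slope * t)


def _base_panel(spec: SynthSpec, rng: np.random.Generator):
    """Per-locus lattice sizes and Dirichlet base frequencies."""
    loci, freqs = [], []
    for l in range(spec.n_loci):
        k = int(rng.integers(spec.min_alleles, spec.max_alleles + 1))
        sizes = spec.base_size + spec.repeat_unit * np.arange(k)
        p = rng.dirichlet(np.full(k, 2.0))
        loci.append(LocusDef(f"L{l + 1:02d}", spec.repeat_unit))
        freqs.append((sizes, p))
    return loci, freqs


def _deform_to_diversity(p: np.ndarray, target_h: float) -> np.ndarray:
    """Mix p toward its most common allele so that 1 - sum q^2 == target_h.

    Solving the quadratic in the mixing weight w of q = (1-w) p + w e_m;
    only deformation toward lower diversity is supported (w in [0, 1]).
    """
    h0 = 1.0 - float(np.sum(p * p))
    if target_h >= h0:
        return p
    m = int(np.argmax(p))
    e = np.zeros_like(p)
    e[m] = 1.0
    d = e - p
    # h(w) = 1 - sum((p + w d)^2) = h0 - 2w p.d - w^2 d.d
    a = float(np.dot(d, d))
    b = 2.0 * float(np.dot(p, d))
    c = target_h - h0
    disc = b * b - 4 * a * c
    w = (-b + np.sqrt(max(disc, 0.0))) / (2 * a)
    w = float(np.clip(w, 0.0, 1.0))
    return (1 - w) * p + w * e


def _sample_group(
    n: int, sizes: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(sizes, size=(n, 2), p=p)


def _assemble(
    spec: SynthSpec,
    loci: list[LocusDef],
    genotypes: dict[tuple[str, str], np.ndarray],
    provenance: str,
) -> GenotypeDataset:
    meta_rows, blocks = [], []
    counter = 0
    for (area, period), g in genotypes.items():
        lo, hi = None, None
        for label, first, last in spec.periods():
            if label == period:
                lo, hi = first, last
        years = np.linspace(lo, hi, g.shape[0]).round().astype(int)
        for i in range(g.shape[0]):
            counter += 1
            meta_rows.append(
                {
                    "id": f"{area}{period}_{i + 1:03d}",
                    "area": area,
                    "year": int(years[i]),
                    "sex": pd.NA,
                    "mother_id": pd.NA,
                }
            )
        blocks.append(g)
    return GenotypeDataset(
        loci=loci,
        meta=pd.DataFrame(meta_rows),
        alleles=np.concatenate(blocks),
        provenance=provenance,
    )


def generate_panmictic(
    spec: SynthSpec, rng: np.random.Generator | int = 0
) -> GenotypeDataset:
    """HWE genotypes from a single allele-frequency pool for every group."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    loci, freqs = _base_panel(spec, rng)
    genotypes = {}
    for area in spec.areas():
        for label, _, _ in spec.periods():
            g = np.empty((spec.n_per_group, spec.n_loci, 2), dtype=np.int64)
            for l, (sizes, p) in enumerate(freqs):
                g[:, l, :] = _sample_group(spec.n_per_group, sizes, p, rng)
            genotypes[(area, label)] = g
    return _assemble(spec, loci, genotypes, "synthetic panmictic")


def generate_structured_series(
    spec: SynthSpec, rng: np.random.Generator | int = 0
) -> tuple[GenotypeDataset, dict]:
    """Spatio-temporally structured genotypes with a truth record.

    Per period t the locus pools are deformed so pool gene diversity
    follows ``logit(h_t) = logit(h_0) + he_logit_slope * t``; per area,
    frequencies are Balding-Nichols draws around the period pool at the
    period's target F_ST.  With ``fst0 == 0`` and flat paths this reduces
    to the panmictic generator.

    Returns ``(dataset, truth)`` where ``truth`` holds the F_ST path, the
    per-period pool diversities and the injected logit slopes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    loci, freqs = _base_panel(spec, rng)
    fst_path = spec.fst_path() if spec.fst0 > 0 else np.zeros(spec.n_periods)
    pool_h = np.zeros((spec.n_periods, spec.n_loci))
    genotypes: dict[tuple[str, str], np.ndarray] = {}
    areas, periods = spec.areas(), spec.periods()
    for t, (label, _, _) in enumerate(periods):
        pools = []
        for l, (sizes, p) in enumerate(freqs):
            h0 = 1.0 - float(np.sum(p * p))
            target = float(expit(logit(h0) + spec.he_logit_slope * t))
            q = _deform_to_diversity(p, target)
            pool_h[t, l] = 1.0 - float(np.sum(q * q))
            pools.append((sizes, q))
        for area in areas:
            g = np.empty((spec.n_per_group, spec.n_loci, 2), dtype=np.int64)
            for l, (sizes, q) in enumerate(pools):
                if fst_path[t] > 0:
                    conc = (1.0 - fst_path[t]) / fst_path[t]
                    qa = rng.dirichlet(np.maximum(q * conc, 1e-9))
                else:
                    qa = q
                g[:, l, :] = _sample_group(spec.n_per_group, sizes, qa, rng)
            genotypes[(area, label)] = g
    ds = _assemble(spec, loci, genotypes, "synthetic structured series")
    if spec.kin_fraction > 0:
        ds = inject_kin(ds, spec.kin_fraction, rng)
    truth = {
        "fst_path": fst_path,
        "pool_diversity": pool_h,
        "he_logit_slope": spec.he_logit_slope,
        "fst_logit_slope": spec.fst_logit_slope,
        "fst0": spec.fst0,
    }
    return ds, truth


def inject_kin(
    ds: GenotypeDataset, kin_fraction: float, rng: np.random.Generator | int = 0
) -> GenotypeDataset:
    """Replace a fraction of each (area, year-cohort) group's individuals
    with Mendelian offspring of same-group mothers, annotating mother_id.

    The father's gamete is drawn from the group allele frequencies, so
    each replaced individual forms one mother-offspring dyad.
    """
    if not 0.0 <= kin_fraction <= 0.5:
        raise ValueError("kin_fraction must be in [0, 0.5]")
    if kin_fraction == 0.0:
        return ds
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = GenotypeDataset(
        loci=ds.loci,
        meta=ds.meta.copy(),
        alleles=ds.alleles.copy(),
        provenance=ds.provenance + " +kin",
    )
    areas = out.meta["area"].to_numpy()
    for area in pd.unique(areas):
        idx = np.flatnonzero(areas == area)
        n_kin = int(round(kin_fraction * idx.size))
        if n_kin == 0:
            continue
        if idx.size - n_kin < 1:
            raise ValueError(f"group {area!r} too small for kin_fraction {kin_fraction}")
        children = rng.choice(idx, size=n_kin, replace=False)
        eligible = np.setdiff1d(idx, children)
        mothers = rng.choice(eligible, size=n_kin, replace=True)
        L = out.n_loci
        pool = out.alleles[idx].reshape(idx.size, L, 2)
        for c, m in zip(children, mothers):
            mat = out.alleles[m, np.arange(L), rng.integers(0, 2, size=L)]
            pat = np.empty(L, dtype=np.int64)
            for l in range(L):
                genes = pool[:, l, :].ravel()
                genes = genes[genes >= 0]
                pat[l] = rng.choice(genes)
            out.alleles[c, :, 0] = mat
            out.alleles[c, :, 1] = pat
            out.meta.loc[c, "mother_id"] = out.meta.loc[m, "id"]
    return out


# ---------------------------------------------------------------------------
# response-level series for trend-estimator calibration
# ---------------------------------------------------------------------------

#: default noise for the Gaussian family (residual SD on the response scale)
LINEAR_SIGMA = {"AR": 0.17, "rw": 0.038}
#: default beta precision (phi) for the (0,1) family
BETA_PHI = {"HE": 800.0, "Gpp": 120.0}
#: typical intercepts on the response scale
INTERCEPTS = {"AR": 6.0, "rw": 0.0, "HE": 0.62, "Gpp": 0.02}


def generate_trend_series(
    slope: float,
    response: str = "AR",
    family: str | None = None,
    n_areas: int = 4,
    n_periods: int = 4,
    area_sd: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Group-level statistic series with a known time slope.

    ``response`` picks study-scale defaults for the intercept and noise
    ('AR' and 'rw' are Gaussian; 'HE' and 'Gpp' are beta on the logit
    scale).  The design is ``n_areas x n_periods`` rows (16 by default,
    matching the filtered monitoring design) with time indexed 1..n_periods.
    Optional Gaussian area intercepts of SD ``area_sd`` act on the linear
    predictor.  Columns: area, time, response.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if family is None:
        family = "linear" if response in LINEAR_SIGMA else "beta"
    t = np.tile(np.arange(1, n_periods + 1), n_areas)
    area = np.repeat([f"A{i + 1}" for i in range(n_areas)], n_periods)
    a_eff = np.repeat(rng.normal(0.0, area_sd, size=n_areas), n_periods)
    mu0 = INTERCEPTS.get(response, 0.5)
    if family == "linear":
        sigma = LINEAR_SIGMA.get(response, 0.1)
        y = mu0 + slope * t + a_eff + rng.normal(0.0, sigma, size=t.size)
    elif family == "beta":
        phi = BETA_PHI.get(response, 200.0)
        eta = logit(mu0) + slope * t + a_eff
        mu = expit(eta)
        y = rng.beta(mu * phi, (1.0 - mu) * phi)
    else:
        raise ValueError(f"unknown family {family!r}")
    return pd.DataFrame({"area": area, "time": t, "response": y})
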