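"""Data model, file I/O and spatio-temporal grouping for diploid microsatellite panels.

The central container is :class:`GenotypeDataset`: an individuals x loci x 2
integer array of allele sizes (base pairs) plus per-individual metadata
(sampling area, sampling year, optional sex and mother id).  Missing alleles
are encoded as :data:`MISSING`.

Two text formats are supported, Genepop and the two-row STRUCTURE layout,
both with round-trip writers.  Grouping assigns each individual to one
(area, period) cell of the monitoring design and applies the minimum
group-size filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing allele
MISSING: int = -1

#: default five-period binning of the 1995-2016 monitoring design
DEFAULT_PERIODS: list[tuple[str, int, int]] = [
    ("T1", 1995, 1999),
    ("T2", 2000, 2004),
    ("T3", 2005, 2009),
    ("T4", 2010, 2014),
    ("T5", 2015, 2016),
]


class ParseError(ValueError):
    """Raised when an input genotype file violates its format contract."""


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: label and base-pair step of its repeat motif."""

    name: str
    repeat_unit: int = 2
    motif_offset: int | None = None

    def __post_init__(self) -> None:
        if self.repeat_unit < 1:
            raise ValueError(f"repeat_unit must be >= 1, got {self.repeat_unit}")


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with individual metadata.

    Parameters
    ----------
    loci
        Ordered locus panel; every individual is typed on this panel.
    meta
        One row per individual with columns ``id``, ``area``, ``year`` and
        optionally ``sex`` and ``mother_id``.
    alleles
        ``(n_individuals, n_loci, 2)`` integer allele sizes in base pairs,
        :data:`MISSING` where untyped.  A locus with any missing allele in an
        individual is treated as entirely missing for that individual.
    """

    loci: list[LocusDef]
    meta: pd.DataFrame
    alleles: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, n_loci, 2)")
        if self.alleles.shape[0] != len(self.meta):
            raise ValueError("metadata and allele matrix disagree on n")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("locus panel and allele matrix disagree on loci")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        ids = self.meta["id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        self.meta = self.meta.reset_index(drop=True)
        # half-missing genotypes are not meaningful: propagate missingness
        half = (self.alleles == MISSING).any(axis=2)
        self.alleles[half] = MISSING

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    @property
    def ids(self) -> list[str]:
        return self.meta["id"].astype(str).tolist()

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n, n_loci)`` mask of fully typed genotypes."""
        return (self.alleles != MISSING).all(axis=2)

    def indices_of(self, ids: list[str]) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None

    def subset(self, ids: list[str]) -> "GenotypeDataset":
        idx = self.indices_of(ids)
        return GenotypeDataset(
            loci=self.loci,
            meta=self.meta.iloc[idx].reset_index(drop=True),
            alleles=self.alleles[idx].copy(),
            provenance=self.provenance,
        )


@dataclass
class GroupTable:
    """The spatio-temporal partition: (area, period) groups and their members."""

    groups: list[tuple[str, str, list[str]]]
    period_bins: list[tuple[str, int, int]]
    removed: list[tuple[str, str, int]] = field(default_factory=list)

    def sizes(self) -> pd.DataFrame:
        rows = [
            {"area": a, "period": p, "n": len(members)}
            for a, p, members in self.groups
        ]
        return pd.DataFrame(rows, columns=["area", "period", "n"])

    def members(self, area: str, period: str) -> list[str]:
        for a, p, m in self.groups:
            if a == area and p == period:
                return m
        raise KeyError(f"no group ({area}, {period})")

    def all_member_ids(self) -> list[str]:
        out: list[str] = []
        for _, _, m in self.groups:
            out.extend(m)
        return out

    @property
    def period_labels(self) -> list[str]:
        return [label for label, _, _ in self.period_bins]


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def _split_sample_id(raw: str) -> tuple[str, str | None, int | None]:
    """Decode ``id`` / ``area:id`` / ``area:id:year`` sample labels."""
    parts = raw.split(":")
    if len(parts) == 1:
        return parts[0], None, None
    if len(parts) == 2:
        return parts[1], parts[0], None
    return parts[1], parts[0], int(parts[2])


def read_genepop(
    path,
    repeat_units: list[int] | int = 2,
    code_offset: int = 0,
    area_labels: list[str] | None = None,
) -> GenotypeDataset:
    """Read a Genepop text file into a :class:`GenotypeDataset`.

    Allele codes (2- or 3-digit per allele) are interpreted as fragment
    sizes after adding ``code_offset``; code 0 is the missing marker.
    POP blocks become sampling areas unless the sample labels embed
    ``area:id:year`` metadata (the convention :func:`write_genepop` uses)
    or ``area_labels`` overrides them.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError(f"{path}: empty file")
    title = lines[0].strip()

    is_pop = lambda s: s.strip().lower() == "pop"
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not is_pop(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if i >= len(lines):
        raise ParseError(f"{path}: no POP block found (line {i + 1})")
    if not locus_names:
        raise ParseError(f"{path}: no locus names before first POP")

    if isinstance(repeat_units, int):
        repeat_units = [repeat_units] * len(locus_names)
    if len(repeat_units) != len(locus_names):
        raise ParseError(
            f"{path}: {len(repeat_units)} repeat units for {len(locus_names)} loci"
        )
    loci = [LocusDef(n, u) for n, u in zip(locus_names, repeat_units)]

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    pop_idx = -1
    digits: int | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if is_pop(line):
            pop_idx += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}:{lineno + 1}: expected 'id , genotypes'")
        raw_id, geno = line.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise ParseError(
                f"{path}:{lineno + 1}: {len(codes)} genotypes for {len(loci)} loci"
            )
        width = len(codes[0])
        if width not in (4, 6) or any(len(c) != width for c in codes):
            raise ParseError(
                f"{path}:{lineno + 1}: allele codes must be uniformly 4 or 6 digits"
            )
        if digits is None:
            digits = width // 2
        elif digits != width // 2:
            raise ParseError(f"{path}:{lineno + 1}: mixed allele-code widths")
        pair_list = []
        for c in codes:
            if not c.isdigit():
                raise ParseError(f"{path}:{lineno + 1}: non-numeric code {c!r}")
            a, b = int(c[:digits]), int(c[digits:])
            pair_list.append(
                (a + code_offset if a else MISSING, b + code_offset if b else MISSING)
            )
        rows.append(np.array(pair_list, dtype=np.int64))
        iid, area, year = _split_sample_id(raw_id.strip())
        if area is None:
            if area_labels is not None:
                area = area_labels[pop_idx]
            else:
                area = f"pop{pop_idx + 1}"
        meta_rows.append(
            {"id": iid, "area": area, "year": year if year is not None else 0}
        )
    if not rows:
        raise ParseError(f"{path}: no samples found")
    meta = pd.DataFrame(meta_rows)
    meta["sex"] = pd.NA
    meta["mother_id"] = pd.NA
    return GenotypeDataset(
        loci=loci, meta=meta, alleles=np.stack(rows), provenance=f"genepop:{title}"
    )


def write_genepop(ds: GenotypeDataset, path, code_offset: int = 0) -> None:
    """Write Genepop text, one POP block per area, ``area:id:year`` labels.

    Allele sizes are written as 3-digit codes after subtracting
    ``code_offset``; missing becomes code 000.
    """
    sizes = ds.alleles[ds.alleles != MISSING]
    if sizes.size and (sizes - code_offset).max() > 999:
        raise ValueError("allele size exceeds 3-digit Genepop code; set code_offset")
    with open(path, "w") as fh:
        title = ds.provenance or "icedrift export"
        fh.write(title.replace("\n", " ") + "\n")
        for name in ds.locus_names:
            fh.write(name + "\n")
        for area in pd.unique(ds.meta["area"]):
            fh.write("POP\n")
            for i in np.flatnonzero((ds.meta["area"] == area).to_numpy()):
                row = ds.meta.iloc[i]
                codes = []
                for a, b in ds.alleles[i]:
                    ca = 0 if a == MISSING else a - code_offset
                    cb = 0 if b == MISSING else b - code_offset
                    codes.append(f"{ca:03d}{cb:03d}")
                fh.write(f"{area}:{row['id']}:{int(row['year'])} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# two-row STRUCTURE layout
# ---------------------------------------------------------------------------

def read_structure_two_row(
    path,
    repeat_units: list[int] | int = 2,
    missing_code: int = -9,
    has_year: bool = False,
    locus_names: list[str] | None = None,
) -> GenotypeDataset:
    """Read a two-row STRUCTURE-format file (one row per haplotype).

    Each individual occupies two consecutive rows; leading columns are
    ``id``, ``population`` and, with ``has_year``, the sampling year.
    ``missing_code`` (default -9) marks missing alleles.  An optional
    header line of locus names is auto-detected.
    """
    with open(path) as fh:
        raw = [ln.split() for ln in fh if ln.strip()]
    if not raw:
        raise ParseError(f"{path}: empty file")
    meta_cols = 3 if has_year else 2
    header: list[str] | None = None
    first_numeric = all(re.fullmatch(r"-?\d+", t) for t in raw[0][meta_cols:])
    if not first_numeric:
        header = raw[0]
        raw = raw[1:]
    if len(raw) % 2:
        raise ParseError(f"{path}: odd number of genotype rows ({len(raw)})")
    n_loci = len(raw[0]) - meta_cols
    if n_loci < 1:
        raise ParseError(f"{path}: no locus columns")
    if locus_names is None:
        locus_names = header if header else [f"L{i + 1}" for i in range(n_loci)]
    if len(locus_names) != n_loci:
        raise ParseError(f"{path}: {len(locus_names)} names for {n_loci} loci")
    if isinstance(repeat_units, int):
        repeat_units = [repeat_units] * n_loci
    loci = [LocusDef(n, u) for n, u in zip(locus_names, repeat_units)]

    alleles = np.empty((len(raw) // 2, n_loci, 2), dtype=np.int64)
    meta_rows = []
    for k in range(0, len(raw), 2):
        r1, r2 = raw[k], raw[k + 1]
        if len(r1) != meta_cols + n_loci or len(r2) != meta_cols + n_loci:
            raise ParseError(f"{path}: row {k + 1} or {k + 2} has wrong column count")
        if r1[:meta_cols] != r2[:meta_cols]:
            raise ParseError(
                f"{path}: rows {k + 1}-{k + 2} belong to different individuals "
                f"({r1[0]!r} vs {r2[0]!r})"
            )
        for j in range(n_loci):
            a, b = int(r1[meta_cols + j]), int(r2[meta_cols + j])
            alleles[k // 2, j, 0] = MISSING if a == missing_code else a
            alleles[k // 2, j, 1] = MISSING if b == missing_code else b
        meta_rows.append(
            {
                "id": r1[0],
                "area": r1[1],
                "year": int(r1[2]) if has_year else 0,
            }
        )
    meta = pd.DataFrame(meta_rows)
    meta["sex"] = pd.NA
    meta["mother_id"] = pd.NA
    return GenotypeDataset(loci=loci, meta=meta, alleles=alleles, provenance="structure")


def write_structure_two_row(
    ds: GenotypeDataset, path, missing_code: int = -9, has_year: bool = True
) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ds.locus_names) + "\n")
        for i in range(ds.n_individuals):
            row = ds.meta.iloc[i]
            lead = [str(row["id"]), str(row["area"])]
            if has_year:
                lead.append(str(int(row["year"])))
            for hap in range(2):
                vals = [
                    str(missing_code if a == MISSING else a)
                    for a in ds.alleles[i, :, hap]
                ]
                fh.write(" ".join(lead + vals) + "\n")


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def assign_periods(
    ds: GenotypeDataset, bins: list[tuple[str, int, int]] | None = None
) -> GroupTable:
    """Partition individuals into (area, period) groups.

    ``bins`` is an ordered list of ``(label, first_year, last_year)``
    inclusive year ranges; defaults to the five monitoring periods.
    Every individual's sampling year must fall in exactly one bin.
    """
    bins = list(bins) if bins is not None else list(DEFAULT_PERIODS)
    for (la, _, hi_a), (lb, lo_b, _) in zip(bins, bins[1:]):
        if lo_b <= hi_a:
            raise ValueError(f"period bins {la!r} and {lb!r} overlap or are unordered")
    years = ds.meta["year"].to_numpy()
    labels = np.full(ds.n_individuals, None, dtype=object)
    for label, lo, hi in bins:
        labels[(years >= lo) & (years <= hi)] = label
    if (labels == None).any():  # noqa: E711
        bad = ds.meta.loc[labels == None, ["id", "year"]]  # noqa: E711
        raise ValueError(
            "sampling years outside all period bins: "
            + ", ".join(f"{r.id}({r.year})" for r in bad.itertuples())
        )
    groups: list[tuple[str, str, list[str]]] = []
    ids = np.asarray(ds.ids, dtype=object)
    areas = ds.meta["area"].to_numpy()
    for area in pd.unique(areas):
        for label, _, _ in bins:
            mask = (areas == area) & (labels == label)
            if mask.any():
                groups.append((str(area), label, list(ids[mask])))
    return GroupTable(groups=groups, period_bins=bins)


def filter_min_group_size(gt: GroupTable, min_n: int = 10) -> GroupTable:
    """Drop groups with fewer than ``min_n`` members (the default mirrors the
    monitoring design's exclusion of periods with fewer than 10 individuals).
    Idempotent; removals are logged."""
    kept, removed = [], list(gt.removed)
    for area, period, members in gt.groups:
        if len(members) >= min_n:
            kept.append((area, period, members))
        else:
            removed.append((area, period, len(members)))
            logger.info("dropping group (%s, %s): n=%d < %d", area, period, len(members), min_n)
    if not kept:
        logger.warning("all groups below min size %d; empty group table", min_n)
    return GroupTable(groups=kept, period_bins=gt.period_bins, removed=removed)
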