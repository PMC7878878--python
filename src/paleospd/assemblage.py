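"""Specimen-table handling and occurrence summaries for dated faunal remains.

A death assemblage is represented as one row per radiocarbon-dated specimen
(lab code, site, taxon, conventional 14C age and error).  This module
derives the zooarchaeological summaries used downstream:

* MNI (minimum number of individuals): specimens of one taxon at one site
  whose calibrated 2-sigma (HPD) intervals overlap are treated as possibly
  the same individual and counted once; clusters are the transitive closure
  of pairwise overlap (single linkage).  Specimens flagged modern or beyond
  the calibration range demonstrably differ in age from all calibrated ones
  and count as singleton occurrences.
* Bins: per site-and-taxon single-linkage clusters of *uncalibrated* 14C
  ages with a gap cutoff ``h``; the permutation unit guarding against
  pseudo-replicated same-event dates.
* FAD/LAD: first and last appearance dates (oldest / youngest calibrated
  median, cal BP).
* Post-threshold fractions and per-cave taxonomic composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calib import (
    CalibratedDensity,
    CalibrationCurve,
    Fraction,
    RangeStatus,
    UncalDate,
    calibrate_date,
)

__all__ = [
    "SpecimenRecord",
    "MNIResult",
    "BinSet",
    "OccurrenceSummary",
    "load_specimens",
    "calibrate_specimens",
    "assign_mni_clusters",
    "make_bins",
    "fad_lad",
    "fraction_after",
    "cave_composition",
]

SPECIMEN_COLUMNS = ["specimen_id", "site_id", "taxon", "c14_age", "c14_error", "fraction"]

#: Genus-level groups used for cave composition summaries.
TAXON_GROUPS = {"leopard": ("panthera",), "hyena": ("hyaena",), "fox": ("vulpes",)}


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    site_id: str
    taxon: str
    date: UncalDate
    density: CalibratedDensity | None = None

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError(f"specimen {self.specimen_id!r}: empty taxon")

    @property
    def status(self) -> RangeStatus | None:
        return None if self.density is None else self.density.status

    @property
    def is_calibrated(self) -> bool:
        return self.density is not None and self.density.is_calibrated


@dataclass(frozen=True)
class MNIResult:
    taxon: str
    clusters: tuple[frozenset[str], ...]
    mni: int
    nisp: int


@dataclass(frozen=True)
class BinSet:
    """Partition of specimens into per-(site, taxon) 14C-age bins."""

    h: float
    bins: tuple[frozenset[str], ...]
    labels: tuple[str, ...]  # taxon mark of each bin
    sites: tuple[str, ...]

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class OccurrenceSummary:
    taxon: str
    fad: int | None  # oldest calibrated median, cal BP
    lad: int | None  # youngest calibrated median, cal BP
    n_calibrated: int
    n_modern: int
    n_beyond: int

    @property
    def defined(self) -> bool:
        return self.fad is not None


def load_specimens(path) -> list[SpecimenRecord]:
    """Read a specimen table (CSV) into records.

    Requires columns specimen_id, site_id, taxon, c14_age, c14_error,
    fraction.  Duplicate specimen ids and non-positive errors are rejected.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "site_id": str, "taxon": str})
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated specimen_id {dup.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=True):
        try:
            age = float(row.c14_age)
            err = float(row.c14_error)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {row.Index + 2}: non-numeric c14_age/c14_error"
            ) from None
        if not np.isfinite(age) or not np.isfinite(err):
            raise ValueError(f"{path}: row {row.Index + 2}: non-numeric c14_age/c14_error")
        frac = Fraction(str(row.fraction)) if pd.notna(row.fraction) else Fraction.unknown
        records.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id),
                site_id=str(row.site_id),
                taxon=str(row.taxon),
                date=UncalDate(lab_id=str(row.specimen_id), c14_age=age,
                               c14_error=err, fraction=frac),
            )
        )
    return records


def calibrate_specimens(records: list[SpecimenRecord], curve: CalibrationCurve,
                        level: float = 0.954) -> list[SpecimenRecord]:
    """Attach a calibrated density (or modern/beyond flag) to every record."""
    return [replace(r, density=calibrate_date(r.date, curve, level)) for r in records]


def _overlaps(hpd_a, hpd_b) -> bool:
    # intervals are (old, young); two intervals intersect when
    # young_a <= old_b and young_b <= old_a
    return any(a[1] <= b[0] and b[1] <= a[0] for a in hpd_a for b in hpd_b)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def assign_mni_clusters(records: list[SpecimenRecord], taxon: str,
                        level: float = 0.954) -> MNIResult:
    """Cluster a taxon's specimens into minimum-number-of-individuals units.

    Two calibrated specimens at the same site are linked when their HPD
    interval sets (at ``level``) overlap; clusters are the transitive
    closure.  Modern and beyond-range specimens are singleton clusters.
    Records must carry densities (see :func:`calibrate_specimens`); the HPD
    is recomputed at ``level`` if it differs from the stored one.
    """
    from .calib import hpd_intervals

    members = [r for r in records if r.taxon == taxon]
    if not members:
        return MNIResult(taxon=taxon, clusters=(), mni=0, nisp=0)
    for r in members:
        if r.density is None:
            raise ValueError(f"specimen {r.specimen_id!r} is not calibrated; "
                             "run calibrate_specimens first")
    calibrated = [r for r in members if r.is_calibrated]
    others = [r for r in members if not r.is_calibrated]
    hpds = {}
    for r in calibrated:
        if abs(r.density.hpd_level - level) < 1e-12 and r.density.hpd:
            hpds[r.specimen_id] = r.density.hpd
        else:
            hpds[r.specimen_id] = tuple(hpd_intervals(r.density, level))
    uf = _UnionFind(len(calibrated))
    for i in range(len(calibrated)):
        for j in range(i + 1, len(calibrated)):
            a, b = calibrated[i], calibrated[j]
            if a.site_id == b.site_id and _overlaps(hpds[a.specimen_id], hpds[b.specimen_id]):
                uf.union(i, j)
    groups: dict[int, set[str]] = {}
    for i, r in enumerate(calibrated):
        groups.setdefault(uf.find(i), set()).add(r.specimen_id)
    clusters = [frozenset(g) for g in groups.values()]
    clusters += [frozenset({r.specimen_id}) for r in others]
    clusters.sort(key=lambda c: sorted(c)[0])
    return MNIResult(taxon=taxon, clusters=tuple(clusters),
                     mni=len(clusters), nisp=len(members))


def make_bins(records: list[SpecimenRecord], h: float) -> BinSet:
    """Single-linkage 14C-age bins with cutoff ``h``, per site and taxon.

    Within one site-and-taxon series, dates closer than or equal to ``h``
    14C yr (by single-linkage gaps) fall in one bin; ``h = 0`` merges only
    exactly equal ages.  Each bin carries its taxon as the permutation mark.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    series: dict[tuple[str, str], list[SpecimenRecord]] = {}
    for r in records:
        series.setdefault((r.site_id, r.taxon), []).append(r)
    bins, labels, sites = [], [], []
    for (site, taxon) in sorted(series):
        group = sorted(series[(site, taxon)], key=lambda r: (r.date.c14_age, r.specimen_id))
        current = [group[0]]
        for prev, nxt in zip(group, group[1:]):
            if nxt.date.c14_age - prev.date.c14_age <= h:
                current.append(nxt)
            else:
                bins.append(frozenset(r.specimen_id for r in current))
                labels.append(taxon)
                sites.append(site)
                current = [nxt]
        bins.append(frozenset(r.specimen_id for r in current))
        labels.append(taxon)
        sites.append(site)
    return BinSet(h=float(h), bins=tuple(bins), labels=tuple(labels), sites=tuple(sites))


def fad_lad(records: list[SpecimenRecord], taxon: str) -> OccurrenceSummary:
    """First/last appearance dates for a taxon (calibrated medians, cal BP).

    Modern and beyond-range specimens are counted but never enter FAD/LAD;
    with no calibrated record the FAD/LAD are explicitly undefined (None).
    """
    members = [r for r in records if r.taxon == taxon]
    for r in members:
        if r.density is None:
            raise ValueError(f"specimen {r.specimen_id!r} is not calibrated")
    medians = [r.density.median for r in members if r.is_calibrated]
    n_modern = sum(r.status is RangeStatus.modern for r in members)
    n_beyond = sum(r.status is RangeStatus.beyond_range for r in members)
    if not medians:
        return OccurrenceSummary(taxon=taxon, fad=None, lad=None, n_calibrated=0,
                                 n_modern=n_modern, n_beyond=n_beyond)
    return OccurrenceSummary(taxon=taxon, fad=max(medians), lad=min(medians),
                             n_calibrated=len(medians), n_modern=n_modern,
                             n_beyond=n_beyond)


def fraction_after(records: list[SpecimenRecord], taxon: str,
                   threshold: float) -> tuple[float, int, int]:
    """Fraction of a taxon's calibrated dates younger than ``threshold``.

    Returns (k/n, k, n) where k counts calibrated medians strictly less than
    ``threshold`` cal BP (cal BP runs backwards, so smaller = younger; a
    median exactly at the threshold is excluded).
    """
    members = [r for r in records if r.taxon == taxon and r.is_calibrated]
    n = len(members)
    if n == 0:
        raise ValueError(f"no calibrated records for taxon {taxon!r}")
    k = sum(r.density.median < threshold for r in members)
    return k / n, k, n


def _group_of(taxon: str) -> str | None:
    t = taxon.lower()
    for group, genera in TAXON_GROUPS.items():
        if any(t.startswith(g) for g in genera):
            return group
    return None


def cave_composition(records: list[SpecimenRecord]) -> pd.DataFrame:
    """Per-site relative abundance of leopard / hyena / fox specimens.

    Genus is inferred from the taxon label (Panthera -> leopard, Hyaena ->
    hyena, Vulpes -> fox); other taxa are ignored.  Proportions sum to 1 at
    every site with at least one grouped specimen.
    """
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        group = _group_of(r.taxon)
        if group is None:
            continue
        counts.setdefault(r.site_id, {g: 0 for g in TAXON_GROUPS})[group] += 1
    rows = []
    for site in sorted(counts):
        total = sum(counts[site].values())
        rows.append({"site_id": site,
                     **{g: counts[site][g] / total for g in TAXON_GROUPS},
                     "n": total})
    return pd.DataFrame(rows, columns=["site_id", *TAXON_GROUPS, "n"])
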