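"""Per-panel allele frequencies and cross-panel statistics.

The minor allele frequency (MAF) is the folded frequency min(AF, 1-AF); the
MMAF of a variant over a set of panels is the maximum MAF among panels where
the variant was observed (absent-in-all counts as 0).  Rarity classes form a
partition: very_rare (MAF < 1%, absent included), rare (1% <= MAF < 5%),
common (MAF >= 5%).  A variant is population-specific when its MAF in the
focal panel exceeds 1% while every reference panel has MAF below 1% (absent
counting as below).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from exopop.vcfio import CohortPanel, VariantKey

VERY_RARE_MAX = 0.01  # exclusive upper bound of very_rare
COMMON_MIN = 0.05  # inclusive lower bound of common

RARITY_CLASSES = ("very_rare", "rare", "common")


@dataclass(frozen=True)
class FrequencyRecord:
    """Allele counts and frequencies for one variant in one panel.

    ``an`` excludes missing genotypes.  ``an == 0`` flags the variant as
    absent (unobserved) in the panel: AF and MAF are then undefined (None).
    """

    key: VariantKey
    panel: str
    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0 or self.ac > self.an:
            raise ValueError(f"invalid counts AC={self.ac}, AN={self.an}")

    @property
    def absent(self) -> bool:
        return self.an == 0

    @property
    def af(self) -> float | None:
        return None if self.absent else self.ac / self.an

    @property
    def maf(self) -> float | None:
        af = self.af
        return None if af is None else min(af, 1.0 - af)


@dataclass(frozen=True)
class OverlapStats:
    focal_label: str
    reference_label: str
    n_focal: int
    n_shared: int

    @property
    def fraction_shared(self) -> float:
        return self.n_shared / self.n_focal

    @property
    def n_novel(self) -> int:
        return self.n_focal - self.n_shared


def allele_counts(panel: CohortPanel) -> list[FrequencyRecord]:
    """One frequency record per variant; AN excludes missing genotypes."""
    records = []
    for i, v in enumerate(panel.variants):
        row = panel.genotypes[i]
        called = ~np.isnan(row)
        an = 2 * int(called.sum())
        ac = int(np.nansum(row))
        records.append(FrequencyRecord(key=v.key, panel=panel.label, ac=ac, an=an))
    return records


def frequency_table(panel: CohortPanel) -> dict[VariantKey, FrequencyRecord]:
    return {r.key: r for r in allele_counts(panel)}


def is_singleton(rec: FrequencyRecord) -> bool:
    """True iff the alternate allele is observed exactly once."""
    if rec.absent:
        raise ValueError("singleton status undefined for an absent record (AN=0)")
    return rec.ac == 1


def overlap_fraction(
    focal: set[VariantKey],
    reference: set[VariantKey],
    focal_label: str = "focal",
    reference_label: str = "reference",
) -> OverlapStats:
    """Fraction of focal variant keys present in the reference key set."""
    if not focal:
        raise ValueError("overlap fraction undefined for an empty focal set")
    n_shared = len(focal & reference)
    return OverlapStats(
        focal_label=focal_label,
        reference_label=reference_label,
        n_focal=len(focal),
        n_shared=n_shared,
    )


def novelty(
    focal: Iterable[VariantKey],
    references: Sequence[set[VariantKey]],
    known_ids: set[VariantKey] | None = None,
) -> dict[VariantKey, bool]:
    """Per-variant novelty: absent from every reference set and from the
    known-identifier catalog."""
    known = known_ids or set()
    return {
        k: all(k not in ref for ref in references) and k not in known
        for k in focal
    }


def rarity_class(
    maf: float | None,
    very_rare_max: float = VERY_RARE_MAX,
    common_min: float = COMMON_MIN,
) -> str:
    """Classify a MAF (or absence, i.e. None) into very_rare / rare / common."""
    if maf is None:
        return "very_rare"
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    if maf < very_rare_max:
        return "very_rare"
    if maf < common_min:
        return "rare"
    return "common"


def mmaf(records: Iterable[FrequencyRecord]) -> float:
    """Maximum MAF over panels where the variant was observed; 0 if absent
    everywhere."""
    best = 0.0
    for r in records:
        if not r.absent:
            best = max(best, r.maf)
    return best


def mmaf_lookup(
    key: VariantKey,
    tables: Mapping[str, Mapping[VariantKey, FrequencyRecord]],
    panels: Sequence[str],
) -> float:
    """MMAF of ``key`` across the named panel frequency tables; a panel not
    containing the key contributes 0 (absent)."""
    if not panels:
        raise ValueError("at least one panel required for MMAF")
    recs = [tables[p][key] for p in panels if key in tables[p]]
    return mmaf(recs)


def population_specific(
    focal_maf: float | None,
    reference_mafs: Iterable[float | None],
    focal_min: float = 0.01,
    reference_max: float = 0.01,
) -> bool:
    """True iff the focal MAF exceeds ``focal_min`` while every reference MAF
    is below ``reference_max`` (absent, i.e. None, counts as below)."""
    if focal_maf is None or focal_maf <= focal_min:
        return False
    return all(m is None or m < reference_max for m in reference_mafs)


def rarity_distribution(
    mafs: Iterable[float | None],
    very_rare_max: float = VERY_RARE_MAX,
    common_min: float = COMMON_MIN,
) -> dict[str, float]:
    """Fraction of variants in each rarity class; fractions sum to 1."""
    counts = {c: 0 for c in RARITY_CLASSES}
    n = 0
    for m in mafs:
        counts[rarity_class(m, very_rare_max, common_min)] += 1
        n += 1
    if n == 0:
        raise ValueError("rarity distribution undefined for empty input")
    return {c: counts[c] / n for c in RARITY_CLASSES}


def write_frequency_table(
    records: Iterable[FrequencyRecord], path: str | Path
) -> None:
    rows = [
        {
            "chrom": r.key[0],
            "pos": r.key[1],
            "ref": r.key[2],
            "alt": r.key[3],
            "panel": r.panel,
            "AC": r.ac,
            "AN": r.an,
            "AF": "" if r.absent else f"{r.af:.6g}",
            "MAF": "" if r.absent else f"{r.maf:.6g}",
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "panel", "AC", "AN", "AF", "MAF"]
    ).to_csv(path, sep="\t", index=False)


def read_frequency_table(
    path: str | Path,
) -> dict[str, dict[VariantKey, FrequencyRecord]]:
    """Read a frequency TSV back into per-panel lookup tables."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    tables: dict[str, dict[VariantKey, FrequencyRecord]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        rec = FrequencyRecord(
            key=key, panel=str(row.panel), ac=int(row.AC), an=int(row.AN)
        )
        tables.setdefault(rec.panel, {})[key] = rec
    return tables
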