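"""Cohort VCF input/output, target-region restriction and QC filtering.

Coordinate conventions: VCF positions are 1-based inclusive and all internal
positions follow that convention; BED intervals are 0-based half-open and are
converted at the boundary.  A genotype is stored as an allele dosage in
{0, 1, 2} with ``NaN`` for missing; a half-called genotype (one missing
allele) counts as missing.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from exopop.errors import MissingGenotypeError, VcfFormatError

VALID_BASES = frozenset("ACGT")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class Variant:
    """A single variant record.

    ``alt`` may hold a comma-joined allele list for multiallelic records as
    read from a VCF; downstream analyses operate on biallelic SNVs only
    (``is_biallelic_snv``), which QC enforces.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_biallelic_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in VALID_BASES
            and self.alt in VALID_BASES
        )


@dataclass
class CohortPanel:
    """A set of variants with per-sample allele dosages for one cohort.

    ``genotypes`` is a float array of shape (n_variants, n_samples) holding
    dosages 0/1/2 with NaN for missing calls.  ``filters`` carries the VCF
    FILTER column per variant ("PASS" or "." meaning unfiltered).
    """

    variants: list[Variant]
    samples: list[str]
    genotypes: np.ndarray
    label: str = "cohort"
    filters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2 or self.genotypes.shape != (
            len(self.variants),
            len(self.samples),
        ):
            raise ValueError(
                f"genotype table shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if not self.filters:
            self.filters = ["."] * len(self.variants)
        if len(self.filters) != len(self.variants):
            raise ValueError("filters length must equal number of variants")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError("variant keys are not unique")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def keys(self) -> list[VariantKey]:
        return [v.key for v in self.variants]

    def call_rate(self) -> np.ndarray:
        """Fraction of samples with a called (non-missing) genotype, per variant."""
        if self.n_samples == 0:
            return np.ones(self.n_variants)
        return 1.0 - np.isnan(self.genotypes).mean(axis=1)

    def carriers(self, index: int) -> list[str]:
        """Samples carrying at least one alternate allele at variant ``index``."""
        row = self.genotypes[index]
        return [s for s, d in zip(self.samples, row) if not np.isnan(d) and d >= 1]

    def subset(self, indices: Sequence[int]) -> "CohortPanel":
        idx = list(indices)
        return CohortPanel(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            genotypes=self.genotypes[idx] if idx else np.empty((0, self.n_samples)),
            label=self.label,
            filters=[self.filters[i] for i in idx],
        )

    def equals(self, other: "CohortPanel") -> bool:
        """Equality on variant keys, sample list and dosages (NaN-aware)."""
        return (
            self.keys() == other.keys()
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes, equal_nan=True)
        )


@dataclass(frozen=True)
class TargetRegionSet:
    """Normalized genomic target intervals, 0-based half-open per chromosome."""

    intervals: Mapping[str, np.ndarray]

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]]
    ) -> "TargetRegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=int)
        return cls(intervals=merged)

    @classmethod
    def from_bed(cls, path: str | Path) -> "TargetRegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        return cls.from_intervals(df.itertuples(index=False, name=None))

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` falls inside an interval."""
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        p0 = pos - 1
        i = int(np.searchsorted(ivs[:, 0], p0, side="right")) - 1
        return i >= 0 and p0 < ivs[i, 1]

    def total_span(self) -> int:
        return int(sum((ivs[:, 1] - ivs[:, 0]).sum() for ivs in self.intervals.values()))


@dataclass(frozen=True)
class QCConfig:
    """Switchable quality filters defining the high-quality SNV working set.

    Defaults: keep records whose FILTER is PASS (or "."), drop non-SNV and
    multiallelic records, and require a genotype call rate of at least 0.9.
    """

    require_pass_filter: bool = True
    biallelic_snv_only: bool = True
    min_call_rate: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must lie in [0, 1]")


def _decode_dosage(gt: tuple | None) -> float:
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return np.nan
    return float(sum(1 for a in gt if a != 0))


def read_variants(
    vcf_path: str | Path,
    region: TargetRegionSet | None = None,
    label: str | None = None,
) -> CohortPanel:
    """Read a multi-sample VCF into a :class:`CohortPanel`.

    Only records whose position falls inside ``region`` (if given) are kept.
    Multiallelic records are retained as-is (comma-joined ALT) for
    :func:`apply_qc` to drop.  A record without a GT field raises
    :class:`MissingGenotypeError` naming the record.
    """
    path = Path(vcf_path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        variants: list[Variant] = []
        filters: list[str] = []
        rows: list[list[float]] = []
        for rec in vf:
            if region is not None and not region.contains(rec.chrom, rec.pos):
                continue
            alts = rec.alts or ()
            alt = ",".join(alts) if alts else "."
            variants.append(
                Variant(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt, id=rec.id)
            )
            flt = ";".join(rec.filter.keys()) if len(rec.filter) else "."
            filters.append(flt)
            row: list[float] = []
            for s in samples:
                sample = rec.samples[s]
                if "GT" not in sample:
                    raise MissingGenotypeError(
                        f"record {rec.chrom}:{rec.pos} {rec.ref}>{alt} has no GT"
                    )
                row.append(_decode_dosage(sample["GT"]))
            rows.append(row)
    genotypes = (
        np.asarray(rows, dtype=float) if rows else np.empty((0, len(samples)))
    )
    return CohortPanel(
        variants=variants,
        samples=samples,
        genotypes=genotypes,
        label=label or path.stem,
        filters=filters,
    )


def apply_qc(
    panel: CohortPanel, config: QCConfig = QCConfig()
) -> tuple[CohortPanel, "OrderedDict[str, int]"]:
    """Apply the configured filters, returning the retained panel and per-filter
    removal counts.

    A removed record is attributed to the first failing filter in the fixed
    order pass_filter -> snv_only -> call_rate, so counts sum to the number
    removed.  Record order is preserved; the operation is idempotent.
    """
    qc_counts: "OrderedDict[str, int]" = OrderedDict()
    removed = np.zeros(panel.n_variants, dtype=bool)

    if config.require_pass_filter:
        fail = np.array(
            [f not in ("PASS", ".") for f in panel.filters], dtype=bool
        )
        fail &= ~removed
        qc_counts["pass_filter"] = int(fail.sum())
        removed |= fail
    if config.biallelic_snv_only:
        fail = np.array([not v.is_biallelic_snv for v in panel.variants], dtype=bool)
        fail &= ~removed
        qc_counts["snv_only"] = int(fail.sum())
        removed |= fail
    if config.min_call_rate > 0:
        fail = panel.call_rate() < config.min_call_rate
        fail &= ~removed
        qc_counts["call_rate"] = int(fail.sum())
        removed |= fail

    kept = [i for i in range(panel.n_variants) if not removed[i]]
    return panel.subset(kept), qc_counts


def write_variants(panel: CohortPanel, path: str | Path) -> None:
    """Write a panel as VCF 4.2, re-readable by :func:`read_variants` into an
    equal panel (keys, samples, dosages, FILTER)."""
    header = pysam.VariantHeader()
    seen: list[str] = []
    for v in panel.variants:
        if v.chrom not in seen:
            seen.append(v.chrom)
    for chrom in seen:
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for flt in sorted({f for f in panel.filters if f not in ("PASS", ".")}):
        for name in flt.split(";"):
            if name not in header.filters:
                header.filters.add(name, None, None, "imported filter")
    for s in panel.samples:
        header.add_sample(s)
    try:
        out = pysam.VariantFile(str(path), "w", header=header)
    except OSError as exc:
        raise OSError(f"cannot write VCF to {path}: {exc}") from exc
    with out:
        for i, v in enumerate(panel.variants):
            alts = tuple(v.alt.split(",")) if v.alt != "." else ("<NON_REF>",)
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref,) + alts, id=v.id
            )
            flt = panel.filters[i]
            if flt != ".":
                for name in flt.split(";"):
                    rec.filter.add(name)
            for j, s in enumerate(panel.samples):
                d = panel.genotypes[i, j]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                elif d == 0:
                    rec.samples[s]["GT"] = (0, 0)
                elif d == 1:
                    rec.samples[s]["GT"] = (0, 1)
                else:
                    rec.samples[s]["GT"] = (1, 1)
            out.write(rec)


def write_qc_report(qc_counts: Mapping[str, int], path: str | Path) -> None:
    """QC removal counts as a two-column TSV (filter_name, removed_count)."""
    pd.DataFrame(
        {"filter_name": list(qc_counts), "removed_count": list(qc_counts.values())}
    ).to_csv(path, sep="\t", index=False)
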