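"""Gene-panel incidental-finding screens and case-cohort filter cascades.

``screen_incidental`` reports high-impact variants falling in a configured
gene panel (ACMG/COSMIC-style) together with the cohort rate: the fraction
of distinct individuals carrying at least one finding.

``screen_cases`` runs the causal-variant filter cascade over a case cohort:
(1) predicted deleterious, (2) recurrent in at least ``min_cases`` cases
(a case "has" a variant iff its dosage is >= 1), (3) rarity under the
configured maximum-MAF (MMAF) panel source.  The stage order fixes how
removals are attributed; the surviving set is the intersection of the three
predicates and hence order-invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from exopop.consequence import ConsequenceCall
from exopop.errors import ConfigError
from exopop.popfreq import FrequencyRecord, mmaf_lookup, rarity_class
from exopop.vcfio import CohortPanel, VariantKey

FreqTables = Mapping[str, Mapping[VariantKey, FrequencyRecord]]


@dataclass(frozen=True)
class GenePanel:
    """A named gene list (e.g. an incidental-findings reporting panel)."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene panel {self.name!r} is empty")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GenePanel":
        """One gene id per line; blank lines and '#' comments ignored."""
        genes = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
        return cls(name=name or Path(path).stem, gene_ids=frozenset(genes))


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of the case-cohort filter cascade."""

    min_cases: int = 3
    rarity_required: str = "very_rare"
    freq_source: tuple[str, ...] = ()
    require_deleterious: bool = True

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.rarity_required not in ("very_rare", "rare", "common"):
            raise ValueError(f"unknown rarity class {self.rarity_required!r}")


@dataclass
class ScreenReport:
    """Before/after accounting for one filter-cascade run."""

    config: ScreenConfig
    n_variants_in: int
    n_variants_out: int
    n_genes_out: int
    removed_by_stage: dict[str, int]
    surviving: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_variants_in - self.n_variants_out != sum(
            self.removed_by_stage.values()
        ):
            raise ValueError("stage removals do not sum to in - out")

    def to_dict(self) -> dict:
        return {
            "config": {
                "min_cases": self.config.min_cases,
                "rarity_required": self.config.rarity_required,
                "freq_source": list(self.config.freq_source),
                "require_deleterious": self.config.require_deleterious,
            },
            "n_variants_in": self.n_variants_in,
            "n_variants_out": self.n_variants_out,
            "n_genes_out": self.n_genes_out,
            "removed_by_stage": dict(self.removed_by_stage),
            "surviving": self.surviving,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.surviving).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ReductionStats:
    n_removed_extra: int
    percent_reduction: float  # one decimal

    @property
    def percent_reduction_int(self) -> int:
        return int(round(self.percent_reduction))


def screen_incidental(
    panel: CohortPanel,
    calls: Mapping[VariantKey, ConsequenceCall],
    gene_panel: GenePanel,
    cohort_size: int | None = None,
    max_maf: float | None = None,
    freq_table: Mapping[VariantKey, FrequencyRecord] | None = None,
) -> tuple[list[dict], float]:
    """Screen a cohort for high-impact variants in panel genes.

    Returns the findings (variant, gene, carriers) and the incidental-finding
    rate: distinct carrier individuals of at least one finding, divided by
    the cohort size, as a percent rounded to two decimals.  ``max_maf``
    optionally restricts findings to variants at or below that cohort MAF.
    """
    cohort_size = cohort_size if cohort_size is not None else panel.n_samples
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    findings: list[dict] = []
    carriers: set[str] = set()
    for i, v in enumerate(panel.variants):
        call = calls.get(v.key)
        if call is None or call.impact != "high":
            continue
        if call.gene_id not in gene_panel.gene_ids:
            continue
        if max_maf is not None and freq_table is not None:
            rec = freq_table.get(v.key)
            if rec is not None and not rec.absent and rec.maf > max_maf:
                continue
        var_carriers = panel.carriers(i)
        if not var_carriers:  # site record without an observed alt allele
            continue
        findings.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": call.gene_id,
                "term": call.term,
                "carriers": var_carriers,
            }
        )
        carriers.update(var_carriers)
    rate = round(100.0 * len(carriers) / cohort_size, 2)
    return findings, rate


def screen_cases(
    case_panel: CohortPanel,
    calls: Mapping[VariantKey, ConsequenceCall],
    deleterious: Mapping[VariantKey, bool],
    freq_tables: FreqTables,
    config: ScreenConfig,
) -> ScreenReport:
    """Run the deleterious -> recurrence -> rarity cascade over a case cohort.

    A case variant absent from a frequency panel counts as MAF 0 there; an
    unknown panel name in ``config.freq_source`` raises :class:`ConfigError`.
    """
    for name in config.freq_source:
        if name not in freq_tables:
            raise ConfigError(f"unknown frequency source panel {name!r}")
    if not config.freq_source:
        raise ConfigError("freq_source must name at least one panel")

    survivors: list[int] = list(range(case_panel.n_variants))
    removed_by_stage: dict[str, int] = {}

    if config.require_deleterious:
        kept = [i for i in survivors
                if deleterious.get(case_panel.variants[i].key, False)]
        removed_by_stage["deleterious"] = len(survivors) - len(kept)
        survivors = kept

    n_cases = (case_panel.genotypes >= 1).sum(axis=1)
    kept = [i for i in survivors if n_cases[i] >= config.min_cases]
    removed_by_stage["recurrence"] = len(survivors) - len(kept)
    survivors = kept

    kept = []
    for i in survivors:
        m = mmaf_lookup(case_panel.variants[i].key, freq_tables,
                        list(config.freq_source))
        if rarity_class(m) == config.rarity_required:
            kept.append(i)
    removed_by_stage["rarity"] = len(survivors) - len(kept)
    survivors = kept

    surviving_rows = []
    genes = set()
    for i in survivors:
        v = case_panel.variants[i]
        call = calls.get(v.key)
        gene = call.gene_id if call is not None else ""
        if gene:
            genes.add(gene)
        surviving_rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": gene,
                "n_cases": int(n_cases[i]),
            }
        )
    return ScreenReport(
        config=config,
        n_variants_in=case_panel.n_variants,
        n_variants_out=len(survivors),
        n_genes_out=len(genes),
        removed_by_stage=removed_by_stage,
        surviving=surviving_rows,
    )


def reduction_from_counts(out_a: int, out_b: int) -> ReductionStats:
    """Reduction achieved by a larger frequency-panel set: survivor count
    ``out_a`` under the smaller set vs ``out_b`` under the larger."""
    if out_a == 0:
        raise ValueError("percent reduction undefined: zero survivors in baseline")
    return ReductionStats(
        n_removed_extra=out_a - out_b,
        percent_reduction=round(100.0 * (out_a - out_b) / out_a, 1),
    )


def reduction_stats(report_a: ScreenReport, report_b: ScreenReport) -> ReductionStats:
    """Before/after reduction between two cascade runs whose frequency-panel
    sets are nested (b's a superset of a's)."""
    if not set(report_a.config.freq_source) <= set(report_b.config.freq_source):
        raise ValueError("report_b's freq_source must contain report_a's")
    return reduction_from_counts(report_a.n_variants_out, report_b.n_variants_out)


def compare_freq_sources(
    case_panel: CohortPanel,
    calls: Mapping[VariantKey, ConsequenceCall],
    deleterious: Mapping[VariantKey, bool],
    freq_tables: FreqTables,
    sources: Mapping[str, Sequence[str]],
    config: ScreenConfig = ScreenConfig(),
) -> list[tuple[str, ScreenReport]]:
    """One cascade run per named panel set on identical upstream inputs,
    sorted by survivor count (descending reports last)."""
    rows = []
    for name in sources:
        cfg = ScreenConfig(
            min_cases=config.min_cases,
            rarity_required=config.rarity_required,
            freq_source=tuple(sources[name]),
            require_deleterious=config.require_deleterious,
        )
        rows.append((name, screen_cases(case_panel, calls, deleterious,
                                        freq_tables, cfg)))
    rows.sort(key=lambda r: (r[1].n_variants_out, r[0]))
    return rows
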