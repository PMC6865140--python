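"""Gene-level burden aggregation and prioritization.

Qualifying population-specific variants are aggregated per gene (each variant
attributed to exactly one gene, that of its most severe consequence call),
then genes are prioritized by burden count combined with the residual
variation intolerance score (RVIS) percentile, and by the count of
deleterious variants.  A robust median + k*MAD rule (plus an explicit
blacklist) removes outlier genes before correlation analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from exopop.consequence import ConsequenceCall
from exopop.vcfio import VariantKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RVISRecord:
    gene_id: str
    rvis_score: float
    percentile: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percentile <= 100.0:
            raise ValueError(f"percentile {self.percentile} outside [0, 100]")


@dataclass(frozen=True)
class GeneBurden:
    gene_id: str
    n_specific: int
    n_deleterious: int = 0
    gene_length: int | None = None
    rvis_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.n_specific < 0 or self.n_deleterious < 0:
            raise ValueError("burden counts must be non-negative")
        if self.n_deleterious > self.n_specific:
            raise ValueError("n_deleterious cannot exceed n_specific")


def burden_by_gene(
    specific_variants: Iterable[VariantKey],
    calls: Mapping[VariantKey, ConsequenceCall],
    impact_filter: set[str] = frozenset({"high", "moderate"}),
    deleterious: Mapping[VariantKey, bool] | None = None,
    gene_lengths: Mapping[str, int] | None = None,
    rvis: Mapping[str, RVISRecord] | None = None,
) -> tuple[list[GeneBurden], int]:
    """Aggregate qualifying variants per gene.

    Each variant contributes once, to the gene of its consequence call, and
    only when the call's impact is in ``impact_filter``.  Variants without a
    call are skipped; the skipped count is logged and returned.
    """
    n_spec: dict[str, int] = {}
    n_del: dict[str, int] = {}
    skipped = 0
    for key in specific_variants:
        call = calls.get(key)
        if call is None:
            skipped += 1
            continue
        if call.impact not in impact_filter:
            continue
        g = call.gene_id
        n_spec[g] = n_spec.get(g, 0) + 1
        if deleterious is not None and deleterious.get(key, False):
            n_del[g] = n_del.get(g, 0) + 1
    if skipped:
        logger.info("burden_by_gene: %d variants without a consequence call skipped",
                    skipped)
    burdens = [
        GeneBurden(
            gene_id=g,
            n_specific=n_spec[g],
            n_deleterious=n_del.get(g, 0),
            gene_length=(gene_lengths or {}).get(g),
            rvis_percentile=(
                rvis[g].percentile if rvis and g in rvis else None
            ),
        )
        for g in sorted(n_spec)
    ]
    return burdens, skipped


def length_correlation(burdens: Sequence[GeneBurden]) -> float:
    """Pearson correlation between per-gene burden counts and genomic gene
    length, over genes with a defined length."""
    pairs = [(b.n_specific, b.gene_length) for b in burdens if b.gene_length]
    if len(pairs) < 3:
        raise ValueError("need at least 3 genes with defined lengths")
    counts = np.array([p[0] for p in pairs], dtype=float)
    lengths = np.array([p[1] for p in pairs], dtype=float)
    if counts.std() == 0 or lengths.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(counts, lengths).statistic)


def filter_outlier_genes(
    burdens: Sequence[GeneBurden],
    mad_k: float = 5.0,
    blacklist: set[str] | None = None,
) -> tuple[list[GeneBurden], dict[str, str]]:
    """Remove outlier genes, reporting each removed gene with a reason.

    The default rule removes genes whose burden exceeds
    median + mad_k * MAD computed over the nonzero burdens; blacklisted
    genes are removed regardless of count.
    """
    blacklist = blacklist or set()
    removed: dict[str, str] = {}
    nonzero = np.array([b.n_specific for b in burdens if b.n_specific > 0], float)
    threshold = None
    if nonzero.size:
        med = float(np.median(nonzero))
        mad = float(stats.median_abs_deviation(nonzero, scale=1.0))
        threshold = med + mad_k * mad
    kept: list[GeneBurden] = []
    for b in burdens:
        if b.gene_id in blacklist:
            removed[b.gene_id] = "blacklisted"
        elif threshold is not None and b.n_specific > threshold:
            removed[b.gene_id] = (
                f"burden {b.n_specific} > median+{mad_k}*MAD ({threshold:.3g})"
            )
        else:
            kept.append(b)
    return kept, removed


def rvis_prioritize(
    burdens: Sequence[GeneBurden],
    rvis: Mapping[str, RVISRecord],
    max_percentile: float,
    min_count: int,
) -> list[GeneBurden]:
    """Genes at or below the RVIS percentile cutoff carrying at least
    ``min_count`` qualifying variants, sorted by (burden desc, percentile
    asc, gene id).  Genes without an RVIS record are excluded and logged."""
    annotated: list[GeneBurden] = []
    unknown = 0
    for b in burdens:
        rec = rvis.get(b.gene_id)
        if rec is None and b.rvis_percentile is None:
            unknown += 1
            continue
        pct = rec.percentile if rec is not None else b.rvis_percentile
        annotated.append(replace(b, rvis_percentile=pct))
    if unknown:
        logger.info("rvis_prioritize: %d genes without RVIS excluded", unknown)
    hits = [
        b
        for b in annotated
        if b.rvis_percentile <= max_percentile and b.n_specific >= min_count
    ]
    hits.sort(key=lambda b: (-b.n_specific, b.rvis_percentile, b.gene_id))
    return hits


def deleterious_burden(
    burdens: Sequence[GeneBurden], min_count: int = 3
) -> tuple[list[GeneBurden], dict[int, int]]:
    """Genes with at least ``min_count`` deleterious qualifying variants,
    plus the full histogram {n_deleterious: n_genes} over genes with >= 1."""
    histogram: dict[int, int] = {}
    for b in burdens:
        if b.n_deleterious > 0:
            histogram[b.n_deleterious] = histogram.get(b.n_deleterious, 0) + 1
    hits = sorted(
        (b for b in burdens if b.n_deleterious >= min_count),
        key=lambda b: (-b.n_deleterious, b.gene_id),
    )
    return hits, dict(sorted(histogram.items()))


def read_rvis(path: str | Path) -> dict[str, RVISRecord]:
    """RVIS TSV (gene, score, percentile) -> lookup by gene id."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.gene)] = RVISRecord(
            gene_id=str(row.gene),
            rvis_score=float(row.score),
            percentile=float(row.percentile),
        )
    return out


def read_scores(
    path: str | Path, threshold: float = 0.5
) -> tuple[dict[VariantKey, float], dict[VariantKey, bool]]:
    """Deleteriousness score TSV (chrom, pos, ref, alt, score[, label]).

    The deleterious flag is the table's label "D" when a label column is
    present, else score > threshold.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    scores: dict[VariantKey, float] = {}
    flags: dict[VariantKey, bool] = {}
    has_label = "label" in df.columns
    for row in df.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        score = float(row.score)
        scores[key] = score
        flags[key] = (str(row.label) == "D") if has_label else (score > threshold)
    return scores, flags


def write_burden_table(burdens: Iterable[GeneBurden], path: str | Path) -> None:
    rows = [
        {
            "gene": b.gene_id,
            "n_specific": b.n_specific,
            "n_deleterious": b.n_deleterious,
            "gene_length": b.gene_length if b.gene_length is not None else "",
            "rvis_percentile": (
                b.rvis_percentile if b.rvis_percentile is not None else ""
            ),
        }
        for b in burdens
    ]
    pd.DataFrame(
        rows,
        columns=["gene", "n_specific", "n_deleterious", "gene_length",
                 "rvis_percentile"],
    ).to_csv(path, sep="\t", index=False)
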