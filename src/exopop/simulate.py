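"""Synthetic multi-population exome cohorts with planted structure.

The generator emulates the study design the pipeline targets: several
populations diverged from a common ancestor under the Balding–Nichols model,
with a focal population carrying a planted set of founder-effect variants
(enriched above 1% MAF in the focal population, near-absent in every
reference population), Hardy–Weinberg genotypes for ~128 individuals per
population, toy coding genes on both strands hosting truth-labelled
consequence variants, and deleteriousness scores correlated with the planted
truth.  Every emitted file is paired with a truth table, so each pipeline
stage can be validated against known ground truth.

Under the Balding–Nichols model a population with divergence parameter F
draws its allele frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) around the
ancestral frequency p; ancestral frequencies follow a U-shaped Beta(0.2,
0.2) truncated to (0.001, 0.5).  Founder variants are overwritten after the
drift draw: focal frequency uniform in the configured focal range, reference
frequencies uniform in (0, ref_maf_max).  Non-planted variants whose true
frequencies would satisfy the population-specific criterion are redrawn, so
the planted set is exactly the set of true population-specific variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from exopop.consequence import (
    SPLICE_WINDOW,
    Transcript,
    TranscriptIndex,
    revcomp,
)
from exopop.errors import GenerationError
from exopop.popfreq import population_specific
from exopop.prioritize import RVISRecord
from exopop.vcfio import CohortPanel, Variant, write_variants

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    n_individuals: int
    fst: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise GenerationError(f"F for {self.label!r} must lie in (0, 1)")


@dataclass(frozen=True)
class FounderSpec:
    """Planted founder-effect variant set.

    Defaults reflect the founder-variant picture: enriched to 1–10% MAF in
    the focal population while essentially absent (< 0.2%) elsewhere.
    """

    n_planted: int = 100
    focal_label: str = "AJ"
    focal_maf_range: tuple[float, float] = (0.011, 0.10)
    ref_maf_max: float = 0.002
    coding_fraction: float = 0.25  # share of planted variants drawn from coding sites

    def __post_init__(self) -> None:
        lo, hi = self.focal_maf_range
        if not (0.01 < lo < hi < 0.5):
            raise GenerationError("focal_maf_range must be ordered within (0.01, 0.5)")
        if not 0.0 < self.ref_maf_max < 0.01:
            raise GenerationError("ref_maf_max must lie in (0, 0.01)")


@dataclass(frozen=True)
class GeneSpec:
    n_genes: int = 24
    exons_per_gene: tuple[int, int] = (2, 5)
    cds_codons: tuple[int, int] = (60, 160)
    minus_strand_fraction: float = 0.4
    utr_bases: tuple[int, int] = (20, 60)
    intron_bases: tuple[int, int] = (30, 120)
    intergenic_bases: tuple[int, int] = (60, 160)


@dataclass(frozen=True)
class ScoreSpec:
    """Score distributions emulating an ensemble deleteriousness predictor:
    Normal(d_mean, sd) for truly deleterious variants, Normal(n_mean, sd)
    otherwise, clipped to [0, 1]; label "D" iff score > 0.5."""

    d_mean: float = 0.9
    n_mean: float = 0.1
    sd: float = 0.05


@dataclass
class SimulationConfig:
    n_variants: int = 2000
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("AJ", 128, 0.05),
            PopulationSpec("EUR", 128, 0.01),
            PopulationSpec("AFR", 128, 0.02),
            PopulationSpec("EAS", 128, 0.02),
            PopulationSpec("SAS", 128, 0.02),
        ]
    )
    founder: FounderSpec = field(default_factory=FounderSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    consequence_mix: dict[str, int] = field(
        default_factory=lambda: {
            "stop_gained": 8,
            "stop_lost": 4,
            "splice_site": 8,
            "missense": 40,
            "synonymous": 24,
            "exonic_unknown": 8,
        }
    )
    missense_deleterious_fraction: float = 0.5
    scores: ScoreSpec = field(default_factory=ScoreSpec)
    n_cases: int = 49  # case cohort drawn from focal-population frequencies
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise GenerationError("population labels must be unique")
        if self.founder.focal_label not in labels:
            raise GenerationError(
                f"focal label {self.founder.focal_label!r} not among populations"
            )
        if self.founder.n_planted > self.n_variants:
            raise GenerationError("n_planted exceeds n_variants")
        if sum(self.consequence_mix.values()) > self.n_variants:
            raise GenerationError("consequence mix exceeds n_variants")

    @property
    def reference_labels(self) -> list[str]:
        return [p.label for p in self.populations
                if p.label != self.founder.focal_label]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "populations" in kwargs:
            kwargs["populations"] = [
                PopulationSpec(**p) for p in kwargs["populations"]
            ]
        for key, typ in (("founder", FounderSpec), ("genes", GeneSpec),
                         ("scores", ScoreSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                for tup in ("focal_maf_range", "exons_per_gene", "cds_codons",
                            "utr_bases", "intron_bases", "intergenic_bases"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = typ(**sub)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(x) for x in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(plain(asdict(self)), sort_keys=True))


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    reference: dict[str, str]
    transcripts: list[Transcript]
    index: TranscriptIndex
    truth_variants: pd.DataFrame  # one row per variant, truth columns
    true_freqs: pd.DataFrame  # per-population true alt-allele frequency
    panels: dict[str, CohortPanel]
    case_panel: CohortPanel
    scores: dict[tuple, float]
    deleterious: dict[tuple, bool]
    rvis: dict[str, RVISRecord]
    gene_panels: dict[str, list[str]]

    @property
    def focal_label(self) -> str:
        return self.config.founder.focal_label


# ---------------------------------------------------------------------------
# gene models


def _random_utr(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(BASES), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    return "ATG" + "".join(body) + stop


def simulate_gene_models(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[Transcript], dict[str, str]]:
    """Build non-overlapping toy genes along one chromosome.

    Each gene is one transcript: a 5' UTR, an ORF (ATG ... stop, no internal
    stops, length divisible by 3) and a 3' UTR, split across exons separated
    by GT..AG introns; the requested fraction lies on the minus strand.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gs = config.genes
    chrom_parts: list[str] = []
    transcripts: list[Transcript] = []
    cursor = 0  # 0-based length so far

    for gi in range(gs.n_genes):
        spacer = _random_utr(rng, *gs.intergenic_bases)
        chrom_parts.append(spacer)
        cursor += len(spacer)

        n_codons = int(rng.integers(gs.cds_codons[0], gs.cds_codons[1] + 1))
        utr5 = _random_utr(rng, *gs.utr_bases)
        cds = _random_cds(rng, n_codons)
        utr3 = _random_utr(rng, *gs.utr_bases)
        tx_seq = utr5 + cds + utr3
        cds_span = (len(utr5), len(utr5) + len(cds))  # transcript space, half-open

        n_exons = int(rng.integers(gs.exons_per_gene[0], gs.exons_per_gene[1] + 1))
        n_exons = min(n_exons, len(tx_seq) // 10)
        # cut points keeping every exon at least 5 bases long
        cuts = sorted(
            rng.choice(np.arange(5, len(tx_seq) - 5), size=n_exons - 1,
                       replace=False)
        ) if n_exons > 1 else []
        cuts = [int(c) for c in cuts]
        spans = list(zip([0] + cuts, cuts + [len(tx_seq)]))  # transcript half-open

        # assemble local genomic sequence: exons + GT..AG introns
        local_parts: list[str] = []
        exon_local: list[tuple[int, int]] = []  # local 0-based half-open
        lpos = 0
        for i, (ts, te) in enumerate(spans):
            local_parts.append(tx_seq[ts:te])
            exon_local.append((lpos, lpos + (te - ts)))
            lpos += te - ts
            if i < len(spans) - 1:
                ilen = int(rng.integers(gs.intron_bases[0], gs.intron_bases[1] + 1))
                intron = "GT" + _random_utr(rng, max(ilen - 4, 4), max(ilen - 4, 4)) + "AG"
                local_parts.append(intron)
                lpos += len(intron)
        local_seq = "".join(local_parts)

        # CDS intervals in local coordinates (intersect exons with cds_span)
        cds_local: list[tuple[int, int]] = []
        for (ts, te), (ls, le) in zip(spans, exon_local):
            s = max(ts, cds_span[0])
            e = min(te, cds_span[1])
            if s < e:
                off = ls - ts
                cds_local.append((s + off, e + off))

        minus = rng.random() < gs.minus_strand_fraction
        L = len(local_seq)
        if minus:
            placed_seq = revcomp(local_seq)
            exon_g = sorted((L - e, L - s) for s, e in exon_local)
            cds_g = sorted((L - e, L - s) for s, e in cds_local)
            strand = "-"
        else:
            placed_seq = local_seq
            exon_g = exon_local
            cds_g = cds_local
            strand = "+"

        offset = cursor
        gene_id = f"G{gi + 1:03d}"
        transcripts.append(
            Transcript(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=config.chrom,
                strand=strand,
                exons=tuple((offset + s + 1, offset + e) for s, e in exon_g),
                cds=tuple((offset + s + 1, offset + e) for s, e in cds_g),
            )
        )
        chrom_parts.append(placed_seq)
        cursor += L

    tail = _random_utr(rng, *gs.intergenic_bases)
    chrom_parts.append(tail)
    reference = {config.chrom: "".join(chrom_parts)}

    # construction check: every CDS translates to exactly one terminal stop
    index = TranscriptIndex(transcripts, reference, strict=True)
    for t in transcripts:
        protein = str(Seq(index.cds_sequence(t.transcript_id)).translate())
        if not protein.startswith("M") or protein.count("*") != 1 or not protein.endswith("*"):
            raise GenerationError(f"malformed ORF in {t.transcript_id}")
    return transcripts, reference


# ---------------------------------------------------------------------------
# consequence injection


def _coding_positions(t: Transcript) -> list[int]:
    """Genomic positions of the CDS in coding (5'->3' mRNA) order."""
    plus_order = [p for s, e in t.cds for p in range(s, e + 1)]
    return plus_order[::-1] if t.strand == "-" else plus_order


def inject_consequences(
    transcripts: Sequence[Transcript],
    reference: Mapping[str, str],
    consequence_mix: Mapping[str, int],
    rng: np.random.Generator,
    max_tries: int = 20000,
) -> list[dict]:
    """Construct truth-labelled SNVs realizing the requested consequence mix.

    Alleles are reported on the plus strand.  Raises
    :class:`GenerationError` when the gene set cannot host the request
    (e.g. too few codons), suggesting larger genes.
    """
    index = TranscriptIndex(transcripts, reference, strict=True)
    coding = [t for t in transcripts if t.is_coding]
    if not coding:
        raise GenerationError("no coding transcripts to inject into")
    used: set[int] = set()
    out: list[dict] = []

    def genome_base(chrom: str, pos: int) -> str:
        return reference[chrom][pos - 1]

    def add(t: Transcript, pos: int, alt_plus: str, term: str) -> None:
        used.add(pos)
        out.append(
            {
                "chrom": t.chrom,
                "pos": pos,
                "ref": genome_base(t.chrom, pos),
                "alt": alt_plus,
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "term": term,
            }
        )

    def try_codon_term(term: str) -> bool:
        t = coding[int(rng.integers(0, len(coding)))]
        cds_seq = index.cds_sequence(t.transcript_id)
        order = _coding_positions(t)
        n_codons = len(cds_seq) // 3
        if term == "stop_lost":
            ci = n_codons - 1
        else:
            if n_codons < 4:
                return False
            ci = int(rng.integers(1, n_codons - 1))  # skip start & stop codons
        codon = cds_seq[3 * ci : 3 * ci + 3]
        ref_aa = str(Seq(codon).translate())
        offsets = list(rng.permutation(3))
        for off in offsets:
            pos = order[3 * ci + off]
            if pos in used:
                continue
            for alt_coding in rng.permutation(list(BASES)):
                if alt_coding == codon[off]:
                    continue
                alt_codon = codon[:off] + alt_coding + codon[off + 1 :]
                alt_aa = str(Seq(alt_codon).translate())
                if ref_aa == alt_aa:
                    got = "synonymous"
                elif alt_aa == "*":
                    got = "stop_gained"
                elif ref_aa == "*":
                    got = "stop_lost"
                else:
                    got = "missense"
                if got == term:
                    alt_plus = alt_coding if t.strand == "+" else revcomp(alt_coding)
                    add(t, pos, alt_plus, term)
                    return True
        return False

    def try_splice() -> bool:
        t = coding[int(rng.integers(0, len(coding)))]
        positions = sorted(t.splice_positions())
        if not positions:
            return False
        pos = positions[int(rng.integers(0, len(positions)))]
        if pos in used:
            return False
        ref = genome_base(t.chrom, pos)
        alts = [b for b in BASES if b != ref]
        add(t, pos, alts[int(rng.integers(0, len(alts)))], "splice_site")
        return True

    def try_utr() -> bool:
        t = coding[int(rng.integers(0, len(coding)))]
        cds_pos = {p for s, e in t.cds for p in range(s, e + 1)}
        utr = [
            p
            for s, e in t.exons
            for p in range(s, e + 1)
            if p not in cds_pos
        ]
        if not utr:
            return False
        pos = utr[int(rng.integers(0, len(utr)))]
        if pos in used:
            return False
        ref = genome_base(t.chrom, pos)
        alts = [b for b in BASES if b != ref]
        add(t, pos, alts[int(rng.integers(0, len(alts)))], "exonic_unknown")
        return True

    for term in ("stop_gained", "stop_lost", "splice_site", "missense",
                 "synonymous", "exonic_unknown"):
        want = int(consequence_mix.get(term, 0))
        got = 0
        tries = 0
        while got < want:
            tries += 1
            if tries > max_tries:
                raise GenerationError(
                    f"could not place {want} {term} variants after {max_tries} "
                    "tries; increase cds_codons or n_genes"
                )
            if term == "splice_site":
                ok = try_splice()
            elif term == "exonic_unknown":
                ok = try_utr()
            else:
                ok = try_codon_term(term)
            if ok:
                got += 1
    return out


# ---------------------------------------------------------------------------
# frequencies, genotypes, scores


def _ancestral_freqs(rng: np.random.Generator, n: int) -> np.ndarray:
    """U-shaped ancestral spectrum: Beta(0.2, 0.2) truncated to (0.001, 0.5)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(0.2, 0.2, size=2 * (n - filled) + 16)
        ok = draw[(draw > 0.001) & (draw < 0.5)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> np.ndarray:
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_frequencies(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    planted: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-population true alt-allele frequency table plus the planted mask.

    Planted founder variants are overwritten after the drift draw; unplanted
    variants satisfying the population-specific criterion on true folded
    frequencies are redrawn so the planted set is exactly the true founder
    set.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_variants
    pops = config.populations
    focal = config.founder.focal_label
    labels = [p.label for p in pops]
    focal_j = labels.index(focal)
    ref_js = [j for j in range(len(pops)) if j != focal_j]

    p = _ancestral_freqs(rng, n)
    freqs = np.column_stack([_balding_nichols(rng, p, sp.fst) for sp in pops])

    if planted is None:
        idx = rng.choice(n, size=config.founder.n_planted, replace=False)
        planted = np.zeros(n, dtype=bool)
        planted[idx] = True
    lo, hi = config.founder.focal_maf_range
    n_pl = int(planted.sum())
    freqs[planted, focal_j] = rng.uniform(lo, hi, size=n_pl)
    for j in ref_js:
        freqs[planted, j] = rng.uniform(0.0, config.founder.ref_maf_max, size=n_pl)

    def is_true_specific(row: np.ndarray) -> bool:
        maf = np.minimum(row, 1.0 - row)
        return population_specific(maf[focal_j], [maf[j] for j in ref_js])

    for i in np.flatnonzero(~planted):
        tries = 0
        while is_true_specific(freqs[i]) and tries < 1000:
            tries += 1
            pi = _ancestral_freqs(rng, 1)[0]
            for j, sp in enumerate(pops):
                freqs[i, j] = _balding_nichols(rng, np.array([pi]), sp.fst)[0]

    df = pd.DataFrame(freqs, columns=labels)
    return df, planted


def simulate_genotypes(
    freqs: pd.DataFrame,
    variants: Sequence[Variant],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, CohortPanel]:
    """Hardy–Weinberg genotypes: dosage ~ Binomial(2, population frequency),
    independently per individual and variant."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    panels: dict[str, CohortPanel] = {}
    for sp in config.populations:
        f = freqs[sp.label].to_numpy()
        dosages = rng.binomial(
            2, f[:, None], size=(len(variants), sp.n_individuals)
        ).astype(float)
        samples = [f"{sp.label}_{i:03d}" for i in range(sp.n_individuals)]
        panels[sp.label] = CohortPanel(
            variants=list(variants),
            samples=samples,
            genotypes=dosages,
            label=sp.label,
            filters=["PASS"] * len(variants),
        )
    return panels


def simulate_scores(
    truth: pd.DataFrame,
    score_model: ScoreSpec,
    rng: np.random.Generator,
) -> tuple[dict[tuple, float], dict[tuple, bool]]:
    """Deleteriousness scores correlated with truth: Normal(d_mean, sd) for
    truly deleterious variants, Normal(n_mean, sd) otherwise, clipped to
    [0, 1]; label "D" iff score > 0.5."""
    scores: dict[tuple, float] = {}
    flags: dict[tuple, bool] = {}
    for row in truth.itertuples(index=False):
        mean = score_model.d_mean if row.deleterious_truth else score_model.n_mean
        s = float(np.clip(rng.normal(mean, score_model.sd) if score_model.sd > 0
                          else mean, 0.0, 1.0))
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        scores[key] = s
        flags[key] = s > 0.5
    return scores, flags


# ---------------------------------------------------------------------------
# full dataset


def _filler_positions(
    config: SimulationConfig,
    index: TranscriptIndex,
    used: set[int],
    n_needed: int,
    rng: np.random.Generator,
) -> list[int]:
    """Unique positions outside exons and splice windows (intergenic or deep
    intronic), so filler variants never acquire a consequence call."""
    chrom_len = len(index.reference[config.chrom])
    blocked = set(used)
    for t in index.transcripts.values():
        for s, e in t.exons:
            blocked.update(range(max(1, s - SPLICE_WINDOW), e + SPLICE_WINDOW + 1))
    candidates = np.array(
        [p for p in range(1, chrom_len + 1) if p not in blocked], dtype=int
    )
    if len(candidates) < n_needed:
        raise GenerationError(
            "chromosome too short for the requested variant count; "
            "increase intergenic_bases or reduce n_variants"
        )
    chosen = rng.choice(candidates, size=n_needed, replace=False)
    return sorted(int(p) for p in chosen)


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run the full generator: gene models, injected consequence variants,
    filler variants, true frequencies with a planted founder set, HWE
    genotype panels, a case cohort, scores, synthetic RVIS, and gene panels.

    Deterministic: a pure function of the config (including its seed).
    """
    config = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(config.seed)

    transcripts, reference = simulate_gene_models(config, rng)
    index = TranscriptIndex(transcripts, reference, strict=True)

    injected = inject_consequences(
        transcripts, reference, config.consequence_mix, rng
    )
    used = {v["pos"] for v in injected}
    n_filler = config.n_variants - len(injected)
    filler_pos = _filler_positions(config, index, used, n_filler, rng)

    rows: list[dict] = []
    for v in injected:
        rows.append(dict(v))
    chrom_seq = reference[config.chrom]
    for pos in filler_pos:
        ref = chrom_seq[pos - 1]
        alts = [b for b in BASES if b != ref]
        rows.append(
            {
                "chrom": config.chrom,
                "pos": pos,
                "ref": ref,
                "alt": alts[int(rng.integers(0, len(alts)))],
                "gene_id": "",
                "transcript_id": "",
                "term": "",
            }
        )
    rows.sort(key=lambda r: r["pos"])
    truth = pd.DataFrame(rows)
    truth["impact"] = truth["term"].map(
        {
            "stop_gained": "high",
            "stop_lost": "high",
            "splice_site": "high",
            "missense": "moderate",
            "synonymous": "low",
            "exonic_unknown": "low",
        }
    ).fillna("")

    # deleterious truth: all high-impact, plus a fraction of missense
    is_high = truth["impact"].eq("high")
    is_missense = truth["term"].eq("missense")
    del_missense = is_missense & (
        rng.random(len(truth)) < config.missense_deleterious_fraction
    )
    truth["deleterious_truth"] = is_high | del_missense

    # founder planting: a configured fraction lands on coding (injected)
    # sites so founder-driven burden and screen signals exist downstream
    coding_rows = np.flatnonzero(truth["term"].ne("").to_numpy())
    other_rows = np.flatnonzero(truth["term"].eq("").to_numpy())
    n_cod = min(
        int(round(config.founder.coding_fraction * config.founder.n_planted)),
        len(coding_rows),
    )
    planted_mask = np.zeros(len(truth), dtype=bool)
    if n_cod > 0:
        planted_mask[rng.choice(coding_rows, size=n_cod, replace=False)] = True
    n_rest = config.founder.n_planted - n_cod
    if n_rest > 0:
        planted_mask[rng.choice(other_rows, size=n_rest, replace=False)] = True

    freqs, planted = simulate_frequencies(config, rng, planted=planted_mask)
    truth["founder"] = planted
    for label in freqs.columns:
        truth[f"freq_{label}"] = freqs[label].to_numpy()

    variants = [
        Variant(chrom=r["chrom"], pos=r["pos"], ref=r["ref"], alt=r["alt"])
        for r in rows
    ]
    panels = simulate_genotypes(freqs, variants, config, rng)

    focal_f = freqs[config.founder.focal_label].to_numpy()
    case_dosages = rng.binomial(
        2, focal_f[:, None], size=(len(variants), config.n_cases)
    ).astype(float)
    case_panel = CohortPanel(
        variants=list(variants),
        samples=[f"CASE_{i:03d}" for i in range(config.n_cases)],
        genotypes=case_dosages,
        label="CASE",
        filters=["PASS"] * len(variants),
    )

    scores, deleterious = simulate_scores(truth, config.scores, rng)

    gene_ids = sorted({t.gene_id for t in transcripts})
    rvis_scores = rng.normal(0.0, 1.0, size=len(gene_ids))
    order = np.argsort(rvis_scores, kind="stable")
    pct = np.empty(len(gene_ids))
    pct[order] = 100.0 * (np.arange(len(gene_ids)) + 1) / len(gene_ids)
    rvis = {
        g: RVISRecord(gene_id=g, rvis_score=float(rvis_scores[i]),
                      percentile=float(pct[i]))
        for i, g in enumerate(gene_ids)
    }

    n_acmg = max(3, len(gene_ids) // 3)
    acmg_like = sorted(
        rng.choice(gene_ids, size=n_acmg, replace=False).tolist()
    )
    n_cosmic = max(3, len(gene_ids) // 4)
    cosmic_like = sorted(
        rng.choice(gene_ids, size=n_cosmic, replace=False).tolist()
    )
    gene_panels = {"acmg_like": acmg_like, "cosmic_like": cosmic_like}

    return SyntheticDataset(
        config=config,
        reference=reference,
        transcripts=transcripts,
        index=index,
        truth_variants=truth,
        true_freqs=freqs,
        panels=panels,
        case_panel=case_panel,
        scores=scores,
        deleterious=deleterious,
        rvis=rvis,
        gene_panels=gene_panels,
    )


# ---------------------------------------------------------------------------
# emission


def _write_fasta(reference: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_gff(transcripts: Sequence[Transcript], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda t: t.exons[0][0]):
            g_start = min(s for s, _ in t.exons)
            g_end = max(e for _, e in t.exons)
            fh.write(
                f"{t.chrom}\texopop\tgene\t{g_start}\t{g_end}\t.\t{t.strand}\t.\t"
                f"ID={t.gene_id}\n"
            )
            fh.write(
                f"{t.chrom}\texopop\tmRNA\t{g_start}\t{g_end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={t.gene_id}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\texopop\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"Parent={t.transcript_id}\n"
                )
            for s, e in t.cds:
                fh.write(
                    f"{t.chrom}\texopop\tCDS\t{s}\t{e}\t.\t{t.strand}\t0\t"
                    f"Parent={t.transcript_id}\n"
                )


def emit(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as files re-readable by the consuming modules.

    Emits per-population VCFs, a GFF3, a FASTA, true/sample frequency TSVs,
    a score TSV, a synthetic RVIS TSV, gene-panel lists, truth tables and a
    YAML echo of the configuration.  Returns the path of each artifact.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for label, panel in {**dataset.panels, "CASE": dataset.case_panel}.items():
        p = out / f"{label}.vcf"
        write_variants(panel, p)
        paths[f"vcf_{label}"] = p

    paths["fasta"] = out / "reference.fa"
    _write_fasta(dataset.reference, paths["fasta"])
    paths["gff"] = out / "genes.gff3"
    _write_gff(dataset.transcripts, paths["gff"])

    paths["true_freqs"] = out / "true_frequencies.tsv"
    tf = dataset.truth_variants[
        ["chrom", "pos", "ref", "alt"]
        + [f"freq_{p.label}" for p in dataset.config.populations]
    ]
    tf.to_csv(paths["true_freqs"], sep="\t", index=False)

    paths["scores"] = out / "scores.tsv"
    rows = []
    for row in dataset.truth_variants.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        s = dataset.scores[key]
        rows.append(
            {
                "chrom": row.chrom,
                "pos": int(row.pos),
                "ref": row.ref,
                "alt": row.alt,
                "score": f"{s:.4f}",
                "label": "D" if dataset.deleterious[key] else "T",
            }
        )
    pd.DataFrame(rows).to_csv(paths["scores"], sep="\t", index=False)

    paths["rvis"] = out / "rvis.tsv"
    pd.DataFrame(
        [
            {"gene": g, "score": f"{r.rvis_score:.4f}",
             "percentile": f"{r.percentile:.2f}"}
            for g, r in sorted(dataset.rvis.items())
        ]
    ).to_csv(paths["rvis"], sep="\t", index=False)

    for name, genes in dataset.gene_panels.items():
        p = out / f"panel_{name}.txt"
        p.write_text("\n".join(genes) + "\n")
        paths[f"panel_{name}"] = p

    paths["truth_variants"] = out / "truth_variants.tsv"
    dataset.truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False)

    paths["config"] = out / "simulation_config.yaml"
    dataset.config.to_yaml(paths["config"])
    return paths
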