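"""Functional consequence classification of SNVs from gene models.

Each coding variant is assigned one of six consequence terms and a
three-level impact class:

* high — stop_gained, stop_lost, or splice_site (within 2 bp of an
  intron/exon junction on the intronic side);
* moderate — missense;
* low — synonymous, or exonic_unknown (exonic but outside any CDS, e.g. UTR).

Codon effects are evaluated by substituting the alternate base into the
strand-corrected CDS and translating the affected codon with the standard
genetic code.  When several transcripts overlap a variant, the most severe
call wins; ties break on the lexicographically smallest transcript id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

from exopop.errors import (
    GeneModelError,
    ReferenceMismatchError,
    ReferenceMissingError,
)
from exopop.vcfio import Variant

TERMS = (
    "stop_gained",
    "stop_lost",
    "splice_site",
    "missense",
    "synonymous",
    "exonic_unknown",
)

# lower rank = more severe; the three high-impact terms rank equally
SEVERITY: dict[str, int] = {
    "stop_gained": 0,
    "stop_lost": 0,
    "splice_site": 0,
    "missense": 1,
    "synonymous": 2,
    "exonic_unknown": 3,
}

IMPACT_OF_TERM: dict[str, str] = {
    "stop_gained": "high",
    "stop_lost": "high",
    "splice_site": "high",
    "missense": "moderate",
    "synonymous": "low",
    "exonic_unknown": "low",
}

SPLICE_WINDOW = 2  # intronic bases on each side of an internal exon boundary

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A transcript model with 1-based inclusive exon and CDS intervals,
    both sorted by genomic position."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        if self.strand not in ("+", "-"):
            errs.append(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if e < s:
                errs.append(f"exon ({s},{e}) is empty")
            if s <= prev_end:
                errs.append("exons overlap or are unsorted")
            prev_end = e
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                errs.append(f"CDS interval ({s},{e}) not contained in an exon")
        if self.cds and self.cds_length % 3 != 0:
            errs.append(f"CDS length {self.cds_length} not divisible by 3")
        return errs

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def internal_boundaries(self) -> list[tuple[int, str]]:
        """(boundary exon coordinate, side) for every internal junction.

        side 'donor_like' = intron begins after the exon end; 'acceptor_like'
        = intron ends before the exon start.  First exon start and last exon
        end are transcript termini, not junctions.
        """
        out: list[tuple[int, str]] = []
        for i, (s, e) in enumerate(self.exons):
            if i < len(self.exons) - 1:
                out.append((e, "donor_like"))
            if i > 0:
                out.append((s, "acceptor_like"))
        return out

    def splice_positions(self) -> set[int]:
        """Intronic positions within SPLICE_WINDOW bp of an internal junction."""
        pos: set[int] = set()
        for b, side in self.internal_boundaries():
            if side == "donor_like":
                pos.update(range(b + 1, b + 1 + SPLICE_WINDOW))
            else:
                pos.update(range(b - SPLICE_WINDOW, b))
        return pos


@dataclass(frozen=True)
class ConsequenceCall:
    variant: Variant
    gene_id: str
    transcript_id: str
    term: str
    impact: str

    def __post_init__(self) -> None:
        if self.term not in TERMS:
            raise ValueError(f"unknown term {self.term!r}")
        if self.impact != IMPACT_OF_TERM[self.term]:
            raise ValueError(
                f"impact {self.impact!r} inconsistent with term {self.term!r}"
            )


class TranscriptIndex:
    """Point-query index over transcript models plus the reference sequence.

    Supports "which transcripts' CDS / exons / splice windows cover position
    p" queries.  Transcripts failing structural validation are rejected and
    recorded in ``rejected`` with named reasons.
    """

    def __init__(
        self,
        transcripts: Iterable[Transcript],
        reference: Mapping[str, str],
        strict: bool = False,
    ) -> None:
        self.reference: dict[str, str] = {c: s.upper() for c, s in reference.items()}
        self.transcripts: dict[str, Transcript] = {}
        self.rejected: dict[str, str] = {}
        self._cds: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        self._splice: dict[str, IntervalTree] = {}
        self._cds_seq_cache: dict[str, str] = {}
        for t in transcripts:
            errs = t.validation_errors()
            if t.chrom not in self.reference:
                raise ReferenceMissingError(
                    f"transcript {t.transcript_id}: chromosome {t.chrom!r} "
                    "absent from the reference"
                )
            chrom_len = len(self.reference[t.chrom])
            if any(e > chrom_len for _, e in t.exons):
                errs.append("exon interval beyond chromosome end")
            if errs:
                if strict:
                    raise GeneModelError(
                        f"transcript {t.transcript_id}: " + "; ".join(errs)
                    )
                self.rejected[t.transcript_id] = "; ".join(errs)
                continue
            self.transcripts[t.transcript_id] = t
            cds_tree = self._cds.setdefault(t.chrom, IntervalTree())
            for s, e in t.cds:
                cds_tree.addi(s, e + 1, t.transcript_id)
            exon_tree = self._exon.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                exon_tree.addi(s, e + 1, t.transcript_id)
            if t.is_coding:
                splice_tree = self._splice.setdefault(t.chrom, IntervalTree())
                for p in sorted(t.splice_positions()):
                    splice_tree.addi(p, p + 1, t.transcript_id)

    def _hits(self, trees: dict[str, IntervalTree], chrom: str, pos: int) -> list[str]:
        tree = trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(pos)})

    def cds_hits(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self._cds, chrom, pos)

    def exon_hits(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self._exon, chrom, pos)

    def splice_hits(self, chrom: str, pos: int) -> list[str]:
        return self._hits(self._splice, chrom, pos)

    def cds_sequence(self, transcript_id: str) -> str:
        """Coding-orientation CDS sequence (5'->3' of the mRNA)."""
        if transcript_id not in self._cds_seq_cache:
            t = self.transcripts[transcript_id]
            chrom = self.reference[t.chrom]
            seq = "".join(chrom[s - 1 : e] for s, e in t.cds)
            if t.strand == "-":
                seq = revcomp(seq)
            self._cds_seq_cache[transcript_id] = seq
        return self._cds_seq_cache[transcript_id]

    def cds_index(self, transcript_id: str, pos: int) -> int:
        """0-based index of genomic position ``pos`` within the coding sequence."""
        t = self.transcripts[transcript_id]
        offset = 0
        plus_index = None
        for s, e in t.cds:
            if s <= pos <= e:
                plus_index = offset + (pos - s)
                break
            offset += e - s + 1
        if plus_index is None:
            raise ValueError(f"position {pos} not in CDS of {transcript_id}")
        if t.strand == "-":
            return t.cds_length - 1 - plus_index
        return plus_index

    def ref_base(self, chrom: str, pos: int) -> str:
        return self.reference[chrom][pos - 1]

    def gene_lengths(self) -> dict[str, int]:
        """Genomic span (min exon start to max exon end) per gene."""
        lo: dict[str, int] = {}
        hi: dict[str, int] = {}
        for t in self.transcripts.values():
            s = min(x for x, _ in t.exons)
            e = max(x for _, x in t.exons)
            lo[t.gene_id] = min(lo.get(t.gene_id, s), s)
            hi[t.gene_id] = max(hi.get(t.gene_id, e), e)
        return {g: hi[g] - lo[g] + 1 for g in lo}


def _transcripts_from_gff(gff_path: str | Path) -> list[Transcript]:
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: list[Transcript] = []
    for feat in db.features_of_type(("mRNA", "transcript")):
        tid = feat.id
        parents = feat.attributes.get("Parent", [])
        gene_id = parents[0] if parents else feat.attributes.get("gene_id", [tid])[0]
        exons = sorted(
            (c.start, c.end) for c in db.children(feat, featuretype="exon")
        )
        cds = sorted((c.start, c.end) for c in db.children(feat, featuretype="CDS"))
        if not exons:
            exons = list(cds)
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return transcripts


def build_transcript_index(
    gff_path: str | Path, fasta_path: str | Path, strict: bool = False
) -> TranscriptIndex:
    """Parse GFF3/GTF gene models and a reference FASTA into a query index.

    Transcripts violating structural invariants (overlapping exons, CDS not
    inside exons, CDS length not divisible by 3) are rejected with named
    reasons (or raise, if ``strict``).  A transcript on a chromosome missing
    from the FASTA raises :class:`ReferenceMissingError`.
    """
    fasta = Fasta(str(fasta_path))
    reference = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
    return TranscriptIndex(_transcripts_from_gff(gff_path), reference, strict=strict)


def _codon_term(index: TranscriptIndex, tid: str, variant: Variant) -> str:
    t = index.transcripts[tid]
    cds_seq = index.cds_sequence(tid)
    i = index.cds_index(tid, variant.pos)
    alt_coding = variant.alt if t.strand == "+" else revcomp(variant.alt)
    codon_start = (i // 3) * 3
    ref_codon = cds_seq[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: i % 3] + alt_coding + ref_codon[i % 3 + 1 :]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense"


def classify_consequence(
    variant: Variant, index: TranscriptIndex
) -> ConsequenceCall | None:
    """Classify a biallelic SNV against all overlapping transcripts.

    Returns ``None`` when no transcript's exon or splice window covers the
    position; otherwise the most severe call.  A REF allele disagreeing with
    the reference sequence raises :class:`ReferenceMismatchError`.
    """
    if not variant.is_biallelic_snv:
        raise ValueError(f"not a biallelic SNV: {variant}")
    chrom, pos = variant.chrom, variant.pos
    splice = index.splice_hits(chrom, pos)
    cds = index.cds_hits(chrom, pos)
    exon = index.exon_hits(chrom, pos)
    if not (splice or cds or exon):
        return None
    genome_base = index.ref_base(chrom, pos)
    if variant.ref != genome_base:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} REF {variant.ref} != reference base {genome_base}"
        )
    candidates: list[tuple[int, str, str]] = []  # (severity, tid, term)
    for tid in splice:
        candidates.append((SEVERITY["splice_site"], tid, "splice_site"))
    for tid in cds:
        term = _codon_term(index, tid, variant)
        candidates.append((SEVERITY[term], tid, term))
    for tid in exon:
        if tid not in cds:
            candidates.append((SEVERITY["exonic_unknown"], tid, "exonic_unknown"))
    sev, tid, term = min(candidates, key=lambda c: (c[0], c[1]))
    return ConsequenceCall(
        variant=variant,
        gene_id=index.transcripts[tid].gene_id,
        transcript_id=tid,
        term=term,
        impact=IMPACT_OF_TERM[term],
    )


def summarize_impacts(calls: Iterable[ConsequenceCall]) -> dict[str, int]:
    """Counts per impact class; ``splice_site`` is the subcount within high."""
    out = {"high": 0, "moderate": 0, "low": 0, "splice_site": 0}
    for c in calls:
        out[c.impact] += 1
        if c.term == "splice_site":
            out["splice_site"] += 1
    return out


def write_consequence_table(
    calls: Iterable[ConsequenceCall], path: str | Path
) -> None:
    import pandas as pd

    rows = [
        {
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "gene": c.gene_id,
            "term": c.term,
            "impact": c.impact,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "term", "impact"]
    ).to_csv(path, sep="\t", index=False)
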