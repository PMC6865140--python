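"""Gene burden aggregation, outlier filtering and prioritization."""

import numpy as np
import pytest

from exopop.consequence import ConsequenceCall
from exopop.prioritize import (
    GeneBurden,
    RVISRecord,
    burden_by_gene,
    deleterious_burden,
    filter_outlier_genes,
    length_correlation,
    read_rvis,
    read_scores,
    rvis_prioritize,
)
from exopop.vcfio import Variant


def make_call(pos, gene, term, impact):
    v = Variant("chr1", pos, "A", "G")
    return v.key, ConsequenceCall(
        variant=v, gene_id=gene, transcript_id=f"{gene}.t1", term=term,
        impact=impact,
    )


@pytest.fixture()
def calls():
    entries = [
        make_call(1, "G1", "missense", "moderate"),
        make_call(2, "G1", "missense", "moderate"),
        make_call(3, "G1", "missense", "moderate"),
        make_call(4, "G1", "synonymous", "low"),
        make_call(5, "G2", "stop_gained", "high"),
        make_call(6, "G2", "missense", "moderate"),
    ]
    return dict(entries)


class TestBurdenByGene:
    def test_impact_filter_excludes_low(self, calls):
        burdens, skipped = burden_by_gene(list(calls), calls)
        by_gene = {b.gene_id: b for b in burdens}
        assert by_gene["G1"].n_specific == 3  # synonymous not counted
        assert by_gene["G2"].n_specific == 2
        assert skipped == 0

    def test_variant_without_call_skipped_and_counted(self, calls):
        keys = list(calls) + [("chr1", 99, "A", "G")]
        burdens, skipped = burden_by_gene(keys, calls)
        assert skipped == 1
        assert sum(b.n_specific for b in burdens) == 5  # conservation

    def test_deleterious_subcount(self, calls):
        deleterious = {k: k[1] in (1, 5) for k in calls}
        burdens, _ = burden_by_gene(list(calls), calls, deleterious=deleterious)
        by_gene = {b.gene_id: b for b in burdens}
        assert by_gene["G1"].n_deleterious == 1
        assert by_gene["G2"].n_deleterious == 1

    def test_planted_truth_recovery(self, small_dataset):
        """Per-gene burdens of planted founder variants match the truth table."""
        truth = small_dataset.truth_variants
        from exopop.consequence import classify_consequence

        calls = {}
        for row in truth[truth.term != ""].itertuples(index=False):
            v = Variant(row.chrom, int(row.pos), row.ref, row.alt)
            calls[v.key] = classify_consequence(v, small_dataset.index)
        specific = [
            (r.chrom, int(r.pos), r.ref, r.alt)
            for r in truth[truth.founder].itertuples(index=False)
        ]
        burdens, _ = burden_by_gene(specific, calls)
        expected = (
            truth[truth.founder & truth.impact.isin(["high", "moderate"])]
            .groupby("gene_id")
            .size()
            .to_dict()
        )
        assert {b.gene_id: b.n_specific for b in burdens} == expected


class TestLengthCorrelation:
    def test_perfect_correlation(self):
        burdens = [GeneBurden(f"G{i}", n_specific=i, gene_length=1000 * i)
                   for i in (1, 2, 3)]
        assert length_correlation(burdens) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        burdens = [
            GeneBurden("G1", 1, gene_length=3),
            GeneBurden("G2", 2, gene_length=2),
            GeneBurden("G3", 3, gene_length=1),
        ]
        assert length_correlation(burdens) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # counts (1,2,3,4) vs lengths (2,1,4,3): r = 0.6 by the closed form
        burdens = [
            GeneBurden("G1", 1, gene_length=2),
            GeneBurden("G2", 2, gene_length=1),
            GeneBurden("G3", 3, gene_length=4),
            GeneBurden("G4", 4, gene_length=3),
        ]
        assert length_correlation(burdens) == pytest.approx(0.6)

    def test_matches_textbook_formula_brute_force(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 9, size=30)
        lengths = rng.integers(500, 5000, size=30)
        burdens = [
            GeneBurden(f"G{i}", int(c), gene_length=int(l))
            for i, (c, l) in enumerate(zip(counts, lengths))
        ]
        x, y = counts.astype(float), lengths.astype(float)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum())
            * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert abs(length_correlation(burdens) - expected) < 1e-12

    def test_zero_variance_rejected(self):
        burdens = [GeneBurden(f"G{i}", 2, gene_length=100 + i) for i in range(4)]
        with pytest.raises(ValueError):
            length_correlation(burdens)


class TestOutlierFilter:
    def test_mad_rule_removes_extreme_gene(self):
        burdens = [GeneBurden(f"G{i}", n) for i, n in enumerate([1, 1, 1, 1, 50])]
        kept, removed = filter_outlier_genes(burdens, mad_k=5.0)
        assert set(removed) == {"G4"}
        assert len(kept) == 4

    def test_no_outliers_is_identity(self):
        burdens = [GeneBurden(f"G{i}", n) for i, n in enumerate([1, 2, 2, 3])]
        kept, removed = filter_outlier_genes(burdens, mad_k=5.0)
        assert kept == burdens and removed == {}

    def test_blacklist_removes_regardless_of_count(self):
        burdens = [GeneBurden("G1", 1), GeneBurden("G2", 1)]
        kept, removed = filter_outlier_genes(burdens, blacklist={"G1"})
        assert removed == {"G1": "blacklisted"}
        assert [b.gene_id for b in kept] == ["G2"]


RVIS = {
    "G1": RVISRecord("G1", -2.0, 0.2),
    "G2": RVISRecord("G2", -1.0, 10.0),
    "G3": RVISRecord("G3", 1.0, 80.0),
}


class TestRvisPrioritize:
    def test_low_percentile_high_burden_retained_first(self):
        burdens = [GeneBurden("G1", 7), GeneBurden("G2", 5), GeneBurden("G3", 9)]
        top = rvis_prioritize(burdens, RVIS, max_percentile=25.0, min_count=4)
        assert [b.gene_id for b in top] == ["G1", "G2"]
        assert top[0].rvis_percentile == 0.2

    def test_unknown_rvis_excluded(self):
        burdens = [GeneBurden("G1", 7), GeneBurden("GX", 9)]
        top = rvis_prioritize(burdens, RVIS, max_percentile=100.0, min_count=0)
        assert [b.gene_id for b in top] == ["G1"]

    def test_fully_relaxed_thresholds_keep_all_annotated(self):
        burdens = [GeneBurden(g, 1) for g in ("G1", "G2", "G3")]
        top = rvis_prioritize(burdens, RVIS, max_percentile=100.0, min_count=0)
        assert len(top) == 3

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(7)
        burdens = [GeneBurden(f"G{i}", int(rng.integers(0, 8))) for i in range(20)]
        rvis = {
            f"G{i}": RVISRecord(f"G{i}", float(rng.normal()),
                                float(rng.uniform(0, 100)))
            for i in range(20)
        }
        base = {b.gene_id for b in rvis_prioritize(burdens, rvis, 20.0, 3)}
        relaxed_pct = {b.gene_id for b in rvis_prioritize(burdens, rvis, 60.0, 3)}
        relaxed_cnt = {b.gene_id for b in rvis_prioritize(burdens, rvis, 20.0, 1)}
        assert base <= relaxed_pct and base <= relaxed_cnt


class TestDeleteriousBurden:
    def test_threshold_and_histogram(self):
        burdens = [
            GeneBurden("G1", 5, n_deleterious=3),
            GeneBurden("G2", 4, n_deleterious=2),
            GeneBurden("G3", 4, n_deleterious=4),
            GeneBurden("G4", 1, n_deleterious=0),
        ]
        hits, hist = deleterious_burden(burdens, min_count=3)
        assert [b.gene_id for b in hits] == ["G3", "G1"]
        assert hist == {2: 1, 3: 1, 4: 1}

    def test_planted_histogram_recovery(self, small_dataset):
        truth = small_dataset.truth_variants
        from exopop.consequence import classify_consequence

        calls = {}
        for row in truth[truth.term != ""].itertuples(index=False):
            v = Variant(row.chrom, int(row.pos), row.ref, row.alt)
            calls[v.key] = classify_consequence(v, small_dataset.index)
        specific = [
            (r.chrom, int(r.pos), r.ref, r.alt)
            for r in truth[truth.founder].itertuples(index=False)
        ]
        deleterious = {
            (r.chrom, int(r.pos), r.ref, r.alt): bool(r.deleterious_truth)
            for r in truth.itertuples(index=False)
        }
        burdens, _ = burden_by_gene(specific, calls, deleterious=deleterious)
        _, hist = deleterious_burden(burdens)
        expected_counts = (
            truth[
                truth.founder
                & truth.deleterious_truth
                & truth.impact.isin(["high", "moderate"])
            ]
            .groupby("gene_id")
            .size()
        )
        expected_hist = expected_counts.value_counts().to_dict()
        assert hist == {int(k): int(v) for k, v in expected_hist.items()}


def test_rvis_and_score_tables_round_trip(small_dataset, tmp_path):
    from exopop.simulate import emit

    paths = emit(small_dataset, tmp_path / "d")
    rvis = read_rvis(paths["rvis"])
    assert set(rvis) == set(small_dataset.rvis)
    for g, r in rvis.items():
        assert r.percentile == pytest.approx(
            small_dataset.rvis[g].percentile, abs=0.01
        )
    scores, flags = read_scores(paths["scores"])
    assert flags == small_dataset.deleterious


def test_gene_burden_invariants():
    with pytest.raises(ValueError):
        GeneBurden("G", n_specific=1, n_deleterious=2)
    with pytest.raises(ValueError):
        RVISRecord("G", 0.0, 101.0)
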