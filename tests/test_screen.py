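"""Incidental-finding screens and the case-cohort filter cascade."""

import numpy as np
import pytest

from exopop.consequence import ConsequenceCall
from exopop.errors import ConfigError
from exopop.popfreq import frequency_table
from exopop.screen import (
    GenePanel,
    ScreenConfig,
    ScreenReport,
    compare_freq_sources,
    reduction_from_counts,
    reduction_stats,
    screen_cases,
    screen_incidental,
)
from exopop.vcfio import CohortPanel, Variant


def call_for(v, gene, term="stop_gained", impact="high"):
    return ConsequenceCall(variant=v, gene_id=gene, transcript_id=f"{gene}.t",
                           term=term, impact=impact)


def cohort(variants, dosage_rows, n_samples, label="AJ"):
    genotypes = np.zeros((len(variants), n_samples))
    for i, carriers in enumerate(dosage_rows):
        for j in carriers:
            genotypes[i, j] = 1
    return CohortPanel(
        variants=variants,
        samples=[f"{label}_{j}" for j in range(n_samples)],
        genotypes=genotypes,
        label=label,
    )


class TestScreenIncidental:
    def test_two_singleton_findings_in_128_gives_1_56_percent(self):
        """Two high-impact panel-gene variants, each a singleton in a distinct
        carrier, over 128 individuals: rate 1.56%."""
        v1, v2 = Variant("chr1", 10, "A", "T"), Variant("chr1", 20, "C", "A")
        panel = cohort([v1, v2], [[3], [40]], 128)
        calls = {v1.key: call_for(v1, "BRCA2_like"),
                 v2.key: call_for(v2, "RYR1_like")}
        gp = GenePanel("acmg", frozenset({"BRCA2_like", "RYR1_like", "OTHER"}))
        findings, rate = screen_incidental(panel, calls, gp)
        assert len(findings) == 2
        assert rate == 1.56

    def test_no_findings_rate_zero(self):
        v = Variant("chr1", 10, "A", "T")
        panel = cohort([v], [[0]], 128)
        calls = {v.key: call_for(v, "NOT_IN_PANEL")}
        gp = GenePanel("acmg", frozenset({"G1"}))
        findings, rate = screen_incidental(panel, calls, gp)
        assert findings == [] and rate == 0.0

    def test_same_carrier_counted_once(self):
        v1, v2 = Variant("chr1", 10, "A", "T"), Variant("chr1", 20, "C", "A")
        panel = cohort([v1, v2], [[3], [3]], 128)
        calls = {v1.key: call_for(v1, "G1"), v2.key: call_for(v2, "G1")}
        gp = GenePanel("acmg", frozenset({"G1"}))
        findings, rate = screen_incidental(panel, calls, gp)
        assert len(findings) == 2
        assert rate == round(100 / 128, 2)  # one distinct carrier

    def test_moderate_impact_not_a_finding(self):
        v = Variant("chr1", 10, "A", "T")
        panel = cohort([v], [[0]], 64)
        calls = {v.key: call_for(v, "G1", term="missense", impact="moderate")}
        gp = GenePanel("acmg", frozenset({"G1"}))
        findings, rate = screen_incidental(panel, calls, gp)
        assert findings == [] and rate == 0.0

    def test_maf_cap_excludes_common_variant(self):
        v = Variant("chr1", 10, "A", "T")
        panel = cohort([v], [[j for j in range(30)]], 64)
        calls = {v.key: call_for(v, "G1")}
        gp = GenePanel("acmg", frozenset({"G1"}))
        freq = frequency_table(panel)
        _, rate_uncapped = screen_incidental(panel, calls, gp)
        _, rate_capped = screen_incidental(panel, calls, gp, max_maf=0.01,
                                           freq_table=freq)
        assert rate_uncapped > 0 and rate_capped == 0.0


@pytest.fixture()
def case_setup():
    """49-case cohort with four variants exercising each cascade stage."""
    variants = [
        Variant("chr1", 10, "A", "T"),  # survives everything
        Variant("chr1", 20, "C", "A"),  # not deleterious
        Variant("chr1", 30, "G", "A"),  # only 2 cases
        Variant("chr1", 40, "T", "C"),  # deleterious+recurrent but common in EUR
    ]
    carriers = [[0, 1, 2, 3], [0, 1, 2], [0, 1], [4, 5, 6]]
    case_panel = cohort(variants, carriers, 49, label="CASE")
    calls = {
        v.key: call_for(v, f"G{i+1}", term="missense", impact="moderate")
        for i, v in enumerate(variants)
    }
    deleterious = {
        variants[0].key: True,
        variants[1].key: False,
        variants[2].key: True,
        variants[3].key: True,
    }
    # EUR panel: variant 4 common (MAF 0.02), others absent/rare
    eur = CohortPanel(
        variants=variants,
        samples=[f"E{j}" for j in range(100)],
        genotypes=np.vstack(
            [
                np.zeros(100),
                np.zeros(100),
                np.zeros(100),
                np.r_[np.ones(4), np.zeros(96)],
            ]
        ),
        label="EUR",
    )
    freq_tables = {"EUR": frequency_table(eur), "CASEFREQ": frequency_table(case_panel)}
    return case_panel, calls, deleterious, freq_tables


class TestScreenCases:
    def test_cascade_stage_attribution(self, case_setup):
        case_panel, calls, deleterious, tables = case_setup
        report = screen_cases(
            case_panel, calls, deleterious, tables,
            ScreenConfig(min_cases=3, freq_source=("EUR",)),
        )
        assert report.removed_by_stage == {
            "deleterious": 1, "recurrence": 1, "rarity": 1
        }
        assert report.n_variants_out == 1
        assert report.surviving[0]["pos"] == 10
        assert report.n_genes_out == 1

    def test_unknown_freq_source_rejected(self, case_setup):
        case_panel, calls, deleterious, tables = case_setup
        with pytest.raises(ConfigError):
            screen_cases(case_panel, calls, deleterious, tables,
                         ScreenConfig(freq_source=("NOPE",)))

    def test_survivor_set_order_invariant(self, case_setup):
        """The surviving set equals the brute-force intersection of the three
        predicates, regardless of cascade attribution order."""
        case_panel, calls, deleterious, tables = case_setup
        from exopop.popfreq import mmaf_lookup, rarity_class

        report = screen_cases(
            case_panel, calls, deleterious, tables,
            ScreenConfig(min_cases=3, freq_source=("EUR",)),
        )
        expected = set()
        n_cases = (case_panel.genotypes >= 1).sum(axis=1)
        for i, v in enumerate(case_panel.variants):
            if (
                deleterious.get(v.key, False)
                and n_cases[i] >= 3
                and rarity_class(mmaf_lookup(v.key, tables, ["EUR"]))
                == "very_rare"
            ):
                expected.add(v.key)
        got = {
            (r["chrom"], r["pos"], r["ref"], r["alt"]) for r in report.surviving
        }
        assert got == expected

    def test_planted_screen_recovery(self, small_dataset):
        """Survivors on synthetic data match an independent truth predicate."""
        from exopop.consequence import classify_consequence
        from exopop.popfreq import mmaf_lookup, rarity_class

        ds = small_dataset
        calls = {}
        truth = ds.truth_variants
        for row in truth[truth.term != ""].itertuples(index=False):
            v = Variant(row.chrom, int(row.pos), row.ref, row.alt)
            calls[v.key] = classify_consequence(v, ds.index)
        tables = {l: frequency_table(p) for l, p in ds.panels.items()}
        sources = tuple(ds.config.reference_labels)
        cfg = ScreenConfig(min_cases=3, freq_source=sources)
        report = screen_cases(ds.case_panel, calls, ds.deleterious, tables, cfg)
        n_cases = (ds.case_panel.genotypes >= 1).sum(axis=1)
        expected = set()
        for i, v in enumerate(ds.case_panel.variants):
            if (
                ds.deleterious.get(v.key, False)
                and n_cases[i] >= 3
                and rarity_class(mmaf_lookup(v.key, tables, list(sources)))
                == "very_rare"
            ):
                expected.add(v.key)
        got = {(r["chrom"], r["pos"], r["ref"], r["alt"])
               for r in report.surviving}
        assert got == expected

    def test_adding_focal_panel_never_increases_survivors(self, small_dataset):
        ds = small_dataset
        tables = {l: frequency_table(p) for l, p in ds.panels.items()}
        refs = ds.config.reference_labels
        cfg = ScreenConfig(min_cases=2, freq_source=tuple(refs))
        rep_refs = screen_cases(ds.case_panel, {}, ds.deleterious, tables, cfg)
        cfg_all = ScreenConfig(
            min_cases=2, freq_source=tuple(refs + [ds.focal_label])
        )
        rep_all = screen_cases(ds.case_panel, {}, ds.deleterious, tables, cfg_all)
        assert rep_all.n_variants_out <= rep_refs.n_variants_out


class TestReduction:
    def test_printed_survivor_counts_give_36_percent(self):
        red = reduction_from_counts(157, 100)
        assert red.n_removed_extra == 57
        assert red.percent_reduction_int == 36

    def test_additional_filtering_count(self):
        red = reduction_from_counts(189, 120)
        assert red.n_removed_extra == 69

    def test_identical_reports_zero_percent(self, case_setup):
        case_panel, calls, deleterious, tables = case_setup
        cfg = ScreenConfig(min_cases=3, freq_source=("EUR",))
        rep = screen_cases(case_panel, calls, deleterious, tables, cfg)
        red = reduction_stats(rep, rep)
        assert red.n_removed_extra == 0 and red.percent_reduction == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            reduction_from_counts(0, 0)

    def test_non_nested_sources_rejected(self, case_setup):
        case_panel, calls, deleterious, tables = case_setup
        a = screen_cases(case_panel, calls, deleterious, tables,
                         ScreenConfig(min_cases=3, freq_source=("EUR",)))
        b = screen_cases(case_panel, calls, deleterious, tables,
                         ScreenConfig(min_cases=3, freq_source=("CASEFREQ",)))
        with pytest.raises(ValueError):
            reduction_stats(a, b)


class TestCompareFreqSources:
    def test_single_source_equals_screen_cases(self, case_setup):
        case_panel, calls, deleterious, tables = case_setup
        cfg = ScreenConfig(min_cases=3, freq_source=("EUR",))
        direct = screen_cases(case_panel, calls, deleterious, tables, cfg)
        rows = compare_freq_sources(case_panel, calls, deleterious, tables,
                                    {"only": ["EUR"]}, cfg)
        assert len(rows) == 1
        assert rows[0][1].to_dict() == direct.to_dict()

    def test_noop_panel_leaves_survivors_unchanged(self, case_setup):
        case_panel, calls, deleterious, tables = case_setup
        # a panel in which every case variant is absent adds nothing
        tables = dict(tables)
        tables["EMPTY"] = {}
        rows = dict(
            compare_freq_sources(
                case_panel, calls, deleterious, tables,
                {"a": ["EUR"], "b": ["EUR", "EMPTY"]},
                ScreenConfig(min_cases=3, freq_source=("EUR",)),
            )
        )
        assert rows["a"].n_variants_out == rows["b"].n_variants_out


def test_gene_panel_from_file(tmp_path):
    p = tmp_path / "panel.txt"
    p.write_text("# comment\nBRCA2\nAPC\n\nMSH6\n")
    gp = GenePanel.from_file(p)
    assert gp.gene_ids == frozenset({"BRCA2", "APC", "MSH6"})
    with pytest.raises(ValueError):
        GenePanel("empty", frozenset())


def test_screen_report_invariant():
    with pytest.raises(ValueError):
        ScreenReport(
            config=ScreenConfig(freq_source=("EUR",)),
            n_variants_in=10,
            n_variants_out=5,
            n_genes_out=2,
            removed_by_stage={"deleterious": 3},
        )
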