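"""End-to-end pipeline orchestration and summary JSON.

``run_pipeline`` executes simulate (optional) -> QC -> consequence ->
population frequencies -> gene prioritization -> cohort screens from a
single YAML configuration, writing every module report plus one summary
JSON holding all headline statistics.  Two runs with the same configuration
and seed produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from exopop import consequence as cq
from exopop import popfreq as pf
from exopop import prioritize as pz
from exopop import screen as sc
from exopop import simulate as sim
from exopop import vcfio
from exopop.errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full pipeline configuration; normally loaded from YAML."""

    outdir: str = "exopop_out"
    seed: int = 0
    simulate: dict[str, Any] | None = field(default_factory=dict)
    focal_label: str = "AJ"
    qc: dict[str, Any] = field(default_factory=dict)
    rarity: dict[str, float] = field(default_factory=dict)
    prioritize: dict[str, Any] = field(
        default_factory=lambda: {"max_percentile": 25.0, "min_count": 3,
                                 "mad_k": 5.0}
    )
    screen: dict[str, Any] = field(default_factory=dict)
    freq_sources: dict[str, list[str]] | None = None
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        """Fail fast on missing inputs before any compute."""
        if self.simulate is None:
            required = ("vcf_focal", "gff", "fasta", "rvis", "scores")
            missing = [k for k in required if k not in self.inputs]
            if missing:
                raise ConfigError(f"missing input paths: {missing}")
            for k, p in self.inputs.items():
                if not Path(p).exists():
                    raise ConfigError(f"input {k!r} does not exist: {p}")


def _round_pct(x: float) -> float:
    return round(x, 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return (and write) the summary dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate (optional) -------------------------------------------------
    if config.simulate is not None:
        sim_cfg_raw = dict(config.simulate)
        sim_cfg_raw.setdefault("seed", config.seed)
        sim_cfg = sim.SimulationConfig.from_dict(sim_cfg_raw)
        dataset = sim.simulate_dataset(sim_cfg)
        data_paths = sim.emit(dataset, out / "data")
        focal_label = dataset.focal_label
        panel_paths = {
            p.label: data_paths[f"vcf_{p.label}"] for p in sim_cfg.populations
        }
        case_path = data_paths["vcf_CASE"]
        gff_path, fasta_path = data_paths["gff"], data_paths["fasta"]
        rvis_path, scores_path = data_paths["rvis"], data_paths["scores"]
        gene_panel_paths = {
            name: data_paths[f"panel_{name}"] for name in dataset.gene_panels
        }
    else:
        focal_label = config.focal_label
        panel_paths = {
            k.removeprefix("vcf_"): Path(v)
            for k, v in config.inputs.items()
            if k.startswith("vcf_") and k != "vcf_cases"
        }
        case_path = (
            Path(config.inputs["vcf_cases"]) if "vcf_cases" in config.inputs
            else None
        )
        gff_path = Path(config.inputs["gff"])
        fasta_path = Path(config.inputs["fasta"])
        rvis_path = Path(config.inputs["rvis"])
        scores_path = Path(config.inputs["scores"])
        gene_panel_paths = {
            k.removeprefix("panel_"): Path(v)
            for k, v in config.inputs.items()
            if k.startswith("panel_")
        }
    if focal_label not in panel_paths:
        raise ConfigError(f"focal panel {focal_label!r} not among inputs")

    # --- QC ------------------------------------------------------------------
    qc_cfg = vcfio.QCConfig(**config.qc)
    region = (
        vcfio.TargetRegionSet.from_bed(config.inputs["bed"])
        if "bed" in config.inputs
        else None
    )
    panels: dict[str, vcfio.CohortPanel] = {}
    qc_summary: dict[str, dict] = {}
    for label in sorted(panel_paths):
        raw = vcfio.read_variants(panel_paths[label], region=region, label=label)
        panel, counts = vcfio.apply_qc(raw, qc_cfg)
        vcfio.write_qc_report(counts, out / f"qc_{label}.tsv")
        panels[label] = panel
        qc_summary[label] = {
            "n_in": raw.n_variants,
            "n_out": panel.n_variants,
            "removed": dict(counts),
        }
    focal = panels[focal_label]
    reference_labels = sorted(l for l in panels if l != focal_label)

    # --- consequence ---------------------------------------------------------
    index = cq.build_transcript_index(gff_path, fasta_path)
    calls: dict[tuple, cq.ConsequenceCall] = {}
    for v in focal.variants:
        call = cq.classify_consequence(v, index)
        if call is not None:
            calls[v.key] = call
    cq.write_consequence_table(calls.values(), out / "consequences.tsv")
    impact_counts = cq.summarize_impacts(calls.values())

    # --- population frequencies ---------------------------------------------
    freq_tables = {label: pf.frequency_table(p) for label, p in panels.items()}
    pf.write_frequency_table(
        [r for label in sorted(panels) for r in freq_tables[label].values()],
        out / "frequencies.tsv",
    )
    focal_keys = {v.key for i, v in enumerate(focal.variants)
                  if freq_tables[focal_label][v.key].ac > 0}
    overlap = {}
    for label in reference_labels:
        ref_keys = {k for k, r in freq_tables[label].items() if r.ac > 0}
        st = pf.overlap_fraction(focal_keys, ref_keys, focal_label, label)
        overlap[label] = {
            "n_focal": st.n_focal,
            "n_shared": st.n_shared,
            "fraction_shared": round(st.fraction_shared, 4),
        }
    n_singletons = sum(
        1 for k in focal_keys if pf.is_singleton(freq_tables[focal_label][k])
    )

    specific_keys = []
    for v in focal.variants:
        frec = freq_tables[focal_label][v.key]
        if frec.absent or frec.ac == 0:
            continue
        ref_mafs = []
        for label in reference_labels:
            rec = freq_tables[label].get(v.key)
            ref_mafs.append(None if rec is None or rec.absent or rec.ac == 0
                            else rec.maf)
        if pf.population_specific(frec.maf, ref_mafs):
            specific_keys.append(v.key)
    n_observed = len(focal_keys)
    specific_summary = {
        "n": len(specific_keys),
        "share_percent": _round_pct(100.0 * len(specific_keys) / n_observed),
    }

    sources = config.freq_sources or {
        "references": reference_labels,
        "all_panels": reference_labels + [focal_label],
    }
    hm_keys = [k for k, c in calls.items() if c.impact in ("high", "moderate")]
    rarity_summary = {}
    for name in sorted(sources):
        mafs = [pf.mmaf_lookup(k, freq_tables, sources[name]) for k in hm_keys]
        dist = pf.rarity_distribution(mafs)
        rarity_summary[name] = {c: _round_pct(100.0 * f) for c, f in dist.items()}

    # --- prioritization ------------------------------------------------------
    scores, deleterious = pz.read_scores(scores_path)
    rvis = pz.read_rvis(rvis_path)
    burdens, skipped = pz.burden_by_gene(
        specific_keys,
        calls,
        impact_filter={"high", "moderate"},
        deleterious=deleterious,
        gene_lengths=index.gene_lengths(),
        rvis=rvis,
    )
    pr = config.prioritize
    kept, outliers = pz.filter_outlier_genes(
        burdens, mad_k=pr.get("mad_k", 5.0),
        blacklist=set(pr.get("blacklist", [])),
    )
    try:
        corr = round(pz.length_correlation(kept), 3)
    except ValueError:
        corr = None
    top = pz.rvis_prioritize(
        kept, rvis, max_percentile=pr.get("max_percentile", 25.0),
        min_count=pr.get("min_count", 3),
    )
    del_genes, del_hist = pz.deleterious_burden(
        burdens, min_count=pr.get("deleterious_min_count", 3)
    )
    pz.write_burden_table(burdens, out / "burden.tsv")
    burden_summary = {
        "n_genes": len(burdens),
        "n_variants_skipped": skipped,
        "outliers_removed": dict(sorted(outliers.items())),
        "length_correlation": corr,
        "prioritized": [
            {"gene": b.gene_id, "n_specific": b.n_specific,
             "rvis_percentile": b.rvis_percentile}
            for b in top
        ],
        "deleterious_histogram": {str(k): v for k, v in del_hist.items()},
        "deleterious_genes": [
            {"gene": b.gene_id, "n_deleterious": b.n_deleterious}
            for b in del_genes
        ],
    }

    # --- screens -------------------------------------------------------------
    incidental_summary = {}
    inc_max_maf = config.screen.get("incidental_max_maf", 0.01)
    for name in sorted(gene_panel_paths):
        gp = sc.GenePanel.from_file(gene_panel_paths[name], name=name)
        findings, rate = sc.screen_incidental(
            focal, calls, gp,
            max_maf=inc_max_maf, freq_table=freq_tables[focal_label],
        )
        incidental_summary[name] = {
            "n_findings": len(findings),
            "rate_percent": rate,
        }

    screen_summary: dict[str, dict] = {}
    reduction_summary = None
    if case_path is not None:
        case_raw = vcfio.read_variants(case_path, region=region, label="CASE")
        case_panel, _ = vcfio.apply_qc(case_raw, qc_cfg)
        screen_cfg = sc.ScreenConfig(
            min_cases=config.screen.get("min_cases", 3),
            rarity_required=config.screen.get("rarity_required", "very_rare"),
            freq_source=tuple(sources[sorted(sources)[0]]),
            require_deleterious=config.screen.get("require_deleterious", True),
        )
        reports = sc.compare_freq_sources(
            case_panel, calls, deleterious, freq_tables, sources, screen_cfg
        )
        for name, rep in reports:
            rep.write_json(out / f"screen_{name}.json")
            screen_summary[name] = {
                "n_variants_in": rep.n_variants_in,
                "n_variants_out": rep.n_variants_out,
                "n_genes_out": rep.n_genes_out,
                "removed_by_stage": dict(rep.removed_by_stage),
            }
        by_name = dict(reports)
        names = sorted(sources, key=lambda n: len(sources[n]))
        small, large = names[0], names[-1]
        if set(sources[small]) <= set(sources[large]) and small != large:
            try:
                red = sc.reduction_stats(by_name[small], by_name[large])
                reduction_summary = {
                    "from": small,
                    "to": large,
                    "n_removed_extra": red.n_removed_extra,
                    "percent_reduction": red.percent_reduction,
                    "percent_reduction_int": red.percent_reduction_int,
                }
            except ValueError:
                reduction_summary = None

    summary = {
        "seed": config.seed,
        "focal_label": focal_label,
        "qc": qc_summary,
        "impact_counts": impact_counts,
        "n_singletons": n_singletons,
        "overlap": overlap,
        "specific_variants": specific_summary,
        "rarity": rarity_summary,
        "burden": burden_summary,
        "incidental": incidental_summary,
        "screen": screen_summary,
        "reduction": reduction_summary,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
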