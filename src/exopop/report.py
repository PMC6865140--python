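"""Summary-JSON validation and human-readable report rendering."""

from __future__ import annotations

import json
from pathlib import Path

# required top-level keys and their expected container types
_SCHEMA: dict[str, type | tuple[type, ...]] = {
    "seed": int,
    "focal_label": str,
    "qc": dict,
    "impact_counts": dict,
    "n_singletons": int,
    "overlap": dict,
    "specific_variants": dict,
    "rarity": dict,
    "burden": dict,
    "incidental": dict,
    "screen": dict,
    "reduction": (dict, type(None)),
}


def validate_summary(summary: dict) -> None:
    """Structural validation of a pipeline summary; raises ValueError."""
    if not isinstance(summary, dict):
        raise ValueError("summary must be a JSON object")
    for key, typ in _SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary key {key!r} has wrong type")
    for cls in ("high", "moderate", "low"):
        if cls not in summary["impact_counts"]:
            raise ValueError(f"impact_counts missing class {cls!r}")


def _table(headers: list[str], rows: list[list]) -> str:
    lines = ["| " + " | ".join(headers) + " |",
             "|" + "|".join("---" for _ in headers) + "|"]
    for row in rows:
        lines.append("| " + " | ".join(str(c) for c in row) + " |")
    return "\n".join(lines)


def render_report(summary_json: str | Path) -> str:
    """Render a pipeline summary as a markdown report with tables for
    cross-population overlap, the gene-burden results, per-source rarity
    distributions and the screen reductions."""
    summary = json.loads(Path(summary_json).read_text())
    validate_summary(summary)
    parts: list[str] = [f"# Exome analysis report (focal: {summary['focal_label']})"]

    ic = summary["impact_counts"]
    parts.append("## Impact classes\n" + _table(
        ["high", "(splice_site)", "moderate", "low"],
        [[ic["high"], ic.get("splice_site", 0), ic["moderate"], ic["low"]]],
    ))

    if summary["overlap"]:
        parts.append("## Cross-population overlap\n" + _table(
            ["reference", "n_focal", "n_shared", "fraction_shared"],
            [
                [lab, d["n_focal"], d["n_shared"], d["fraction_shared"]]
                for lab, d in sorted(summary["overlap"].items())
            ],
        ))

    sv = summary["specific_variants"]
    parts.append(
        f"## Population-specific variants\n\n{sv['n']} variants "
        f"({sv['share_percent']}% of observed focal variants)."
    )

    b = summary["burden"]
    if b.get("deleterious_histogram"):
        parts.append("## Deleterious burden histogram\n" + _table(
            ["n_deleterious_specific", "n_genes"],
            [[k, v] for k, v in sorted(
                b["deleterious_histogram"].items(), key=lambda kv: int(kv[0])
            )],
        ))
    if b.get("prioritized"):
        parts.append("## Intolerant genes with high burden\n" + _table(
            ["gene", "n_specific", "rvis_percentile"],
            [[g["gene"], g["n_specific"], g["rvis_percentile"]]
             for g in b["prioritized"]],
        ))
    if b.get("length_correlation") is not None:
        parts.append(
            f"Burden vs gene length Pearson r = {b['length_correlation']}."
        )

    if summary["rarity"]:
        classes = ["very_rare", "rare", "common"]
        parts.append("## Rarity distributions (percent, by MMAF source)\n" + _table(
            ["source"] + classes,
            [[name] + [d[c] for c in classes]
             for name, d in sorted(summary["rarity"].items())],
        ))

    if summary["incidental"]:
        parts.append("## Incidental-finding screens\n" + _table(
            ["gene panel", "n_findings", "rate_percent"],
            [[n, d["n_findings"], d["rate_percent"]]
             for n, d in sorted(summary["incidental"].items())],
        ))

    if summary["screen"]:
        parts.append("## Case-cohort screens\n" + _table(
            ["source", "in", "out", "genes", "removed_by_stage"],
            [
                [n, d["n_variants_in"], d["n_variants_out"], d["n_genes_out"],
                 json.dumps(d["removed_by_stage"], sort_keys=True)]
                for n, d in sorted(summary["screen"].items())
            ],
        ))
    red = summary["reduction"]
    if red:
        parts.append(
            f"Adding the focal panel ({red['from']} -> {red['to']}) removed "
            f"{red['n_removed_extra']} additional variants: "
            f"{red['percent_reduction']}% ({red['percent_reduction_int']}%) "
            "reduction."
        )
    return "\n\n".join(parts) + "\n"
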