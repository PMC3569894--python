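"""Human-readable markdown report of a tiered search run."""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence


def _tier_table(tier: Mapping) -> List[str]:
    lines = [
        "| rank | candidate | Cscore | Dscore | Combiscore | selected |",
        "|---:|---|---:|---:|---:|:---:|",
    ]
    selected = set(tier["selected"])
    for rank, row in enumerate(tier["scores"], start=1):
        mark = "yes" if row["owner"] in selected else ""
        lines.append(
            f"| {rank} | {row['owner']} | {row['cscore']:.9f} | "
            f"{row['dscore']:.9f} | {row['combiscore']:.9f} | {mark} |"
        )
    return lines


def render_report(
    tiers: Mapping,
    enrichment: Optional[Mapping[str, Sequence[Mapping]]] = None,
    manifest: Optional[Mapping] = None,
) -> str:
    """Render tiers.json-shaped data as a ranked markdown report.

    Mirrors the published presentation: one descending-Combiscore table per
    tier with the mean-derived threshold annotated, a selection tree, and
    (optionally) per-candidate pathway-enrichment summaries.
    """
    lines: List[str] = ["# Combination ranking report", ""]
    if manifest:
        lines += [
            f"- run digest: `{manifest.get('manifest_digest', 'n/a')}`",
            f"- seed: {manifest.get('seed', 'n/a')}",
            "",
        ]

    any_selected = False
    for tier in tiers.get("tiers", []):
        name = tier["tier"]
        lines.append(f"## Tier: {name}s")
        if not tier["scores"]:
            lines += ["", "_No candidates scored in this tier._", ""]
            continue
        lines += [
            "",
            f"- candidates scored: {tier['n_scored']}",
            f"- mean Combiscore: {tier['mean_combiscore']:.9f}",
            f"- selection threshold (inclusive >=): {tier['threshold']:.9f}",
            "",
        ]
        lines += _tier_table(tier)
        lines.append("")
        if tier["selected"]:
            any_selected = True
            lines.append("Selected (seed the next tier):")
            lines += [f"- {owner}" for owner in tier["selected"]]
        else:
            lines.append("_No candidates reached the threshold in this tier._")
        lines.append("")

    if not any_selected:
        lines += ["## No candidates selected", "",
                  "No tier produced candidates at or above its threshold.", ""]

    if enrichment:
        lines += ["## Pathway overrepresentation (top 3 per candidate)", ""]
        for owner in sorted(enrichment):
            rows = enrichment[owner]
            lines.append(f"### {owner}")
            if not rows:
                lines += ["", "_No pathways tested._", ""]
                continue
            lines += [
                "",
                "| pathway | overlap k | pathway size K | p | BH-adjusted p |",
                "|---|---:|---:|---:|---:|",
            ]
            for row in rows[:3]:
                lines.append(
                    f"| {row['pathway_id']} | {row['k']} | {row['K']} | "
                    f"{row['p_value']:.3g} | {row['adjusted_p']:.3g} |"
                )
            lines.append("")
    return "\n".join(lines) + "\n"
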