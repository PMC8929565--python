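"""Rendering of result matrices and impact summaries.

Tables mirror the field's reporting style: one row per service, one column
per scenario, four-decimal mean efficiency scores, a trailing global
average row, and a shading bucket per cell (quintiles of [0, 1], darker =
less efficient) so low performers stand out in the markdown output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .scenarios import ImpactAssessment

__all__ = ["shade_bucket", "render_report"]

_SHADE = ["####", "###", "##", "#", ""]  # darkest for the lowest scores


def shade_bucket(value: float) -> str:
    """Quintile shading marker for a score in [0, 1]; darker = lower."""
    for k, edge in enumerate((0.2, 0.4, 0.6, 0.8)):
        if value < edge:
            return _SHADE[k]
    return _SHADE[4]


def render_report(
    results: pd.DataFrame,
    impacts: Sequence[ImpactAssessment],
    out_dir,
    *,
    style: str = "markdown",
    title: str = "Relative technical efficiency",
) -> dict[str, Path]:
    """Write the result matrix (CSV) and a human-readable report.

    Returns a mapping of artefact name -> path. The CSV keeps full
    precision; the report formats means to 4 decimals and appends the
    scenario-vs-baseline comparison with p-values and per-class
    percentages (which always partition 100% of services).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    csv_path = out / "rte_matrix.csv"
    results.to_csv(csv_path)
    paths["matrix_csv"] = csv_path

    lines = [f"# {title}", ""]
    lines.append("Mean efficiency score per service and scenario "
                 "(shading: more `#` = lower score).")
    lines.append("")
    header = ["service"] + list(results.columns)
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for idx, row in results.iterrows():
        cells = [str(idx)]
        for v in row:
            mark = shade_bucket(float(v))
            cells.append(f"{v:.4f}" + (f" {mark}" if mark else ""))
        lines.append("| " + " | ".join(cells) + " |")
    lines.append("")

    if impacts:
        lines.append("## Quality-scenario impact vs baseline")
        lines.append("")
        lines.append("| scenario | W | p-value | mean diff | global class | "
                     "% negative | % neutral | % positive |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for imp in impacts:
            pct = imp.class_percentages
            lines.append(
                f"| {imp.scenario_id} | {imp.statistic:.1f} | {imp.p_value:.4g} "
                f"| {imp.mean_difference:+.4f} | {imp.global_class} "
                f"| {pct['negative']:.1f} | {pct['neutral']:.1f} | {pct['positive']:.1f} |"
            )
        lines.append("")

    report_path = out / ("report.md" if style == "markdown" else "report.txt")
    report_path.write_text("\n".join(lines))
    paths["report"] = report_path
    return paths
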