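"""Individual report generation: drug index, per-drug sections, summary table.

The report mirrors a pharmacist-facing layout: an index of affected drugs
(each a working intra-document link to its section), one section per drug
with the DrugBank-style description followed by the sample's matched
variant rows, and a flat summary table.  Drugs carrying at least one
FDA-pharmacogenomic-biomarker-labeled match are highlighted in the index.
Output formats are HTML and Markdown; rendering is deterministic, so
identical inputs yield byte-identical files.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import MatchedAnnotation
from .knowledgebase import DrugRecord, KnowledgeBase

__all__ = ["IndividualReport", "build_report", "render_report"]

SUMMARY_COLUMNS = ("SNP ID", "evidence level", "gene", "genotype",
                   "aspect", "direction", "description")
WIDE_COLUMNS = ("SNP ID", "evidence level", "gene", "genotype",
                "efficacy", "dosage", "toxicity", "description")

FDA_MARKER = "★ FDA biomarker"


@dataclass
class IndividualReport:
    """Assembled per-sample report contents, ready for rendering."""

    sample_id: str
    drug_index: list[str]
    sections: dict[str, tuple[DrugRecord | None, list[MatchedAnnotation]]]
    summary_table: list[MatchedAnnotation]
    fda_flags: set[str] = field(default_factory=set)


def _section_sort_key(m: MatchedAnnotation):
    return (m.annotation.evidence.rank, m.annotation.rsid, m.annotation.aspect)


def build_report(matches: list[MatchedAnnotation], kb: KnowledgeBase) -> IndividualReport:
    """Assemble an :class:`IndividualReport` from one sample's matches.

    The drug index is the sorted set of matched drug names; every match
    appears in exactly one section (its drug's) and exactly once in the
    summary table.  Raises ``ValueError`` if matches span several samples.
    """
    sample_ids = {m.sample_id for m in matches}
    if len(sample_ids) > 1:
        raise ValueError(f"matches span multiple samples: {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids), "")

    drug_index = sorted({m.annotation.drug_name for m in matches})
    sections = {}
    for drug in drug_index:
        rows = sorted(
            (m for m in matches if m.annotation.drug_name == drug),
            key=_section_sort_key,
        )
        sections[drug] = (kb.drugs.get(drug), rows)

    summary = [m for drug in drug_index for m in sections[drug][1]]
    fda_flags = {m.annotation.drug_name for m in matches if m.annotation.fda_labeled}
    return IndividualReport(
        sample_id=sample_id,
        drug_index=drug_index,
        sections=sections,
        summary_table=summary,
        fda_flags=fda_flags,
    )


def _anchor(drug: str) -> str:
    return "drug-" + "".join(c if c.isalnum() else "-" for c in drug.lower())


def _row_cells(m: MatchedAnnotation, wide: bool) -> list[str]:
    a = m.annotation
    if not wide:
        return [a.rsid, a.evidence.code, a.gene_symbol, a.genotype,
                a.aspect, a.direction, a.description]
    aspect_cells = {asp: "" for asp in ("efficacy", "dosage", "toxicity")}
    aspect_cells[a.aspect] = a.direction
    return [a.rsid, a.evidence.code, a.gene_symbol, a.genotype,
            aspect_cells["efficacy"], aspect_cells["dosage"],
            aspect_cells["toxicity"], a.description]


def render_report(
    report: IndividualReport,
    fmt: str,
    out: str | Path,
    wide: bool = False,
    index_by: str = "drug",
) -> None:
    """Render a report to HTML or Markdown at ``out``.

    ``wide=True`` switches the summary table to sparse efficacy/dosage/
    toxicity columns; ``index_by="category"`` groups the index by drug
    functional category instead of listing drug names flat.
    """
    if fmt == "html":
        text = _render_html(report, wide, index_by)
    elif fmt == "markdown":
        text = _render_markdown(report, wide, index_by)
    else:
        raise ValueError(f"unknown report format {fmt!r}; use html or markdown")
    Path(out).write_text(text, encoding="utf-8")


def _index_entries(report: IndividualReport, index_by: str):
    """Yield (heading_or_None, drug) pairs for the report index."""
    if index_by == "drug":
        for drug in report.drug_index:
            yield None, drug
        return
    by_cat: dict[str, list[str]] = {}
    for drug in report.drug_index:
        record = report.sections[drug][0]
        cats = record.categories if record and record.categories else ("Uncategorized",)
        for cat in cats:
            by_cat.setdefault(cat, []).append(drug)
    for cat in sorted(by_cat):
        for drug in by_cat[cat]:
            yield cat, drug


def _render_markdown(report: IndividualReport, wide: bool, index_by: str) -> str:
    cols = WIDE_COLUMNS if wide else SUMMARY_COLUMNS
    lines = [f"# Pharmacogenomics report — {report.sample_id}", ""]
    if not report.drug_index:
        lines += ["No drug-response findings: no genotype matched the knowledge base.", ""]
        return "\n".join(lines)

    lines += ["## Drug index", ""]
    last_cat = object()
    for cat, drug in _index_entries(report, index_by):
        if cat is not None and cat != last_cat:
            lines.append(f"- **{cat}**")
            last_cat = cat
        marker = f" ({FDA_MARKER})" if drug in report.fda_flags else ""
        prefix = "  - " if cat is not None else "- "
        lines.append(f"{prefix}[{drug}](#{_anchor(drug)}){marker}")
    lines.append("")

    for drug in report.drug_index:
        record, rows = report.sections[drug]
        lines += [f'## {drug} <a id="{_anchor(drug)}"></a>', ""]
        if drug in report.fda_flags:
            lines += [f"*{FDA_MARKER}: this drug carries FDA pharmacogenomic "
                      f"biomarker labeling relevant to this sample.*", ""]
        if record and record.description:
            lines += [record.description, ""]
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "|".join(["---"] * len(cols)) + "|")
        for m in rows:
            lines.append("| " + " | ".join(_row_cells(m, wide)) + " |")
        lines.append("")

    lines += ["## Summary table", "",
              "| " + " | ".join(cols) + " |",
              "|" + "|".join(["---"] * len(cols)) + "|"]
    for m in report.summary_table:
        lines.append("| " + " | ".join(_row_cells(m, wide)) + " |")
    lines.append("")
    return "\n".join(lines)


def _render_html(report: IndividualReport, wide: bool, index_by: str) -> str:
    cols = WIDE_COLUMNS if wide else SUMMARY_COLUMNS
    e = _html.escape
    parts = [
        "<!DOCTYPE html>",
        '<html><head><meta charset="utf-8">',
        f"<title>Pharmacogenomics report — {e(report.sample_id)}</title>",
        "<style>table{border-collapse:collapse} td,th{border:1px solid #999;"
        "padding:4px 8px} .fda{background:#fff3bf}</style>",
        "</head><body>",
        f"<h1>Pharmacogenomics report — {e(report.sample_id)}</h1>",
    ]
    if not report.drug_index:
        parts += ["<p>No drug-response findings: no genotype matched the "
                  "knowledge base.</p>", "</body></html>", ""]
        return "\n".join(parts)

    parts += ["<h2>Drug index</h2>", "<ul>"]
    last_cat = object()
    cat_open = False
    for cat, drug in _index_entries(report, index_by):
        if cat is not None and cat != last_cat:
            if cat_open:
                parts.append("</ul></li>")
            parts.append(f"<li><strong>{e(cat)}</strong><ul>")
            last_cat, cat_open = cat, True
        marker = f' <span class="fda">{e(FDA_MARKER)}</span>' if drug in report.fda_flags else ""
        parts.append(f'<li><a href="#{_anchor(drug)}">{e(drug)}</a>{marker}</li>')
    if cat_open:
        parts.append("</ul></li>")
    parts.append("</ul>")

    def table(rows: list[MatchedAnnotation], table_class: str) -> list[str]:
        out = [f'<table class="{table_class}"><thead><tr>']
        out += [f"<th>{e(c)}</th>" for c in cols]
        out.append("</tr></thead><tbody>")
        for m in rows:
            out.append("<tr>" + "".join(f"<td>{e(c)}</td>" for c in _row_cells(m, wide))
                       + "</tr>")
        out.append("</tbody></table>")
        return out

    for drug in report.drug_index:
        record, rows = report.sections[drug]
        parts.append(f'<h2 id="{_anchor(drug)}">{e(drug)}</h2>')
        if drug in report.fda_flags:
            parts.append(f'<p class="fda">{e(FDA_MARKER)}: this drug carries FDA '
                         "pharmacogenomic biomarker labeling relevant to this sample.</p>")
        if record and record.description:
            parts.append(f"<p>{e(record.description)}</p>")
        parts += table(rows, "section")

    parts.append("<h2>Summary table</h2>")
    parts += table(report.summary_table, "summary")
    parts += ["</body></html>", ""]
    return "\n".join(parts)
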