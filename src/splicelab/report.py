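"""Static HTML report and genome-browser URL templating.

The report collects each stage's TSV outputs into one HTML page with
client-side sortable tables; stages that did not run render a "not run"
placeholder. Feature rows can be decorated with genome-browser links
rendered from a URL template with ``{chrom}``, ``{start}``, ``{end}``
and ``{tracks}`` placeholders (coordinates appear 1-based inclusive in
URLs, matching browser conventions).
"""

from __future__ import annotations

import html
from pathlib import Path

import pandas as pd

REQUIRED_PLACEHOLDERS = ("{chrom}", "{start}", "{end}", "{tracks}")

_SORT_JS = """
function sortTable(table, col) {
  const rows = Array.from(table.tBodies[0].rows);
  const dir = table.dataset.dir === 'asc' ? -1 : 1;
  table.dataset.dir = dir === 1 ? 'asc' : 'desc';
  rows.sort((a, b) => {
    const x = a.cells[col].innerText, y = b.cells[col].innerText;
    const nx = parseFloat(x), ny = parseFloat(y);
    if (!isNaN(nx) && !isNaN(ny)) return dir * (nx - ny);
    return dir * x.localeCompare(y);
  });
  rows.forEach(r => table.tBodies[0].appendChild(r));
}
document.querySelectorAll('th').forEach((th) => {
  th.style.cursor = 'pointer';
  th.addEventListener('click', () =>
    sortTable(th.closest('table'), th.cellIndex));
});
"""

SECTIONS = [
    ("junctions", "Junction counts", "junctions_counts.tsv"),
    ("exons", "Exon counts", "exons_counts.tsv"),
    ("anchors", "Anchor counts", "anchors_counts.tsv"),
    ("diff", "Differential usage and expression", "diff_*.tsv"),
    ("judge", "juDGE", "judge_*.tsv"),
    ("classes", "Donor site classes", "classes_*.tsv"),
    ("scanrbp", "RNA-maps", "rnamap_*.tsv"),
]

MAX_ROWS = 200


def browser_url(template: str, chrom: str, start: int, end: int,
                sample_ids: list[str]) -> str:
    """Render a genome-browser URL for a 0-based half-open interval.

    The interval appears in the URL as 1-based inclusive
    (``start + 1 .. end``); track names join with commas in input order.
    """
    missing = [p for p in REQUIRED_PLACEHOLDERS if p not in template]
    if missing:
        raise ValueError(f"URL template missing placeholders: {missing}")
    return template.format(chrom=chrom, start=start + 1, end=end,
                           tracks=",".join(sample_ids))


def _table_html(df: pd.DataFrame, url_template: str | None,
                sample_ids: list[str]) -> str:
    df = df.head(MAX_ROWS).copy()
    link_col = None
    id_col = "junction_id" if "junction_id" in df.columns else (
        "feature_id" if "feature_id" in df.columns else None)
    if url_template and id_col is not None:
        links = []
        for val in df[id_col].astype(str):
            try:
                chrom, span, _strand = val.rsplit(":", 2)
                s, e = span.split("-")
                links.append(browser_url(url_template, chrom, int(s), int(e),
                                         sample_ids))
            except ValueError:
                links.append("")
        df["browser"] = [f'<a href="{html.escape(u, quote=True)}">view</a>'
                         if u else "" for u in links]
        link_col = "browser"
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    body_rows = []
    for _, row in df.iterrows():
        cells = []
        for col, v in row.items():
            text = str(v) if col == link_col else html.escape(str(v))
            cells.append(f"<td>{text}</td>")
        body_rows.append("<tr>" + "".join(cells) + "</tr>")
    return (f"<table><thead><tr>{head}</tr></thead>"
            f"<tbody>{''.join(body_rows)}</tbody></table>")


def build_report(manifest: pd.DataFrame, out_dir: str | Path,
                 url_template: str | None = None,
                 sample_ids: list[str] | None = None) -> Path:
    """Write ``report.html`` summarizing every stage's TSV outputs."""
    out_dir = Path(out_dir)
    ran = set(manifest["stage"]) if len(manifest) else set()
    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'>",
             "<title>splicelab report</title>",
             "<style>body{font-family:sans-serif;margin:2em}"
             "table{border-collapse:collapse;font-size:12px}"
             "td,th{border:1px solid #ccc;padding:2px 6px}"
             "th{background:#eee}</style></head><body>",
             "<h1>splicelab report</h1>"]
    sample_ids = sample_ids or []
    for stage, title, pattern in SECTIONS:
        parts.append(f"<h2>{title}</h2>")
        if stage not in ran:
            parts.append("<p><em>not run</em></p>")
            continue
        files = sorted(out_dir.glob(pattern))
        if not files:
            parts.append("<p><em>not run</em></p>")
            continue
        for path in files:
            try:
                df = pd.read_csv(path, sep="\t", comment="#")
            except Exception:
                continue
            parts.append(f"<h3>{html.escape(path.name)}</h3>")
            parts.append(_table_html(df, url_template, sample_ids))
    images = sorted(out_dir.glob("*.png"))
    if images:
        parts.append("<h2>Plots</h2>")
        for img in images:
            parts.append(f"<figure><img src='{img.name}' width='480'>"
                         f"<figcaption>{html.escape(img.name)}</figcaption></figure>")
    parts.append(f"<script>{_SORT_JS}</script></body></html>")
    path = out_dir / "report.html"
    path.write_text("\n".join(parts))
    return path
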