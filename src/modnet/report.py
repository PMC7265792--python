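"""Minimal static HTML report with client-side searchable tables.

Stdlib string templating only; the report is a single self-contained page
linking the TSV artifacts and inlining each table with a per-table filter
box (vanilla JavaScript substring match on rows).
"""

from __future__ import annotations

import html
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 2em; }}
th, td {{ border: 1px solid #999; padding: 2px 8px; font-size: 13px; }}
th {{ background: #eee; }}
input.filter {{ margin: 4px 0; width: 24em; }}
</style>
<script>
function filterTable(inputId, tableId) {{
  var q = document.getElementById(inputId).value.toLowerCase();
  var rows = document.getElementById(tableId).tBodies[0].rows;
  for (var i = 0; i < rows.length; i++) {{
    rows[i].style.display =
      rows[i].textContent.toLowerCase().indexOf(q) >= 0 ? "" : "none";
  }}
}}
</script>
</head>
<body>
<h1>{title}</h1>
{body}
</body>
</html>
"""


def _table_html(frame: pd.DataFrame, table_id: str, max_rows: int = 2000) -> str:
    shown = frame.head(max_rows)
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in shown.columns)
    body_rows = []
    for _, row in shown.iterrows():
        cells = "".join(f"<td>{html.escape(str(v))}</td>" for v in row)
        body_rows.append(f"<tr>{cells}</tr>")
    note = ""
    if len(frame) > max_rows:
        note = f"<p>(showing first {max_rows} of {len(frame)} rows)</p>"
    return (
        f'<input class="filter" id="f_{table_id}" placeholder="filter rows..." '
        f'onkeyup="filterTable(\'f_{table_id}\', \'{table_id}\')">\n'
        f'<table id="{table_id}"><thead><tr>{head}</tr></thead>'
        f"<tbody>{''.join(body_rows)}</tbody></table>{note}"
    )


def render_report(
    tables: Dict[str, pd.DataFrame],
    title: str = "Regulatory module network report",
    artifacts: Optional[Sequence[str]] = None,
) -> str:
    """Render section-per-table HTML; ``tables`` maps section title -> frame."""
    sections: List[str] = []
    if artifacts:
        links = "".join(
            f'<li><a href="{html.escape(a)}">{html.escape(a)}</a></li>' for a in artifacts
        )
        sections.append(f"<h2>Artifacts</h2><ul>{links}</ul>")
    for i, (name, frame) in enumerate(tables.items()):
        sections.append(f"<h2>{html.escape(name)}</h2>")
        if frame is None or not len(frame):
            sections.append("<p>(empty)</p>")
        else:
            sections.append(_table_html(frame, f"t{i}"))
    return _PAGE.format(title=html.escape(title), body="\n".join(sections))


def write_report(tables: Dict[str, pd.DataFrame], path, **kwargs) -> Path:
    path = Path(path)
    path.write_text(render_report(tables, **kwargs), encoding="utf-8")
    return path
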