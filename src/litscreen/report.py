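"""Serialization of triage results.

The canonical output is a flat table with one row per (candidate,
publication); candidates without publications still emit one row so the
spreadsheet accounts for every input.  TSV is the byte-stable canonical
format; XLSX renders the same rows, splitting into numbered sheets
before the Office Open XML limit of 1,048,576 rows per sheet is hit —
never truncating silently.
"""

from __future__ import annotations

import csv
import io
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .model import CategorizedCandidate, Category

#: Hard per-sheet row limit of the XLSX format (header included).
EXCEL_MAX_ROWS = 1_048_576

#: Column order of the report table (documented contract; stable).
REPORT_COLUMNS = [
    "candidate_id",
    "gene_name",
    "gene_synonyms",
    "protein_names",
    "taxon_id",
    "query",
    "backend",
    "category",
    "total_hits",
    "supermatch_count",
    "ambiguous_terms",
    "pub_id",
    "title",
    "pub_date",
    "is_review",
    "supermatch",
    "results_link",
]


def rows_for(cands: Sequence[CategorizedCandidate]) -> Iterator[tuple[str, ...]]:
    """Yield report rows: candidates sorted by category ascending then
    input order; one row per publication, or a single publication-empty
    row for candidates with no hits.  Missing values serialize as empty
    strings, dates as ISO-8601."""
    from .retrieve import is_review

    indexed = sorted(enumerate(cands), key=lambda t: (int(t[1].category), t[0]))
    for _, cc in indexed:
        cand, res = cc.candidate, cc.result
        base = (
            cand.input.raw_id,
            ";".join(cand.gene_names),
            ";".join(cand.gene_synonyms),
            ";".join(cand.protein_names),
            str(cand.input.taxon_id),
            res.query.expression,
            res.query.spec.backend.value,
            str(int(cc.category)),
            str(res.total_hits),
            str(cc.supermatch_count),
            ";".join(res.query.ambiguous_terms),
        )
        link = res.results_link or ""
        if not res.records:
            yield base + ("", "", "", "", "", link)
            continue
        for rec, flag in zip(res.records, cc.supermatch_flags):
            yield base + (
                rec.pub_id,
                rec.title,
                rec.pub_date.isoformat() if rec.pub_date else "",
                str(is_review(rec)).lower(),
                flag.value,
                link,
            )


# ---------------------------------------------------------------------------
# TSV


def write_tsv(rows: Iterable[Sequence[str]], path: str | Path) -> None:
    """Byte-identical across runs on identical input (deterministic
    column order, LF line endings, minimal quoting)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        writer.writerows(rows)


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    """Parse a written report back into row dicts (exact field-level
    round trip of :func:`write_tsv`)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return list(reader)


# ---------------------------------------------------------------------------
# XLSX


def write_xlsx(
    rows: Iterable[Sequence[str]],
    path: str | Path,
    row_limit: int = EXCEL_MAX_ROWS,
) -> list[int]:
    """Write rows into ``results``, ``results_2``, ... sheets, each
    holding at most ``row_limit`` rows including its header.

    Returns the per-sheet data-row counts.  Uses a streaming (write-only)
    workbook so row count is bounded by disk, not memory.
    """
    from openpyxl import Workbook

    if row_limit < 2:
        raise ValueError("row_limit must leave room for a header and one row")
    wb = Workbook(write_only=True)
    per_sheet = row_limit - 1  # header occupies one row
    counts: list[int] = []
    ws = None
    n_in_sheet = 0
    for row in rows:
        if ws is None or n_in_sheet >= per_sheet:
            sheet_no = len(counts) + 1
            ws = wb.create_sheet("results" if sheet_no == 1 else f"results_{sheet_no}")
            ws.append(REPORT_COLUMNS)
            counts.append(0)
            n_in_sheet = 0
        ws.append(list(row))
        n_in_sheet += 1
        counts[-1] = n_in_sheet
    if ws is None:
        ws = wb.create_sheet("results")
        ws.append(REPORT_COLUMNS)
        counts.append(0)
    wb.save(path)
    return counts


def xlsx_sheet_row_counts(path: str | Path) -> list[int]:
    """Rows per worksheet, counted by streaming the sheet XML straight
    from the archive (reading millions of rows through a spreadsheet
    library would be needlessly slow)."""
    counts = []
    with zipfile.ZipFile(path) as zf:
        sheet_names = sorted(
            n for n in zf.namelist()
            if n.startswith("xl/worksheets/sheet") and n.endswith(".xml")
        )
        for name in sheet_names:
            n_rows = 0
            with zf.open(name) as fh:
                tail = b""
                while True:
                    chunk = fh.read(1 << 20)
                    if not chunk:
                        break
                    buf = tail + chunk
                    n_rows += buf.count(b"<row")
                    tail = buf[-3:]  # a 4-byte match cannot be double-counted
            counts.append(n_rows)
    return counts


def write_report(
    cands: Sequence[CategorizedCandidate],
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Serialize categorized candidates to ``tsv`` or ``xlsx``."""
    rows = rows_for(cands)
    if fmt == "tsv":
        write_tsv(rows, path)
    elif fmt == "xlsx":
        write_xlsx(rows, path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'xlsx')")


# ---------------------------------------------------------------------------
# Summary pie charts

#: Category colour convention used in all summary figures.
CATEGORY_COLORS = {
    Category.REVIEW: "#E69F00",        # orange
    Category.PUBLICATION: "#F0E442",   # yellow
    Category.NO_PUBLICATION: "#0072B2",  # blue
    Category.INVALID: "#999999",       # grey
}


@dataclass(frozen=True)
class PieChart:
    """A rendered pie plus the wedge fractions read back from the
    drawn wedges (not from the input counts), so callers can check
    self-consistency."""

    path: Path
    wedge_fractions: dict[Category, float]


def plot_category_pies(
    summaries: dict[str, dict[Category, int]],
    out_dir: str | Path,
    fmt: str = "png",
) -> dict[str, PieChart]:
    """One pie per group; wedge sizes are category counts over the group
    total.  An all-zero group renders a 'no candidates' placeholder
    instead of crashing."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not summaries:
        raise ValueError("summaries must be non-empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    charts: dict[str, PieChart] = {}
    for group, counts in summaries.items():
        fig, ax = plt.subplots(figsize=(4, 4))
        total = sum(counts.get(c, 0) for c in Category)
        fractions: dict[Category, float] = {}
        if total == 0:
            ax.annotate("no candidates", (0.5, 0.5), ha="center", va="center")
            ax.set_axis_off()
        else:
            cats = [c for c in Category if counts.get(c, 0) > 0]
            wedges, _ = ax.pie(
                [counts[c] for c in cats],
                labels=[f"Category {int(c)}" for c in cats],
                colors=[CATEGORY_COLORS[c] for c in cats],
                startangle=90,
                counterclock=False,
            )
            for c, w in zip(cats, wedges):
                fractions[c] = abs(w.theta2 - w.theta1) / 360.0
        ax.set_title(group)
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in group)
        path = out / f"categories_{safe}.{fmt}"
        fig.savefig(path)
        plt.close(fig)
        charts[group] = PieChart(path=path, wedge_fractions=fractions)
    return charts
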