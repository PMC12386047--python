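"""Readers and writers for judgment data and result tables.

Judgment CSV schema (UTF-8, comma-separated, header required):
``coin_id,gender_group,context,participant_id,position_swapped,judged_fake_facet``
with context as C0-C3, facets as integers 0-3, position_swapped as
true/false.  Invalid rows are rejected with row-level diagnostics.

Results are written as a TSV mirroring the study's per-coin table (Coin,
p0..p3, Gender, Delta, CbD, Interval, Contextual) and a companion accuracy
summary TSV; numbers are rendered to 2 decimals for display only — full
precision is retained in memory.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Dict, Iterable, List, Sequence, Tuple, Union

import pandas as pd

from cbdcoin.datamodel import (
    ContextCounts,
    ContextLabel,
    ContextualityResult,
    JudgmentRecord,
    designated_outcome,
)

JUDGMENT_COLUMNS = (
    "coin_id",
    "gender_group",
    "context",
    "participant_id",
    "position_swapped",
    "judged_fake_facet",
)

Source = Union[str, Path, IO[str], IO[bytes]]


class SchemaError(ValueError):
    """Malformed input file: bad header or invalid rows."""


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean {x!r}")


def read_judgments(source: Source) -> List[JudgmentRecord]:
    """Read and validate a judgment CSV; any invalid row fails the read.

    Error messages carry 1-based data row numbers so malformed files can be
    fixed by hand.
    """
    df = pd.read_csv(source, dtype=str)
    missing = [c for c in JUDGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"judgment CSV missing column(s): {missing}")
    records: List[JudgmentRecord] = []
    problems: List[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                JudgmentRecord(
                    coin_id=int(row.coin_id),
                    gender_group=str(row.gender_group).strip(),
                    context=ContextLabel.from_string(str(row.context)),
                    participant_id=str(row.participant_id),
                    position_swapped=_parse_bool(row.position_swapped),
                    judged_fake_facet=int(row.judged_fake_facet),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {row_no}: {exc}")
    if problems:
        shown = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        raise SchemaError(f"{len(problems)} invalid row(s): {shown}{more}")
    return records


def write_judgments(records: Iterable[JudgmentRecord], sink: Source) -> None:
    _judgments_frame(list(records)).to_csv(sink, index=False)


def _judgments_frame(records: Sequence[JudgmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coin_id": [r.coin_id for r in records],
            "gender_group": [r.gender_group for r in records],
            "context": [r.context.label for r in records],
            "participant_id": [r.participant_id for r in records],
            "position_swapped": [r.position_swapped for r in records],
            "judged_fake_facet": [r.judged_fake_facet for r in records],
        },
        columns=list(JUDGMENT_COLUMNS),
    )


def tally(records: Iterable[JudgmentRecord]) -> List[ContextCounts]:
    """Per-(coin, context) tallies: n judgments, k matching the designated
    outcome.  Cells with no records are simply absent; downstream analysis
    treats missing cells as errors."""
    acc: Dict[Tuple[int, int], List[int]] = {}
    for r in records:
        key = (r.coin_id, r.context.index)
        cell = acc.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += r.judged_fake_facet == designated_outcome(r.context)
    return [
        ContextCounts(coin_id=coin, context=ContextLabel(ctx), n=n, k=k)
        for (coin, ctx), (n, k) in sorted(acc.items())
    ]


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def results_frame(results: Sequence[ContextualityResult]) -> pd.DataFrame:
    """Study-table-shaped frame (2-decimal display strings)."""
    rows = []
    for r in sorted(results, key=lambda r: r.coin_id):
        if r.marginals is None:
            raise ValueError(f"result for coin {r.coin_id} carries no marginals")
        rows.append(
            {
                "Coin": r.coin_id,
                "p0": _fmt(r.marginals[0]),
                "p1": _fmt(r.marginals[1]),
                "p2": _fmt(r.marginals[2]),
                "p3": _fmt(r.marginals[3]),
                "Gender": r.marginals.gender_group,
                "Delta": _fmt(r.delta),
                "CbD": _fmt(r.cbd_value),
                "Interval": f"[{_fmt(r.ci_lower)},{_fmt(r.ci_upper)}]",
                "Contextual": "yes" if r.contextual else "no",
                "BootSE": _fmt(r.boot_se) if r.boot_se is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Coin", "p0", "p1", "p2", "p3", "Gender",
            "Delta", "CbD", "Interval", "Contextual", "BootSE",
        ],
    )


def write_results(
    results: Sequence[ContextualityResult],
    summary: "pd.DataFrame | None",
    sink: Source,
    summary_sink: "Source | None" = None,
) -> None:
    """Write the per-coin results TSV and, optionally, the accuracy summary TSV."""
    results_frame(results).to_csv(sink, sep="\t", index=False)
    if summary is not None:
        if summary_sink is None:
            raise ValueError("summary provided but no summary_sink")
        summary.to_csv(summary_sink, sep="\t", index=False)


def read_marginals_table(source: Source) -> pd.DataFrame:
    """Read a marginals TSV/CSV with columns Coin, p0..p3, Gender and
    optional per-context count columns n0..n3."""
    text: "str | None" = None
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    required = ["Coin", "p0", "p1", "p2", "p3", "Gender"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"marginals table missing column(s): {missing}")
    return df
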