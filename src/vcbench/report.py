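"""Report formatting: metric tables, Venn tables, p-value printing.

Rounding follows the conventions of the benchmark tables this package
emulates: 3 decimals for recall/precision/Frac_NA/F1, 5 for the Ts/Tv
ratio, 4 for the missense/silent ratio.  Undefined metrics print as
``NA``.  p-values below 5e-4 print as ``0.000``; exact values are kept in
the JSON output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .benchmark import ConcordanceTable, DiscreteCounts
from .metrics import ContinuousMetrics

__all__ = [
    "fmt",
    "format_p",
    "metrics_row",
    "metrics_frame",
    "write_metrics",
    "venn_frame",
]

METRIC_COLUMNS = ["caller", "TP", "FP", "FN", "I", "NAC",
                  "Recall", "Precision", "Frac_NA", "F1_Score"]


def fmt(value: Optional[float], ndigits: int = 3) -> str:
    """Fixed-point string, or ``NA`` for an undefined metric."""
    return "NA" if value is None else f"{value:.{ndigits}f}"


def format_p(p: float) -> str:
    """p-values under 5e-4 print as 0.000, mirroring common table style."""
    return "0.000" if p < 5e-4 else f"{p:.3f}"


def metrics_row(name: str, counts: DiscreteCounts, cm: ContinuousMetrics) -> Dict[str, object]:
    """One caller's row in benchmark-table column order."""
    return {
        "caller": name,
        "TP": counts.tp,
        "FP": counts.fp,
        "FN": counts.fn,
        "I": counts.i,
        "NAC": counts.nac,
        "Recall": fmt(cm.recall),
        "Precision": fmt(cm.precision),
        "Frac_NA": fmt(cm.frac_na),
        "F1_Score": fmt(cm.f1),
    }


def metrics_frame(rows: Sequence[Mapping[str, object]]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=METRIC_COLUMNS)


def write_metrics(
    rows: Sequence[Mapping[str, object]],
    raw: Mapping[str, Mapping[str, object]],
    tsv_path,
    json_path,
) -> None:
    """Write the rounded TSV table and an unrounded JSON mirror."""
    metrics_frame(rows).to_csv(tsv_path, sep="\t", index=False)
    Path(json_path).write_text(json.dumps(raw, indent=2, sort_keys=True))


def venn_frame(table: ConcordanceTable) -> pd.DataFrame:
    """Exclusive Venn cells as a two-column table (cell, count)."""
    return pd.DataFrame(table.rows(), columns=["cell", "count"])
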