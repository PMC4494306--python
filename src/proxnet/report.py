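"""Cross-network comparison: densities, %positive and stability per group.

The summary row that lets groups (or species, or housing conditions) be
compared on one line: the density of the positive network, the density of
the negative network, their sum, the positive share of the total density in
percent, and the day-to-day stability index. All quantities are computed
unrounded and rounded only when rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .association import SignedAssociation
from .network import build_graph, density
from .stability import StabilitySeries

__all__ = ["ComparisonRow", "compare_networks", "render_report"]


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    positive_density: float
    negative_density: float
    total_density: float
    pct_positive: float
    stability: float

    def rounded(self, ndigits: int = 2) -> dict:
        return {
            "label": self.label,
            "positive": round(self.positive_density, ndigits),
            "negative": round(self.negative_density, ndigits),
            "total": round(self.total_density, ndigits),
            "pct_positive": round(self.pct_positive, ndigits),
            "stability": round(self.stability, ndigits) if not math.isnan(self.stability) else float("nan"),
        }


def compare_networks(entries) -> list:
    """One :class:`ComparisonRow` per ``(label, association, stability)`` entry.

    ``stability`` may be a :class:`~proxnet.stability.StabilitySeries`, a
    bare number (a pre-computed mean consecutive correlation), or None.
    Rows are computed independently, so their order follows the entries.
    """
    rows = []
    for label, assoc, stab in entries:
        if not isinstance(assoc, SignedAssociation):
            raise TypeError(f"entry {label!r}: expected a SignedAssociation")
        dpos = density(build_graph(assoc, "positive"))
        dneg = density(build_graph(assoc, "negative"))
        total = dpos + dneg
        pct = 100.0 * dpos / total if total > 0 else float("nan")
        if isinstance(stab, StabilitySeries):
            stab_val = stab.mean_consecutive_r
        elif stab is None:
            stab_val = float("nan")
        else:
            stab_val = float(stab)
        rows.append(ComparisonRow(label, dpos, dneg, total, pct, stab_val))
    return rows


def render_report(rows, csv_path, text_path=None, ndigits: int = 2) -> pd.DataFrame:
    """Write the comparison table as CSV (and optionally fixed-width text).

    Values are rounded to ``ndigits`` decimals at this point only. Returns
    the rendered DataFrame. An empty row list yields a header-only file.
    """
    cols = ["label", "positive", "negative", "total", "pct_positive", "stability"]
    table = pd.DataFrame([r.rounded(ndigits) for r in rows], columns=cols)
    table.to_csv(csv_path, index=False, float_format=f"%.{ndigits}f")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(table.to_string(index=False, float_format=lambda v: f"{v:.{ndigits}f}"))
            fh.write("\n")
    return table


def read_report(csv_path) -> pd.DataFrame:
    """Re-read a rendered comparison CSV (rendered precision only)."""
    return pd.read_csv(Path(csv_path))
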