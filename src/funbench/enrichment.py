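"""Bin-wise enrichment of predicted siblings.

Pairs are binned by sequence identity, TM-score or SNN score; for each bin a
method's predicted siblings are compared against the full pair universe with
a two-sided Fisher exact test, Benjamini-Hochberg adjusted across the bins
of one variable.  Significance glyphs: '+'/'-' for p in [0.001, 0.05],
'++'/'--' for p < 0.001, direction from the odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinScheme",
    "EnrichmentRow",
    "bin_pairs",
    "fisher_enrichment",
    "bh_adjust",
    "enrichment_table",
    "DEFAULT_SCHEMES",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class BinScheme:
    """Ordered bin edges over one pair variable.

    Bins are left-closed/right-open; the last bin is right-closed so the
    top of the range is covered.
    """

    variable: str  # 'seq_identity' | 'tm_score' | 'snn_score'
    edges: tuple

    def __post_init__(self):
        if len(self.edges) < 2:
            raise EnrichmentError("a bin scheme needs at least two edges")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise EnrichmentError(f"bin edges must be strictly increasing: {self.edges}")

    @property
    def labels(self) -> list:
        return [
            f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges, self.edges[1:])
        ]

    def assign(self, value: float) -> str:
        edges = self.edges
        if value < edges[0] or value > edges[-1]:
            raise EnrichmentError(
                f"{self.variable} value {value} outside binned range [{edges[0]}, {edges[-1]}]"
            )
        idx = int(np.searchsorted(edges, value, side="right")) - 1
        idx = min(idx, len(edges) - 2)  # top edge falls in the last bin
        return self.labels[idx]


#: bin layouts used throughout: identity in percent, scores in [0, 1]
DEFAULT_SCHEMES = {
    "seq_identity": BinScheme("seq_identity", (0.0, 40.0, 60.0, 80.0, 90.0)),
    "tm_score": BinScheme("tm_score", (0.0, 0.5, 0.7, 1.0)),
    "snn_score": BinScheme("snn_score", (0.0, 0.5, 0.98, 1.0)),
}


@dataclass(frozen=True)
class EnrichmentRow:
    bin: str
    in_bin_predicted: int
    predicted_total: int
    in_bin_universe: int
    universe_total: int
    odds_ratio: float
    p_value: float
    p_adjusted: float = float("nan")
    glyph: str = ""


def bin_pairs(pairs: Iterable, scheme: BinScheme) -> dict:
    """Group pairs by bin; every bin label appears (possibly empty)."""
    out = {label: [] for label in scheme.labels}
    for pair in pairs:
        value = getattr(pair, scheme.variable)
        out[scheme.assign(value)].append(pair)
    return out


def fisher_enrichment(
    in_bin_predicted: int,
    predicted_total: int,
    in_bin_universe: int,
    universe_total: int,
    bin_label: str = "",
) -> EnrichmentRow:
    """Two-sided Fisher exact test of a bin's share among predicted siblings
    versus the whole pair universe.

    The 2x2 table contrasts predicted vs non-predicted pairs, in-bin vs
    out-of-bin.  The odds ratio is the conditional MLE-free sample odds
    ratio; with a zero cell it is inf/0 and the direction flag still follows
    the table.
    """
    if not (
        0 <= in_bin_predicted <= predicted_total <= universe_total
        and 0 <= in_bin_universe <= universe_total
        and in_bin_predicted <= in_bin_universe
    ):
        raise EnrichmentError(
            "inconsistent counts: need in_bin_predicted <= predicted_total, "
            "in_bin_predicted <= in_bin_universe <= universe_total"
        )
    a = in_bin_predicted
    b = predicted_total - in_bin_predicted
    c = in_bin_universe - in_bin_predicted
    d = (universe_total - predicted_total) - c
    if d < 0:
        raise EnrichmentError("inconsistent counts: universe smaller than its parts")
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentRow(
        bin=bin_label,
        in_bin_predicted=in_bin_predicted,
        predicted_total=predicted_total,
        in_bin_universe=in_bin_universe,
        universe_total=universe_total,
        odds_ratio=float(odds_ratio),
        p_value=float(p),
    )


def bh_adjust(pvalues: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    return multipletests(pvalues, method="fdr_bh")[1].tolist()


def _glyph(p: float, odds_ratio: float) -> str:
    if np.isnan(p) or p >= 0.05:
        return ""
    up = odds_ratio > 1
    if p < 0.001:
        return "++" if up else "--"
    return "+" if up else "-"


def enrichment_table(
    predicted_siblings: Iterable,
    universe: Iterable,
    scheme: BinScheme,
    use_adjusted_glyphs: bool = True,
) -> pd.DataFrame:
    """Per-bin enrichment of a method's predicted siblings within a universe.

    Returns one row per bin with counts, odds ratio, raw and BH-adjusted
    two-sided Fisher p (adjusted across this variable's bins), and the
    significance glyph.
    """
    predicted = list(predicted_siblings)
    universe = list(universe)
    pred_bins = bin_pairs(predicted, scheme)
    univ_bins = bin_pairs(universe, scheme)
    rows = []
    for label in scheme.labels:
        rows.append(
            fisher_enrichment(
                len(pred_bins[label]),
                len(predicted),
                len(univ_bins[label]),
                len(universe),
                bin_label=label,
            )
        )
    adjusted = bh_adjust([r.p_value for r in rows])
    records = []
    for row, p_adj in zip(rows, adjusted):
        p_for_glyph = p_adj if use_adjusted_glyphs else row.p_value
        records.append(
            {
                "variable": scheme.variable,
                "bin": row.bin,
                "in_bin_predicted": row.in_bin_predicted,
                "predicted_total": row.predicted_total,
                "in_bin_universe": row.in_bin_universe,
                "universe_total": row.universe_total,
                "odds_ratio": row.odds_ratio,
                "p_value": row.p_value,
                "p_adjusted": p_adj,
                "glyph": _glyph(p_for_glyph, row.odds_ratio),
            }
        )
    return pd.DataFrame(records)
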