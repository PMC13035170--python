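"""Descriptive statistics over validated evidence reports.

Produces the distribution summaries commonly shown for a glycopeptide
identification campaign — calculated monoisotopic mass, engine ion score
and peptide length — as quartiles plus binned histograms, together with a
confidence-tier by strain cross-tabulation.  Peptide length uses width-5
bins anchored at zero so the 15-19 bin is directly reportable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .validator import EvidenceReport

__all__ = ["DistributionSummary", "summarize", "tier_by_strain"]

VARIABLES = ("mr_calc", "ion_score", "peptide_length")


@dataclass(frozen=True)
class DistributionSummary:
    variable: str
    n: int
    min: float
    max: float
    q1: float
    median: float
    q3: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    mode_bin: str

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"[{lo:g}, {hi:g})"
            for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:])
        ]
        return pd.DataFrame({"bin": labels, "count": self.counts})


def _bin(values: np.ndarray, width: float, anchor: float = 0.0):
    lo = anchor + np.floor((values.min() - anchor) / width) * width
    hi = anchor + (np.floor((values.max() - anchor) / width) + 1) * width
    edges = np.arange(lo, hi + width / 2, width)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def _summary(variable: str, values: np.ndarray, width: float) -> DistributionSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    edges, counts = _bin(values, width)
    imode = int(np.argmax(counts))
    lo, hi = edges[imode], edges[imode + 1]
    if variable == "peptide_length":
        # integer-valued: label the bin by its inclusive integer range
        mode_label = f"{int(lo)}-{int(hi) - 1}"
    else:
        mode_label = f"[{lo:g}, {hi:g})"
    return DistributionSummary(
        variable=variable,
        n=values.size,
        min=float(values.min()),
        max=float(values.max()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        mode_bin=mode_label,
    )


def summarize(reports: Sequence[EvidenceReport]) -> dict[str, DistributionSummary]:
    """One DistributionSummary per variable (mass, ion score, length)."""
    if not reports:
        raise ValueError("no reports to summarize")
    masses = np.array([r.mr_calc for r in reports])
    scores = np.array([r.psm.ion_score for r in reports])
    lengths = np.array([float(r.peptide_length) for r in reports])
    return {
        "mr_calc": _summary("mr_calc", masses, width=250.0),
        "ion_score": _summary("ion_score", scores, width=5.0),
        "peptide_length": _summary("peptide_length", lengths, width=5.0),
    }


def tier_by_strain(reports: Sequence[EvidenceReport]) -> pd.DataFrame:
    """Cross-tabulate confidence tiers by source strain."""
    if not reports:
        raise ValueError("no reports to tabulate")
    df = pd.DataFrame(
        {
            "strain": [r.psm.source_strain or "unspecified" for r in reports],
            "tier": [r.tier.tier.value for r in reports],
        }
    )
    return pd.crosstab(df["strain"], df["tier"])
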