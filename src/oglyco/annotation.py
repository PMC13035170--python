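"""Downstream annotation: over-representation analysis and ortholog agreement.

Enrichment is a self-contained hypergeometric over-representation test of
a query gene set against GMT term collections, Benjamini-Hochberg adjusted
across all tested terms, with the adjusted values binned at the reporting
thresholds < 0.01, < 0.001 and < 1e-4.  Ortholog agreement tallies, for a
query gene list mapped through two independent ortholog databases, how
many genes each source maps, how many both or neither map, and the
fraction with an ortholog in at least one source.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "TermAnnotation",
    "EnrichmentResult",
    "OrthologRecord",
    "OrthologAgreement",
    "FDR_BINS",
    "read_gmt",
    "benjamini_hochberg",
    "fdr_bin",
    "enrich",
    "read_ortholog_table",
    "ortholog_agreement",
]

#: Reporting thresholds for adjusted p-values, most stringent first.
FDR_BINS = ((1e-4, "<1e-4"), (1e-3, "<0.001"), (1e-2, "<0.01"))

NAMESPACES = {"BP", "MF", "CC", "pathway", "domain"}


@dataclass(frozen=True)
class TermAnnotation:
    """A named gene set (GO term, pathway, domain...)."""

    term_id: str
    term_name: str
    genes: frozenset[str]
    namespace: str = "BP"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"term {self.term_id}: unknown namespace {self.namespace!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term: TermAnnotation
    overlap: int
    p_value: float
    fdr: float
    fdr_bin: str


@dataclass(frozen=True)
class OrthologRecord:
    worm_gene: str
    source: str
    human_ortholog: str | None  # None encodes explicit absence


@dataclass(frozen=True)
class OrthologAgreement:
    n_genes: int
    per_source: dict[str, int]
    both_sources: int
    neither: int
    percent_any_source: float


def read_gmt(path: str | Path, namespace: str = "BP") -> list[TermAnnotation]:
    """Read a GMT file: tab-separated ``term_id  description  gene1  gene2...``.

    Lines with no genes are skipped.  Duplicate term ids raise.
    """
    terms: list[TermAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term_id, name, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                continue
            if term_id in seen:
                raise ValueError(f"duplicate term id {term_id!r} in {path}")
            seen.add(term_id)
            terms.append(TermAnnotation(term_id, name, frozenset(genes), namespace))
    return terms


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment; returns adjusted values in the input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fdr_bin(fdr: float) -> str:
    for threshold, label in FDR_BINS:
        if fdr < threshold:
            return label
    return "ns"


def enrich(
    query: Iterable[str],
    terms: Sequence[TermAnnotation],
    background: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query set in each term.

    The p-value for a term with K background-restricted genes, a query of
    size n drawn from a background of size N, and observed overlap k is
    the upper hypergeometric tail P(X >= k).  Terms with no background
    overlap are skipped.  Background defaults to the union of all term
    gene sets.  Results are sorted by (fdr, term_id).
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if background is None:
        background = set().union(*(t.genes for t in terms))
    else:
        background = set(background)
    if not query <= background:
        raise ValueError(
            f"{len(query - background)} query genes absent from the background"
        )
    N, n = len(background), len(query)
    tested: list[tuple[TermAnnotation, int, float]] = []
    for t in terms:
        term_genes = t.genes & background
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((t, k, min(p, 1.0)))
    if not tested:
        return []
    fdrs = benjamini_hochberg([p for _, _, p in tested])
    results = [
        EnrichmentResult(term=t, overlap=k, p_value=p, fdr=float(q), fdr_bin=fdr_bin(float(q)))
        for (t, k, p), q in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.term.term_id))
    return results


def read_ortholog_table(path: str | Path, source: str) -> list[OrthologRecord]:
    """Read a CSV of ``worm_gene,human_ortholog`` rows for one source.

    An empty human_ortholog field encodes explicit absence.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("worm_gene", "human_ortholog"):
        if col not in df.columns:
            raise ValueError(f"ortholog table missing column {col!r}")
    return [
        OrthologRecord(
            worm_gene=row["worm_gene"],
            source=source,
            human_ortholog=row["human_ortholog"] or None,
        )
        for _, row in df.iterrows()
    ]


def ortholog_agreement(records: Sequence[OrthologRecord]) -> OrthologAgreement:
    """Tally two-source ortholog mapping agreement over a query gene list.

    Every worm gene must appear once per source (absence is an explicit
    row with no ortholog); duplicate (gene, source) rows raise.  The
    headline number is the percentage of genes with an ortholog in at
    least one source.
    """
    seen: set[tuple[str, str]] = set()
    mapped: dict[str, dict[str, bool]] = {}
    sources: set[str] = set()
    for r in records:
        key = (r.worm_gene, r.source)
        if key in seen:
            raise ValueError(f"duplicate ortholog row for {key}")
        seen.add(key)
        sources.add(r.source)
        mapped.setdefault(r.worm_gene, {})[r.source] = r.human_ortholog is not None
    for gene, by_source in mapped.items():
        missing = sources - set(by_source)
        if missing:
            raise ValueError(f"gene {gene!r} missing from sources {sorted(missing)}")
    n = len(mapped)
    per_source = {
        s: sum(1 for g in mapped.values() if g[s]) for s in sorted(sources)
    }
    both = sum(1 for g in mapped.values() if all(g.values()))
    neither = sum(1 for g in mapped.values() if not any(g.values()))
    pct = 100.0 * (n - neither) / n if n else 0.0
    return OrthologAgreement(
        n_genes=n,
        per_source=per_source,
        both_sources=both,
        neither=neither,
        percent_any_source=pct,
    )
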