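"""Metabolite-set over-representation analysis.

Hypergeometric enrichment of a query metabolite set against a GMT pathway
library, the standard test behind over-representation tools.  The design
this package implements reports raw pathway p-values against a relatively
permissive significance level (0.10 by default); an optional
Benjamini-Hochberg column is provided for users who want multiplicity
control across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .io_formats import PathwayLibrary, ValidationError


@dataclass(frozen=True)
class EnrichmentRow:
    """One pathway's over-representation result."""

    pathway: str
    size: int            # members in the universe (m)
    hits: int            # overlap with the query (k)
    expected: float      # n * m / N
    pval: float          # P(X >= k), hypergeometric upper tail
    fdr: float           # Benjamini-Hochberg across the tested pathways
    significant: bool

    def as_dict(self) -> dict:
        return {
            "pathway": self.pathway, "size": self.size, "hits": self.hits,
            "expected": self.expected, "pval": self.pval, "fdr": self.fdr,
            "significant": self.significant,
        }


def map_metabolites(
    query: Iterable[str],
    library: PathwayLibrary,
) -> tuple[set[str], list[str]]:
    """Case-insensitive exact match of query identifiers to the universe.

    Returns the matched universe identifiers and the unmatched raw query
    strings (reported, never silently dropped); duplicate queries collapse.
    """
    query = list(query)
    if not query:
        raise ValidationError("empty metabolite query")
    fold = {u.casefold(): u for u in library.universe}
    matched: set[str] = set()
    unmatched: list[str] = []
    for q in dict.fromkeys(query):  # de-dup, keep order for the report
        hit = fold.get(q.casefold())
        if hit is None:
            unmatched.append(q)
        else:
            matched.add(hit)
    return matched, unmatched


def ora_hypergeometric(
    query: set[str],
    library: PathwayLibrary,
    alpha: float = 0.10,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation per pathway.

    For a pathway of size m in a universe of size N and a query of size n
    with k overlapping members, ``p = P(X >= k)`` for X ~
    Hypergeometric(N, m, n), the observed k included.  Rows come back
    sorted by p (ties by name); the ``significant`` flag compares the raw p
    against ``alpha``.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    universe = library.universe
    stray = query - universe
    if stray:
        raise ValidationError(
            f"query metabolites outside the library universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name, members in library.pathways.items():
        if not members <= universe:
            raise ValidationError(f"pathway {name!r} exceeds the universe")
        m = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        rows.append((name, m, k, n * m / N, min(p, 1.0)))
    rows.sort(key=lambda t: (t[4], t[0]))
    # Benjamini-Hochberg over the tested pathways (informational column)
    P = len(rows)
    fdr = [0.0] * P
    running = 1.0
    for i in range(P - 1, -1, -1):
        running = min(running, rows[i][4] * P / (i + 1))
        fdr[i] = running
    return [
        EnrichmentRow(pathway=name, size=m, hits=k, expected=exp, pval=p,
                      fdr=fdr[i], significant=p < alpha)
        for i, (name, m, k, exp, p) in enumerate(rows)
    ]


def enrich_report(
    results: Sequence,
    library: PathwayLibrary,
    p_cutoff: float = 0.05,
    alpha: float = 0.10,
    metabolite_attr: str = "metabolite",
    pval_attr: str = "pval",
) -> dict[str, object]:
    """Enrichment of the metabolites passing a per-metabolite p cutoff.

    ``results`` is any sequence of objects (or mappings) carrying a
    metabolite identifier and a p-value — GRS scan rows or per-metabolite
    MR estimates.  Metabolites with ``p < p_cutoff`` form the query; the
    report carries the enrichment table, the unmatched identifiers and a
    warning flag when the query is empty.
    """
    def get(r, attr):
        if isinstance(r, dict):
            return r[attr]
        return getattr(r, attr)

    query_ids = sorted({get(r, metabolite_attr) for r in results
                        if get(r, pval_attr) < p_cutoff})
    if not query_ids:
        return {"rows": [], "unmatched": [], "query_size": 0, "warning":
                f"no metabolites below p < {p_cutoff}"}
    matched, unmatched = map_metabolites(query_ids, library)
    rows = ora_hypergeometric(matched, library, alpha=alpha) if matched else []
    return {"rows": rows, "unmatched": unmatched,
            "query_size": len(query_ids), "warning": None}
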