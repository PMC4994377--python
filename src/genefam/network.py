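"""Ortholog-projected interaction networks and GO-term enrichment.

Interaction knowledge for a poorly annotated genome is borrowed from a model
organism: family genes are mapped to model-organism orthologs, every
interaction edge incident to a mapped ortholog is projected back as a
(family gene, partner) pair, and projected partner sets are tested for GO
term over-representation with the upper-tail hypergeometric test and
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class NetworkStats:
    n_mapped_genes: int
    n_projected_edges: int
    mean_edges_per_gene: float  # rounded to 1 decimal
    degree: dict[str, int]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # annotated in query
    K: int  # annotated in background
    n: int  # query size
    N: int  # background size
    p: float
    q: float
    significant: bool


def project_network(
    ortholog_map: pd.DataFrame, edges: pd.DataFrame
) -> tuple[NetworkStats, pd.DataFrame]:
    """Project model-organism edges onto family genes through orthology.

    ``ortholog_map`` has columns ``family_gene``, ``ortholog`` (many family
    genes may share an ortholog); ``edges`` has columns ``a``, ``b`` over
    model-organism ids.  Each undirected edge incident to a mapped ortholog
    yields one (family gene, partner) pair; pairs are de-duplicated.  The
    mean is the projected pair count over the number of family genes with at
    least one pair, rounded to one decimal.
    """
    if ortholog_map.duplicated(["family_gene", "ortholog"]).any():
        raise ValueError("duplicate ortholog pairs")
    by_ortholog: dict[str, list[str]] = {}
    for _, row in ortholog_map.iterrows():
        by_ortholog.setdefault(row["ortholog"], []).append(row["family_gene"])
    pairs = set()
    for _, e in edges.iterrows():
        a, b = e["a"], e["b"]
        for fam in by_ortholog.get(a, ()):
            pairs.add((fam, b))
        for fam in by_ortholog.get(b, ()):
            pairs.add((fam, a))
    degree: dict[str, int] = {}
    for fam, _ in pairs:
        degree[fam] = degree.get(fam, 0) + 1
    n_mapped = len(degree)
    mean = round(len(pairs) / n_mapped, 1) if n_mapped else 0.0
    table = pd.DataFrame(sorted(pairs), columns=["family_gene", "partner"])
    return NetworkStats(n_mapped, len(pairs), mean, degree), table


def hypergeom_enrich(
    query: set[str],
    annotation: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of GO terms in a gene set.

    ``annotation`` maps gene -> set of terms.  p = P(X >= k) where X is
    hypergeometric(N, K, n); q is BH-adjusted across the tested terms;
    significance is q < alpha.
    """
    stray = query - background
    if stray:
        raise ValueError(f"query genes absent from background: {sorted(stray)}")
    N, n = len(background), len(query)
    terms: dict[str, tuple[int, int]] = {}
    all_terms = sorted({t for g in background for t in annotation.get(g, ())})
    for term in all_terms:
        K = sum(1 for g in background if term in annotation.get(g, ()))
        k = sum(1 for g in query if term in annotation.get(g, ()))
        terms[term] = (k, K)
    if not terms:
        return []
    pvals = [
        float(stats.hypergeom.sf(k - 1, N, K, n)) for k, K in terms.values()
    ]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentResult(term, k, K, n, N, p, float(q), bool(q < alpha))
        for (term, (k, K)), p, q in zip(terms.items(), pvals, qvals)
    ]
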