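"""Exact enrichment statistics for AS-gene characterization.

Fisher's exact test (two-sided, minimum-likelihood convention) asks
whether a protein domain occurs more often among alternatively spliced
genes than among constitutively spliced ones; the upper-tail
hypergeometric test with Benjamini-Hochberg FDR control scores GO-term
over-representation of AS genes against the whole-transcriptome
background.  Both tests enumerate the exact hypergeometric distribution
(log-space pmf); no asymptotic approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .errors import ValidationError

#: relative slack when comparing pmf values in the minimum-likelihood sum,
#: absorbing floating-point noise (same convention as mainstream stats tools)
_PMF_RELTOL = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table.

    a = AS genes with the domain, b = AS genes without,
    c = constitutive genes with, d = constitutive genes without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("2x2 counts must be non-negative")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # AS genes with term
    K: int  # background genes with term
    n: int  # AS gene count
    N: int  # background size
    p: float
    p_adj: float = 1.0
    flagged: bool = False


def fisher_exact_2x2(table: TwoByTwo) -> float:
    """Two-sided Fisher exact p by summing all same-margin tables whose
    hypergeometric probability does not exceed the observed table's."""
    r1, r2, c1, _c2 = table.margins
    if min(table.margins) == 0:
        raise ValidationError("Fisher test undefined: a margin is zero")
    n_total = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, r1, c1)
    p_obs = hypergeom.pmf(table.a, n_total, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + _PMF_RELTOL)].sum())
    return min(1.0, p)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def domain_as_enrichment(
    domain_counts: dict[str, tuple[int, int]],
    n_as: int,
    n_constitutive: int,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Per-domain Fisher tests of over-occurrence in AS genes.

    ``domain_counts`` maps domain -> (AS genes carrying it, constitutive
    genes carrying it); occurrence is gene-level presence/absence.  A
    domain is flagged when p < alpha AND its AS-gene proportion exceeds
    its constitutive proportion (the two-sided p is kept comparable with
    standard tools; "higher frequency" is a post-hoc direction filter).
    """
    results = []
    for domain in sorted(domain_counts):
        k_as, k_const = domain_counts[domain]
        if k_as > n_as or k_const > n_constitutive:
            raise ValidationError(f"counts for {domain} exceed group totals")
        table = TwoByTwo(k_as, n_as - k_as, k_const, n_constitutive - k_const)
        try:
            p = fisher_exact_2x2(table)
        except ValidationError:
            p = 1.0  # degenerate margin: no information
        higher = (k_as / n_as) > (k_const / n_constitutive)
        results.append(
            EnrichmentResult(
                term_id=domain,
                k=k_as,
                K=k_as + k_const,
                n=n_as,
                N=n_as + n_constitutive,
                p=p,
                flagged=bool(p < alpha and higher),
            )
        )
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def go_enrichment_bh(
    as_genes: set[str],
    gene_terms: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric GO enrichment of AS genes, BH-corrected.

    Annotations are taken as given (no GO-graph ancestor propagation).
    Results are sorted by raw p; ``flagged`` marks p_adj < alpha.
    """
    missing = as_genes - background
    if missing:
        raise ValidationError(f"AS genes absent from background: {sorted(missing)[:5]}")
    N = len(background)
    n = len(as_genes)
    term_bg: dict[str, int] = {}
    term_as: dict[str, int] = {}
    for gene in background:
        for term in gene_terms.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in as_genes:
                term_as[term] = term_as.get(term, 0) + 1
    results = [
        EnrichmentResult(
            term_id=term,
            k=term_as.get(term, 0),
            K=K,
            n=n,
            N=N,
            p=hypergeom_upper_tail(term_as.get(term, 0), N, K, n),
        )
        for term, K in sorted(term_bg.items())
    ]
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        r.flagged = bool(r.p_adj < alpha)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def results_to_rows(results: list[EnrichmentResult]) -> list[dict]:
    return [
        {
            "term_id": r.term_id,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p": r.p,
            "p_adj": r.p_adj,
            "flagged": r.flagged,
        }
        for r in results
    ]
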