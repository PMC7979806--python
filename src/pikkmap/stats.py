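"""Domain enrichment, overlap and surface-fraction summaries.

Enrichment asks whether residues of interest (e.g. conserved residues
mutated in cancer) concentrate in a region such as the kinase domain beyond
its share of the protein length.  Fold enrichment is (k/n) / f_dom, and the
headline p-value is the one-sided binomial tail P(X >= k) with X ~
Binomial(n, f_dom); a hypergeometric alternative (sampling residues without
replacement from the protein) is reported when integer lengths are given.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats as sps

__all__ = [
    "EnrichmentResult",
    "OverlapResult",
    "domain_enrichment",
    "enrich_domains",
    "overlap_analysis",
    "surface_fraction",
]


@dataclass
class EnrichmentResult:
    domain: Optional[str]
    k: int
    n: int
    f_dom: float
    fold: float
    p_value: float  # one-sided binomial tail P(X >= k)
    p_hypergeom: Optional[float] = None
    p_adjusted: Optional[float] = None


@dataclass
class OverlapResult:
    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    k_way_intersection: int
    union: int


def domain_enrichment(
    k: int,
    n: int,
    domain_len: Optional[int] = None,
    protein_len: Optional[int] = None,
    f_dom: Optional[float] = None,
    domain: Optional[str] = None,
) -> EnrichmentResult:
    """Enrichment of ``k`` of ``n`` tested residues in a domain.

    Provide either integer ``domain_len``/``protein_len`` (then
    ``f_dom = domain_len / protein_len`` and the hypergeometric alternative
    is also computed) or the length fraction ``f_dom`` directly.
    """
    if f_dom is None:
        if not domain_len or not protein_len:
            raise ValueError("give either f_dom or domain_len and protein_len")
        if domain_len <= 0 or domain_len > protein_len:
            raise ValueError("need 0 < domain_len <= protein_len")
        f_dom = domain_len / protein_len
    if not (0.0 < f_dom <= 1.0):
        raise ValueError("f_dom must lie in (0, 1]")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if n == 0:
        raise ValueError("n must be positive")

    fold = (k / n) / f_dom
    # Exact binomial tail; scipy sums the pmf, no normal approximation.
    p_value = float(sps.binom.sf(k - 1, n, f_dom))
    p_hyper = None
    if domain_len is not None and protein_len is not None:
        if n > protein_len:
            raise ValueError("n cannot exceed protein_len for the hypergeometric tail")
        p_hyper = float(sps.hypergeom.sf(k - 1, protein_len, domain_len, n))
    return EnrichmentResult(
        domain=domain, k=k, n=n, f_dom=f_dom, fold=fold, p_value=p_value,
        p_hypergeom=p_hyper,
    )


def enrich_domains(
    positions: Iterable[int],
    dmap,
    protein_len: int,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Scan every interval of a domain map for enrichment of ``positions``.

    ``adjust=True`` applies Benjamini-Hochberg across the scanned domains
    (off by default; single-domain questions need no correction).
    """
    positions = sorted(set(positions))
    n = len(positions)
    results = []
    for name, start, end in dmap.intervals:
        k = sum(1 for p in positions if start <= p <= end)
        results.append(
            domain_enrichment(
                k, n, domain_len=end - start + 1, protein_len=protein_len, domain=name
            )
        )
    if adjust and results:
        m = len(results)
        order = sorted(range(m), key=lambda i: results[i].p_value)
        prev = 1.0
        for rank_from_end, idx in enumerate(reversed(order)):
            rank = m - rank_from_end
            adj = min(prev, results[idx].p_value * m / rank)
            results[idx].p_adjusted = adj
            prev = adj
    return results


def overlap_analysis(
    sets: Mapping[str, Iterable] | Sequence[tuple[str, Iterable]],
) -> OverlapResult:
    """Exact pairwise and k-way overlaps among labelled residue sets."""
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = list(sets)
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate set labels")
    if len(items) < 2:
        raise ValueError("need at least two sets")
    as_sets = {label: set(values) for label, values in items}
    pairwise = {
        (a, b): len(as_sets[a] & as_sets[b]) for a, b in combinations(labels, 2)
    }
    k_way = set.intersection(*as_sets.values())
    union = set.union(*as_sets.values())
    return OverlapResult(
        sizes={label: len(s) for label, s in as_sets.items()},
        pairwise=pairwise,
        k_way_intersection=len(k_way),
        union=len(union),
    )


def surface_fraction(
    profile, subset: Optional[Iterable[tuple[str, int]]] = None
) -> dict:
    """Surface counts over resolved residues (optionally a subset of keys).

    Unresolved residues (subset keys absent from the SASA profile) are
    reported separately and excluded from the denominator.  When nothing in
    the subset is resolved the fraction is undefined (None) and flagged.
    """
    keys = list(profile.residues) if subset is None else list(subset)
    n_surface = n_resolved = n_unresolved = 0
    for key in keys:
        rs = profile.residues.get(tuple(key))
        if rs is None or rs.burial is None:
            n_unresolved += 1
            continue
        n_resolved += 1
        if rs.burial == "surface":
            n_surface += 1
    return {
        "n_surface": n_surface,
        "n_resolved": n_resolved,
        "n_unresolved": n_unresolved,
        "fraction": (n_surface / n_resolved) if n_resolved else None,
    }
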