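"""Pathway over-representation by the right-tailed Fisher's exact test.

Given a query list of molecule IDs (KEGG compounds, proteins, or any
opaque strings), pathway member sets and an explicit universe, each
pathway is scored by the hypergeometric right tail

    p = P(X >= hits),  X ~ Hypergeom(|universe|, |pathway|, |query|)

and by the coverage ratio hits / pathway size.  The universe is a
required, auditable input — there is no hidden background — and no
multiple-testing adjustment is applied to the reported p (a
Benjamini-Hochberg column is emitted as an optional extra).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

__all__ = ["PathwaySet", "EnrichmentResult", "read_gmt", "fisher_enrichment"]


@dataclass(frozen=True)
class PathwaySet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.name!r} has no members")


@dataclass
class EnrichmentResult:
    pathway: str
    hits: int
    pathway_size: int
    ratio: float
    p_value: float
    query_size: int
    universe_size: int
    bh_p: float | None = None


def read_gmt(path) -> list[PathwaySet]:
    """Parse a GMT file: name <TAB> description <TAB> member IDs..."""
    sets: list[PathwaySet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT needs name, description and "
                    "at least one member"
                )
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise ValueError(f"{path}: line {lineno}: empty member list")
            sets.append(PathwaySet(fields[0], members, fields[1]))
    if not sets:
        raise ValueError(f"{path}: no pathway sets found")
    return sets


def fisher_enrichment(
    query: set[str],
    pathways: list[PathwaySet],
    universe: set[str],
    top: int | None = 10,
) -> list[EnrichmentResult]:
    """Right-tailed Fisher over-representation of ``query`` in each pathway.

    Query IDs outside the universe are dropped (they cannot be drawn);
    pathway member sets are intersected with the universe.  Results are
    sorted by ascending p-value; ``top`` limits the report (None = all).
    """
    if not universe:
        raise ValueError("universe is empty")
    query_in = set(query) & set(universe)
    if not query_in:
        raise ValueError("query is empty after intersecting with the universe")
    M = len(universe)
    N = len(query_in)
    results: list[EnrichmentResult] = []
    for pw in pathways:
        members = pw.members & set(universe)
        if not members:
            continue
        n = len(members)
        hits = len(query_in & members)
        p = float(hypergeom.sf(hits - 1, M, n, N)) if hits > 0 else 1.0
        results.append(
            EnrichmentResult(
                pathway=pw.name,
                hits=hits,
                pathway_size=n,
                ratio=hits / n,
                p_value=min(p, 1.0),
                query_size=N,
                universe_size=M,
            )
        )
    if results:
        # optional BH column: the Storey step-up with pi0 forced to 1
        import numpy as np

        p_arr = np.array([r.p_value for r in results])
        m = p_arr.size
        order = np.argsort(p_arr, kind="stable")
        q_sorted = p_arr[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum(np.minimum.accumulate(q_sorted[::-1])[::-1], 1.0)
        bh = np.empty(m)
        bh[order] = q_sorted
        for r, q in zip(results, bh):
            r.bh_p = float(q)
    results.sort(key=lambda r: (r.p_value, -r.hits, r.pathway))
    return results[:top] if top else results
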