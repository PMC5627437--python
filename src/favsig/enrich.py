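"""Fisher's-exact over-representation of gene sets.

Gene sets are supplied as GMT files (tab-separated: set name, description,
member genes). Enrichment of a query gene list (e.g. the favorable or the
unfavorable signature) against each set is tested with a one-sided Fisher's
exact test on the 2x2 table of in-query/in-set membership over a finite
background universe — by default the genes that entered the screen, not the
whole genome. The one-sided p equals the hypergeometric tail
P(X >= overlap). Raw p-values are reported and thresholded at p < alpha;
no multiple-testing correction is applied at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "fisher_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested over."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        empty = [nm for nm, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def with_universe(self, universe) -> "GeneSetCollection":
        return GeneSetCollection(dict(self.sets), set(universe))


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    overlapping_genes: list[str]

    def __post_init__(self) -> None:
        assert self.overlap <= min(self.set_size, self.query_size)


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate set names are an error; duplicate genes within a set are
    counted once (the dedup is logged). An empty file yields an empty
    collection with a warning.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected "
                    f"name, description and at least one gene"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = [g for g in parts[2:] if g]
            dedup = set(members)
            if len(dedup) < len(members):
                logger.info("set %r: %d duplicate members collapsed",
                            name, len(members) - len(dedup))
            sets[name] = dedup
    if not sets:
        logger.warning("empty GMT file %s", path)
    return GeneSetCollection(sets, set(universe) if universe is not None else set())


def fisher_enrichment(
    query,
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact enrichment of ``query`` in each gene set.

    Query and sets are intersected with the collection's universe before
    testing; an empty query after intersection is an error. Results are
    sorted by ascending p; the ``alpha`` threshold defines the significant
    view (``[r for r in results if r.p_value < alpha]``) and is recorded
    only for the caller's convenience — all sets are returned.
    """
    universe = set(collection.universe)
    if not universe:
        raise ValueError("collection has no background universe")
    q = set(query) & universe
    if not q:
        raise ValueError("query is empty after intersection with the universe")
    N, K = len(universe), len(q)
    results = []
    for name, members in collection.sets.items():
        s = members & universe
        if len(s) < len(members):
            logger.debug("set %r: %d members outside universe ignored",
                         name, len(members) - len(s))
        if not s:
            continue
        overlap = q & s
        k, M = len(overlap), len(s)
        table = [[k, K - k], [M - k, N - K - (M - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        results.append(EnrichmentResult(
            set_name=name, overlap=k, set_size=M, query_size=K,
            universe_size=N, p_value=float(p),
            overlapping_genes=sorted(overlap),
        ))
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results."""
    return pd.DataFrame(
        [{
            "set_name": r.set_name, "overlap": r.overlap,
            "set_size": r.set_size, "query_size": r.query_size,
            "universe_size": r.universe_size, "p_value": r.p_value,
            "overlapping_genes": ",".join(r.overlapping_genes),
        } for r in results]
    )
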