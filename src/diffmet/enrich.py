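"""Pathway over-representation analysis on annotated metabolite lists.

Pathways are plain identifier sets (GMT files); enrichment of a hit
list against a reference universe uses the one-sided hypergeometric
upper tail, with Benjamini-Hochberg adjustment across pathways. Output
mirrors the standard reporting shape: pathway, overlap size, pathway
size (restricted to the reference), and the overlapping identifiers.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

from scipy import stats

from .datatypes import EnrichmentResult
from .diffabund import fdr_adjust


class ParseError(ValueError):
    pass


class DataError(ValueError):
    pass


def load_pathways(path) -> dict[str, set[str]]:
    """Parse a GMT file into pathway -> member-id sets.

    Each line: name, description, then tab-separated member ids.
    Duplicate members within a pathway are counted once.
    """
    db: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            name = parts[0]
            members = {p for p in parts[2:] if p}
            if not members:
                raise ParseError(f"{path}:{lineno}: pathway {name!r} has no members")
            db[name] = members
    if not db:
        warnings.warn(f"pathway file {path} contains no pathways", stacklevel=2)
    return db


def write_gmt(db: Mapping[str, Iterable[str]], path, description: str = "na") -> None:
    """Write a pathway database as GMT (members sorted for determinism)."""
    with open(path, "w") as fh:
        for name in sorted(db):
            members = sorted(set(db[name]))
            fh.write("\t".join([name, description, *members]) + "\n")


def hypergeom_pvalue(k: int, M: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(universe M, category K, draws N)."""
    if k <= 0:
        return 1.0
    return float(min(stats.hypergeom.sf(k - 1, M, K, N), 1.0))


def ora_test(
    hits: Iterable[str],
    reference: Iterable[str],
    db: Mapping[str, Iterable[str]],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each pathway in the hit list.

    ``reference`` is the universe (all metabolites surviving QC and
    annotation); pathway sizes are counted after intersection with it.
    For a universe of M ids, a pathway of K, and N hits overlapping the
    pathway in k ids, p = P(X >= k) with X ~ Hypergeom(M, K, N).
    Pathways with no overlap are reported with p = 1. Results are sorted
    by raw p (ties by name) and BH-adjusted across all tested pathways;
    ``alpha`` is the conventional adjusted-p cutoff stored for callers.
    """
    del alpha  # significance flagging is left to callers / CLI
    hits = set(hits)
    reference = set(reference)
    stray = hits - reference
    if stray:
        raise DataError(
            f"{len(stray)} hit id(s) not in the reference universe, e.g. {sorted(stray)[0]!r}"
        )
    M, N = len(reference), len(hits)
    results = []
    for name in sorted(db):
        members = set(db[name]) & reference
        overlap = sorted(hits & members)
        K, k = len(members), len(overlap)
        p = 1.0 if K == 0 else hypergeom_pvalue(k, M, K, N)
        results.append(
            EnrichmentResult(
                pathway=name,
                overlap_size=k,
                pathway_size=K,
                overlap=tuple(overlap),
                p_value=p,
            )
        )
    if results:
        _, adj = fdr_adjust([r.p_value for r in results], q=0.01)
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results
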