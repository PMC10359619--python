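"""Cross-network module overlap statistics and marker-list comparison.

Every pair (module A, module B) is summarized by the number of shared
genes, the Jaccard index |A∩B| / |A∪B|, the shared fraction of each
set, and a Fisher exact test of over-representation against a gene
universe: the one-sided p-value is the hypergeometric tail
P(X >= n_shared) for X ~ Hypergeom(universe, |A|, |B|). The universe
choice changes p-values materially, so it is an explicit parameter:
the union or intersection of the two collections' genes, or an
explicit gene set. Benjamini-Hochberg adjustment is applied across all
pairs of one comparison run.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

UniverseSpec = Literal["union", "intersection"]

OVERLAP_COLUMNS = [
    "module_a", "module_b", "size_a", "size_b", "n_shared", "jaccard",
    "fraction_of_a", "fraction_of_b", "fisher_p", "fisher_p_adjusted",
    "universe_size",
]


def _resolve_universe(
    sets_a: Mapping[str, set[str]],
    sets_b: Mapping[str, set[str]],
    universe: UniverseSpec | Iterable[str],
) -> set[str]:
    all_a: set[str] = set().union(*sets_a.values()) if sets_a else set()
    all_b: set[str] = set().union(*sets_b.values()) if sets_b else set()
    if universe == "union":
        return all_a | all_b
    if universe == "intersection":
        return all_a & all_b
    return set(universe)


def fisher_enrichment_p(n_shared: int, size_a: int, size_b: int, universe_size: int) -> float:
    """One-sided (enrichment) Fisher exact p: P(overlap >= n_shared)
    under Hypergeom(universe_size, size_a, size_b)."""
    return float(stats.hypergeom.sf(n_shared - 1, universe_size, size_a, size_b))


def compare_module_sets(
    sets_a: Mapping[str, Iterable[str]],
    sets_b: Mapping[str, Iterable[str]],
    universe: UniverseSpec | Iterable[str] = "union",
    alternative: Literal["enrichment", "two-sided"] = "enrichment",
) -> pd.DataFrame:
    """Overlap statistics for every (module in A, module in B) pair.

    Genes outside the universe are dropped from the sets with a
    warning; a set left empty by that (disjoint from the universe) is
    an error, as is an empty input set or an empty universe.
    """
    sa = {k: set(v) for k, v in sets_a.items()}
    sb = {k: set(v) for k, v in sets_b.items()}
    for name, s in list(sa.items()) + list(sb.items()):
        if not s:
            raise ValueError(f"set {name!r} is empty")
    uni = _resolve_universe(sa, sb, universe)
    if not uni:
        raise ValueError("gene universe is empty")
    for coll, coll_name in ((sa, "A"), (sb, "B")):
        for name, s in coll.items():
            outside = s - uni
            if outside:
                logger.warning(
                    "dropping %d genes of %s set %r outside the universe",
                    len(outside), coll_name, name,
                )
                coll[name] = s & uni
            if not coll[name]:
                raise ValueError(f"{coll_name} set {name!r} is disjoint from the universe")
    N = len(uni)
    rows = []
    for name_a, a in sa.items():
        for name_b, b in sb.items():
            shared = len(a & b)
            union_size = len(a | b)
            if alternative == "enrichment":
                p = fisher_enrichment_p(shared, len(a), len(b), N)
            else:
                table = [
                    [shared, len(a) - shared],
                    [len(b) - shared, N - union_size],
                ]
                p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            rows.append(
                {
                    "module_a": name_a,
                    "module_b": name_b,
                    "size_a": len(a),
                    "size_b": len(b),
                    "n_shared": shared,
                    "jaccard": shared / union_size if union_size else 0.0,
                    "fraction_of_a": shared / len(a),
                    "fraction_of_b": shared / len(b),
                    "fisher_p": p,
                    "universe_size": N,
                }
            )
    result = pd.DataFrame(rows)
    result["fisher_p_adjusted"] = multipletests(result["fisher_p"].to_numpy(), method="fdr_bh")[1]
    return result[OVERLAP_COLUMNS]


def compare_to_marker_lists(
    sets: Mapping[str, Iterable[str]],
    markers: Mapping[str, Iterable[str]],
    universe: UniverseSpec | Iterable[str] = "union",
) -> pd.DataFrame:
    """Overlap of co-expression modules with external marker-gene lists
    (e.g. cell-type markers from single-cell clusters)."""
    return compare_module_sets(sets, markers, universe=universe)


def filter_comparison(
    result: pd.DataFrame,
    min_jaccard: float = 0.05,
    max_adjusted_p: float = 0.05,
) -> pd.DataFrame:
    """Keep pairs with Jaccard strictly above ``min_jaccard`` and
    adjusted p at most ``max_adjusted_p`` — the edge list of a module
    comparison graph (edge weight = Jaccard)."""
    if not 0.0 <= min_jaccard <= 1.0 or not 0.0 <= max_adjusted_p <= 1.0:
        raise ValueError("thresholds must be in [0, 1]")
    keep = (result["jaccard"] > min_jaccard) & (result["fisher_p_adjusted"] <= max_adjusted_p)
    return result[keep].reset_index(drop=True)


def comparison_edge_list(result: pd.DataFrame) -> pd.DataFrame:
    """Graph-ready edge list: source, target, jaccard weight, adjusted p."""
    return result[["module_a", "module_b", "jaccard", "fisher_p_adjusted"]].rename(
        columns={"module_a": "source", "module_b": "target", "jaccard": "weight"}
    )


def read_gene_sets(path, name_col: int = 0, gene_col: int = 1) -> dict[str, set[str]]:
    """Read a two-column TSV (set name, gene id) into a dict of sets."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for name, group in df.groupby(df.columns[name_col]):
        out[str(name)] = set(group[df.columns[gene_col]].astype(str))
    return out
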