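"""Gene-set over-representation of called genes and category summaries.

Over-representation is a one-sided hypergeometric tail: with a universe of N
genes, a set annotating K of them and n genes called, the p-value for seeing
k called members is P(X >= k), X ~ Hypergeom(N, K, n). Rows mirror the
familiar changed/total report layout. The direction summary counts up- and
down-regulated genes per flat category (a gene in several categories counts
once in each; genes in none fall under "unclassified").
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .errors import PipelineError
from .io import GeneSetCollection

UNCLASSIFIED = "unclassified"


def hypergeometric_enrichment(
    called: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    adjust: bool = False,
) -> pd.DataFrame:
    """One-sided over-representation p-value per gene set.

    Set members are intersected with the universe before testing; sets with
    no member in the universe are omitted. Rows are sorted by p-value.
    ``adjust=True`` adds a Benjamini-Hochberg column.
    """
    called = set(called)
    universe = set(universe)
    stray = called - universe
    if stray:
        raise PipelineError(
            "called genes outside the universe: "
            + ", ".join(sorted(stray)[:10])
        )
    N, n = len(universe), len(called)
    rows = []
    for set_id, gs in sets.items():
        members = set(gs.members) & universe
        total = len(members)
        if total == 0:
            continue
        changed = len(members & called)
        p = float(hypergeom.sf(changed - 1, N, total, n))
        rows.append({
            "set_id": set_id,
            "description": gs.description,
            "changed": changed,
            "total": total,
            "p_value": min(p, 1.0),
        })
    out = pd.DataFrame(
        rows, columns=["set_id", "description", "changed", "total", "p_value"]
    )
    out = out.sort_values(["p_value", "set_id"]).reset_index(drop=True)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def summarize_categories(
    directions: Mapping[str, str],
    category_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-category totals and up/down split of the called genes.

    ``directions`` maps called gene -> 'up'/'down'; ``category_map`` maps
    gene -> its categories (possibly several; counted once in each).
    """
    counts: dict[str, dict[str, int]] = {}
    for gene, direction in directions.items():
        cats = list(category_map.get(gene, [])) or [UNCLASSIFIED]
        for cat in cats:
            c = counts.setdefault(cat, {"n_total": 0, "n_up": 0, "n_down": 0})
            c["n_total"] += 1
            c["n_up" if direction == "up" else "n_down"] += 1
    rows = [{"category": cat, **c} for cat, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["category", "n_total", "n_up", "n_down"])
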