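"""Fisher's-exact (hypergeometric) gene-set over-representation analysis.

Given a foreground (proteins carrying at least one significant site in a
contrast) and a background universe (all quantified proteins by default),
each gene set is scored with the one-sided hypergeometric upper-tail
p-value — identical to a one-sided Fisher's exact test on the 2×2 overlap
table — and an enrichment score (k/n)/(K/N).  Results are ranked by
(p ascending, enrichment score descending, set id) for a deterministic
top-N selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import DataError, DifferentialTable, GeneSetCollection

__all__ = ["fisher_enrichment", "top_pathways", "subcellular_classify",
           "foreground_proteins", "hypergeometric_upper_tail"]


def hypergeometric_upper_tail(k, N, K, n):
    """P(X ≥ k) for X ~ Hypergeom(N, K, n): the one-sided Fisher p-value.

    Accepts scalars or arrays; k=0 gives 1 exactly.
    """
    return stats.hypergeom.sf(np.asarray(k) - 1, N, K, n)

RESULT_COLUMNS = ["set_id", "set_name", "category", "k", "K", "n", "N",
                  "fisher_p", "enrichment_score", "rank"]


def _clean(proteins) -> set[str]:
    return {str(p).upper() for p in proteins}


def foreground_proteins(dt: DifferentialTable) -> set[str]:
    """Proteins (gene symbols) with ≥1 significant site in the contrast."""
    return _clean(dt.significant["gene_name"])


def fisher_enrichment(foreground, background, gene_sets: GeneSetCollection,
                      category: str | None = None, alpha: float = 0.05,
                      p_adjust: str = "none") -> pd.DataFrame:
    """One-sided over-representation test for every gene set.

    Sets are intersected with the background before testing; sets with no
    background members are dropped.  ``k=0`` sets get p = 1 (the upper tail
    includes zero).
    """
    fg = _clean(foreground)
    bg = _clean(background)
    if not bg:
        raise DataError("background universe is empty")
    if not fg <= bg:
        extra = sorted(fg - bg)[:5]
        raise DataError(f"foreground not a subset of background, e.g. {extra}")
    if p_adjust not in ("none", "BH"):
        raise DataError(f"p_adjust must be 'none' or 'BH', got {p_adjust!r}")
    sets = gene_sets.by_category(category) if category else gene_sets
    N, n = len(bg), len(fg)
    rows = []
    for gs in sets:
        members = set(gs.members) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & fg)
        p = float(hypergeometric_upper_tail(k, N, K, n))
        score = (k / n) / (K / N) if n and K else 0.0
        rows.append({"set_id": gs.set_id, "set_name": gs.name,
                     "category": gs.category, "k": k, "K": K, "n": n, "N": N,
                     "fisher_p": min(p, 1.0), "enrichment_score": score})
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if df.empty:
        df["rank"] = pd.Series(dtype=int)
        return df
    if p_adjust == "BH":
        df["p_adjusted"] = multipletests(df["fisher_p"], method="fdr_bh")[1]
    df = df.sort_values(["fisher_p", "enrichment_score", "set_id"],
                        ascending=[True, False, True], ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["significant"] = df["fisher_p"] < alpha
    return df


def top_pathways(results: pd.DataFrame, n: int = 20,
                 category: str | None = "KEGG") -> pd.DataFrame:
    """First ``n`` sets by (p asc, enrichment score desc, set id) within a category."""
    df = results
    if category is not None and "category" in df.columns:
        df = df[df["category"] == category]
    df = df.sort_values(["fisher_p", "enrichment_score", "set_id"],
                        ascending=[True, False, True], ignore_index=True)
    return df.head(n).copy()


def subcellular_classify(proteins, gene_sets: GeneSetCollection) -> pd.DataFrame:
    """Tabulate proteins per subcellular compartment.

    A protein annotated to several compartments counts in each (so count
    fractions may exceed 1 when summed); proteins in ≥2 compartments and
    unannotated proteins are tallied under ``multi`` and ``unassigned``.
    """
    prots = _clean(proteins)
    compartments = gene_sets.by_category("SUBCELL")
    n = len(prots)
    membership: dict[str, int] = {p: 0 for p in prots}
    rows = []
    for gs in compartments:
        hits = set(gs.members) & prots
        for p in hits:
            membership[p] += 1
        rows.append({"compartment": gs.set_id, "name": gs.name,
                     "count": len(hits),
                     "fraction": len(hits) / n if n else 0.0})
    n_multi = sum(1 for v in membership.values() if v >= 2)
    n_unassigned = sum(1 for v in membership.values() if v == 0)
    rows.append({"compartment": "multi", "name": "in >=2 compartments",
                 "count": n_multi, "fraction": n_multi / n if n else 0.0})
    rows.append({"compartment": "unassigned", "name": "no compartment annotation",
                 "count": n_unassigned,
                 "fraction": n_unassigned / n if n else 0.0})
    return pd.DataFrame(rows, columns=["compartment", "name", "count", "fraction"])
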