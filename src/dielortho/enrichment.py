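"""GO over-representation (hypergeometric tail) and functional-category tags.

Classic one-sided hypergeometric over-representation of a study set against a
background of expressed, annotated genes, BH-corrected within each GO
namespace.  Fold-change-stratified study sets reproduce the common practice of
testing strongly day- or night-upregulated subsets separately.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import adjust_bh, select_stratum
from .io import GoTable


def hypergeom_enrich(
    study: Iterable[str],
    background: Iterable[str],
    go: GoTable,
    min_bg: int = 3,
    bh_scope: str = "namespace",
) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric p-values.

    For a term with K background hits, a study set of size n drawn from N
    background genes, and k study hits: p = P(X >= k), X ~
    Hypergeometric(N, K, n).  Terms with K < min_bg are skipped.  BH is
    applied within namespace ("namespace") or across all terms ("global").
    """
    study_set = set(study)
    bg_set = set(background)
    offenders = sorted(study_set - bg_set)
    if offenders:
        raise ValueError(f"study genes missing from background: {offenders[:10]}")
    if bh_scope not in ("namespace", "global"):
        raise ValueError("bh_scope must be 'namespace' or 'global'")

    rec = go.records[go.records["gene_id"].isin(bg_set)]
    N = len(bg_set)
    n = len(study_set)
    rows = []
    for (go_id, ns), sub in rec.groupby(["go_id", "go_namespace"], sort=True):
        genes = set(sub["gene_id"])
        K = len(genes)
        if K < min_bg:
            continue
        k = len(genes & study_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        rows.append(
            {
                "go_id": go_id,
                "go_namespace": ns,
                "category": go.category_map.get(go_id, "other"),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": min(p, 1.0),
                "fold": fold,
            }
        )
    out = pd.DataFrame(
        rows, columns=["go_id", "go_namespace", "category", "k", "n", "K", "N", "p", "fold"]
    )
    if out.empty:
        out["adj_p"] = pd.Series(dtype=float)
        return out
    if bh_scope == "global":
        out["adj_p"] = adjust_bh(out["p"].to_numpy())
    else:
        out["adj_p"] = np.nan
        for ns, idx in out.groupby("go_namespace").groups.items():
            out.loc[idx, "adj_p"] = adjust_bh(out.loc[idx, "p"].to_numpy())
    return out


def stratified_enrich(
    de: pd.DataFrame,
    strata: Sequence[str],
    background: Iterable[str],
    go: GoTable,
    gene_map: Mapping[str, str] | None = None,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Run enrichment for each fold-change window over significant genes.

    Windows are strings like "<=-5", ">=5", ">=2" (log2 units).  ``gene_map``
    optionally translates DE gene ids (transcripts) to the annotation
    namespace (reference genes).  Each result carries a ``study_size``
    attribute entry in the returned dict as (window -> DataFrame).
    """
    bg = set(background)
    results: dict[str, pd.DataFrame] = {}
    for window in strata:
        selected = select_stratum(de, window)["gene_id"]
        if gene_map is not None:
            study = {gene_map[g] for g in selected if g in gene_map}
        else:
            study = set(selected)
        study &= bg
        res = hypergeom_enrich(study, bg, go, **kwargs)
        res.attrs["study_size"] = len(study)
        res.attrs["window"] = window
        results[window] = res
    return results


def tag_functional_categories(
    genes: Iterable[str], go: GoTable
) -> dict[str, set[str]]:
    """Per gene, the union of functional categories of its GO terms; genes
    with none are tagged {"other"}."""
    out: dict[str, set[str]] = {}
    for g in genes:
        cats = go.categories_for_gene(g)
        out[g] = cats if cats else {"other"}
    return out
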