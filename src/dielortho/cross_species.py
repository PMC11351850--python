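"""Ortholog collapse, expression-pattern classification and candidate ranking.

The central procedure: per-species DE tables are collapsed onto shared
reference genes through the ortholog map, each shared gene is classified by
the signs and significance of its two fold changes (concordant, flipped,
single-species-strong), flips are checked for diel coincidence (day-up in the
diurnal species and night-up in the nocturnal one), and candidates are ranked
by three criteria: differentially expressed in both species, diel-coincident,
and annotated to a sensory/circadian functional category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GoTable, SampleDesign, FUNCTIONAL_CATEGORIES
from .orthology import OrthologMap

PATTERNS = (
    "concordant_day",
    "concordant_night",
    "flipped",
    "single_species_strong",
    "not_shared",
)


def collapse_to_reference(
    de_tables: Mapping[str, pd.DataFrame],
    omap: OrthologMap,
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Attach each transcript's DE result to its reference gene.

    When several transcripts of one species hit the same reference gene, the
    one with the smallest adjusted p is kept (ties: largest |log2fc|, then
    smallest transcript id).  Returns a wide table indexed by reference gene
    with per-species columns (log2fc_<sp>, adj_p_<sp>, significant_<sp>,
    transcript_<sp>) and a per-species report of mapped/unmapped transcript
    counts and collapse multiplicity.
    """
    species = sorted(de_tables)
    per_species_best: dict[str, pd.DataFrame] = {}
    report: dict[str, dict[str, int]] = {}
    for sp in species:
        de = de_tables[sp].copy()
        tmap = omap.by_species.get(sp, {})
        de["ref_gene"] = de["gene_id"].map(tmap)
        unmapped = int(de["ref_gene"].isna().sum())
        mapped = de.dropna(subset=["ref_gene"]).copy()
        mapped["abs_lfc"] = mapped["log2fc"].abs()
        mapped = mapped.sort_values(
            ["ref_gene", "adj_p", "abs_lfc", "gene_id"],
            ascending=[True, True, False, True],
            kind="stable",
        )
        best = mapped.drop_duplicates(subset="ref_gene", keep="first").set_index("ref_gene")
        report[sp] = {
            "n_transcripts": len(de),
            "n_mapped": len(mapped),
            "n_unmapped": unmapped,
            "n_reference_genes": len(best),
        }
        per_species_best[sp] = best

    all_refs = sorted(set().union(*(b.index for b in per_species_best.values())))
    out = pd.DataFrame(index=pd.Index(all_refs, name="ref_gene"))
    for sp in species:
        best = per_species_best[sp]
        out[f"log2fc_{sp}"] = best["log2fc"]
        out[f"adj_p_{sp}"] = best["adj_p"]
        if "log10_adj_p" in best.columns:
            out[f"log10_adj_p_{sp}"] = best["log10_adj_p"]
        sig = best["significant"].reindex(all_refs)
        out[f"significant_{sp}"] = sig.notna() & (sig == True)  # noqa: E712
        out[f"transcript_{sp}"] = best["gene_id"]
    return out, report


def classify_pattern(
    lfc_a: float,
    sig_a: bool,
    lfc_b: float,
    sig_b: bool,
    strong_lfc: float = 5.0,
) -> str:
    """Cross-species expression pattern for one reference gene.

    Both significant and same sign -> concordant (night if both positive);
    both significant and opposite signs -> flipped; significant in exactly one
    species with |log2fc| >= strong_lfc -> single_species_strong; otherwise
    not_shared.
    """
    a_val = 0.0 if lfc_a is None or np.isnan(lfc_a) else lfc_a
    b_val = 0.0 if lfc_b is None or np.isnan(lfc_b) else lfc_b
    if sig_a and sig_b:
        if a_val * b_val < 0:
            return "flipped"
        if a_val > 0 and b_val > 0:
            return "concordant_night"
        if a_val < 0 and b_val < 0:
            return "concordant_day"
        return "not_shared"  # a zero fold change cannot be oriented
    if sig_a != sig_b:
        lone = a_val if sig_a else b_val
        if abs(lone) >= strong_lfc:
            return "single_species_strong"
    return "not_shared"


def diel_coincidence(
    lfc_by_species: Mapping[str, float],
    niche_by_species: Mapping[str, str],
) -> tuple[bool, str]:
    """True iff each species' fold-change sign matches its activity phase:
    negative (day-up) in the diurnal species, positive (night-up) in the
    nocturnal one.  Returns (flag, note); a zero or missing fold change makes
    the call undefined (False, "undefined")."""
    for sp, lfc in lfc_by_species.items():
        if lfc is None or np.isnan(lfc) or lfc == 0.0:
            return False, "undefined"
    for sp, lfc in lfc_by_species.items():
        niche = niche_by_species[sp]
        if niche == "diurnal" and lfc >= 0:
            return False, ""
        if niche == "nocturnal" and lfc <= 0:
            return False, ""
    return True, ""


def rest_phase_coincidence(
    lfc_by_species: Mapping[str, float],
    niche_by_species: Mapping[str, str],
) -> tuple[bool, str]:
    """The opposite reading (rest-phase upregulation), for sensitivity
    analysis."""
    flipped = {sp: (None if v is None else -v) for sp, v in lfc_by_species.items()}
    return diel_coincidence(flipped, niche_by_species)


def build_flip_records(
    collapsed: pd.DataFrame,
    design: Sequence[SampleDesign],
    strong_lfc: float = 5.0,
    coincidence: str = "active",
) -> pd.DataFrame:
    """Classify every collapsed reference gene and evaluate diel coincidence.

    Output columns: per-species lfc/adj_p/significant, pattern,
    diel_coincident, coincidence_note, min_adj_p, source.
    """
    niche = {s.species: s.activity_niche for s in design}
    species = sorted(
        {c.split("log2fc_", 1)[1] for c in collapsed.columns if c.startswith("log2fc_")}
    )
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species in collapsed table, got {species}")
    sp_a, sp_b = species
    coin_fn = diel_coincidence if coincidence == "active" else rest_phase_coincidence

    rows = []
    for ref, row in collapsed.iterrows():
        lfc_a, lfc_b = row[f"log2fc_{sp_a}"], row[f"log2fc_{sp_b}"]
        sig_a, sig_b = bool(row[f"significant_{sp_a}"]), bool(row[f"significant_{sp_b}"])
        pattern = classify_pattern(lfc_a, sig_a, lfc_b, sig_b, strong_lfc)
        both_present = not (pd.isna(lfc_a) or pd.isna(lfc_b))
        if both_present:
            coincident, note = coin_fn(
                {sp_a: lfc_a, sp_b: lfc_b}, {sp_a: niche[sp_a], sp_b: niche[sp_b]}
            )
        else:
            coincident, note = False, "undefined"
        adj_ps = [row[f"adj_p_{sp}"] for sp in species if not pd.isna(row[f"adj_p_{sp}"])]
        log_adj = []
        for sp in species:
            col = f"log10_adj_p_{sp}"
            if col in row.index and not pd.isna(row[col]):
                log_adj.append(row[col])
            elif not pd.isna(row[f"adj_p_{sp}"]):
                log_adj.append(np.log10(max(row[f"adj_p_{sp}"], 1e-300)))
        rows.append(
            {
                "ref_gene": ref,
                f"log2fc_{sp_a}": lfc_a,
                f"adj_p_{sp_a}": row[f"adj_p_{sp_a}"],
                f"significant_{sp_a}": sig_a,
                f"log2fc_{sp_b}": lfc_b,
                f"adj_p_{sp_b}": row[f"adj_p_{sp_b}"],
                f"significant_{sp_b}": sig_b,
                "pattern": pattern,
                "diel_coincident": coincident,
                "coincidence_note": note,
                "min_adj_p": min(adj_ps) if adj_ps else np.nan,
                "evidence": sum(log_adj) if log_adj else 0.0,
                "source": "reference_collapse",
            }
        )
    return pd.DataFrame(rows).set_index("ref_gene")


def ortholog_pair_de(
    de_tables: Mapping[str, pd.DataFrame],
    omap: OrthologMap,
    design: Sequence[SampleDesign],
    strong_lfc: float = 5.0,
    coincidence: str = "active",
) -> pd.DataFrame:
    """Flip records from direct cross-species transcript pairs where both
    transcripts are significant, without requiring a reference-gene anchor.

    Rows are indexed by the reference gene when both transcripts map to one,
    otherwise by a pair id "<tA>|<tB>".
    """
    niche = {s.species: s.activity_niche for s in design}
    coin_fn = diel_coincidence if coincidence == "active" else rest_phase_coincidence
    indexed = {sp: t.set_index("gene_id") for sp, t in de_tables.items()}

    rows = []
    for (s1, t1, s2, t2) in sorted(omap.pairwise):
        if s1 not in indexed or s2 not in indexed:
            continue
        if t1 not in indexed[s1].index or t2 not in indexed[s2].index:
            continue
        r1, r2 = indexed[s1].loc[t1], indexed[s2].loc[t2]
        if not (bool(r1["significant"]) and bool(r2["significant"])):
            continue
        ref1 = omap.reference_for(s1, t1)
        ref2 = omap.reference_for(s2, t2)
        ref = ref1 if (ref1 is not None and ref1 == ref2) else None
        pattern = classify_pattern(
            r1["log2fc"], True, r2["log2fc"], True, strong_lfc
        )
        coincident, note = coin_fn(
            {s1: r1["log2fc"], s2: r2["log2fc"]},
            {s1: niche[s1], s2: niche[s2]},
        )
        log_adj = [
            r[ "log10_adj_p"] if "log10_adj_p" in r.index and not pd.isna(r["log10_adj_p"])
            else np.log10(max(r["adj_p"], 1e-300))
            for r in (r1, r2)
        ]
        rows.append(
            {
                "ref_gene": ref if ref is not None else f"{t1}|{t2}",
                f"log2fc_{s1}": r1["log2fc"],
                f"adj_p_{s1}": r1["adj_p"],
                f"significant_{s1}": True,
                f"log2fc_{s2}": r2["log2fc"],
                f"adj_p_{s2}": r2["adj_p"],
                f"significant_{s2}": True,
                "pattern": pattern,
                "diel_coincident": coincident,
                "coincidence_note": note,
                "min_adj_p": min(r1["adj_p"], r2["adj_p"]),
                "evidence": sum(log_adj),
                "source": "ortholog_pair",
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.set_index("ref_gene")


def merge_flip_records(collapse_records: pd.DataFrame, pair_records: pd.DataFrame) -> pd.DataFrame:
    """Union of the two record sources, de-duplicated by reference gene; a
    gene found by both routes keeps the collapse row with source
    "reference_collapse+ortholog_pair"."""
    if pair_records.empty:
        return collapse_records
    merged = collapse_records.copy()
    overlap = merged.index.intersection(pair_records.index)
    merged.loc[overlap, "source"] = "reference_collapse+ortholog_pair"
    extra = pair_records.loc[~pair_records.index.isin(merged.index)]
    return pd.concat([merged, extra])


def rank_candidates(
    records: pd.DataFrame,
    go: GoTable,
    categories: Sequence[str] = FUNCTIONAL_CATEGORIES,
) -> pd.DataFrame:
    """Score each record on the three candidate criteria and rank.

    (i) de_in_both — significant in both species (pattern concordant or
    flipped); (ii) diel_coincident; (iii) functional_category_hit — any GO
    term in the sensory/circadian categories.  score = number of true
    criteria; sorted by score descending, then min adjusted p ascending, then
    largest |log2fc| descending (adjusted p-values underflow to 0 for very
    strong effects, so the fold change breaks those ties), then gene id.
    """
    cats = set(categories)
    lfc_cols = [c for c in records.columns if c.startswith("log2fc_")]
    rows = []
    for ref, row in records.iterrows():
        de_in_both = row["pattern"] in ("concordant_day", "concordant_night", "flipped")
        gene_cats = go.categories_for_gene(ref) & cats
        functional = len(gene_cats) > 0
        score = int(de_in_both) + int(bool(row["diel_coincident"])) + int(functional)
        abs_lfcs = [abs(row[c]) for c in lfc_cols if not pd.isna(row[c])]
        rows.append(
            {
                "ref_gene": ref,
                "de_in_both": de_in_both,
                "diel_coincident": bool(row["diel_coincident"]),
                "functional_category_hit": functional,
                "categories": ",".join(sorted(gene_cats)),
                "score": score,
                "min_adj_p": row["min_adj_p"],
                "evidence": row.get("evidence", 0.0),
                "max_abs_lfc": max(abs_lfcs) if abs_lfcs else 0.0,
                "pattern": row["pattern"],
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out = out.sort_values(
        ["score", "evidence", "max_abs_lfc", "ref_gene"],
        ascending=[False, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
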