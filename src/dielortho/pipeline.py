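"""End-to-end orchestration on synthetic data, plus evaluation against truth.

Stage order: simulate -> TPM filter -> normalize -> DE (exact and Wald per
species) -> orthology (sequence RBH, or the planted map) -> collapse to
reference genes -> pattern classification and diel coincidence -> candidate
ranking with GO categories -> enrichment -> co-expression network ->
conservation profile.  Every stage's wall time and warnings land in the run
manifest; written files are digested so identical configs give identical
digests for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import cross_species as xs
from . import de as de_mod
from .coexpression import CoexpressionNetwork, preprocess_expression
from .conservation import (
    block_jaccard,
    column_conservation,
    find_blocks,
    focal_mutations,
)
from .enrichment import hypergeom_enrich
from .io import CountMatrix, GoTable, SampleDesign, filter_low_expression
from .orthology import OrthologMap, build_orthogroups, orthogroups_to_frame
from .simulate import SimBundle, SimConfig, TruthTable, simulate_all


@dataclass(frozen=True)
class PipelineParams:
    """Knobs for the analysis stages (the simulation itself is SimConfig)."""

    alpha: float = 0.05
    lfc_min: float = 2.0
    strong_lfc: float = 5.0
    normalizer: str = "tmm"
    de_method: str = "consensus"  # exact | wald | consensus
    orthology: str = "rbh"  # rbh | truth
    power: int | str = "auto"
    network_type: str = "signed"
    min_module_size: int = 10
    cut_height: float = 0.85
    kme_min: float = 0.8
    tau: float = 0.8
    min_block: int = 30
    coincidence: str = "active"
    run_network: bool = True
    run_conservation: bool = True
    run_enrichment: bool = True
    tpm_filter: bool = True
    tpm_threshold: float = 1.0


@dataclass
class EvaluationReport:
    """Detection quality against the planted truth; rates in [0, 1], None
    where undefined (e.g. precision with zero detections)."""

    flip_sensitivity: float | None = None
    flip_precision: float | None = None
    candidate_rank_key_gene: int | None = None
    module_ari: float | None = None
    enrichment_detected: bool | None = None
    enrichment_min_adj_p: float | None = None
    block_jaccard_score: float | None = None
    focal_mutations_total: int | None = None
    focal_mutations_in_block: int | None = None


@dataclass
class PipelineResult:
    bundle: SimBundle
    params: PipelineParams
    de_tables: dict[str, dict[str, pd.DataFrame]]
    consensus: dict[str, set[str]]
    omap: OrthologMap
    orthogroups: pd.DataFrame
    collapsed: pd.DataFrame
    collapse_report: dict
    flips: pd.DataFrame
    candidates: pd.DataFrame
    enrichment: pd.DataFrame | None
    network: CoexpressionNetwork | None
    profile: object | None
    mutation_overlap: object | None
    report: EvaluationReport
    manifest: dict


def _truth_orthomap(bundle: SimBundle) -> OrthologMap:
    omap = OrthologMap(by_species={sp: dict(m) for sp, m in bundle.orthology.transcript_map.items()})
    sp_a, sp_b = bundle.config.species
    for ta, tb in bundle.orthology.one_to_one_pairs:
        first, second = sorted([(sp_a, ta), (sp_b, tb)])
        omap.pairwise.add((first[0], first[1], second[0], second[1]))
    return omap


def run_pipeline(
    cfg: SimConfig,
    params: PipelineParams = PipelineParams(),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg, params),
        "stages": [],
        "warnings": [],
        "digests": {},
    }

    def stage(name):
        return _StageTimer(name, manifest)

    with stage("simulate"):
        bundle = simulate_all(cfg)

    with stage("filter"):
        counts: dict[str, CountMatrix] = {}
        for sp, m in bundle.counts.items():
            if params.tpm_filter:
                kept, dropped = filter_low_expression(
                    m, params.tpm_threshold, zero_sample_policy="zero"
                )
                counts[sp] = kept
                manifest["warnings"].append(f"{sp}: dropped {len(dropped)} low-TPM transcripts")
            else:
                counts[sp] = m

    with stage("de"):
        de_tables: dict[str, dict[str, pd.DataFrame]] = {}
        factors: dict[str, de_mod.NormFactors] = {}
        consensus: dict[str, set[str]] = {}
        for sp, m in counts.items():
            if params.normalizer == "tmm":
                fac = de_mod.normalize_tmm(m)
            elif params.normalizer == "median_ratio":
                fac = de_mod.normalize_median_ratio(m)
            else:
                raise ValueError(f"unknown normalizer {params.normalizer!r}")
            factors[sp] = fac
            phi = de_mod.estimate_dispersion(m, fac)
            exact = de_mod.exact_test(m, fac, phi, alpha=params.alpha, lfc_min=params.lfc_min)
            wald = de_mod.wald_test(m, fac, phi, alpha=params.alpha, lfc_min=params.lfc_min)
            shared, sizes = de_mod.method_consensus(exact, wald)
            de_tables[sp] = {"exact": exact, "wald": wald}
            consensus[sp] = shared
            manifest["warnings"].append(f"{sp}: consensus sizes {sizes}")

    with stage("orthology"):
        if params.orthology == "truth":
            omap = _truth_orthomap(bundle)
            groups_frame = pd.DataFrame()
        else:
            groups, omap, log = build_orthogroups(
                bundle.orthology.ref_proteome, bundle.orthology.proteomes
            )
            groups_frame = orthogroups_to_frame(groups)
            manifest["warnings"].extend(log)

    with stage("compare"):
        primary = {}
        for sp in counts:
            method = params.de_method if params.de_method != "consensus" else "exact"
            table = de_tables[sp][method].copy()
            if params.de_method == "consensus":
                table["significant"] = table["significant"] & table["gene_id"].isin(
                    consensus[sp]
                )
            primary[sp] = table
        collapsed, collapse_report = xs.collapse_to_reference(primary, omap)
        flips = xs.build_flip_records(
            collapsed, bundle.design, params.strong_lfc, params.coincidence
        )
        pair_records = xs.ortholog_pair_de(
            primary, omap, bundle.design, params.strong_lfc, params.coincidence
        )
        flips = xs.merge_flip_records(flips, pair_records)

    with stage("candidates"):
        candidates = xs.rank_candidates(flips, bundle.go)

    enrichment_res = None
    if params.run_enrichment:
        with stage("enrichment"):
            annotated = set(bundle.go.records["gene_id"])
            expressed = set(collapsed.index)
            background = expressed & annotated
            flipped_genes = set(flips.index[flips["pattern"] == "flipped"]) & background
            enrichment_res = hypergeom_enrich(flipped_genes, background, bundle.go)

    network = None
    if params.run_network:
        with stage("network"):
            expr, dropped = preprocess_expression(
                counts,
                factors,
                combined=True,
                gene_map=omap.by_species,
                shared_genes_only=True,
            )
            if dropped:
                manifest["warnings"].append(f"network: dropped {len(dropped)} constant genes")
            network = CoexpressionNetwork(
                power=params.power,
                network_type=params.network_type,
                min_module_size=params.min_module_size,
                cut_height=params.cut_height,
                kme_min=params.kme_min,
            )
            network.fit(expr, design=bundle.design)

    profile = None
    overlap = None
    if params.run_conservation:
        with stage("conservation"):
            profile = column_conservation(bundle.msa, reference_id="REF")
            find_blocks(profile, tau=params.tau, min_block=params.min_block)
            overlap = focal_mutations(bundle.msa, "FOCAL_A", "FOCAL_B", profile)

    with stage("evaluate"):
        report = evaluate_against_truth(
            truth=bundle.truth,
            flips=flips,
            candidates=candidates,
            network=network,
            enrichment=enrichment_res,
            profile=profile,
            overlap=overlap,
        )

    result = PipelineResult(
        bundle=bundle,
        params=params,
        de_tables=de_tables,
        consensus=consensus,
        omap=omap,
        orthogroups=groups_frame,
        collapsed=collapsed,
        collapse_report=collapse_report,
        flips=flips,
        candidates=candidates,
        enrichment=enrichment_res,
        network=network,
        profile=profile,
        mutation_overlap=overlap,
        report=report,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def evaluate_against_truth(
    truth: TruthTable,
    flips: pd.DataFrame | None = None,
    candidates: pd.DataFrame | None = None,
    network: CoexpressionNetwork | None = None,
    enrichment: pd.DataFrame | None = None,
    profile=None,
    overlap=None,
) -> EvaluationReport:
    """Join stage outputs to the planted truth.

    flip sensitivity = detected flips / planted flips at the reference-gene
    level; precision analogous (None when nothing was detected); module ARI
    over genes assigned to a non-grey module; enrichment detected = any
    planted circadian term at BH-adjusted p < 0.05.
    """
    report = EvaluationReport()
    planted = set(truth.genes_in_class("flipped_coincident")) | set(
        truth.genes_in_class("flipped_anticoincident")
    )
    if flips is not None and planted:
        detected = set(flips.index[flips["pattern"] == "flipped"])
        detected = {g for g in detected if "|" not in g}
        tp = len(detected & planted)
        report.flip_sensitivity = tp / len(planted)
        report.flip_precision = tp / len(detected) if detected else None

    if candidates is not None and len(candidates):
        keys = truth.genes.index[truth.genes["is_key_gene"]]
        if len(keys):
            hit = candidates[candidates["ref_gene"] == keys[0]]
            report.candidate_rank_key_gene = int(hit["rank"].iloc[0]) if len(hit) else None

    if network is not None:
        labels = network.labels_
        nongrey = labels.index[labels != "grey"]
        if len(nongrey):
            truth_mod = _planted_structure_labels(truth).reindex(nongrey).fillna("none")
            report.module_ari = float(
                adjusted_rand_score(truth_mod.to_numpy(), labels.loc[nongrey].to_numpy())
            )

    if enrichment is not None and len(enrichment):
        circadian = enrichment[enrichment["category"] == "circadian"]
        if len(circadian):
            report.enrichment_min_adj_p = float(circadian["adj_p"].min())
            report.enrichment_detected = bool((circadian["adj_p"] < 0.05).any())

    if profile is not None and truth.block_spans:
        report.block_jaccard_score = block_jaccard(profile.blocks, truth.block_spans)
    if overlap is not None:
        report.focal_mutations_total = overlap.n_total
        report.focal_mutations_in_block = overlap.n_in_block

    return report


def _planted_structure_labels(truth: TruthTable) -> pd.Series:
    """One label per reference gene covering every planted co-varying group:
    module ids, plus the DE classes (flipped / concordant / single-species
    genes share strong planted expression patterns and legitimately cluster
    together); everything else is "none"."""
    genes = truth.genes
    labels = []
    for ref, row in genes.iterrows():
        if row["module_id"]:
            labels.append(row["module_id"])
        elif row["de_class"] in ("flipped_coincident", "flipped_anticoincident"):
            labels.append("de_" + row["de_class"])
        elif row["de_class"].startswith("concordant"):
            labels.append("de_" + row["de_class"])
        elif row["de_class"] == "single_species":
            lfcs = {c: row[c] for c in genes.columns if c.startswith("true_lfc_")}
            sp = next((c for c, v in lfcs.items() if v != 0), "none")
            direction = "up" if lfcs.get(sp, 0) > 0 else "dn"
            labels.append(f"de_single_{sp}_{direction}")
        else:
            labels.append("none")
    return pd.Series(labels, index=genes.index)


class _StageTimer:
    def __init__(self, name: str, manifest: dict):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.catcher = warnings.catch_warnings(record=True)
        self.records = self.catcher.__enter__()
        warnings.simplefilter("always")
        return self

    def __exit__(self, exc_type, exc, tb):
        self.catcher.__exit__(exc_type, exc, tb)
        if exc_type is not None:
            self.manifest["stages"].append(
                {"name": self.name, "seconds": time.perf_counter() - self.t0, "failed": True}
            )
            raise RuntimeError(f"pipeline stage {self.name!r} failed") from exc
        for w in self.records:
            self.manifest["warnings"].append(f"{self.name}: {w.message}")
        self.manifest["stages"].append(
            {"name": self.name, "seconds": round(time.perf_counter() - self.t0, 3)}
        )
        return False


def _config_hash(cfg: SimConfig, params: PipelineParams) -> str:
    payload = json.dumps(
        {"sim": asdict(cfg), "params": asdict(params)}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    from .io import write_counts, write_design, write_go
    from .conservation import write_msa

    out_dir.mkdir(parents=True, exist_ok=True)
    for sp, m in result.bundle.counts.items():
        write_counts(m, out_dir / f"counts_{sp}.tsv")
    write_design(result.bundle.design, out_dir / "samples.tsv")
    write_go(result.bundle.go, out_dir / "go.tsv", out_dir / "go_categories.tsv")
    write_msa(result.bundle.msa, out_dir / "family.afa")
    for sp, tables in result.de_tables.items():
        for method, df in tables.items():
            df.to_csv(out_dir / f"de_{sp}_{method}.tsv", sep="\t", index=False)
    if len(result.orthogroups):
        result.orthogroups.to_csv(out_dir / "orthogroups.tsv", sep="\t", index=False)
    result.flips.to_csv(out_dir / "flips.tsv", sep="\t")
    result.candidates.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    if result.network is not None:
        result.network.labels_.rename("module").to_csv(out_dir / "modules.tsv", sep="\t")
        result.network.eigengenes_.to_csv(out_dir / "eigengenes.tsv", sep="\t")
        result.network.trait_table_.to_csv(out_dir / "module_trait.tsv", sep="\t", index=False)
    if result.profile is not None:
        result.profile.to_frame().to_csv(out_dir / "conservation.tsv", sep="\t", index=False)
    truth_path = out_dir / "truth.tsv"
    result.bundle.truth.genes.to_csv(truth_path, sep="\t")
    report_path = out_dir / "evaluation.json"
    report_path.write_text(json.dumps(asdict(result.report), indent=2, default=str))
    for path in sorted(out_dir.iterdir()):
        if path.is_file():
            result.manifest["digests"][path.name] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()[:16]
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
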