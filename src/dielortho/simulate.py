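"""Synthetic two-species day-night transcriptome generator with planted truth.

Emulates the study design the pipeline targets: two closely related species
with opposite diel niches (one diurnal, one nocturnal), sampled at midday and
midnight with three replicates per species x phase, counts drawn from a
negative-binomial model.  On top of the null background it plants:

* differential-expression classes — coincident flips (day-up in the diurnal
  species, night-up in the nocturnal one), anticoincident flips, concordant
  day/night genes, and single-species responders;
* one "key" candidate gene: a coincident flip with a larger effect and a
  guaranteed circadian GO annotation, emulating a headline sensory/circadian
  candidate;
* an orthology structure anchored to a reference proteome (1:1, many-to-1 and
  species-specific transcripts) with mutated protein copies so that
  reciprocal-best-hit search can recover the map from sequence alone;
* co-expression modules (species-specific, diel-driven and shared latent);
* GO annotations with controlled circadian enrichment among flipped genes;
* a gap-free protein-family alignment with conserved blocks and a controlled
  number of focal-pair mutations inside/outside the blocks.

Everything is deterministic under a fixed seed: each sub-generator draws from
its own child stream of the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GoTable, SampleDesign, FUNCTIONAL_CATEGORIES

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DE_CLASSES = (
    "flipped_coincident",
    "flipped_anticoincident",
    "concordant_day",
    "concordant_night",
    "single_species",
    "null",
)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class ProteinConfig:
    """Protein-family simulator: conserved blocks and focal-pair mutations."""

    ref_length: int = 400
    block_spans: tuple[tuple[int, int], ...] = ((100, 210),)
    in_block_sub_rate: float = 0.02
    out_block_sub_rate: float = 0.30
    n_species: int = 18
    focal_mut_in_block: int = 3
    focal_mut_out_block: int = 20


@dataclass(frozen=True)
class SimConfig:
    """Full study-condition description; defaults are the conditions the
    pipeline is validated under."""

    seed: int = 0
    n_ref_genes: int = 2000
    # orthology class proportions (must sum to 1)
    frac_one_to_one: float = 0.8
    frac_many_to_one: float = 0.1
    frac_species_specific: float = 0.1
    # design
    species: tuple[str, str] = ("AN", "DR")
    niches: tuple[str, str] = ("diurnal", "nocturnal")
    n_replicates: int = 3
    # count model
    baseline_log_mean: float = 4.5
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1
    lib_size_mean: float = 1.0
    lib_size_cv: float = 0.2
    # planted DE
    n_flipped: int = 50
    n_flipped_anti: int = 0
    n_concordant: int = 30
    n_single_species: int = 20
    planted_lfc: float = 6.0
    key_gene: bool = True
    key_gene_lfc: float = 12.0
    key_gene_log_mean: float = 6.0  # robustly expressed, not left to the lottery
    # modules
    n_modules: int = 4
    module_size: int = 50
    module_noise_sd: float = 0.3
    module_amplitude: float = 1.5
    module_kinds: tuple[str, ...] = ("species", "species", "diel", "shared")
    module_factor_jitter: float = 0.3
    secondary_mu_sd: float = 0.3
    # GO planting
    n_go_per_category: int = 3
    n_go_other: int = 12
    go_base_rate: float = 0.02
    go_enrich_factor: float = 10.0
    # orthology proteins
    orth_protein_length: int = 120
    orth_sub_rate: float = 0.05
    orth_secondary_sub_rate: float = 0.10
    # protein family
    protein: ProteinConfig = field(default_factory=ProteinConfig)

    def __post_init__(self) -> None:
        fracs = (self.frac_one_to_one, self.frac_many_to_one, self.frac_species_specific)
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("orthology class proportions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"orthology class proportions sum to {sum(fracs)}, not 1")
        n_de = self.n_flipped + self.n_flipped_anti + self.n_concordant + self.n_single_species
        n_one = round(self.frac_one_to_one * self.n_ref_genes)
        if n_de + self.n_modules * self.module_size > n_one:
            raise ConfigError(
                "planted DE genes plus module genes exceed the available "
                f"one-to-one genes ({n_one})"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        p = self.protein
        spans = sorted(p.block_spans)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ConfigError("block_spans must be non-overlapping")
        if spans and (spans[0][0] < 0 or spans[-1][1] > p.ref_length):
            raise ConfigError("block_spans must lie within ref_length")
        n_in = sum(e - s for s, e in p.block_spans)
        if p.focal_mut_in_block > n_in:
            raise ConfigError("focal_mut_in_block exceeds in-block columns")
        if p.focal_mut_out_block > p.ref_length - n_in:
            raise ConfigError("focal_mut_out_block exceeds out-of-block columns")
        if len(self.module_kinds) != self.n_modules:
            raise ConfigError("module_kinds must have n_modules entries")


@dataclass
class TruthTable:
    """Planted ground truth: one row per reference gene, plus the protein
    family's block spans and focal mutation columns."""

    genes: pd.DataFrame  # index ref_gene; de_class, true_lfc_<sp>, module_id, is_key_gene
    block_spans: tuple[tuple[int, int], ...] = ()
    focal_in_block_columns: tuple[int, ...] = ()
    focal_out_block_columns: tuple[int, ...] = ()

    def class_counts(self) -> dict[str, int]:
        return self.genes["de_class"].value_counts().to_dict()

    def genes_in_class(self, de_class: str) -> list[str]:
        return self.genes.index[self.genes["de_class"] == de_class].tolist()


@dataclass
class OrthologySim:
    """Planted transcript -> reference map and the mutated proteomes."""

    transcript_map: dict[str, dict[str, str]]  # species -> transcript -> ref gene
    proteomes: dict[str, dict[str, str]]  # species -> transcript -> protein
    ref_proteome: dict[str, str]
    one_to_one_pairs: set[tuple[str, str]]  # planted (speciesA, speciesB) transcript pairs


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# planted structure shared by all generators
# ---------------------------------------------------------------------------

def _plant(cfg: SimConfig) -> tuple[pd.DataFrame, dict[str, list[tuple[str, str]]]]:
    """Assign every reference gene an orthology class, a DE class, per-species
    true log2 fold changes and a module id; derive the transcript lists.

    Returns the truth gene table and, per species, the ordered list of
    (transcript_id, ref_gene) tuples.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_ref_genes
    ref_genes = [f"BM{i:05d}" for i in range(n)]

    n_ss = round(cfg.frac_species_specific * n)
    n_m1 = round(cfg.frac_many_to_one * n)
    order = rng.permutation(n)
    orth_class = np.full(n, "one_to_one", dtype=object)
    orth_class[order[:n_ss]] = "species_specific"
    orth_class[order[n_ss : n_ss + n_m1]] = "many_to_one"

    sp_a, sp_b = cfg.species
    one_idx = np.flatnonzero(orth_class == "one_to_one")
    one_idx = one_idx[rng.permutation(len(one_idx))]

    de_class = np.full(n, "null", dtype=object)
    lfc = {sp: np.zeros(n) for sp in cfg.species}
    is_key = np.zeros(n, dtype=bool)
    half = cfg.planted_lfc / 2.0
    diurnal_sp = cfg.species[cfg.niches.index("diurnal")]
    nocturnal_sp = cfg.species[cfg.niches.index("nocturnal")]

    pos = 0
    flip_idx = one_idx[pos : pos + cfg.n_flipped]
    pos += cfg.n_flipped
    for j, gi in enumerate(flip_idx):
        de_class[gi] = "flipped_coincident"
        h = cfg.key_gene_lfc / 2.0 if (cfg.key_gene and j == 0) else half
        lfc[diurnal_sp][gi] = -h
        lfc[nocturnal_sp][gi] = +h
        if cfg.key_gene and j == 0:
            is_key[gi] = True

    anti_idx = one_idx[pos : pos + cfg.n_flipped_anti]
    pos += cfg.n_flipped_anti
    for gi in anti_idx:
        de_class[gi] = "flipped_anticoincident"
        lfc[diurnal_sp][gi] = +half
        lfc[nocturnal_sp][gi] = -half

    conc_idx = one_idx[pos : pos + cfg.n_concordant]
    pos += cfg.n_concordant
    for j, gi in enumerate(conc_idx):
        sign = -1.0 if j < len(conc_idx) // 2 else +1.0
        de_class[gi] = "concordant_day" if sign < 0 else "concordant_night"
        lfc[sp_a][gi] = sign * half
        lfc[sp_b][gi] = sign * half

    single_idx = one_idx[pos : pos + cfg.n_single_species]
    pos += cfg.n_single_species
    for j, gi in enumerate(single_idx):
        de_class[gi] = "single_species"
        sp = cfg.species[j % 2]
        lfc[sp][gi] = cfg.planted_lfc * (1.0 if rng.random() < 0.5 else -1.0)

    module_id = np.full(n, "", dtype=object)
    for k in range(cfg.n_modules):
        mod_idx = one_idx[pos : pos + cfg.module_size]
        pos += cfg.module_size
        module_id[mod_idx] = f"M{k + 1}"

    genes = pd.DataFrame(
        {
            "orth_class": orth_class,
            "de_class": de_class,
            **{f"true_lfc_{sp}": lfc[sp] for sp in cfg.species},
            "module_id": module_id,
            "is_key_gene": is_key,
        },
        index=pd.Index(ref_genes, name="ref_gene"),
    )

    # transcript structure: one_to_one -> 1 per species; many_to_one -> 2 in
    # one species, 1 in the other; species_specific -> 1 in one species only
    t_rng = _rng(cfg, 1)
    per_species: dict[str, list[tuple[str, str]]] = {sp: [] for sp in cfg.species}
    for gi, ref in enumerate(ref_genes):
        cls = orth_class[gi]
        if cls == "one_to_one":
            for sp in cfg.species:
                per_species[sp].append((ref, "primary"))
        elif cls == "many_to_one":
            doubled = cfg.species[int(t_rng.integers(2))]
            for sp in cfg.species:
                per_species[sp].append((ref, "primary"))
                if sp == doubled:
                    per_species[sp].append((ref, "secondary"))
        else:  # species_specific
            sp = cfg.species[int(t_rng.integers(2))]
            per_species[sp].append((ref, "primary"))

    named: dict[str, list[tuple[str, str]]] = {}
    for sp in cfg.species:
        entries = per_species[sp]
        shuffle = t_rng.permutation(len(entries))
        names = {int(k): f"{sp}_t{i:06d}" for i, k in enumerate(shuffle)}
        named[sp] = [(names[i], entries[i][0]) for i in range(len(entries))]
    return genes, named


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each position with a different residue at the given rate."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def simulate_counts(
    cfg: SimConfig,
) -> tuple[dict[str, CountMatrix], list[SampleDesign], TruthTable]:
    """Draw negative-binomial count matrices for both species.

    counts[g, s] ~ NB(mean = lib_s * mu_g * 2^(lfc/2 * phase_sign) *
    module_effect, variance = mu + dispersion * mu^2), phase_sign +1 at night.
    """
    genes, transcripts = _plant(cfg)
    rng = _rng(cfg, 2)

    designs: list[SampleDesign] = []
    per_species_design: dict[str, list[SampleDesign]] = {}
    for sp, niche in zip(cfg.species, cfg.niches):
        rows = []
        for phase in ("day", "night"):
            for r in range(1, cfg.n_replicates + 1):
                rows.append(
                    SampleDesign(
                        sample_id=f"{sp}_{phase[0].upper()}{r}",
                        species=sp,
                        diel_phase=phase,
                        activity_niche=niche,
                        replicate=r,
                    )
                )
        per_species_design[sp] = rows
        designs.extend(rows)

    sigma2 = math.log(1.0 + cfg.lib_size_cv**2)
    matrices: dict[str, CountMatrix] = {}

    # per-sample module latent factors are drawn once per module over the full
    # combined design, so shared modules co-vary across species
    mod_rng = _rng(cfg, 3)
    module_factors: dict[str, dict[str, float]] = {}
    module_ids = sorted({m for m in genes["module_id"] if m})
    for mid, kind in zip(module_ids, cfg.module_kinds):
        factors: dict[str, float] = {}
        target_sp = cfg.species[(int(mid[1:]) - 1) % 2]
        for s in designs:
            if kind == "species":
                # elevated and co-varying in the target species, zero loading
                # in the other species
                if s.species == target_sp:
                    f = 1.0 + mod_rng.normal(0.0, cfg.module_factor_jitter)
                else:
                    f = 0.0
            elif kind == "diel":
                base = 0.5 if s.diel_phase == "night" else -0.5
                f = base + mod_rng.normal(0.0, cfg.module_factor_jitter)
            else:  # shared latent, scaled to match the other planted effects
                f = mod_rng.normal(0.0, 0.5)
            factors[s.sample_id] = f
        module_factors[mid] = factors

    # one baseline per reference gene, shared across species (orthologs keep
    # their expression level); secondary transcripts jitter around it
    mu_ref = {
        ref: float(np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd)))
        for ref in genes.index
    }
    for ref in genes.index[genes["is_key_gene"]]:
        mu_ref[ref] = float(np.exp(cfg.key_gene_log_mean))

    for sp in cfg.species:
        tlist = transcripts[sp]
        n_t = len(tlist)
        samples = per_species_design[sp]
        n_s = len(samples)

        mu_t = np.empty(n_t)
        seen: set[str] = set()
        for i, (_, ref) in enumerate(tlist):
            mu_t[i] = mu_ref[ref]
            if ref in seen:
                mu_t[i] *= float(np.exp(rng.normal(0.0, cfg.secondary_mu_sd)))
            seen.add(ref)
        lengths = rng.integers(500, 3001, size=n_t)
        libs = cfg.lib_size_mean * np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size=n_s))

        lfc_col = genes[f"true_lfc_{sp}"]
        lfc_t = np.array([lfc_col[ref] for _, ref in tlist])
        mod_t = np.array([genes.loc[ref, "module_id"] for _, ref in tlist], dtype=object)

        phase_sign = np.array([+1.0 if s.diel_phase == "night" else -1.0 for s in samples])
        mean = mu_t[:, None] * libs[None, :] * 2.0 ** (lfc_t[:, None] * phase_sign[None, :] / 2.0)

        has_mod = mod_t != ""
        if has_mod.any():
            fac = np.zeros((n_t, n_s))
            for i in np.flatnonzero(has_mod):
                f = module_factors[mod_t[i]]
                fac[i] = [f[s.sample_id] for s in samples]
            noise = rng.normal(0.0, cfg.module_noise_sd, size=(n_t, n_s))
            effect = np.exp(cfg.module_amplitude * fac + noise)
            effect[~has_mod] = 1.0
            mean = mean * effect

        if cfg.dispersion > 0:
            r = 1.0 / cfg.dispersion
            p = r / (r + mean)
            counts = rng.negative_binomial(r, p)
        else:
            counts = rng.poisson(mean)

        matrices[sp] = CountMatrix(
            gene_ids=[t for t, _ in tlist],
            samples=samples,
            counts=counts.astype(np.int64),
            lengths=lengths,
        )

    return matrices, designs, TruthTable(genes=genes)


def simulate_orthology(cfg: SimConfig) -> OrthologySim:
    """Emit the transcript -> reference map plus mutated protein copies.

    Every transcript's protein is a point-substituted copy of its reference
    gene's protein (secondary transcripts of many-to-one genes mutate at a
    higher rate), so sequence-based reciprocal-best-hit search can recover the
    planted map.
    """
    genes, transcripts = _plant(cfg)
    rng = _rng(cfg, 4)

    n = cfg.n_ref_genes
    ref_seqs = {
        ref: rng.choice(AMINO_ACIDS, size=cfg.orth_protein_length)
        for ref in genes.index
    }
    ref_proteome = {ref: "".join(s) for ref, s in ref_seqs.items()}

    transcript_map: dict[str, dict[str, str]] = {}
    proteomes: dict[str, dict[str, str]] = {}
    for sp in cfg.species:
        tmap: dict[str, str] = {}
        prot: dict[str, str] = {}
        seen_ref: set[str] = set()
        for tid, ref in transcripts[sp]:
            rate = cfg.orth_secondary_sub_rate if ref in seen_ref else cfg.orth_sub_rate
            seen_ref.add(ref)
            prot[tid] = "".join(_mutate(rng, ref_seqs[ref], rate))
            tmap[tid] = ref
        transcript_map[sp] = tmap
        proteomes[sp] = prot

    sp_a, sp_b = cfg.species
    inv_a = {ref: tid for tid, ref in transcripts[sp_a]}
    inv_b = {ref: tid for tid, ref in transcripts[sp_b]}
    pairs = {
        (inv_a[ref], inv_b[ref])
        for ref in genes.index[genes["orth_class"] == "one_to_one"]
    }
    return OrthologySim(
        transcript_map=transcript_map,
        proteomes=proteomes,
        ref_proteome=ref_proteome,
        one_to_one_pairs=pairs,
    )


def simulate_go(cfg: SimConfig, truth: TruthTable) -> GoTable:
    """Annotate reference genes with GO terms.

    Background genes receive every term at ``go_base_rate``; circadian-category
    terms hit flipped-coincident genes at ``go_enrich_factor`` times that rate.
    The key gene always carries a circadian term.
    """
    rng = _rng(cfg, 5)
    terms: list[tuple[str, str, str]] = []  # (go_id, namespace, category or "")
    counter = 1
    for cat in FUNCTIONAL_CATEGORIES:
        for _ in range(cfg.n_go_per_category):
            terms.append((f"GO:{counter:07d}", "BP", cat))
            counter += 1
    namespaces = ("BP", "MF", "CC")
    for j in range(cfg.n_go_other):
        terms.append((f"GO:{counter:07d}", namespaces[j % 3], ""))
        counter += 1

    flipped = set(truth.genes_in_class("flipped_coincident"))
    key_genes = truth.genes.index[truth.genes["is_key_gene"]].tolist()

    records = []
    for go_id, ns, cat in terms:
        enriched = cat == "circadian"
        for gene in truth.genes.index:
            rate = cfg.go_base_rate
            if enriched and gene in flipped:
                rate = min(1.0, cfg.go_enrich_factor * cfg.go_base_rate)
            if rng.random() < rate:
                records.append({"gene_id": gene, "go_id": go_id, "go_namespace": ns})
    first_circadian = next(g for g, _, c in terms if c == "circadian")
    for gene in key_genes:
        records.append({"gene_id": gene, "go_id": first_circadian, "go_namespace": "BP"})

    df = pd.DataFrame(records, columns=["gene_id", "go_id", "go_namespace"])
    df = df.drop_duplicates(subset=["gene_id", "go_id"]).reset_index(drop=True)
    category_map = {go_id: cat for go_id, _, cat in terms if cat}
    return GoTable(records=df, category_map=category_map)


def simulate_protein_family(cfg: SimConfig) -> tuple[dict[str, str], TruthTable]:
    """Simulate a gap-free protein-family alignment with conserved blocks.

    Columns inside the block spans substitute at ``in_block_sub_rate`` per
    sequence, outside at ``out_block_sub_rate``.  The two focal sequences
    differ at exactly focal_mut_in_block + focal_mut_out_block columns, placed
    accordingly.
    """
    p = cfg.protein
    rng = _rng(cfg, 6)
    ancestor = rng.choice(AMINO_ACIDS, size=p.ref_length)

    in_block = np.zeros(p.ref_length, dtype=bool)
    for s, e in p.block_spans:
        in_block[s:e] = True
    rates = np.where(in_block, p.in_block_sub_rate, p.out_block_sub_rate)

    def mutate_columns(seq: np.ndarray) -> np.ndarray:
        out = seq.copy()
        hit = rng.random(len(seq)) < rates
        for i in np.flatnonzero(hit):
            out[i] = rng.choice(AMINO_ACIDS[AMINO_ACIDS != out[i]])
        return out

    msa: dict[str, str] = {"REF": "".join(ancestor)}
    for i in range(2, p.n_species + 1):
        msa[f"SP{i:02d}"] = "".join(mutate_columns(ancestor))

    focal_a = mutate_columns(ancestor)
    in_cols = rng.choice(np.flatnonzero(in_block), size=p.focal_mut_in_block, replace=False)
    out_cols = rng.choice(np.flatnonzero(~in_block), size=p.focal_mut_out_block, replace=False)
    focal_b = focal_a.copy()
    for i in np.concatenate([in_cols, out_cols]).astype(int):
        focal_b[i] = rng.choice(AMINO_ACIDS[AMINO_ACIDS != focal_a[i]])
    msa["FOCAL_A"] = "".join(focal_a)
    msa["FOCAL_B"] = "".join(focal_b)

    truth = TruthTable(
        genes=pd.DataFrame(index=pd.Index([], name="ref_gene")),
        block_spans=tuple(tuple(b) for b in p.block_spans),
        focal_in_block_columns=tuple(sorted(int(c) for c in in_cols)),
        focal_out_block_columns=tuple(sorted(int(c) for c in out_cols)),
    )
    return msa, truth


@dataclass
class SimBundle:
    """Everything one simulated study provides."""

    config: SimConfig
    counts: dict[str, CountMatrix]
    design: list[SampleDesign]
    truth: TruthTable
    orthology: OrthologySim
    go: GoTable
    msa: dict[str, str]
    protein_truth: TruthTable


def simulate_all(cfg: SimConfig) -> SimBundle:
    """Run every generator under one config (each from its own seed stream)."""
    counts, design, truth = simulate_counts(cfg)
    orthology = simulate_orthology(cfg)
    go = simulate_go(cfg, truth)
    msa, protein_truth = simulate_protein_family(cfg)
    truth.block_spans = protein_truth.block_spans
    truth.focal_in_block_columns = protein_truth.focal_in_block_columns
    truth.focal_out_block_columns = protein_truth.focal_out_block_columns
    return SimBundle(
        config=cfg,
        counts=counts,
        design=design,
        truth=truth,
        orthology=orthology,
        go=go,
        msa=msa,
        protein_truth=protein_truth,
    )
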