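"""Weighted co-expression network: soft-threshold adjacency, topological
overlap, module detection, eigengenes and module-trait correlation.

The construction follows the standard weighted-network recipe: adjacency
a_ij = |cor|^beta (unsigned) or ((1+cor)/2)^beta (signed), topological overlap
TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), average-linkage
clustering on 1 - TOM with a static cut (a fixed fraction of the maximum merge
height), size-ordered color labels ("grey" = unassigned), and module
eigengenes as the first principal component of each module's standardized
expression.  The combined-species analysis concatenates both species' samples
over the shared annotated gene set, which is what exposes species-specific
modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin

from .de import NormFactors
from .io import CountMatrix, SampleDesign

#: size-ordered module color names, after the widely used convention
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue",
)
UNASSIGNED = "grey"


def preprocess_expression(
    matrices: Mapping[str, CountMatrix],
    factors: Mapping[str, NormFactors],
    combined: bool = True,
    gene_map: Mapping[str, Mapping[str, str]] | None = None,
    shared_genes_only: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """log2(normalized count + 1), z-scored per gene; samples x genes.

    With ``combined`` the two species' samples are concatenated over the
    shared gene set: ``gene_map`` (species -> transcript -> reference gene)
    collapses transcripts onto reference genes (best = first transcript kept
    per gene after sorting, deterministic), and only genes present in every
    species are retained when ``shared_genes_only``.  Constant genes are
    dropped and reported.
    """
    frames = []
    for sp in sorted(matrices):
        m = matrices[sp]
        z = m.counts / factors[sp].factors[None, :]
        expr = pd.DataFrame(
            np.log2(z + 1.0).T, index=m.sample_ids, columns=m.gene_ids
        )
        if gene_map is not None:
            tmap = gene_map.get(sp, {})
            keep = [g for g in expr.columns if g in tmap]
            expr = expr[keep]
            expr.columns = [tmap[g] for g in keep]
            expr = expr.loc[:, ~expr.columns.duplicated(keep="first")]
        frames.append(expr)

    if combined:
        if shared_genes_only and len(frames) > 1:
            shared = set(frames[0].columns)
            for f in frames[1:]:
                shared &= set(f.columns)
            order = [g for g in frames[0].columns if g in shared]
            frames = [f[order] for f in frames]
        expr = pd.concat(frames, axis=0, join="inner")
    else:
        if len(frames) != 1:
            raise ValueError("combined=False expects exactly one species")
        expr = frames[0]

    sd = expr.std(axis=0, ddof=0)
    dropped = sd.index[sd == 0].tolist()
    expr = expr.loc[:, sd > 0]
    expr = (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=0)
    return expr, dropped


def adjacency(expr: np.ndarray, power: int, network_type: str = "signed") -> np.ndarray:
    """Soft-threshold adjacency from Pearson correlations; zero diagonal."""
    cor = np.corrcoef(np.asarray(expr, dtype=float).T)
    cor = np.clip(cor, -1.0, 1.0)
    if network_type == "unsigned":
        a = np.abs(cor) ** power
    elif network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError("network_type must be 'unsigned' or 'signed'")
    np.fill_diagonal(a, 0.0)
    return a


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix from an adjacency; unit diagonal."""
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def adjacency_tom(
    expr: np.ndarray, power: int, network_type: str = "signed"
) -> np.ndarray:
    return tom_similarity(adjacency(expr, power, network_type))


def pick_soft_power(
    expr: np.ndarray,
    candidate_powers: Sequence[int] = tuple(range(1, 21)),
    network_type: str = "signed",
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Scale-free-topology criterion: smallest power whose connectivity
    distribution fits log10 p(k) ~ log10 k with R^2 >= target (and negative
    slope); falls back to the argmax R^2 with a warning."""
    rows = []
    for beta in candidate_powers:
        a = adjacency(expr, beta, network_type)
        k = a.sum(axis=1)
        r2, slope = _scale_free_r2(k, n_bins)
        rows.append({"power": beta, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[(table["r2"] >= r2_target) & (table["slope"] < 0)]
    if len(ok):
        return int(ok.iloc[0]["power"]), table
    warnings.warn("no candidate power reached the scale-free R^2 target; using argmax R^2")
    best = table.loc[(table["r2"] * np.sign(-table["slope"])).idxmax(), "power"]
    return int(best), table


def _scale_free_r2(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if len(k) < n_bins or k.max() == k.min():
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)  # equal-width bins
    edges[-1] += 1e-9
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / len(k)))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - pred) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2, float(slope)


def detect_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    min_module_size: int = 10,
    cut_height: float = 0.85,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut at
    ``cut_height`` x the maximum merge height; clusters below
    ``min_module_size`` become "grey"; surviving clusters get size-ordered
    color labels (ties broken by smallest member id)."""
    n = tom.shape[0]
    if n != len(gene_ids):
        raise ValueError("gene_ids must match the TOM dimension")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    max_h = Z[:, 2].max() if len(Z) else 0.0
    raw = fcluster(Z, t=cut_height * max_h, criterion="distance")

    labels = pd.Series([UNASSIGNED] * n, index=list(gene_ids), dtype=object)
    clusters = []
    for c in np.unique(raw):
        members = np.flatnonzero(raw == c)
        if len(members) >= min_module_size:
            clusters.append((len(members), min(gene_ids[i] for i in members), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for rank, (_, _, members) in enumerate(clusters):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[members] = color
    return labels


def prune_by_membership(
    expr: pd.DataFrame,
    labels: pd.Series,
    kme_min: float = 0.8,
    min_module_size: int = 10,
) -> pd.Series:
    """Module-membership (kME) pruning: genes whose correlation with their
    module's eigengene falls below ``kme_min`` are reassigned to grey, and
    modules dropping below ``min_module_size`` dissolve.  One pass; removes
    noise genes that a static tree cut attaches to real modules."""
    labels = labels.copy()
    eig = module_eigengenes(expr, labels)
    for mod in list(eig.index):
        members = labels.index[labels == mod]
        e = eig.loc[mod].to_numpy(dtype=float)
        for g in members:
            c = np.corrcoef(e, expr[g].to_numpy(dtype=float))[0, 1]
            if not np.isfinite(c) or c < kme_min:
                labels.loc[g] = UNASSIGNED
        if (labels == mod).sum() < min_module_size:
            labels.loc[labels == mod] = UNASSIGNED
    return _relabel_by_size(labels)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    clusters = []
    for mod in set(labels) - {UNASSIGNED}:
        members = labels.index[labels == mod]
        clusters.append((len(members), min(members), mod))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    mapping = {
        old: (MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}")
        for rank, (_, _, old) in enumerate(clusters)
    }
    return labels.map(lambda m: mapping.get(m, UNASSIGNED))


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component per module (modules x samples), sign-oriented
    so the mean correlation with member genes is positive, unit variance."""
    modules = sorted(set(labels) - {UNASSIGNED})
    rows = {}
    for mod in modules:
        members = labels.index[labels == mod]
        sub = expr[members].to_numpy()
        sub = (sub - sub.mean(axis=0)) / np.where(sub.std(axis=0) > 0, sub.std(axis=0), 1.0)
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        eig = u[:, 0]
        cors = np.array([np.corrcoef(eig, sub[:, j])[0, 1] for j in range(sub.shape[1])])
        if np.nanmean(cors) < 0:
            eig = -eig
        sd = eig.std(ddof=1)
        rows[mod] = eig / sd if sd > 0 else eig
    return pd.DataFrame(rows, index=expr.index).T


def module_trait(
    eigengenes: pd.DataFrame, design: Sequence[SampleDesign]
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with binary traits (diel phase:
    day=0/night=1; species: first=0/second=1 when two species are present),
    p-values from the t distribution with n-2 df."""
    by_id = {s.sample_id: s for s in design}
    samples = list(eigengenes.columns)
    phase = np.array([1.0 if by_id[s].diel_phase == "night" else 0.0 for s in samples])
    traits = {"diel_phase": phase}
    species = sorted({by_id[s].species for s in samples})
    if len(species) == 2:
        traits["species"] = np.array(
            [1.0 if by_id[s].species == species[1] else 0.0 for s in samples]
        )
    rows = []
    for mod in eigengenes.index:
        eig = eigengenes.loc[mod].to_numpy(dtype=float)
        for trait, vec in traits.items():
            if np.std(vec) == 0 or np.std(eig) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = pearsonr(eig, vec)
            rows.append({"module": mod, "trait": trait, "cor": r, "p": p})
    return pd.DataFrame(rows)


class CoexpressionNetwork(BaseEstimator, ClusterMixin):
    """Weighted co-expression network as a scikit-learn clusterer.

    ``fit(X)`` takes samples x genes expression (already normalized/
    log-transformed; z-scoring is applied internally).  Fitted attributes:
    ``power_``, ``power_table_``, ``tom_``, ``labels_`` (color per gene),
    ``eigengenes_`` (modules x samples), ``trait_table_`` when a design is
    passed to fit.
    """

    def __init__(
        self,
        power: int | str = "auto",
        network_type: str = "signed",
        min_module_size: int = 10,
        cut_height: float = 0.85,
        candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
        r2_target: float = 0.8,
        kme_min: float = 0.8,
    ):
        self.power = power
        self.network_type = network_type
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.candidate_powers = candidate_powers
        self.r2_target = r2_target
        self.kme_min = kme_min

    def fit(self, X, y=None, design: Sequence[SampleDesign] | None = None):
        if isinstance(X, pd.DataFrame):
            expr = X
        else:
            X = np.asarray(X, dtype=float)
            expr = pd.DataFrame(
                X,
                index=[f"s{i}" for i in range(X.shape[0])],
                columns=[f"g{j}" for j in range(X.shape[1])],
            )
        values = expr.to_numpy(dtype=float)
        sd = values.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant genes must be removed before fitting")
        values = (values - values.mean(axis=0)) / sd

        if self.power == "auto":
            self.power_, self.power_table_ = pick_soft_power(
                values, self.candidate_powers, self.network_type, self.r2_target
            )
        else:
            self.power_ = int(self.power)
            self.power_table_ = None
        self.tom_ = adjacency_tom(values, self.power_, self.network_type)
        labels = detect_modules(
            self.tom_, list(expr.columns), self.min_module_size, self.cut_height
        )
        zframe = pd.DataFrame(values, index=expr.index, columns=expr.columns)
        if self.kme_min is not None and set(labels) - {UNASSIGNED}:
            labels = prune_by_membership(
                zframe, labels, kme_min=self.kme_min, min_module_size=self.min_module_size
            )
        self.labels_ = labels
        self.eigengenes_ = module_eigengenes(zframe, labels)
        if design is not None:
            self.trait_table_ = module_trait(self.eigengenes_, design)
        return self
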