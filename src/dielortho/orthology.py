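"""Reciprocal-best-hit orthology anchored to a reference proteome.

Pairwise protein similarity is Smith-Waterman local alignment under BLOSUM62
(gap open 11, extend 1).  Reciprocal best hits (RBH) between proteomes define
ortholog links; connected components containing exactly one reference gene
become orthogroups, and one representative transcript per species per group is
selected by identity to the reference (length as tie-break within a tolerance
band).

For large proteomes, candidate hits are shortlisted by shared k-mer counts
before full alignment; exhaustive all-vs-all scoring is used automatically for
small inputs and can be forced with ``prefilter="never"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

_EXHAUSTIVE_LIMIT = 250_000  # |A| x |B| above which the k-mer prefilter kicks in


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_score(a: str, b: str) -> tuple[float, float]:
    """Smith-Waterman score and identity (matches / aligned columns)."""
    if not a or not b:
        return 0.0, 0.0
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return float(score), 0.0
    aln = next(iter(_ALIGNER.align(a, b)))
    matches = 0
    columns = 0
    sa, sb = aln[0], aln[1]
    for ca, cb in zip(sa, sb):
        columns += 1
        if ca == cb and ca != "-":
            matches += 1
    identity = matches / columns if columns else 0.0
    return float(score), identity


def _score_only(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    return float(_ALIGNER.score(a, b))


def _kmer_index(proteome: Mapping[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for pid, seq in proteome.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(pid)
    return index


def _candidates(
    query: str, index: dict[str, set[str]], k: int, top: int
) -> list[str]:
    hits: dict[str, int] = {}
    for i in range(len(query) - k + 1):
        for pid in index.get(query[i : i + k], ()):
            hits[pid] = hits.get(pid, 0) + 1
    ranked = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    return [pid for pid, _ in ranked[:top]]


def _best_hits(
    A: Mapping[str, str],
    B: Mapping[str, str],
    prefilter: bool,
    k: int = 4,
    top: int = 8,
    cache: dict | None = None,
) -> dict[str, tuple[str, float]]:
    """Best hit in B for every member of A (tie-break: identity, then id)."""
    index = _kmer_index(B, k) if prefilter else None
    best: dict[str, tuple[str, float]] = {}
    b_ids = sorted(B)

    def score(aid: str, bid: str) -> float:
        if cache is None:
            return _score_only(A[aid], B[bid])
        key = (aid, bid) if aid <= bid else (bid, aid)
        if key not in cache:
            cache[key] = _score_only(A[aid], B[bid])
        return cache[key]

    for aid in sorted(A):
        seq = A[aid]
        cands = _candidates(seq, index, k, top) if prefilter else b_ids
        if not cands:
            cands = []
        scored = [(bid, score(aid, bid)) for bid in cands]
        if not scored:
            continue
        top_score = max(s for _, s in scored)
        if top_score <= 0:
            continue
        tied = sorted(bid for bid, s in scored if s == top_score)
        if len(tied) > 1:
            tied.sort(key=lambda bid: (-pairwise_score(seq, B[bid])[1], bid))
        best[aid] = (tied[0], top_score)
    return best


def reciprocal_best_hits(
    A: Mapping[str, str],
    B: Mapping[str, str],
    prefilter: str = "auto",
) -> set[tuple[str, str]]:
    """Pairs (a, b) where b is a's top hit in B and a is b's top hit in A.

    ``prefilter``: "auto" (k-mer shortlist for large inputs), "always",
    "never".
    """
    if not A or not B:
        warnings.warn("empty proteome; no reciprocal best hits")
        return set()
    if prefilter == "auto":
        use = len(A) * len(B) > _EXHAUSTIVE_LIMIT
    elif prefilter in ("always", "never"):
        use = prefilter == "always"
    else:
        raise ValueError("prefilter must be 'auto', 'always' or 'never'")
    cache: dict = {}
    ab = _best_hits(A, B, use, cache=cache)
    ba = _best_hits(B, A, use, cache=cache)
    return {
        (a, b)
        for a, (b, _) in ab.items()
        if b in ba and ba[b][0] == a
    }


@dataclass
class OrthogroupMember:
    species: str
    transcript_id: str
    identity_to_reference: float
    length: int
    is_representative: bool = False


@dataclass
class Orthogroup:
    group_id: str
    reference_gene: str
    members: list[OrthogroupMember] = field(default_factory=list)


@dataclass
class OrthologMap:
    """transcript -> reference gene per species, plus direct cross-species
    transcript pairs (kept even without a reference anchor)."""

    by_species: dict[str, dict[str, str]] = field(default_factory=dict)
    pairwise: set[tuple[str, str, str, str]] = field(default_factory=set)
    # pairwise entries: (species_a, transcript_a, species_b, transcript_b)

    def reference_for(self, species: str, transcript: str) -> str | None:
        return self.by_species.get(species, {}).get(transcript)


def build_orthogroups(
    ref_proteome: Mapping[str, str],
    species_proteomes: Mapping[str, Mapping[str, str]],
    prefilter: str = "auto",
) -> tuple[list[Orthogroup], OrthologMap, list[str]]:
    """RBH graphs species<->reference and species<->species; connected
    components with exactly one reference gene become orthogroups.

    Components with multiple reference genes are split by assigning each
    transcript to its higher-scoring reference (logged).  Components without a
    reference gene are kept as reference-free pairwise links.  Returns
    (orthogroups, ortholog map, log messages).
    """
    log: list[str] = []
    graph = nx.Graph()
    species_list = sorted(species_proteomes)

    for sp in species_list:
        for a, b in reciprocal_best_hits(species_proteomes[sp], ref_proteome, prefilter):
            graph.add_edge((sp, a), ("__ref__", b))
    for sp1, sp2 in itertools.combinations(species_list, 2):
        for a, b in reciprocal_best_hits(
            species_proteomes[sp1], species_proteomes[sp2], prefilter
        ):
            graph.add_edge((sp1, a), (sp2, b))

    groups: list[Orthogroup] = []
    omap = OrthologMap(by_species={sp: {} for sp in species_list})
    gid = 0
    for comp in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        refs = sorted(g for tag, g in comp if tag == "__ref__")
        transcripts = sorted((tag, t) for tag, t in comp if tag != "__ref__")
        if not refs:
            # reference-free: keep the cross-species RBH edges
            for (t1, t2) in graph.subgraph(comp).edges:
                (s1, a), (s2, b) = sorted([t1, t2])
                omap.pairwise.add((s1, a, s2, b))
            continue
        assignment: dict[tuple[str, str], str] = {}
        if len(refs) == 1:
            assignment = {t: refs[0] for t in transcripts}
        else:
            log.append(
                f"component with reference genes {refs} split by best-hit assignment"
            )
            for sp, tid in transcripts:
                seq = species_proteomes[sp][tid]
                best_ref = max(refs, key=lambda r: (_score_only(seq, ref_proteome[r]), r))
                assignment[(sp, tid)] = best_ref
        for ref in refs:
            members = [
                OrthogroupMember(
                    species=sp,
                    transcript_id=tid,
                    identity_to_reference=pairwise_score(
                        species_proteomes[sp][tid], ref_proteome[ref]
                    )[1],
                    length=len(species_proteomes[sp][tid]),
                )
                for (sp, tid) in transcripts
                if assignment[(sp, tid)] == ref
            ]
            if not members:
                continue
            gid += 1
            group = Orthogroup(group_id=f"OG{gid:05d}", reference_gene=ref, members=members)
            select_representative(group)
            groups.append(group)
            for mem in members:
                omap.by_species[mem.species][mem.transcript_id] = ref
        # cross-species pairwise links inside anchored components too
        for (t1, t2) in graph.subgraph(comp).edges:
            if t1[0] == "__ref__" or t2[0] == "__ref__":
                continue
            (s1, a), (s2, b) = sorted([t1, t2])
            omap.pairwise.add((s1, a, s2, b))
    return groups, omap, log


def select_representative(
    g: Orthogroup, tie_tol: float = 0.01, prefer: str = "identity"
) -> dict[str, OrthogroupMember]:
    """Flag one representative per species: maximize identity to the
    reference; among members within ``tie_tol`` identity of the best, take the
    longest; final ties break to the lexicographically smallest id.

    ``prefer="length"`` swaps the precedence (longest first, identity within
    ties).
    """
    for m in g.members:
        m.is_representative = False
    chosen: dict[str, OrthogroupMember] = {}
    by_species: dict[str, list[OrthogroupMember]] = {}
    for m in g.members:
        by_species.setdefault(m.species, []).append(m)
    for sp, members in by_species.items():
        if prefer == "identity":
            best_ident = max(m.identity_to_reference for m in members)
            pool = [m for m in members if m.identity_to_reference >= best_ident - tie_tol]
            pool.sort(key=lambda m: (-m.length, m.transcript_id))
        elif prefer == "length":
            best_len = max(m.length for m in members)
            pool = [m for m in members if m.length == best_len]
            pool.sort(key=lambda m: (-m.identity_to_reference, m.transcript_id))
        else:
            raise ValueError("prefer must be 'identity' or 'length'")
        pool[0].is_representative = True
        chosen[sp] = pool[0]
    return chosen


def orthogroups_to_frame(groups: Iterable[Orthogroup]) -> pd.DataFrame:
    rows = [
        {
            "group_id": g.group_id,
            "reference_gene": g.reference_gene,
            "species": m.species,
            "transcript_id": m.transcript_id,
            "identity": m.identity_to_reference,
            "length": m.length,
            "is_representative": m.is_representative,
        }
        for g in groups
        for m in g.members
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "reference_gene",
            "species",
            "transcript_id",
            "identity",
            "length",
            "is_representative",
        ],
    )
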