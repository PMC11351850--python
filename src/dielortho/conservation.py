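"""Alignment-based conservation profiling and focal-pair mutation mapping.

A sequence-level conservation score replaces structure-aware evolutionary
rate estimation: per alignment column, raw = (1 - H / ln 20) * (1 -
gap_fraction), with H the Shannon entropy of the non-gap residue frequencies
(natural log, normalized by the 20-letter alphabet regardless of what is
observed).  Scores are smoothed with a centered moving mean (window 5, edges
truncated), graded 1-9 by noniles (9 = most conserved), and maximal runs of
high-scoring columns become conserved blocks — the sequence-level proxy for
functional domains.  Mutations between two focal sequences are mapped onto the
blocks, yielding the in-block overlap count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

LN20 = math.log(20.0)
GAP = "-"


def read_msa(path: str | Path) -> dict[str, str]:
    """Aligned FASTA -> ordered mapping id -> aligned sequence."""
    msa = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in msa.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal aligned lengths: {sorted(lengths)}")
    return msa


def write_msa(msa: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.items():
            fh.write(f">{name}\n{seq}\n")


@dataclass
class ConservationProfile:
    msa_id: str
    n_sequences: int
    raw: np.ndarray
    smoothed: np.ndarray
    gap_fraction: np.ndarray
    grades: np.ndarray
    blocks: list[tuple[int, int]] = field(default_factory=list)
    reference_id: str | None = None
    column_to_ref: dict[int, int] = field(default_factory=dict)  # 1-based positions

    def in_block(self, column: int) -> bool:
        return any(s <= column < e for s, e in self.blocks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(len(self.raw)),
                "raw": self.raw,
                "smoothed": self.smoothed,
                "grade": self.grades,
                "gap_fraction": self.gap_fraction,
                "in_block": [self.in_block(c) for c in range(len(self.raw))],
            }
        )


@dataclass
class MutationOverlap:
    focal_a: str
    focal_b: str
    mutations: pd.DataFrame  # column, residue_a, residue_b, reference_position, in_block, grade
    indel_columns: list[int]

    @property
    def n_total(self) -> int:
        return len(self.mutations)

    @property
    def n_in_block(self) -> int:
        return int(self.mutations["in_block"].sum())


def column_conservation(
    msa: Mapping[str, str],
    gap_penalty: bool = True,
    smooth_window: int = 5,
    msa_id: str = "msa",
    reference_id: str | None = None,
) -> ConservationProfile:
    """Per-column raw and smoothed conservation scores with 1-9 grades."""
    if len(msa) < 3:
        raise ValueError("conservation requires at least 3 sequences")
    seqs = list(msa.values())
    ncol = len(seqs[0])
    arr = np.array([list(s) for s in seqs])

    raw = np.zeros(ncol)
    gap_fraction = np.zeros(ncol)
    for c in range(ncol):
        col = arr[:, c]
        gaps = col == GAP
        gap_fraction[c] = gaps.mean()
        residues = col[~gaps]
        if len(residues) == 0:
            raw[c] = 0.0
            continue
        _, counts = np.unique(residues, return_counts=True)
        freqs = counts / counts.sum()
        h = float(-(freqs * np.log(freqs)).sum())
        score = 1.0 - h / LN20
        if gap_penalty:
            score *= 1.0 - gap_fraction[c]
        raw[c] = max(score, 0.0)

    smoothed = _moving_mean(raw, smooth_window)
    grades = _nonile_grades(smoothed)

    profile = ConservationProfile(
        msa_id=msa_id,
        n_sequences=len(msa),
        raw=raw,
        smoothed=smoothed,
        gap_fraction=gap_fraction,
        grades=grades,
    )
    if reference_id is not None:
        set_reference(profile, msa, reference_id)
    return profile


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def _nonile_grades(smoothed: np.ndarray) -> np.ndarray:
    qs = np.quantile(smoothed, np.linspace(0, 1, 10)[1:-1])
    return (np.digitize(smoothed, qs, right=True) + 1).astype(int)


def set_reference(
    profile: ConservationProfile, msa: Mapping[str, str], reference_id: str
) -> None:
    """Build the alignment-column -> ungapped reference position map
    (1-based) over the reference's non-gap columns."""
    if reference_id not in msa:
        raise KeyError(f"reference id {reference_id!r} absent from MSA")
    profile.reference_id = reference_id
    profile.column_to_ref = {}
    pos = 0
    for c, ch in enumerate(msa[reference_id]):
        if ch != GAP:
            pos += 1
            profile.column_to_ref[c] = pos


def find_blocks(
    profile: ConservationProfile, tau: float = 0.8, min_block: int = 30
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_block consecutive columns with smoothed score
    >= tau; stored on the profile and returned (half-open intervals)."""
    above = profile.smoothed >= tau
    blocks: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_block:
                blocks.append((start, i))
            start = None
    if start is not None and len(above) - start >= min_block:
        blocks.append((start, len(above)))
    profile.blocks = blocks
    return blocks


def focal_mutations(
    msa: Mapping[str, str],
    focal_a: str,
    focal_b: str,
    profile: ConservationProfile,
) -> MutationOverlap:
    """Columns where both focal residues are non-gap and differ; counts how
    many fall inside conserved blocks.  Columns where exactly one focal
    residue is a gap are reported separately as indel sites."""
    for fid in (focal_a, focal_b):
        if fid not in msa:
            raise KeyError(f"focal id {fid!r} absent from MSA")
    sa, sb = msa[focal_a], msa[focal_b]
    rows = []
    indels = []
    for c, (ra, rb) in enumerate(zip(sa, sb)):
        if (ra == GAP) != (rb == GAP):
            indels.append(c)
            continue
        if ra != GAP and ra != rb:
            rows.append(
                {
                    "column": c,
                    "residue_a": ra,
                    "residue_b": rb,
                    "reference_position": profile.column_to_ref.get(c, pd.NA),
                    "in_block": profile.in_block(c),
                    "grade": int(profile.grades[c]),
                }
            )
    mutations = pd.DataFrame(
        rows,
        columns=["column", "residue_a", "residue_b", "reference_position", "in_block", "grade"],
    )
    return MutationOverlap(
        focal_a=focal_a, focal_b=focal_b, mutations=mutations, indel_columns=indels
    )


def compare_ortholog_lengths(
    msa: Mapping[str, str],
    ref_id: str,
    other_id: str,
    profile: ConservationProfile,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Map conserved blocks onto each sequence's ungapped coordinates.

    A block is "shared" when both sequences have non-gap residues over at
    least ``min_coverage`` of its columns, otherwise "lineage_specific" to the
    sequence that covers it — the signature of a lineage-specific conserved
    region absent from the shorter ortholog.
    """
    for sid in (ref_id, other_id):
        if sid not in msa:
            raise KeyError(f"sequence id {sid!r} absent from MSA")
    rows = []
    for start, end in profile.blocks:
        cov = {}
        spans = {}
        for sid in (ref_id, other_id):
            seq = msa[sid]
            nongap = [c for c in range(start, end) if seq[c] != GAP]
            cov[sid] = len(nongap) / (end - start)
            if nongap:
                ungapped_start = sum(1 for ch in seq[: nongap[0]] if ch != GAP) + 1
                ungapped_end = ungapped_start + len(nongap) - 1
                spans[sid] = (ungapped_start, ungapped_end)
            else:
                spans[sid] = (pd.NA, pd.NA)
        both = cov[ref_id] >= min_coverage and cov[other_id] >= min_coverage
        if both:
            status = "shared"
        elif cov[ref_id] >= min_coverage:
            status = f"lineage_specific:{ref_id}"
        elif cov[other_id] >= min_coverage:
            status = f"lineage_specific:{other_id}"
        else:
            status = "uncovered"
        rows.append(
            {
                "block_start": start,
                "block_end": end,
                f"coverage_{ref_id}": cov[ref_id],
                f"coverage_{other_id}": cov[other_id],
                f"span_{ref_id}": spans[ref_id],
                f"span_{other_id}": spans[other_id],
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def block_jaccard(
    blocks_a: Sequence[tuple[int, int]], blocks_b: Sequence[tuple[int, int]]
) -> float:
    """Jaccard index of the column sets covered by two block lists."""
    set_a = {c for s, e in blocks_a for c in range(s, e)}
    set_b = {c for s, e in blocks_b for c in range(s, e)}
    if not set_a and not set_b:
        return 1.0
    return len(set_a & set_b) / len(set_a | set_b)
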