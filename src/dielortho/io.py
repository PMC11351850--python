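"""Core data model and file I/O.

Count matrices are genes x samples integer tables with an attached sample
design (species, diel phase, activity niche, replicate).  All downstream
stages — normalization, differential expression, ortholog collapse,
co-expression — consume these containers.  Expression units (TPM) and the
low-expression prefilter live here because they gate every later stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DIEL_PHASES = ("day", "night")
ACTIVITY_NICHES = ("diurnal", "nocturnal")

#: the six functional categories used for candidate tagging, plus the catch-all
FUNCTIONAL_CATEGORIES = (
    "vision",
    "smell",
    "hearing",
    "circadian",
    "behaviour",
    "brain",
)


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class ReconciliationError(ValueError):
    """Counts and design tables disagree about the sample set."""


@dataclass(frozen=True)
class SampleDesign:
    """One RNA-seq library: which animal, when it was sampled, and its niche."""

    sample_id: str
    species: str
    diel_phase: str
    activity_niche: str
    replicate: int

    def __post_init__(self) -> None:
        if self.diel_phase not in DIEL_PHASES:
            raise ValueError(f"diel_phase must be one of {DIEL_PHASES}, got {self.diel_phase!r}")
        if self.activity_niche not in ACTIVITY_NICHES:
            raise ValueError(
                f"activity_niche must be one of {ACTIVITY_NICHES}, got {self.activity_niche!r}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


def validate_design(samples: Sequence[SampleDesign]) -> None:
    """Check design invariants: unique ids, >=2 samples per species x phase,
    constant activity niche within species."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    by_species: dict[str, list[SampleDesign]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(s)
    for sp, group in by_species.items():
        niches = {s.activity_niche for s in group}
        if len(niches) > 1:
            raise ValueError(f"species {sp!r} has inconsistent activity_niche: {sorted(niches)}")
        for phase in DIEL_PHASES:
            n = sum(1 for s in group if s.diel_phase == phase)
            if n < 2:
                raise ValueError(
                    f"species {sp!r} has {n} sample(s) for phase {phase!r}; need >=2"
                )


@dataclass
class CountMatrix:
    """Integer counts, genes x samples, with per-gene lengths when known."""

    gene_ids: list[str]
    samples: list[SampleDesign]
    counts: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths)
            if self.lengths.shape != (len(self.gene_ids),):
                raise ValueError("lengths must align 1:1 with gene_ids")
            if np.any(self.lengths <= 0):
                raise ValueError("lengths must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            samples=list(self.samples),
            counts=self.counts[idx],
            lengths=None if self.lengths is None else self.lengths[idx],
        )

    def group_indices(self) -> dict[str, np.ndarray]:
        """Column indices per diel phase."""
        return {
            phase: np.array([j for j, s in enumerate(self.samples) if s.diel_phase == phase], dtype=int)
            for phase in DIEL_PHASES
        }


@dataclass
class GoTable:
    """gene -> GO annotations plus the GO -> functional-category map."""

    records: pd.DataFrame  # columns: gene_id, go_id, go_namespace
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene_id", "go_id", "go_namespace"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"GO records missing columns: {sorted(missing)}")
        if self.records.duplicated(subset=["gene_id", "go_id"]).any():
            raise ValueError("(gene_id, go_id) pairs must be unique")
        for go_id in self.category_map:
            if not _is_go_id(go_id):
                raise ValueError(f"malformed GO identifier in category map: {go_id!r}")

    def genes_with_term(self, go_id: str) -> set[str]:
        return set(self.records.loc[self.records["go_id"] == go_id, "gene_id"])

    def terms_for_gene(self, gene_id: str) -> set[str]:
        return set(self.records.loc[self.records["gene_id"] == gene_id, "go_id"])

    def categories_for_gene(self, gene_id: str) -> set[str]:
        cats = {self.category_map.get(t) for t in self.terms_for_gene(gene_id)}
        cats.discard(None)
        return cats  # type: ignore[return-value]


def _is_go_id(go_id: str) -> bool:
    return (
        go_id.startswith("GO:")
        and len(go_id) == 10
        and go_id[3:].isdigit()
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "diel_phase", "activity_niche", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design file {path} missing columns: {sorted(missing)}")
    samples = [
        SampleDesign(
            sample_id=row.sample_id,
            species=row.species,
            diel_phase=row.diel_phase,
            activity_niche=row.activity_niche,
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]
    validate_design(samples)
    return samples


def write_design(samples: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "species": s.species,
                "diel_phase": s.diel_phase,
                "activity_niche": s.activity_niche,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path,
    design_path: str | Path,
    lengths_path: str | Path | None = None,
    allow_fractional: bool = False,
    allow_design_superset: bool = False,
) -> CountMatrix:
    """Read a counts TSV (first column gene_id, remaining columns sample ids)
    and its sample design table.

    Sample columns are reordered to match design order.  Counts must parse as
    integers; with ``allow_fractional`` estimated counts are rounded
    half-to-even instead of rejected.  ``allow_design_superset`` permits a
    design table covering more samples than this counts file (e.g. a shared
    two-species design with per-species counts files); counts samples missing
    from the design always error.
    """
    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise FormatError(f"first column of {path} must be 'gene_id', got {df.columns[0]!r}")
    gene_ids = df["gene_id"].tolist()
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        # report the first offending data line (1-based, + header)
        line = int(df.index[df["gene_id"] == dupes[0]][1]) + 2
        raise FormatError(f"duplicate gene id {dupes[0]!r} (line {line})")

    file_samples = list(df.columns[1:])
    design_ids = [s.sample_id for s in design]
    extra = sorted(set(file_samples) - set(design_ids))
    absent = sorted(set(design_ids) - set(file_samples))
    if allow_design_superset and not extra:
        design = [s for s in design if s.sample_id in set(file_samples)]
        design_ids = [s.sample_id for s in design]
        absent = []
    if extra or absent:
        raise ReconciliationError(
            f"sample mismatch between {path} and design: "
            f"in counts but not design: {extra}; in design but not counts: {absent}"
        )

    values = df[design_ids].to_numpy()
    as_float = values.astype(float)
    if not np.allclose(as_float, np.round(as_float), atol=0, rtol=0):
        if allow_fractional:
            as_float = _round_half_even(as_float)
        else:
            bad = np.argwhere(as_float != np.round(as_float))[0]
            raise FormatError(
                f"non-integer count {values[bad[0], bad[1]]!r} for gene "
                f"{gene_ids[bad[0]]!r}, sample {design_ids[bad[1]]!r}"
            )
    counts = as_float.astype(np.int64)

    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", dtype={0: str})
        lengths = ldf.set_index(ldf.columns[0]).iloc[:, 0].reindex(gene_ids).to_numpy(float)
        if np.isnan(lengths).any():
            missing_genes = [g for g, v in zip(gene_ids, lengths) if np.isnan(v)]
            raise FormatError(f"lengths file missing genes: {missing_genes[:5]}")
    return CountMatrix(gene_ids=gene_ids, samples=design, counts=counts, lengths=lengths)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_go(path: str | Path, category_path: str | Path | None = None) -> GoTable:
    records = pd.read_csv(path, sep="\t", dtype=str)
    category_map: dict[str, str] = {}
    if category_path is not None:
        cdf = pd.read_csv(category_path, sep="\t", dtype=str)
        category_map = dict(zip(cdf["go_id"], cdf["category"]))
    return GoTable(records=records, category_map=category_map)


def write_go(go: GoTable, path: str | Path, category_path: str | Path | None = None) -> None:
    go.records.to_csv(path, sep="\t", index=False)
    if category_path is not None:
        pd.DataFrame(
            {"go_id": list(go.category_map), "category": list(go.category_map.values())}
        ).to_csv(category_path, sep="\t", index=False)


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x)


# ---------------------------------------------------------------------------
# expression units and prefilter
# ---------------------------------------------------------------------------

def compute_tpm(m: CountMatrix, zero_sample_policy: str = "error") -> np.ndarray:
    """Transcripts per million, genes x samples.

    tpm[g, s] = (counts[g, s] / length[g]) / sum_h(counts[h, s] / length[h]) * 1e6.
    Each sample column sums to 1e6.  ``zero_sample_policy`` controls all-zero
    columns: "error" raises, "zero" emits an all-zero column.
    """
    if m.lengths is None:
        raise ValueError("compute_tpm requires gene lengths")
    if zero_sample_policy not in ("error", "zero"):
        raise ValueError("zero_sample_policy must be 'error' or 'zero'")
    rate = m.counts / m.lengths[:, None]
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        if zero_sample_policy == "error":
            bad = [m.sample_ids[j] for j in np.flatnonzero(zero_cols)]
            raise ValueError(f"all-zero sample column(s): {bad}")
        colsum = np.where(zero_cols, 1.0, colsum)
    return rate / colsum * 1e6


def filter_low_expression(
    m: CountMatrix,
    tpm_threshold: float = 1.0,
    min_samples: int = 1,
    zero_sample_policy: str = "error",
) -> tuple[CountMatrix, list[str]]:
    """Drop genes below ``tpm_threshold`` TPM (inclusive retention: TPM == 1
    with threshold 1 is kept) in fewer than ``min_samples`` samples.

    Returns the filtered matrix and the list of dropped gene ids.
    """
    if tpm_threshold <= 0:
        raise ValueError("tpm_threshold must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    tpm = compute_tpm(m, zero_sample_policy=zero_sample_policy)
    keep = (tpm >= tpm_threshold).sum(axis=1) >= min_samples
    dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
    kept = m.subset_genes([g for g, k in zip(m.gene_ids, keep) if k])
    return kept, dropped
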