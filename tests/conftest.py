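import numpy as np
import pytest

from dielortho import SimConfig, simulate_all
from dielortho.io import CountMatrix, SampleDesign


def small_config(seed: int = 42, **overrides) -> SimConfig:
    """A miniature study: fast enough for unit tests, same structure."""
    kw = dict(
        seed=seed,
        n_ref_genes=120,
        n_flipped=8,
        n_concordant=4,
        n_single_species=4,
        n_modules=2,
        module_size=10,
        module_kinds=("species", "diel"),
        n_go_per_category=2,
        n_go_other=4,
        orth_protein_length=80,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_all(small_config())


def make_design(n_day=2, n_night=2, species="AN", niche="diurnal"):
    samples = []
    for i in range(n_day):
        samples.append(SampleDesign(f"{species}_D{i+1}", species, "day", niche, i + 1))
    for i in range(n_night):
        samples.append(SampleDesign(f"{species}_N{i+1}", species, "night", niche, i + 1))
    return samples


def make_counts(counts, lengths=None, **design_kw):
    counts = np.asarray(counts)
    samples = make_design(**design_kw) if design_kw else make_design(
        n_day=counts.shape[1] // 2, n_night=counts.shape[1] - counts.shape[1] // 2
    )
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        samples=samples[: counts.shape[1]],
        counts=counts,
        lengths=None if lengths is None else np.asarray(lengths),
    )
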