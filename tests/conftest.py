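"""Shared synthetic datasets for the test suite.

All fixtures are generated programmatically from fixed seeds; the
session-scoped ones are reused across modules to keep the suite fast.
"""

import pytest

from xstress.synthetic_data import SimConfig, generate_dataset

SMALL_CORE = {
    "common_up": 2, "common_down": 1,
    "opposite_a_up": 1, "opposite_a_down": 1,
    "a_only_up": 2, "a_only_down": 2,
    "b_only_up": 1, "b_only_down": 1,
}


@pytest.fixture(scope="session")
def dataset_default():
    """Default study conditions (3,000 + 2,000 genes, 4 stresses)."""
    return generate_dataset(SimConfig(seed=101))


@pytest.fixture(scope="session")
def dataset_noise_free():
    """Zero within-replicate noise: downstream calls must be exact."""
    return generate_dataset(SimConfig(seed=202, sigma_within=0.0))


@pytest.fixture(scope="session")
def dataset_small():
    """A small dataset for IO round-trips and file-level checks."""
    return generate_dataset(SimConfig(seed=303, n_genes_a=300,
                                      n_genes_b=250,
                                      core_counts=dict(SMALL_CORE)))


@pytest.fixture(scope="session")
def dataset_motif500():
    """Sized so the planted-motif target set holds ~500 promoters, the
    scale at which the 6-mer ratio statistics are characterized."""
    return generate_dataset(SimConfig(seed=505, n_genes_a=3750,
                                      n_genes_b=2500,
                                      frac_de_per_stress=0.5))


@pytest.fixture(scope="session")
def dataset_species_motifs():
    """Species-wide planted promoter motifs: every up-set of species A
    shares two motifs, every up-set of species B two others, so motif
    ratios are correlated within species."""
    motifs = []
    for stress in ("drought", "salt", "cold", "heat"):
        motifs += [("GGCGCC", f"a_{stress}_up", 2.0),
                   ("CACGTG", f"a_{stress}_up", 2.0),
                   ("AAGCTT", f"b_{stress}_up", 2.0),
                   ("GGATCC", f"b_{stress}_up", 2.0)]
    cfg = SimConfig(seed=404, n_genes_a=1500, n_genes_b=1200,
                    frac_de_per_stress=0.35, planted_motifs=motifs,
                    core_counts=dict(SMALL_CORE))
    return generate_dataset(cfg)
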