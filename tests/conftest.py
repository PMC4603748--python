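"""Shared synthetic fixtures.

All fixtures are generated programmatically at test time from the package's
own synthetic-data module.  Desk-scale study conditions: a 5,000-COG
universe with genomes at the 1.5% feature density of full-scale profiles
(75 COGs/genome); the noise-free single-marker recovery checks use sparser
genomes (30 COGs) where a lone marker is recoverable exactly (see
docs/methods.md for the density dependence).
"""

from __future__ import annotations

import pytest

from cogtrait.synthetic_data import (
    PlantedTraitSpec,
    VirtualPopulationSpec,
    generate_planted_trait,
    generate_virtual_population,
)

SPARSE_POP = dict(n_genomes=80, universe_size=5000, mean_genome_size=30)
DENSE_POP = dict(n_genomes=80, universe_size=5000, mean_genome_size=75)


@pytest.fixture(scope="session")
def separable_data():
    """Noise-free single-marker trait: perfectly separable by 'TRAIT0000'."""
    pop = generate_virtual_population(VirtualPopulationSpec(**SPARSE_POP, seed=915))
    return generate_planted_trait(
        pop,
        PlantedTraitSpec("single_marker", ("TRAIT0000",), seed=916),
    )


@pytest.fixture(scope="session")
def absence_data():
    """Absence-driven trait (genome-reduction regime): 50 markers present in
    every negative, at least 25 deleted from each positive."""
    markers = tuple(f"TRAIT{j:04d}" for j in range(50))
    pop = generate_virtual_population(
        VirtualPopulationSpec(
            n_genomes=100, universe_size=5000, mean_genome_size=75, seed=11
        )
    )
    return generate_planted_trait(
        pop,
        PlantedTraitSpec("absence_driven", markers, k=25, seed=12),
    )
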