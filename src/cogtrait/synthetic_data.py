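"""Virtual species and planted phenotypic traits.

Every other module is testable at desk scale with these generators: virtual
genomes are uniform random subsets of a large COG universe (the worst-case
scaling regime of ~200,000 features and thousands of genomes), and traits
are planted with a known genetic architecture so that feature-ranking and
cross-validation behaviour can be checked against ground truth.

Three trait architectures are supported:

* ``single_marker`` -- one marker COG is inserted into every positive
  genome and into negatives with a configurable background rate; the
  one-gene-one-trait regime (e.g. *amoA* for ammonia oxidation).
* ``k_of_m_presence`` -- each positive receives at least k of m marker
  COGs; a many-genes-to-one-trait presence regime (porins, regulators).
* ``absence_driven`` -- all m markers are first inserted into every genome
  and then at least k of them are *deleted* from each positive, so the
  trait is predicted by gene absence.  This emulates genome-reduced
  lifestyles such as obligate intracellularity, where the top-ranked
  model features are negative predictors.

Labels can additionally be flipped with a ``label_noise`` probability, and
``random_labels`` assigns labels independently of the genotype for null
calibration and scaling runs.

Any pre-existing occurrences of the marker COGs are stripped from the
population before planting, so the noise-free architecture invariants are
exact rather than approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import GenotypeProfile, Label, PhenotypeTable

__all__ = [
    "ARCHITECTURES",
    "VirtualPopulationSpec",
    "PlantedTraitSpec",
    "PlantedTraitTruth",
    "generate_virtual_population",
    "generate_planted_trait",
    "random_labels",
    "truth_to_json",
]

ARCHITECTURES = ("single_marker", "k_of_m_presence", "absence_driven")


@dataclass(frozen=True)
class VirtualPopulationSpec:
    """Parameters of a virtual-species population.

    Defaults mirror the worst-case scaling setup: a feature universe of
    200,000 COGs with genome sizes around 3,000 (an average-bacterium-sized
    profile; configurable).  ``size_dispersion`` is the variance-to-mean
    ratio of the genome-size distribution: 0 gives constant sizes, 1 the
    Poisson default, >1 a negative binomial.
    """

    n_genomes: int
    universe_size: int = 200_000
    mean_genome_size: int = 3_000
    size_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be positive")
        if self.universe_size < 1:
            raise ValueError("universe_size must be positive")
        if not 1 <= self.mean_genome_size <= self.universe_size:
            raise ValueError(
                f"mean_genome_size={self.mean_genome_size} must lie in "
                f"[1, universe_size={self.universe_size}]"
            )
        if self.size_dispersion < 0:
            raise ValueError("size_dispersion must be non-negative")
        if 0 < self.size_dispersion < 1:
            raise ValueError(
                "size_dispersion must be 0 (constant sizes) or >= 1 "
                "(Poisson / negative binomial)"
            )


def _cog_name(index: int) -> str:
    return f"COG{index:06d}"


def _draw_sizes(spec: VirtualPopulationSpec, rng: np.random.Generator) -> np.ndarray:
    mean = spec.mean_genome_size
    d = spec.size_dispersion
    if d == 0:
        sizes = np.full(spec.n_genomes, mean, dtype=np.int64)
    elif d == 1:
        sizes = rng.poisson(mean, size=spec.n_genomes)
    else:
        # negative binomial with variance d * mean: r successes, p = 1/d
        r = mean / (d - 1)
        sizes = rng.negative_binomial(r, 1.0 / d, size=spec.n_genomes)
    return np.clip(sizes, 1, spec.universe_size)


def generate_virtual_population(
    spec: VirtualPopulationSpec,
) -> list[GenotypeProfile]:
    """Draw ``n_genomes`` profiles, each a uniform random subset (without
    replacement) of the COG universe, deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    sizes = _draw_sizes(spec, rng)
    profiles = []
    for i, size in enumerate(sizes):
        idx = rng.choice(spec.universe_size, size=int(size), replace=False)
        profiles.append(
            GenotypeProfile(
                genome_id=f"vg{i:05d}",
                cogs=frozenset(_cog_name(j) for j in idx),
            )
        )
    return profiles


@dataclass(frozen=True)
class PlantedTraitSpec:
    """Genetic architecture of a planted trait (see module docstring)."""

    architecture: str
    marker_cogs: tuple[str, ...]
    k: int = 1
    marker_rate_in_negatives: float = 0.0
    label_noise: float = 0.0
    fraction_positive: float = 0.5
    seed: int = 0
    trait_name: str = "planted_trait"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}"
            )
        if not self.marker_cogs:
            raise ValueError("marker_cogs must be non-empty")
        if len(set(self.marker_cogs)) != len(self.marker_cogs):
            raise ValueError("marker_cogs contains duplicates")
        if self.architecture == "single_marker" and len(self.marker_cogs) != 1:
            raise ValueError("single_marker architecture takes exactly one marker")
        if not 1 <= self.k <= len(self.marker_cogs):
            raise ValueError(
                f"k={self.k} must lie in [1, {len(self.marker_cogs)}]"
            )
        for p, name in [
            (self.marker_rate_in_negatives, "marker_rate_in_negatives"),
            (self.label_noise, "label_noise"),
            (self.fraction_positive, "fraction_positive"),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")


@dataclass(frozen=True)
class PlantedTraitTruth:
    """Ground-truth record written alongside a planted trait, so ranking
    tests never have to reverse-engineer the generator."""

    architecture: str
    marker_cogs: tuple[str, ...]
    k: int
    label_noise: float
    seed: int
    true_labels: dict[str, Label]  # pre-noise labels


def generate_planted_trait(
    profiles: Sequence[GenotypeProfile], spec: PlantedTraitSpec
) -> tuple[list[GenotypeProfile], PhenotypeTable, PlantedTraitTruth]:
    """Plant a trait into a population.

    Marker COGs are first stripped from every genome, then re-inserted (or
    deleted) according to the architecture, so that with zero noise the
    construction invariants are exact: e.g. for ``absence_driven`` every
    positive lacks at least k of the m markers while every negative carries
    all m.  Observed labels flip with probability ``label_noise``; the
    returned truth record keeps the pre-noise labels.
    """
    markers = spec.marker_cogs
    genome_ids = {p.genome_id for p in profiles}
    if genome_ids & set(markers):
        raise ValueError("marker COG ids collide with genome ids")
    rng = np.random.default_rng(spec.seed)
    m = len(markers)

    true_labels: dict[str, Label] = {}
    observed: dict[str, Label] = {}
    out_profiles: list[GenotypeProfile] = []
    for p in profiles:
        cogs = set(p.cogs) - set(markers)
        positive = bool(rng.random() < spec.fraction_positive)
        if spec.architecture == "single_marker":
            if positive or rng.random() < spec.marker_rate_in_negatives:
                cogs.add(markers[0])
        elif spec.architecture == "k_of_m_presence":
            if positive:
                count = int(rng.integers(spec.k, m + 1))
                for j in rng.choice(m, size=count, replace=False):
                    cogs.add(markers[j])
            else:
                for marker in markers:
                    if rng.random() < spec.marker_rate_in_negatives:
                        cogs.add(marker)
        else:  # absence_driven
            cogs.update(markers)
            if positive:
                count = int(rng.integers(spec.k, m + 1))
                for j in rng.choice(m, size=count, replace=False):
                    cogs.discard(markers[j])
        true = Label.POSITIVE if positive else Label.NEGATIVE
        flipped = bool(rng.random() < spec.label_noise)
        obs = true
        if flipped:
            obs = Label.NEGATIVE if positive else Label.POSITIVE
        true_labels[p.genome_id] = true
        observed[p.genome_id] = obs
        out_profiles.append(GenotypeProfile(p.genome_id, frozenset(cogs)))

    table = PhenotypeTable(trait_name=spec.trait_name, labels=observed)
    truth = PlantedTraitTruth(
        architecture=spec.architecture,
        marker_cogs=markers,
        k=spec.k,
        label_noise=spec.label_noise,
        seed=spec.seed,
        true_labels=true_labels,
    )
    return out_profiles, table, truth


def random_labels(
    profiles: Sequence[GenotypeProfile],
    fraction_positive: float,
    seed: int,
    trait_name: str = "random_trait",
) -> PhenotypeTable:
    """Assign labels independently of the genotype (null traits and scaling
    runs); each genome is POSITIVE with probability ``fraction_positive``."""
    if not 0 < fraction_positive < 1:
        raise ValueError(
            f"fraction_positive must lie strictly in (0, 1), "
            f"got {fraction_positive}"
        )
    rng = np.random.default_rng(seed)
    draws = rng.random(len(profiles))
    return PhenotypeTable(
        trait_name=trait_name,
        labels={
            p.genome_id: Label.POSITIVE if d < fraction_positive else Label.NEGATIVE
            for p, d in zip(profiles, draws)
        },
    )


def truth_to_json(truth: PlantedTraitTruth) -> str:
    return json.dumps(
        {
            "architecture": truth.architecture,
            "marker_cogs": list(truth.marker_cogs),
            "k": truth.k,
            "label_noise": truth.label_noise,
            "seed": truth.seed,
            "true_labels": {
                g: l.value for g, l in sorted(truth.true_labels.items())
            },
        },
        sort_keys=True,
        indent=2,
    ) + "\n"
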