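"""Brute-force permutation null band for cross-validated balanced accuracy.

Generates the fixed 80-genome null-calibration population, then for each of
1,000 permutations of a balanced label vector runs the full replicated
5-fold cross-validation and records the mean balanced accuracy.  The 2.5th
and 97.5th percentiles of that distribution are the 95% null band frozen
into the test suite: a CV run on genotype-independent labels should land
inside it.

Run from the repository root:

    python scripts/null_band.py [--permutations 1000] [--seed 915]
"""

from __future__ import annotations

import argparse

import numpy as np

from cogtrait.evaluation import crossvalidate
from cogtrait.genotype_io import Label, PhenotypeTable
from cogtrait.synthetic_data import VirtualPopulationSpec, generate_virtual_population

# the null-calibration study population (see docs/methods.md)
POPULATION = VirtualPopulationSpec(
    n_genomes=80, universe_size=5000, mean_genome_size=30, seed=915
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--permutations", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=915)
    args = ap.parse_args()

    profiles = generate_virtual_population(POPULATION)
    base = np.array([Label.POSITIVE] * 40 + [Label.NEGATIVE] * 40)
    rng = np.random.default_rng(args.seed)
    means = []
    for i in range(args.permutations):
        perm = rng.permutation(len(base))
        table = PhenotypeTable(
            "null_trait",
            {p.genome_id: base[j] for p, j in zip(profiles, perm)},
        )
        res = crossvalidate(profiles, table, k=5, n_replicates=10, seed=i)
        means.append(res.mean_ba)
        if (i + 1) % 100 == 0:
            print(f"{i + 1} permutations done", flush=True)

    means = np.asarray(means)
    lo, hi = np.percentile(means, [2.5, 97.5])
    print(f"n = {len(means)}")
    print(f"mean of means = {means.mean():.4f}")
    print(f"95% band = [{lo:.4f}, {hi:.4f}]")
    print(f"min/max = [{means.min():.4f}, {means.max():.4f}]")


if __name__ == "__main__":
    main()
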