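"""Balanced accuracy, replicated cross-validation, and the genome
incompleteness robustness protocol.

Prediction quality is measured as *balanced accuracy*, the mean of
sensitivity and selectivity:

    BA = 1/2 * ( TP/(TP+FN) + TN/(TN+FP) )

which is robust to class imbalance: any classifier that assigns all genomes
to one class scores exactly 0.5 whenever both classes are present in the
evaluation set.

Cross-validation follows the replicated k-fold scheme: per replicate the
genomes are shuffled (replicate seed = base seed + replicate index), split
into k stratified folds, and the true/false prediction counts are pooled
over the k folds *before* one balanced accuracy is computed per replicate;
mean and standard deviation are then taken over replicates (defaults: k=5,
10 replicates).

The incompleteness protocol emulates metagenome-assembled genomes (MAGs):
trait models are trained on intact genomes while each held-out test genome
is degraded by random removal of a fixed fraction of its COGs before
prediction, producing a balanced-accuracy response curve over completeness
levels.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .genotype_io import GenotypeProfile, Label, PhenotypeTable
from .trait_model import DEFAULT_COST_C, Prediction, predict, train

__all__ = [
    "ConfusionCounts",
    "CVResult",
    "CompletenessCurve",
    "balanced_accuracy",
    "confusion_from_predictions",
    "crossvalidate",
    "simulate_incompleteness",
    "completeness_curve",
    "DEFAULT_LEVELS",
    "cv_result_tsv",
    "cv_result_json",
    "curve_tsv",
    "curve_json",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31
DEFAULT_LEVELS: tuple[float, ...] = tuple(x / 10 for x in range(1, 10))


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false prediction counts for one evaluation replicate."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity TP/(TP+FN) and selectivity TN/(TN+FP)."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("balanced accuracy undefined without both classes")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def confusion_from_predictions(
    predictions: Sequence[Prediction], truth: dict[str, Label]
) -> ConfusionCounts:
    """Tally a prediction list against POSITIVE/NEGATIVE reference labels."""
    tp = tn = fp = fn = 0
    for pred in predictions:
        true = truth[pred.genome_id]
        if true is Label.POSITIVE:
            if pred.label is Label.POSITIVE:
                tp += 1
            else:
                fn += 1
        elif true is Label.NEGATIVE:
            if pred.label is Label.NEGATIVE:
                tn += 1
            else:
                fp += 1
        else:
            raise ValueError(
                f"genome {pred.genome_id!r} has UNKNOWN reference label"
            )
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass
class CVResult:
    trait_name: str
    replicates: list[ConfusionCounts]
    balanced_accuracies: list[float]
    mean_ba: float
    sd_ba: float
    k: int
    n_replicates: int
    seed: int
    n_genomes: int = 0


@dataclass
class CompletenessCurve:
    """Mean/sd balanced accuracy per genome-completeness level, with the
    intact-genome cross-validation baseline."""

    trait_name: str
    levels: list[float]
    mean_ba: list[float]
    sd_ba: list[float]
    n_replicates_per_level: int
    baseline_mean_ba: float
    seed: int = 0


def _usable_examples(
    profiles: Sequence[GenotypeProfile], labels: PhenotypeTable
) -> tuple[list[GenotypeProfile], np.ndarray]:
    """Genomes with a classified label and a genotype, in canonical order."""
    by_id = {p.genome_id: p for p in profiles}
    pairs = sorted(
        (g, l) for g, l in labels.classified().items() if g in by_id
    )
    n_missing = len(labels.classified()) - len(pairs)
    if n_missing:
        logger.warning(
            "%d labelled genome(s) lack genotype profiles and were excluded",
            n_missing,
        )
    usable = [by_id[g] for g, _ in pairs]
    y = np.fromiter(
        (1 if l is Label.POSITIVE else 0 for _, l in pairs),
        dtype=np.int64,
        count=len(pairs),
    )
    return usable, y


def _check_class_sizes(y: np.ndarray, k: int) -> None:
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"too few examples for stratified {k}-fold cross-validation "
            f"({n_pos} positive, {n_neg} negative); use a smaller k"
        )


def _replicate_confusion(
    usable: list[GenotypeProfile],
    truth: dict[str, Label],
    y: np.ndarray,
    trait_name: str,
    k: int,
    fold_seed: int,
    cost_C: float,
    kernel: str,
    stratified: bool,
    degrade_rng: np.random.Generator | None = None,
    removal_fraction: float = 0.0,
) -> ConfusionCounts:
    """One replicate: pool confusion counts over the k folds.

    Training folds always use intact genomes; when ``degrade_rng`` is given,
    each held-out genome loses ``removal_fraction`` of its COGs before
    prediction (the incompleteness protocol).
    """
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=k, shuffle=True, random_state=fold_seed)
    counts = ConfusionCounts()
    for train_idx, test_idx in splitter.split(np.zeros(len(usable)), y):
        train_profiles = [usable[i] for i in train_idx]
        fold_labels = PhenotypeTable(
            trait_name, {p.genome_id: truth[p.genome_id] for p in train_profiles}
        )
        model = train(train_profiles, fold_labels, cost_C=cost_C, kernel=kernel)
        test_profiles = [usable[i] for i in test_idx]
        if degrade_rng is not None and removal_fraction > 0:
            test_profiles = [
                simulate_incompleteness(p, removal_fraction, degrade_rng)
                for p in test_profiles
            ]
        counts = counts + confusion_from_predictions(
            predict(model, test_profiles), truth
        )
    return counts


def crossvalidate(
    profiles: Sequence[GenotypeProfile],
    labels: PhenotypeTable,
    k: int = 5,
    n_replicates: int = 10,
    seed: int = 0,
    cost_C: float = DEFAULT_COST_C,
    kernel: str = "linear",
    stratified: bool = True,
) -> CVResult:
    """Replicated stratified k-fold cross-validation.

    One balanced accuracy per replicate (confusion counts pooled over that
    replicate's folds); the replicate fold-shuffle seed is
    ``(seed + replicate_index) mod 2**31`` so identical seeds give
    bit-identical results.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    usable, y = _usable_examples(profiles, labels)
    _check_class_sizes(y, k)
    truth = {p.genome_id: labels.labels[p.genome_id] for p in usable}

    replicates: list[ConfusionCounts] = []
    bas: list[float] = []
    for r in range(n_replicates):
        counts = _replicate_confusion(
            usable,
            truth,
            y,
            labels.trait_name,
            k,
            fold_seed=(seed + r) % _SEED_MOD,
            cost_C=cost_C,
            kernel=kernel,
            stratified=stratified,
        )
        replicates.append(counts)
        bas.append(balanced_accuracy(counts))
    mean_ba = float(np.mean(bas))
    sd_ba = float(np.std(bas, ddof=1)) if len(bas) > 1 else 0.0
    return CVResult(
        trait_name=labels.trait_name,
        replicates=replicates,
        balanced_accuracies=bas,
        mean_ba=mean_ba,
        sd_ba=sd_ba,
        k=k,
        n_replicates=n_replicates,
        seed=seed,
        n_genomes=len(usable),
    )


def simulate_incompleteness(
    profile: GenotypeProfile,
    removal_fraction: float,
    rng: np.random.Generator | int,
) -> GenotypeProfile:
    """Degrade a genome by removing ``round(x * |cogs|)`` COGs uniformly
    without replacement (round half away from zero), emulating an incomplete
    metagenomic bin.  The genome id is unchanged."""
    if not 0 <= removal_fraction < 1:
        raise ValueError(
            f"removal fraction must be in [0, 1), got {removal_fraction}"
        )
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    ordered = sorted(profile.cogs)
    n_remove = int(math.floor(removal_fraction * len(ordered) + 0.5))
    if n_remove == 0:
        return profile
    removed_idx = rng.choice(len(ordered), size=n_remove, replace=False)
    removed = {ordered[i] for i in removed_idx}
    return GenotypeProfile(profile.genome_id, profile.cogs - removed)


def _derive_seed(seed: int, level: float, replicate: int) -> int:
    """Stable, hash-based sub-seed (< 2**31) for a removal RNG stream."""
    key = f"{seed}:{level:.10f}:{replicate}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % _SEED_MOD


def completeness_curve(
    profiles: Sequence[GenotypeProfile],
    labels: PhenotypeTable,
    levels: Sequence[float] = DEFAULT_LEVELS,
    reps_per_level: int = 3,
    k: int = 5,
    seed: int = 0,
    cost_C: float = DEFAULT_COST_C,
    kernel: str = "linear",
    stratified: bool = True,
    baseline_replicates: int = 10,
) -> CompletenessCurve:
    """Balanced-accuracy response to simulated genome incompleteness.

    For each completeness level c and replicate: stratified k-fold
    cross-validation where training folds use intact genomes and every test
    genome is degraded by removal fraction 1 - c before prediction.  Fold
    shuffling reuses the plain cross-validation seed schedule (seed +
    replicate), so a level of 1.0 reproduces ``crossvalidate`` exactly;
    only the COG-removal stream is level-specific.  The intact-genome
    baseline is a plain cross-validation with ``baseline_replicates``
    replicates.
    """
    levels = [float(l) for l in levels]
    if not levels:
        raise ValueError("at least one completeness level required")
    if any(not 0 < l <= 1 for l in levels):
        raise ValueError("completeness levels must lie in (0, 1]")
    if any(b >= a for a, b in zip(levels[1:], levels)):
        raise ValueError("completeness levels must be strictly increasing")
    if reps_per_level < 1:
        raise ValueError("reps_per_level must be at least 1")

    usable, y = _usable_examples(profiles, labels)
    _check_class_sizes(y, k)
    truth = {p.genome_id: labels.labels[p.genome_id] for p in usable}

    baseline = crossvalidate(
        profiles,
        labels,
        k=k,
        n_replicates=baseline_replicates,
        seed=seed,
        cost_C=cost_C,
        kernel=kernel,
        stratified=stratified,
    )

    mean_per_level: list[float] = []
    sd_per_level: list[float] = []
    for level in levels:
        bas: list[float] = []
        for rep in range(reps_per_level):
            rng = np.random.default_rng(_derive_seed(seed, level, rep))
            counts = _replicate_confusion(
                usable,
                truth,
                y,
                labels.trait_name,
                k,
                fold_seed=(seed + rep) % _SEED_MOD,
                cost_C=cost_C,
                kernel=kernel,
                stratified=stratified,
                degrade_rng=rng,
                removal_fraction=1.0 - level,
            )
            bas.append(balanced_accuracy(counts))
        mean_per_level.append(float(np.mean(bas)))
        sd_per_level.append(float(np.std(bas, ddof=1)) if len(bas) > 1 else 0.0)

    return CompletenessCurve(
        trait_name=labels.trait_name,
        levels=levels,
        mean_ba=mean_per_level,
        sd_ba=sd_per_level,
        n_replicates_per_level=reps_per_level,
        baseline_mean_ba=baseline.mean_ba,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# report serialization (TSV row-per-replicate + JSON summary); floats are
# written with repr so identical seeds give byte-identical reports

def cv_result_tsv(result: CVResult) -> str:
    lines = ["replicate\ttp\ttn\tfp\tfn\tbalanced_accuracy"]
    for i, (c, ba) in enumerate(
        zip(result.replicates, result.balanced_accuracies), start=1
    ):
        lines.append(f"{i}\t{c.tp}\t{c.tn}\t{c.fp}\t{c.fn}\t{ba!r}")
    return "\n".join(lines) + "\n"


def cv_result_json(result: CVResult) -> str:
    return json.dumps(
        {
            "trait": result.trait_name,
            "k": result.k,
            "n_replicates": result.n_replicates,
            "n_genomes": result.n_genomes,
            "seed": result.seed,
            "balanced_accuracies": result.balanced_accuracies,
            "mean_ba": result.mean_ba,
            "sd_ba": result.sd_ba,
        },
        sort_keys=True,
        indent=2,
    ) + "\n"


def curve_tsv(curve: CompletenessCurve) -> str:
    lines = ["completeness\tmean_ba\tsd_ba"]
    for level, m, s in zip(curve.levels, curve.mean_ba, curve.sd_ba):
        lines.append(f"{level!r}\t{m!r}\t{s!r}")
    return "\n".join(lines) + "\n"


def curve_json(curve: CompletenessCurve) -> str:
    return json.dumps(
        {
            "trait": curve.trait_name,
            "levels": curve.levels,
            "mean_ba": curve.mean_ba,
            "sd_ba": curve.sd_ba,
            "n_replicates_per_level": curve.n_replicates_per_level,
            "baseline_mean_ba": curve.baseline_mean_ba,
            "seed": curve.seed,
        },
        sort_keys=True,
        indent=2,
    ) + "\n"
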