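"""Linear-SVM trait models on binary COG presence/absence features.

Each genome is encoded as a binary vector over a COG *vocabulary* fixed at
training time (1 = COG present).  No scaling or centering is applied: the
features are presence/absence indicators and a 0/1 encoding keeps the design
matrix sparse and the weights interpretable.  The soft-margin cost defaults
to C = 5, the framework's standard setting for this problem class.

For the (default) linear kernel the model is fully described by one signed
weight per vocabulary COG plus a bias; the decision value of a genome is the
sum of the weights of its present vocabulary COGs plus the bias, and the
genome is called trait-POSITIVE iff that value is strictly positive (a tie
at exactly zero conservatively predicts NEGATIVE).  A *negative predictor*
is a feature whose absence pushes the decision value toward the positive
class -- the signature of traits driven by genome reduction, such as an
obligate intracellular lifestyle.

COGs encountered at prediction time that are absent from the vocabulary
cannot receive a feature index and are silently dropped (a per-call count is
logged): metagenomic inputs routinely contain thousands of novel COGs and a
per-COG warning would be noise.

Non-linear kernels (rbf, polynomial, sigmoid) are available behind the
``kernel`` switch for comparison experiments only; they do not expose
per-feature weights, so feature ranking and text serialization are
unavailable for them.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.svm import SVC

from .genotype_io import GenotypeProfile, Label, PhenotypeTable

__all__ = [
    "FeatureDirection",
    "RankedFeature",
    "TraitModel",
    "Prediction",
    "SingleClassError",
    "ModelFormatError",
    "RankingUnsupportedError",
    "DEFAULT_COST_C",
    "KERNELS",
    "train",
    "predict",
    "rank_features",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

DEFAULT_COST_C = 5.0
#: canonical kernel names; "polynomial" is accepted as an alias of "poly"
KERNELS = ("linear", "rbf", "poly", "sigmoid")
_SOLVER_TOL = 1e-4
_MODEL_FORMAT_HEADER = "# cogtrait model format v1"


class SingleClassError(ValueError):
    """Training set contains only one class after exclusions."""


class ModelFormatError(ValueError):
    """Model file is corrupted, truncated, or of an unknown version."""


class RankingUnsupportedError(ValueError):
    """Feature ranking requested for a model without per-feature weights."""


class FeatureDirection(enum.Enum):
    """Whether a feature's presence or its absence predicts the trait.

    Derived from the weight sign: strictly positive weights mean presence
    predicts the positive class; weights <= 0 (including exact zeros) are
    classed as absence-predictive.
    """

    PRESENCE_PREDICTS_POSITIVE = "presence_predicts_positive"
    ABSENCE_PREDICTS_POSITIVE = "absence_predicts_positive"


@dataclass(frozen=True)
class RankedFeature:
    cog: str
    weight: float
    rank: int  # 1-based, by descending |weight|
    direction: FeatureDirection


@dataclass(frozen=True)
class Prediction:
    genome_id: str
    label: Label
    decision_value: float


@dataclass
class TraitModel:
    """A trained binary trait classifier over a frozen COG vocabulary.

    ``weights`` is one signed real per vocabulary entry for the linear
    kernel and ``None`` otherwise (``supports_ranking`` tells which).
    """

    trait_name: str
    vocabulary: tuple[str, ...]
    weights: np.ndarray | None
    bias: float
    cost_C: float = DEFAULT_COST_C
    kernel: str = "linear"
    n_train_pos: int = 0
    n_train_neg: int = 0
    _estimator: SVC | None = field(default=None, repr=False, compare=False)
    _vocab_index: dict[str, int] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if list(self.vocabulary) != sorted(set(self.vocabulary)):
            raise ValueError("vocabulary must be sorted and duplicate-free")
        if self.weights is not None and len(self.weights) != len(self.vocabulary):
            raise ValueError("one weight per vocabulary COG required")
        if not self._vocab_index:
            self._vocab_index = {c: i for i, c in enumerate(self.vocabulary)}

    @property
    def supports_ranking(self) -> bool:
        return self.kernel == "linear" and self.weights is not None


def _canonical_kernel(kernel: str) -> str:
    k = {"polynomial": "poly"}.get(kernel, kernel)
    if k not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")
    return k


def _encode(
    profiles: Sequence[GenotypeProfile], vocab_index: dict[str, int]
) -> tuple[sp.csr_matrix, int]:
    """Binary CSR design matrix; returns (matrix, count of dropped COGs)."""
    indptr = [0]
    indices: list[int] = []
    n_unseen = 0
    for p in profiles:
        row = []
        for cog in p.cogs:
            j = vocab_index.get(cog)
            if j is None:
                n_unseen += 1
            else:
                row.append(j)
        row.sort()
        indices.extend(row)
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.ones(len(indices), dtype=np.float64), indices, indptr),
        shape=(len(profiles), len(vocab_index)),
    )
    return X, n_unseen


def train(
    profiles: Sequence[GenotypeProfile],
    labels: PhenotypeTable,
    cost_C: float = DEFAULT_COST_C,
    kernel: str = "linear",
) -> TraitModel:
    """Fit a soft-margin SVM on the labelled genomes.

    UNKNOWN-labelled genomes and labelled genomes without a genotype profile
    are excluded (the latter with a logged count).  The vocabulary is the
    sorted union of COGs over the training genomes; training rows are
    ordered by genome id so the fit is invariant to input permutation.
    """
    kernel = _canonical_kernel(kernel)
    if cost_C <= 0:
        raise ValueError(f"cost_C must be positive, got {cost_C}")
    by_id: dict[str, GenotypeProfile] = {}
    for p in profiles:
        if p.genome_id in by_id:
            raise ValueError(f"duplicate genome {p.genome_id!r} in profiles")
        by_id[p.genome_id] = p

    usable: list[tuple[str, Label]] = []
    n_missing = 0
    for genome_id, label in labels.labels.items():
        if label is Label.UNKNOWN:
            continue
        if genome_id not in by_id:
            n_missing += 1
            continue
        usable.append((genome_id, label))
    if n_missing:
        logger.warning(
            "%d labelled genome(s) lack genotype profiles and were excluded",
            n_missing,
        )
    usable.sort()  # canonical row order => permutation-invariant fit

    n_pos = sum(1 for _, l in usable if l is Label.POSITIVE)
    n_neg = len(usable) - n_pos
    if n_pos == 0:
        raise SingleClassError(
            f"trait {labels.trait_name!r} has no positive examples"
        )
    if n_neg == 0:
        raise SingleClassError(
            f"trait {labels.trait_name!r} has no negative examples"
        )

    train_profiles = [by_id[g] for g, _ in usable]
    vocabulary = tuple(sorted(set().union(*(p.cogs for p in train_profiles))))
    if not vocabulary:
        raise ValueError("training genomes contain no COGs")
    vocab_index = {c: i for i, c in enumerate(vocabulary)}
    X, _ = _encode(train_profiles, vocab_index)
    y = np.fromiter(
        (1 if l is Label.POSITIVE else 0 for _, l in usable),
        dtype=np.int64,
        count=len(usable),
    )

    est = SVC(
        C=cost_C,
        kernel=kernel,
        tol=_SOLVER_TOL,
        random_state=0,
        cache_size=256,
    )
    est.fit(X, y)

    if kernel == "linear":
        weights = np.asarray(est.coef_.todense()).ravel().astype(np.float64)
        estimator = None
    else:
        weights = None
        estimator = est
    return TraitModel(
        trait_name=labels.trait_name,
        vocabulary=vocabulary,
        weights=weights,
        bias=float(est.intercept_[0]),
        cost_C=float(cost_C),
        kernel=kernel,
        n_train_pos=n_pos,
        n_train_neg=n_neg,
        _estimator=estimator,
        _vocab_index=vocab_index,
    )


def predict(
    model: TraitModel, profiles: Sequence[GenotypeProfile]
) -> list[Prediction]:
    """Classify genomes; COGs outside the model vocabulary are ignored.

    The decision value of a genome with no vocabulary COG at all is exactly
    the bias, mirroring the collapse to one-class assignment the method
    shows when a genome carries too little information.
    """
    X, n_unseen = _encode(profiles, model._vocab_index)
    if n_unseen:
        logger.info(
            "ignored %d COG occurrence(s) absent from the model vocabulary",
            n_unseen,
        )
    if model.kernel == "linear":
        decision = X @ model.weights + model.bias
    else:
        if model._estimator is None:
            raise ValueError("non-linear model lacks its fitted estimator")
        decision = model._estimator.decision_function(X)
    return [
        Prediction(
            genome_id=p.genome_id,
            label=Label.POSITIVE if dv > 0 else Label.NEGATIVE,
            decision_value=float(dv),
        )
        for p, dv in zip(profiles, decision)
    ]


def rank_features(
    model: TraitModel, top_n: int | None = None
) -> list[RankedFeature]:
    """Rank vocabulary COGs by decreasing |weight| (ties: lexicographic id).

    Only linear-kernel models expose weights; ``top_n=None`` returns the
    full vocabulary.
    """
    if not model.supports_ranking:
        raise RankingUnsupportedError("feature ranking requires a linear kernel")
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be a positive integer or None")
    w = model.weights
    order = sorted(
        range(len(model.vocabulary)),
        key=lambda i: (-abs(w[i]), model.vocabulary[i]),
    )
    if top_n is not None:
        order = order[:top_n]
    return [
        RankedFeature(
            cog=model.vocabulary[i],
            weight=float(w[i]),
            rank=rank,
            direction=(
                FeatureDirection.PRESENCE_PREDICTS_POSITIVE
                if w[i] > 0
                else FeatureDirection.ABSENCE_PREDICTS_POSITIVE
            ),
        )
        for rank, i in enumerate(order, start=1)
    ]


def save_model(model: TraitModel, path: str | Path) -> None:
    """Write the versioned text serialization (linear kernel only).

    Floats are written with ``repr`` (shortest round-trip), so
    save -> load -> save is byte-identical.
    """
    if model.weights is None:
        raise ValueError(
            "only linear-kernel models can be serialized: "
            f"kernel {model.kernel!r} has no per-feature weights"
        )
    lines = [
        _MODEL_FORMAT_HEADER,
        "[meta]",
        f"trait = {model.trait_name}",
        f"cost_C = {model.cost_C!r}",
        f"kernel = {model.kernel}",
        f"n_train_pos = {model.n_train_pos}",
        f"n_train_neg = {model.n_train_neg}",
        f"n_features = {len(model.vocabulary)}",
        "[bias]",
        repr(model.bias),
        "[features]",
    ]
    lines.extend(
        f"{cog}\t{float(w)!r}" for cog, w in zip(model.vocabulary, model.weights)
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _meta_value(lines: list[str], idx: int, key: str, path: str | Path) -> str:
    if idx >= len(lines) or not lines[idx].startswith(f"{key} = "):
        raise ModelFormatError(f"{path}: expected '{key} = ...' in [meta]")
    return lines[idx][len(key) + 3 :]


def load_model(path: str | Path) -> TraitModel:
    """Parse a model file written by :func:`save_model`."""
    try:
        with open(path, "r", encoding="utf-8", newline=None) as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise ModelFormatError(f"{path}: cannot read model file: {exc}") from exc
    if not lines or lines[0] != _MODEL_FORMAT_HEADER:
        raise ModelFormatError(
            f"{path}: not a cogtrait v1 model file "
            f"(header {lines[0]!r} unexpected)" if lines
            else f"{path}: empty model file"
        )
    if len(lines) < 11 or lines[1] != "[meta]":
        raise ModelFormatError(f"{path}: truncated model file")
    try:
        trait_name = _meta_value(lines, 2, "trait", path)
        cost_C = float(_meta_value(lines, 3, "cost_C", path))
        kernel = _meta_value(lines, 4, "kernel", path)
        n_train_pos = int(_meta_value(lines, 5, "n_train_pos", path))
        n_train_neg = int(_meta_value(lines, 6, "n_train_neg", path))
        n_features = int(_meta_value(lines, 7, "n_features", path))
        if lines[8] != "[bias]":
            raise ModelFormatError(f"{path}: missing [bias] section")
        bias = float(lines[9])
        if lines[10] != "[features]":
            raise ModelFormatError(f"{path}: missing [features] section")
        vocabulary: list[str] = []
        weights: list[float] = []
        for line in lines[11:]:
            cog, _, w = line.partition("\t")
            if not _:
                raise ModelFormatError(f"{path}: malformed feature line {line!r}")
            vocabulary.append(cog)
            weights.append(float(w))
    except (ValueError, IndexError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"{path}: corrupted model file: {exc}") from exc
    if len(vocabulary) != n_features:
        raise ModelFormatError(
            f"{path}: [features] lists {len(vocabulary)} entries "
            f"but [meta] declares {n_features} (truncated file?)"
        )
    return TraitModel(
        trait_name=trait_name,
        vocabulary=tuple(vocabulary),
        weights=np.asarray(weights, dtype=np.float64),
        bias=bias,
        cost_C=cost_C,
        kernel=kernel,
        n_train_pos=n_train_pos,
        n_train_neg=n_train_neg,
    )
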