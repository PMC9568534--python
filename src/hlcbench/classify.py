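"""Random-forest cell-identity classification and the dataset compatibility gate.

A forest is trained on the top-variance genes of the normalized training
matrix (default 5000 genes, 500 trees, mandatory seed) and evaluated by its
out-of-bag (OOB) error.  New datasets are admitted to cross-study scoring
only if every one of their PHH/liver control samples receives a PHH/liver
classification probability of at least the gate threshold (default 0.45):
a benchmark control the forest cannot recognize as liver would corrupt the
anchoring of all similarity scores in that dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._errors import ValidationError
from .io import SampleMetadata, PHH_SOURCE
from .normalize import NormalizedMatrix

GATE_THRESHOLD = 0.45


@dataclass
class ClassifierModel:
    """Trained random forest plus everything needed to reuse it.

    Carries the selected gene list, per-gene training means (for imputing
    genes missing from a query), class labels, the recorded seed, and the
    out-of-bag error with per-class confusion counts.
    """

    forest: RandomForestClassifier
    gene_ids: list[str]
    classes: list[str]
    training_gene_means: pd.Series
    n_trees: int
    seed: int
    oob_error: float
    oob_confusion: pd.DataFrame = field(repr=False, default=None)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ClassifierModel":
        return joblib.load(path)


@dataclass
class GateDecision:
    """Verdict on whether a new dataset's PHH/liver controls anchor properly."""

    dataset_id: str
    probabilities: pd.Series  # per control sample, PHH/liver probability
    threshold: float
    compatible: bool

    @property
    def verdict(self) -> str:
        return "compatible" if self.compatible else "not recommended"


def train_classifier(
    matrix: NormalizedMatrix,
    labels: pd.Series,
    n_top_genes: int = 5000,
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierModel:
    """Train a random forest on the top-variance genes with OOB evaluation."""
    labels = labels.loc[matrix.sample_ids]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least two classes")
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            f"class(es) with a single sample: {list(thin.index)}"
        )
    df = matrix.data
    if n_top_genes > df.shape[0]:
        warnings.warn(
            f"n_top_genes={n_top_genes} exceeds available genes ({df.shape[0]}); "
            "using all genes"
        )
        n_top_genes = df.shape[0]
    variances = df.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[:n_top_genes]
    sub = df.loc[top]
    x = sub.to_numpy().T
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(x, labels.to_numpy())
    oob_error = 1.0 - float(forest.oob_score_)
    oob_pred = np.asarray(forest.classes_)[
        np.argmax(forest.oob_decision_function_, axis=1)
    ]
    confusion = pd.crosstab(
        pd.Series(labels.to_numpy(), name="true"),
        pd.Series(oob_pred, name="oob_predicted"),
    )
    return ClassifierModel(
        forest=forest,
        gene_ids=list(top),
        classes=list(forest.classes_),
        training_gene_means=sub.mean(axis=1),
        n_trees=n_trees,
        seed=seed,
        oob_error=oob_error,
        oob_confusion=confusion,
    )


def classify_probabilities(
    model: ClassifierModel, matrix: NormalizedMatrix, min_overlap: float = 0.8
) -> pd.DataFrame:
    """Per-sample class probabilities (fraction of trees voting each class).

    The query matrix must cover at least ``min_overlap`` of the model's gene
    list; missing genes are imputed at the training-set gene mean (an
    extreme value like zero would distort votes on the VST scale).
    """
    present = [g for g in model.gene_ids if g in set(matrix.gene_ids)]
    overlap = len(present) / len(model.gene_ids)
    if overlap < min_overlap:
        raise ValidationError(
            f"query covers only {overlap:.1%} of the model's genes "
            f"(minimum {min_overlap:.0%})"
        )
    features = pd.DataFrame(
        np.tile(model.training_gene_means.to_numpy()[:, None], matrix.data.shape[1]),
        index=model.gene_ids,
        columns=matrix.sample_ids,
    )
    features.loc[present] = matrix.data.loc[present].to_numpy()
    probs = model.forest.predict_proba(features.to_numpy().T)
    return pd.DataFrame(probs, index=matrix.sample_ids, columns=model.classes)


def compatibility_gate(
    probabilities: pd.Series,
    threshold: float = GATE_THRESHOLD,
    dataset_id: str = "query",
) -> GateDecision:
    """Gate a dataset on its PHH/liver controls' classification probabilities.

    The verdict is "not recommended" when *any* control's PHH/liver
    probability falls strictly below the threshold (one unrecognizable
    benchmark sample invalidates cross-study anchoring); a probability
    exactly at the threshold passes.
    """
    if len(probabilities) == 0:
        raise ValidationError(
            "no PHH/Liver control samples in the query; new datasets should "
            "always include PHH/liver control samples"
        )
    compatible = bool((probabilities >= threshold).all())
    return GateDecision(
        dataset_id=dataset_id,
        probabilities=probabilities,
        threshold=threshold,
        compatible=compatible,
    )


def gate_dataset(
    model: ClassifierModel,
    matrix: NormalizedMatrix,
    metadata: SampleMetadata,
    threshold: float = GATE_THRESHOLD,
    dataset_id: str = "query",
) -> GateDecision:
    """Classify a query dataset's PHH/liver controls and apply the gate."""
    controls = [s for s in metadata.phh_controls() if s in matrix.sample_ids]
    if not controls:
        raise ValidationError(
            "no PHH/Liver control samples in the query; new datasets should "
            "always include PHH/liver control samples"
        )
    if PHH_SOURCE not in model.classes:
        raise ValidationError("model was not trained with a PHH/Liver class")
    probs = classify_probabilities(model, matrix)
    phh_probs = probs.loc[controls, PHH_SOURCE]
    phh_probs.name = "phh_probability"
    return compatibility_gate(phh_probs, threshold=threshold, dataset_id=dataset_id)
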