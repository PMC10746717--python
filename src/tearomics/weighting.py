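"""Uncertainty-weighted feature attributions and global rankings.

The classifiers emit a probability for each severity level.  Each
prediction is placed in one of three groups against a confidence
threshold tau (default 0.6):

* **Positive**   — correct prediction with probability > tau,
* **Negative**   — incorrect prediction with probability > tau,
* **Borderline** — probability <= tau, regardless of correctness.

Attributions are then reweighted so that confident correct predictions
speak louder and confident mistakes are muted:

    Positive:    weighted = original / (1 - p)
    Negative:    weighted = original * (1 - p)
    Borderline:  weighted = original

with p the class's predicted probability, clipped to [eps, 1 - eps]
(eps = 1e-6) so the Positive factor cannot blow up when a tree ensemble
outputs a probability numerically equal to 1.  Both factors are strictly
positive, so weighting never flips an attribution's sign.

For multiclass models the weighting is applied per class using each
class's own predicted probability: on a correct prediction the predicted
class is upweighted and every other class downweighted; on an incorrect
prediction the true class is upweighted and all wrong classes (including
the predicted one) downweighted.

Two aggregation modes mirror the two use cases:

* ``incl_bl`` — all samples kept; confident ones reweighted, borderline
  ones untouched.  Requires ground-truth labels.
* ``excl_bl`` — borderline samples dropped; the remaining attributions
  are NOT reweighted.  Needs no ground truth.

Global importance per protein is the sum over retained samples of the
absolute weighted attribution (a signed-sum variant is available), and
rankings are compared at a top-k cutoff (default 15).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tearomics.attribution import AttributionSet

POSITIVE = "Positive"
NEGATIVE = "Negative"
BORDERLINE = "Borderline"
CONFIDENT = "Confident"  # unlabelled cohorts: correctness unknowable

DEFAULT_TAU = 0.6
PROB_EPS = 1e-6


@dataclass(frozen=True)
class PredictionRecord:
    sample_id: str
    predicted_label: int
    predicted_probability: float
    group: str
    true_label: int | None = None


@dataclass
class WeightedAttributionSet:
    """Attribution tensor after weighting / borderline filtering."""

    values: np.ndarray  # (n_retained, n_classes, n_features)
    base_values: np.ndarray
    feature_accessions: list[str]
    class_labels: np.ndarray
    sample_ids: list[str]
    records: list[PredictionRecord]
    mode: str


@dataclass
class FeatureRanking:
    """Descending importance ranking; ties broken by accession."""

    entries: list[tuple[str, float]]
    k: int = 15

    def top(self, k: int | None = None) -> list[str]:
        k = self.k if k is None else k
        return [acc for acc, _ in self.entries[:k]]

    def rank_of(self, accession: str) -> int | None:
        for i, (acc, _) in enumerate(self.entries, start=1):
            if acc == accession:
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.entries) + 1),
             "accession": [a for a, _ in self.entries],
             "score": [s for _, s in self.entries]}
        )


@dataclass
class RankComparison:
    """Top-k differences between two rankings (b judged against a)."""

    k: int
    new_in_b: list[str]
    shifts: dict[str, tuple[int | None, int]] = field(default_factory=dict)

    def shift_magnitudes(self) -> dict[str, int]:
        return {acc: abs(rb - ra) for acc, (ra, rb) in self.shifts.items() if ra is not None}


def group_predictions(
    predicted_labels,
    predicted_probabilities,
    true_labels=None,
    tau: float = DEFAULT_TAU,
    sample_ids=None,
) -> list[PredictionRecord]:
    """Assign each prediction to Positive / Negative / Borderline.

    ``predicted_probabilities`` are the probabilities of the predicted
    class.  Comparisons are strict: probability > tau is confident,
    <= tau is borderline.  Without true labels only Confident/Borderline
    can be assigned (enough for the excl_bl mode).
    """
    predicted_labels = np.asarray(predicted_labels)
    probs = np.asarray(predicted_probabilities, dtype=float)
    if predicted_labels.shape[0] != probs.shape[0]:
        raise ValueError("predicted labels and probabilities misaligned")
    if true_labels is not None and len(true_labels) != len(predicted_labels):
        raise ValueError("true labels misaligned with predictions")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(predicted_labels))]

    records = []
    for i, (pred, p) in enumerate(zip(predicted_labels, probs)):
        if p <= tau:
            group = BORDERLINE
        elif true_labels is None:
            group = CONFIDENT
        else:
            group = POSITIVE if pred == true_labels[i] else NEGATIVE
        records.append(
            PredictionRecord(
                sample_id=str(sample_ids[i]),
                predicted_label=int(pred),
                predicted_probability=float(p),
                group=group,
                true_label=None if true_labels is None else int(true_labels[i]),
            )
        )
    return records


def weight_value(original: float, p: float, group: str) -> float:
    """Reweight one attribution by its prediction's confidence group."""
    p = min(max(float(p), PROB_EPS), 1.0 - PROB_EPS)
    if group == POSITIVE:
        return float(original) / (1.0 - p)
    if group == NEGATIVE:
        return float(original) * (1.0 - p)
    return float(original)


def weight_attributions(
    attr: AttributionSet,
    records: list[PredictionRecord],
    probabilities: np.ndarray,
    mode: str = "incl_bl",
) -> WeightedAttributionSet:
    """Apply the uncertainty weighting (incl_bl) or borderline filter (excl_bl).

    ``probabilities`` is the samples x classes matrix aligned with
    ``attr.class_labels``; the per-class weighting uses each class's own
    predicted probability.
    """
    if mode not in ("incl_bl", "excl_bl"):
        raise ValueError(f"unknown mode {mode!r}")
    n, n_classes, _ = attr.values.shape
    if len(records) != n:
        raise ValueError("records misaligned with attribution samples")
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape != (n, n_classes):
        raise ValueError("probability matrix misaligned with attributions")

    if mode == "excl_bl":
        keep = [i for i, r in enumerate(records) if r.group != BORDERLINE]
        if not keep:
            raise ValueError("all samples are borderline; nothing to retain")
        return WeightedAttributionSet(
            values=attr.values[keep].copy(),
            base_values=attr.base_values.copy(),
            feature_accessions=list(attr.feature_accessions),
            class_labels=attr.class_labels.copy(),
            sample_ids=[attr.sample_ids[i] for i in keep],
            records=[records[i] for i in keep],
            mode=mode,
        )

    if any(r.true_label is None for r in records):
        raise ValueError("incl_bl weighting requires ground-truth labels")

    label_to_col = {int(cl): i for i, cl in enumerate(attr.class_labels)}
    values = attr.values.copy()
    p_clip = np.clip(probabilities, PROB_EPS, 1.0 - PROB_EPS)
    for i, rec in enumerate(records):
        if rec.group == BORDERLINE:
            continue
        up_col = label_to_col[rec.predicted_label if rec.group == POSITIVE else rec.true_label]
        for c in range(n_classes):
            factor = 1.0 / (1.0 - p_clip[i, c]) if c == up_col else (1.0 - p_clip[i, c])
            values[i, c, :] *= factor
    return WeightedAttributionSet(
        values=values,
        base_values=attr.base_values.copy(),
        feature_accessions=list(attr.feature_accessions),
        class_labels=attr.class_labels.copy(),
        sample_ids=list(attr.sample_ids),
        records=list(records),
        mode=mode,
    )


def aggregate_importance(
    w: WeightedAttributionSet | AttributionSet,
    class_of_interest: int | None = None,
    k: int = 15,
    signed: bool = False,
) -> FeatureRanking:
    """Global per-protein importance: sum over retained samples.

    Default is the sum of absolute attribution values; ``signed=True``
    sums signed values and ranks by the magnitude of that sum.  For
    multiclass models ``class_of_interest=None`` aggregates over all
    classes; binary callers typically pass the positive class.
    """
    values = w.values
    if values.shape[0] == 0:
        raise ValueError("no retained samples to aggregate")
    if class_of_interest is not None:
        matches = np.flatnonzero(w.class_labels == class_of_interest)
        if matches.size == 0:
            raise ValueError(f"class {class_of_interest} not in class labels")
        values = values[:, matches[0]: matches[0] + 1, :]
    summed = values.sum(axis=(0, 1)) if signed else np.abs(values).sum(axis=(0, 1))
    scores = np.abs(summed) if signed else summed
    order = sorted(zip(w.feature_accessions, scores), key=lambda t: (-t[1], t[0]))
    return FeatureRanking(entries=[(a, float(s)) for a, s in order], k=k)


def compare_rankings(a: FeatureRanking, b: FeatureRanking, k: int = 15) -> RankComparison:
    """Report rank shifts and which top-k proteins of b are new vs a."""
    if k > len(a.entries) or k > len(b.entries):
        raise ValueError("k exceeds ranking length")
    top_a = a.top(k)
    top_b = b.top(k)
    new = [acc for acc in top_b if acc not in top_a]
    shifts = {acc: (a.rank_of(acc), b.rank_of(acc)) for acc in top_b}
    return RankComparison(k=k, new_in_b=new, shifts=shifts)


def ranking_to_tsv(ranking: FeatureRanking, path: str | Path,
                   names: pd.Series | None = None,
                   comparison: RankComparison | None = None,
                   k: int | None = None) -> None:
    """Write the top-k ranking as TSV (rank, accession, name, score, flag_new)."""
    k = ranking.k if k is None else k
    frame = ranking.to_frame().head(k)
    if names is not None:
        frame["name"] = [names.get(acc, "") for acc in frame["accession"]]
    if comparison is not None:
        new = set(comparison.new_in_b)
        frame["flag_new"] = [acc in new for acc in frame["accession"]]
    frame.to_csv(path, sep="\t", index=False)
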