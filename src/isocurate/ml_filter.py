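"""Random-forest isoform/artifact filter.

A random forest is trained on classification-table attributes of a
true-positive (TP) and a true-negative (TN) transcript set and used to
score the probability that each transcript model is a genuine isoform.
When no lists are supplied, the TP set defaults to FSM reference-match
transcripts and the TN set to NNC transcripts with at least one
noncanonical junction; in that case the junction-canonicality and
distance-to-reference-end attributes are excluded from training to avoid
learning the set definitions themselves. Both sets are balanced by
downsampling the larger to the size of the smaller, then capped.

Multi-exon transcripts are kept when P(isoform) >= threshold (0.7 by
default, inclusive). Mono-exon transcripts carry no junction attributes
and are not scored: they pass unless ``drop_mono_exon`` is set. FSM
transcripts can be forced in with ``force_fsm_in``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .rules_filter import FilterDecision

MIN_TRAINING_SIZE = 250
DEFAULT_THRESHOLD = 0.7

#: Identifier, genome-structure and category columns never used as features.
ALWAYS_EXCLUDED = [
    "isoform", "chrom", "strand", "structural_category", "subcategory",
    "associated_gene", "associated_transcript",
]

#: Extra exclusions when TP/TN sets are derived from the categories
#: themselves (junction canonicality and reference-end distances).
AUTO_SET_EXCLUSIONS = [
    "all_canonical", "min_cov_canonical",
    "diff_to_TSS", "diff_to_TTS", "diff_to_gene_TSS", "diff_to_gene_TTS",
]


class TrainingSetError(ValueError):
    pass


@dataclass
class TrainingSpec:
    tp_ids: Optional[Sequence[str]] = None   # None -> automatic selection
    tn_ids: Optional[Sequence[str]] = None
    min_size: int = MIN_TRAINING_SIZE
    max_size: Optional[int] = None
    excluded_columns: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD
    force_fsm_in: bool = False
    drop_mono_exon: bool = False
    seed: int = 0
    n_trees: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        self.min_size = max(self.min_size, MIN_TRAINING_SIZE)


def auto_training_sets(records: pd.DataFrame, spec: TrainingSpec
                       ) -> tuple[list[str], list[str], list[str]]:
    """Build the TP/TN id lists and any automatic feature exclusions.

    User-supplied lists are used verbatim (after a size check); automatic
    selection takes reference-match transcripts as TP and noncanonical NNC
    transcripts as TN and adds the auto exclusions. The larger set is
    downsampled (seeded) to the smaller, then both are capped at
    ``max_size``.
    """
    auto = spec.tp_ids is None and spec.tn_ids is None
    if auto:
        tp = records.loc[records["subcategory"] == "reference_match",
                         "isoform"].tolist()
        tn = records.loc[(records["structural_category"] == "NNC") &
                         (~records["all_canonical"].astype(bool)),
                         "isoform"].tolist()
        extra = list(AUTO_SET_EXCLUSIONS)
    else:
        if spec.tp_ids is None or spec.tn_ids is None:
            raise TrainingSetError("supply both TP and TN lists, or neither")
        known = set(records["isoform"])
        tp = [t for t in spec.tp_ids if t in known]
        tn = [t for t in spec.tn_ids if t in known]
        extra = []
    for name, ids in (("true-positive", tp), ("true-negative", tn)):
        if len(ids) < spec.min_size:
            raise TrainingSetError(
                f"{name} set has {len(ids)} transcripts; at least "
                f"{spec.min_size} are required for the filter to run")
    rng = np.random.default_rng(spec.seed)
    target = min(len(tp), len(tn))
    if spec.max_size is not None:
        target = min(target, spec.max_size)
    tp = sorted(rng.choice(tp, size=target, replace=False).tolist())
    tn = sorted(rng.choice(tn, size=target, replace=False).tolist())
    return tp, tn, extra


@dataclass
class MLModel:
    forest: RandomForestClassifier
    feature_columns: list[str]
    numeric_columns: list[str]
    categorical_levels: dict[str, list[str]]
    medians: pd.Series
    importances: pd.Series
    holdout_accuracy: float

    def predict_proba(self, records: pd.DataFrame) -> pd.Series:
        """P(isoform) for each row, indexed like ``records``."""
        X = _design_matrix(records, self.numeric_columns,
                           self.categorical_levels, self.medians)
        X = X.reindex(columns=self.feature_columns, fill_value=0.0)
        iso_col = list(self.forest.classes_).index(1)
        return pd.Series(self.forest.predict_proba(X.values)[:, iso_col],
                         index=records.index)


def _feature_columns(records: pd.DataFrame,
                     excluded: Sequence[str]) -> tuple[list[str], list[str]]:
    drop = set(ALWAYS_EXCLUDED) | set(excluded)
    numeric, categorical = [], []
    for col in records.columns:
        if col in drop:
            continue
        if pd.api.types.is_bool_dtype(records[col]) or \
                pd.api.types.is_numeric_dtype(records[col]):
            numeric.append(col)
        else:
            categorical.append(col)
    return numeric, categorical


def _design_matrix(records: pd.DataFrame, numeric: Sequence[str],
                   categorical_levels: dict[str, list[str]],
                   medians: pd.Series) -> pd.DataFrame:
    parts = []
    num = records.reindex(columns=list(numeric)).astype(float)
    num = num.fillna(medians)
    num = num.fillna(0.0)  # columns that were all-missing at training time
    parts.append(num)
    for col, levels in categorical_levels.items():
        vals = records[col].fillna("NA").astype(str) if col in records else \
            pd.Series("NA", index=records.index)
        for level in levels:
            parts.append((vals == level).astype(float).rename(f"{col}={level}"))
    return pd.concat(parts, axis=1)


def train(records: pd.DataFrame, tp_ids: Sequence[str],
          tn_ids: Sequence[str], spec: TrainingSpec,
          extra_excluded: Sequence[str] = ()) -> MLModel:
    """Fit the random forest on balanced TP/TN sets.

    Diagnostics (variable importances and held-out accuracy from a
    stratified 80/20 split) are computed first; the reported model is then
    refitted on the full training data. Deterministic for a fixed seed.
    """
    excluded = list(spec.excluded_columns) + list(extra_excluded)
    numeric, categorical = _feature_columns(records, excluded)
    by_id = records.set_index("isoform", drop=False)
    training = pd.concat([by_id.loc[list(tp_ids)], by_id.loc[list(tn_ids)]])
    y = np.concatenate([np.ones(len(tp_ids), dtype=int),
                        np.zeros(len(tn_ids), dtype=int)])

    medians = training.reindex(columns=numeric).astype(float).median()
    levels = {col: sorted(training[col].fillna("NA").astype(str).unique())
              for col in categorical}
    X = _design_matrix(training, numeric, levels, medians)
    feature_columns = list(X.columns)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X.values, y, test_size=0.2, stratify=y, random_state=spec.seed)
    probe = RandomForestClassifier(n_estimators=spec.n_trees,
                                   random_state=spec.seed)
    probe.fit(X_tr, y_tr)
    holdout = float(probe.score(X_te, y_te))

    forest = RandomForestClassifier(n_estimators=spec.n_trees,
                                    random_state=spec.seed)
    forest.fit(X.values, y)
    importances = pd.Series(forest.feature_importances_,
                            index=feature_columns).sort_values(ascending=False)
    return MLModel(forest=forest, feature_columns=feature_columns,
                   numeric_columns=numeric, categorical_levels=levels,
                   medians=medians, importances=importances,
                   holdout_accuracy=holdout)


def score_and_filter(records: pd.DataFrame, model, spec: TrainingSpec
                     ) -> list[FilterDecision]:
    """Turn model probabilities into isoform/artifact decisions.

    ``model`` needs only a ``predict_proba(records) -> Series`` method.
    """
    probs = model.predict_proba(records)
    decisions = []
    for idx, row in records.iterrows():
        tid = row["isoform"]
        mono = int(row["exons"]) == 1
        if mono:
            if spec.drop_mono_exon:
                decisions.append(FilterDecision(tid, "artifact",
                                                reasons=["mono_exon"]))
            else:
                decisions.append(FilterDecision(tid, "isoform"))
            continue
        p = float(probs.loc[idx])
        if spec.force_fsm_in and row["structural_category"] == "FSM":
            decisions.append(FilterDecision(tid, "isoform", probability=p))
            continue
        if p >= spec.threshold:
            decisions.append(FilterDecision(tid, "isoform", probability=p))
        else:
            decisions.append(FilterDecision(tid, "artifact",
                                            reasons=["ml_probability"],
                                            probability=p))
    return decisions


def run_ml_filter(records: pd.DataFrame, spec: TrainingSpec
                  ) -> tuple[list[FilterDecision], MLModel]:
    """Train (auto or user-listed sets) and filter in one call."""
    tp, tn, extra = auto_training_sets(records, spec)
    model = train(records, tp, tn, spec, extra_excluded=extra)
    return score_and_filter(records, model, spec), model
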