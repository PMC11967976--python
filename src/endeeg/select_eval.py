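"""Chi-square feature selection, classifiers, and validation strategies.

Everything here is leakage-guarded by construction: channel rankings,
feature-bin ranges, chi-square scores and classifier fits are derived
from training units only, and the resulting column set / model is then
applied unchanged to the test units. The ADHD group is the positive
class for sensitivity/specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from endeeg.channel_rank import (
    EntropyConfig,
    class_channel_entropies,
    rank_channels,
    select_top,
)
from endeeg.eeg_io import Recording
from endeeg.errors import ValidationError
from endeeg.features import SegmentationConfig, channel_feature_table

META_COLUMNS = ["subject_id", "label", "segment_index"]
POSITIVE_LABEL = "adhd"

STRATEGIES = ("chrono-70-30", "random-70-30-x10", "kfold-10")
SELECTION_RULES = ("top-k", "above-median-score", "alpha-critical")
CLASSIFIER_KINDS = ("svm-rbf", "knn", "ensemble")


@dataclass
class ChiSquareConfig:
    """Equal-width binning and retention rule for chi-square selection.

    ``above-median-score`` (default) keeps features scoring strictly
    above the median score; ``top-k`` keeps the k best; ``alpha-critical``
    keeps features whose score exceeds the chi-square critical value at
    ``alpha`` with ``n_feature_bins - 1`` degrees of freedom.
    """

    n_feature_bins: int = 10
    selection_rule: str = "above-median-score"
    k: int | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_feature_bins < 2:
            raise ValidationError("n_feature_bins must be >= 2")
        if self.selection_rule not in SELECTION_RULES:
            raise ValidationError(f"selection_rule must be one of {SELECTION_RULES}")


@dataclass
class SplitConfig:
    strategy: str = "chrono-70-30"
    granularity: str = "subject"
    seed: int = 0
    train_fraction: float = 0.7
    n_folds: int = 10
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"strategy must be one of {STRATEGIES}")
        if self.granularity not in ("subject", "segment"):
            raise ValidationError("granularity must be 'subject' or 'segment'")


@dataclass
class ClassifierSpec:
    """One of three documented-default classifiers.

    knn: k = 1, Euclidean. svm-rbf: C = 1, gamma = 'scale'
    (1 / (n_features * feature variance)). ensemble: 100 bagged decision
    trees, seeded. Any default is overridable through ``params``.
    """

    kind: str = "knn"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValidationError(f"classifier kind must be one of {CLASSIFIER_KINDS}")


def split_meta(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate provenance columns from feature columns."""
    feats = [c for c in table.columns if c not in META_COLUMNS]
    return table[META_COLUMNS], table[feats]


def concat_channel_features(tables: list[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Horizontally concatenate per-channel feature tables in ranked order.

    Tables must be row-aligned on (subject_id, segment_index); feature
    columns are prefixed with the channel name.
    """
    if not tables:
        raise ValidationError("no channel tables to concatenate")
    ref_keys = None
    pieces = []
    for channel, table in tables:
        meta, feats = split_meta(table)
        keys = list(zip(meta["subject_id"], meta["segment_index"]))
        if ref_keys is None:
            ref_keys = keys
            pieces.append(meta.reset_index(drop=True))
        elif keys != ref_keys:
            raise ValidationError(
                f"channel {channel!r} feature rows are not aligned with the first table"
            )
        feats = feats.reset_index(drop=True)
        feats.columns = [f"{channel}:{c}" for c in feats.columns]
        pieces.append(feats)
    return pd.concat(pieces, axis=1)


def chi_square_scores(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    cfg: ChiSquareConfig | None = None,
) -> pd.Series:
    """Chi-square statistic of each (binned feature) x class table.

    Each feature is discretized into ``n_feature_bins`` equal-width bins
    over its training range; the statistic is sum((O - E)^2 / E) over the
    bins-by-class contingency table, with empty bins dropped. A constant
    feature scores exactly 0.
    """
    cfg = cfg or ChiSquareConfig()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValidationError("chi-square scoring needs both classes in the training rows")
    class_masks = [labels == c for c in classes]
    n_bins = cfg.n_feature_bins
    scores = {}
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"feature {col!r} has non-finite values")
        lo, hi = v.min(), v.max()
        if not lo < hi:
            scores[col] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        bin_idx = np.clip(np.digitize(v, edges[1:-1]), 0, n_bins - 1)
        observed = np.stack(
            [np.bincount(bin_idx[m], minlength=n_bins) for m in class_masks], axis=1
        ).astype(float)
        observed = observed[observed.sum(axis=1) > 0]
        expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / observed.sum()
        scores[col] = float(np.sum((observed - expected) ** 2 / expected))
    return pd.Series(scores)


def select_features(
    features: pd.DataFrame,
    scores: pd.Series,
    cfg: ChiSquareConfig | None = None,
) -> pd.DataFrame:
    """Reduce a feature table per the retention rule; ties and the final
    column order follow the original column order."""
    cfg = cfg or ChiSquareConfig()
    cols = list(features.columns)
    svals = scores.reindex(cols).to_numpy(dtype=float)
    if cfg.selection_rule == "top-k":
        if cfg.k is None or not 1 <= cfg.k <= len(cols):
            raise ValidationError(f"top-k rule needs 1 <= k <= {len(cols)}, got {cfg.k}")
        order = np.argsort(-svals, kind="stable")[: cfg.k]
        keep = sorted(order)
    elif cfg.selection_rule == "above-median-score":
        med = np.median(svals)
        keep = [i for i, s in enumerate(svals) if s > med]
        if not keep:  # all-equal scores: keep everything rather than nothing
            keep = list(range(len(cols)))
    else:  # alpha-critical
        from scipy.stats import chi2

        crit = chi2.ppf(1 - cfg.alpha, df=cfg.n_feature_bins - 1)
        keep = [i for i, s in enumerate(svals) if s > crit]
        if not keep:
            keep = [int(np.argmax(svals))]
    return features.iloc[:, keep]


def _build_classifier(spec: ClassifierSpec, seed: int):
    from sklearn.ensemble import BaggingClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    p = spec.params
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=int(p.get("k", 1)), metric=p.get("metric", "euclidean"))
    if spec.kind == "svm-rbf":
        return SVC(C=float(p.get("C", 1.0)), kernel="rbf", gamma=p.get("gamma", "scale"))
    return BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=int(p.get("n_estimators", 100)),
        random_state=seed,
    )


def fit_predict(
    spec: ClassifierSpec,
    train_features: pd.DataFrame,
    train_labels,
    test_features: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Train one classifier and label the test rows. Deterministic given
    the spec parameters and seed."""
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set contains a single class")
    clf = _build_classifier(spec, seed)
    clf.fit(train_features.to_numpy(dtype=float), y)
    return clf.predict(test_features.to_numpy(dtype=float))


def metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(accuracy %, sensitivity %, specificity %) from confusion counts.

    ADHD is the positive class. An undefined component (no positives or
    no negatives in the test rows) is reported as NaN with a warning.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValidationError("confusion counts must be non-negative")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValidationError("empty confusion table")
    acc = 100.0 * (tp + tn) / total
    if tp + fn == 0:
        warnings.warn("no positive test rows: sensitivity undefined", stacklevel=2)
        sens = float("nan")
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative test rows: specificity undefined", stacklevel=2)
        spec = float("nan")
    else:
        spec = 100.0 * tn / (tn + fp)
    return acc, sens, spec


def confusion_counts(y_true, y_pred, positive: str = POSITIVE_LABEL) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    return tp, fn, tn, fp


# ------------------------------------------------------------ evaluate ----

@dataclass
class EvaluationReport:
    """Metrics of one pipeline configuration under one validation scheme.

    ``folds`` holds the per-fold/per-repeat breakdown; the top-level
    accuracy/sensitivity/specificity aggregate per strategy (single fold
    for the chronological split, mean over repeats for the repeated
    random split, pooled confusion counts for k-fold).
    """

    config: dict
    folds: list[dict]
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)


@dataclass
class _Unit:
    """One splittable validation unit: a subject, or one of its windows."""

    rec_index: int
    seg_index: int | None
    label: str


def _make_units(recordings: list[Recording], granularity: str, window: int) -> list[_Unit]:
    units = []
    if granularity == "subject":
        for i, rec in enumerate(recordings):
            units.append(_Unit(i, None, rec.label))
    else:
        for i, rec in enumerate(recordings):
            for s in range(rec.n_samples // window):
                units.append(_Unit(i, s, rec.label))
    return units


def _subset_recordings(
    recordings: list[Recording], units: list[_Unit], window: int
) -> list[Recording]:
    """Materialize the recordings view of a unit subset.

    Subject units pass whole recordings through; segment units slice the
    chosen windows out of each recording and concatenate them, so that
    re-segmentation with the same window size recovers exactly those
    windows.
    """
    out = []
    by_rec: dict[int, list[int | None]] = {}
    for u in units:
        by_rec.setdefault(u.rec_index, []).append(u.seg_index)
    for rec_idx in sorted(by_rec):
        rec = recordings[rec_idx]
        segs = by_rec[rec_idx]
        if segs == [None]:
            out.append(rec)
            continue
        cols = np.concatenate(
            [np.arange(s * window, (s + 1) * window) for s in sorted(segs)]
        )
        out.append(
            Recording(
                subject_id=rec.subject_id,
                label=rec.label,
                fs=rec.fs,
                channel_names=list(rec.channel_names),
                data=rec.data[:, cols],
            )
        )
    return out


def _splits(units: list[_Unit], cfg: SplitConfig):
    """Yield (train_units, test_units) per the strategy."""
    y = np.array([u.label for u in units])
    n = len(units)
    if cfg.strategy == "chrono-70-30":
        if cfg.granularity == "segment":
            # chronological within each recording: first 70% of its windows
            train, test = [], []
            by_rec: dict[int, list[_Unit]] = {}
            for u in units:
                by_rec.setdefault(u.rec_index, []).append(u)
            for rec_units in by_rec.values():
                rec_units = sorted(rec_units, key=lambda u: u.seg_index)
                cut = int(len(rec_units) * cfg.train_fraction + 1e-9)
                train.extend(rec_units[:cut])
                test.extend(rec_units[cut:])
            yield train, test
        else:
            cut = int(n * cfg.train_fraction + 1e-9)
            yield units[:cut], units[cut:]
    elif cfg.strategy == "random-70-30-x10":
        from sklearn.model_selection import StratifiedShuffleSplit

        splitter = StratifiedShuffleSplit(
            n_splits=cfg.n_repeats, train_size=cfg.train_fraction, random_state=cfg.seed
        )
        for tr, te in splitter.split(np.zeros(n), y):
            yield [units[i] for i in tr], [units[i] for i in te]
    else:  # kfold-10
        from sklearn.model_selection import StratifiedKFold

        if n < cfg.n_folds:
            raise ValidationError(f"{n} units is fewer than {cfg.n_folds} folds")
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        for tr, te in splitter.split(np.zeros(n), y):
            yield [units[i] for i in tr], [units[i] for i in te]


def evaluate(
    recordings: list[Recording],
    criterion: str = "end",
    top_n: int = 3,
    extractor: str = "slbp",
    classifier: ClassifierSpec | None = None,
    split: SplitConfig | None = None,
    entropy_cfg: EntropyConfig | None = None,
    seg_cfg: SegmentationConfig | None = None,
    chi_cfg: ChiSquareConfig | None = None,
    apply_chi_square: bool = True,
    **extractor_cfgs,
) -> EvaluationReport:
    """Run the full selection-and-classification pipeline under one
    validation strategy.

    Per fold: channels are ranked on the training units only (EnD or
    pooled-entropy criterion), the top ``top_n`` channels' segment
    features are extracted for train and test, optionally reduced by
    chi-square selection fitted on the training rows, and the classifier
    is trained and scored on held-out segments. Test channels follow the
    training-derived ranking throughout.
    """
    classifier = classifier or ClassifierSpec()
    split = split or SplitConfig()
    entropy_cfg = entropy_cfg or EntropyConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    chi_cfg = chi_cfg or ChiSquareConfig()
    if not recordings:
        raise ValidationError("empty cohort")
    if not 1 <= top_n <= recordings[0].n_channels:
        raise ValidationError(
            f"top_n must be in [1, {recordings[0].n_channels}], got {top_n}"
        )

    units = _make_units(recordings, split.granularity, seg_cfg.window_samples)
    folds = []
    for fold_idx, (train_units, test_units) in enumerate(_splits(units, split)):
        if not train_units or not test_units:
            raise ValidationError("degenerate split: empty train or test side")
        train_recs = _subset_recordings(recordings, train_units, seg_cfg.window_samples)
        test_recs = _subset_recordings(recordings, test_units, seg_cfg.window_samples)

        table = class_channel_entropies(train_recs, entropy_cfg)
        ranked = rank_channels(table, criterion)
        channels = select_top(ranked, top_n, criterion)

        train_tabs = [
            (ch, channel_feature_table(train_recs, ch, extractor, seg_cfg,
                                       entropy_cfg=entropy_cfg, **extractor_cfgs))
            for ch in channels
        ]
        test_tabs = [
            (ch, channel_feature_table(test_recs, ch, extractor, seg_cfg,
                                       entropy_cfg=entropy_cfg, **extractor_cfgs))
            for ch in channels
        ]
        train_fm = concat_channel_features(train_tabs)
        test_fm = concat_channel_features(test_tabs)
        train_meta, train_X = split_meta(train_fm)
        test_meta, test_X = split_meta(test_fm)

        if apply_chi_square:
            scores = chi_square_scores(train_X, train_meta["label"], chi_cfg)
            train_X = select_features(train_X, scores, chi_cfg)
            test_X = test_X[train_X.columns]

        y_pred = fit_predict(classifier, train_X, train_meta["label"], test_X, seed=split.seed)
        tp, fn, tn, fp = confusion_counts(test_meta["label"], y_pred)
        acc, sens, spec = metrics(tp, fn, tn, fp)
        folds.append(
            {
                "fold": fold_idx,
                "channels": channels,
                "n_train_segments": len(train_fm),
                "n_test_segments": len(test_fm),
                "n_features": train_X.shape[1],
                "tp": tp, "fn": fn, "tn": tn, "fp": fp,
                "accuracy": acc, "sensitivity": sens, "specificity": spec,
            }
        )

    confusion = {
        k: int(sum(f[k] for f in folds)) for k in ("tp", "fn", "tn", "fp")
    }
    if split.strategy == "kfold-10":
        acc, sens, spec = metrics(**confusion)
    elif split.strategy == "random-70-30-x10":
        acc = float(np.mean([f["accuracy"] for f in folds]))
        sens = float(np.mean([f["sensitivity"] for f in folds]))
        spec = float(np.mean([f["specificity"] for f in folds]))
    else:
        acc, sens, spec = folds[0]["accuracy"], folds[0]["sensitivity"], folds[0]["specificity"]

    config = {
        "criterion": criterion,
        "top_n": top_n,
        "extractor": extractor,
        "classifier": classifier.kind,
        "strategy": split.strategy,
        "granularity": split.granularity,
        "seed": split.seed,
        "n_bins": entropy_cfg.n_bins,
        "range_policy": entropy_cfg.range_policy,
        "window_samples": seg_cfg.window_samples,
        "chi_square": apply_chi_square,
    }
    return EvaluationReport(
        config=config,
        folds=folds,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        confusion=confusion,
    )
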