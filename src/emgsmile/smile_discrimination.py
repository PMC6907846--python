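"""Posed-vs-spontaneous statistics and intra-individual SVM classification.

Two complementary analyses run on the feature table:

* a balanced comparison — classes are shuffled and the majority class
  undersampled to the minority size, then each of the six features is
  compared with a pooled-variance two-sample t-test (df = n1 + n2 − 2),
  Bonferroni-corrected across the six tests, with a 95% CI of the mean
  difference and Cohen's d.  The reported difference is posed − spontaneous.
* an intra-individual classifier — per producer, features are standardized
  on the training split and an RBF-kernel SVM is evaluated over repeated
  stratified 70/15/15 train/validation/test splits; producers with fewer
  than two smiles of either type are excluded.  Accuracy is reported on the
  held-out test split (validation-split accuracy is also recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .envelope_features import FRAME_TO_FEATURE
from .io_core import PipelineConfig, child_rng, logger


@dataclass(frozen=True)
class FeatureComparison:
    """One feature's balanced posed-vs-spontaneous test."""

    feature_name: str
    mean_difference: float  # posed - spontaneous
    t_statistic: float
    degrees_of_freedom: int
    ci95: tuple[float, float]
    cohens_d: float
    p_raw: float
    p_bonferroni: float
    n_per_class: int


@dataclass
class ClassifierReport:
    """Per-producer intra-individual SVM result."""

    producer_id: str
    n_posed: int
    n_spontaneous: int
    accuracies: list[float] = field(default_factory=list)
    val_accuracies: list[float] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies)) if self.accuracies else float("nan")

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def balance_classes(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Shuffle and undersample the majority class to the minority size.

    Never fabricates rows: the output is a subset of the input with equal
    class counts.
    """
    counts = df["smile_type"].value_counts()
    for cls in ("posed", "spontaneous"):
        if counts.get(cls, 0) == 0:
            raise ValueError(f"class {cls!r} absent; cannot balance")
    rng = child_rng(seed, "balance")
    shuffled = df.sample(frac=1.0, random_state=int(rng.integers(2 ** 31)))
    n_min = int(counts.min())
    parts = [shuffled[shuffled["smile_type"] == cls].iloc[:n_min]
             for cls in ("posed", "spontaneous")]
    return pd.concat(parts, axis=0)


def compare_feature(posed: np.ndarray, spontaneous: np.ndarray,
                    n_tests: int = 1, feature_name: str = "") -> FeatureComparison:
    """Pooled-variance two-sample t-test of one feature, posed − spontaneous."""
    posed = np.asarray(posed, dtype=float)
    spontaneous = np.asarray(spontaneous, dtype=float)
    n1, n2 = len(posed), len(spontaneous)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per class")
    df_ = n1 + n2 - 2
    diff = float(posed.mean() - spontaneous.mean())
    pooled_var = ((n1 - 1) * posed.var(ddof=1) + (n2 - 1) * spontaneous.var(ddof=1)) / df_
    if pooled_var == 0.0:
        # both samples constant: identical means -> no evidence of difference
        t_stat, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
        se = 0.0
    else:
        se = float(np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2)))
        t_stat = diff / se
        p = 2.0 * stats.t.sf(abs(t_stat), df_)
    half = stats.t.ppf(0.975, df_) * se
    d = diff / np.sqrt(pooled_var) if pooled_var > 0 else 0.0
    return FeatureComparison(
        feature_name=feature_name,
        mean_difference=diff,
        t_statistic=float(t_stat),
        degrees_of_freedom=df_,
        ci95=(diff - half, diff + half),
        cohens_d=float(d),
        p_raw=float(p),
        p_bonferroni=float(min(1.0, p * n_tests)),
        n_per_class=min(n1, n2),
    )


def run_feature_study(features: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Balanced Bonferroni-corrected t-tests of all six smile features."""
    cfg = cfg or PipelineConfig()
    balanced = balance_classes(features, seed=cfg.seed)
    n_tests = len(FRAME_TO_FEATURE)
    logger.info("feature study: %d rows per class after balancing, %d tests",
                (balanced["smile_type"] == "posed").sum(), n_tests)
    results = []
    for column, name in FRAME_TO_FEATURE.items():
        cmp = compare_feature(
            balanced.loc[balanced["smile_type"] == "posed", column].to_numpy(),
            balanced.loc[balanced["smile_type"] == "spontaneous", column].to_numpy(),
            n_tests=n_tests,
            feature_name=name,
        )
        results.append({
            "feature": cmp.feature_name,
            "mean_difference": cmp.mean_difference,
            "t": cmp.t_statistic,
            "df": cmp.degrees_of_freedom,
            "ci_low": cmp.ci95[0],
            "ci_high": cmp.ci95[1],
            "cohens_d": cmp.cohens_d,
            "p_raw": cmp.p_raw,
            "p_bonferroni": cmp.p_bonferroni,
            "n_per_class": cmp.n_per_class,
        })
    return pd.DataFrame(results)


def _stratified_split(labels: np.ndarray, train_frac: float, val_frac: float,
                      rng: np.random.Generator):
    """Per-class shuffled 70/15/15 index split; train keeps >= 1 per class."""
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = max(1, int(round(train_frac * n)))
        n_val = int(round(val_frac * n))
        if n_train + n_val >= n:  # keep at least one test observation
            n_val = max(0, n - n_train - 1)
        train.extend(idx[:n_train])
        val.extend(idx[n_train : n_train + n_val])
        test.extend(idx[n_train + n_val :])
    return np.array(train), np.array(val), np.array(test)


def classify_intra_individual(features: pd.DataFrame, cfg: PipelineConfig | None = None,
                              seed: int | None = None):
    """Per-producer RBF-SVM over repeated stratified 70/15/15 splits.

    Features are standardized with training-split statistics only.  Returns
    ``(reports, summary)`` where summary holds the cohort mean and SD of the
    per-producer mean test accuracies.
    """
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    feature_cols = list(FRAME_TO_FEATURE)
    reports: list[ClassifierReport] = []
    for pid, group in features.groupby("producer_id", sort=True):
        n_posed = int((group["smile_type"] == "posed").sum())
        n_spont = int((group["smile_type"] == "spontaneous").sum())
        report = ClassifierReport(producer_id=str(pid), n_posed=n_posed, n_spontaneous=n_spont)
        if n_posed < 2 or n_spont < 2:
            report.excluded = True
            report.exclusion_reason = "fewer than two smiles per class"
            reports.append(report)
            continue
        X = group[feature_cols].to_numpy(dtype=float)
        y = (group["smile_type"] == "spontaneous").to_numpy(dtype=int)
        rng = child_rng(seed, f"classifier/{pid}")
        for _ in range(cfg.n_split_repeats):
            tr, va, te = _stratified_split(y, cfg.train_frac, cfg.val_frac, rng)
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Z = (X - mu) / sd
            clf = SVC(C=cfg.svm_c, gamma=cfg.svm_gamma, kernel="rbf")
            clf.fit(Z[tr], y[tr])
            report.accuracies.append(float(np.mean(clf.predict(Z[te]) == y[te])))
            if len(va):
                report.val_accuracies.append(float(np.mean(clf.predict(Z[va]) == y[va])))
        reports.append(report)

    eligible = [r for r in reports if not r.excluded]
    if not eligible:
        raise ValueError("no producer has at least two smiles of each type")
    per_producer = np.array([r.mean_accuracy for r in eligible])
    summary = {
        "n_producers": len(eligible),
        "n_excluded": len(reports) - len(eligible),
        "mean_accuracy": float(per_producer.mean()),
        "sd_accuracy": float(per_producer.std(ddof=1)) if len(per_producer) > 1 else 0.0,
        "mean_val_accuracy": float(np.mean([np.mean(r.val_accuracies) for r in eligible
                                            if r.val_accuracies])) if any(r.val_accuracies for r in eligible) else float("nan"),
    }
    logger.info("intra-individual SVM: %d producers, mean accuracy %.3f (SD %.3f)",
                summary["n_producers"], summary["mean_accuracy"], summary["sd_accuracy"])
    return reports, summary


def reports_to_frame(reports: list[ClassifierReport]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "producer_id": r.producer_id,
            "n_posed": r.n_posed,
            "n_spontaneous": r.n_spontaneous,
            "mean_accuracy": r.mean_accuracy,
            "sd_accuracy": r.sd_accuracy,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
        }
        for r in reports
    ])
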