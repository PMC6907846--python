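"""Human-judgment analytics: forced-choice accuracy, 2×2 contingency tables,
Yates-corrected chi-square, Cohen's and Fleiss' kappa, and a one-sample
t-test of perceiver accuracy against chance.

The published forced-choice confusion tables ship as package fixtures
(``data/table2.csv``: stimulus type × correctness; ``data/table3.csv``:
ethnic match × correctness) so the contingency statistics can be recomputed
from the printed counts.  Note the published tables' columns are
*correctness*, not the judged label; the stimulus × judged-label table is
reconstructed from (true type, correctness): a correct judgment of a posed
smile is a "posed" response, an incorrect one a "spontaneous" response, and
vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .io_core import EmptyInputError, MalformedInputError

TRUE_TYPES = ("posed", "spontaneous")


@dataclass(frozen=True)
class JudgmentRecord:
    """One perceiver's forced-choice judgment of one stimulus."""

    perceiver_id: str
    stimulus_id: str
    producer_id: str
    true_type: str
    judged_type: str
    confidence: float = 50.0
    perceiver_ethnicity: str = ""
    producer_ethnicity: str = ""

    def __post_init__(self) -> None:
        if self.true_type not in TRUE_TYPES or self.judged_type not in TRUE_TYPES:
            raise ValueError("true_type and judged_type must be 'posed' or 'spontaneous'")
        if not 0 <= self.confidence <= 100:
            raise ValueError("confidence must lie in [0, 100]")

    @property
    def correct(self) -> bool:
        return self.judged_type == self.true_type

    @property
    def ethnic_match(self) -> bool:
        return self.perceiver_ethnicity == self.producer_ethnicity


@dataclass
class ContingencyTable2x2:
    """A 2×2 count table with labelled rows and columns."""

    counts: np.ndarray
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def round_percent(x: float) -> int:
    """Round a proportion to the nearest percent, half away from zero."""
    return int(np.floor(abs(x) * 100 + 0.5) * np.sign(x))


# ---------------------------------------------------------------------------
# judgment tables
# ---------------------------------------------------------------------------

_JUDGMENT_COLUMNS = ["perceiver_id", "stimulus_id", "producer_id", "true_type",
                     "judged_type", "confidence", "perceiver_ethnicity", "producer_ethnicity"]


def read_judgments(path: str | Path) -> list[JudgmentRecord]:
    df = pd.read_csv(path).fillna({"perceiver_ethnicity": "", "producer_ethnicity": ""})
    missing = [c for c in _JUDGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(JudgmentRecord(
                perceiver_id=str(row.perceiver_id), stimulus_id=str(row.stimulus_id),
                producer_id=str(row.producer_id), true_type=str(row.true_type),
                judged_type=str(row.judged_type), confidence=float(row.confidence),
                perceiver_ethnicity=str(row.perceiver_ethnicity),
                producer_ethnicity=str(row.producer_ethnicity)))
        except ValueError as exc:
            raise MalformedInputError(f"{path}: row {i + 1}: {exc}") from exc
    return records


def write_judgments(records: Iterable[JudgmentRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=_JUDGMENT_COLUMNS).to_csv(path, index=False)


def accuracy_summary(records: Sequence[JudgmentRecord]) -> dict:
    """Overall, per-true-type and per-perceiver accuracy of the judgments."""
    if not records:
        raise EmptyInputError("no judgment records")
    df = pd.DataFrame({
        "perceiver": [r.perceiver_id for r in records],
        "true_type": [r.true_type for r in records],
        "correct": [r.correct for r in records],
    })
    return {
        "n": len(df),
        "overall": float(df["correct"].mean()),
        "by_true_type": df.groupby("true_type")["correct"].mean().to_dict(),
        "per_perceiver": df.groupby("perceiver")["correct"].mean().to_dict(),
    }


_FACTORS = {
    "true_type": lambda r: r.true_type,
    "judged_type": lambda r: r.judged_type,
    "correct": lambda r: "correct" if r.correct else "incorrect",
    "ethnic_match": lambda r: "match" if r.ethnic_match else "mismatch",
    "perceiver_ethnicity": lambda r: r.perceiver_ethnicity,
    "producer_ethnicity": lambda r: r.producer_ethnicity,
}


def build_table(records: Sequence[JudgmentRecord], rows: str, cols: str) -> ContingencyTable2x2:
    """Cross-tabulate two binary factors of the judgment records.

    Factor names: ``true_type``, ``judged_type``, ``correct``,
    ``ethnic_match``, ``perceiver_ethnicity``, ``producer_ethnicity``.
    """
    if rows not in _FACTORS or cols not in _FACTORS:
        raise ValueError(f"unknown factor; choose from {sorted(_FACTORS)}")
    r_vals = [_FACTORS[rows](r) for r in records]
    c_vals = [_FACTORS[cols](r) for r in records]
    r_levels = sorted(set(r_vals))
    c_levels = sorted(set(c_vals))
    if len(r_levels) != 2 or len(c_levels) != 2:
        raise ValueError(
            f"factors must be binary on the data (got {len(r_levels)} x {len(c_levels)} levels)"
        )
    counts = np.zeros((2, 2), dtype=int)
    for rv, cv in zip(r_vals, c_vals):
        counts[r_levels.index(rv), c_levels.index(cv)] += 1
    return ContingencyTable2x2(counts, tuple(r_levels), tuple(c_levels))


# ---------------------------------------------------------------------------
# published confusion-table fixtures
# ---------------------------------------------------------------------------

def _load_fixture(name: str) -> ContingencyTable2x2:
    with resources.files("emgsmile.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return ContingencyTable2x2(
        df[["incorrect", "correct"]].to_numpy(),
        tuple(df.index), ("incorrect", "correct"),
    )


def load_judgment_table() -> ContingencyTable2x2:
    """Published stimulus type × correctness counts (3942 forced-choice trials)."""
    return _load_fixture("table2.csv")


def load_ethnicity_table() -> ContingencyTable2x2:
    """Published ethnic match/mismatch × correctness counts."""
    return _load_fixture("table3.csv")


def judged_label_table(correctness: ContingencyTable2x2) -> ContingencyTable2x2:
    """Stimulus × judged-label table from a stimulus × correctness table.

    Rows must be the true types.  For a posed stimulus, a correct judgment
    is a "posed" response; for a spontaneous stimulus it is a "spontaneous"
    response.
    """
    if set(correctness.row_labels) != set(TRUE_TYPES):
        raise ValueError("rows must be the true smile types")
    if tuple(correctness.col_labels) != ("incorrect", "correct"):
        raise ValueError("columns must be (incorrect, correct)")
    counts = np.zeros((2, 2), dtype=int)
    for i, true_type in enumerate(correctness.row_labels):
        wrong, right = correctness.counts[i]
        j_correct = TRUE_TYPES.index(true_type)
        counts[i, j_correct] = right
        counts[i, 1 - j_correct] = wrong
    return ContingencyTable2x2(counts, correctness.row_labels, TRUE_TYPES)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def chi_square_2x2(table: ContingencyTable2x2, continuity_correction: bool = True):
    """Pearson chi-square of independence, Yates-corrected by default.

    Returns ``(chi2, df, p)`` with df = 1.  The continuity correction is the
    default because it is what reproduces the published test statistics.
    """
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("a zero margin gives an expected count of 0")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=continuity_correction)
    return float(chi2), int(df), float(p)


def cohens_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Chance-corrected agreement between two raters on categorical labels."""
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("raters must have equal, non-zero length")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return 1.0  # both raters constant and identical: perfect agreement
    # degenerate: each rater constant but different -> p_e may be 1 with p_o < 1
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        raise ValueError("degenerate ratings: both raters constant but disagreeing")
    return float(cohen_kappa_score(a, b))


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for items × raters categorical ratings.

    Every item must be rated by the same number of raters; missing ratings
    must be handled (e.g. listwise) by the caller.
    """
    arr = np.asarray(ratings, dtype=object)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("ratings must be a 2-D items x raters array with >= 2 raters")
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in arr.ravel()):
        raise ValueError("missing ratings; drop incomplete items before calling")
    table, _ = aggregate_raters(arr)
    if np.all(table.max(axis=1) == table.sum(axis=1)):
        return 1.0  # unanimous on every item (statsmodels yields nan when p_e = 1)
    return float(_sm_fleiss_kappa(table))


def ttest_vs_chance(per_perceiver_accuracy: Sequence[float], mu: float = 0.5):
    """One-sample t-test of perceiver accuracies against chance.

    Returns ``(t, df, p, d)`` with Cohen's d = (mean − mu)/sd.  Zero variance
    is reported as an infinite-t path (t = ±inf, p = 0) unless the mean
    equals mu exactly.
    """
    acc = np.asarray(per_perceiver_accuracy, dtype=float)
    if len(acc) < 2:
        raise ValueError("need at least 2 accuracies")
    sd = acc.std(ddof=1)
    df = len(acc) - 1
    if sd == 0:
        if acc.mean() == mu:
            return 0.0, df, 1.0, 0.0
        t = np.inf * np.sign(acc.mean() - mu)
        return float(t), df, 0.0, float(t)
    res = stats.ttest_1samp(acc, mu)
    d = float((acc.mean() - mu) / sd)
    return float(res.statistic), df, float(res.pvalue), d
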