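"""Cross-validated evaluation of the univariate pain scale.

Binary classification: cs/db trials are "no-pain", lp/hp trials "pain"; a
held-out trial is predicted painful when its raw score exceeds the model's
db|lp cutpoint.  Folds are mice (leave-one-mouse-out) or whole strains
(leave-one-strain-out); standardization and the ordinal fit are redone on
every training fold, so no information leaks from held-out trials.

Uncertainty is quantified by a nonparametric percentile bootstrap over the
per-trial correctness indicators, and chance performance by a null model
that assigns classes with their training-set probabilities without looking
at features (expected accuracy sum_c p_c^2).  Strain-level accuracy
differences are compared with Welch's unequal-variance two-sample t-test on
per-trial correctness indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config
from .errors import ModelError, PawsError
from .io import PAIN_STIMULI, STIMULI
from .pain_scale import PainScaleModel, fit_ordinal_scale, score_table

logger = logging.getLogger("paws")


@dataclass
class CVResult:
    """Held-out predictions and summary accuracy for one CV scheme."""

    records: pd.DataFrame       # one row per input trial
    accuracy: float
    ci_low: float
    ci_high: float
    null_accuracy: float        # analytic expectation of the null model
    scheme: str                 # 'loo_mouse' or 'loo_strain'
    feature_set: str
    n_evaluated: int
    skipped_folds: tuple[str, ...] = ()
    per_strain_accuracy: dict[str, float] | None = None

    def correct_flags(self, strain: str | None = None) -> np.ndarray:
        """Per-trial correctness indicators (evaluated trials only)."""
        rec = self.records[self.records["evaluated"]]
        if strain is not None:
            rec = rec[rec["strain"] == strain]
        return rec["correct"].to_numpy(dtype=float)


def binary_pain_labels(table: pd.DataFrame) -> np.ndarray:
    """True binary labels: lp/hp -> pain (True), cs/db -> no-pain (False)."""
    return table["stimulus"].astype(str).isin(PAIN_STIMULI).to_numpy()


def _run_cv(
    table: pd.DataFrame,
    fold_key: list[str],
    features: str,
    config: Config | None,
    scheme: str,
    n_boot: int,
    seed: int,
) -> CVResult:
    table = table.reset_index(drop=True)
    groups = table[fold_key].astype(str).agg("|".join, axis=1)
    fold_ids = groups.unique()
    if len(fold_ids) < 2:
        raise PawsError(f"{scheme} needs at least 2 folds, got {len(fold_ids)}")

    evaluated = np.zeros(len(table), dtype=bool)
    predicted = np.zeros(len(table), dtype=bool)
    skipped: list[str] = []
    present_overall = {s for s in STIMULI if (table["stimulus"].astype(str) == s).any()}
    for fold in fold_ids:
        test_mask = (groups == fold).to_numpy()
        train = table[~test_mask]
        train_classes = set(train["stimulus"].astype(str))
        if train_classes != present_overall:
            skipped.append(fold)
            logger.warning("fold %s skipped: training set missing class(es) %s",
                           fold, sorted(present_overall - train_classes))
            continue
        model = fit_ordinal_scale(train, features, config)
        if model.pain_cutpoint is None:
            skipped.append(fold)
            logger.warning("fold %s skipped: no db|lp boundary in training fit", fold)
            continue
        scored = score_table(model, table[test_mask])
        predicted[test_mask] = scored["predicted_pain"].to_numpy(dtype=bool)
        evaluated[test_mask] = True

    truth = binary_pain_labels(table)
    correct = (predicted == truth) & evaluated
    flags = correct[evaluated].astype(float)
    if flags.size == 0:
        raise PawsError("no trials evaluated: all folds skipped")
    accuracy = float(flags.mean())
    ci_low, ci_high = bootstrap_ci(flags, n_boot=n_boot, seed=seed)
    null_acc, _ = null_model(table, seed=seed)

    records = pd.DataFrame({
        "trial_id": table["trial_id"] if "trial_id" in table else np.arange(len(table)),
        "strain": table["strain"].astype(str),
        "mouse_id": table["mouse_id"].astype(str),
        "stimulus": table["stimulus"].astype(str),
        "fold": groups,
        "evaluated": evaluated,
        "predicted_pain": predicted,
        "true_pain": truth,
        "correct": correct,
    })

    per_strain = None
    if scheme == "loo_strain":
        per_strain = {
            s: float(sub["correct"].mean())
            for s, sub in records[records["evaluated"]].groupby("strain", observed=True)
        }
    return CVResult(
        records=records,
        accuracy=accuracy,
        ci_low=ci_low,
        ci_high=ci_high,
        null_accuracy=null_acc,
        scheme=scheme,
        feature_set=features,
        n_evaluated=int(evaluated.sum()),
        skipped_folds=tuple(skipped),
        per_strain_accuracy=per_strain,
    )


def loo_by_mouse(
    table: pd.DataFrame,
    features: str = "post",
    config: Config | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> CVResult:
    """Leave-one-mouse-out CV; mice are identified by (strain, mouse_id)."""
    return _run_cv(table, ["strain", "mouse_id"], features, config,
                   "loo_mouse", n_boot, seed)


def loo_by_strain(
    table: pd.DataFrame,
    features: str = "post",
    config: Config | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> CVResult:
    """Leave-one-strain-out CV, with per-strain held-out accuracies."""
    return _run_cv(table, ["strain"], features, config, "loo_strain", n_boot, seed)


def null_model(table: pd.DataFrame, seed: int = 0) -> tuple[float, float]:
    """Chance-level baseline that ignores the features entirely.

    Classes are assigned with their empirical probabilities in the data, so
    the expected binary accuracy is ``sum_c p_c^2``.  Returns
    ``(expected_accuracy, realized_accuracy)`` where the second entry is one
    seeded stochastic realization.
    """
    truth = binary_pain_labels(table)
    p_pain = float(truth.mean())
    expected = p_pain**2 + (1 - p_pain) ** 2
    rng = np.random.default_rng(seed)
    draws = rng.random(len(truth)) < p_pain
    realized = float((draws == truth).mean())
    return expected, realized


def bootstrap_ci(
    correct_flags: np.ndarray | list[float],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of per-trial correctness flags."""
    flags = np.asarray(correct_flags, dtype=float)
    n = flags.size
    if n < 2:
        raise PawsError(f"bootstrap needs at least 2 trials, got {n}")
    if n_boot < 1:
        raise PawsError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = flags[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def welch_compare(
    flags_a: np.ndarray | list[float],
    flags_b: np.ndarray | list[float],
    alternative: str = "greater",
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test on per-trial correctness indicators.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    ``alternative`` is 'greater' (mean(a) > mean(b)), 'less', or 'two-sided'.
    """
    a = np.asarray(flags_a, dtype=float)
    b = np.asarray(flags_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PawsError("both samples need n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise PawsError("undefined t statistic: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)
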