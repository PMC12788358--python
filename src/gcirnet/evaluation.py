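"""Subject-wise evaluation and model-comparison statistics.

Accuracy is measured with stratified shuffle splits (default 5
repetitions, 80/20), the full training-dependent pipeline refit per
split.  Cohorts are stratified into Good / Mid / Bad groups by a
reference model's accuracy (>80 / [60, 80] / <60 %), and models are
compared with a Friedman test over subjects, Holm-corrected pairwise
paired-t or Wilcoxon signed-rank tests, and per-subject average ranks.
The per-model "average p-value" is the mean of its corrected pairwise
p-values against all other models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "make_splits",
    "evaluate_subject",
    "stratify_groups",
    "group_gains",
    "friedman_test",
    "pairwise_tests",
    "average_ranking",
]

GROUPS = ("Good", "Mid", "Bad")


def make_splits(
    labels: np.ndarray,
    n_splits: int = 5,
    test_size: float = 0.2,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified shuffle splits over one-hot (or integer) labels."""
    labels = np.asarray(labels)
    cls = np.argmax(labels, axis=1) if labels.ndim == 2 else labels
    _, counts = np.unique(cls, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples for stratification")
    splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros(len(cls)), cls)]


def evaluate_subject(
    estimator_factory: Callable[[], object],
    X: np.ndarray,
    labels: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
) -> dict[str, float | np.ndarray]:
    """Mean +/- sd test accuracy (%) of a refit-per-split estimator.

    ``estimator_factory`` returns a fresh object with ``fit(X, y)`` and
    ``predict(X) -> class indices`` per split.  A split that fails to
    train is skipped with a warning; the mean is over successes.
    """
    if len(splits) < 2:
        raise ValueError("need at least 2 splits")
    labels = np.asarray(labels)
    cls = np.argmax(labels, axis=1) if labels.ndim == 2 else labels
    accs: list[float] = []
    for k, (tr, te) in enumerate(splits):
        try:
            est = estimator_factory()
            est.fit(X[tr], labels[tr])
            pred = np.asarray(est.predict(X[te]))
            accs.append(100.0 * float(np.mean(pred == cls[te])))
        except Exception as exc:  # noqa: BLE001 — report and continue
            warnings.warn(f"split {k} failed to train: {exc}")
    if not accs:
        raise RuntimeError("all splits failed to train")
    arr = np.asarray(accs)
    return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=0)), "per_split": arr}


def stratify_groups(ref_acc: dict[str, float] | Sequence[float]) -> dict:
    """Good (>80), Mid ([60, 80]), Bad (<60) assignment from reference accuracy."""
    if isinstance(ref_acc, dict):
        items = list(ref_acc.items())
    else:
        items = list(enumerate(ref_acc))

    def _group(a: float) -> str:
        if a > 80.0:
            return "Good"
        if a >= 60.0:
            return "Mid"
        return "Bad"

    return {subject: _group(acc) for subject, acc in items}


def group_gains(
    ref: dict[str, float] | Sequence[float],
    new: dict[str, float] | Sequence[float],
    groups: dict,
) -> dict[str, dict[str, float | None]]:
    """Per-group mean accuracy of both models and the gain (new - ref)."""
    ref_d = dict(ref) if isinstance(ref, dict) else dict(enumerate(ref))
    new_d = dict(new) if isinstance(new, dict) else dict(enumerate(new))
    if set(ref_d) != set(new_d) or set(groups) != set(ref_d):
        raise ValueError("ref, new and groups must cover the same subjects")
    out: dict[str, dict[str, float | None]] = {}
    for grp in GROUPS:
        members = [s for s, g in groups.items() if g == grp]
        if not members:
            out[grp] = {"ref": None, "new": None, "gain": None, "n": 0}
            continue
        r = float(np.mean([ref_d[s] for s in members]))
        m = float(np.mean([new_d[s] for s in members]))
        out[grp] = {"ref": r, "new": m, "gain": m - r, "n": len(members)}
    return out


def friedman_test(acc: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over a subjects x models accuracy matrix.

    Rank-based (average ranks on ties) with the asymptotic chi-square
    p-value.  Identical columns give statistic 0, p = 1.
    """
    acc = np.asarray(acc, dtype=np.float64)
    if acc.ndim != 2 or acc.shape[0] < 2 or acc.shape[1] < 2:
        raise ValueError("need a subjects x models matrix with >= 2 of each")
    if not np.all(np.isfinite(acc)):
        raise ValueError("accuracy matrix has missing cells")
    n, k = acc.shape
    # rank within each subject (1 = lowest value; the statistic is
    # invariant to rank direction)
    ranks = np.apply_along_axis(stats.rankdata, 1, acc)
    rbar = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2)
    # tie correction (average-rank ties shrink the statistic's scale)
    ties = 0.0
    for row in acc:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction > 0:
        stat = stat / correction
    p = float(stats.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return float(stat), p


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=np.float64)
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class PairwiseResult:
    p_matrix: np.ndarray          # models x models corrected p (diag NaN)
    raw_p: np.ndarray
    avg_p: np.ndarray             # per-model mean corrected p vs. all others


def pairwise_tests(acc: np.ndarray, test: str = "paired-t") -> PairwiseResult:
    """All-pairs paired tests with Holm correction over the pair family.

    ``test`` is ``"paired-t"`` or ``"wilcoxon"``.  Zero-variance paired
    differences give p = 1 with a warning.  The per-model average of
    corrected p-values against all others is also returned.
    """
    acc = np.asarray(acc, dtype=np.float64)
    n, k = acc.shape
    if test == "wilcoxon" and n < 6:
        raise ValueError("Wilcoxon signed-rank needs at least 6 subjects")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        d = acc[:, i] - acc[:, j]
        if np.allclose(d, 0.0):
            warnings.warn(f"identical columns {i}, {j}: p set to 1")
            raw[idx] = 1.0
            continue
        if test == "paired-t":
            if np.std(d) == 0:
                warnings.warn(f"zero-variance differences for pair ({i}, {j}); p set to 1")
                raw[idx] = 1.0
            else:
                raw[idx] = stats.ttest_rel(acc[:, i], acc[:, j]).pvalue
        elif test == "wilcoxon":
            try:
                raw[idx] = stats.wilcoxon(acc[:, i], acc[:, j], method="exact").pvalue
            except ValueError:
                raw[idx] = stats.wilcoxon(acc[:, i], acc[:, j], method="auto").pvalue
        else:
            raise ValueError(f"unknown test '{test}'")
    adj = _holm(raw)
    pmat = np.full((k, k), np.nan)
    rmat = np.full((k, k), np.nan)
    for idx, (i, j) in enumerate(pairs):
        pmat[i, j] = pmat[j, i] = adj[idx]
        rmat[i, j] = rmat[j, i] = raw[idx]
    avg = np.array([np.nanmean(np.delete(pmat[i], i)) for i in range(k)])
    return PairwiseResult(p_matrix=pmat, raw_p=rmat, avg_p=avg)


def average_ranking(acc: np.ndarray) -> np.ndarray:
    """Per-model mean rank over subjects (rank 1 = best, ties averaged)."""
    acc = np.asarray(acc, dtype=np.float64)
    ranks = np.apply_along_axis(lambda row: stats.rankdata(-row), 1, acc)
    return ranks.mean(axis=0)
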