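"""Evaluation protocol: repeated random 8:2 splits, ROC/AUC with
Youden-optimal operating points, split-level paired t-tests with
Bonferroni correction, and the 1-to-4-timepoint ablation harness.

Splits are drawn at the case (patient) level so no lesion contributes to
both train and test.  Each of the 10 splits is an independent random
partition derived from the master seed; sensitivity and specificity are
reported at the test-set-derived Youden cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SplitPlan:
    n_splits: int = 10
    test_fraction: float = 0.2
    seed: int = 0
    #: draw the test fraction within each class separately.  Plain random
    #: splitting matches the protocol; stratification is an opt-in guard
    #: for small cohorts where a random 20% test set could otherwise be
    #: single-class and leave the ROC undefined.
    stratify: bool = False


def make_splits(
    ids: list[str], plan: SplitPlan, labels=None
) -> list[tuple[list[str], list[str]]]:
    """Random train/test partitions of the grouping units.

    Deterministic under the plan seed; every split covers all units with
    empty intersection.  ``labels`` (aligned with ``ids``) are only
    required for stratified plans.
    """
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 grouping units to split")
    if plan.stratify:
        if labels is None:
            raise ValueError("stratified splitting needs labels")
        labels = np.asarray(labels)
        groups = [np.flatnonzero(labels == v) for v in np.unique(labels)]
    else:
        groups = [np.arange(n)]
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 0x591]))
    splits = []
    for _ in range(plan.n_splits):
        test_idx: list[int] = []
        for g in groups:
            order = g[rng.permutation(len(g))]
            n_test = max(1, int(round(plan.test_fraction * len(g))))
            test_idx.extend(order[:n_test])
        test_set = set(test_idx)
        test = sorted(ids[i] for i in test_set)
        train = sorted(ids[i] for i in range(n) if i not in test_set)
        splits.append((train, test))
    return splits


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC with half credit for ties (Mann-Whitney)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Cutoff maximising J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores
    plus +/-infinity; a case is called positive when score >= cutoff.
    Ties in J are broken toward higher specificity, then higher cutoff.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]]
    )
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for c in candidates:
        pred = scores >= c
        sens = float((pred & (labels == 1)).sum() / n_pos)
        spec = float((~pred & (labels == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, spec, c)
        if best is None or key > (best[0], best[2], best[3]):
            best = (j, sens, spec, c)
    return best[3], best[1], best[2]


def paired_t(auc_a, auc_b) -> float:
    """Two-sided paired t-test p-value over split-level metrics.

    Identical difference vectors (zero variance) are a degeneracy error
    rather than a silent p-value.
    """
    a = np.asarray(auc_a, dtype=np.float64)
    b = np.asarray(auc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of >= 2 paired values")
    d = a - b
    if np.allclose(d, d[0]):
        raise ValueError("degenerate differences: paired values differ by a constant")
    return float(stats.ttest_rel(a, b).pvalue)


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise corrected significance threshold alpha / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


# --------------------------------------------------------------------------
# protocol objects


@dataclass
class RocSummary:
    """Scores + labels of one (model, split) evaluation with ROC metrics."""

    model_id: str
    split_id: int
    scores: np.ndarray
    labels: np.ndarray
    n_timepoints: int = 4
    auc: float = field(init=False)
    cutoff: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels).astype(int)
        self.auc = roc_auc(self.scores, self.labels)
        self.cutoff, self.sensitivity, self.specificity = youden_cutoff(
            self.scores, self.labels
        )


@dataclass
class ComparisonTable:
    """Pairwise paired-t p-values over split AUCs, Bonferroni-flagged."""

    model_ids: list[str]
    p_values: pd.DataFrame
    threshold: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.p_values < self.threshold


def compare_models(
    summaries: list[RocSummary], alpha: float = 0.05, k: int = 4
) -> ComparisonTable:
    ids = sorted({s.model_id for s in summaries})
    auc_by_model = {
        m: [s.auc for s in sorted(
            (x for x in summaries if x.model_id == m), key=lambda x: x.split_id
        )]
        for m in ids
    }
    p = pd.DataFrame(np.nan, index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        pv = paired_t(auc_by_model[a], auc_by_model[b])
        p.loc[a, b] = pv
        p.loc[b, a] = pv
    return ComparisonTable(ids, p, bonferroni_threshold(alpha, k))


def run_protocol(
    data,
    arms: list[str],
    plan: SplitPlan | None = None,
    seed: int = 0,
    n_timepoints: int = 4,
    train_config=None,
) -> list[RocSummary]:
    """Train each arm on every split's training set and score its test set."""
    from .models import make_model

    plan = plan or SplitPlan(seed=seed)
    splits = make_splits(data.ids, plan, labels=data.labels)
    summaries = []
    for split_id, (train_ids, test_ids) in enumerate(splits):
        train, test = data.subset(train_ids), data.subset(test_ids)
        for arm in arms:
            model = make_model(arm, train, n_timepoints, train_config=train_config)
            res = model.fit(seed=seed * 1009 + split_id)
            scores = res.predict(test)
            summaries.append(
                RocSummary(arm, split_id, scores, test.labels, n_timepoints)
            )
    return summaries


def run_timepoint_ablation(
    data,
    arm: str = "conv_gru_2d",
    ks=(1, 2, 3, 4),
    plan: SplitPlan | None = None,
    seed: int = 0,
    train_config=None,
) -> pd.DataFrame:
    """AUC of one arm as a function of the number of sequential scans.

    The same splits, augmentation and schedule are reused for every k;
    only the sequence length changes.  Returns a table with one row per
    (k, split).
    """
    from .models import make_model

    max_t = min(c.n_timepoints for c in data.cases)
    if max(ks) > max_t:
        raise ValueError(f"requested {max(ks)} timepoints, cohort has {max_t}")
    plan = plan or SplitPlan(seed=seed)
    splits = make_splits(data.ids, plan, labels=data.labels)
    rows = []
    for k in ks:
        for split_id, (train_ids, test_ids) in enumerate(splits):
            train, test = data.subset(train_ids), data.subset(test_ids)
            model = make_model(arm, train, n_timepoints=k, train_config=train_config)
            res = model.fit(seed=seed * 1009 + split_id)
            scores = res.predict(test)
            summ = RocSummary(f"{arm}_k{k}", split_id, scores, test.labels, k)
            rows.append(
                {
                    "n_timepoints": k,
                    "split_id": split_id,
                    "auc": summ.auc,
                    "sensitivity": summ.sensitivity,
                    "specificity": summ.specificity,
                }
            )
    return pd.DataFrame(rows)


def compile_report(summaries: list[RocSummary], out_dir: str | Path) -> dict:
    """Write per-split metric and pairwise-p CSVs plus a JSON digest.

    Every number in the report is recomputed from the stored scores.
    """
    if not summaries:
        raise ValueError("no results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "model": s.model_id,
            "split": s.split_id,
            "auc": s.auc,
            "specificity": s.specificity,
            "sensitivity": s.sensitivity,
        }
        for s in sorted(summaries, key=lambda s: (s.model_id, s.split_id))
    ]
    per_split = pd.DataFrame(rows)
    agg = per_split.groupby("model")[["auc", "specificity", "sensitivity"]].agg(
        ["mean", "std"]
    )
    per_split.to_csv(out / "per_split_metrics.csv", index=False)
    agg.to_csv(out / "model_means.csv")
    digest = {
        "models": {
            m: {
                "mean_auc": float(g["auc"].mean()),
                "sd_auc": float(g["auc"].std(ddof=1)) if len(g) > 1 else 0.0,
                "n_splits": int(len(g)),
            }
            for m, g in per_split.groupby("model")
        }
    }
    if per_split["model"].nunique() >= 2 and per_split["split"].nunique() >= 2:
        table = compare_models(summaries)
        table.p_values.to_csv(out / "pairwise_p_values.csv")
        digest["bonferroni_threshold"] = table.threshold
    (out / "summary.json").write_text(json.dumps(digest, indent=2))
    return digest
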