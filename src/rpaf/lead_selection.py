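"""Forward stepwise search for the minimal informative ECG-lead subset.

Phase 1 scores every single lead by k-fold cross-validated F1 and seeds the
subset with the best one.  Each later phase scores the incumbent subset
extended by each remaining lead and accepts the best extension only if its
mean F1 strictly exceeds the incumbent's; the search stops otherwise.  All
candidates within a run are scored on identical record-disjoint folds so
comparisons are paired, and Welch two-sample t-tests against the phase
winner are reported descriptively (they are not the stopping rule).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from rpaf.dataset import LeadImageDataset
from rpaf.evaluation import confusion, metrics, stratified_folds
from rpaf.synthetic_ecg import STANDARD_12_LEADS


@dataclass(frozen=True)
class SelectionConfig:
    """Search parameters; ``fusion`` picks how a subset's RP images enter
    the classifier ("stack" = channel concatenation, "mean" = early fusion
    by image averaging, which keeps model capacity constant across subset
    sizes)."""

    k_folds: int = 5
    metric: str = "F1"
    alpha: float = 0.05
    max_subset: Optional[int] = None  # None -> up to n_leads
    fusion: str = "stack"
    seed: int = 0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.metric != "F1":
            raise ValueError("only the F1 metric is supported")
        if self.fusion not in ("stack", "mean"):
            raise ValueError("fusion must be 'stack' or 'mean'")


@dataclass
class CandidateResult:
    subset: tuple[str, ...]
    fold_scores: list[float]
    mean_f1: float
    p_value_vs_best: float


@dataclass
class PhaseResult:
    phase: int
    candidates: list[CandidateResult]
    best: CandidateResult
    accepted: bool


@dataclass
class SelectionReport:
    phases: list[PhaseResult] = field(default_factory=list)
    chosen_subset: tuple[str, ...] = ()
    stopped_reason: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path


def two_sample_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between two groups of fold scores.

    Degenerate case: both groups constant -> p = 1 when the means agree
    (no evidence of difference), 0 otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 scores")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    with warnings.catch_warnings():
        # near-identical groups trigger a precision-loss warning; the
        # resulting p is ~1 and the exactly-degenerate case is handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def _canonical_rank(lead: str) -> int:
    try:
        return STANDARD_12_LEADS.index(lead)
    except ValueError:
        return len(STANDARD_12_LEADS)


def score_subset(
    leads: Sequence[str],
    dataset: LeadImageDataset,
    model_factory: Callable[[int], object],
    cfg: SelectionConfig = SelectionConfig(),
) -> list[float]:
    """Per-fold F1 scores of a lead subset under k-fold CV.

    Folds depend only on (dataset, cfg.seed), so every subset scored with
    the same config sees identical partitions.  ``model_factory(in_channels)``
    must return a fresh estimator with fit/predict for the stacked input.
    """
    cfg.validate()
    if not leads:
        raise ValueError("lead subset must be non-empty")
    X = dataset.stack(leads, fusion=cfg.fusion)
    y = dataset.labels
    scores = []
    for tr, te in stratified_folds(y, cfg.k_folds, cfg.seed):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("a fold contains a single class")
        model = model_factory(X.shape[1])
        model.fit(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te]))
        f1 = metrics(confusion(y[te], pred, positive=1)).f1
        # a fold with no positive predictions has undefined precision; as a
        # detector score that is a 0, not a missing value
        scores.append(0.0 if np.isnan(f1) else f1)
    return scores


def forward_stepwise(
    dataset: LeadImageDataset,
    model_factory: Callable[[int], object],
    cfg: SelectionConfig = SelectionConfig(),
) -> SelectionReport:
    """Greedy forward search over lead subsets by mean CV F1.

    Ties on mean F1 break toward the canonical 12-lead order.  Accepted
    phases therefore have strictly increasing mean F1 and each phase's
    subset extends the previous one by a single lead.
    """
    cfg.validate()
    all_leads = list(dataset.leads)
    if len(all_leads) < 2:
        raise ValueError("need at least 2 leads to search")
    max_subset = cfg.max_subset if cfg.max_subset is not None else len(all_leads)

    report = SelectionReport()
    incumbent: tuple[str, ...] = ()
    incumbent_mean = -np.inf
    phase = 0
    while len(incumbent) < max_subset:
        phase += 1
        remaining = [l for l in all_leads if l not in incumbent]
        if not remaining:
            report.stopped_reason = "max_subset"
            break
        candidates = []
        for lead in remaining:
            subset = incumbent + (lead,)
            fold_scores = score_subset(subset, dataset, model_factory, cfg)
            candidates.append(
                CandidateResult(
                    subset=subset,
                    fold_scores=[float(s) for s in fold_scores],
                    mean_f1=float(np.mean(fold_scores)),
                    p_value_vs_best=np.nan,
                )
            )
        best = max(
            candidates,
            key=lambda c: (c.mean_f1, -_canonical_rank(c.subset[-1])),
        )
        for cand in candidates:
            cand.p_value_vs_best = (
                1.0 if cand is best else two_sample_t_test(best.fold_scores, cand.fold_scores)
            )
        accepted = best.mean_f1 > incumbent_mean
        report.phases.append(PhaseResult(phase=phase, candidates=candidates, best=best, accepted=accepted))
        if not accepted:
            report.stopped_reason = "no_improvement"
            break
        incumbent = best.subset
        incumbent_mean = best.mean_f1
    else:
        report.stopped_reason = "max_subset"
    report.chosen_subset = incumbent
    return report
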