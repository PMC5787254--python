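"""Discrimination of horizon mortality by the frailty score.

The index's predictive capacity is measured as the probability that a
randomly chosen patient who died before the horizon carries a higher
score than a randomly chosen survivor, with ties credited one half — the
Mann–Whitney form of the area under the ROC curve.  For grouped data
(patients binned into the seven published categories) this reduces to
pair counting over the category order; for continuous scores the same
statistic is the rank-based AUC.  A Youden scan over the band boundaries
picks the operating cutoff maximising sensitivity + specificity - 1.

Deaths before the horizon define the positive class and everyone alive at
the horizon is a negative — valid only under complete follow-up, which is
the validation design (administrative censoring at 24 months, nobody lost
to follow-up).  :func:`horizon_classes` therefore refuses data containing
censoring before the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .cohort_io import GroupedOutcomeCounts
from .instrument import BAND_LOWER, BAND_MIDPOINTS

__all__ = [
    "YoudenResult",
    "RocResult",
    "grouped_auc",
    "continuous_auc",
    "expand_grouped",
    "youden_scan",
    "bootstrap_auc_ci",
    "horizon_classes",
    "roc_analysis",
]


@dataclass
class YoudenResult:
    """Youden-optimal operating point for a horizon."""

    cutoff: float
    j: float
    sensitivity: float
    specificity: float
    scan: pd.DataFrame  # one row per candidate cutoff

    def rounded(self) -> dict:
        """Two-decimal display form matching the instrument's reporting precision."""
        return {
            "cutoff": self.cutoff,
            "j": round(self.j, 2),
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
        }


@dataclass
class RocResult:
    horizon_months: Optional[int]
    auc: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    points: pd.DataFrame  # threshold, sensitivity, specificity
    youden_best: YoudenResult


def _check_counts(counts: GroupedOutcomeCounts) -> tuple[np.ndarray, np.ndarray]:
    deceased = np.asarray(counts.deceased, dtype=float)
    alive = np.asarray(counts.alive, dtype=float)
    if deceased.sum() == 0 or alive.sum() == 0:
        raise ValueError("AUC undefined: need at least one deceased and one alive patient")
    return deceased, alive


def grouped_auc(counts: GroupedOutcomeCounts) -> float:
    """Tie-corrected Mann–Whitney AUC over ordered score bands.

    AUC = (sum_j D_j * A_{<j} + 1/2 sum_j D_j * A_j) / (D * A) where D_j
    and A_j are deceased/alive counts in band j (ordered low to high) and
    A_{<j} the alive count in strictly lower bands.
    """
    deceased, alive = _check_counts(counts)
    alive_below = np.concatenate(([0.0], np.cumsum(alive)[:-1]))
    concordant = float(np.sum(deceased * alive_below))
    ties = float(np.sum(deceased * alive))
    return (concordant + 0.5 * ties) / (deceased.sum() * alive.sum())


def continuous_auc(scores: Sequence[float], deceased: Sequence[bool]) -> float:
    """Rank-based Mann–Whitney AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    deceased = np.asarray(deceased).astype(bool)
    if scores.shape != deceased.shape:
        raise ValueError("scores and deceased must have equal length")
    if deceased.all() or not deceased.any():
        raise ValueError("AUC undefined: both outcome classes must be present")
    return float(roc_auc_score(deceased, scores))


def expand_grouped(counts: GroupedOutcomeCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient expansion of grouped counts using band midpoint scores."""
    scores, status = [], []
    for midpoint, n_alive, n_dead in zip(BAND_MIDPOINTS, counts.alive, counts.deceased):
        scores.extend([midpoint] * (n_alive + n_dead))
        status.extend([False] * n_alive + [True] * n_dead)
    return np.asarray(scores), np.asarray(status)


def youden_scan(counts: GroupedOutcomeCounts) -> YoudenResult:
    """Scan band lower bounds as cutoffs and return the Youden optimum.

    A patient tests positive when their band's lower bound is at or above
    the cutoff.  Ties in J resolve to the lowest cutoff.
    """
    deceased, alive = _check_counts(counts)
    n_dead, n_alive = deceased.sum(), alive.sum()
    rows = []
    for k in range(1, len(counts.bands)):
        cutoff = BAND_LOWER[k]
        sens = deceased[k:].sum() / n_dead
        spec = alive[:k].sum() / n_alive
        rows.append(
            {
                "cutoff": cutoff,
                "sensitivity": sens,
                "specificity": spec,
                "j": sens + spec - 1.0,
            }
        )
    scan = pd.DataFrame(rows)
    best = scan.loc[scan["j"].idxmax()]
    return YoudenResult(
        cutoff=float(best["cutoff"]),
        j=float(best["j"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        scan=scan,
    )


def bootstrap_auc_ci(
    scores: Sequence[float],
    deceased: Sequence[bool],
    n_boot: int = 2000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval for the AUC.

    Resamples patients with replacement; a resample missing one of the
    outcome classes (possible in tiny or very unbalanced samples) is
    redrawn so the AUC stays defined in every replicate.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores = np.asarray(scores, dtype=float)
    deceased = np.asarray(deceased).astype(bool)
    continuous_auc(scores, deceased)  # validates shapes and classes
    rng = np.random.default_rng(seed)
    n = scores.size
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            sample = deceased[idx]
            if sample.any() and not sample.all():
                break
        else:  # pragma: no cover - requires pathological inputs
            raise RuntimeError("could not draw a two-class bootstrap resample")
        stats[b] = continuous_auc(scores[idx], sample)
    low, high = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def horizon_classes(
    time_months: Sequence[float],
    event: Sequence[bool],
    horizon_months: float,
) -> np.ndarray:
    """Deceased-by-horizon indicator, refusing pre-horizon censoring.

    Patients censored before the horizon have unknown status there; this
    estimator assumes complete follow-up and raises instead of silently
    treating them as survivors.
    """
    time_months = np.asarray(time_months, dtype=float)
    event = np.asarray(event).astype(bool)
    censored_early = (~event) & (time_months < horizon_months)
    if censored_early.any():
        raise ValueError(
            f"{int(censored_early.sum())} patient(s) censored before "
            f"{horizon_months} months; horizon ROC requires complete follow-up"
        )
    return event & (time_months <= horizon_months)


def roc_analysis(
    scores: Sequence[float],
    time_months: Sequence[float],
    event: Sequence[bool],
    horizon_months: int,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> RocResult:
    """Full ROC analysis of continuous scores at a mortality horizon."""
    scores = np.asarray(scores, dtype=float)
    positive = horizon_classes(time_months, event, horizon_months)
    auc = continuous_auc(scores, positive)
    ci_low, ci_high = bootstrap_auc_ci(scores, positive, n_boot=n_boot, seed=seed)

    thresholds = np.unique(scores)
    n_pos, n_neg = positive.sum(), (~positive).sum()
    rows = []
    for threshold in thresholds:
        test_pos = scores >= threshold
        rows.append(
            {
                "threshold": float(threshold),
                "sensitivity": float((test_pos & positive).sum() / n_pos),
                "specificity": float((~test_pos & ~positive).sum() / n_neg),
            }
        )
    points = pd.DataFrame(rows)
    j = points["sensitivity"] + points["specificity"] - 1.0
    best = points.loc[j.idxmax()]
    youden = YoudenResult(
        cutoff=float(best["threshold"]),
        j=float(j.max()),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        scan=points.assign(j=j),
    )
    return RocResult(
        horizon_months=horizon_months,
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        points=points,
        youden_best=youden,
    )
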