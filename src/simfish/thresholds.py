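"""Similarity-threshold confidence analysis.

The similarity between a query and the nearest reference ligand of a
predicted target quantifies how much that prediction can be trusted: below
a fingerprint-specific threshold the hit is indistinguishable from the
background similarity between random molecules, whatever its rank.  This
module provides:

* :func:`apply_threshold` — drop predictions whose best-neighbor
  similarity falls below tau (ranks are kept, so "top-10" always means the
  top-10 of the unfiltered ranking);
* :func:`threshold_sweep` — metrics over the full tau grid (step 0.01),
  precision-recall pairs for curves, and the balanced threshold tau_F1
  (smallest tau attaining the maximum F1);
* :func:`bin_precision_profile` — precision and background-target counts
  in 10 equal-width similarity bins, from which the true-positive onset
  threshold tau_TP is read;
* :func:`improved_enrichment_rate` — the fold reduction in targets that
  must be picked per true positive when the threshold is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import MetricsReport, TFEvent, compute_metrics
from .scoring import PredictionList


def apply_threshold(prediction: PredictionList, tau: float) -> PredictionList:
    """Remove entries with best-neighbor similarity below tau.

    Filtering acts on the top-1 Tc to the target (``best_similarity``)
    even when the ranking score was a KNN average.  Surviving entries keep
    their pre-filter ranks.
    """
    if tau < 0:
        raise ValueError("threshold must be non-negative")
    entries = tuple(e for e in prediction.entries if e.best_similarity >= tau)
    return PredictionList(
        query_id=prediction.query_id,
        scheme=prediction.scheme,
        kind=prediction.kind,
        entries=entries,
    )


def retained_count(events: list[TFEvent], n: int, tau: float | None) -> int:
    """Total retained top-n predictions across events at threshold tau."""
    total = 0
    for ev in events:
        entries = ev.prediction.top(n)
        if tau is not None:
            entries = tuple(e for e in entries if e.best_similarity >= tau)
        total += len(entries)
    return total


@dataclass(frozen=True)
class ThresholdSweepResult:
    kind: str
    n: int
    grid: tuple[float, ...]
    reports: tuple[MetricsReport, ...]  # one per grid point
    tau_f1: float
    max_f1: float
    tau_tp: float | None  # onset threshold from the bin profile

    def pr_curve(self) -> list[tuple[float, float]]:
        """(recall, precision) pairs along the grid, for curve plotting."""
        return [(r.recall, r.precision) for r in self.reports]

    def report_at(self, tau: float) -> MetricsReport:
        for g, r in zip(self.grid, self.reports):
            if abs(g - tau) < 1e-9:
                return r
        raise KeyError(f"tau {tau} not on the sweep grid")


@dataclass(frozen=True)
class BinProfile:
    """Precision and background counts in 10 equal-width similarity bins.

    Each retained top-n prediction is assigned to the bin containing its
    best-neighbor similarity; bins are [lo, hi) with the last bin closed.
    ``counts`` are the background-target counts (all retained predictions)
    and ``precision`` the known-target fraction per bin (NaN for empty
    bins).
    """

    n: int
    edges: tuple[float, ...]  # 11 edges, 0.0 .. 1.0
    counts: tuple[int, ...]
    tp_counts: tuple[int, ...]
    precision: tuple[float, ...]


def bin_precision_profile(events: list[TFEvent], n: int = 10) -> BinProfile:
    """Per-bin precision of top-n predictions over 10 similarity bins."""
    edges = np.linspace(0.0, 1.0, 11)
    counts = np.zeros(10, dtype=int)
    tps = np.zeros(10, dtype=int)
    for ev in events:
        known = ev.query.known_targets
        for entry in ev.prediction.top(n):
            idx = min(int(entry.best_similarity * 10), 9)
            counts[idx] += 1
            if entry.target_id in known:
                tps[idx] += 1
    precision = tuple(
        (tps[i] / counts[i]) if counts[i] else float("nan") for i in range(10)
    )
    return BinProfile(
        n=n,
        edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        tp_counts=tuple(int(t) for t in tps),
        precision=precision,
    )


def detect_tp_onset(profile: BinProfile, precision_floor: float = 0.0) -> float:
    """Lower edge of the first bin whose precision exceeds the floor.

    With the default floor of 0 this is the first bin containing any true
    positive: below that similarity, predictions are background noise.
    """
    for i in range(10):
        if profile.counts[i] and profile.precision[i] > precision_floor:
            return profile.edges[i]
    raise ValueError("no bin exceeds the precision floor (no true positives?)")


def improved_enrichment_rate(
    events: list[TFEvent], n: int, tau: float
) -> float:
    """Fold reduction in picks needed per true positive at threshold tau.

    At equal recall the number of targets one must pick scales with the
    inverse precision (picks per true positive = 1/PR), so the improvement
    is the precision ratio PR_n(tau) / PR_n(0).  Identically 1 at tau = 0.
    """
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    base = compute_metrics(events, n, tau=None).precision
    if base == 0:
        raise ValueError("baseline precision is 0; enrichment rate undefined")
    return compute_metrics(events, n, tau=tau).precision / base


def threshold_sweep(
    events: list[TFEvent],
    n: int = 10,
    step: float = 0.01,
    kind: str = "",
) -> ThresholdSweepResult:
    """Metrics across the full similarity-cutoff grid {0, step, ..., 1}.

    tau_F1 is the smallest grid point attaining the maximum F1 (reported
    at the grid resolution); tau_TP is read from the 10-bin precision
    profile when any true positive exists.
    """
    if not 0 < step <= 1:
        raise ValueError("step must lie in (0, 1]")
    n_steps = round(1.0 / step)
    grid = tuple(round(i * step, 10) for i in range(n_steps + 1))
    reports = tuple(
        compute_metrics(events, n, tau=tau) for tau in grid
    )
    f1s = [r.f1 for r in reports]
    max_f1 = max(f1s)
    tau_f1 = grid[int(np.argmax(f1s))]  # argmax takes the first (smallest tau)
    try:
        tau_tp = detect_tp_onset(bin_precision_profile(events, n))
    except ValueError:
        tau_tp = None
    return ThresholdSweepResult(
        kind=kind, n=n, grid=grid, reports=reports,
        tau_f1=float(tau_f1), max_f1=float(max_f1), tau_tp=tau_tp,
    )
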