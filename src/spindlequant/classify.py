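"""Rule-based classification of spindle-elongation trajectories.

A trace is scored with three rules anchored at SPB separation (t = 0):

* r10 — the spindle exceeds 2 μm at some sampled point in (0, 10] min;
* r15 — the spindle exceeds 2.5 μm at some sampled point in (0, 15] min;
* reach6 — the spindle reaches 6 μm within (0, 60] min.

Cells that never reach 6 μm are "failed" regardless of early kinetics.
Otherwise agreement of r10 and r15 gives "immediate" (both true) or "normal"
(both false).  Disagreement produces a conflict that is curated with the
inflection-point heuristics implemented here; every curation decision is
recorded so the provenance of each label is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .core import CellRecord, SpindleTrajectory
from .params import ClassifierConfig

_EPS = 1e-9

DEFAULT_CONFIG = ClassifierConfig()


@dataclass
class RuleFlags:
    """Outcome of the three threshold rules on one trace."""

    r10: bool
    r15: bool
    reach6: bool


@dataclass
class InflectionReport:
    """Best continuous two-segment piecewise-linear fit of a trace.

    ``clear`` marks an anaphase-onset-like inflection: the post-breakpoint
    slope dominates the pre-slope and the two-segment fit removes most of the
    single-line residual.
    """

    breakpoint_time: float
    pre_slope: float
    post_slope: float
    sse_reduction: float
    clear: bool


@dataclass
class ClassificationResult:
    label: str
    flags: RuleFlags
    conflict: str  # none | immediate/normal | normal/immediate
    curation_rule_applied: str
    inflection: Optional[InflectionReport] = None

    def as_dict(self) -> dict:
        d = {
            "label": self.label,
            "r10": self.flags.r10,
            "r15": self.flags.r15,
            "reach6": self.flags.reach6,
            "conflict": self.conflict,
            "curation": self.curation_rule_applied,
        }
        if self.inflection is not None:
            d["inflection_clear"] = self.inflection.clear
            d["breakpoint_time"] = self.inflection.breakpoint_time
        return d


def rule_flags(traj: SpindleTrajectory, config: ClassifierConfig = DEFAULT_CONFIG) -> RuleFlags:
    """Evaluate the three threshold rules by direct scan of the samples.

    Thresholds at 10/15 min are strict ("more than 2 μm"); the 6 μm rule is
    inclusive ("elongate to 6 μm").  Intervals are half-open (0, T]: the
    formation frame itself is excluded.  Traces shorter than 60 min evaluate
    reach6 over the available window with a warning.
    """
    t, y = traj.times, traj.lengths
    if t[-1] < config.t_rule15 - _EPS:
        raise ValueError("trajectory must cover at least 15 min for rule evaluation")
    if t[-1] < config.t_end - _EPS:
        warnings.warn(
            f"trajectory covers only {t[-1]:.0f} min; reach6 evaluated over the available window"
        )
    in10 = (t > _EPS) & (t <= config.t_rule10 + _EPS)
    in15 = (t > _EPS) & (t <= config.t_rule15 + _EPS)
    in60 = (t > _EPS) & (t <= config.t_end + _EPS)
    return RuleFlags(
        r10=bool(np.any(y[in10] > config.thresh_10)),
        r15=bool(np.any(y[in15] > config.thresh_15)),
        reach6=bool(np.any(y[in60] >= config.thresh_reach)),
    )


def _hinge_fit(t: np.ndarray, y: np.ndarray, tb: float) -> tuple[float, float, float]:
    """Continuous two-segment least squares with a hinge at ``tb``.

    Returns (sse, pre_slope, post_slope)."""
    X = np.column_stack([np.ones_like(t), t, np.maximum(t - tb, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), float(beta[1]), float(beta[1] + beta[2])


def detect_inflection(
    traj: SpindleTrajectory, config: ClassifierConfig = DEFAULT_CONFIG
) -> InflectionReport:
    """Locate the anaphase-onset inflection as the best two-segment fit.

    The trace is lightly median-smoothed (window ``smooth_window``) before
    fitting and truncated shortly after it first approaches its maximum, so
    the hinge tracks the onset of rapid elongation rather than the terminal
    anaphase plateau.  Every interior sample of the window is tried as the
    hinge.  ``clear`` requires post_slope ≥ slope_ratio_min × max(pre_slope,
    slope_floor) and a fractional SSE reduction ≥ sse_min relative to the
    single-line fit.
    """
    t, y = traj.times, traj.lengths.copy()
    if t.size < 6:
        raise ValueError("inflection detection needs at least 6 samples")
    k = config.smooth_window
    if k >= 3 and k % 2 == 1 and t.size > k:
        y = medfilt(y, kernel_size=k)

    span = float(y.max() - y.min())
    near_peak = np.nonzero(y >= y.min() + 0.95 * span)[0]
    end = int(near_peak[0]) + 3 if near_peak.size else t.size
    end = min(max(end, 12), t.size)
    t, y = t[:end], y[:end]

    X1 = np.column_stack([np.ones_like(t), t])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid1 = y - X1 @ beta1
    sse1 = float(resid1 @ resid1)

    best = None
    for tb in t[2:-3]:
        sse, pre, post = _hinge_fit(t, y, tb)
        if best is None or sse < best[0]:
            best = (sse, pre, post, float(tb))
    if best is None:  # fewer than 6 interior candidates
        return InflectionReport(float(t[t.size // 2]), float(beta1[1]), float(beta1[1]), 0.0, False)
    sse, pre, post, tb = best
    reduction = 1.0 - sse / sse1 if sse1 > 1e-12 else 0.0
    clear = (
        post >= config.slope_ratio_min * max(pre, config.slope_floor)
        and reduction >= config.sse_min
        and post > pre
    )
    return InflectionReport(tb, pre, post, reduction, bool(clear))


def _transient_crossing(traj: SpindleTrajectory, config: ClassifierConfig) -> bool:
    """'Elongated past 2 μm in a single time point', transient reading: the
    threshold is exceeded at exactly one frame within (0, 10]."""
    t, y = traj.times, traj.lengths
    in10 = (t > _EPS) & (t <= config.t_rule10 + _EPS)
    return int(np.sum(y[in10] > config.thresh_10)) == 1


def _step_crossing(traj: SpindleTrajectory, config: ClassifierConfig) -> bool:
    """Alternative reading: the 2 μm threshold is crossed in one frame-to-frame
    step of at least ``step_min`` μm within (0, 10]."""
    t, y = traj.times, traj.lengths
    for i in range(1, t.size):
        if _EPS < t[i] <= config.t_rule10 + _EPS:
            if y[i - 1] <= config.thresh_10 < y[i] and (y[i] - y[i - 1]) >= config.step_min:
                return True
    return False


def _shortening_between(traj: SpindleTrajectory, t0: float, t1: float, min_drop: float) -> bool:
    t, y = traj.times, traj.lengths
    for i in range(1, t.size):
        if t[i - 1] >= t0 - _EPS and t[i] <= t1 + _EPS:
            if y[i - 1] - y[i] >= min_drop:
                return True
    return False


def _slow_continuous(traj: SpindleTrajectory, horizon: float = 30.0) -> bool:
    """Median frame-to-frame increment positive over (0, horizon]."""
    t, y = traj.times, traj.lengths
    sel = (t > _EPS) & (t <= horizon + _EPS)
    idx = np.where(sel)[0]
    if idx.size < 2:
        return False
    return float(np.median(np.diff(y[idx]))) > 0.0


def classify(
    traj: SpindleTrajectory, config: ClassifierConfig = DEFAULT_CONFIG
) -> ClassificationResult:
    """Classify one trajectory as normal / immediate / failed.

    Precedence: a trace that never reaches 6 μm is "failed".  Otherwise
    agreement of the 10- and 15-min rules decides directly; disagreement is
    curated with the inflection heuristics, and a conflict that neither
    curation clause resolves falls back to the verdict of the longer-horizon
    15-min rule, flagged ``unresolved``.
    """
    flags = rule_flags(traj, config)
    conflict = "none"
    if flags.r10 and not flags.r15:
        conflict = "immediate/normal"
    elif flags.r15 and not flags.r10:
        conflict = "normal/immediate"

    infl = detect_inflection(traj, config) if len(traj) >= 6 else None

    if not flags.reach6:
        return ClassificationResult("failed", flags, conflict, "failed_never_reaches_6um", infl)

    if conflict == "none":
        label = "immediate" if flags.r10 else "normal"
        return ClassificationResult(label, flags, conflict, f"rules_agree_{label}", infl)

    if conflict == "immediate/normal":
        crossing = (
            _transient_crossing(traj, config)
            if config.crossing_mode == "transient"
            else _step_crossing(traj, config)
        )
        if crossing and infl is not None and infl.clear:
            return ClassificationResult(
                "normal", flags, conflict, "curated_single_point_crossing_with_inflection", infl
            )
        if (infl is None or not infl.clear) and _shortening_between(
            traj, 10.0, 15.0, config.shortening_min
        ):
            return ClassificationResult(
                "immediate", flags, conflict, "curated_no_inflection_shortening_10_15", infl
            )
        # unresolved: fall back to the 15-min rule's verdict (here: normal)
        return ClassificationResult("normal", flags, conflict, "unresolved_default_r15", infl)

    # conflict == "normal/immediate"
    if (
        infl is not None
        and infl.clear
        and 10.0 - _EPS <= infl.breakpoint_time <= 15.0 + _EPS
    ):
        return ClassificationResult(
            "normal", flags, conflict, "curated_anaphase_onset_10_15", infl
        )
    if (infl is None or not infl.clear) and _slow_continuous(traj):
        return ClassificationResult(
            "immediate", flags, conflict, "curated_slow_continuous_elongation", infl
        )
    return ClassificationResult("immediate", flags, conflict, "unresolved_default_r15", infl)


def classify_population(
    records: Sequence[Union[CellRecord, SpindleTrajectory]],
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, dict]:
    """Classify every cell and tabulate class and conflict fractions.

    Returns a per-cell table (one row per cell, with rule flags, conflict and
    curation provenance, plus the ground-truth class when available) and a
    dict of fractions with exact counts.
    """
    if len(records) == 0:
        raise ValueError("classify_population needs at least one record")
    rows = []
    for i, rec in enumerate(records):
        if isinstance(rec, CellRecord):
            traj, cid, true_cls = rec.trajectory, rec.cell_id, rec.true_class
        else:
            traj, cid, true_cls = rec, f"cell{i:04d}", None
        res = classify(traj, config)
        row = {"cell_id": cid, "true_class": true_cls}
        row.update(res.as_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    n = len(table)
    counts = table["label"].value_counts().to_dict()
    fractions = {
        "n": n,
        "counts": {k: int(counts.get(k, 0)) for k in ("normal", "immediate", "failed")},
        "fractions": {
            k: counts.get(k, 0) / n for k in ("normal", "immediate", "failed")
        },
        "n_conflict": int((table["conflict"] != "none").sum()),
        "conflict_fraction": float((table["conflict"] != "none").mean()),
    }
    return table, fractions
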