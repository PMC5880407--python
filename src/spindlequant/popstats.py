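"""Population-level statistics of mitotic timing and chromosome segregation.

Separation timing applies the 0-floor rule: when sister-chromatid separation
precedes spindle formation the interval is defined as 0.  Cells whose sisters
segregate to the same pole ("failed") are excluded from timing means and
analyzed separately as fate fractions.  Dispersion is reported as SD (n−1
denominator) and SEM = SD/√n; two-sample comparisons use Student's t-test
(Welch by default, pooled variance available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .core import CellRecord, SisterTrack, SpindleTrajectory
from .classify import InflectionReport


@dataclass
class PopulationSummary:
    """Mean ± SD/SEM plus category fractions for one measured variable."""

    n: int
    mean: Optional[float]
    sd: Optional[float]
    sem: Optional[float]
    fractions: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "sem": self.sem,
            "fractions": self.fractions,
        }


def separation_timing(cell: CellRecord | SisterTrack) -> float:
    """Time from spindle formation to sister separation, floored at 0 min.

    Failed-fate cells are analyzed separately and rejected here; censored
    cells (no separation observed) have no defined timing.
    """
    track = cell.sister_track if isinstance(cell, CellRecord) else cell
    if track is None:
        raise ValueError("cell has no sister track")
    if track.fate == "failed":
        raise ValueError("failed-fate cells are excluded from separation timing")
    if track.separation_time is None:
        raise ValueError("separation not observed (censored)")
    return max(0.0, float(track.separation_time))


def separation_timing_population(
    cells: Iterable[CellRecord | SisterTrack],
) -> tuple[np.ndarray, dict]:
    """Floored separation times over a population, excluding failed and
    censored cells (tallied in the returned accounting dict)."""
    times, n_failed, n_censored = [], 0, 0
    for c in cells:
        track = c.sister_track if isinstance(c, CellRecord) else c
        if track is None or track.separation_time is None:
            n_censored += 1
            continue
        if track.fate == "failed":
            n_failed += 1
            continue
        times.append(max(0.0, float(track.separation_time)))
    if n_censored:
        warnings.warn(f"{n_censored} cells censored (no separation observed); excluded")
    return np.asarray(times), {
        "n_timed": len(times),
        "n_failed": n_failed,
        "n_censored": n_censored,
    }


def fate_fraction(cells: Iterable[CellRecord | SisterTrack]) -> dict:
    """Fractions of accurate vs failed sister segregation over scored cells.

    Cells without a scorable endpoint are counted as unscorable and excluded
    from the denominator; fractions are reported over exactly the scored n.
    """
    n_acc = n_fail = n_unscorable = 0
    for c in cells:
        track = c.sister_track if isinstance(c, CellRecord) else c
        if track is None:
            n_unscorable += 1
        elif track.fate == "failed":
            n_fail += 1
        else:
            n_acc += 1
    n = n_acc + n_fail
    return {
        "n": n,
        "n_unscorable": n_unscorable,
        "accurate": n_acc / n if n else float("nan"),
        "failed": n_fail / n if n else float("nan"),
    }


def metaphase_duration(traj: SpindleTrajectory, inflection: InflectionReport) -> float:
    """Time between spindle formation and anaphase onset for a normal cell.

    Defined as the breakpoint of a clear inflection; undefined otherwise
    (immediate cells have no metaphase-to-anaphase transition)."""
    if not inflection.clear:
        raise ValueError("no clear anaphase-onset inflection; metaphase duration undefined")
    return float(inflection.breakpoint_time)


def two_sample_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test.

    Welch (unequal variance) by default; set ``equal_var=True`` for the
    pooled-variance variant.  Returns (t, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def summarize(
    values: Sequence[float],
    categories: Optional[Sequence[str]] = None,
) -> PopulationSummary:
    """Mean, SD (n−1), SEM and optional category fractions.

    With a single value the SD and SEM are undefined and reported as None."""
    v = np.asarray(values, dtype=float)
    fractions: dict = {}
    if categories is not None:
        cats = list(categories)
        total = len(cats)
        for name in sorted(set(cats)):
            fractions[name] = cats.count(name) / total if total else float("nan")
    if v.size == 0:
        return PopulationSummary(0, None, None, None, fractions)
    mean = float(v.mean())
    if v.size < 2:
        return PopulationSummary(1, mean, None, None, fractions)
    sd = float(v.std(ddof=1))
    return PopulationSummary(int(v.size), mean, sd, sd / math.sqrt(v.size), fractions)


def floored_normal_mean(mean: float, sd: float) -> float:
    """Closed-form E[max(0, X)] for X ~ N(mean, sd).

    Used as an exact cross-check of the Monte-Carlo oracle for the floored
    separation-timing distribution."""
    if sd == 0:
        return max(0.0, mean)
    z = mean / sd
    return mean * stats.norm.cdf(z) + sd * stats.norm.pdf(z)


def monte_carlo_floored_mean(
    mean: float, sd: float, n: int = 1_000_000, seed: int = 0
) -> float:
    """Monte-Carlo estimate of the floored-normal population mean."""
    rng = np.random.default_rng(seed)
    return float(np.maximum(rng.normal(mean, sd, size=n), 0.0).mean())
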