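"""Plain-binomial misclassification analysis ("danger zones").

With m mosquitoes treated as independent Bernoulli trials at a net's true
rate p, the net passes when the event count reaches the discretized cutoff.
A net whose true rate sits near the cutoff then carries a non-trivial
probability of landing on the wrong side of it.  The *danger zone* is the
interval of true rates where that misclassification probability exceeds a
risk threshold (10% by default).

Deliberately no hierarchy here: variability between nets, sides and cones is
ignored, which makes the zone a property of the design (m = 25 x cones) and
the cutoff alone.

Conventions: the minimal passing count is the integer nearest cutoff*m (for
the knock-down cutoff with 3 cones this is 71 of 75, a discretized pass mark
of 94.7% rather than 96.0%); interval limits are the exact roots of the
binomial tail at the risk threshold, reported to 0.1 pp; the width is the
difference of the unrounded roots, also to 0.1 pp.  Because each tail is
monotone in p on its side of the cutoff, the roots are unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom

from .assay import OutcomeKind

__all__ = [
    "DangerZone",
    "pass_count",
    "misclassification_probability",
    "find_danger_zone",
    "danger_zone_table",
]

MOSQUITOES_PER_CONE = 5
SIDES_PER_NET = 5


def pass_count(m: int, cutoff: float) -> int:
    """Minimal event count regarded as passing: cutoff*m to the nearest integer.

    Halves round up (47.5 -> 48).  Never below 1.
    """
    return max(1, math.floor(cutoff * m + 0.5))


def misclassification_probability(
    p_true: float, m: int, cutoff: float, threshold: int | None = None
) -> float:
    """Probability that m i.i.d. trials at rate ``p_true`` are misclassified.

    A net with ``p_true >= cutoff`` is truly valid and is misclassified when
    the count falls short of the pass mark, P(X < t); a truly invalid net is
    misclassified when the count reaches it, P(X >= t).  Exact binomial
    tails, no normal approximation.
    """
    if not 0 <= p_true <= 1:
        raise ValueError("p_true must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    t = pass_count(m, cutoff) if threshold is None else threshold
    if p_true >= cutoff:
        return float(binom.cdf(t - 1, m, p_true))
    return float(binom.sf(t - 1, m, p_true))


@dataclass(frozen=True)
class DangerZone:
    """Interval of true rates with misclassification risk above the threshold."""

    outcome: OutcomeKind
    n_cones: int
    m: int
    cutoff: float
    risk_threshold: float
    lower: float | None  # exact root, proportion scale; None if that side is safe
    upper: float | None

    @property
    def is_empty(self) -> bool:
        return self.lower is None and self.upper is None

    @property
    def lower_pct(self) -> float | None:
        return None if self.lower is None else round(self.lower * 100, 1)

    @property
    def upper_pct(self) -> float | None:
        return None if self.upper is None else round(self.upper * 100, 1)

    @property
    def range_pp(self) -> float:
        """Width in percentage points, from the unrounded limits.

        A side with no risk excess contributes from the cutoff itself, so a
        one-sided zone still has a finite width; an empty zone has width 0.
        """
        if self.is_empty:
            return 0.0
        lo = self.cutoff if self.lower is None else self.lower
        hi = self.cutoff if self.upper is None else self.upper
        return round((hi - lo) * 100, 1)


def find_danger_zone(
    n_cones: int,
    outcome: OutcomeKind | str = OutcomeKind.MORTALITY,
    cutoff: float | None = None,
    risk_threshold: float = 0.10,
) -> DangerZone:
    """Locate the danger zone for a 5-side design with ``n_cones`` per side.

    The lower limit is the root of P(X >= t | p) = risk on p < cutoff (that
    tail increases in p towards the cutoff); the upper limit is the root of
    P(X < t | p) = risk on p >= cutoff (decreasing in p).  A side on which
    the risk never exceeds the threshold is reported as ``None``.
    """
    if not 1 <= n_cones <= 4:
        raise ValueError("n_cones must be in 1..4")
    outcome = OutcomeKind(outcome) if isinstance(outcome, str) else outcome
    if outcome is OutcomeKind.MIXED:
        raise ValueError("danger zones are defined per single endpoint")
    if cutoff is None:
        cutoff = 0.80 if outcome is OutcomeKind.MORTALITY else 0.95
    if not 0 < risk_threshold < 1:
        raise ValueError("risk_threshold must be in (0, 1)")

    m = MOSQUITOES_PER_CONE * SIDES_PER_NET * n_cones
    t = pass_count(m, cutoff)
    eps = 1e-12

    lower: float | None = None
    # risk on the invalid side approaches its supremum as p -> cutoff
    if binom.sf(t - 1, m, cutoff - eps) > risk_threshold:
        f = lambda p: binom.sf(t - 1, m, p) - risk_threshold
        if f(eps) < 0:
            lower = float(brentq(f, eps, cutoff - eps, xtol=1e-13))
        # else the whole invalid side is dangerous; leave the zone open at 0
        else:  # pragma: no cover - needs risk_threshold below P(X>=t | p~0)
            lower = 0.0

    upper: float | None = None
    if binom.cdf(t - 1, m, cutoff) > risk_threshold:
        g = lambda p: binom.cdf(t - 1, m, p) - risk_threshold
        if g(1 - eps) < 0:
            upper = float(brentq(g, cutoff, 1 - eps, xtol=1e-13))
        else:  # pragma: no cover - degenerate: even perfect nets fail often
            upper = 1.0

    return DangerZone(outcome, n_cones, m, cutoff, risk_threshold, lower, upper)


def danger_zone_table(
    mortality_cutoff: float = 0.80,
    kd_cutoff: float = 0.95,
    risk_threshold: float = 0.10,
) -> pd.DataFrame:
    """The 4-cone-counts x 2-endpoints table of danger zones.

    One row per (n_cones, outcome), ordered by n_cones; includes the width in
    pp and the relative width increase versus the 4-cone design of the same
    endpoint (in percent, rounded to integer).
    """
    zones = []
    for n_cones in range(1, 5):
        for outcome, cutoff in (
            (OutcomeKind.MORTALITY, mortality_cutoff),
            (OutcomeKind.KD, kd_cutoff),
        ):
            zones.append(find_danger_zone(n_cones, outcome, cutoff, risk_threshold))

    ref_width = {
        z.outcome: z.range_pp for z in zones if z.n_cones == 4 and not z.is_empty
    }
    rows = []
    for z in zones:
        rel = None
        base = ref_width.get(z.outcome)
        if base:
            rel = round(100 * (z.range_pp / base - 1))
        rows.append(
            {
                "n_cones": z.n_cones,
                "outcome": z.outcome.value,
                "m": z.m,
                "cutoff": z.cutoff,
                "lower_pct": z.lower_pct,
                "upper_pct": z.upper_pct,
                "range_pp": z.range_pp,
                "rel_range_vs_4_cones_pct": rel,
                "empty": z.is_empty,
            }
        )
    return pd.DataFrame(rows)
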