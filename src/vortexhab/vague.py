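"""Vague-set suitability and similarity scoring of reach mean vorticity.

A vague set extends a fuzzy set by giving each element both a support degree
t and an opposition degree f (with hesitation pi = 1 - t - f), represented
as the interval [t, 1 - f]. A reach's cross-sectional mean vorticity x is
mapped to a vague value by a piecewise-linear membership family anchored on
the suitable interval 0.17-0.35 1/s and boundary interval 0.02-1.0 1/s
observed in natural spawning grounds. Two reaches are then compared with

    SIM = 1 - |dt - df| / 4 - (|dt| + |df|) / 4,

classified on a five-band scale, and a restoration is called effective when
SIM rises by more than 5% over its pre-restoration value.

The membership family is implemented exactly as published, including the
1 - 0.1 denominator of the third branch and the resulting jump
discontinuities of 1 - f at x = 0.2 and x = 0.35. On part of the third
branch (x roughly in (0.283, 0.35)) the family violates the vague condition
t <= 1 - f; this is preserved and flagged rather than silently repaired,
with clamping available behind an explicit option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError, UndefinedRateError

__all__ = [
    "VagueValue",
    "SuitabilityIntervals",
    "SimilarityReport",
    "vague_value",
    "hesitation",
    "similarity",
    "classify",
    "restoration_rate",
    "score_reach",
    "CLASS_BANDS",
    "EFFECTIVENESS_THRESHOLD_PCT",
]

#: Similarity class bands: left-closed, right-open, final band closed at 1.
CLASS_BANDS = (
    (0.00, 0.15, "Extremely low"),
    (0.15, 0.35, "Lower"),
    (0.35, 0.65, "Low"),
    (0.65, 0.75, "General"),
    (0.75, 1.00, "Good"),
)

#: A restoration counts as effective only when SIM rises by strictly more
#: than this percentage.
EFFECTIVENESS_THRESHOLD_PCT = 5.0


@dataclass(frozen=True)
class VagueValue:
    """Vague value [t, 1 - f]: support degree and one minus opposition degree.

    The vague condition t <= 1 - f is checked, not enforced: the published
    membership family breaks it on part of its domain, and
    ``vague_condition_violated`` surfaces that.
    """

    t: float
    one_minus_f: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0 and 0.0 <= self.one_minus_f <= 1.0):
            raise ValueError("t and 1 - f must lie in [0, 1]")

    @property
    def f(self) -> float:
        """Opposition degree."""
        return 1.0 - self.one_minus_f

    @property
    def hesitation(self) -> float:
        """pi = 1 - t - f = (1 - f) - t; negative where the vague condition fails."""
        return self.one_minus_f - self.t

    @property
    def vague_condition_violated(self) -> bool:
        return self.t > self.one_minus_f


@dataclass(frozen=True)
class SuitabilityIntervals:
    """Anchors of the vorticity membership family (all in 1/s).

    ``appropriate`` is the suitable interval of natural spawning grounds,
    ``boundary`` the outer interval beyond which membership drops to (0, 0).
    ``rising_anchor`` (0.2) splits the rising limb; ``third_branch_anchor``
    (0.1) is the denominator anchor of the third branch, kept as published.
    """

    appropriate: tuple[float, float] = (0.17, 0.35)
    boundary: tuple[float, float] = (0.02, 1.0)
    rising_anchor: float = 0.2
    third_branch_anchor: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        a_lo, a_hi = self.appropriate
        if not (lo < a_lo < a_hi < hi):
            raise ValueError("boundary interval must strictly contain the appropriate one")
        if not (lo < self.rising_anchor < a_hi):
            raise ValueError("membership breakpoints must be strictly increasing")


@dataclass
class SimilarityReport:
    """Similarity of a restored reach (A) to the natural reference (B)."""

    u: float
    u_tilde: float
    v_A: VagueValue
    v_B: VagueValue
    sim: float
    similarity_class: str
    rate_pct: float | None = None
    effective: bool | None = None

    def to_dict(self) -> dict:
        return {
            "u_restored": self.u,
            "u_natural": self.u_tilde,
            "v_A": {"t": self.v_A.t, "one_minus_f": self.v_A.one_minus_f,
                    "hesitation": self.v_A.hesitation,
                    "vague_condition_violated": self.v_A.vague_condition_violated},
            "v_B": {"t": self.v_B.t, "one_minus_f": self.v_B.one_minus_f,
                    "hesitation": self.v_B.hesitation,
                    "vague_condition_violated": self.v_B.vague_condition_violated},
            "sim": self.sim,
            "class": self.similarity_class,
            "rate_pct": self.rate_pct,
            "effective": self.effective,
        }


def vague_value(
    x: float,
    intervals: SuitabilityIntervals | None = None,
    clamp: bool = False,
) -> VagueValue:
    """Map a reach mean vorticity x (1/s) to its vague value (t, 1 - f).

    Piecewise linear with branches (a = 0.02, m = 0.2, u = 0.35, o = 1.0):

    - x <= a or x >= o: (0, 0)
    - a < x < m: t = (x-a)/(u-a), 1-f = (x-a)/(m-a)
    - m <= x < u: t = (x-a)/(u-a), 1-f = (o-x)/(o-0.1)
    - u <= x < o: t = (o-x)/(o-m), 1-f = (o-x)/(o-u)

    ``clamp=True`` caps t at 1 - f where the family breaks the vague
    condition; by default the violation is preserved and flagged.
    """
    iv = intervals or SuitabilityIntervals()
    if not (x == x) or x == float("inf"):
        raise ContractError("x must be finite")
    if x < 0:
        raise ContractError("mean vorticity cannot be negative")
    a, o = iv.boundary
    m = iv.rising_anchor
    u = iv.appropriate[1]
    if x <= a or x >= o:
        t, omf = 0.0, 0.0
    elif x < m:
        t = (x - a) / (u - a)
        omf = (x - a) / (m - a)
    elif x < u:
        t = (x - a) / (u - a)
        omf = (o - x) / (o - iv.third_branch_anchor)
    else:
        t = (o - x) / (o - m)
        omf = (o - x) / (o - u)
    if clamp:
        t = min(t, omf)
    return VagueValue(t=t, one_minus_f=omf)


def hesitation(v: VagueValue) -> float:
    """Hesitation degree pi = 1 - t - f; negative values are passed through
    (see :attr:`VagueValue.vague_condition_violated`)."""
    return v.hesitation


def similarity(v_A: VagueValue, v_B: VagueValue) -> float:
    """SIM = 1 - |dt - df|/4 - (|dt| + |df|)/4 in [0, 1]; 1 iff the values match."""
    dt = v_A.t - v_B.t
    df = v_A.f - v_B.f
    return 1.0 - abs(dt - df) / 4.0 - (abs(dt) + abs(df)) / 4.0


def classify(sim: float) -> str:
    """Five-band similarity label; bands are [lo, hi) with the last closed at 1."""
    if not (0.0 <= sim <= 1.0):
        raise ContractError("SIM must lie in [0, 1]")
    for lo, hi, label in CLASS_BANDS:
        if lo <= sim < hi:
            return label
    return CLASS_BANDS[-1][2]  # sim == 1.0


def restoration_rate(sim_after: float, sim_previous: float) -> tuple[float, bool]:
    """Percent change R of SIM after restoration; effective iff R > 5% strictly."""
    if sim_previous <= 0:
        raise UndefinedRateError("pre-restoration similarity must be positive")
    r = (sim_after - sim_previous) / sim_previous * 100.0
    # strict ">" up to float round-off, so an exactly-5% rise is not effective
    return r, round(r, 9) > EFFECTIVENESS_THRESHOLD_PCT


def score_reach(
    u_restored: float,
    u_natural: float,
    intervals: SuitabilityIntervals | None = None,
    sim_previous: float | None = None,
    clamp: bool = False,
) -> SimilarityReport:
    """Score a restored reach against the natural reference.

    Both reaches are mapped through the same membership family (the natural
    reference defines it; no separate family is published for restored
    reaches). When ``sim_previous`` (the pre-restoration SIM) is given, the
    effectiveness rate is included.
    """
    v_a = vague_value(u_restored, intervals, clamp=clamp)
    v_b = vague_value(u_natural, intervals, clamp=clamp)
    sim = similarity(v_a, v_b)
    report = SimilarityReport(
        u=u_restored,
        u_tilde=u_natural,
        v_A=v_a,
        v_B=v_b,
        sim=sim,
        similarity_class=classify(sim),
    )
    if sim_previous is not None:
        report.rate_pct, report.effective = restoration_rate(sim, sim_previous)
    return report
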