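"""Axiomatic stress-tests for severity aggregators.

A change vector [dA, dB, dC] adds signed AIS points to the first, second and
third most severe injury of a profile; the result is re-sorted to canonical
descending order before scoring, because the aggregators are functions of
the grade multiset.  Three pathologies of non-linear aggregators are
detected by exhaustive scans over the 55-profile universe:

* **compensation anomalies** — the same change vector improves one patient's
  score while degrading another's (no fixed trade-off rate between grades);
* **rank reversals** — two patients receiving the identical sequence of
  changes swap priority along the way;
* **independence violations** — two pairs of patients that differ only in
  one shared grade respond to an identical change with a priority flip in
  one pair but not the other.

For the linear aggregator (power 1, unit weights) the score delta of a
change is profile-independent, so all three detectors are provably empty;
the scans confirm this.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

from .profiles import (
    AIS_MAX,
    AIS_MIN,
    AISProfile,
    Scorer,
    ValidationError,
    as_scorer,
    enumerate_profiles,
    make_profile,
)

__all__ = [
    "ChangeVector",
    "AxiomViolation",
    "ChangeNotApplicableError",
    "apply_change",
    "change_effect",
    "find_compensation_anomalies",
    "trace_rank_reversals",
    "find_independence_violations",
    "SINGLE_POINT_CHANGES",
]


class ChangeNotApplicableError(ValueError):
    """The change would push a grade outside 0..5."""


class ChangeVector(NamedTuple):
    """Signed AIS-point changes to the (A, B, C) components of a profile."""

    dA: int
    dB: int
    dC: int

    def applicable_to(self, profile: AISProfile) -> bool:
        return all(
            AIS_MIN <= g + d <= AIS_MAX for g, d in zip(profile, self)
        )

    def __str__(self) -> str:
        return f"[{self.dA:+d},{self.dB:+d},{self.dC:+d}]".replace("+0", "0").replace("-0", "0")


#: The six elementary changes: one AIS point up or down on one component.
SINGLE_POINT_CHANGES = tuple(
    ChangeVector(*v)
    for v in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


@dataclass(frozen=True)
class AxiomViolation:
    kind: str            #: compensation | rank_reversal | independence
    actors: tuple        #: the profiles involved
    trace: tuple         #: ((profile, score), ...) states along the scenario
    description: str

    def revalidate(self, spec: Scorer) -> bool:
        """True iff every recorded score recomputes from its profile."""
        fn = as_scorer(spec)
        return all(fn(p) == s for p, s in self.trace)


def apply_change(profile: AISProfile, change: ChangeVector) -> AISProfile:
    """Component-wise addition followed by re-canonicalisation.

    E.g. (4,3,2) + [-1,0,+1] = (3,3,3), and (4,4,0) + [-1,0,0] yields the
    profile scored as (4,3,0).
    """
    for label, g, d in zip("ABC", profile, change):
        if not AIS_MIN <= g + d <= AIS_MAX:
            raise ChangeNotApplicableError(
                f"change {tuple(change)} moves component {label} of {profile} "
                f"to {g + d}, outside {AIS_MIN}..{AIS_MAX}"
            )
    return make_profile((profile.A + change.dA, profile.B + change.dB, profile.C + change.dC))


def change_effect(profile: AISProfile, change: ChangeVector, spec: Scorer):
    """score(profile + change) - score(profile)."""
    fn = as_scorer(spec)
    return fn(apply_change(profile, change)) - fn(profile)


def find_compensation_anomalies(
    spec: Scorer, change: ChangeVector, profiles: Sequence[AISProfile] | None = None
) -> list[AxiomViolation]:
    """Profile pairs for which the same change has opposite-signed effects.

    A fixed-trade-off (e.g. linear) aggregator gives every profile the same
    delta, so no pair can disagree in sign; the quadratic aggregator already
    fails this for the change [0,+1,-2].
    """
    fn = as_scorer(spec)
    profs = enumerate_profiles() if profiles is None else list(profiles)
    deltas = {
        p: change_effect(p, change, spec) for p in profs if change.applicable_to(p)
    }
    improved = sorted((p for p, d in deltas.items() if d < 0), reverse=True)
    degraded = sorted((p for p, d in deltas.items() if d > 0), reverse=True)
    out = []
    for worse in degraded:
        for better in improved:
            out.append(
                AxiomViolation(
                    kind="compensation",
                    actors=(worse, better),
                    trace=(
                        (worse, fn(worse)),
                        (apply_change(worse, change), fn(apply_change(worse, change))),
                        (better, fn(better)),
                        (apply_change(better, change), fn(apply_change(better, change))),
                    ),
                    description=(
                        f"change {change} degrades {worse} (delta {deltas[worse]:+}) "
                        f"but improves {better} (delta {deltas[better]:+})"
                    ),
                )
            )
    return out


def _strict_order(sx, sy) -> int:
    return (sx > sy) - (sx < sy)


def trace_rank_reversals(
    x: AISProfile,
    y: AISProfile,
    changes: Sequence[ChangeVector],
    spec: Scorer,
) -> list[AxiomViolation]:
    """Apply each change to BOTH patients and record every priority flip.

    A flip is a step at which the strict order of the two scores reverses
    (ties neither flip nor reset the tracked order).
    """
    fn = as_scorer(spec)
    cur_x, cur_y = x, y
    trace = [(cur_x, fn(cur_x)), (cur_y, fn(cur_y))]
    last_order = _strict_order(fn(cur_x), fn(cur_y))
    flips = []
    for step, change in enumerate(changes):
        for who, prof in (("first", cur_x), ("second", cur_y)):
            if not change.applicable_to(prof):
                raise ChangeNotApplicableError(
                    f"step {step}: change {change} not applicable to the "
                    f"{who} patient's profile {prof}"
                )
        cur_x, cur_y = apply_change(cur_x, change), apply_change(cur_y, change)
        sx, sy = fn(cur_x), fn(cur_y)
        trace += [(cur_x, sx), (cur_y, sy)]
        order = _strict_order(sx, sy)
        if order != 0 and last_order != 0 and order != last_order:
            flips.append(
                AxiomViolation(
                    kind="rank_reversal",
                    actors=(x, y),
                    trace=tuple(trace),
                    description=(
                        f"after step {step} (change {change}) the priority of "
                        f"{x} vs {y} flips: scores now {sx} vs {sy}"
                    ),
                )
            )
        if order != 0:
            last_order = order
    return flips


def find_independence_violations(
    spec: Scorer,
    shifts: Sequence[ChangeVector] | None = None,
    changes: Sequence[ChangeVector] | None = None,
) -> list[AxiomViolation]:
    """Quadruples (x, y, x', y') witnessing an independence failure.

    x' and y' are x and y with ONE shared component raised by the same
    shift (default +1 on a single component, the worked-example pattern);
    the shifted profiles must remain in descending order as written, so the
    shared component is the same criterion in all four profiles.  An
    identical change vector applied to all four then flips the strict
    priority order within exactly one of the two pairs.  All comparisons
    are strict; ties disqualify a quadruple.
    """
    fn = as_scorer(spec)
    shift_set = tuple(shifts) if shifts is not None else tuple(
        c for c in SINGLE_POINT_CHANGES if sum(c) > 0
    )
    change_set = tuple(changes) if changes is not None else SINGLE_POINT_CHANGES
    profs = enumerate_profiles()
    out = []
    for shift in shift_set:
        for x, y in combinations(profs, 2):
            xs_raw = tuple(g + d for g, d in zip(x, shift))
            ys_raw = tuple(g + d for g, d in zip(y, shift))
            if not all(AIS_MIN <= g <= AIS_MAX for g in xs_raw + ys_raw):
                continue
            # keep the shifted component in place: no re-sorting allowed here
            if not (xs_raw[0] >= xs_raw[1] >= xs_raw[2] and ys_raw[0] >= ys_raw[1] >= ys_raw[2]):
                continue
            xp, yp = AISProfile(*xs_raw), AISProfile(*ys_raw)
            for change in change_set:
                quad = (x, y, xp, yp)
                if not all(change.applicable_to(q) for q in quad):
                    continue
                before = [fn(q) for q in quad]
                after = [fn(apply_change(q, change)) for q in quad]
                o1, o2 = _strict_order(before[0], before[1]), _strict_order(before[2], before[3])
                t1, t2 = _strict_order(after[0], after[1]), _strict_order(after[2], after[3])
                if 0 in (o1, o2, t1, t2):
                    continue
                flip_base, flip_shifted = o1 != t1, o2 != t2
                if flip_base != flip_shifted:
                    states = tuple(
                        (q, s) for q, s in zip(
                            quad + tuple(apply_change(q, change) for q in quad),
                            before + after,
                        )
                    )
                    out.append(
                        AxiomViolation(
                            kind="independence",
                            actors=quad,
                            trace=states,
                            description=(
                                f"shift {shift}, change {change}: pair "
                                f"({x}, {y}) {'flips' if flip_base else 'holds'} "
                                f"while pair ({xp}, {yp}) "
                                f"{'flips' if flip_shifted else 'holds'}"
                            ),
                        )
                    )
    out.sort(key=lambda v: v.actors)
    return out
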