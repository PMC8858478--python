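"""AIS profiles and the weighted power-sum family of severity aggregators.

An AIS profile is the ordered triplet (A, B, C) of a patient's three highest
Abbreviated Injury Scale grades, each an integer in 0..5 with A >= B >= C.
The Injury Severity Score (ISS) is the power-sum aggregator with exponent 2
and unit weights, ``A**2 + B**2 + C**2``; the plain sum (exponent 1) and the
sum of cubes (exponent 3) are the two comparators studied alongside it.

All combinatorial quantities here (score domains, ranks) are exact integer
arithmetic so that downstream pair counts are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence, Union

import pandas as pd

__all__ = [
    "AIS_MIN",
    "AIS_MAX",
    "AISProfile",
    "AggregationSpec",
    "SUM",
    "ISS",
    "CUBES",
    "Scorer",
    "ValidationError",
    "DomainError",
    "make_profile",
    "as_scorer",
    "score",
    "enumerate_profiles",
    "score_domain",
    "rank_of_score",
    "domain_table",
]

AIS_MIN = 0
AIS_MAX = 5


class ValidationError(ValueError):
    """Raised for out-of-range or malformed grades, weights or powers."""


class DomainError(KeyError):
    """Raised when a score is not achievable by any profile."""


class AISProfile(NamedTuple):
    """Canonical (A, B, C) triplet of the three highest AIS grades, A>=B>=C."""

    A: int
    B: int
    C: int

    def __str__(self) -> str:  # e.g. "(4,3,0)" as the tables print profiles
        return f"({self.A},{self.B},{self.C})"


def make_profile(grades: Sequence[int]) -> AISProfile:
    """Build a canonical profile from three AIS grades in any order.

    Grades are validated (integers in 0..5) and sorted descending; the
    aggregators are functions of the grade multiset, so region identity
    is deliberately discarded here.
    """
    grades = tuple(grades)
    if len(grades) != 3:
        raise ValidationError(f"expected exactly 3 AIS grades, got {len(grades)}")
    for g in grades:
        if isinstance(g, bool) or not isinstance(g, (int,)):
            raise ValidationError(f"AIS grade {g!r} is not an integer")
        if not AIS_MIN <= g <= AIS_MAX:
            raise ValidationError(
                f"AIS grade {g} outside the valid range {AIS_MIN}..{AIS_MAX}"
            )
    a, b, c = sorted(grades, reverse=True)
    return AISProfile(a, b, c)


@dataclass(frozen=True)
class AggregationSpec:
    """Weighted power-sum aggregator ``wA*A**p + wB*B**p + wC*C**p``.

    ``power=2`` with unit weights is the ISS; ``power=1`` the plain sum;
    ``power=3`` the sum of cubes.  Weights must be non-negative; scores are
    exact integers whenever the weights are integers.
    """

    power: int
    weights: tuple = (1, 1, 1)
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.power, int) or self.power < 1:
            raise ValidationError(f"power must be a positive integer, got {self.power!r}")
        if len(self.weights) != 3 or any(w < 0 for w in self.weights):
            raise ValidationError(f"weights must be three non-negative reals, got {self.weights!r}")
        if not self.name:
            object.__setattr__(self, "name", f"power{self.power}")

    def __call__(self, profile: AISProfile):
        wa, wb, wc = self.weights
        p = self.power
        return wa * profile.A**p + wb * profile.B**p + wc * profile.C**p


#: The three aggregators the comparison study runs on.
SUM = AggregationSpec(power=1, name="sum")
ISS = AggregationSpec(power=2, name="iss")
CUBES = AggregationSpec(power=3, name="cubes")

#: Anything that maps a profile to a (real) severity score.  Every operation
#: that takes an AggregationSpec also accepts a plain callable with the same
#: monotonicity contract.
Scorer = Union[AggregationSpec, Callable[[AISProfile], float]]


def as_scorer(spec: Scorer) -> Callable[[AISProfile], float]:
    if callable(spec):
        return spec
    raise ValidationError(f"not a scorer: {spec!r}")


def score(profile: AISProfile, spec: Scorer):
    """Severity score of ``profile`` under ``spec``."""
    return as_scorer(spec)(profile)


def enumerate_profiles(include_zero: bool = False) -> list[AISProfile]:
    """All canonical profiles, sorted lexicographically descending.

    55 profiles with (0,0,0) excluded (the default), 56 with it included.
    """
    out = [
        AISProfile(a, b, c)
        for a in range(AIS_MAX, AIS_MIN - 1, -1)
        for b in range(a, AIS_MIN - 1, -1)
        for c in range(b, AIS_MIN - 1, -1)
        if include_zero or (a, b, c) != (0, 0, 0)
    ]
    out.sort(reverse=True)
    return out


def score_domain(spec: Scorer, profiles: Iterable[AISProfile] | None = None) -> list:
    """Sorted distinct achievable scores over the 55 non-zero profiles."""
    fn = as_scorer(spec)
    profs = enumerate_profiles() if profiles is None else list(profiles)
    return sorted({fn(p) for p in profs})


def rank_of_score(value, spec: Scorer, profiles: Iterable[AISProfile] | None = None) -> int:
    """1-based ordinal rank of ``value`` within the score domain of ``spec``."""
    domain = score_domain(spec, profiles)
    try:
        return domain.index(value) + 1
    except ValueError:
        raise DomainError(
            f"score {value!r} is not achievable by any profile under {spec!r}"
        ) from None


def domain_table(specs: Sequence[AggregationSpec] = (SUM, ISS, CUBES)) -> pd.DataFrame:
    """Rank-aligned table of achievable scores, one column per aggregator.

    Shorter domains are padded with <NA> below their maximum rank, mirroring
    how the comparison table in the source data lays the three scales side
    by side.
    """
    domains = {s.name: score_domain(s) for s in specs}
    n = max(len(d) for d in domains.values())
    cols = {"rank": range(1, n + 1)}
    for name, dom in domains.items():
        cols[name] = list(dom) + [None] * (n - len(dom))
    return pd.DataFrame(cols).astype({name: "Int64" for name in domains})
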