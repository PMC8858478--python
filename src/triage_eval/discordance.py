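"""Pairwise discordance between two severity aggregators.

Two profiles x, y are *discordant* under aggregators f and g when the two
functions order them strictly oppositely: (f(x) > f(y) and g(x) < g(y)) or
(f(x) < f(y) and g(x) > g(y)).  A pair on which either function ties is
neither concordant nor discordant.

Two counts are reported.  ``n_discordant_unordered`` counts each discordant
{x, y} once — the combinatorially natural number over the C(55,2) = 1485
unordered pairs.  ``n_discordant`` counts each such pair in both orders
(i.e. twice); the published comparison of these aggregators uses that
ordered count over the unordered denominator (84 pairs, 5.66%, for ISS vs
cubes), so the headline ``fraction`` follows the same convention to stay
comparable with the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .profiles import AISProfile, Scorer, as_scorer, enumerate_profiles

__all__ = ["PairOrder", "DiscordanceReport", "compare_pair", "discordance"]


class PairOrder(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    TIED = "tied"


def compare_pair(x: AISProfile, y: AISProfile, spec_a: Scorer, spec_b: Scorer) -> PairOrder:
    """Classify how two aggregators order the pair {x, y}."""
    fa, fb = as_scorer(spec_a), as_scorer(spec_b)
    ax, ay = fa(x), fa(y)
    bx, by = fb(x), fb(y)
    if ax == ay or bx == by:
        return PairOrder.TIED
    if (ax > ay) == (bx > by):
        return PairOrder.CONCORDANT
    return PairOrder.DISCORDANT


@dataclass(frozen=True)
class DiscordanceReport:
    spec_a: str
    spec_b: str
    n_pairs: int                       #: unordered pairs examined, n(n-1)/2
    n_discordant_unordered: int        #: each discordant {x,y} counted once
    n_tied: int
    pairs: tuple = field(repr=False)   #: the discordant pairs, each once

    @property
    def n_discordant(self) -> int:
        """Discordant count with each pair taken in both orders (2x)."""
        return 2 * self.n_discordant_unordered

    @property
    def fraction(self) -> float:
        """n_discordant / n_pairs — the convention of the published counts."""
        return self.n_discordant / self.n_pairs

    @property
    def fraction_unordered(self) -> float:
        return self.n_discordant_unordered / self.n_pairs

    def to_frame(self, spec_a: Scorer | None = None, spec_b: Scorer | None = None) -> pd.DataFrame:
        """One row per discordant pair; scores included when specs given."""
        rows = []
        for x, y in self.pairs:
            row = {"profile_x": str(x), "profile_y": str(y)}
            if spec_a is not None:
                fa = as_scorer(spec_a)
                row["score_ax"], row["score_ay"] = fa(x), fa(y)
            if spec_b is not None:
                fb = as_scorer(spec_b)
                row["score_bx"], row["score_by"] = fb(x), fb(y)
            rows.append(row)
        cols = ["profile_x", "profile_y", "score_ax", "score_ay", "score_bx", "score_by"]
        return pd.DataFrame(rows, columns=[c for c in cols if rows and c in rows[0]] or cols[:2])


def discordance(
    spec_a: Scorer,
    spec_b: Scorer,
    profiles: Sequence[AISProfile] | None = None,
) -> DiscordanceReport:
    """Exhaustive discordance scan over all unordered profile pairs.

    Defaults to the 55 non-zero canonical profiles (1485 pairs).  Output
    pair ordering is deterministic: pairs are emitted in descending
    lexicographic order of the first profile.
    """
    profs = enumerate_profiles() if profiles is None else sorted(profiles, reverse=True)
    if len(profs) < 2:
        raise ValueError("need at least 2 profiles to compare")
    fa, fb = as_scorer(spec_a), as_scorer(spec_b)
    sa = {p: fa(p) for p in profs}
    sb = {p: fb(p) for p in profs}
    disc, tied = [], 0
    n_pairs = 0
    for x, y in combinations(profs, 2):
        n_pairs += 1
        ax, ay, bx, by = sa[x], sa[y], sb[x], sb[y]
        if ax == ay or bx == by:
            tied += 1
        elif (ax > ay) != (bx > by):
            disc.append((x, y))
    return DiscordanceReport(
        spec_a=getattr(spec_a, "name", repr(spec_a)),
        spec_b=getattr(spec_b, "name", repr(spec_b)),
        n_pairs=n_pairs,
        n_discordant_unordered=len(disc),
        n_tied=tied,
        pairs=tuple(disc),
    )
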