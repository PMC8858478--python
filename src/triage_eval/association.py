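"""Association between severity scores and mortality.

Pearson product-moment correlation (the historical yardstick for severity
scores) and discrete information-theoretic measures: plug-in entropy, mutual
information MI(X,Y) = H(X) - H(X|Y) and its normalised form
NMI = 2*MI / (H(X) + H(Y)), all in bits (log base 2).

MI and NMI use the plug-in (maximum-likelihood) estimator on the exact
observed values treated as categories.  Significance is assessed by a seeded
permutation test with the add-one estimate p = (1 + #{perm >= obs}) / (1 + B).

Also here: the unbiased sample variance and the score-domain gap report used
to demonstrate that the ISS scale carries no cardinal meaning (unequal gaps
between consecutive achievable scores inflate variances arbitrarily).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import (
    AISProfile,
    Scorer,
    ValidationError,
    as_scorer,
    make_profile,
    score_domain,
)

__all__ = [
    "OutcomeTable",
    "DiscreteDistribution",
    "UndefinedStatisticError",
    "pearson",
    "empirical_distribution",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "normalized_mi",
    "permutation_pvalue",
    "sample_variance",
    "cardinality_gap_report",
]


class UndefinedStatisticError(ValueError):
    """A statistic whose defining denominator is zero (e.g. zero variance)."""


@dataclass(frozen=True)
class OutcomeTable:
    """Rows of (profile, outcome, weight) — e.g. mortality rate per profile."""

    profiles: tuple
    outcomes: tuple
    weights: tuple = ()
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValidationError("an outcome table needs at least 2 rows")
        if len(self.outcomes) != len(self.profiles):
            raise ValidationError("profiles and outcomes must have equal length")
        if not self.weights:
            object.__setattr__(self, "weights", (1.0,) * len(self.profiles))
        if len(self.weights) != len(self.profiles) or any(w <= 0 for w in self.weights):
            raise ValidationError("weights must be positive, one per row")
        if not all(np.isfinite(self.outcomes)):
            raise ValidationError("outcomes must be finite")

    def __len__(self) -> int:
        return len(self.profiles)

    def score_column(self, spec: Scorer) -> list:
        fn = as_scorer(spec)
        return [fn(p) for p in self.profiles]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "OutcomeTable":
        profiles = tuple(
            make_profile((int(r.A), int(r.B), int(r.C))) for r in df.itertuples()
        )
        weights = tuple(float(w) for w in df["weight"]) if "weight" in df else ()
        return cls(profiles, tuple(float(o) for o in df["outcome"]), weights, label)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "") -> "OutcomeTable":
        """Read a table with header ``A,B,C,outcome[,weight]``."""
        return cls.from_frame(pd.read_csv(path), label=label or Path(path).stem)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "A": [p.A for p in self.profiles],
                "B": [p.B for p in self.profiles],
                "C": [p.C for p in self.profiles],
                "outcome": self.outcomes,
                "weight": self.weights,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DiscreteDistribution:
    """Categorical distribution over a finite support."""

    support: tuple
    probabilities: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(self.support) != len(p):
            raise ValidationError("support and probabilities must align")
        if len(set(self.support)) != len(self.support):
            raise ValidationError("support values must be distinct")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must be non-negative and sum to 1")


def empirical_distribution(values: Iterable) -> DiscreteDistribution:
    """Plug-in distribution of observed values treated as categories."""
    ser = pd.Series(list(values))
    counts = ser.value_counts(sort=False)
    n = counts.sum()
    return DiscreteDistribution(tuple(counts.index), tuple(counts / n))


# ---------------------------------------------------------------- Pearson

def pearson(x: Sequence[float], y: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Product-moment correlation; weighted moments when weights are given."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("x and y must be equal-length 1-d sequences of length >= 2")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx == 0 or vy == 0:
        raise UndefinedStatisticError(
            "correlation is undefined when either variable has zero variance"
        )
    return float(cov / np.sqrt(vx * vy))


# ------------------------------------------------------- entropy / MI / NMI

def entropy(d: DiscreteDistribution | Iterable, base: float = 2.0) -> float:
    """Shannon entropy; 0*log(0) taken as 0.  Accepts raw values too."""
    if not isinstance(d, DiscreteDistribution):
        d = empirical_distribution(d)
    p = np.asarray(d.probabilities, dtype=float)
    p = p[p > 0]
    return float(-(p * (np.log(p) / np.log(base))).sum())


def _paired(x: Iterable, y: Iterable) -> tuple[list, list]:
    x, y = list(x), list(y)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    return x, y


def joint_entropy(x: Iterable, y: Iterable, base: float = 2.0) -> float:
    x, y = _paired(x, y)
    return entropy(list(zip(x, y)), base=base)


def conditional_entropy(x: Iterable, y: Iterable, base: float = 2.0) -> float:
    """H(X|Y) = -sum_{x,y} p(x,y) * log(p(x,y) / p(y)) under the plug-in law."""
    x, y = _paired(x, y)
    n = len(x)
    joint = pd.Series(list(zip(x, y))).value_counts(sort=False) / n
    py = pd.Series(y).value_counts(sort=False) / n
    h = 0.0
    for (_, yv), pxy in joint.items():
        h -= pxy * (np.log(pxy / py[yv]) / np.log(base))
    return float(h)


def mutual_information(x: Iterable, y: Iterable, base: float = 2.0) -> float:
    """Plug-in MI(X,Y) = H(X) - H(X|Y), in bits by default."""
    x, y = _paired(x, y)
    mi = entropy(x, base=base) - conditional_entropy(x, y, base=base)
    return max(0.0, float(mi))  # clip the ~1e-16 negatives of float round-off


def normalized_mi(x: Iterable, y: Iterable, base: float = 2.0) -> float:
    """NMI(X,Y) = 2*MI / (H(X) + H(Y)), in [0, 1]."""
    x, y = _paired(x, y)
    hx, hy = entropy(x, base=base), entropy(y, base=base)
    if hx + hy == 0:
        raise UndefinedStatisticError("NMI is undefined when both variables are constant")
    return float(2.0 * mutual_information(x, y, base=base) / (hx + hy))


_STATISTICS = {
    "mi": mutual_information,
    "nmi": normalized_mi,
    "pearson": lambda x, y: pearson([float(v) for v in x], [float(v) for v in y]),
}


def permutation_pvalue(
    x: Sequence,
    y: Sequence,
    statistic: str = "nmi",
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Seeded permutation test of association between x and y.

    One column (y) is permuted ``n_perm`` times; the p-value uses the
    add-one formula p = (1 + #{T_perm >= T_obs}) / (1 + n_perm), so the
    smallest attainable p is 1/(1 + n_perm).
    """
    if statistic not in _STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    x, y = _paired(x, y)
    stat = _STATISTICS[statistic]
    observed = stat(x, y)
    rng = np.random.default_rng(seed)
    y_arr = np.asarray(y, dtype=object)
    hits = 0
    for _ in range(n_perm):
        perm = y_arr[rng.permutation(len(y_arr))]
        if stat(x, list(perm)) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ------------------------------------------------ cardinality / variance demo

def sample_variance(values: Sequence[float]) -> float:
    """Unbiased (n-1 denominator) sample variance."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValidationError("sample variance needs at least 2 values")
    return float(values.var(ddof=1))


@dataclass(frozen=True)
class GapReport:
    """Gaps between consecutive achievable scores of an aggregator."""

    spec: str
    rows: tuple  #: (rank, score, gap-to-next-score); last gap is None
    gaps_monotone: bool  #: False flags a scale whose gaps shrink after growing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rank", "score", "gap"])


def cardinality_gap_report(spec: Scorer) -> GapReport:
    """Gap structure of a score domain.

    A genuinely interval-valued scale would have non-decreasing (ideally
    constant) gaps; the ISS domain's gap sequence rises and falls (3 between
    ranks 32 and 33, back to 1 between 34 and 35), which is the demonstration
    that differences of ISS values carry no cardinal meaning.
    """
    domain = score_domain(spec)
    gaps = [b - a for a, b in zip(domain, domain[1:])]
    rows = tuple(
        (r, s, gaps[r - 1] if r - 1 < len(gaps) else None)
        for r, s in enumerate(domain, start=1)
    )
    monotone = all(g2 >= g1 for g1, g2 in zip(gaps, gaps[1:]))
    return GapReport(spec=getattr(spec, "name", repr(spec)), rows=rows, gaps_monotone=monotone)
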