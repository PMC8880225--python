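"""One-way ANOVA and Duncan's multiple range test with compact letters.

This generates the ``a, b, ...`` superscripts of composition tables: per
analyte, replicate values per group are decomposed by one-way ANOVA, and
group means are compared with Duncan's stepwise studentized-range procedure
at protection level ``alpha_p = 1 - (1 - alpha)^(p-1)`` for a span of ``p``
ranked means.  Groups sharing a letter are not significantly different.

With exactly two groups the procedure reduces to a protected least
significant difference, so the letter verdict coincides with the ANOVA
``p < alpha`` decision.

Degenerate inputs follow fixed conventions: zero within-group variance gives
``p = 1`` when all means are equal and ``p = 0`` otherwise; a group whose
replicates are identically zero (a below-detection analyte) is excluded from
the error-variance pooling with a warning; unequal group sizes use the
harmonic mean n in the critical range, also with a warning.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import ValidationError

__all__ = [
    "GroupedMeasurements",
    "AnovaResult",
    "LetterDisplay",
    "one_way_anova",
    "duncan_mrt",
    "from_summary",
]


@dataclass
class GroupedMeasurements:
    """Replicate values per group for one analyte."""

    analyte: str
    groups: dict[str, list[float]]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError(f"{self.analyte}: need >= 2 groups")
        for label, values in self.groups.items():
            if len(values) < 2:
                raise ValidationError(
                    f"{self.analyte}/{label}: need >= 2 replicates"
                )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    mse: float


@dataclass
class LetterDisplay:
    """Compact letter display plus the quantities behind it."""

    analyte: str
    letters: dict[str, str]
    means: dict[str, float]
    sds: dict[str, float]
    anova: AnovaResult
    notes: list[str] = field(default_factory=list)

    def same_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def one_way_anova(gm: GroupedMeasurements) -> AnovaResult:
    """Standard one-way decomposition; p from the F distribution."""
    arrays = [np.asarray(v, dtype=float) for v in gm.groups.values()]
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    mse = ss_within / df_within
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_between, df_within, 0.0)
        return AnovaResult(math.inf, 0.0, df_between, df_within, 0.0)
    f = (ss_between / df_between) / mse
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within, float(mse))


def _critical_ranges(
    alpha: float, k: int, df: int, mse: float, n: float
) -> dict[int, float]:
    """Duncan least significant ranges R_p for spans p = 2..k."""
    ranges = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_p, p, df)
        ranges[p] = float(q) * math.sqrt(mse / n)
    return ranges


def _homogeneous_stretches(
    means: list[float], ranges: dict[int, float] | None
) -> list[tuple[int, int]]:
    """Maximal non-significant stretches of descending-ranked means.

    ``ranges=None`` is the zero-variance convention: means differ iff they
    are unequal.
    """
    k = len(means)
    found: set[tuple[int, int]] = set()

    def test(i: int, j: int) -> None:
        if i == j:
            found.add((i, j))
            return
        span = j - i + 1
        limit = 0.0 if ranges is None else ranges[span]
        if means[i] - means[j] <= limit:
            found.add((i, j))
        else:
            test(i, j - 1)
            test(i + 1, j)

    test(0, k - 1)
    maximal = [
        s
        for s in sorted(found)
        if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in found)
    ]
    return maximal


def duncan_mrt(gm: GroupedMeasurements) -> LetterDisplay:
    """Duncan's multiple range test, rendered as compact letters.

    The homogeneous-group partition is determined on descending-ranked means
    and is invariant to group input order.  Letter *names* follow the table
    convention of the published composition tables: "a" anchors to the
    first-listed group, except that all-zero (below-detection) groups are
    named last.  When nothing differs every group reads "a".
    """
    anova = one_way_anova(gm)
    notes: list[str] = []
    labels = list(gm.groups)
    means = {g: float(np.mean(v)) for g, v in gm.groups.items()}
    sds = {g: float(np.std(v, ddof=1)) for g, v in gm.groups.items()}

    # Below-detection groups (identically zero) carry no analytical error:
    # pool the error variance over the remaining groups only.
    nonzero = [g for g in labels if any(v != 0 for v in gm.groups[g])]
    if nonzero and len(nonzero) < len(labels):
        notes.append(
            "zero-valued group(s) excluded from error-variance pooling: "
            + ", ".join(sorted(set(labels) - set(nonzero)))
        )
        ss = sum(
            float(((np.asarray(gm.groups[g]) - means[g]) ** 2).sum())
            for g in nonzero
        )
        df = sum(len(gm.groups[g]) - 1 for g in nonzero)
        mse, df_within = ss / df, df
    else:
        mse, df_within = anova.mse, anova.df_within

    sizes = {len(v) for v in gm.groups.values()}
    if len(sizes) > 1:
        n_eff = len(labels) / sum(1.0 / len(v) for v in gm.groups.values())
        notes.append(f"unequal group sizes; harmonic mean n = {n_eff:.3f} used")
        warnings.warn(notes[-1], stacklevel=2)
    else:
        n_eff = float(sizes.pop())

    # Descending means; stable sort keeps input order among ties.
    ranked = sorted(labels, key=lambda g: -means[g])
    ranked_means = [means[g] for g in ranked]
    if mse == 0.0:
        notes.append("zero pooled variance; letters reflect exact mean equality")
        stretches = _homogeneous_stretches(ranked_means, None)
    else:
        ranges = _critical_ranges(gm.alpha, len(ranked), df_within, mse, n_eff)
        stretches = _homogeneous_stretches(ranked_means, ranges)

    # Name stretches by the input position of their earliest member,
    # demoting all-zero groups, so "a" anchors like the published tables.
    def naming_key(stretch: tuple[int, int]) -> tuple[int, int]:
        members = ranked[stretch[0]: stretch[1] + 1]
        return min(
            (0 if g in nonzero else 1, labels.index(g)) for g in members
        )

    letters = {g: "" for g in labels}
    for idx, (i, j) in enumerate(sorted(stretches, key=naming_key)):
        letter = string.ascii_lowercase[idx]
        for pos in range(i, j + 1):
            letters[ranked[pos]] += letter
    letters = {g: "".join(sorted(s)) for g, s in letters.items()}
    return LetterDisplay(
        analyte=gm.analyte,
        letters=letters,
        means=means,
        sds=sds,
        anova=anova,
        notes=notes,
    )


def from_summary(
    analyte: str,
    summary: dict[str, tuple[float, float]],
    n: int = 3,
    alpha: float = 0.05,
) -> GroupedMeasurements:
    """Reconstruct replicate groups from published (mean, SD) pairs.

    For the published-table case n = 3 the exact-moment triplet
    {m - s, m, m + s} is used, whose sample mean and SD equal (m, s) exactly.
    """
    from .synthetic import replicate_triplets

    return GroupedMeasurements(
        analyte=analyte,
        groups={g: replicate_triplets(m, s, n=n) for g, (m, s) in summary.items()},
        alpha=alpha,
    )
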