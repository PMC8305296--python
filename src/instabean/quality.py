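"""Derived quality indices and group comparisons for dried/rehydrated beans.

Covers the rehydration potential (yield Y = W_e/W_0 and relative rehydration
moisture RRM = M_e/M_c), the CIELAB total colour difference dE*, the degree
of starch retrogradation DR% = 100 dH_R/dH_G from DSC enthalpies, and
treatment comparison by one-way ANOVA with pairwise t-tests summarised as a
compact letter display (groups sharing a letter are not significantly
different).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import InvalidInputError

__all__ = [
    "ColorMeasurement",
    "ThermalRecord",
    "GroupComparison",
    "rehydration_yield",
    "relative_rehydration_moisture",
    "delta_e",
    "mean_delta_e",
    "degree_retrogradation",
    "group_compare",
    "compact_letter_display",
    "format_group_summary",
]


@dataclass(frozen=True)
class ColorMeasurement:
    """CIELAB colour triple: L* lightness (0-100), a* red-green, b* yellow-blue."""

    l: float
    a: float
    b: float

    def __post_init__(self):
        if not (0.0 <= self.l <= 100.0):
            raise InvalidInputError(f"L* must lie in [0, 100], got {self.l}")

    def as_array(self) -> np.ndarray:
        return np.array([self.l, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class ThermalRecord:
    """DSC summary: peak temperature (degC), gelatinisation enthalpy of the
    native starch dH_G and melting enthalpy of retrograded starch dH_R (J/g)."""

    t_p: float
    dh_g: float
    dh_r: float

    def __post_init__(self):
        if self.dh_g < 0 or self.dh_r < 0:
            raise InvalidInputError("enthalpies must be >= 0")


def rehydration_yield(w_e: float, w_0: float) -> float:
    """Rehydration yield Y = W_e / W_0 (saturated over initial weight)."""
    if w_0 <= 0:
        raise InvalidInputError("initial weight must be > 0")
    return w_e / w_0


def relative_rehydration_moisture(m_e: float, m_c: float) -> float:
    """RRM = M_e / M_c: equilibrium moisture relative to the freshly cooked bean."""
    if m_c <= 0:
        raise InvalidInputError("cooked-reference moisture must be > 0")
    return m_e / m_c


def _as_lab(c) -> np.ndarray:
    if isinstance(c, ColorMeasurement):
        return c.as_array()
    arr = np.asarray(c, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError("a colour is an (L*, a*, b*) triple")
    return arr


def delta_e(sample, reference) -> float:
    """Total colour difference dE* = ||(L*, a*, b*) - (L0*, a0*, b0*)||_2.

    Symmetric in its arguments; the reference is conventionally the control
    (fresh beans for dried samples, cooked beans for rehydrated ones).
    """
    return float(np.linalg.norm(_as_lab(sample) - _as_lab(reference)))


def mean_delta_e(samples: Sequence, references: Sequence) -> float:
    """Mean of per-replicate dE* over paired sample/reference replicates."""
    samples = list(samples)
    references = list(references)
    if len(samples) != len(references) or not samples:
        raise InvalidInputError("need equal, non-zero numbers of replicates")
    return float(np.mean([delta_e(s, r) for s, r in zip(samples, references)]))


def degree_retrogradation(record: ThermalRecord) -> float:
    """DR% = 100 * dH_R / dH_G, the retrograded fraction of the starch."""
    if record.dh_g <= 0:
        raise InvalidInputError("gelatinisation enthalpy must be > 0")
    return 100.0 * record.dh_r / record.dh_g


# ---------------------------------------------------------------------------
# group comparison: ANOVA, pairwise t-tests, compact letter display
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    anova_f: float
    anova_p: float
    pairwise_p: pd.DataFrame  # symmetric matrix of pairwise t-test p-values
    letters: dict  # group label -> letter string
    means: dict
    sds: dict
    alpha: float


def compact_letter_display(
    labels: Sequence[str],
    significant: Mapping[tuple, bool],
    order_by: Optional[Mapping[str, float]] = None,
) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant[(i, j)]`` is True when groups i and j differ.  Starting
    from a single letter column containing every group, each significant
    pair splits any column containing both; columns that become subsets of
    another are absorbed.  Letters are assigned to columns ordered by the
    highest-ranked member (rank = descending ``order_by`` value, or input
    order), which makes the display deterministic given the p-value matrix.
    """
    labels = list(labels)
    if order_by is not None:
        ranked = sorted(labels, key=lambda g: (-order_by[g], labels.index(g)))
    else:
        ranked = labels
    rank = {g: i for i, g in enumerate(ranked)}

    def is_sig(i, j):
        return bool(significant.get((i, j), significant.get((j, i), False)))

    columns = [set(labels)]
    for i, j in itertools.combinations(labels, 2):
        if not is_sig(i, j):
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for drop in (i, j):
                new = col - {drop}
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        # absorb columns that became redundant
        columns = [
            c for c in columns
            if not any(c < other for other in columns if other is not c)
        ]
    columns.sort(key=lambda c: min(rank[g] for g in c))
    letters = {g: "" for g in labels}
    for idx, col in enumerate(columns):
        letter = chr(ord("a") + idx) if idx < 26 else f"z{idx}"
        for g in sorted(col, key=rank.get):
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in labels}


def group_compare(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    equal_var: bool = False,
    correction: Optional[str] = None,
) -> GroupComparison:
    """One-way ANOVA plus all pairwise t-tests with a letter display.

    Pairwise tests are Welch (unpooled) by default; ``equal_var=True`` pools
    variances.  ``correction="holm"`` applies a Holm step-down adjustment to
    the pairwise p-values (off by default, mirroring plain Student-t
    treatment comparison at the stated alpha).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise InvalidInputError("need >= 2 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise InvalidInputError(f"group {g!r} needs >= 2 replicates")
    if all(np.var(arr) == 0 for arr in arrays.values()):
        raise InvalidInputError("zero within-group variance in every group")

    f_stat, anova_p = stats.f_oneway(*arrays.values())

    pairs = list(itertools.combinations(labels, 2))
    pvals = {}
    for i, j in pairs:
        res = stats.ttest_ind(arrays[i], arrays[j], equal_var=equal_var)
        pvals[(i, j)] = float(res.pvalue)
    if correction == "holm":
        order = sorted(pairs, key=lambda p: pvals[p])
        m = len(pairs)
        running = 0.0
        for k, pair in enumerate(order):
            adj = min(1.0, (m - k) * pvals[pair])
            running = max(running, adj)
            pvals[pair] = running
    elif correction is not None:
        raise InvalidInputError(f"unknown correction {correction!r}")

    pmat = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    for (i, j), p in pvals.items():
        pmat.loc[i, j] = pmat.loc[j, i] = p

    significant = {pair: p < alpha for pair, p in pvals.items()}
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    sds = {g: float(arr.std(ddof=1)) for g, arr in arrays.items()}
    letters = compact_letter_display(labels, significant, order_by=means)
    return GroupComparison(
        anova_f=float(f_stat),
        anova_p=float(anova_p),
        pairwise_p=pmat,
        letters=letters,
        means=means,
        sds=sds,
        alpha=alpha,
    )


def format_group_summary(comparison: GroupComparison, decimals: int = 2) -> dict:
    """'mean ± sd ^letter^' strings per group, the conventional table cell."""
    out = {}
    for g in comparison.means:
        out[g] = (
            f"{comparison.means[g]:.{decimals}f} ± "
            f"{comparison.sds[g]:.{decimals}f} ^{comparison.letters[g]}^"
        )
    return out
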