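"""Bile-acid quantification summaries and the shared rank statistics.

Per-sample analyte *content* is ``A * V / M`` (nmol/g) for solid samples —
concentration A (nmol/L) times extraction volume V (L) over weighed mass
M (g) — while liquid samples report the concentration A directly (nmol/L).
Derived summaries: total bile acids (sum over all measured analytes),
12-OH vs non-12-OH class sums (classic vs alternative synthesis pathway),
and the CDCA/CA and β-MCA/CA ratios that index the pathway balance.  Group
contrasts use the two-sided Wilcoxon rank-sum test, exact by full labeling
enumeration for small groups.  The min–max rescale used for pathway-activity
scores, ``(V_cur − V_min)/(V_max − V_min)`` per pathway per group, also
lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .io import BAConcentrationTable, ParameterError, canonical_analyte

logger = logging.getLogger("spatzone")

EXACT_MAX_GROUP_SIZE = 10


# ---------------------------------------------------------------------------
# Class map
# ---------------------------------------------------------------------------

@dataclass
class BAClassMap:
    """Analyte → class (``12-OH`` | ``non-12-OH`` | ``unclassified``) mapping.

    The shipped default covers the 36 canonical analytes; conjugates inherit
    the class of their core bile acid, and analytes whose 12-OH status is
    genuinely ambiguous (UCA, NorCA, NorDCA, 3-oxoCA, APCA, Dio-LCA) are
    left unclassified rather than guessed.  The map is data — load a custom
    one with :meth:`from_csv`.
    """

    classes: dict[str, str]

    VALID = ("12-OH", "non-12-OH", "unclassified")

    def __post_init__(self) -> None:
        bad = {v for v in self.classes.values()} - set(self.VALID)
        if bad:
            raise ParameterError(
                f"invalid class labels {sorted(bad)}; allowed: {self.VALID}")
        self.classes = {canonical_analyte(k): v for k, v in self.classes.items()}

    def __getitem__(self, analyte: str) -> str:
        return self.classes.get(canonical_analyte(analyte), "unclassified")

    def coverage(self, analytes: list[str]) -> dict[str, list[str]]:
        """Partition ``analytes`` by assigned class (unknown → unclassified)."""
        out: dict[str, list[str]] = {c: [] for c in self.VALID}
        for a in analytes:
            out[self[a]].append(a)
        return out

    @classmethod
    def from_csv(cls, path) -> "BAClassMap":
        df = pd.read_csv(path)
        for col in ("analyte", "ba_class"):
            if col not in df.columns:
                raise ParameterError(f"{path}: missing column {col!r}")
        return cls(dict(zip(df["analyte"].astype(str), df["ba_class"].astype(str))))


def default_class_map() -> BAClassMap:
    """The packaged 36-analyte 12-OH classification."""
    ref = resources.files("spatzone.data").joinpath("ba_classes.csv")
    with resources.as_file(ref) as path:
        return BAClassMap.from_csv(path)


# ---------------------------------------------------------------------------
# Content, totals, class sums, ratios
# ---------------------------------------------------------------------------

def ba_content(a, v, m):
    """Content ``A * V / M`` in nmol/g for a solid sample.

    ``a`` is the calibrated concentration (nmol/L), ``v`` the extraction
    volume (L) and ``m`` the weighed sample mass (g).  Accepts scalars or
    aligned arrays.
    """
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(v <= 0) or np.any(m <= 0):
        raise ParameterError("V and M must be positive")
    return a * v / m


@dataclass
class BAProfile:
    """Per-sample contents and derived summaries for one concentration table.

    ``contents`` is samples x analytes in nmol/g for solid samples and
    nmol/L for liquid ones (tracked in ``units``).  ``summary`` carries one
    row per sample: total, class sums, the two diagnostic ratios, and the
    group label.
    """

    contents: pd.DataFrame
    summary: pd.DataFrame
    units: pd.Series
    class_coverage: dict[str, list[str]]


def ba_profile(table: BAConcentrationTable,
               class_map: BAClassMap | None = None) -> BAProfile:
    """Compute contents, totals, 12-OH/non-12-OH sums and ratios per sample.

    Missing concentrations count as zero in totals and class sums (logged)
    but make a ratio missing when they hit its denominator; the ratio is
    also missing whenever the CA content is zero.
    """
    if class_map is None:
        class_map = default_class_map()
    conc = table.concentrations
    n_missing = int(conc.isna().sum().sum())
    if n_missing:
        logger.warning("%d missing concentrations treated as 0 in sums", n_missing)

    solid = table.meta["matrix_type"] == "solid"
    contents = conc.copy().astype(float)
    factor = (table.meta["volume_l"] / table.meta["mass_g"]).where(solid, 1.0)
    contents = contents.mul(factor, axis=0)
    units = pd.Series(np.where(solid, "nmol/g", "nmol/L"), index=conc.index)

    filled = contents.fillna(0.0)
    coverage = class_map.coverage(list(conc.columns))
    if coverage["unclassified"]:
        logger.warning("analytes excluded from class sums (unclassified): %s",
                       coverage["unclassified"])

    def _class_sum(cls: str) -> pd.Series:
        cols = coverage[cls]
        return filled[cols].sum(axis=1) if cols else pd.Series(0.0, index=filled.index)

    def _ratio(num: str, den: str) -> pd.Series:
        if num not in contents.columns or den not in contents.columns:
            return pd.Series(np.nan, index=contents.index)
        d = contents[den]
        return contents[num].where(d > 0) / d.where(d > 0)

    summary = pd.DataFrame({
        "group": table.meta["group"],
        "total": filled.sum(axis=1),
        "sum_12OH": _class_sum("12-OH"),
        "sum_non12OH": _class_sum("non-12-OH"),
        "sum_unclassified": _class_sum("unclassified"),
        "CDCA_to_CA": _ratio("CDCA", "CA"),
        "bMCA_to_CA": _ratio("b-MCA", "CA"),
    })
    return BAProfile(contents=contents, summary=summary, units=units,
                     class_coverage=coverage)


def ba_totals(profile: BAProfile) -> pd.Series:
    """Total bile-acid content per sample (sum over all measured analytes)."""
    return profile.summary["total"]


def class_sums(profile: BAProfile) -> pd.DataFrame:
    """12-OH and non-12-OH sums per sample (classified analytes only)."""
    return profile.summary[["sum_12OH", "sum_non12OH"]]


def ba_ratios(profile: BAProfile) -> pd.DataFrame:
    """CDCA/CA and β-MCA/CA per sample (missing where CA content is 0)."""
    return profile.summary[["CDCA_to_CA", "bMCA_to_CA"]]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _all_labelings(n_total: int, n1: int) -> np.ndarray:
    """All C(n_total, n1) index subsets, one row each (cached)."""
    return np.array(list(combinations(range(n_total), n1)), dtype=np.intp)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n1+n2, n1) group labelings.

    The statistic is the midrank sum of group ``a``; its permutation null is
    symmetric about ``n1 (N+1) / 2`` even under ties, so the two-sided
    p-value is the fraction of labelings at least as far from the center as
    the observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1, n_total = len(a), len(pooled)
    center = n1 * (n_total + 1) / 2.0
    observed = abs(ranks[:n1].sum() - center)
    sums = ranks[_all_labelings(n_total, n1)].sum(axis=1)
    # midrank sums are exact binary fractions, so the comparison is tie-safe
    hits = int(np.count_nonzero(np.abs(sums - center) >= observed))
    return hits / comb(n_total, n1)


def group_compare(values_a, values_b, *, force_method: str | None = None
                  ) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value for two independent groups.

    Exact (full labeling enumeration, tie-safe) when both groups have at
    most 10 observations, otherwise the normal approximation with
    continuity and tie correction.  Returns ``(p, method)`` with
    ``method`` in ``{"exact", "normal_approx"}``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    method = force_method
    if method is None:
        method = ("exact" if max(a.size, b.size) <= EXACT_MAX_GROUP_SIZE
                  else "normal_approx")
    if method == "exact":
        return _exact_rank_sum_p(a, b), "exact"
    if method == "normal_approx":
        if np.ptp(np.concatenate([a, b])) == 0:
            return 1.0, "normal_approx"  # degenerate: all values identical
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
        return float(res.pvalue), "normal_approx"
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Pathway-activity min–max rescale
# ---------------------------------------------------------------------------

@dataclass
class NormalizationRecord:
    """One pathway-activity value with its group min/max (V_min ≤ V_cur ≤ V_max)."""

    v_cur: float
    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if not self.v_min <= self.v_cur <= self.v_max:
            raise ParameterError(
                f"require V_min <= V_cur <= V_max, got "
                f"({self.v_min}, {self.v_cur}, {self.v_max})")

    @property
    def scaled(self) -> float:
        if self.v_max == self.v_min:
            return 0.0
        return (self.v_cur - self.v_min) / (self.v_max - self.v_min)


def minmax_rescale(scores: pd.DataFrame,
                   value: str = "score",
                   by: tuple[str, ...] = ("pathway", "group")) -> pd.Series:
    """Rescale activity scores to [0, 1] within each pathway x group.

    ``(V_cur − V_min)/(V_max − V_min)`` per group; a constant group maps to
    all zeros with a warning.
    """
    for col in (*by, value):
        if col not in scores.columns:
            raise ParameterError(f"scores is missing column {col!r}")

    def _scale(s: pd.Series) -> pd.Series:
        lo, hi = s.min(), s.max()
        if hi == lo:
            logger.warning("constant activity group (V_min == V_max): "
                           "scaled scores set to 0")
            return pd.Series(0.0, index=s.index)
        return (s - lo) / (hi - lo)

    return (scores.groupby(list(by), group_keys=False)[value]
            .apply(_scale).rename("scaled"))
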