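"""Two-group comparison statistics for texture parameter tables.

The battery applied to each analysed parameter is: a Wilcoxon-Mann-Whitney
test for location differences and a Levene test for dispersion
differences, with Shapiro-Wilk available for normality screening. P values
are reported unadjusted — no multiple-comparison correction is applied
anywhere, and the output schema has no adjusted-P column.

The default Mann-Whitney P value uses the large-sample normal
approximation without continuity correction and without tie correction,
``z = (U − n1 n2 / 2) / sqrt(n1 n2 (n1 + n2 + 1) / 12)``; a tie-corrected
variance and exact enumeration (small samples) are available as options.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from microwear.io import SpecimenRecord
from microwear.iso25178 import PARAMETER_NAMES

__all__ = [
    "TestResult",
    "ComparisonTable",
    "DATASET_TAGS",
    "mann_whitney_u",
    "u_normal_pvalue",
    "shapiro_wilk",
    "levene",
    "compare_groups",
]

#: the three study contrasts: locality (on the lingual facet, autumn),
#: season (lingual facet, descriptive only), and facet (autumn, pooled)
DATASET_TAGS = ("locality_T3_autumn", "season_T3", "facet_autumn")


@dataclass(frozen=True)
class TestResult:
    """One two-group test outcome."""

    statistic_name: str
    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str
    z: float | None = None
    ties_present: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.p_two_sided) and not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError(f"p={self.p_two_sided} outside [0, 1]")


def u_normal_pvalue(U: float, n1: int, n2: int) -> float:
    """Two-sided P for a Mann-Whitney U under the no-tie normal approximation.

    No continuity correction is applied; P is symmetric about the null mean
    ``n1*n2/2`` and decreases monotonically in ``|U − n1*n2/2|``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U={U} outside [0, {n1 * n2}]")
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (U - mu) / sigma
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """U for group a by midranks; second value reports whether ties occurred."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: a.size].sum()
    u1 = r1 - a.size * (a.size + 1) / 2.0
    ties = np.unique(pooled).size < pooled.size
    return float(u1), ties


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided P by enumerating all group labelings of the pooled data."""
    pooled = np.concatenate([a, b])
    n1, n = a.size, a.size + b.size
    ranks = sps.rankdata(pooled)
    mu = n1 * b.size / 2.0
    u_obs, _ = _u_statistic(a, b)
    dev = abs(u_obs - mu) - 1e-9
    hits = total = 0
    offset = n1 * (n1 + 1) / 2.0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "normal_approx"
) -> TestResult:
    """Wilcoxon-Mann-Whitney test for a location difference between two groups.

    ``method`` is one of ``normal_approx`` (default; no continuity or tie
    correction), ``normal_approx_tie_corrected`` (tie-corrected variance),
    or ``exact`` (full enumeration, total sample size at most 14).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u, ties = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    if method == "exact":
        if n1 + n2 > 14:
            raise ValueError("exact enumeration limited to n1 + n2 <= 14")
        p = _exact_two_sided_p(a, b)
        return TestResult("U", u, p, n1, n2, "exact", z=None, ties_present=ties)
    if method == "normal_approx":
        sigma2 = n1 * n2 * (n1 + n2 + 1) / 12.0
    elif method == "normal_approx_tie_corrected":
        pooled = np.concatenate([a, b])
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / ((n) * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    else:
        raise ValueError(f"unknown method {method!r}")
    if sigma2 <= 0:
        raise ValueError("degenerate data: zero variance of U")
    z = (u - mu) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult("U", u, p, n1, n2, method, z=float(z), ties_present=ties)


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant input)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("constant input: W undefined")
    w, p = sps.shapiro(x)
    return TestResult("W_shapiro", float(w), float(p), x.size, 0, "shapiro_wilk")


def levene(a: Sequence[float], b: Sequence[float], center: str = "mean") -> TestResult:
    """Levene test for a dispersion difference between two groups.

    Classic Levene centers deviations on the group mean (the default);
    ``center='median'`` gives the Brown-Forsythe variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Levene test needs at least 2 values per group")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    centerfun = np.mean if center == "mean" else np.median
    dev_a = np.abs(a - centerfun(a))
    dev_b = np.abs(b - centerfun(b))
    if np.ptp(np.concatenate([dev_a, dev_b])) == 0.0:
        raise ValueError("degenerate data: all absolute deviations equal")
    f, p = sps.levene(a, b, center=center)
    return TestResult(
        "W_levene", float(f), float(p), a.size, b.size, f"levene_{center}"
    )


@dataclass
class ComparisonTable:
    """Per-parameter two-group comparison for one study contrast.

    ``location`` and ``dispersion`` map parameter name → TestResult for
    tested contrasts; descriptive-only contrasts carry group medians
    instead. The schema never contains adjusted P values.
    """

    dataset: str
    group_labels: tuple[str, str]
    location: dict[str, TestResult]
    dispersion: dict[str, TestResult]
    descriptive: pd.DataFrame | None = None

    def to_dataframe(self) -> pd.DataFrame:
        if self.descriptive is not None:
            return self.descriptive
        rows = []
        for name in sorted(self.location):
            loc = self.location[name]
            disp = self.dispersion.get(name)
            rows.append(
                {
                    "parameter": name,
                    "U": loc.statistic,
                    "P_location": loc.p_two_sided,
                    "n1": loc.n1,
                    "n2": loc.n2,
                    "levene_W": disp.statistic if disp else np.nan,
                    "P_dispersion": disp.p_two_sided if disp else np.nan,
                    "ties": loc.ties_present,
                }
            )
        return pd.DataFrame(rows)


_DATASET_FILTERS = {
    "locality_T3_autumn": (
        lambda r: r.facet == "T3" and r.season == "autumn",
        "locality",
        ("Kilpisjärvi", "Pallasjärvi"),
    ),
    "season_T3": (lambda r: r.facet == "T3", "season", ("autumn", "spring")),
    "facet_autumn": (lambda r: r.season == "autumn", "facet", ("T2", "T3")),
}


def compare_groups(
    records: Sequence[SpecimenRecord],
    dataset: str,
    parameters: Sequence[str] | None = None,
    mw_method: str = "normal_approx",
    levene_center: str = "mean",
) -> ComparisonTable:
    """Run the per-parameter test battery for one study contrast.

    ``dataset`` is one of :data:`DATASET_TAGS`. Records missing a parameter
    are dropped pairwise for that parameter only. The season contrast is
    summarized descriptively (group medians) because its spring group is
    too small to test; the other contrasts get Mann-Whitney + Levene per
    parameter with unadjusted P values.
    """
    if dataset not in _DATASET_FILTERS:
        raise ValueError(f"unknown dataset tag {dataset!r}; choose from {DATASET_TAGS}")
    keep, group_field, labels = _DATASET_FILTERS[dataset]
    params = tuple(parameters) if parameters is not None else PARAMETER_NAMES
    filtered = [r for r in records if keep(r) and r.parameters is not None]
    groups = {lab: [r for r in filtered if getattr(r, group_field) == lab] for lab in labels}
    for lab, rs in groups.items():
        if not rs:
            raise ValueError(
                f"dataset {dataset!r}: group {group_field}={lab!r} empty after filtering"
            )

    def values(lab: str, name: str) -> np.ndarray:
        v = np.array([r.parameters.get(name, np.nan) for r in groups[lab]], dtype=float)
        return v[np.isfinite(v)]

    if dataset == "season_T3":
        rows = []
        for name in params:
            row = {"parameter": name}
            for lab in labels:
                v = values(lab, name)
                row[f"median_{lab}"] = float(np.median(v)) if v.size else np.nan
                row[f"n_{lab}"] = int(v.size)
            rows.append(row)
        return ComparisonTable(
            dataset=dataset,
            group_labels=labels,
            location={},
            dispersion={},
            descriptive=pd.DataFrame(rows),
        )

    location: dict[str, TestResult] = {}
    dispersion: dict[str, TestResult] = {}
    for name in params:
        va, vb = values(labels[0], name), values(labels[1], name)
        if va.size == 0 or vb.size == 0:
            continue
        location[name] = mann_whitney_u(va, vb, method=mw_method)
        try:
            dispersion[name] = levene(va, vb, center=levene_center)
        except ValueError:
            pass  # degenerate dispersion — location result still reported
    return ComparisonTable(
        dataset=dataset, group_labels=labels, location=location, dispersion=dispersion
    )
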