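"""Agreement metrics, canonical variates, age-banded reference intervals,
profile flagging, group comparison, and the stain-index QC utility.

Conventions that matter downstream:

* MNB (mean normalized bias) is reference-anchored and signed:
  mean over pairs of 100 x (b - a) / a with ``a`` the reference analysis;
  pairs with a == 0 are excluded with a warning.
* Concordance requires |MNB| <= band AND r^2 >= threshold AND p <= cutoff.
* Percentiles use linear interpolation (the R type-7 default).
* The Mann-Whitney U test is exact (full enumeration / distribution
  recursion) for small groups and normal-approximated with tie correction
  otherwise.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NumericalError, ValidationError

__all__ = [
    "AgreementConfig",
    "AgreementReport",
    "AgeBandSpec",
    "ReferenceIntervalTable",
    "agreement",
    "canonical_variates",
    "reference_intervals",
    "flag_profile",
    "compare_groups",
    "stain_index",
    "default_age_bands",
]


# ---------------------------------------------------------------------------
# Agreement


@dataclass(frozen=True)
class AgreementConfig:
    r2_min: float = 0.9
    mnb_band: float = 15.0  # percent half-width
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.r2_min <= 1):
            raise ValidationError("r2_min must be in (0, 1]")
        if self.mnb_band <= 0:
            raise ValidationError("mnb_band must be positive")


@dataclass
class AgreementReport:
    per_population: pd.DataFrame  # population, n_pairs, r2, p, mnb, concordant
    not_identified: tuple[str, ...]
    config: AgreementConfig

    @property
    def fraction_concordant(self) -> float:
        flags = self.per_population["concordant"].dropna()
        return float(flags.mean()) if len(flags) else math.nan

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": {
                    "r2_min": self.config.r2_min,
                    "mnb_band": self.config.mnb_band,
                    "p_max": self.config.p_max,
                },
                "not_identified": list(self.not_identified),
                "populations": self.per_population.to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )


def agreement(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    config: AgreementConfig = AgreementConfig(),
) -> AgreementReport:
    """Per-population agreement between two analyses.

    ``pairs`` maps a population name to (reference values, comparison
    values) across samples.  A population whose vectors are empty or
    mismatched in either analysis is reported as not identified.
    """
    rows = []
    not_identified = []
    for pop, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0 or a.size != b.size:
            not_identified.append(pop)
            continue
        if np.any(a < 0) or np.any(b < 0):
            raise ValidationError(f"{pop}: agreement values must be non-negative")
        nonzero = a != 0
        if not np.all(nonzero):
            warnings.warn(
                f"{pop}: {int((~nonzero).sum())} pair(s) with zero reference "
                "excluded from MNB",
                stacklevel=2,
            )
        mnb = (
            float(np.mean(100.0 * (b[nonzero] - a[nonzero]) / a[nonzero]))
            if nonzero.any()
            else math.nan
        )
        if a.size >= 2 and np.std(a) > 0 and np.std(b) > 0:
            r, p = sps.pearsonr(a, b)
            r2 = float(r**2)
            p = float(p)
        elif a.size >= 2 and np.array_equal(a, b):
            r2, p = 1.0, 0.0  # identical analyses are perfectly concordant
        else:
            r2, p = math.nan, math.nan
        conc: bool | float
        if math.isnan(mnb):
            conc = math.nan
        elif a.size >= 2:
            conc = (
                abs(mnb) <= config.mnb_band
                and not math.isnan(r2)
                and r2 >= config.r2_min
                and p <= config.p_max
            )
        else:
            conc = abs(mnb) <= config.mnb_band  # single pair: bias band only
        rows.append(
            {"population": pop, "n_pairs": int(a.size), "r2": r2, "p": p,
             "mnb": mnb, "concordant": conc}
        )
    return AgreementReport(
        per_population=pd.DataFrame(
            rows, columns=["population", "n_pairs", "r2", "p", "mnb", "concordant"]
        ),
        not_identified=tuple(not_identified),
        config=config,
    )


# ---------------------------------------------------------------------------
# Canonical variates


def canonical_variates(
    groups: Mapping[str, np.ndarray],
    markers: Sequence[str],
    shrinkage: float = 1e-8,
) -> dict:
    """Fisher discriminant axes on standardized observations.

    Returns a dict with ``loadings`` (markers x axes), per-marker
    ``ca1_contributions`` (percent, squared-loading normalized),
    ``eigenvalues``, ``projections`` and ``centroids`` per group.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    mats = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, m in mats.items():
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValidationError(f"group {g!r} needs >= 2 observations")
        if m.shape[1] != len(markers):
            raise ValidationError(f"group {g!r} has wrong marker count")
    stacked = np.vstack(list(mats.values()))
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    z = {g: (m - mu) / sd for g, m in mats.items()}
    grand = np.vstack(list(z.values())).mean(axis=0)

    p = len(markers)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for g, m in z.items():
        c = m.mean(axis=0)
        d = m - c
        sw += d.T @ d
        diff = (c - grand)[:, None]
        sb += m.shape[0] * (diff @ diff.T)

    if np.allclose(sb, 0):
        warnings.warn("between-group scatter is ~0: groups are identical",
                      stacklevel=2)
    lam = shrinkage
    while True:
        sw_reg = sw + lam * np.trace(sw + np.eye(p)) / p * np.eye(p)
        try:
            np.linalg.cholesky(sw_reg)
            break
        except np.linalg.LinAlgError:
            lam *= 10
            warnings.warn(
                f"singular within-group scatter; shrinkage raised to {lam:g}",
                stacklevel=2,
            )
    from scipy.linalg import eigh

    evals, evecs = eigh(sb, sw_reg)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    n_axes = min(len(names) - 1, p)
    loadings = evecs[:, :n_axes]
    w1 = loadings[:, 0] ** 2
    contrib = dict(zip(markers, map(float, 100.0 * w1 / w1.sum())))
    projections = {g: m @ loadings for g, m in z.items()}
    centroids = {g: pr.mean(axis=0) for g, pr in projections.items()}
    return {
        "markers": list(markers),
        "loadings": loadings,
        "eigenvalues": evals[:n_axes],
        "ca1_contributions": contrib,
        "projections": projections,
        "centroids": centroids,
    }


# ---------------------------------------------------------------------------
# Age bands and reference intervals

CB_LABEL = "cb"


@dataclass(frozen=True)
class AgeBandSpec:
    """Ordered, non-overlapping [low, high) age bands covering 0-120 years,
    plus a special pre-birth cord-blood band."""

    bands: tuple[tuple[str, float, float], ...]
    cb_label: str = CB_LABEL

    def __post_init__(self) -> None:
        prev_hi = None
        for label, lo, hi in self.bands:
            if hi <= lo:
                raise ValidationError(f"band {label!r}: high must exceed low")
            if prev_hi is not None and lo < prev_hi:
                raise ValidationError(f"band {label!r} overlaps its predecessor")
            prev_hi = hi

    def labels(self) -> tuple[str, ...]:
        return (self.cb_label,) + tuple(b[0] for b in self.bands)

    def band_of(self, age: float | str) -> str:
        if isinstance(age, str):
            if age.lower() == self.cb_label:
                return self.cb_label
            raise ValidationError(f"unknown age label {age!r}")
        if age < 0:
            raise ValidationError("negative age")
        for label, lo, hi in self.bands:
            if lo <= age < hi:
                return label
        raise ValidationError(
            f"age {age} outside all bands {[b[0] for b in self.bands]}"
        )


def default_age_bands() -> AgeBandSpec:
    """CB plus bands anchored at 2 months, 2, 5, 10, 18, 40, 60, 80 years."""
    return AgeBandSpec(
        bands=(
            ("2mo-2y", 2.0 / 12.0, 2.0),
            ("2-5y", 2.0, 5.0),
            ("5-10y", 5.0, 10.0),
            ("10-18y", 10.0, 18.0),
            ("18-40y", 18.0, 40.0),
            ("40-60y", 40.0, 60.0),
            ("60-80y", 60.0, 80.0),
            ("80+y", 80.0, 120.0),
        )
    )


DEFAULT_PERCENTILES = (10, 25, 50, 75, 90)


@dataclass
class ReferenceIntervalTable:
    """Per population x band order statistics of absolute counts."""

    table: pd.DataFrame  # columns: population, band, n, min, p10..p90, max, low_n
    bands: AgeBandSpec
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    min_band_n: int = 10

    def lookup(self, population: str, band: str) -> pd.Series:
        sel = self.table[
            (self.table["population"] == population) & (self.table["band"] == band)
        ]
        if sel.empty:
            raise ValidationError(
                f"no interval for population {population!r} in band {band!r}"
            )
        return sel.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bands: AgeBandSpec | None = None) -> "ReferenceIntervalTable":
        df = pd.read_csv(path)
        pct = tuple(
            float(c[1:]) for c in df.columns if c.startswith("p") and c[1:].replace(".", "").isdigit()
        )
        return cls(table=df, bands=bands or default_age_bands(), percentiles=pct)


def reference_intervals(
    cohort: pd.DataFrame,
    ages: Sequence[float | str],
    bands: AgeBandSpec | None = None,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    min_band_n: int = 10,
) -> ReferenceIntervalTable:
    """Percentile envelopes per population and age band.

    ``cohort`` holds one row per sample and one column per population
    (absolute counts); ``ages`` aligns with the rows and may contain the CB
    label.  Percentiles use linear interpolation (type-7).
    """
    bands = bands or default_age_bands()
    if len(ages) != len(cohort):
        raise ValidationError("ages must align with cohort rows")
    band_of_sample = [bands.band_of(a) for a in ages]
    rows = []
    df = cohort.copy()
    df["__band"] = band_of_sample
    for band, grp in df.groupby("__band", sort=False):
        for pop in cohort.columns:
            vals = grp[pop].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            row = {
                "population": pop,
                "band": band,
                "n": int(vals.size),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "low_n": bool(vals.size < min_band_n),
            }
            for q in percentiles:
                row[f"p{q:g}"] = float(np.percentile(vals, q))  # type-7 linear
            rows.append(row)
    cols = ["population", "band", "n", "min"] + [f"p{q:g}" for q in percentiles] + ["max", "low_n"]
    table = pd.DataFrame(rows)[cols]
    order = {l: i for i, l in enumerate(bands.labels())}
    table = table.sort_values(
        ["population", "band"], key=lambda s: s.map(order).fillna(-1) if s.name == "band" else s
    ).reset_index(drop=True)
    return ReferenceIntervalTable(
        table=table, bands=bands, percentiles=tuple(percentiles), min_band_n=min_band_n
    )


def flag_profile(
    patient: Mapping[str, float],
    age: float | str,
    intervals: ReferenceIntervalTable,
    low_pct: float = 10,
    high_pct: float = 90,
) -> pd.DataFrame:
    """Flag each population low (< p10), high (> p90), or normal for the
    patient's age band."""
    band = intervals.bands.band_of(age)
    rows = []
    for pop, value in patient.items():
        try:
            ref = intervals.lookup(pop, band)
        except ValidationError:
            rows.append({"population": pop, "value": value, "band": band,
                         "flag": "no-reference", "band_n": 0})
            continue
        lo, hi = ref[f"p{low_pct:g}"], ref[f"p{high_pct:g}"]
        flag = "low" if value < lo else ("high" if value > hi else "normal")
        rows.append({"population": pop, "value": float(value), "band": band,
                     "flag": flag, "band_n": int(ref["n"]),
                     f"p{low_pct:g}": float(lo), f"p{high_pct:g}": float(hi)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """count[u] of rank arrangements with U statistic u (no ties)."""
    # f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u)
    max_u = n1 * n2
    prev = {(0, j): np.array([1] + [0] * max_u, dtype=object) for j in range(n2 + 1)}
    table = dict(prev)
    for m in range(1, n1 + 1):
        table[(m, 0)] = np.array([1] + [0] * max_u, dtype=object)
        for n in range(1, n2 + 1):
            shifted = np.zeros(max_u + 1, dtype=object)
            shifted[n:] = table[(m - 1, n)][: max_u + 1 - n]
            table[(m, n)] = shifted + table[(m, n - 1)]
    return table[(n1, n2)]


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #(a_i > b_j) + 0.5 #(a_i == b_j)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    exact_limit: int = 20,
    enumeration_limit: int = 200_000,
) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact for small groups: via the U-count recursion when there are no
    ties, or full enumeration of group assignments when feasible; a normal
    approximation with tie correction and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u = _u_statistic(a, b)
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    method = "normal"
    if not has_ties and max(n1, n2) <= exact_limit:
        counts = _u_distribution(n1, n2)
        total = sum(counts)
        ui = int(round(u))
        p_le = sum(counts[: ui + 1]) / total
        p_ge = sum(counts[ui:]) / total
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
        method = "exact-distribution"
    elif has_ties and math.comb(n1 + n2, n1) <= enumeration_limit:
        stats_all = []
        idx = np.arange(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            stats_all.append(_u_statistic(combined[mask], combined[~mask]))
        stats_all = np.asarray(stats_all)
        eps = 1e-9
        p_le = np.mean(stats_all <= u + eps)
        p_ge = np.mean(stats_all >= u - eps)
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
        method = "exact-enumeration"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(var) if u != mu else 0.0
            p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
    return {
        "U": u,
        "n1": int(n1),
        "n2": int(n2),
        "p": p,
        "significant": bool(p < alpha),
        "alpha": alpha,
        "method": method,
    }


# ---------------------------------------------------------------------------
# Stain index


def stain_index(pos_values: Sequence[float], neg_values: Sequence[float]) -> float:
    """(median(pos) - median(neg)) / (2 x SD(neg)) on raw intensities."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both vectors must be non-empty")
    sd = float(np.std(neg, ddof=1)) if neg.size > 1 else 0.0
    if sd == 0:
        raise NumericalError("stain index undefined: negative population SD is 0")
    return float((np.median(pos) - np.median(neg)) / (2.0 * sd))
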