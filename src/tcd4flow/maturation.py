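"""PCA-based maturation-pathway staging and marker-contribution analysis.

Events are projected onto the first principal component of their
standardized maturation markers, oriented so the orientation marker
(CD45RA by default) is high at stage 1 (naive end), ranked, and split into
equal-count stages (20 by default).  Adjacent stages whose per-marker
median phenotypes discretize identically can then be merged, which reduces
the arbitrary fine staging to the canonical N/CM/TM/EM/TE resolution on
suitable input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .panel import ThresholdSet

__all__ = [
    "MaturationPath",
    "ContributionReport",
    "stage_pathway",
    "merge_stages",
    "marker_contributions",
]


@dataclass
class MaturationPath:
    """Result of staging events along the maturation axis."""

    stage: np.ndarray  # per-event stage index, 1-based, 1 = least mature
    markers: tuple[str, ...]
    events: np.ndarray  # the marker-restricted event matrix (transformed)
    loading: np.ndarray  # PC1 loading vector (oriented)
    n_stages: int

    @property
    def stage_stats(self) -> pd.DataFrame:
        rows = []
        for s in range(1, self.n_stages + 1):
            sel = self.events[self.stage == s]
            for j, m in enumerate(self.markers):
                rows.append(
                    {
                        "stage": s,
                        "marker": m,
                        "median": float(np.median(sel[:, j])) if sel.size else np.nan,
                        "sd": float(np.std(sel[:, j])) if sel.size else np.nan,
                        "n_events": int(sel.shape[0]),
                    }
                )
        return pd.DataFrame(rows)

    def stage_medians(self) -> np.ndarray:
        """(n_stages, n_markers) matrix of per-stage medians."""
        out = np.full((self.n_stages, len(self.markers)), np.nan)
        for s in range(1, self.n_stages + 1):
            sel = self.events[self.stage == s]
            if sel.size:
                out[s - 1] = np.median(sel, axis=0)
        return out

    def to_csv(self, path) -> None:
        self.stage_stats.to_csv(path, index=False)


@dataclass
class ContributionReport:
    """Per-marker percentage contributions to PC1/PC2."""

    markers: tuple[str, ...]
    pc1_contributions: dict[str, float]
    pc2_contributions: dict[str, float]
    eigenvalues: np.ndarray
    excluded: tuple[str, ...] = ()
    note: str = "PC sign is arbitrary; contributions use squared loadings."

    def sorted_pc1(self) -> list[tuple[str, float]]:
        return sorted(self.pc1_contributions.items(), key=lambda kv: -kv[1])


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    z = np.zeros_like(x)
    z[:, keep] = (x[:, keep] - mu[keep]) / sd[keep]
    return z, keep


def _pca(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Loadings (columns) and eigenvalues of the covariance of z."""
    # SVD of the centered matrix is stabler than eigh on the Gram matrix
    _, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    eig = s**2 / max(z.shape[0] - 1, 1)
    return vt.T, eig


def stage_pathway(
    events: np.ndarray | pd.DataFrame,
    n_stages: int = 20,
    orientation_marker: str = "CD45RA",
    markers: Sequence[str] | None = None,
) -> MaturationPath:
    """Rank events along PC1 of the maturation markers and bin into
    ``n_stages`` equal-count stages (remainders go to the earliest bins).
    """
    if isinstance(events, pd.DataFrame):
        markers = tuple(events.columns)
        x = events.to_numpy(dtype=float)
    else:
        x = np.asarray(events, dtype=float)
        if markers is None:
            raise ValidationError("matrix input requires an explicit marker list")
        markers = tuple(markers)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 markers")
    n = x.shape[0]
    if n_stages < 1:
        raise ValidationError("n_stages must be >= 1")
    if n_stages > n:
        raise ValidationError(f"n_stages ({n_stages}) exceeds event count ({n})")
    if orientation_marker not in markers:
        raise ConfigurationError(
            f"orientation marker {orientation_marker!r} not among {markers}"
        )

    z, _ = _standardize(x)
    loadings, _ = _pca(z)
    pc1 = loadings[:, 0]
    score = z @ pc1
    om = x[:, markers.index(orientation_marker)]
    # naive end first: the orientation marker must decrease along the axis
    if np.corrcoef(score, om)[0, 1] > 0:
        pc1 = -pc1
        score = -score

    order = np.lexsort((np.arange(n), score))  # event index breaks ties
    stage = np.empty(n, dtype=int)
    bins = np.array_split(order, n_stages)  # larger bins first (earliest)
    for s, idx in enumerate(bins, start=1):
        stage[idx] = s
    return MaturationPath(
        stage=stage, markers=markers, events=x, loading=pc1, n_stages=n_stages
    )


def merge_stages(path: MaturationPath, thresholds: ThresholdSet) -> MaturationPath:
    """Merge maximal runs of adjacent stages with identical discretized
    median phenotypes; merged stages are relabeled 1..k in order."""
    missing = [m for m in path.markers if m not in thresholds.cutpoints]
    if missing:
        raise ConfigurationError(f"thresholds missing maturation markers: {missing}")
    medians = path.stage_medians()
    codes = []
    for s in range(path.n_stages):
        code = tuple(
            int(thresholds.levels_for(m, np.asarray([medians[s, j]]))[0])
            for j, m in enumerate(path.markers)
        )
        codes.append(code)
    new_of_old = np.empty(path.n_stages, dtype=int)
    k = 0
    prev = None
    for s, code in enumerate(codes):
        if code != prev:
            k += 1
            prev = code
        new_of_old[s] = k
    return MaturationPath(
        stage=new_of_old[path.stage - 1],
        markers=path.markers,
        events=path.events,
        loading=path.loading,
        n_stages=k,
    )


def marker_contributions(
    events: np.ndarray | pd.DataFrame,
    markers: Sequence[str] | None = None,
) -> ContributionReport:
    """Percentage contribution of each marker to PC1 (and PC2):
    100 x loading(m)^2 / sum of squared loadings."""
    if isinstance(events, pd.DataFrame):
        markers = tuple(events.columns)
        x = events.to_numpy(dtype=float)
    else:
        x = np.asarray(events, dtype=float)
        if markers is None:
            raise ValidationError("matrix input requires an explicit marker list")
        markers = tuple(markers)
    if x.shape[0] < 3:
        raise ValidationError("need >= 3 events for a contribution report")

    z, keep = _standardize(x)
    excluded = tuple(m for m, k in zip(markers, keep) if not k)
    if excluded:
        warnings.warn(
            f"constant markers excluded from PCA: {excluded}", stacklevel=2
        )
    kept_markers = tuple(m for m, k in zip(markers, keep) if k)
    zk = z[:, keep]
    if zk.shape[1] == 0:
        raise ValidationError("all markers are constant")
    if zk.shape[1] == 1:
        # the single varying marker carries the whole axis
        return ContributionReport(
            markers=kept_markers,
            pc1_contributions={kept_markers[0]: 100.0},
            pc2_contributions={},
            eigenvalues=np.asarray([float(np.var(zk[:, 0], ddof=1))]),
            excluded=excluded,
        )
    loadings, eig = _pca(zk)

    def contrib(component: int) -> dict[str, float]:
        w = loadings[:, component] ** 2
        w = 100.0 * w / w.sum()
        return dict(zip(kept_markers, map(float, w)))

    return ContributionReport(
        markers=kept_markers,
        pc1_contributions=contrib(0),
        pc2_contributions=contrib(1) if loadings.shape[1] > 1 else {},
        eigenvalues=eig,
        excluded=excluded,
    )
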