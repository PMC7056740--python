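"""Database-guided automated gating.

A reference database pools per-population multivariate statistics
(shrinkage-regularized mean/covariance in transformed space) from labeled
samples.  New samples are then classified top-down through the taxonomy: at
each level an event joins the sibling population with the smallest
Mahalanobis distance on that level's discriminating markers, subject to a
maximum-radius gate; events beyond the radius of every sibling are novelty
flagged and fall into the level's unclassified bin.  Populations ending up
with fewer than ``min_cluster`` events (default 10) are suppressed from the
report while keeping their counts internally, so conservation invariants
survive suppression.

Everything here is deterministic: distance ties break by higher prior, then
lexicographic name.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .fcs_io import FlowSample
from .stats import AgreementConfig, AgreementReport, agreement
from .taxonomy import (
    UNCLASSIFIED_PREFIX,
    GatingResult,
    PopulationNode,
    Taxonomy,
)

__all__ = [
    "ReferencePopulationStats",
    "ReferenceDatabase",
    "AutoGateResult",
    "build_reference",
    "auto_gate",
    "compare_analyses",
]


@dataclass
class ReferencePopulationStats:
    """Pooled multivariate summary of one population."""

    population: str
    markers: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray  # shrinkage-regularized, symmetric PSD
    n_events: int
    prior: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValidationError(f"{self.population}: covariance shape mismatch")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValidationError(f"{self.population}: covariance not symmetric")

    def submatrix(self, idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        idx = np.asarray(idx, dtype=int)
        return self.mean[idx], self.covariance[np.ix_(idx, idx)]

    def to_jsonable(self) -> dict:
        return {
            "population": self.population,
            "markers": list(self.markers),
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "n_events": self.n_events,
            "prior": self.prior,
        }

    @classmethod
    def from_jsonable(cls, d: Mapping) -> "ReferencePopulationStats":
        return cls(
            population=d["population"],
            markers=tuple(d["markers"]),
            mean=np.asarray(d["mean"], float),
            covariance=np.asarray(d["covariance"], float),
            n_events=int(d["n_events"]),
            prior=float(d["prior"]),
        )


@dataclass
class ReferenceDatabase:
    """Per-population statistics pooled from labeled reference samples."""

    taxonomy: Taxonomy
    stats: dict[str, ReferencePopulationStats]
    markers: tuple[str, ...]
    provenance: tuple[str, ...] = ()
    config: dict = field(default_factory=dict)

    def has(self, population: str) -> bool:
        return population in self.stats

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": list(self.markers),
                "provenance": list(self.provenance),
                "config": self.config,
                "taxonomy": json.loads(self.taxonomy.to_json()),
                "stats": {k: v.to_jsonable() for k, v in self.stats.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceDatabase":
        raw = json.loads(text)
        return cls(
            taxonomy=Taxonomy.from_json(json.dumps(raw["taxonomy"])),
            stats={
                k: ReferencePopulationStats.from_jsonable(v)
                for k, v in raw["stats"].items()
            },
            markers=tuple(raw["markers"]),
            provenance=tuple(raw.get("provenance", ())),
            config=dict(raw.get("config", {})),
        )


def _leaf_sets(taxonomy: Taxonomy) -> dict[str, set[str]]:
    """node name -> set of leaf names in its subtree (aliases skipped)."""
    out: dict[str, set[str]] = {}

    def visit(node: PopulationNode) -> set[str]:
        real = [c for c in node.children if c.alias_of is None]
        if not real:
            s = {node.name}
        else:
            s = set()
            for c in real:
                s |= visit(c)
        out[node.name] = s
        return s

    visit(taxonomy.root)
    return out


def build_reference(
    labeled: Sequence[tuple[FlowSample, np.ndarray]],
    taxonomy: Taxonomy | None = None,
    shrinkage: float = 0.1,
    min_events: int = 3,
) -> ReferenceDatabase:
    """Pool per-population mean/covariance across labeled samples.

    ``labeled`` pairs a *transformed* FlowSample with a per-event leaf label
    vector.  Covariances are shrunk toward their diagonal:
    (1 - lambda) * S + lambda * diag(S).  Populations with fewer than
    ``min_events`` pooled events are omitted with a warning; labels outside
    the taxonomy are ignored.
    """
    if not labeled:
        raise ValidationError("need at least one labeled sample")
    from .taxonomy import build_taxonomy

    tax = taxonomy if taxonomy is not None else build_taxonomy()
    first_labels = None
    pooled: dict[str, list[np.ndarray]] = {}
    provenance = []
    for i, (sample, labels) in enumerate(labeled):
        if sample.transform_state != "transformed":
            raise ValidationError("reference samples must be transformed")
        labels = np.asarray(labels)
        if labels.shape[0] != sample.n_events:
            raise ValidationError("label vector length != event count")
        if first_labels is None:
            first_labels = sample.channel_labels
        elif sample.channel_labels != first_labels:
            raise ValidationError("panel mismatch between labeled samples")
        provenance.append(str(sample.metadata.get("TCD4_SAMPLE_ID", f"sample-{i}")))
        for leaf in np.unique(labels):
            if leaf not in tax:
                continue
            pooled.setdefault(leaf, []).append(sample.events[labels == leaf])

    markers = first_labels
    leaf_sets = _leaf_sets(tax)
    stats: dict[str, ReferencePopulationStats] = {}
    total_events = 0
    node_events: dict[str, np.ndarray] = {}
    for node in tax.nodes():
        if node.alias_of is not None:
            continue
        chunks = [
            np.vstack(pooled[leaf])
            for leaf in leaf_sets[node.name]
            if leaf in pooled
        ]
        if not chunks:
            continue
        ev = np.vstack(chunks)
        node_events[node.name] = ev
    if "leukocytes" in node_events:
        total_events = node_events["leukocytes"].shape[0]

    for name, ev in node_events.items():
        n = ev.shape[0]
        if n < min_events:
            warnings.warn(
                f"{name}: only {n} pooled events (< {min_events}); stats omitted",
                stacklevel=2,
            )
            continue
        mean = ev.mean(axis=0)
        cov = np.cov(ev, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
        node = tax.node(name)
        parent_n = (
            node_events[node.parent.name].shape[0]
            if node.parent and node.parent.name in node_events
            else total_events or n
        )
        stats[name] = ReferencePopulationStats(
            population=name,
            markers=tuple(markers),
            mean=mean,
            covariance=cov,
            n_events=n,
            prior=n / parent_n if parent_n else 0.0,
        )

    return ReferenceDatabase(
        taxonomy=tax,
        stats=stats,
        markers=tuple(markers),
        provenance=tuple(provenance),
        config={"shrinkage": shrinkage, "min_events": min_events},
    )


@dataclass
class AutoGateResult:
    """GatingResult plus reporting suppression and novelty flags."""

    gating: GatingResult
    suppressed: tuple[str, ...]  # populations with < min_cluster events
    novelty: np.ndarray  # per-event flag: outside all reference radii
    min_cluster: int

    @property
    def labels(self) -> np.ndarray:
        return self.gating.labels

    def reported_counts(self) -> dict[str, int]:
        """Counts with suppressed populations excluded from the report."""
        return {
            k: v
            for k, v in self.gating.counts.items()
            if k not in self.suppressed
        }

    def report_frame(self) -> pd.DataFrame:
        df = self.gating.to_frame()
        df["suppressed"] = df["population"].isin(self.suppressed)
        return df[~df["suppressed"]].drop(columns=["suppressed"])


def auto_gate(
    sample: FlowSample,
    db: ReferenceDatabase,
    min_cluster: int = 10,
    max_radius: float = 4.0,
    on_empty_level: str = "stop",
) -> AutoGateResult:
    """Classify a transformed sample against the reference database.

    Deterministic top-down Mahalanobis assignment per the module docstring.
    ``min_cluster`` applies to reporting only; assignments are kept
    internally so parent/child conservation always holds.

    ``on_empty_level`` controls what happens when events reach a node none
    of whose children has database statistics: ``"stop"`` (default) keeps
    the events at that node, as for an undivided cluster; ``"error"``
    raises a classification error naming the level.  The root must always
    have statistics.
    """
    if on_empty_level not in ("stop", "error"):
        raise ValidationError("on_empty_level must be 'stop' or 'error'")
    if sample.transform_state != "transformed":
        raise ValidationError("auto_gate requires a transformed sample")
    if sample.channel_labels != db.markers:
        raise ConfigurationError(
            "sample channels do not match the database's marker order"
        )
    from scipy.stats import chi2, norm

    tax = db.taxonomy
    col = {m: i for i, m in enumerate(db.markers)}
    n = sample.n_events
    x = sample.events
    label = np.empty(n, dtype=object)
    novelty = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    # the radius is a univariate-SD equivalent: gate at the chi^2 quantile
    # matching P(|z| <= radius) for the level's dimensionality
    cover = 2.0 * norm.cdf(max_radius) - 1.0

    def gate_threshold(k: int) -> float:
        return float(chi2.ppf(cover, df=k))

    def descend(node: PopulationNode, idx: np.ndarray) -> None:
        counts[node.name] = counts.get(node.name, 0) + idx.size
        real = [c for c in node.children if c.alias_of is None]
        if not real or idx.size == 0:
            if not real:
                label[idx] = node.name
            for d in node.walk():
                counts.setdefault(d.name, 0)
            if real:
                counts.setdefault(node.unclassified_name, 0)
            return
        competitors = [c for c in real if db.has(c.name)]
        if not competitors:
            if on_empty_level == "error":
                raise ConfigurationError(
                    f"empty database at level {node.name!r}: no child has statistics"
                )
            # undivided cluster: events stay here, in the level's bin, so
            # the children + bin partition of the node still holds
            label[idx] = node.unclassified_name
            counts[node.unclassified_name] = (
                counts.get(node.unclassified_name, 0) + idx.size
            )
            for d in node.walk():
                counts.setdefault(d.name, 0)
            return
        midx = [col[m] for m in node.child_markers] if node.child_markers else list(col.values())
        sub = x[np.ix_(idx, midx)]
        d2 = np.empty((idx.size, len(competitors)))
        for j, child in enumerate(competitors):
            mu, cov = db.stats[child.name].submatrix(midx)
            cov = cov + 1e-9 * np.eye(len(midx))
            diff = sub - mu
            sol = np.linalg.solve(cov, diff.T)
            d2[:, j] = np.einsum("ij,ji->i", diff, sol)
        # deterministic tie-break: higher prior, then lexicographic name
        tie_rank = sorted(
            range(len(competitors)),
            key=lambda j: (-db.stats[competitors[j].name].prior,
                           competitors[j].name),
        )
        d2_ranked = d2[:, tie_rank]
        best_ranked = np.argmin(d2_ranked, axis=1)
        best = np.asarray(tie_rank)[best_ranked]
        best_d2 = d2[np.arange(idx.size), best]
        outside = best_d2 > gate_threshold(len(midx))
        novel_idx = idx[outside]
        novelty[novel_idx] = True
        label[novel_idx] = node.unclassified_name
        counts[node.unclassified_name] = counts.get(node.unclassified_name, 0) + novel_idx.size
        counts.setdefault(node.unclassified_name, 0)
        for j, child in enumerate(competitors):
            descend(child, idx[(best == j) & ~outside])
        for child in real:
            if child not in competitors:
                for d in child.walk():
                    counts.setdefault(d.name, 0)

    all_idx = np.arange(n)
    root = tax.root
    if not db.has(root.name):
        raise ConfigurationError("empty database at level 'leukocytes'")
    midx = [col[m] for m in root.child_markers] if root.child_markers else list(col.values())
    mu, cov = db.stats[root.name].submatrix(midx)
    cov = cov + 1e-9 * np.eye(len(midx))
    diff = x[:, midx] - mu
    d2 = np.einsum("ij,ji->i", diff, np.linalg.solve(cov, diff.T))
    in_root = d2 <= gate_threshold(len(midx))
    pre = all_idx[~in_root]
    label[pre] = UNCLASSIFIED_PREFIX + "total"
    novelty[pre] = True
    counts[UNCLASSIFIED_PREFIX + "total"] = pre.size
    descend(root, all_idx[in_root])

    for node in tax.nodes():
        if node.alias_of is not None:
            counts[node.name] = counts.get(node.alias_of, 0)

    gating = GatingResult(labels=label, counts=counts, taxonomy=tax, n_events=n)
    suppressed = tuple(
        sorted(
            name
            for name in counts
            if not name.startswith(UNCLASSIFIED_PREFIX)
            and counts[name] < min_cluster
        )
    )
    return AutoGateResult(
        gating=gating, suppressed=suppressed, novelty=novelty, min_cluster=min_cluster
    )


def compare_analyses(
    a: GatingResult | Sequence[GatingResult],
    b: GatingResult | Sequence[GatingResult],
    config: AgreementConfig = AgreementConfig(),
    populations: Sequence[str] | None = None,
) -> AgreementReport:
    """Agreement between two gating analyses (or paired lists of analyses)
    on per-population percentages of parent."""
    a_list = [a] if isinstance(a, GatingResult) else list(a)
    b_list = [b] if isinstance(b, GatingResult) else list(b)
    if len(a_list) != len(b_list):
        raise ValidationError("paired analysis lists must have equal length")
    tax = a_list[0].taxonomy
    for r in a_list + b_list:
        if r.taxonomy.version != tax.version:
            raise ValidationError("taxonomy mismatch between analyses")
    pops = (
        list(populations)
        if populations is not None
        else tax.reportable_populations()
    )

    def pct_parent(result: GatingResult, pop: str) -> float:
        node = result.taxonomy.node(pop)
        if node.alias_of:
            node = result.taxonomy.node(node.alias_of)
        ev = result.count(node.name)
        pn = result.count(node.parent.name) if node.parent else result.n_events
        return 100.0 * ev / pn if pn else np.nan

    pairs = {}
    for pop in pops:
        av = np.array([pct_parent(r, pop) for r in a_list])
        bv = np.array([pct_parent(r, pop) for r in b_list])
        ok = ~(np.isnan(av) | np.isnan(bv))
        pairs[pop] = (av[ok], bv[ok])
    return agreement(pairs, config)
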