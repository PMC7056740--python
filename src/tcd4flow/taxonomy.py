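"""The hierarchical CD4 T-cell gating taxonomy and event classifier.

The default tree gates leukocytes -> lymphocytes -> T cells -> CD4 T cells
and then splits three major branches in sequence: Tregs (CD25hi CD127-/lo),
TFH (CD185+ among non-Tregs), and classical Th (CD185-/lo among non-Tregs).
Each branch carries a naive population, receptor-defined memory subsets
(Th1, Th2, Th17, Th1/Th17, Th22, two additional receptor codes, and an
other-memory catch-all), and CM/TM/EM/TE maturation stages within every
memory subset.  Treg-like TFH cells (CD25hi CD127-/lo CD185+) live inside
the Treg branch and are mirrored as a non-counted alias under TFH.

Children at every node are evaluated in declared order; events failing all
sibling rules fall into that level's explicitly reported unclassified bin,
so sibling populations plus the bin always partition the parent exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .fcs_io import FlowSample
from .panel import (
    CHEMOKINE_RECEPTORS,
    MATURATION_MARKERS,
    Level,
    PhenotypeCode,
    ThresholdSet,
    discretize_matrix,
)

__all__ = [
    "PopulationNode",
    "Taxonomy",
    "GatingResult",
    "build_taxonomy",
    "classify_events",
    "summarize",
    "UNCLASSIFIED_PREFIX",
]

UNCLASSIFIED_PREFIX = "unclassified:"

#: Receptor codes for memory T-helper subsets (and their Th-like analogues
#: in the Treg and TFH branches).
RECEPTOR_SUBSET_CODES: dict[str, dict[str, str]] = {
    "th1": {"CD183": "+", "CD194": "-", "CD196": "-", "CCR10": "-"},
    "th2": {"CD183": "-", "CD194": "+", "CD196": "-", "CCR10": "-"},
    "th17": {"CD183": "-", "CD194": "+", "CD196": "+", "CCR10": "-"},
    "th1_th17": {"CD183": "+", "CD194": "-", "CD196": "+", "CCR10": "-"},
    "th22": {"CD183": "-", "CD194": "+", "CD196": "+", "CCR10": "+"},
    "cxcr3_ccr4": {"CD183": "+", "CD194": "+", "CD196": "-", "CCR10": "-"},
    "ccr4_ccr10": {"CD183": "-", "CD194": "+", "CD196": "-", "CCR10": "+"},
}

#: Maturation stage codes on CD27 / CD45RA / CD62L.
STAGE_CODES: dict[str, dict[str, str]] = {
    "cm": {"CD27": "+", "CD45RA": "-", "CD62L": "+"},
    "tm": {"CD27": "+", "CD45RA": "-", "CD62L": "-"},
    "em": {"CD27": "-", "CD45RA": "-", "CD62L": "any"},
    "te": {"CD27": "-", "CD45RA": "+", "CD62L": "-"},
}

NAIVE_CODE: dict[str, str] = {
    "CD27": "+",
    "CD45RA": "+",
    "CD62L": "+",
    "CD183": "-",
    "CD194": "-",
    "CD196": "-",
    "CCR10": "-",
}


@dataclass
class PopulationNode:
    """One population in the gating tree.

    ``rule`` is a PhenotypeCode applied relative to the parent; a
    ``fallback`` node matches whatever its ordered siblings did not.
    ``alias_of`` marks virtual mirror nodes that report another node's
    events and never count as distinct populations.
    """

    name: str
    rule: PhenotypeCode = field(default_factory=PhenotypeCode)
    lineage: str = "pre-gate"
    stage: str | None = None
    reportable: bool = True
    fallback: bool = False
    alias_of: str | None = None
    child_markers: tuple[str, ...] = ()
    parent: "PopulationNode | None" = field(default=None, repr=False)
    children: list["PopulationNode"] = field(default_factory=list, repr=False)

    def add(self, node: "PopulationNode") -> "PopulationNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def unclassified_name(self) -> str:
        return UNCLASSIFIED_PREFIX + self.name

    def walk(self) -> Iterator["PopulationNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Taxonomy:
    """Rooted gating tree."""

    root: PopulationNode
    version: str = "tcd4-default-1"

    def __post_init__(self) -> None:
        names = [n.name for n in self.root.walk()]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate population names: {dup}")
        self._index = {n.name: n for n in self.root.walk()}

    def node(self, name: str) -> PopulationNode:
        if name not in self._index:
            raise ConfigurationError(f"unknown population {name!r}")
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def nodes(self) -> list[PopulationNode]:
        return list(self.root.walk())

    def reportable_populations(self) -> list[str]:
        """Distinct reportable populations (aliases excluded)."""
        return [
            n.name
            for n in self.root.walk()
            if n.reportable and n.alias_of is None
        ]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.walk() if not n.children and n.alias_of is None]

    def markers_used(self) -> set[str]:
        used: set[str] = set()
        for n in self.root.walk():
            used.update(n.rule)
        return used

    def to_json(self) -> str:
        def encode(node: PopulationNode) -> dict:
            return {
                "name": node.name,
                "rule": node.rule.to_jsonable(),
                "lineage": node.lineage,
                "stage": node.stage,
                "reportable": node.reportable,
                "fallback": node.fallback,
                "alias_of": node.alias_of,
                "child_markers": list(node.child_markers),
                "children": [encode(c) for c in node.children],
            }

        return json.dumps({"version": self.version, "root": encode(self.root)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Taxonomy":
        raw = json.loads(text)

        def decode(d: dict) -> PopulationNode:
            node = PopulationNode(
                name=d["name"],
                rule=PhenotypeCode.from_jsonable(d["rule"]),
                lineage=d["lineage"],
                stage=d.get("stage"),
                reportable=d["reportable"],
                fallback=d.get("fallback", False),
                alias_of=d.get("alias_of"),
                child_markers=tuple(d.get("child_markers", ())),
            )
            for c in d.get("children", []):
                node.add(decode(c))
            return node

        return cls(root=decode(raw["root"]), version=raw.get("version", "?"))


# ---------------------------------------------------------------------------
# Tree construction


def _add_stages(subset: PopulationNode, lineage: str) -> None:
    subset.child_markers = MATURATION_MARKERS
    for stage, code in STAGE_CODES.items():
        subset.add(
            PopulationNode(
                name=f"{subset.name}/{stage}",
                rule=PhenotypeCode(code),
                lineage=lineage,
                stage=stage.upper(),
            )
        )


def _add_branch_interior(branch: PopulationNode, lineage: str) -> None:
    """naive + receptor-defined memory subsets + other-memory, with stages."""
    branch.add(
        PopulationNode(
            name=f"{branch.name}/naive",
            rule=PhenotypeCode(NAIVE_CODE),
            lineage=lineage,
            stage="N",
        )
    )
    for subset, code in RECEPTOR_SUBSET_CODES.items():
        node = branch.add(
            PopulationNode(
                name=f"{branch.name}/{subset}",
                rule=PhenotypeCode(code),
                lineage=lineage,
            )
        )
        _add_stages(node, lineage)
    other = branch.add(
        PopulationNode(
            name=f"{branch.name}/other_memory",
            rule=PhenotypeCode(),
            lineage=lineage,
            fallback=True,
        )
    )
    _add_stages(other, lineage)


def build_taxonomy(
    include_scm: bool = False,
    extended: bool = False,
    version: str = "tcd4-default-1",
) -> Taxonomy:
    """Build the default gating tree (>= 89 reportable CD4 populations).

    ``include_scm`` adds a stem-cell-memory-like split (CD183lo and/or
    CD194lo naive profile) under classical-Th naive cells.  ``extended``
    reserves the deeper Treg/TFH stage splits; the default tree already
    carries them, so the flag currently only tags the version string.
    """
    root = PopulationNode(
        name="leukocytes",
        rule=PhenotypeCode({"CD45": frozenset({Level.LO, Level.POS, Level.HI})}),
        reportable=False,
        child_markers=("CD45", "SSC-A"),
    )
    lymph = root.add(
        PopulationNode(
            name="lymphocytes",
            rule=PhenotypeCode({"CD45": "hi", "SSC-A": "-"}),
            reportable=False,
            child_markers=("CD3", "CD4"),
        )
    )
    tcells = lymph.add(
        PopulationNode(
            name="t_cells",
            rule=PhenotypeCode({"CD3": "+"}),
            reportable=False,
            child_markers=("CD3", "CD4"),
        )
    )
    cd4 = tcells.add(
        PopulationNode(
            name="cd4_t",
            rule=PhenotypeCode({"CD4": "+"}),
            lineage="CD4T",
            child_markers=("CD25", "CD127", "CD185"),
        )
    )

    # order matters: Treg gate first, then TFH among non-Treg, then classical
    # the naive/other-memory split is invisible to the receptors alone, so
    # branch-level discrimination also sees the maturation markers
    branch_markers = CHEMOKINE_RECEPTORS + MATURATION_MARKERS
    treg = cd4.add(
        PopulationNode(
            name="treg",
            rule=PhenotypeCode({"CD25": "hi", "CD127": "-/lo"}),
            lineage="Treg",
            child_markers=branch_markers + ("CD185",),
        )
    )
    tfh = cd4.add(
        PopulationNode(
            name="tfh",
            rule=PhenotypeCode({"CD185": "+"}),
            lineage="TFH",
            child_markers=branch_markers,
        )
    )
    classical = cd4.add(
        PopulationNode(
            name="classical_th",
            rule=PhenotypeCode({"CD185": "-/lo"}),
            lineage="classicalTh",
            child_markers=branch_markers,
        )
    )

    # Treg-like TFH sits inside the Treg branch (evaluated first) ...
    treg.add(
        PopulationNode(
            name="treg/treg_like_tfh",
            rule=PhenotypeCode({"CD185": "+"}),
            lineage="Treg",
        )
    )
    _add_branch_interior(treg, "Treg")
    _add_branch_interior(tfh, "TFH")
    _add_branch_interior(classical, "classicalTh")

    # ... and is mirrored as a virtual, non-counted alias under TFH
    tfh.add(
        PopulationNode(
            name="tfh/treg_like_tfh_alias",
            rule=PhenotypeCode(),
            lineage="TFH",
            reportable=False,
            alias_of="treg/treg_like_tfh",
        )
    )

    if include_scm:
        naive = None
        for child in classical.children:
            if child.name == "classical_th/naive":
                naive = child
        naive.child_markers = ("CD183", "CD194")
        naive.add(
            PopulationNode(
                name="classical_th/naive/scm_like",
                rule=PhenotypeCode({"CD183": "lo"}),
                lineage="classicalTh",
            )
        )
        naive.add(
            PopulationNode(
                name="classical_th/naive/scm_like_ccr4",
                rule=PhenotypeCode({"CD194": "lo"}),
                lineage="classicalTh",
            )
        )
        naive.add(
            PopulationNode(
                name="classical_th/naive/conventional",
                rule=PhenotypeCode(),
                lineage="classicalTh",
                fallback=True,
            )
        )

    tax = Taxonomy(root=root, version=version + ("-ext" if extended else ""))
    n = len(tax.reportable_populations())
    if n < 89:
        raise ValidationError(
            f"default taxonomy must enumerate >= 89 reportable populations, got {n}"
        )
    return tax


# ---------------------------------------------------------------------------
# Classification


@dataclass
class GatingResult:
    """Per-event labels plus hierarchical counts for one sample."""

    labels: np.ndarray  # per-event leaf or unclassified label
    counts: dict[str, int]  # population (incl. unclassified bins) -> events
    taxonomy: Taxonomy
    n_events: int

    def count(self, name: str) -> int:
        return self.counts.get(name, 0)

    def subtree_count(self, name: str) -> int:
        return self.counts.get(name, 0)

    def to_frame(self, leukocyte_conc: float | None = None) -> pd.DataFrame:
        return summarize(self, leukocyte_conc=leukocyte_conc)

    def to_label_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"event": np.arange(self.n_events), "label": self.labels})


def _alias_labels(label: np.ndarray, taxonomy: Taxonomy) -> None:
    # aliases never receive events directly; nothing to rewrite
    return


def classify_events(
    sample: FlowSample,
    thresholds: ThresholdSet,
    taxonomy: Taxonomy,
) -> GatingResult:
    """Assign every event to exactly one leaf (or unclassified bin).

    Events are pushed root-to-leaf; at each node the children's phenotype
    rules are evaluated in declared order on the event's discretized levels,
    a ``fallback`` child receives whatever its siblings rejected, and events
    failing every sibling land in the node's unclassified bin.
    """
    if sample.transform_state != "transformed":
        raise ValidationError("classify_events requires a transformed sample")
    markers_needed = taxonomy.markers_used()
    missing = sorted(m for m in markers_needed if m not in thresholds.cutpoints)
    if missing:
        raise ConfigurationError(
            f"thresholds missing markers used by the taxonomy: {missing}"
        )
    labels_in_sample = set(sample.channel_labels)
    absent = sorted(m for m in markers_needed if m not in labels_in_sample)
    if absent:
        raise ConfigurationError(
            f"sample is missing taxonomy markers: {absent}"
        )

    levels = discretize_matrix(
        sample.events, list(sample.channel_labels), thresholds,
        markers=sorted(markers_needed),
    )
    n = sample.n_events
    label = np.empty(n, dtype=object)
    counts: dict[str, int] = {}

    def rule_mask(rule: PhenotypeCode, idx: np.ndarray) -> np.ndarray:
        mask = np.ones(idx.size, dtype=bool)
        for marker, allowed in rule.items():
            lv = levels[marker][idx]
            allowed_codes = np.array(sorted(int(a) for a in allowed), dtype=np.int8)
            mask &= np.isin(lv, allowed_codes)
        return mask

    def descend(node: PopulationNode, idx: np.ndarray) -> None:
        counts[node.name] = counts.get(node.name, 0) + idx.size
        real_children = [c for c in node.children if c.alias_of is None]
        if not real_children:
            label[idx] = node.name
            return
        remaining = idx
        fallback_child = None
        for child in real_children:
            if child.fallback:
                fallback_child = child
                continue
            m = rule_mask(child.rule, remaining)
            chosen = remaining[m]
            remaining = remaining[~m]
            if chosen.size:
                descend(child, chosen)
            else:
                counts.setdefault(child.name, 0)
                for d in child.walk():
                    counts.setdefault(d.name, 0)
        if fallback_child is not None:
            if remaining.size:
                descend(fallback_child, remaining)
            else:
                for d in fallback_child.walk():
                    counts.setdefault(d.name, 0)
            remaining = np.empty(0, dtype=int)
        counts[node.unclassified_name] = counts.get(node.unclassified_name, 0) + remaining.size
        label[remaining] = node.unclassified_name

    all_idx = np.arange(n)
    root = taxonomy.root
    root_match = rule_mask(root.rule, all_idx)
    pre_root = all_idx[~root_match]
    label[pre_root] = UNCLASSIFIED_PREFIX + "total"
    counts[UNCLASSIFIED_PREFIX + "total"] = pre_root.size
    descend(root, all_idx[root_match])

    # mirror alias counts for reporting
    for node in taxonomy.nodes():
        if node.alias_of is not None:
            counts[node.name] = counts.get(node.alias_of, 0)

    return GatingResult(labels=label, counts=counts, taxonomy=taxonomy, n_events=n)


def summarize(
    result: GatingResult,
    leukocyte_conc: float | None = None,
) -> pd.DataFrame:
    """Tidy per-population table: events, % of parent, % of CD4 T cells,
    and absolute counts when a leukocyte concentration (cells/uL) is given.

    Absolute count = population events / leukocyte events x concentration.
    """
    if leukocyte_conc is not None and leukocyte_conc <= 0:
        raise ValidationError("leukocyte concentration must be positive")
    tax = result.taxonomy
    rows = []
    leuko = result.count("leukocytes")
    cd4 = result.count("cd4_t") if "cd4_t" in tax else None

    def emit(name: str, parent: str | None, reportable: bool, alias_of=None):
        ev = result.count(name)
        pn = result.count(parent) if parent else None
        pct_parent = (100.0 * ev / pn) if pn else math.nan
        pct_cd4 = (100.0 * ev / cd4) if cd4 else math.nan
        absc = (ev / leuko * leukocyte_conc) if (leukocyte_conc and leuko) else math.nan
        rows.append(
            {
                "population": name,
                "parent": parent,
                "events": ev,
                "pct_parent": pct_parent,
                "pct_cd4": pct_cd4,
                "abs_count": absc,
                "reportable": reportable,
                "alias_of": alias_of,
            }
        )

    for node in tax.nodes():
        parent = node.parent.name if node.parent else None
        emit(node.name, parent, node.reportable, node.alias_of)
        if node.children and any(c.alias_of is None for c in node.children):
            emit(node.unclassified_name, node.name, False)
    emit(UNCLASSIFIED_PREFIX + "total", None, False)
    df = pd.DataFrame(rows)
    if result.n_events == 0:
        df["pct_parent"] = math.nan
        df["pct_cd4"] = math.nan
        df.attrs["empty_sample"] = True
    return df
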