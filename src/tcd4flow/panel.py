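"""The 14-marker TCD4 panel, per-marker discretization thresholds, and
discrete phenotype codes.

A :class:`PhenotypeCode` maps marker names to *sets* of admissible
:class:`Level` values, which is how shorthand such as ``CD127-/lo`` (the set
``{neg, lo}``) or ``CD62L±`` (any level) is modeled.  Discretization follows
a documented tie-break: a value exactly at a cutpoint belongs to the upper
level.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Level",
    "Marker",
    "Panel",
    "PhenotypeCode",
    "ThresholdSet",
    "default_tcd4_panel",
    "fit_thresholds",
    "discretize",
    "discretize_matrix",
    "parse_level_spec",
    "FLUOROCHROME_MARKERS",
    "SCATTER_CHANNELS",
    "MATURATION_MARKERS",
    "CHEMOKINE_RECEPTORS",
]


class Level(enum.IntEnum):
    """Ordered discrete expression level: neg < lo < pos < hi."""

    NEG = 0
    LO = 1
    POS = 2
    HI = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


ALL_LEVELS = frozenset(Level)

#: Levels produced by k cutpoints (k = 1, 2, 3).
_LEVEL_SEQUENCES = {
    1: (Level.NEG, Level.POS),
    2: (Level.NEG, Level.LO, Level.POS),
    3: (Level.NEG, Level.LO, Level.POS, Level.HI),
}

# Canonical channel order of the 14-fluorochrome tube (stain positions).
FLUOROCHROME_MARKERS: tuple[str, ...] = (
    "CD27",
    "CD45RA",
    "cyCD154",
    "CD62L",
    "CD127",
    "CD3",
    "CD25",
    "CCR10",
    "CD183",
    "CD196",
    "CD194",
    "CD185",
    "CD45",
    "CD4",
)

SCATTER_CHANNELS: tuple[str, ...] = ("FSC-A", "SSC-A")

MATURATION_MARKERS: tuple[str, ...] = ("CD27", "CD45RA", "CD62L")

CHEMOKINE_RECEPTORS: tuple[str, ...] = ("CD183", "CD194", "CD196", "CCR10")


@dataclass(frozen=True)
class Marker:
    """A stain with its detector channel mapping."""

    name: str
    channel: str


@dataclass(frozen=True)
class Panel:
    """An ordered marker panel (scatter channels first, then fluorochromes)."""

    markers: tuple[Marker, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    @property
    def fluorescence_names(self) -> tuple[str, ...]:
        return tuple(
            m.name for m in self.markers if m.name not in SCATTER_CHANNELS
        )

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def channel_of(self, marker: str) -> str:
        for m in self.markers:
            if m.name == marker:
                return m.channel
        raise ConfigurationError(f"marker {marker!r} not in panel")

    def to_json(self) -> str:
        return json.dumps(
            [{"name": m.name, "channel": m.channel} for m in self.markers],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Panel":
        raw = json.loads(text)
        return cls(tuple(Marker(d["name"], d["channel"]) for d in raw))


def default_tcd4_panel() -> Panel:
    """The default TCD4 tube: FSC/SSC plus 14 fluorescence markers in
    canonical stain order."""
    markers = [Marker(n, n) for n in SCATTER_CHANNELS]
    for i, name in enumerate(FLUOROCHROME_MARKERS, start=1):
        markers.append(Marker(name, f"FL{i}-A"))
    return Panel(tuple(markers))


# ---------------------------------------------------------------------------
# Phenotype codes


def parse_level_spec(spec: str) -> frozenset[Level]:
    """Parse shorthand level notation into a level set.

    ``"+"`` -> {pos, hi} and ``"-"`` -> {neg, lo}: positivity in gating
    practice means at-or-above the positivity cut, so its complement
    includes dim events.  ``"lo"`` -> {lo}; ``"hi"`` -> {hi}; ``"neg"`` ->
    {neg} (strict); ``"-/lo"`` -> {neg, lo}; ``"+/hi"`` -> {pos, hi};
    ``"any"`` / ``"+-"`` / ``"±"`` -> all levels.
    """
    key = spec.strip().lower()
    table = {
        "+": frozenset({Level.POS, Level.HI}),
        "pos": frozenset({Level.POS, Level.HI}),
        "-": frozenset({Level.NEG, Level.LO}),
        "neg": frozenset({Level.NEG}),
        "lo": frozenset({Level.LO}),
        "hi": frozenset({Level.HI}),
        "-/lo": frozenset({Level.NEG, Level.LO}),
        "neg/lo": frozenset({Level.NEG, Level.LO}),
        "+/hi": frozenset({Level.POS, Level.HI}),
        "any": ALL_LEVELS,
        "+-": ALL_LEVELS,
        "±": ALL_LEVELS,
    }
    if key not in table:
        raise ValidationError(f"unknown level spec {spec!r}")
    return table[key]


class PhenotypeCode(dict):
    """Mapping marker name -> frozenset of admissible Levels.

    Markers omitted from the mapping match any level.
    """

    def __init__(self, mapping: Mapping[str, Iterable[Level] | str] = ()):
        super().__init__()
        for marker, levels in dict(mapping).items():
            if isinstance(levels, str):
                levels = parse_level_spec(levels)
            self[marker] = frozenset(Level(l) for l in levels)

    def matches(self, levels: Mapping[str, Level]) -> bool:
        return all(
            marker in levels and levels[marker] in allowed
            for marker, allowed in self.items()
        )

    def validate_markers(self, panel: Panel) -> None:
        unknown = [m for m in self if m not in panel]
        if unknown:
            raise ConfigurationError(
                f"phenotype code references markers outside the panel: {unknown}"
            )

    def to_jsonable(self) -> dict:
        return {m: sorted(l.name.lower() for l in s) for m, s in self.items()}

    @classmethod
    def from_jsonable(cls, raw: Mapping[str, Sequence[str]]) -> "PhenotypeCode":
        return cls(
            {m: frozenset(Level[l.upper()] for l in ls) for m, ls in raw.items()}
        )


# ---------------------------------------------------------------------------
# Thresholds


@dataclass
class ThresholdSet:
    """Per-marker cutpoints (1-3, strictly increasing) in transformed units.

    k cutpoints partition a marker axis into the first k+1 levels of
    neg | lo | pos | hi. Values exactly at a cutpoint take the upper level.
    """

    cutpoints: dict[str, np.ndarray]
    provenance: str = "manual"

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for marker, cuts in self.cutpoints.items():
            arr = np.asarray(cuts, dtype=float).ravel()
            if arr.size < 1 or arr.size > 3:
                raise ValidationError(
                    f"{marker}: need 1-3 cutpoints, got {arr.size}"
                )
            if not np.all(np.diff(arr) > 0):
                raise ValidationError(
                    f"{marker}: cutpoints must be strictly increasing"
                )
            clean[marker] = arr
        self.cutpoints = clean

    def markers(self) -> tuple[str, ...]:
        return tuple(self.cutpoints)

    def levels_for(self, marker: str, values: np.ndarray) -> np.ndarray:
        """Vectorized level assignment for one marker (returns int codes)."""
        if marker not in self.cutpoints:
            raise ConfigurationError(f"no thresholds for marker {marker!r}")
        cuts = self.cutpoints[marker]
        seq = _LEVEL_SEQUENCES[cuts.size]
        idx = np.searchsorted(cuts, np.asarray(values, dtype=float), side="right")
        table = np.array([int(l) for l in seq], dtype=np.int8)
        return table[idx]

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "cutpoints": {m: list(map(float, c)) for m, c in self.cutpoints.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSet":
        raw = json.loads(text)
        return cls(
            cutpoints={m: np.asarray(c, float) for m, c in raw["cutpoints"].items()},
            provenance=raw.get("provenance", "manual"),
        )


def discretize(
    event: Mapping[str, float] | np.ndarray,
    thresholds: ThresholdSet,
    marker_order: Sequence[str] | None = None,
) -> dict[str, Level]:
    """Discretize a single event into a marker -> Level mapping.

    ``event`` is either a mapping marker->value or a vector aligned with
    ``marker_order``.
    """
    if isinstance(event, Mapping):
        items = dict(event)
    else:
        if marker_order is None:
            raise ValidationError("vector events require marker_order")
        items = dict(zip(marker_order, np.asarray(event, float)))
    out: dict[str, Level] = {}
    for marker, value in items.items():
        code = thresholds.levels_for(marker, np.asarray([value]))[0]
        out[marker] = Level(int(code))
    return out


def discretize_matrix(
    events: np.ndarray,
    marker_order: Sequence[str],
    thresholds: ThresholdSet,
    markers: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Discretize a full event matrix; returns marker -> int8 level codes."""
    col = {m: i for i, m in enumerate(marker_order)}
    use = markers if markers is not None else marker_order
    out = {}
    for marker in use:
        if marker not in col:
            raise ConfigurationError(f"marker {marker!r} not in event matrix")
        out[marker] = thresholds.levels_for(marker, events[:, col[marker]])
    return out


# ---------------------------------------------------------------------------
# Threshold fitting


def _valley_cutpoint(values: np.ndarray) -> float | None:
    """Minimum of a KDE between the two largest modes; None if unimodal."""
    from scipy.stats import gaussian_kde

    v = np.asarray(values, float)
    if np.ptp(v) == 0:
        return None
    kde = gaussian_kde(v)
    grid = np.linspace(v.min(), v.max(), 512)
    dens = kde(grid)
    # local maxima (interior)
    is_max = np.r_[False, (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]), False]
    peaks = np.flatnonzero(is_max)
    if peaks.size < 2:
        return None
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])


def fit_thresholds(
    sample,
    panel: Panel,
    strategy: str = "valley",
    quantiles: Sequence[float] = (0.5,),
    anchor_offsets: Sequence[float] = (3.0,),
    anchor_reference_marker: str = "CD3",
) -> ThresholdSet:
    """Fit per-marker cutpoints on a transformed sample.

    Strategies:

    ``valley``
        one cutpoint at the KDE minimum between the two largest modes;
        unimodal channels fall back to ``quantile`` with a warning.
    ``quantile``
        cutpoints at the configured quantiles of each marker.
    ``anchored``
        cutpoints at mean + k*SD of an internal negative reference
        population (events negative for ``anchor_reference_marker`` under a
        median split).
    ``generator-truth``
        pass through the thresholds recorded by the simulator in the
        sample metadata.
    """
    from .fcs_io import FlowSample  # local import to avoid a cycle

    if not isinstance(sample, FlowSample):
        raise ValidationError("fit_thresholds expects a FlowSample")
    if strategy == "generator-truth":
        raw = sample.metadata.get("TCD4_TRUTH_THRESHOLDS")
        if raw is None:
            raise ConfigurationError(
                "sample carries no generator-truth thresholds"
            )
        ts = ThresholdSet.from_json(raw)
        ts.provenance = "generator-truth"
        return ts
    if sample.transform_state != "transformed":
        raise ValidationError("sample must be transformed before fitting")
    if sample.events.shape[0] < 500:
        raise ValidationError("need >= 500 events to fit thresholds")

    names = [c.marker or c.short_name for c in sample.channels]
    col = {n: i for i, n in enumerate(names)}
    cut: dict[str, np.ndarray] = {}
    fluor = set(panel.fluorescence_names)

    if strategy == "anchored":
        ref_col = col.get(anchor_reference_marker)
        if ref_col is None:
            raise ConfigurationError(
                f"anchor marker {anchor_reference_marker!r} not in sample"
            )
        ref_vals = sample.events[:, ref_col]
        neg_mask = ref_vals <= np.median(ref_vals)

    for marker in panel.names:
        if marker not in col:
            raise ConfigurationError(f"panel marker {marker!r} not in sample")
        values = sample.events[:, col[marker]]
        if np.ptp(values) == 0:
            warnings.warn(
                f"{marker}: constant channel, falling back to quantile",
                stacklevel=2,
            )
            cut[marker] = np.asarray([float(values[0])])
            continue
        if strategy == "valley" and marker in fluor:
            point = _valley_cutpoint(values)
            if point is None:
                warnings.warn(
                    f"{marker}: unimodal under 'valley', falling back to quantile",
                    stacklevel=2,
                )
                cut[marker] = np.quantile(values, quantiles)
            else:
                cut[marker] = np.asarray([point])
        elif strategy in ("quantile", "valley"):
            cut[marker] = np.quantile(values, quantiles)
        elif strategy == "anchored":
            base = sample.events[neg_mask, col[marker]]
            mu, sd = float(np.mean(base)), float(np.std(base))
            cut[marker] = np.asarray([mu + k * sd for k in anchor_offsets])
        else:
            raise ValidationError(f"unknown strategy {strategy!r}")
    return ThresholdSet(cutpoints=cut, provenance="fitted")
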