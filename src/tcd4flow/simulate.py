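"""Synthetic whole-blood sample generator with ground-truth labels.

Every pipeline stage is testable offline: populations are drawn as
independent per-marker Gaussians around discrete level anchors in
transformed space, inverse-transformed to raw intensities, and emitted as a
regular :class:`~tcd4flow.fcs_io.FlowSample` together with per-event truth
labels, the generating spec, and the generator's own thresholds.

Level anchors default to neg=0.3, lo=1.0, pos=2.2, hi=3.2 (logicle-like
display units) with SD 0.25; these are invented, documented, and
configurable - the goal is exercising the machinery, not mimicking donors.
Scatter channels are generated directly in (synthetic) linear units on the
same anchor scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .fcs_io import ChannelInfo, FlowSample, SpilloverMatrix, TransformSpec
from .panel import (
    FLUOROCHROME_MARKERS,
    SCATTER_CHANNELS,
    Level,
    ThresholdSet,
    default_tcd4_panel,
)
from .taxonomy import Taxonomy, build_taxonomy

__all__ = [
    "PopulationTemplate",
    "SampleSpec",
    "SyntheticSample",
    "LEVEL_ANCHORS",
    "TRUTH_CUTPOINTS",
    "AGE_BANDS",
    "default_templates",
    "generator_truth_thresholds",
    "simulate_sample",
    "simulate_cohort",
    "simulate_maturation_events",
    "canonical_maturation_events",
]

#: Transformed-space anchor per discrete level.
LEVEL_ANCHORS: dict[Level, float] = {
    Level.NEG: 0.3,
    Level.LO: 1.0,
    Level.POS: 2.2,
    Level.HI: 3.2,
}

#: Midpoints between anchors; the generator's own discretization truth.
TRUTH_CUTPOINTS: tuple[float, float, float] = (0.65, 1.6, 2.7)

DEFAULT_SD = 0.25

#: Age band labels shared with the reference-interval machinery.
AGE_BANDS: tuple[str, ...] = (
    "cb", "2mo-2y", "2-5y", "5-10y", "10-18y",
    "18-40y", "40-60y", "60-80y", "80+y",
)

#: Representative donor age (years) used when a spec gives none; cord blood
#: is tagged with age 0 plus a CB flag.
_BAND_AGE = {
    "cb": 0.0, "2mo-2y": 1.0, "2-5y": 3.5, "5-10y": 7.5, "10-18y": 14.0,
    "18-40y": 30.0, "40-60y": 50.0, "60-80y": 70.0, "80+y": 85.0,
}

ALL_MARKERS: tuple[str, ...] = SCATTER_CHANNELS + FLUOROCHROME_MARKERS


@dataclass(frozen=True)
class PopulationTemplate:
    """Phenotype template for one planted population."""

    name: str  # ground-truth name (taxonomy leaf for CD4 populations)
    expected_leaf: str  # label classify_events should produce
    levels: Mapping[str, Level]  # per-marker discrete level
    frequency: float  # fraction of total events
    sd: float = DEFAULT_SD

    def mean_vector(self) -> np.ndarray:
        return np.array(
            [LEVEL_ANCHORS[self.levels.get(m, Level.NEG)] for m in ALL_MARKERS]
        )


@dataclass(frozen=True)
class SampleSpec:
    """Deterministic recipe for one synthetic sample."""

    n_events: int
    templates: tuple[PopulationTemplate, ...]
    seed: int
    age_band: str = "18-40y"
    age_years: float | None = None
    leukocyte_conc: float = 6000.0  # cells/uL
    noise_scale: float = 1.0
    spillover_strength: float = 0.0
    sample_id: str = "synthetic"
    exact_counts: bool = False  # largest-remainder counts instead of multinomial

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")
        if self.seed is None:
            raise ValidationError("a seed is mandatory; no unseeded randomness")
        total = sum(t.frequency for t in self.templates)
        if total > 1.0 + 1e-9:
            raise ValidationError(f"template frequencies sum to {total:.4f} > 1")
        if any(t.sd <= 0 for t in self.templates):
            raise ValidationError("template SDs must be positive")

    def to_jsonable(self) -> dict:
        return {
            "n_events": self.n_events,
            "seed": self.seed,
            "age_band": self.age_band,
            "age_years": self.age_years,
            "leukocyte_conc": self.leukocyte_conc,
            "noise_scale": self.noise_scale,
            "spillover_strength": self.spillover_strength,
            "sample_id": self.sample_id,
            "exact_counts": self.exact_counts,
            "templates": [
                {
                    "name": t.name,
                    "expected_leaf": t.expected_leaf,
                    "levels": {m: int(l) for m, l in t.levels.items()},
                    "frequency": t.frequency,
                    "sd": t.sd,
                }
                for t in self.templates
            ],
        }


@dataclass
class SyntheticSample:
    """A raw-space FlowSample plus its generating truth."""

    sample: FlowSample
    labels: np.ndarray  # per-event ground-truth template name
    expected_leaves: np.ndarray  # per-event label the classifier should emit
    spec: SampleSpec
    truth_thresholds: ThresholdSet
    transform: TransformSpec
    planned_counts: dict[str, int]

    @property
    def n_events(self) -> int:
        return self.sample.n_events


def generator_truth_thresholds() -> ThresholdSet:
    cuts = {m: np.asarray(TRUTH_CUTPOINTS) for m in ALL_MARKERS}
    return ThresholdSet(cutpoints=cuts, provenance="generator-truth")


def default_transform() -> TransformSpec:
    """The simulator's fluorescence transform (exactly invertible)."""
    return TransformSpec(kind="asinh", parameters={"cofactor": 150.0})


# ---------------------------------------------------------------------------
# Template construction from the taxonomy


_L = Level


def _path_levels(taxonomy: Taxonomy, leaf: str) -> dict[str, Level]:
    """Representative per-marker level for a leaf, accumulated root-to-leaf.

    Constrained markers take the lowest admissible level of the
    intersected rule sets (so '+' -> pos, '-/lo' -> neg, 'hi' -> hi);
    unconstrained markers default to neg except CD127, which defaults to
    pos outside the Treg branch so non-Tregs never brush the Treg gate.
    """
    node = taxonomy.node(leaf)
    allowed: dict[str, frozenset[Level]] = {}
    chain = []
    while node is not None:
        chain.append(node)
        node = node.parent
    in_treg = any(n.name == "treg" for n in chain)
    for n in reversed(chain):
        for marker, levels in n.rule.items():
            allowed[marker] = allowed.get(marker, frozenset(Level)) & levels
    out: dict[str, Level] = {}
    for marker in ALL_MARKERS:
        if marker in allowed:
            if not allowed[marker]:
                raise ValidationError(f"{leaf}: contradictory rule on {marker}")
            out[marker] = min(allowed[marker])
        elif marker == "CD127" and not in_treg:
            out[marker] = _L.POS
        elif marker == "FSC-A":
            out[marker] = _L.POS
        else:
            out[marker] = _L.NEG
    return out


_FILLER_TEMPLATES: tuple[tuple[str, str, dict[str, Level]], ...] = (
    (
        "filler/non_t_lymphocyte",
        "unclassified:lymphocytes",
        {"FSC-A": _L.POS, "SSC-A": _L.NEG, "CD45": _L.HI},
    ),
    (
        "filler/cd4neg_t",
        "unclassified:t_cells",
        {"FSC-A": _L.POS, "SSC-A": _L.NEG, "CD45": _L.HI, "CD3": _L.POS,
         "CD127": _L.POS},
    ),
    (
        "filler/monocyte",
        "unclassified:leukocytes",
        {"FSC-A": _L.HI, "SSC-A": _L.LO, "CD45": _L.POS, "CD4": _L.LO},
    ),
    (
        "filler/granulocyte",
        "unclassified:leukocytes",
        {"FSC-A": _L.HI, "SSC-A": _L.POS, "CD45": _L.POS},
    ),
)

# per-band knobs: (lymph frac, cd4-of-leuko multiplier on lymph, treg share,
# tfh share, naive share, stage weights shift toward effector)
_BAND_PROFILE = {
    #        lymph  tregW  tfhW  naive  effector_shift
    "cb":     (0.55, 0.08, 0.010, 0.90, 0.0),
    "2mo-2y": (0.55, 0.09, 0.030, 0.80, 0.0),
    "2-5y":   (0.45, 0.07, 0.050, 0.70, 0.1),
    "5-10y":  (0.42, 0.06, 0.060, 0.60, 0.1),
    "10-18y": (0.38, 0.06, 0.080, 0.50, 0.2),
    "18-40y": (0.35, 0.06, 0.100, 0.45, 0.2),
    "40-60y": (0.33, 0.06, 0.110, 0.40, 0.3),
    "60-80y": (0.32, 0.06, 0.120, 0.35, 0.4),
    "80+y":   (0.30, 0.06, 0.120, 0.30, 0.5),
}

# memory receptor-subset weights (within the memory compartment)
_SUBSET_WEIGHTS = {
    "th1": 0.28, "th2": 0.18, "th17": 0.18, "th1_th17": 0.10,
    "th22": 0.08, "cxcr3_ccr4": 0.06, "ccr4_ccr10": 0.04, "other_memory": 0.08,
}
# cord blood: Th1/Th17 and Th22 are absent; Th1, Th17, novel codes near zero
_SUBSET_WEIGHTS_CB = {
    "th1": 0.02, "th2": 0.70, "th17": 0.02, "th1_th17": 0.0,
    "th22": 0.0, "cxcr3_ccr4": 0.01, "ccr4_ccr10": 0.0, "other_memory": 0.25,
}

_STAGE_WEIGHTS = {"cm": 0.40, "tm": 0.25, "em": 0.25, "te": 0.10}


def default_templates(
    age_band: str,
    taxonomy: Taxonomy | None = None,
    sd: float = DEFAULT_SD,
) -> tuple[PopulationTemplate, ...]:
    """Age-plausible templates for every default taxonomy leaf plus non-CD4
    filler populations.  Frequencies are illustrative, not donor values."""
    if age_band not in _BAND_PROFILE:
        raise ValidationError(
            f"unknown age band {age_band!r}; known bands: {sorted(_BAND_PROFILE)}"
        )
    tax = taxonomy if taxonomy is not None else build_taxonomy()
    lymph, treg_w, tfh_w, naive_share, shift = _BAND_PROFILE[age_band]
    cd4_frac = lymph * 0.7 * 0.6  # of leukocytes: T cells 70% of lymph, CD4 60% of T
    classical_w = 1.0 - treg_w - tfh_w
    subset_w = _SUBSET_WEIGHTS_CB if age_band == "cb" else _SUBSET_WEIGHTS
    stage_w = {
        "cm": _STAGE_WEIGHTS["cm"] * (1 - shift * 0.5),
        "tm": _STAGE_WEIGHTS["tm"],
        "em": _STAGE_WEIGHTS["em"] * (1 + shift * 0.5),
        "te": _STAGE_WEIGHTS["te"] * (1 + shift),
    }
    zs = sum(stage_w.values())
    stage_w = {k: v / zs for k, v in stage_w.items()}
    zsub = sum(subset_w.values())

    branch_w = {"treg": treg_w, "tfh": tfh_w, "classical_th": classical_w}
    treg_like_tfh_share = 0.0 if age_band == "cb" else 0.05

    templates: list[PopulationTemplate] = []
    for branch, bw in branch_w.items():
        base = cd4_frac * bw
        interior = base
        if branch == "treg" and treg_like_tfh_share > 0:
            leaf = "treg/treg_like_tfh"
            templates.append(
                PopulationTemplate(
                    name=leaf, expected_leaf=leaf,
                    levels=_path_levels(tax, leaf),
                    frequency=base * treg_like_tfh_share, sd=sd,
                )
            )
            interior = base * (1 - treg_like_tfh_share)
        leaf = f"{branch}/naive"
        templates.append(
            PopulationTemplate(
                name=leaf, expected_leaf=leaf,
                levels=_path_levels(tax, leaf),
                frequency=interior * naive_share, sd=sd,
            )
        )
        memory = interior * (1 - naive_share)
        for subset, sw in subset_w.items():
            for stage, stw in stage_w.items():
                freq = memory * sw / zsub * stw
                if freq <= 0:
                    continue
                leaf = f"{branch}/{subset}/{stage}"
                templates.append(
                    PopulationTemplate(
                        name=leaf, expected_leaf=leaf,
                        levels=_path_levels(tax, leaf),
                        frequency=freq, sd=sd,
                    )
                )

    cd8ish = lymph * 0.7 * 0.4
    non_t_lymph = lymph * 0.3
    mono = 0.08
    granulo = max(0.0, 1.0 - lymph - mono - 1e-9)
    filler_freq = {
        "filler/non_t_lymphocyte": non_t_lymph,
        "filler/cd4neg_t": cd8ish,
        "filler/monocyte": mono,
        "filler/granulocyte": granulo,
    }
    for name, expected, levels in _FILLER_TEMPLATES:
        templates.append(
            PopulationTemplate(
                name=name, expected_leaf=expected, levels=levels,
                frequency=filler_freq[name], sd=sd,
            )
        )
    total = sum(t.frequency for t in templates)
    if total > 1.0:  # numerical slack: renormalize
        templates = [replace(t, frequency=t.frequency / total) for t in templates]
    return tuple(templates)


# ---------------------------------------------------------------------------
# Sampling


def _largest_remainder_counts(freqs: np.ndarray, n: int) -> np.ndarray:
    raw = freqs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _synthetic_spillover(strength: float) -> SpilloverMatrix:
    n = len(FLUOROCHROME_MARKERS)
    m = np.eye(n)
    for i in range(n - 1):
        m[i, i + 1] = strength
        m[i + 1, i] = strength / 2
    panel = default_tcd4_panel()
    names = tuple(panel.channel_of(mk) for mk in FLUOROCHROME_MARKERS)
    return SpilloverMatrix(names, m)


def simulate_sample(spec: SampleSpec) -> SyntheticSample:
    """Draw one synthetic sample; same spec -> bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    panel = default_tcd4_panel()
    tf = default_transform()

    freqs = np.array([t.frequency for t in spec.templates])
    rest = 1.0 - freqs.sum()
    probs = np.append(freqs, max(rest, 0.0))
    probs = probs / probs.sum()
    if spec.exact_counts:
        counts = _largest_remainder_counts(probs, spec.n_events)
    else:
        counts = rng.multinomial(spec.n_events, probs)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    expected: list[np.ndarray] = []
    planned: dict[str, int] = {}
    n_mark = len(ALL_MARKERS)
    filler_rest = PopulationTemplate(
        name="filler/unmodeled",
        expected_leaf="unclassified:total",
        levels={"CD45": _L.NEG, "FSC-A": _L.NEG, "SSC-A": _L.NEG},
        frequency=0.0,
    )
    all_templates = list(spec.templates) + [filler_rest]
    for t, k in zip(all_templates, counts):
        planned[t.name] = int(k)
        if k == 0:
            continue
        mean = t.mean_vector()
        sd = t.sd * spec.noise_scale
        if sd > 0:
            ev = rng.normal(loc=mean, scale=sd, size=(k, n_mark))
        else:
            ev = np.tile(mean, (k, 1))
        blocks.append(ev)
        labels.append(np.repeat(t.name, k))
        expected.append(np.repeat(t.expected_leaf, k))

    events_t = np.vstack(blocks)
    label_arr = np.concatenate(labels)
    expected_arr = np.concatenate(expected)
    perm = rng.permutation(spec.n_events)
    events_t = events_t[perm]
    label_arr = label_arr[perm]
    expected_arr = expected_arr[perm]

    # transformed -> raw: fluorescence through the inverse transform,
    # scatter stays in linear units
    raw = events_t.copy()
    n_scatter = len(SCATTER_CHANNELS)
    raw[:, n_scatter:] = tf.inverse(events_t[:, n_scatter:])

    spill = None
    if spec.spillover_strength > 0:
        spill = _synthetic_spillover(spec.spillover_strength)
        # observed = S @ true (matches the compensation convention)
        raw[:, n_scatter:] = raw[:, n_scatter:] @ spill.matrix.T

    channels = [
        ChannelInfo(index=i + 1, short_name=m.channel, marker=m.name,
                    range=262144.0)
        for i, m in enumerate(panel.markers)
    ]
    truth = generator_truth_thresholds()
    age = spec.age_years if spec.age_years is not None else _BAND_AGE[spec.age_band]
    sample = FlowSample(
        channels=channels,
        events=raw,
        spillover=spill,
        transform_state="raw",
        metadata={
            "TCD4_SAMPLE_ID": spec.sample_id,
            "TCD4_AGE_BAND": spec.age_band,
            "TCD4_AGE_YEARS": repr(float(age)),
            "TCD4_LEUKO_CONC": repr(float(spec.leukocyte_conc)),
            "TCD4_TRUTH_THRESHOLDS": truth.to_json(),
            "TCD4_TRANSFORM_SPEC": json.dumps(tf.to_jsonable()),
        },
    )
    return SyntheticSample(
        sample=sample,
        labels=label_arr,
        expected_leaves=expected_arr,
        spec=spec,
        truth_thresholds=truth,
        transform=tf,
        planned_counts=planned,
    )


def prepare_for_gating(synth: SyntheticSample) -> FlowSample:
    """Compensate (when spillover was mixed in) and transform back into the
    generator's display space."""
    from .fcs_io import compensate, transform

    s = synth.sample
    if s.spillover is not None:
        s = compensate(s)
    fluor = [m for m in ALL_MARKERS if m not in SCATTER_CHANNELS]
    return transform(s, synth.transform, channels=fluor)


def simulate_cohort(
    age_distribution: Sequence[tuple[str, int]],
    base_seed: int,
    n_events: int = 20000,
    noise_scale: float = 1.0,
    conc_lognorm: tuple[float, float] = (8.7, 0.25),  # ln-space mean/sd, ~6000/uL
) -> list[SyntheticSample]:
    """Independent samples over age bands; per-sample seeds derive from
    base_seed + index and concentrations from a configured log-normal."""
    for band, n in age_distribution:
        if band not in _BAND_PROFILE:
            raise ValidationError(f"unknown age band {band!r}")
        if n < 1:
            raise ValidationError("n_samples must be >= 1 per band")
    out: list[SyntheticSample] = []
    idx = 0
    for band, n in age_distribution:
        for _ in range(n):
            seed = base_seed + idx
            rng = np.random.default_rng(seed * 7919 + 13)
            conc = float(np.exp(rng.normal(*conc_lognorm)))
            if band == "cb":
                age = 0.0
            else:
                lo, hi = _band_age_range(band)
                age = float(rng.uniform(lo, hi))
            spec = SampleSpec(
                n_events=n_events,
                templates=default_templates(band),
                seed=seed,
                age_band=band,
                age_years=age,
                leukocyte_conc=conc,
                noise_scale=noise_scale,
                sample_id=f"cohort-{idx:03d}",
            )
            out.append(simulate_sample(spec))
            idx += 1
    return out


def _band_age_range(band: str) -> tuple[float, float]:
    return {
        "2mo-2y": (0.167, 2.0), "2-5y": (2.0, 5.0), "5-10y": (5.0, 10.0),
        "10-18y": (10.0, 18.0), "18-40y": (18.0, 40.0),
        "40-60y": (40.0, 60.0), "60-80y": (60.0, 80.0), "80+y": (80.0, 95.0),
    }[band]


# ---------------------------------------------------------------------------
# Maturation-specific generators (transformed-space event matrices)


def simulate_maturation_events(
    n: int, seed: int, noise_sd: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Events on CD27/CD45RA/CD62L driven by a latent maturation coordinate.

    Returns (events[n,3], latent[n]); each marker decreases monotonically
    with the latent coordinate but with a different breakpoint, so the
    principal axis tracks the latent ordering.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    hi, lo = LEVEL_ANCHORS[_L.POS], LEVEL_ANCHORS[_L.NEG]
    span = hi - lo

    def ramp(x, start, width):
        return hi - span * np.clip((x - start) / width, 0.0, 1.0)

    cd45ra = ramp(u, 0.00, 0.30)
    cd62l = ramp(u, 0.25, 0.35)
    cd27 = ramp(u, 0.50, 0.50)
    ev = np.column_stack([cd27, cd45ra, cd62l])
    ev += rng.normal(0.0, noise_sd, size=ev.shape)
    return ev, u


#: canonical stage phenotypes on (CD27, CD45RA, CD62L)
CANONICAL_STAGE_LEVELS: dict[str, tuple[Level, Level, Level]] = {
    "N": (_L.POS, _L.POS, _L.POS),
    "CM": (_L.POS, _L.NEG, _L.POS),
    "TM": (_L.POS, _L.NEG, _L.NEG),
    "EM": (_L.NEG, _L.NEG, _L.NEG),
    "TE": (_L.NEG, _L.POS, _L.NEG),
}

#: frequencies chosen so 20 equal-count bins align with stage boundaries
CANONICAL_STAGE_FREQS: dict[str, float] = {
    "N": 0.35, "CM": 0.25, "TM": 0.15, "EM": 0.15, "TE": 0.10,
}


def canonical_maturation_events(
    n: int, seed: int, noise_sd: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical N/CM/TM/EM/TE blood on the three maturation markers.

    Returns (events[n,3], stage_labels[n]).  Counts are exact
    (largest-remainder), so equal-count staging at 20 bins never straddles
    a population boundary when n is a multiple of 20.
    """
    rng = np.random.default_rng(seed)
    names = list(CANONICAL_STAGE_FREQS)
    freqs = np.array([CANONICAL_STAGE_FREQS[s] for s in names])
    counts = _largest_remainder_counts(freqs, n)
    blocks, labels = [], []
    for name, k in zip(names, counts):
        if k == 0:
            continue
        mean = np.array([LEVEL_ANCHORS[l] for l in CANONICAL_STAGE_LEVELS[name]])
        blocks.append(rng.normal(mean, noise_sd, size=(k, 3)))
        labels.append(np.repeat(name, k))
    return np.vstack(blocks), np.concatenate(labels)
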