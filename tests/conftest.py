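"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import tcd4flow as t


@pytest.fixture(scope="session")
def taxonomy():
    return t.build_taxonomy()


@pytest.fixture(scope="session")
def truth_thresholds():
    return t.generator_truth_thresholds()


@pytest.fixture(scope="session")
def adult_templates():
    return t.default_templates("18-40y")


def _make_sample(templates, seed, n_events, noise_scale, **kw):
    spec = t.SampleSpec(
        n_events=n_events,
        templates=templates,
        seed=seed,
        noise_scale=noise_scale,
        **kw,
    )
    return t.simulate_sample(spec)


@pytest.fixture(scope="session")
def zero_noise_synth(adult_templates):
    return _make_sample(adult_templates, seed=101, n_events=10000, noise_scale=0.0)


@pytest.fixture(scope="session")
def noisy_synth(adult_templates):
    return _make_sample(adult_templates, seed=202, n_events=50000, noise_scale=1.0)


@pytest.fixture(scope="session")
def moderate_noise_synth(adult_templates):
    # SD = 25% of the smallest inter-level anchor gap (0.7 * 0.25 = 0.175)
    return _make_sample(adult_templates, seed=303, n_events=50000, noise_scale=0.7)


@pytest.fixture(scope="session")
def zero_noise_result(zero_noise_synth, truth_thresholds, taxonomy):
    sample = t.prepare_for_gating(zero_noise_synth)
    return t.classify_events(sample, truth_thresholds, taxonomy)


@pytest.fixture(scope="session")
def noisy_result(noisy_synth, truth_thresholds, taxonomy):
    sample = t.prepare_for_gating(noisy_synth)
    return t.classify_events(sample, truth_thresholds, taxonomy)


@pytest.fixture(scope="session")
def reference_db(taxonomy, adult_templates):
    """Database pooled from three simulated 'centers'."""
    labeled = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in (11, 12, 13):
            synth = _make_sample(
                adult_templates, seed=seed, n_events=50000, noise_scale=0.4,
                sample_id=f"center-{seed}",
            )
            labeled.append((t.prepare_for_gating(synth), synth.expected_leaves))
        return t.build_reference(labeled, taxonomy=taxonomy)


@pytest.fixture(scope="session")
def autogate_test_synth(adult_templates):
    return _make_sample(
        adult_templates, seed=14, n_events=50000, noise_scale=0.4,
        sample_id="prospective",
    )


def gate_with_planted(db, k, n=20000, seed=55, pop="classical_th/th22/te"):
    """Auto-gate a sample in which ``pop`` has exactly k planted events."""
    from dataclasses import replace

    base = [tpl for tpl in t.default_templates("18-40y") if tpl.name != pop]
    total_base = sum(tpl.frequency for tpl in base)
    base = [
        replace(tpl, frequency=tpl.frequency / total_base * (1 - k / n))
        for tpl in base
    ]
    planted = next(
        tpl for tpl in t.default_templates("18-40y") if tpl.name == pop
    )
    templates = tuple(base) + (replace(planted, frequency=k / n),)
    spec = t.SampleSpec(
        n_events=n, templates=templates, seed=seed, noise_scale=0.3,
        exact_counts=True, sample_id=f"planted-{k}",
    )
    synth = t.simulate_sample(spec)
    assert synth.planned_counts[pop] == k
    return t.auto_gate(t.prepare_for_gating(synth), db)


@pytest.fixture
def planted_gate():
    return gate_with_planted
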