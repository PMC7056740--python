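"""Reference database construction and database-guided auto-gating tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import tcd4flow as t
from tcd4flow.errors import ConfigurationError, ValidationError
from tcd4flow.fcs_io import ChannelInfo, FlowSample
from tcd4flow.simulate import LEVEL_ANCHORS, ALL_MARKERS


def _labeled(synth):
    return (t.prepare_for_gating(synth), synth.expected_leaves)


def _simulate(seed, n=20000, noise=0.4, band="18-40y", **kw):
    spec = t.SampleSpec(
        n_events=n, templates=t.default_templates(band), seed=seed,
        noise_scale=noise, sample_id=f"s{seed}", **kw,
    )
    return t.simulate_sample(spec)


class TestBuildReference:
    def test_single_sample_means(self, taxonomy):
        synth = _simulate(31)
        sample, labels = _labeled(synth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            db = t.build_reference([(sample, labels)], taxonomy=taxonomy)
        leaf = "classical_th/naive"
        expected = sample.events[labels == leaf].mean(axis=0)
        np.testing.assert_allclose(db.stats[leaf].mean, expected)

    def test_two_sample_pooled_mean_oracle(self, taxonomy):
        s1, l1 = _labeled(_simulate(32, n=15000))
        s2, l2 = _labeled(_simulate(33, n=25000))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            db = t.build_reference([(s1, l1), (s2, l2)], taxonomy=taxonomy)
        leaf = "classical_th/th1/cm"
        # brute-force oracle: concatenate and average
        cat = np.vstack([s1.events[l1 == leaf], s2.events[l2 == leaf]])
        np.testing.assert_allclose(db.stats[leaf].mean, cat.mean(axis=0))
        # equivalently (n1 m1 + n2 m2) / (n1 + n2)
        n1, n2 = (l1 == leaf).sum(), (l2 == leaf).sum()
        m1 = s1.events[l1 == leaf].mean(axis=0)
        m2 = s2.events[l2 == leaf].mean(axis=0)
        np.testing.assert_allclose(
            db.stats[leaf].mean, (n1 * m1 + n2 * m2) / (n1 + n2)
        )
        assert db.stats[leaf].n_events == n1 + n2

    def test_three_center_means_near_templates(self, reference_db, adult_templates):
        by_name = {tpl.name: tpl for tpl in adult_templates}
        col = {m: i for i, m in enumerate(ALL_MARKERS)}
        for leaf in ("classical_th/naive", "classical_th/th1/cm", "treg/naive"):
            st = reference_db.stats[leaf]
            tpl = by_name[leaf]
            se = tpl.sd * 0.4 / np.sqrt(st.n_events)  # noise_scale 0.4
            for m in ("CD3", "CD4", "CD183", "CD27"):
                anchor = LEVEL_ANCHORS[tpl.levels[m]]
                assert abs(st.mean[col[m]] - anchor) < 3 * se + 1e-9, (leaf, m)

    def test_covariance_shrinkage_and_symmetry(self, reference_db):
        st = reference_db.stats["classical_th/naive"]
        np.testing.assert_allclose(st.covariance, st.covariance.T)
        assert np.all(np.linalg.eigvalsh(st.covariance) > 0)

    def test_small_population_omitted_with_warning(self, taxonomy):
        synth = _simulate(34, n=300)
        sample, labels = _labeled(synth)
        with pytest.warns(UserWarning, match="pooled events"):
            db = t.build_reference([(sample, labels)], taxonomy=taxonomy)
        # something was skipped: not every reportable node has stats
        assert len(db.stats) < len(taxonomy.nodes())

    def test_panel_mismatch_rejected(self, taxonomy):
        s1, l1 = _labeled(_simulate(35, n=2000))
        s2, l2 = _labeled(_simulate(36, n=2000))
        s2.channels = list(reversed(s2.channels))
        s2.events = s2.events[:, ::-1]
        with pytest.raises(ValidationError, match="panel"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t.build_reference([(s1, l1), (s2, l2)], taxonomy=taxonomy)

    def test_priors_sum_to_at_most_one(self, reference_db, taxonomy):
        for node in taxonomy.nodes():
            kids = [c.name for c in node.children if c.alias_of is None]
            priors = [
                reference_db.stats[k].prior for k in kids if reference_db.has(k)
            ]
            assert sum(priors) <= 1.0 + 1e-9, node.name

    def test_json_round_trip(self, reference_db):
        back = t.ReferenceDatabase.from_json(reference_db.to_json())
        assert set(back.stats) == set(reference_db.stats)
        np.testing.assert_allclose(
            back.stats["cd4_t"].mean, reference_db.stats["cd4_t"].mean
        )
        assert back.markers == reference_db.markers


class TestAutoGate:
    def test_well_separated_high_accuracy(self, reference_db, autogate_test_synth, taxonomy):
        synth = autogate_test_synth
        res = t.auto_gate(t.prepare_for_gating(synth), reference_db)
        leaves = set(taxonomy.leaf_names())
        is_leaf = np.array([l in leaves for l in synth.expected_leaves])
        acc = np.mean(res.labels[is_leaf] == synth.expected_leaves[is_leaf])
        assert acc >= 0.99
        # filler populations never land in a CD4 population
        fillers = ~is_leaf
        assert all(
            str(l).startswith("unclassified:") for l in res.labels[fillers]
        )

    def test_min_cluster_step_function(self, reference_db, planted_gate):
        """Planted population reported at exactly min_cluster events."""
        for k, expect_reported in ((9, False), (10, True)):
            res = planted_gate(reference_db, k)
            pop = "classical_th/th22/te"
            assert res.gating.count(pop) == k
            reported = pop not in res.suppressed
            assert reported is expect_reported, k
            # suppressed populations keep counts internally
            assert res.gating.count(pop) == k

    def test_two_time_points_identical(self, reference_db, autogate_test_synth):
        sample = t.prepare_for_gating(autogate_test_synth)
        r1 = t.auto_gate(sample, reference_db)
        r2 = t.auto_gate(sample, reference_db)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.gating.counts == r2.gating.counts
        assert r1.suppressed == r2.suppressed
        same = [
            r1.gating.count(p) == r2.gating.count(p)
            for p in r1.gating.taxonomy.reportable_populations()
        ]
        assert np.mean(same) == 1.0  # 100% agreement

    def test_partition_conservation(self, reference_db, autogate_test_synth, taxonomy):
        res = t.auto_gate(t.prepare_for_gating(autogate_test_synth), reference_db)
        g = res.gating
        for node in taxonomy.nodes():
            real = [c for c in node.children if c.alias_of is None]
            if not real:
                continue
            total = sum(g.count(c.name) for c in real) + g.count(
                node.unclassified_name
            )
            assert total == g.count(node.name), node.name

    def test_nearest_centroid_under_identity_covariance(self):
        """With identity covariances auto-gating must reduce to
        nearest-centroid assignment (independent oracle)."""
        tax = t.build_taxonomy()
        markers = ALL_MARKERS
        col = {m: i for i, m in enumerate(markers)}
        templates = {
            tpl.name: tpl for tpl in t.default_templates("18-40y")
            if not tpl.name.startswith("filler")
        }
        from tcd4flow.autogate import ReferencePopulationStats, _leaf_sets

        leaf_sets = _leaf_sets(tax)
        stats = {}
        for node in tax.nodes():
            if node.alias_of is not None:
                continue
            member_leaves = [l for l in leaf_sets[node.name] if l in templates]
            if not member_leaves:
                continue
            means = np.array(
                [templates[l].mean_vector() for l in member_leaves]
            )
            stats[node.name] = ReferencePopulationStats(
                population=node.name,
                markers=markers,
                mean=means.mean(axis=0),
                covariance=np.eye(len(markers)),
                n_events=100 * len(member_leaves),
                prior=0.5,
            )
        db = t.ReferenceDatabase(
            taxonomy=tax, stats=stats, markers=markers
        )
        synth = _simulate(41, n=4000, noise=0.3)
        sample = t.prepare_for_gating(synth)
        res = t.auto_gate(sample, db, max_radius=20.0)

        # oracle: greedy nearest centroid (Euclidean) down the tree
        def oracle_label(x):
            node = tax.root
            while True:
                real = [
                    c for c in node.children
                    if c.alias_of is None and c.name in stats
                ]
                if not real:
                    return node.name
                midx = [col[m] for m in node.child_markers] if node.child_markers else list(range(len(markers)))
                d = [
                    np.sum((x[midx] - stats[c.name].mean[midx]) ** 2)
                    for c in real
                ]
                node = real[int(np.argmin(d))]

        leaves = set(tax.leaf_names())
        idx = [i for i, l in enumerate(synth.expected_leaves) if l in leaves][:300]
        for i in idx:
            assert res.labels[i] == oracle_label(sample.events[i]), i

    def test_frequency_recovery_within_binomial_ci(
        self, reference_db, autogate_test_synth, taxonomy
    ):
        """Auto-gated population frequencies match the generator's plan
        within 99% binomial CIs (oracle: normal-approximation CI)."""
        synth = autogate_test_synth
        res = t.auto_gate(t.prepare_for_gating(synth), reference_db)
        n = synth.n_events
        planned = synth.planned_counts
        checked = 0
        for pop in ("cd4_t", "classical_th", "treg", "tfh", "classical_th/naive"):
            node_leaves = {
                l for l in taxonomy.leaf_names() if l.startswith(pop + "/") or l == pop
            }
            k_planned = sum(planned.get(l, 0) for l in node_leaves)
            if k_planned < 50:
                continue
            p_hat = k_planned / n
            # binomial 99% CI around the planned draw, plus a 1% slack for
            # classification error at this noise level
            half = 2.576 * np.sqrt(p_hat * (1 - p_hat) / n) + 0.01 * p_hat + 5 / n
            observed = res.gating.count(pop) / n
            assert abs(observed - p_hat) <= half, (pop, observed, p_hat)
            checked += 1
        assert checked >= 3

    def test_empty_database_level_error(self, taxonomy):
        from tcd4flow.autogate import ReferencePopulationStats

        markers = ALL_MARKERS
        stats = {
            "leukocytes": ReferencePopulationStats(
                population="leukocytes",
                markers=markers,
                mean=np.zeros(len(markers)),
                covariance=np.eye(len(markers)),
                n_events=100,
                prior=1.0,
            )
        }
        db = t.ReferenceDatabase(taxonomy=taxonomy, stats=stats, markers=markers)
        synth = _simulate(42, n=500, noise=0.0)
        with pytest.raises(ConfigurationError, match="lymphocytes|level"):
            t.auto_gate(
                t.prepare_for_gating(synth), db, max_radius=50.0,
                on_empty_level="error",
            )
        # default: the undivided cluster keeps its events at that level
        res = t.auto_gate(t.prepare_for_gating(synth), db, max_radius=50.0)
        assert res.gating.count("unclassified:leukocytes") > 0

    def test_untransformed_rejected(self, reference_db):
        synth = _simulate(43, n=100)
        with pytest.raises(ValidationError):
            t.auto_gate(synth.sample, reference_db)


class TestCompareAnalyses:
    def test_identity_is_concordant(self, reference_db, autogate_test_synth):
        sample = t.prepare_for_gating(autogate_test_synth)
        r = t.auto_gate(sample, reference_db).gating
        rep = t.compare_analyses([r, r], [r, r])
        mnb = rep.per_population["mnb"].dropna()
        assert (mnb == 0).all()
        assert rep.per_population["concordant"].dropna().all()

    def test_twenty_percent_bias_discordant(self):
        rng = np.random.default_rng(60)
        a = rng.uniform(5, 50, size=(8,))
        pairs = {"pop": (a, 1.2 * a)}
        rep = t.agreement(pairs)
        row = rep.per_population.iloc[0]
        assert row["mnb"] == pytest.approx(20.0)
        assert not row["concordant"]

    def test_taxonomy_mismatch(self, zero_noise_result):
        other = t.build_taxonomy(version="other")
        res2 = t.GatingResult(
            labels=zero_noise_result.labels,
            counts=zero_noise_result.counts,
            taxonomy=other,
            n_events=zero_noise_result.n_events,
        )
        with pytest.raises(ValidationError, match="taxonomy"):
            t.compare_analyses(zero_noise_result, res2)
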