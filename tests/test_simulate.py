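"""Statistical calibration and determinism of the synthetic-data generator."""

import dataclasses
import datetime as dt
from collections import Counter

import numpy as np
import pytest

from carevoice import GeneratorConfig, Source, ValidationError
from carevoice.simulate import (
    DEFAULT_CLASS_PROBS,
    SourceProfile,
    draw_stars,
    generate_feedback,
    generate_inspections,
    generate_labelled_corpus,
    generate_organisations,
    rating_thresholds,
    star_mean,
)


class TestOrganisations:
    def test_counts_and_parent_resolution(self):
        cfg = GeneratorConfig(n_trusts=2, hospitals_per_trust=3, seed=0)
        registry, quality = generate_organisations(cfg)
        assert len(registry.trusts()) == 2
        hospitals = registry.hospitals()
        assert len(hospitals) == 6
        for h in hospitals:
            assert registry[h.parent_trust_id].kind.value == "trust"
        assert set(quality) == {o.org_id for o in registry}

    def test_same_seed_identical(self):
        cfg = GeneratorConfig(n_trusts=5, hospitals_per_trust=(1, 3), seed=42)
        r1, q1 = generate_organisations(cfg)
        r2, q2 = generate_organisations(cfg)
        assert [o.org_id for o in r1] == [o.org_id for o in r2]
        assert q1 == q2

    def test_hospital_quality_standard_normal(self):
        # 5,000 trusts x 2 hospitals: mean of q within 3 standard errors of 0,
        # variance near 1 (trust share + hospital deviation sum to unit variance)
        cfg = GeneratorConfig(n_trusts=5000, hospitals_per_trust=2, seed=7)
        registry, quality = generate_organisations(cfg)
        q = np.array([quality[h.org_id] for h in registry.hospitals()])
        assert len(q) == 10000
        # hospitals within a trust are correlated; bound the SE conservatively
        se = np.sqrt(2.0 / len(q))
        assert abs(q.mean()) < 3 * se
        assert abs(q.var() - 1.0) < 0.1


class TestStars:
    def test_mean_calibration(self, rng):
        s = draw_stars(np.full(50000, 3.85), rng)
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - 3.85) < 3 * se

    def test_star_mean_inversion(self):
        targets = np.array([1.2, 2.0, 3.85, 4.13, 4.28, 4.9])
        from carevoice.simulate import star_location_for_mean

        mu = star_location_for_mean(targets)
        np.testing.assert_allclose(star_mean(mu), targets, atol=1e-8)

    def test_quality_monotone(self):
        # expected star mean is monotone in latent quality by construction
        cfg = GeneratorConfig()
        eff = cfg.quality_effect
        assert star_mean(np.array([0.0])) is not None
        hi = np.clip(3.85 + 0.3 * 2, 1, 5)
        lo = np.clip(3.85 + 0.3 * -2, 1, 5)
        assert hi > lo


class TestFeedback:
    def _tiny_cfg(self, **kw):
        base = dict(
            n_trusts=2, hospitals_per_trust=2,
            period=(dt.date(2016, 3, 1), dt.date(2016, 5, 31)), seed=5,
        )
        base.update(kw)
        return GeneratorConfig(**base)

    def test_zero_rate_empty(self):
        cfg = self._tiny_cfg()
        cfg.source_profiles = {
            Source.rating_site: SourceProfile(0.0, 3.85),
            Source.social_review: SourceProfile(0.0, 4.13),
            Source.microblog: SourceProfile(0.0, 4.28, relevance_fraction=0.09),
        }
        registry, quality = generate_organisations(cfg)
        assert generate_feedback(registry, quality, cfg) == []

    def test_star_sources_always_scored_microblog_never(self):
        cfg = self._tiny_cfg()
        registry, quality = generate_organisations(cfg)
        items = generate_feedback(registry, quality, cfg)
        for it in items:
            if it.source is Source.microblog:
                assert it.stars is None and it.text
            else:
                assert it.stars is not None and 1 <= it.stars <= 5

    def test_determinism(self):
        cfg = self._tiny_cfg()
        registry, quality = generate_organisations(cfg)
        a = generate_feedback(registry, quality, cfg)
        b = generate_feedback(registry, quality, cfg)
        assert a == b

    def test_marginal_mean_at_zero_quality_effect(self):
        # big single-source sample: empirical mean within 3 SE of configured mean
        cfg = self._tiny_cfg(quality_effect=0.0, n_trusts=30, hospitals_per_trust=3)
        cfg.source_profiles = {Source.rating_site: SourceProfile(5.0, 3.85)}
        registry, quality = generate_organisations(cfg)
        items = generate_feedback(registry, quality, cfg)
        stars = np.array([it.stars for it in items])
        assert len(stars) > 30000
        se = stars.std() / np.sqrt(len(stars))
        assert abs(stars.mean() - 3.85) < 3 * se

    def test_quality_effect_orders_organisations(self):
        cfg = self._tiny_cfg(quality_effect=0.3, n_trusts=2, hospitals_per_trust=1)
        registry, _ = generate_organisations(cfg)
        hosp = registry.hospitals()
        quality = {o.org_id: 0.0 for o in registry}
        quality[hosp[0].org_id] = 2.0
        quality[hosp[1].org_id] = -2.0
        cfg.source_profiles = {Source.rating_site: SourceProfile(5.0, 3.85)}
        items = generate_feedback(registry, quality, cfg)
        mean = {
            h.org_id: np.mean([it.stars for it in items if it.org_id == h.org_id])
            for h in hosp
        }
        assert mean[hosp[0].org_id] > mean[hosp[1].org_id]

    def test_changepoint_drops_stars(self):
        from carevoice.simulate import Changepoint

        cfg = self._tiny_cfg(n_trusts=1, hospitals_per_trust=1)
        registry, quality = generate_organisations(cfg)
        org = registry.hospitals()[0].org_id
        cfg.source_profiles = {Source.rating_site: SourceProfile(8.0, 4.0)}
        cfg.changepoint = Changepoint(org_ids=(org,), date=dt.date(2016, 4, 15), star_drop=2.0)
        items = generate_feedback(registry, quality, cfg)
        before = [it.stars for it in items if it.date < dt.date(2016, 4, 15)]
        after = [it.stars for it in items if it.date >= dt.date(2016, 4, 15)]
        assert np.mean(after) < np.mean(before) - 1.0


class TestInspections:
    def test_degenerate_base_probs(self):
        cfg = GeneratorConfig(n_trusts=10, hospitals_per_trust=1,
                              rating_base_probs=(0, 1, 0, 0), unrated_fraction=0.0, seed=1)
        registry, quality = generate_organisations(cfg)
        ratings = {i.rating for i in generate_inspections(registry, quality, cfg)}
        assert ratings == {"Requires improvement"}

    def test_outstanding_fraction_calibrated(self):
        cfg = GeneratorConfig(n_trusts=5000, hospitals_per_trust=1, unrated_fraction=0.0, seed=9)
        registry, quality = generate_organisations(cfg)
        insp = generate_inspections(registry, quality, cfg)
        frac = np.mean([i.rating == "Outstanding" for i in insp])
        se = np.sqrt(0.03 * 0.97 / len(insp))
        assert abs(frac - 0.03) < 3 * se

    def test_extreme_slope_orders_ratings_by_quality(self):
        from carevoice.types import rating_index

        cfg = GeneratorConfig(n_trusts=100, hospitals_per_trust=1,
                              rating_quality_slope=1000.0, unrated_fraction=0.0, seed=2)
        registry, quality = generate_organisations(cfg)
        insp = generate_inspections(registry, quality, cfg)
        pairs = sorted((quality[i.org_id], rating_index(i.rating)) for i in insp)
        codes = [k for _, k in pairs]
        assert codes == sorted(codes)

    def test_marginal_thresholds_reproduce_base_probs(self):
        thetas = rating_thresholds((0.10, 0.61, 0.26, 0.03), 2.0)
        from scipy.special import expit

        rng = np.random.default_rng(0)
        q = rng.normal(size=400000)
        cum = expit(thetas[None, :] - 2.0 * q[:, None])
        u = rng.uniform(size=len(q))
        counts = np.bincount((u[:, None] > cum).sum(axis=1), minlength=4) / len(q)
        np.testing.assert_allclose(counts, [0.10, 0.61, 0.26, 0.03], atol=0.005)


class TestCorpus:
    def test_class_imbalance_matches_probs(self):
        n = 5869
        corpus = generate_labelled_corpus(n, seed=0)
        counts = Counter(item.label for item in corpus)
        # expected 'safety' count = 13 under the coded-sample proportions
        expected_safety = n * DEFAULT_CLASS_PROBS[3]
        assert abs(expected_safety - 13) < 0.01
        se = np.sqrt(n * DEFAULT_CLASS_PROBS[3])
        assert abs(counts["safety"] - expected_safety) < 4 * se + 1

    def test_separation_one_disjoint_vocabularies(self):
        corpus = generate_labelled_corpus(400, separation=1.0, seed=1)
        vocab = {}
        for item in corpus:
            for tok in item.text.split():
                vocab.setdefault(tok, set()).add(item.label)
        # topic tokens never shared across classes (tone tokens are shared
        # across classes by design: they encode stars, not topic)
        for tok, labels in vocab.items():
            if not tok.startswith("tone"):
                assert len(labels) == 1

    def test_separation_zero_identical_vocabulary(self):
        corpus = generate_labelled_corpus(400, separation=0.0, seed=1)
        for item in corpus:
            for tok in item.text.split():
                assert tok.startswith(("common_", "tone_any_"))

    def test_bad_class_probs_rejected(self):
        with pytest.raises(ValidationError):
            generate_labelled_corpus(10, class_probs=(0.5, 0.5, 0.0, 0.0, 0.1))

    def test_stars_only_on_care_quality(self):
        corpus = generate_labelled_corpus(300, seed=2)
        for item in corpus:
            assert (item.stars is None) == (item.label == "not_care_quality")
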