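import numpy as np
import pytest

from facematch import (
    CohortSpec,
    ConfigError,
    FaceParams,
    GeneratorConfig,
    RankConfig,
    RatingModel,
    evaluate_cohort,
    generate_clinician_scores,
    generate_embedding_facebase,
    generate_face_image,
    sample_face_params,
)


def small_config(**kwargs):
    defaults = dict(
        cohorts=tuple(CohortSpec(f"S{i}", 5) for i in range(2)),
        n_controls=10,
        d=16,
        sigma_b=1.0,
        sigma_w=0.5,
        sigma_e=0.25,
        seed=42,
    )
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


class TestEmbeddingGenerator:
    def test_counts_and_norms(self):
        fb = generate_embedding_facebase(small_config())
        assert len(fb) == 20
        assert np.allclose(np.linalg.norm(fb.embeddings, axis=1), 1.0, atol=1e-12)

    def test_determinism(self):
        cfg = small_config()
        fb1 = generate_embedding_facebase(cfg)
        fb2 = generate_embedding_facebase(cfg)
        assert fb1.records == fb2.records
        assert np.array_equal(fb1.embeddings, fb2.embeddings)

    def test_seed_changes_output(self):
        fb1 = generate_embedding_facebase(small_config(seed=1))
        fb2 = generate_embedding_facebase(small_config(seed=2))
        assert not np.array_equal(fb1.embeddings, fb2.embeddings)

    def test_multi_image_individuals(self):
        cfg = small_config(
            cohorts=(CohortSpec("S0", 40, multi_image_fraction=1.0),)
        )
        fb = generate_embedding_facebase(cfg)
        per_individual = {}
        for r in fb.records:
            if not r.is_control:
                per_individual.setdefault(r.individual_id, []).append(r.image_id)
        assert sum(len(v) for v in per_individual.values()) == 40
        assert any(len(v) > 1 for v in per_individual.values())
        # dotted image ids, identity carried by individual_id
        for ind, ids in per_individual.items():
            assert ids == [f"{ind}.{j}" for j in range(1, len(ids) + 1)]

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            small_config(d=1)
        with pytest.raises(ConfigError):
            small_config(sigma_b=-0.1)
        with pytest.raises(ConfigError):
            CohortSpec("CONTROL", 5)

    def test_high_separation_forces_retrieval(self):
        # strong between-cohort signal: mean top-1 same-cohort rate >= 0.9
        rates = []
        for seed in range(20):
            cfg = GeneratorConfig(
                cohorts=tuple(CohortSpec(f"S{i}", 20) for i in range(10)),
                n_controls=200,
                d=16,
                sigma_b=5.0,
                sigma_w=0.5,
                sigma_e=0.5,
                seed=seed,
            )
            fb = generate_embedding_facebase(cfg)
            hits = total = 0
            for cohort in fb.syndrome_cohorts:
                (match, nomatch) = evaluate_cohort(fb, cohort, RankConfig((1,)))[1]
                hits += match
                total += match + nomatch
            rates.append(hits / total)
        assert np.mean(rates) >= 0.9

    def test_signal_monotonicity_in_sigma_b(self):
        grid = [0.0, 0.5, 1.0, 2.0, 4.0]
        mean_rates = []
        for sigma_b in grid:
            rates = []
            for seed in range(8):
                cfg = GeneratorConfig(
                    cohorts=tuple(CohortSpec(f"S{i}", 15) for i in range(4)),
                    n_controls=60,
                    d=8,
                    sigma_b=sigma_b,
                    sigma_w=0.5,
                    sigma_e=0.25,
                    seed=seed,
                )
                fb = generate_embedding_facebase(cfg)
                hits = total = 0
                for cohort in fb.syndrome_cohorts:
                    match, nomatch = evaluate_cohort(fb, cohort, RankConfig((1,)))[1]
                    hits, total = hits + match, total + match + nomatch
                rates.append(hits / total)
            mean_rates.append(np.mean(rates))
        for lo, hi in zip(mean_rates, mean_rates[1:]):
            assert hi >= lo - 0.02  # non-decreasing up to seed noise


class TestClinicianScores:
    def test_all_definite(self):
        fb = generate_embedding_facebase(small_config())
        table = generate_clinician_scores(fb, RatingModel(p_definite=1.0), seed=0)
        assert all(t == (1, 1, 1) for _, t in table.items())

    def test_all_unlikely(self):
        fb = generate_embedding_facebase(small_config())
        table = generate_clinician_scores(
            fb, RatingModel(p_definite=0.0, p_possible=0.0), seed=0
        )
        assert all(t == (2, 2, 2) for _, t in table.items())

    def test_controls_not_scored(self):
        fb = generate_embedding_facebase(small_config())
        table = generate_clinician_scores(fb, RatingModel(p_definite=0.5), seed=0)
        assert len(table) == 10
        assert all(not fb.record(i).is_control for i, _ in table.items())

    def test_marginal_rate_converges(self):
        cfg = small_config(cohorts=(CohortSpec("S0", 1000),), n_controls=0)
        fb = generate_embedding_facebase(cfg)
        table = generate_clinician_scores(fb, RatingModel(p_definite=0.6), seed=7)
        scores = np.array([t for _, t in table.items()])
        rate = (scores == 1).mean()
        se = np.sqrt(0.6 * 0.4 / scores.size)
        assert abs(rate - 0.6) < 3 * se

    def test_determinism(self):
        fb = generate_embedding_facebase(small_config())
        model = RatingModel(p_definite=0.5, p_possible=0.3, rater_correlation=0.5)
        t1 = generate_clinician_scores(fb, model, seed=3)
        t2 = generate_clinician_scores(fb, model, seed=3)
        assert t1.scores == t2.scores

    def test_rater_correlation_increases_agreement(self):
        cfg = small_config(cohorts=(CohortSpec("S0", 2000),), n_controls=0)
        fb = generate_embedding_facebase(cfg)

        def agreement(rho):
            table = generate_clinician_scores(
                fb, RatingModel(p_definite=0.5, rater_correlation=rho), seed=11
            )
            triples = np.array([t for _, t in table.items()])
            return np.mean(triples[:, 0] == triples[:, 1])

        assert agreement(1.0) > agreement(0.0) + 0.2

    def test_missing_cohort_in_model(self):
        fb = generate_embedding_facebase(small_config())
        with pytest.raises(ConfigError, match="missing"):
            generate_clinician_scores(fb, RatingModel(p_definite={"S0": 0.5}), seed=0)

    def test_probability_mass_validated(self):
        fb = generate_embedding_facebase(small_config())
        with pytest.raises(ConfigError, match="<= 1"):
            generate_clinician_scores(
                fb, RatingModel(p_definite=0.8, p_possible=0.5), seed=0
            )


class TestFaceSketch:
    def test_pixel_identical_for_same_inputs(self):
        p = sample_face_params(np.random.default_rng(0))
        img1 = generate_face_image(p, age_scale=1.0, noise_seed=5)
        img2 = generate_face_image(p, age_scale=1.0, noise_seed=5)
        assert np.array_equal(img1, img2)

    def test_age_scale_changes_image(self):
        p = sample_face_params(np.random.default_rng(0))
        img1 = generate_face_image(p, age_scale=1.0, noise_seed=5)
        img2 = generate_face_image(p, age_scale=1.2, noise_seed=5)
        assert not np.array_equal(img1, img2)

    def test_midpoint_features_inside_canvas(self):
        img = generate_face_image(FaceParams(), noise_sigma=0.0, shade_amp=0.0, size=64)
        # background untouched along the border -> all geometry contained
        border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
        assert np.all(border == 32)

    def test_canvas_minimum(self):
        with pytest.raises(ConfigError):
            generate_face_image(FaceParams(), size=16)

    def test_age_pair_beats_median_stranger_similarity(self):
        # the same person at age scales 1.0 vs 1.2 should look more alike
        # (to the DCT descriptor) than the median stranger does
        from facematch import DescriptorParams, cosine_similarity, embed_image

        params = DescriptorParams()
        rng = np.random.default_rng(123)
        people = [sample_face_params(rng) for _ in range(20)]
        hits = 0
        for i in range(20):
            young = embed_image(generate_face_image(people[i], 1.0, noise_seed=i), params)
            old = embed_image(
                generate_face_image(people[i], 1.2, noise_seed=i + 100), params
            )
            strangers = [
                cosine_similarity(
                    young,
                    embed_image(
                        generate_face_image(people[j], 1.0, noise_seed=j + 200), params
                    ),
                )
                for j in range(20)
                if j != i
            ]
            hits += cosine_similarity(young, old) > np.median(strangers)
        assert hits >= 18  # 90% of individuals
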