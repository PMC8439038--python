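"""Synthetic-study generator: distributions, round-trips, determinism."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from seroindex.elisa import QCConfig, process_plate
from seroindex.io import plates_from_frame
from seroindex.simulate import (
    CohortSpec,
    LogNormalComponent,
    PlateNoise,
    ResponseModel,
    StudySpec,
    cohort_rng,
    demo_spec,
    generate_cohort,
    generate_plate_readings,
    generate_study,
    generate_subject,
    joint_latent_table,
    write_study,
)


def small_cohort(**kw):
    defaults = dict(name="eira", n=50, prevalence_cit=0.5, prevalence_native=0.3)
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestJointLatentTable:
    @pytest.mark.parametrize("theta", [0.25, 1.0, 4.0])
    @pytest.mark.parametrize("p1, p2", [(0.3, 0.4), (0.78, 0.2), (0.95, 0.06)])
    def test_margins_and_cross_ratio(self, theta, p1, p2):
        t = joint_latent_table(p1, p2, theta)
        assert t.sum() == pytest.approx(1.0)
        assert t[1].sum() == pytest.approx(p1)
        assert t[:, 1].sum() == pytest.approx(p2)
        cross = (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])
        assert cross == pytest.approx(theta)

    def test_independence_at_unit_odds(self):
        t = joint_latent_table(0.4, 0.25, 1.0)
        assert t[1, 1] == pytest.approx(0.1)


class TestGenerateSubject:
    def test_zero_prevalence_draws_only_negative_component(self, rng):
        spec = small_cohort(prevalence_cit=0.0, prevalence_native=0.0)
        subjects = [generate_subject(spec, rng, f"S{i}") for i in range(200)]
        assert not any(s["latent_cit_positive"] for s in subjects)
        # negative component: log-mean -2.12 => all draws comfortably below
        # the positive component's bulk
        upper = math.exp(spec.neg_component.log_mean + 5 * spec.neg_component.log_sd)
        assert max(s["cit_net_true"] for s in subjects) < upper

    def test_se_effect_monotone_in_copies(self, rng):
        spec = small_cohort(
            se_distribution=(0.34, 0.33, 0.33), se_effect_on_cit=1.4,
            prevalence_cit=0.5,
        )
        subjects = [generate_subject(spec, rng, f"S{i}") for i in range(10_000)]
        means = [
            np.mean([s["cit_net_true"] for s in subjects if s["se_copies"] == k])
            for k in (0, 1, 2)
        ]
        assert means[0] < means[1] < means[2]

    def test_latent_independence_at_unit_odds(self, rng):
        spec = small_cohort(joint_dependence=1.0)
        subjects = [generate_subject(spec, rng, f"S{i}") for i in range(10_000)]
        table = np.zeros((2, 2))
        for s in subjects:
            table[int(s["latent_cit_positive"]), int(s["latent_native_positive"])] += 1
        _, p, _, _ = sps.chi2_contingency(table)
        assert p > 0.001

    def test_response_probability_recovered(self):
        """The configured P(responder | negative delta) is recovered.

        A single draw can fall in the 5% CI-miss tail, so coverage is
        checked over several seeds rather than asserted for one draw.
        """
        logit87 = math.log(0.87 / 0.13)
        spec = small_cohort(
            n=2000, prevalence_cit=0.3, prevalence_native=0.4,
            treatment="mtx",
            response_model=ResponseModel(
                intercept=0.0, coef_native=0.0, coef_negative_delta=logit87
            ),
        )
        covered = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            subjects = [generate_subject(spec, rng, f"S{i}") for i in range(2000)]
            neg = [
                s for s in subjects
                if s["cit_net_true"] - s["native_net_true"] < 0
            ]
            k, n = sum(s["eular_responder_6m"] for s in neg), len(neg)
            ci = sps.binomtest(k, n).proportion_ci(
                confidence_level=0.95, method="exact"
            )
            covered += ci.low <= 0.87 <= ci.high
        assert covered >= n_seeds - 1

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            small_cohort(prevalence_cit=1.4)
        with pytest.raises(ValueError):
            small_cohort(se_distribution=(0.5, 0.2, 0.2))


class TestPlateReadings:
    def test_noiseless_round_trip(self, rng):
        noise = PlateNoise(replicate_cv=0.0)
        ag450, ag620, bg450, bg620 = generate_plate_readings(0.42, noise, rng)
        net = np.mean(ag450 - ag620) - np.mean(bg450 - bg620)
        assert net == pytest.approx(0.42, abs=1e-12)

    def test_mean_recovered_within_one_percent(self, rng):
        noise = PlateNoise(replicate_cv=0.10)
        true_net = 0.8
        nets = []
        for _ in range(10_000):
            ag450, ag620, bg450, bg620 = generate_plate_readings(true_net, noise, rng)
            nets.append(np.mean(ag450 - ag620) - np.mean(bg450 - bg620))
        assert np.mean(nets) == pytest.approx(true_net, rel=0.01)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            PlateNoise(replicate_cv=-0.1)


class TestGenerateStudy:
    def test_fixed_seed_reproduces_bytes(self, tmp_path):
        spec = demo_spec(seed=7, scale=0.12)
        out_a = write_study(generate_study(spec), tmp_path / "a")
        out_b = write_study(generate_study(demo_spec(seed=7, scale=0.12)), tmp_path / "b")
        for key in ("cohort", "covariates", "truth"):
            assert out_a[key].read_bytes() == out_b[key].read_bytes()
        for pa, pb in zip(out_a["plates"], out_b["plates"]):
            assert pa.read_bytes() == pb.read_bytes()

    def test_adding_a_cohort_does_not_perturb_others(self):
        base = StudySpec(cohorts=[small_cohort(name="eira", n=30)], seed=3)
        extended = StudySpec(
            cohorts=[small_cohort(name="eira", n=30), small_cohort(name="sle", n=20)],
            seed=3,
        )
        a = generate_cohort(base.cohorts[0], base.seed)
        b = generate_cohort(extended.cohorts[0], extended.seed)
        assert [s["cit_net_true"] for s in a] == [s["cit_net_true"] for s in b]

    def test_duplicate_cohort_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            StudySpec(cohorts=[small_cohort(), small_cohort()])

    def test_every_subject_on_exactly_one_plate_per_antigen(self):
        study = generate_study(StudySpec(cohorts=[small_cohort(n=45)], seed=1,
                                         samples_per_plate=20))
        wells = study.wells
        for antigen in ("cit-DL", "DL"):
            sub = wells[(wells.role == "antigen") & (wells.antigen_id == antigen)]
            plates_per_subject = sub.groupby("sample_id")["plate_id"].nunique()
            assert (plates_per_subject == 1).all()
            assert len(plates_per_subject) == 45

    def test_ground_truth_covers_all_subjects(self):
        study = generate_study(StudySpec(cohorts=[small_cohort(n=25)], seed=2))
        assert set(study.ground_truth.subject_id) == {
            r.subject_id for r in study.subject_records
        }

    def test_measured_nets_track_truth(self):
        study = generate_study(StudySpec(cohorts=[small_cohort(n=60)], seed=4))
        truth = study.ground_truth.set_index("subject_id")
        errs = [
            r.cit_net - truth.loc[r.subject_id, "cit_net_true"]
            for r in study.subject_records
        ]
        assert abs(np.mean(errs)) < 0.02
        assert np.percentile(np.abs(errs), 95) < 0.25

    def test_failing_plate_is_detected_by_qc(self):
        spec = StudySpec(cohorts=[small_cohort(n=20)], seed=5,
                         include_failing_plate=True)
        study = generate_study(spec)
        config = QCConfig(
            expected_positive_control_od=spec.plate_noise.positive_control_od,
            expected_secondary_od=spec.plate_noise.secondary_mean_od,
        )
        validity = {}
        for plate in plates_from_frame(study.wells):
            qc, _ = process_plate(plate, config)
            validity[plate.plate_id] = qc.valid
        assert validity[max(validity)] is False  # the appended plate
        assert sum(not v for v in validity.values()) == 1

    def test_empty_study_is_schema_valid(self, tmp_path):
        spec = StudySpec(cohorts=[], seed=0)
        study = generate_study(spec)
        assert len(study.subject_records) == 0
        out = write_study(study, tmp_path)
        assert out["cohort"].read_text().startswith("subject_id\t")

    def test_negative_measured_nets_occur(self):
        # background noise occasionally exceeds antigen noise for low titres
        study = generate_study(
            StudySpec(cohorts=[small_cohort(name="healthy", n=300,
                                            prevalence_cit=0.0,
                                            prevalence_native=0.0)], seed=6)
        )
        assert any(r.cit_net < 0 for r in study.subject_records)


def test_cohort_rng_streams_are_name_keyed():
    a = cohort_rng(11, "eira").standard_normal(3)
    b = cohort_rng(11, "eira").standard_normal(3)
    c = cohort_rng(11, "sle").standard_normal(3)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
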