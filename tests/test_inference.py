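"""Hierarchical model correctness: exact likelihood kernels, determinism,
closed-form cross-checks and subgroup interaction behaviour."""

import warnings

import numpy as np
import pytest

from peepbayes.inference import (
    HierarchicalModelSpec,
    ModelError,
    build_model,
    fit_duration_model,
    fit_mortality_model,
    fit_subgroup_interaction,
    fit_vfd_model,
    subgroup_indicator,
)
from peepbayes.priors import PriorSpec
from peepbayes.synthetic import SimulationConfig, simulate_trial
from peepbayes.trial_data import Arm, TrialDataset

import _oracles
from conftest import make_record, random_dataset

FAST = dict(n_chains=2, n_warmup=400, n_draws=500, thin=4)


def _spec(registry, outcome, label="neutral", **kw):
    reg, het = registry
    base = dict(
        outcome=outcome,
        treatment_prior=reg[(outcome, label)],
        heterogeneity_prior=het,
        seed=1,
    )
    base.update(kw)
    return HierarchicalModelSpec(**base)


def _quiet(fn, *args):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args)


@pytest.fixture(scope="module")
def tiny():
    """Six patients, two hospitals, three VFD levels."""
    recs = [
        make_record("a", 1, Arm.LOWER_PEEP, vfd=0, duration=20.0),
        make_record("b", 1, Arm.HIGHER_PEEP, died=True),
        make_record("c", 1, Arm.LOWER_PEEP, vfd=14, duration=6.0),
        make_record("d", 2, Arm.HIGHER_PEEP, vfd=14, duration=8.0),
        make_record("e", 2, Arm.LOWER_PEEP, vfd=28, duration=0.5),
        make_record("f", 2, Arm.HIGHER_PEEP, vfd=28, duration=1.0),
    ]
    return TrialDataset(recs, 2)


class TestLikelihoodOracleEquivalence:
    """The vectorized kernels equal naive per-patient sums, up to a constant."""

    def _compare(self, model, oracle, ndim, rng):
        ref_pt = 0.1 * rng.standard_normal(ndim)
        base_impl = model.log_posterior(ref_pt)
        base_oracle = oracle(ref_pt)
        for _ in range(5):
            pt = 0.8 * rng.standard_normal(ndim)
            diff_impl = model.log_posterior(pt) - base_impl
            diff_oracle = oracle(pt) - base_oracle
            assert diff_impl == pytest.approx(diff_oracle, abs=1e-8)

    def test_vfd_kernel(self, tiny, registry):
        spec = _spec(registry, "vfd")
        model = build_model(tiny, spec)
        rng = np.random.default_rng(0)
        self._compare(
            model,
            lambda p: _oracles.vfd_log_posterior(tiny, spec, p),
            model.ndim,
            rng,
        )

    def test_mortality_kernel(self, tiny, registry):
        spec = _spec(registry, "mortality_28d")
        model = build_model(tiny, spec)
        rng = np.random.default_rng(1)
        self._compare(
            model,
            lambda p: _oracles.mortality_log_posterior(tiny, spec, p),
            model.ndim,
            rng,
        )

    def test_mortality_interaction_kernel(self, tiny, registry):
        spec = _spec(
            registry,
            "mortality_28d",
            interaction_covariate="cardiac_arrest",
            interaction_prior=PriorSpec(
                "mortality_28d", "neutral", 0.0, 1.0, "log_odds_ratio"
            ),
        )
        sg = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 1.0])
        model = build_model(tiny, spec, subgroup=sg)
        rng = np.random.default_rng(2)
        self._compare(
            model,
            lambda p: _oracles.mortality_log_posterior(tiny, spec, p, subgroup=sg),
            model.ndim,
            rng,
        )

    def test_duration_kernel(self, tiny, registry):
        spec = _spec(registry, "duration")
        model = build_model(tiny, spec)
        rng = np.random.default_rng(3)
        self._compare(
            model,
            lambda p: _oracles.duration_log_posterior(tiny, spec, p),
            model.ndim,
            rng,
        )


class TestSamplerContracts:
    def test_identical_seed_reproduces_draws_exactly(self, registry):
        data = random_dataset(n=50, seed=8)
        spec = _spec(registry, "mortality_28d", **FAST)
        a = _quiet(fit_mortality_model, data, spec)
        b = _quiet(fit_mortality_model, data, spec)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.tau, b.tau)
        assert a.diagnostics == b.diagnostics

    def test_draw_shapes_and_invariants(self, registry):
        data = random_dataset(n=60, seed=9)
        spec = _spec(registry, "vfd", **FAST)
        res = _quiet(fit_vfd_model, data, spec)
        assert len(res.theta) == len(res.tau) == res.n_chains * res.n_draws
        assert (res.tau >= 0).all()
        cuts = res.nuisance["cutpoints"]
        assert cuts.shape == (len(res.theta), 28)
        assert (np.diff(cuts, axis=1) > 0).all()

    def test_degenerate_outcomes_rejected(self, registry):
        flat = TrialDataset(
            [
                make_record("a", arm=Arm.LOWER_PEEP, vfd=5),
                make_record("b", arm=Arm.HIGHER_PEEP, vfd=5),
            ],
            1,
        )
        with pytest.raises(ModelError, match="single VFD category"):
            _quiet(fit_vfd_model, flat, _spec(registry, "vfd", **FAST))
        with pytest.raises(ModelError, match="single class"):
            _quiet(
                fit_mortality_model, flat, _spec(registry, "mortality_28d", **FAST)
            )

    def test_wrong_outcome_routing_rejected(self, registry):
        data = random_dataset(n=20, seed=1)
        with pytest.raises(ModelError):
            fit_vfd_model(data, _spec(registry, "mortality_28d", **FAST))


class TestClosedFormCrossChecks:
    def test_mortality_matches_contingency_table_odds_ratio(self, registry):
        # 100 dead / 200 alive in the lower arm, 150/150 in the higher arm
        recs = []
        for i in range(300):
            recs.append(
                make_record(f"l{i}", 1, Arm.LOWER_PEEP, vfd=20, died=i < 100)
            )
        for i in range(300):
            recs.append(
                make_record(f"h{i}", 1, Arm.HIGHER_PEEP, vfd=20, died=i < 150)
            )
        data = TrialDataset(recs, 1)
        flat_prior = PriorSpec(
            "mortality_28d", "neutral", 0.0, 10.0, "log_odds_ratio"
        )
        reg, het = registry
        spec = HierarchicalModelSpec(
            outcome="mortality_28d",
            treatment_prior=flat_prior,
            heterogeneity_prior=het,
            tau_fixed=0.0,
            seed=4,
            **{k: v for k, v in FAST.items()},
        )
        res = _quiet(fit_mortality_model, data, spec)
        sample_log_or = np.log((100 / 200) / (150 / 150))
        assert np.median(res.theta) == pytest.approx(sample_log_or, abs=0.08)

    def test_duration_matches_least_squares_mean_difference(self, registry):
        rng = np.random.default_rng(12)
        recs = []
        for i in range(40):
            recs.append(
                make_record(
                    f"l{i}", 1, Arm.LOWER_PEEP, vfd=20,
                    duration=4.0 + 0.3 * rng.standard_normal(),
                )
            )
            recs.append(
                make_record(
                    f"h{i}", 1, Arm.HIGHER_PEEP, vfd=20,
                    duration=5.0 + 0.3 * rng.standard_normal(),
                )
            )
        data = TrialDataset(recs, 1)
        durs = np.array([r.vent_duration_days for r in data.records])
        arms = np.array([r.arm == Arm.LOWER_PEEP for r in data.records])
        ols_md = durs[arms].mean() - durs[~arms].mean()
        flat_prior = PriorSpec(
            "duration", "neutral", 0.0, 10.0, "mean_difference_days"
        )
        reg, het = registry
        spec = HierarchicalModelSpec(
            outcome="duration",
            treatment_prior=flat_prior,
            heterogeneity_prior=het,
            tau_fixed=0.0,
            seed=5,
            **FAST,
        )
        res = _quiet(fit_duration_model, data, spec)
        assert np.mean(res.theta) == pytest.approx(ols_md, abs=0.05)
        assert ols_md == pytest.approx(-1.0, abs=0.2)

    def test_posterior_matches_prior_without_treatment_information(
        self, registry, no_information_dataset
    ):
        spec = _spec(
            registry, "mortality_28d", "neutral",
            n_chains=2, n_warmup=600, n_draws=1000, thin=8,
        )
        res = _quiet(fit_mortality_model, no_information_dataset, spec)
        assert np.mean(res.theta) == pytest.approx(0.0, abs=0.06)
        assert np.std(res.theta) == pytest.approx(0.35, rel=0.10)


class TestPriorInfluence:
    def test_optimistic_prior_never_lowers_probability_of_benefit(self, registry):
        data = simulate_trial(
            SimulationConfig(n_patients=400, n_hospitals=4, seed=21)
        )
        p_ben = {}
        for label in ("pessimistic", "neutral", "optimistic"):
            spec = _spec(registry, "mortality_28d", label, **FAST)
            res = _quiet(fit_mortality_model, data, spec)
            p_ben[label] = float(np.mean(res.theta < 0.0))
        assert p_ben["pessimistic"] <= p_ben["neutral"] + 0.02
        assert p_ben["neutral"] <= p_ben["optimistic"] + 0.02


class TestSubgroupInteraction:
    def test_cutoff_dichotomization(self):
        recs = [
            make_record("a", arm=Arm.LOWER_PEEP, bmi=35.0, apache=90.0),
            make_record("b", arm=Arm.HIGHER_PEEP, bmi=25.0, apache=40.0),
            make_record("c", arm=Arm.LOWER_PEEP, bmi=None, pf_ratio=150.0),
        ]
        data = TrialDataset(recs, 1)
        ind, complete = subgroup_indicator(data, "bmi")
        assert list(ind[:2]) == [1.0, 0.0]
        assert list(complete) == [True, True, False]
        ind, _ = subgroup_indicator(data, "apache")
        assert list(ind[:2]) == [1.0, 0.0]

    def test_constant_indicator_rejected(self, registry):
        recs = [
            make_record(f"p{i}", 1, Arm.LOWER_PEEP if i % 2 else Arm.HIGHER_PEEP,
                        vfd=20, died=i % 3 == 0, duration=None if i % 3 == 0 else 4.0,
                        cardiac_arrest=False)
            for i in range(12)
        ]
        data = TrialDataset(recs, 1)
        spec = _spec(
            registry,
            "mortality_28d",
            interaction_covariate="cardiac_arrest",
            interaction_prior=PriorSpec(
                "mortality_28d", "neutral", 0.0, 1.0, "log_odds_ratio"
            ),
            **FAST,
        )
        with pytest.raises(ModelError, match="constant"):
            _quiet(fit_subgroup_interaction, data, spec)

    def test_empty_cell_named_in_error(self, registry):
        recs = [
            make_record("a", 1, Arm.LOWER_PEEP, vfd=20, died=True, duration=None,
                        cardiac_arrest=True),
            make_record("b", 1, Arm.LOWER_PEEP, vfd=20, cardiac_arrest=False),
            make_record("c", 1, Arm.HIGHER_PEEP, vfd=20, cardiac_arrest=False),
            make_record("d", 1, Arm.HIGHER_PEEP, vfd=20, died=True, duration=None,
                        cardiac_arrest=False),
        ]
        data = TrialDataset(recs, 1)
        spec = _spec(
            registry,
            "mortality_28d",
            interaction_covariate="cardiac_arrest",
            interaction_prior=PriorSpec(
                "mortality_28d", "neutral", 0.0, 1.0, "log_odds_ratio"
            ),
            **FAST,
        )
        with pytest.raises(ModelError, match="empty subgroup cell"):
            _quiet(fit_subgroup_interaction, data, spec)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ModelError, match="unknown subgroup"):
            subgroup_indicator(random_dataset(10), "height")

    def test_interaction_recovery_when_effect_confined_to_subgroup(self, registry):
        # Treatment lowers mortality only among cardiac-arrest patients:
        # the interaction coefficient is log 2 on the harm side for others.
        rng = np.random.default_rng(31)
        n = 4000
        recs = []
        for i in range(n):
            low = i % 2 == 0
            sub = bool(rng.random() < 0.5)
            eta = -0.3 + (np.log(2.0) if (low and sub) else 0.0)
            died = bool(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            recs.append(
                make_record(
                    f"p{i}", 1 + i % 3,
                    Arm.LOWER_PEEP if low else Arm.HIGHER_PEEP,
                    vfd=0 if died else 20, died=died,
                    duration=None if died else 4.0,
                    cardiac_arrest=sub,
                )
            )
        data = TrialDataset(recs, 3)
        spec = _spec(
            registry,
            "mortality_28d",
            interaction_covariate="cardiac_arrest",
            interaction_prior=PriorSpec(
                "mortality_28d", "neutral", 0.0, 2.0, "log_odds_ratio"
            ),
            seed=6,
            **FAST,
        )
        res = _quiet(fit_subgroup_interaction, data, spec)
        med = float(np.median(res.interaction))
        assert np.log(1.4) < med < np.log(2.9)

    def test_missing_covariate_rows_dropped_with_warning(self, registry):
        data = random_dataset(n=60, seed=14)
        data.records[0].bmi = None
        for r in data.records[1:]:
            r.bmi = 25.0 if int(r.patient_id[1:]) % 3 else 32.0
        spec = _spec(
            registry,
            "mortality_28d",
            interaction_covariate="bmi",
            interaction_prior=PriorSpec(
                "mortality_28d", "neutral", 0.0, 1.0, "log_odds_ratio"
            ),
            **FAST,
        )
        with pytest.warns(UserWarning, match="complete-case"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                warnings.filterwarnings("always", message=".*complete-case.*")
                res = fit_subgroup_interaction(data, spec)
        assert res.interaction is not None
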