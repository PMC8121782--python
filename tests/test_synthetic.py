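"""Cohort simulation: reproducibility, marginal fidelity, copula mode and
the closed-form metric oracle."""

import numpy as np
import pytest

from thalscore import (
    GenotypeFrequencyTable,
    Severity,
    SimulationConfig,
    expected_metrics,
    simulate_cohort,
)
from thalscore.errors import ConfigError
from thalscore.evaluation import evaluate_model
from thalscore.risk_score import score_cohort

MILD, MODERATE, SEVERE = Severity.MILD, Severity.MODERATE, Severity.SEVERE


def table_from_probs(probs_by_group, sizes):
    """probs_by_group: {Severity: {snp_id: {genotype: prob}}}."""
    counts = {}
    for group, per_snp in probs_by_group.items():
        for snp_id, genos in per_snp.items():
            for geno, p in genos.items():
                counts.setdefault(snp_id, {}).setdefault(geno, {})[group] = p
    rows = []
    import pandas as pd

    for snp_id, per_geno in counts.items():
        for geno, per_group in per_geno.items():
            row = {"snp_id": snp_id, "genotype": geno}
            for group, p in per_group.items():
                row[group.label] = 100 * p
            rows.append(row)
    frame = pd.DataFrame(rows).set_index(["snp_id", "genotype"]).fillna(0.0)
    return GenotypeFrequencyTable(frame=frame, group_sizes=sizes)


def genotype_codes(cohort, snp_id, score_map):
    return np.array(
        [score_map[p.genotypes[snp_id]] for p in cohort if p.genotypes[snp_id]]
    )


class TestSimulateCohort:
    def test_same_seed_identical_cohort(self, freq_table, system):
        config = SimulationConfig(frequency_table=freq_table, seed=11)
        c1 = simulate_cohort(config, system)
        c2 = simulate_cohort(config, system)
        assert [p.genotypes for p in c1] == [p.genotypes for p in c2]
        assert [p.patient_id for p in c1] == [p.patient_id for p in c2]

    def test_different_seed_differs(self, freq_table, system):
        c1 = simulate_cohort(SimulationConfig(frequency_table=freq_table, seed=1), system)
        c2 = simulate_cohort(SimulationConfig(frequency_table=freq_table, seed=2), system)
        assert [p.genotypes for p in c1] != [p.genotypes for p in c2]

    def test_group_sizes_follow_table_by_default(self, freq_table, system):
        cohort = simulate_cohort(
            SimulationConfig(frequency_table=freq_table, seed=3), system
        )
        assert len(cohort) == 668
        assert cohort.group_sizes() == {MILD: 180, MODERATE: 181, SEVERE: 307}

    def test_no_missingness_by_default(self, freq_table, system):
        cohort = simulate_cohort(
            SimulationConfig(frequency_table=freq_table, seed=4), system
        )
        assert all(g is not None for p in cohort for g in p.genotypes.values())

    def test_missing_rate_applied(self, freq_table, system):
        cohort = simulate_cohort(
            SimulationConfig(frequency_table=freq_table, seed=5, missing_rate=0.2),
            system,
        )
        calls = [g for p in cohort for g in p.genotypes.values()]
        frac = sum(g is None for g in calls) / len(calls)
        assert 0.15 < frac < 0.25

    def test_degenerate_marginals(self, system):
        table = table_from_probs(
            {MILD: {"rs766432": {"AA": 1.0, "AC": 0.0, "CC": 0.0}}},
            {MILD: 25},
        )
        cohort = simulate_cohort(
            SimulationConfig(frequency_table=table, seed=6), system
        )
        assert all(p.genotypes["rs766432"] == "AA" for p in cohort)

    def test_marginals_recovered_at_large_n(self, freq_table, system):
        """Empirical per-group genotype frequencies sit inside 3-sigma
        binomial bands of the configured marginals at n ~ 1e5."""
        sizes = {g: 150 * n for g, n in freq_table.group_sizes.items()}
        cohort = simulate_cohort(
            SimulationConfig(frequency_table=freq_table, group_sizes=sizes, seed=9),
            system,
        )
        by_group = {g: [p for p in cohort if p.severity == g] for g in sizes}
        for snp_id in freq_table.snp_ids:
            for group, n in sizes.items():
                pct = freq_table.percentages(snp_id, group)
                emp = {g: 0 for g in pct}
                for p in by_group[group]:
                    emp[p.genotypes[snp_id]] += 1
                for geno, percent in pct.items():
                    p_target = percent / 100
                    band = 3 * np.sqrt(p_target * (1 - p_target) / n)
                    assert abs(emp[geno] / n - p_target) <= band + 1e-12

    def test_study_sized_cohort_within_99pct_bands(self, freq_table, system):
        """At the study's own group sizes (180/181/307, seed 7) every
        per-group per-SNP genotype frequency lands inside the 99% binomial
        band around its configured marginal."""
        cohort = simulate_cohort(
            SimulationConfig(frequency_table=freq_table, seed=7), system
        )
        by_group = {g: [p for p in cohort if p.severity == g]
                    for g in freq_table.group_sizes}
        z99 = 2.5758293035489004
        for snp_id in freq_table.snp_ids:
            for group, n in freq_table.group_sizes.items():
                pct = freq_table.percentages(snp_id, group)
                emp = {g: 0 for g in pct}
                for p in by_group[group]:
                    emp[p.genotypes[snp_id]] += 1
                for geno, percent in pct.items():
                    p_target = percent / 100
                    band = z99 * np.sqrt(p_target * (1 - p_target) / n)
                    assert abs(emp[geno] / n - p_target) <= band + 1e-12

    def test_invalid_config_rejected(self, freq_table):
        with pytest.raises(ConfigError):
            SimulationConfig(frequency_table=freq_table, missing_rate=1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(frequency_table=freq_table, joint_mode="chain")
        with pytest.raises(ConfigError):
            SimulationConfig(
                frequency_table=freq_table, group_sizes={MILD: 0, SEVERE: 5}
            )

    def test_frequencies_not_summing_rejected(self, system):
        table = table_from_probs(
            {MILD: {"rs766432": {"AA": 0.6, "AC": 0.3, "CC": 0.1}}},
            {MILD: 10},
        )
        # corrupt after construction to bypass the read-time check
        table.frame.loc[("rs766432", "AA"), "mild"] = 80.0
        with pytest.raises(ConfigError):
            simulate_cohort(
                SimulationConfig(frequency_table=table, seed=1), system
            )


class TestCopulaMode:
    def test_zero_correlation_matches_independent_statistically(
        self, freq_table, system
    ):
        n = {g: 4000 for g in freq_table.group_sizes}
        ind = simulate_cohort(
            SimulationConfig(frequency_table=freq_table, group_sizes=n, seed=21),
            system,
        )
        cop = simulate_cohort(
            SimulationConfig(
                frequency_table=freq_table, group_sizes=n, seed=22,
                joint_mode="copula", copula_correlation=0.0,
            ),
            system,
        )
        for snp in system.snps:
            a = genotype_codes(ind, snp.snp_id, dict(snp.score_map))
            b = genotype_codes(cop, snp.snp_id, dict(snp.score_map))
            assert abs(a.mean() - b.mean()) < 0.05

    def test_positive_correlation_couples_snp_scores(self, freq_table, system):
        n = {g: 4000 for g in freq_table.group_sizes}
        cop = simulate_cohort(
            SimulationConfig(
                frequency_table=freq_table, group_sizes=n, seed=23,
                joint_mode="copula", copula_correlation=0.8,
            ),
            system,
        )
        s1 = genotype_codes(cop, "rs766432", dict(system.snp("rs766432").score_map))
        s2 = genotype_codes(cop, "rs9399137", dict(system.snp("rs9399137").score_map))
        r = np.corrcoef(s1, s2)[0, 1]
        assert r > 0.3

    def test_copula_preserves_marginals(self, freq_table, system):
        sizes = {SEVERE: 40000}
        cohort = simulate_cohort(
            SimulationConfig(
                frequency_table=freq_table, group_sizes=sizes, seed=24,
                joint_mode="copula", copula_correlation=0.6,
            ),
            system,
        )
        pct = freq_table.percentages("rs72872548", SEVERE)
        emp = {g: 0 for g in pct}
        for p in cohort:
            emp[p.genotypes["rs72872548"]] += 1
        for geno, percent in pct.items():
            p_target = percent / 100
            band = 4 * np.sqrt(p_target * (1 - p_target) / sizes[SEVERE])
            assert abs(emp[geno] / sizes[SEVERE] - p_target) <= band


class TestExpectedMetrics:
    def test_separable_marginals_are_perfectly_classified(self, system):
        hi = {"rs766432": {"AA": 1.0}, "rs9399137": {"TT": 1.0},
              "rs72872548": {"CC": 1.0}}
        lo = {"rs766432": {"CC": 1.0}, "rs9399137": {"CC": 1.0},
              "rs72872548": {"AA": 1.0}}
        table = table_from_probs(
            {MILD: lo, MODERATE: lo, SEVERE: hi},
            {MILD: 10, MODERATE: 10, SEVERE: 10},
        )
        config = SimulationConfig(frequency_table=table)
        for model in system.models:
            em = expected_metrics(config, model, "pessimistic", system)
            assert em.sensitivity == pytest.approx(1.0)
            assert em.specificity == pytest.approx(1.0)

    def test_uniform_marginals_accuracy_is_one_third(self, system):
        """With identical uniform marginals in all groups the predicted
        class is independent of the true class, so three equally sized
        groups give accuracy exactly 1/3 whatever the binning."""
        uniform = {
            snp.snp_id: {g: 1 / 3 for g in snp.genotypes} for snp in system.snps
        }
        table = table_from_probs(
            {MILD: uniform, MODERATE: uniform, SEVERE: uniform},
            {MILD: 30, MODERATE: 30, SEVERE: 30},
        )
        config = SimulationConfig(frequency_table=table)
        for model in system.models:
            em = expected_metrics(config, model, "pessimistic", system)
            assert em.accuracy == pytest.approx(1 / 3, abs=1e-12)

    def test_frozen_regression_value(self, freq_table, system):
        """Exact enumeration on the published marginals, model 3,
        pessimistic policy (value frozen from this enumeration)."""
        config = SimulationConfig(frequency_table=freq_table)
        em = expected_metrics(config, system.model("model3"), "pessimistic", system)
        assert em.sensitivity == pytest.approx(0.2154388876, abs=1e-9)
        assert em.specificity == pytest.approx(0.9316473744, abs=1e-9)
        assert em.accuracy == pytest.approx(0.3783891610, abs=1e-9)

    def test_copula_mode_unsupported(self, freq_table, system):
        config = SimulationConfig(frequency_table=freq_table, joint_mode="copula")
        with pytest.raises(ConfigError):
            expected_metrics(config, system.model("model1"), "pessimistic", system)

    def test_monte_carlo_converges_to_enumeration(self, freq_table, system):
        """Simulation + evaluation agrees with the closed form within
        3 standard errors at a moderately large n."""
        sizes = {g: 30 * n for g, n in freq_table.group_sizes.items()}
        config = SimulationConfig(
            frequency_table=freq_table, group_sizes=sizes, seed=31
        )
        cohort = simulate_cohort(config, system)
        scored, _ = score_cohort(cohort, system)
        n_sev = sizes[SEVERE]
        n_not = sizes[MILD] + sizes[MODERATE]
        n_all = n_sev + n_not
        for model in system.models:
            em = expected_metrics(config, model, "pessimistic", system)
            ev = evaluate_model(scored, cohort, model, policy="pessimistic")
            for got, exp, n in [
                (ev.sensitivity, em.sensitivity, n_sev),
                (ev.specificity, em.specificity, n_not),
                (ev.accuracy, em.accuracy, n_all),
            ]:
                se = np.sqrt(exp * (1 - exp) / n)
                assert abs(got - exp) <= 3 * se + 1e-12
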