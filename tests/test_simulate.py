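"""Clonal-lineage simulator: determinism, event semantics, rate recovery."""

import numpy as np
import pytest

from limerad import (
    LineageBranch,
    SimParams,
    classify_matrix,
    default_lineage_tree,
    estimate_rates,
    paperlike_params,
    simulate,
)


def _params(loh=0.0, mut=0.0, **kwargs):
    defaults = dict(n_sites=2000, p_het=0.5, seed=123)
    defaults.update(kwargs)
    return SimParams(branches=default_lineage_tree(loh=loh, mut=mut), **defaults)


class TestDeterminism:
    def test_identical_seed_identical_result(self):
        p = paperlike_params(n_sites=3000, seed=77)
        r1, r2 = simulate(p), simulate(p)
        assert r1.matrix == r2.matrix
        assert (r1.truth["founder"] == r2.truth["founder"]).all()
        assert (r1.truth["true_category"] == r2.truth["true_category"]).all()

    def test_different_seed_differs(self):
        a = simulate(paperlike_params(n_sites=3000, seed=1))
        b = simulate(paperlike_params(n_sites=3000, seed=2))
        assert a.matrix != b.matrix


class TestEventModel:
    def test_no_event_limit_is_pure_category_a(self, partition):
        res = simulate(_params())
        # every tip identical to the founder
        for acc in res.matrix.accession_ids:
            assert (res.matrix.column(acc) == res.truth["founder"]).all()
        report, _ = classify_matrix(res.matrix, partition)
        n_founder_het = int(np.isin(res.truth["founder"], list("MRWSYK")).sum())
        assert report.counts["A"] == n_founder_het
        assert sum(report.counts.values()) == report.counts["A"]

    def test_certain_loh_on_cluster2_ancestor_gives_pure_c(self, partition):
        res = simulate(_params(loh={"indonesian_ancestor": 1.0}))
        report, _ = classify_matrix(res.matrix, partition)
        assert report.counts["C"] > 0
        assert sum(report.counts.values()) == report.counts["C"]
        assert estimate_rates(res, report)["r_loh_cluster2"] == 1.0

    def test_noise_free_truth_categories_match_classification(self, partition):
        res = simulate(paperlike_params(n_sites=4000, seed=5))
        # rebuild with the same inherited events but no observation noise
        p = res.params
        clean = SimParams(
            n_sites=p.n_sites, p_het=p.p_het, branches=p.branches,
            r_dropout=0.0, e_error=0.0, seed=p.seed,
        )
        res_clean = simulate(clean)
        report, _ = classify_matrix(res_clean.matrix, partition)
        truth = res_clean.truth["true_category"]
        assert (truth[report.kept_sites] == report.per_site).all()
        assert (truth == ".").sum() == p.n_sites - len(report.kept_sites)

    def test_founder_het_fraction_near_p_het(self):
        p = _params(n_sites=20_000, p_het=0.37, seed=9)
        res = simulate(p)
        frac = np.isin(res.truth["founder"], list("MRWSYK")).mean()
        se = np.sqrt(0.37 * 0.63 / p.n_sites)
        assert abs(frac - 0.37) < 3 * se

    def test_dropout_shifts_mass_toward_derived_hom_classes(self, partition):
        # dropout resolves single tips' hets, producing within-cluster
        # het/hom mixtures: the E/F/G/H classes grow at A/C/D's expense
        def efgh_mass(r_dropout, seed):
            p = _params(
                loh={"bhutanese_ancestor": 0.2, "indonesian_ancestor": 0.2},
                n_sites=4000,
                r_dropout=r_dropout,
                seed=seed,
            )
            report, _ = classify_matrix(simulate(p).matrix, partition)
            return sum(report.counts[c] for c in "EFGH")

        seeds = [11, 12, 13, 14, 15]
        means = [
            np.mean([efgh_mass(r, s) for s in seeds]) for r in (0.0, 0.05, 0.2)
        ]
        assert means[0] < means[1] < means[2]

    def test_tract_mode_runs_and_is_deterministic(self):
        p = _params(
            loh={"indonesian_ancestor": 0.3},
            loh_mode="tract",
            tract_mean_length=50.0,
            seed=21,
        )
        r1, r2 = simulate(p), simulate(p)
        assert r1.matrix == r2.matrix
        # tract LOH still only resolves heterozygous founder sites
        hom_founder = ~np.isin(r1.truth["founder"], list("MRWSYK"))
        for acc in r1.matrix.accession_ids:
            assert (
                r1.matrix.column(acc)[hom_founder] == r1.truth["founder"][hom_founder]
            ).all()


class TestRateRecovery:
    def test_planted_rate_recovered_within_binomial_error(self, partition):
        rate = 0.2
        p = _params(loh={"indonesian_ancestor": rate}, n_sites=20_000, seed=31)
        res = simulate(p)
        report, _ = classify_matrix(res.matrix, partition)
        est = estimate_rates(res, report)
        n = report.counts["A"] + report.counts["C"]
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(est["r_loh_cluster2"] - rate) < 3 * se
        assert not est["r_loh_cluster2_undefined"]

    def test_zero_rates_estimate_zero(self, partition):
        res = simulate(_params())
        report, _ = classify_matrix(res.matrix, partition)
        est = estimate_rates(res, report)
        assert est["r_loh_cluster2"] == 0.0
        assert est["r_loh_cluster1"] == 0.0

    def test_zero_denominator_flagged(self, partition):
        # all-hom founder: no A or C sites at all
        res = simulate(_params(p_het=0.0, mut=0.0))
        report, _ = classify_matrix(res.matrix, partition)
        est = estimate_rates(res, report)
        assert est["r_loh_cluster2_undefined"]
        assert np.isnan(est["r_loh_cluster2"])


class TestValidation:
    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            LineageBranch("founder", "x", r_loh=1.5)
        with pytest.raises(ValueError):
            SimParams(n_sites=10, p_het=-0.1, branches=default_lineage_tree())

    def test_second_root_rejected(self):
        bad = default_lineage_tree() + [LineageBranch("ghost", "orphan")]
        with pytest.raises(ValueError, match="rooted"):
            SimParams(n_sites=10, p_het=0.5, branches=bad)

    def test_cycle_rejected(self):
        bad = default_lineage_tree() + [
            LineageBranch("x", "y"),
            LineageBranch("y", "x"),
        ]
        with pytest.raises(ValueError, match="unreachable"):
            SimParams(n_sites=10, p_het=0.5, branches=bad)

    def test_duplicate_child_rejected(self):
        bad = default_lineage_tree() + [LineageBranch("founder", "Bhutan-09015")]
        with pytest.raises(ValueError, match="one parent"):
            SimParams(n_sites=10, p_het=0.5, branches=bad)
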