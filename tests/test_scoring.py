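"""Kernel score correctness, limits, monotonicity, and detection summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gbmcaf import (
    ASTROCYTE_PANEL,
    CAF_PANEL,
    MarkerPanel,
    SimulationConfig,
    astrocyte_probability,
    gaussian_kernel,
    high_score_cutoff,
    log_normalize,
    marker_prevalence,
    negative_selection,
    panel_coverage,
    panel_probability,
    simulate_counts,
)
from gbmcaf.exceptions import GeneLookupError, PanelError, ParameterError

from conftest import make_counts, make_norm


def oracle_score(pos_u, neg_u, h):
    """Independent straight-line transcription of the score formula."""
    n = len(pos_u) + len(neg_u)
    s = 0.0
    for u in pos_u:
        s += 1.0 - math.exp(-(u * u) / (2.0 * h * h))
    for u in neg_u:
        s += math.exp(-(u * u) / (2.0 * h * h))
    return min(1.0, max(0.0, s / n))


class TestKernel:
    def test_closed_forms(self):
        assert gaussian_kernel(0.0, 1.0) == pytest.approx(1.0, abs=1e-12)
        assert gaussian_kernel(2.0, 2.0) == pytest.approx(math.exp(-0.5), abs=1e-12)
        assert gaussian_kernel(4.0, 1.0) == pytest.approx(math.exp(-8.0), abs=1e-12)

    def test_strictly_decreasing_in_magnitude(self):
        u = np.linspace(0, 5, 50)
        k = gaussian_kernel(u, 1.3)
        assert np.all(np.diff(k) < 0)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_kernel(1.0, 0.0)


class TestPanelProbability:
    @given(
        us=st.lists(st.floats(0, 8), min_size=1, max_size=3),
        h=st.floats(0.2, 3.0),
        n_pos=st.integers(0, 3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_independent_oracle_small_panels(self, us, h, n_pos):
        n_pos = min(n_pos, len(us))
        pos = [f"P{i}" for i in range(n_pos)]
        neg = [f"N{i}" for i in range(len(us) - n_pos)]
        if not pos:
            pos, neg = ["P0"], neg[:-1]
            us = us[:1] + us[1:]
        panel = MarkerPanel("t", positives=pos, negatives=neg)
        data = {g: [u] for g, u in zip(pos + neg, us)}
        res = panel_probability(make_norm(data), panel, h=h)
        expected = oracle_score(us[: len(pos)], us[len(pos):], h)
        assert res.p.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_cell_scores_five_fourteenths(self):
        data = {g: [0.0] for g in CAF_PANEL.positives + CAF_PANEL.negatives}
        res = panel_probability(make_norm(data), CAF_PANEL)
        assert res.p.iloc[0] == pytest.approx(5.0 / 14.0, abs=1e-12)
        assert res.n == 14

    def test_saturated_positives_score_one(self):
        data = {g: [50.0] for g in CAF_PANEL.positives}
        data.update({g: [0.0] for g in CAF_PANEL.negatives})
        res = panel_probability(make_norm(data), CAF_PANEL)
        assert res.p.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_saturated_negatives_score_zero(self):
        data = {g: [0.0] for g in CAF_PANEL.positives}
        data.update({g: [50.0] for g in CAF_PANEL.negatives})
        res = panel_probability(make_norm(data), CAF_PANEL)
        assert res.p.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_genes_dropped_and_n_reduced(self):
        data = {"ACTA2": [1.0], "PTPRC": [0.0]}
        with pytest.warns(UserWarning, match="absent"):
            res = panel_probability(make_norm(data), CAF_PANEL)
        assert res.n == 2
        assert len(res.missing_genes) == 12

    def test_no_panel_gene_present_raises(self):
        with pytest.raises(PanelError):
            panel_probability(make_norm({"OTHER": [1.0]}), CAF_PANEL)

    def test_monotone_in_positive_and_negative_markers(self):
        base = {g: [1.0] for g in CAF_PANEL.positives + CAF_PANEL.negatives}
        p0 = panel_probability(make_norm(base), CAF_PANEL).p.iloc[0]
        up = dict(base, ACTA2=[2.0])
        assert panel_probability(make_norm(up), CAF_PANEL).p.iloc[0] > p0
        up_neg = dict(base, PTPRC=[2.0])
        assert panel_probability(make_norm(up_neg), CAF_PANEL).p.iloc[0] < p0

    def test_invariant_to_gene_permutation_and_outside_genes(self):
        rng = np.random.default_rng(0)
        vals = {g: list(rng.uniform(0, 3, 4)) for g in CAF_PANEL.positives + CAF_PANEL.negatives}
        p1 = panel_probability(make_norm(vals), CAF_PANEL).p
        shuffled = dict(reversed(list(vals.items())))
        shuffled["IRRELEVANT"] = [9.0, 9.0, 9.0, 9.0]
        p2 = panel_probability(make_norm(shuffled), CAF_PANEL).p
        assert np.allclose(p1.values, p2.values, atol=1e-12)

    def test_bandwidth_limits(self):
        rng = np.random.default_rng(1)
        vals = {g: list(rng.uniform(0.5, 3, 5)) for g in CAF_PANEL.positives + CAF_PANEL.negatives}
        norm = make_norm(vals)
        # h -> inf: every kernel -> 1, so p -> |negatives| / n
        p_inf = panel_probability(norm, CAF_PANEL, h=1e9).p
        assert np.allclose(p_inf.values, 5.0 / 14.0, atol=1e-9)
        # h -> 0+: kernel becomes the zero/nonzero indicator
        rng2 = np.random.default_rng(2)
        vals_zero = {}
        for g in vals:
            v = rng2.uniform(0.5, 3, 5)
            v[rng2.random(5) < 0.5] = 0.0
            vals_zero[g] = list(v)
        norm0 = make_norm(vals_zero)
        p_small = panel_probability(norm0, CAF_PANEL, h=1e-6).p
        pos_nonzero = np.array([[vals_zero[g][i] != 0 for g in CAF_PANEL.positives] for i in range(5)])
        neg_zero = np.array([[vals_zero[g][i] == 0 for g in CAF_PANEL.negatives] for i in range(5)])
        expected = (pos_nonzero.sum(axis=1) + neg_zero.sum(axis=1)) / 14.0
        assert np.allclose(p_small.values, expected, atol=1e-9)

    def test_caf_score_separates_planted_cafs(self, default_run):
        pytest.importorskip("sklearn")
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score((default_run.truth == "CAF").to_numpy(), default_run.scores.p.values)
        assert auc >= 0.95


class TestAstrocyteScore:
    def test_all_positive_panel_limits(self):
        zero = make_norm({g: [0.0] for g in ASTROCYTE_PANEL.positives})
        assert astrocyte_probability(zero).p.iloc[0] == pytest.approx(0.0, abs=1e-12)
        sat = make_norm({g: [50.0] for g in ASTROCYTE_PANEL.positives})
        assert astrocyte_probability(sat).p.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_no_cell_high_in_both_caf_and_astrocyte_scores(self):
        cfg = SimulationConfig(
            n_cells=1500,
            population_fractions={"CAF": 0.5, "astrocyte": 0.5},
            seed=13,
        )
        lab = simulate_counts(cfg)
        norm = log_normalize(lab.counts)
        caf_p = panel_probability(norm, CAF_PANEL).p.values
        astro_p = astrocyte_probability(norm).p.values
        top_caf = caf_p >= np.quantile(caf_p, 0.9)
        top_astro = astro_p >= np.quantile(astro_p, 0.9)
        assert not np.any(top_caf & top_astro)


class TestNegativeSelection:
    def test_single_detection_excludes(self):
        m = make_counts({"EPCAM": [1, 0], "PECAM1": [0, 0], "CSPG4": [0, 0], "PTPRC": [0, 0]})
        res = negative_selection(m)
        assert list(res.retained) == [False, True]
        assert res.exclusion_tally["EPCAM"] == 1

    def test_absent_gene_skipped_with_warning(self):
        m = make_counts({"EPCAM": [0, 1]})
        with pytest.warns(UserWarning, match="skipped"):
            res = negative_selection(m)
        assert res.missing_genes == ["PECAM1", "CSPG4", "PTPRC"]

    def test_planted_contaminants_retention_matches_binomial_oracle(self):
        fractions = {"CAF": 0.75, "epithelial_immune": 0.08, "endothelial": 0.08, "pericyte": 0.09}
        lab = simulate_counts(SimulationConfig(n_cells=2000, population_fractions=fractions, seed=9))
        res = negative_selection(lab.counts)
        lo, hi = stats.binom.interval(0.99, 2000, 0.75)
        # contaminant markers are near-saturated at the default fold, so the
        # retained count tracks the planted CAF count
        assert lo <= res.retained.sum() <= hi


class TestPrevalenceAndCoverage:
    def test_trivial_prevalences(self):
        m = make_counts({"ACTA2": [0, 0, 0]})
        assert marker_prevalence(m, "ACTA2") == 0.0
        m2 = make_counts({"ACTA2": [1, 3, 2]})
        assert marker_prevalence(m2, "ACTA2") == 1.0

    def test_absent_gene_is_lookup_error(self):
        with pytest.raises(GeneLookupError):
            marker_prevalence(make_counts({"A": [1]}), "ACTA2")

    def test_prevalence_matches_analytic_detection_oracle(self):
        cfg = SimulationConfig(n_cells=1500, seed=17)
        lab = simulate_counts(cfg)
        caf = (lab.truth_labels == "CAF").to_numpy()
        observed = marker_prevalence(lab.counts, "ACTA2", within=caf)
        # independent Monte Carlo of the generator's law for one marker gene
        rng = np.random.default_rng(99_999)
        mu_ln, sg = cfg.depth_lognormal_mu_sigma
        depth = rng.lognormal(mu_ln, sg, 20000)
        mito = rng.beta(*cfg.mito_fraction_beta_params, 20000)
        n_caf_markers = len(cfg.marker_assignments["CAF"])
        n_regular = 2000 - sum(len(v) for v in cfg.marker_assignments.values())
        total_w = n_regular * cfg.baseline_mean + n_caf_markers * cfg.baseline_mean * cfg.marker_fold_change
        mu = depth * (1 - mito) * cfg.baseline_mean * cfg.marker_fold_change / total_w
        r = 1.0 / cfg.nb_dispersion
        expected = 1.0 - np.mean((r / (r + mu)) ** r)
        assert observed == pytest.approx(expected, abs=0.02)

    def test_single_gene_coverage_reduces_to_prevalence(self):
        m = make_counts({"ACTA2": [1, 0, 2]})
        assert panel_coverage(m, ["ACTA2"]) == marker_prevalence(m, "ACTA2")

    def test_coverage_dominates_best_single_prevalence(self, default_run):
        m = default_run.matrix
        cov = panel_coverage(m, CAF_PANEL.positives)
        best = max(marker_prevalence(m, g) for g in CAF_PANEL.positives)
        assert cov >= best

    def test_all_zero_matrix_coverage_zero(self):
        m = make_counts({"ACTA2": [0, 0], "FAP": [0, 0]})
        assert panel_coverage(m, ["ACTA2", "FAP"]) == 0.0


class TestHighScoreCutoff:
    def test_fixed_cutoff_flags(self, default_run):
        res = high_score_cutoff(default_run.scores, "fixed", 0.6)
        caf_truth = (default_run.truth == "CAF").to_numpy()
        flagged = res.mask
        precision = caf_truth[flagged].mean()
        recall = flagged[caf_truth].mean()
        assert precision >= 0.90 and recall >= 0.90

    def test_quantile_and_tie_semantics(self):
        import pandas as pd

        from gbmcaf.scoring import ScoreResult

        scores = ScoreResult(p=pd.Series([0.2, 0.7]), n=14, bandwidth=1.0)
        fixed = high_score_cutoff(scores, "fixed", 0.6)
        assert fixed.mask.sum() == 1
        sym = ScoreResult(p=pd.Series([0.1, 0.1, 0.9, 0.9]), n=14, bandwidth=1.0)
        q = high_score_cutoff(sym, "quantile", 0.5)
        assert q.mask.sum() == 2  # ties broken toward flagging

    def test_bad_quantile_rejected(self):
        import pandas as pd

        from gbmcaf.scoring import ScoreResult

        scores = ScoreResult(p=pd.Series([0.5]), n=14, bandwidth=1.0)
        with pytest.raises(ParameterError):
            high_score_cutoff(scores, "quantile", 1.5)
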