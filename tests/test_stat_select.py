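"""Data-driven selectors: oracle-backed properties and sample-mode behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from confsel import (
    CausalDAG,
    CITestBackend,
    DagGenSpec,
    LinearSEM,
    backward_select,
    change_in_estimate_select,
    forward_select,
    hdps_rank,
    hdps_score,
    is_valid_adjustment_set,
    make_figure_dag,
    random_dag,
    random_sem,
    sample_dataset,
    split_sample_estimate,
    true_total_effect,
)
from confsel.stat_select import InsufficientSampleError, POST_SELECTION_WARNING


def fig3_with_isolated_covariate():
    return CausalDAG(
        {"A", "Y", "C", "U", "X"},
        [("U", "A"), ("U", "C"), ("C", "Y"), ("A", "Y")],
        "A",
        "Y",
        latent={"U"},
    )


def rct_binary_data(n=100_000, seed=3):
    """Randomized exposure, prognostic binary covariate, logistic outcome."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    c = rng.integers(0, 2, n)
    y = (rng.random(n) < expit(-1.0 + 1.0 * a + 2.0 * c)).astype(int)
    return pd.DataFrame({"A": a, "C": c, "Y": y})


class TestBackend:
    def test_exactly_one_source(self, fig3):
        with pytest.raises(ValueError):
            CITestBackend()
        with pytest.raises(ValueError):
            CITestBackend(data=pd.DataFrame({"A": [1.0]}), dag=fig3)

    def test_oracle_mode_answers_by_d_separation(self, fig3):
        backend = CITestBackend(dag=fig3)
        assert not backend.independent("C", "Y", ["A"])
        assert backend.independent("C", "Y", ["A"]) is False

    def test_sample_mode_recovers_population_independence(self):
        sem = LinearSEM.with_unit_parameters(make_figure_dag("fig1"))
        df = sample_dataset(sem, n=20_000, seed=1)
        rng = np.random.default_rng(2)
        df["X"] = rng.normal(size=len(df))  # independent of everything
        backend = CITestBackend(data=df)
        assert backend.independent("X", "Y", ["A", "C"])
        assert not backend.independent("C", "Y", ["A"])


class TestBackwardSelect:
    def test_oracle_drops_isolated_covariate(self):
        run = backward_select(fig3_with_isolated_covariate(), ["C", "X"])
        assert run.selected == ("C",)
        assert POST_SELECTION_WARNING in run.warnings

    def test_everything_kept_when_all_parents_of_outcome(self):
        dag = CausalDAG(
            {"A", "Y", "C1", "C2"},
            [("C1", "Y"), ("C2", "Y"), ("C1", "A"), ("A", "Y")],
            "A",
            "Y",
        )
        run = backward_select(dag, ["C1", "C2"])
        assert set(run.selected) == {"C1", "C2"}

    def test_empty_candidates(self, fig3):
        assert backward_select(fig3, []).selected == ()

    def test_sample_size_guard(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 4)),
                          columns=["A", "Y", "C1", "C2"])
        with pytest.raises(InsufficientSampleError):
            backward_select(df, ["C1", "C2"])

    def test_sufficiency_under_the_oracle(self):
        """Full set valid ⇒ backward-selected set valid (oracle backend)."""
        kept = 0
        for seed in range(400):
            dag = random_dag(DagGenSpec(n_measured=4, n_latent=1, seed=seed))
            cov = sorted(dag.measured_covariates)
            if not bool(is_valid_adjustment_set(dag, cov)):
                continue
            run = backward_select(dag, cov)
            assert bool(is_valid_adjustment_set(dag, run.selected)), (seed, run)
            kept += 1
        assert kept >= 100


class TestForwardSelect:
    def test_oracle_fig3(self, fig3):
        assert forward_select(fig3, ["C"]).selected == ("C",)

    def test_mbias_covariate_admitted_marginally(self, fig2):
        # L is associated with Y given A (open path L <- U2 -> Y), so forward
        # selection admits it; sufficiency needs the *full* candidate set to
        # be sufficient, which {L} on this graph is not.
        assert forward_select(fig2, ["L"]).selected == ("L",)

    def test_empty_candidates(self, fig3):
        assert forward_select(fig3, []).selected == ()

    def test_input_order_is_respected(self):
        dag = CausalDAG(
            {"A", "Y", "C1", "C2"},
            [("C1", "A"), ("C1", "Y"), ("C2", "A"), ("C2", "Y"), ("A", "Y")],
            "A",
            "Y",
        )
        run = forward_select(dag, ["C2", "C1"])
        assert run.selected[0] == "C2"

    def test_sufficiency_under_the_oracle(self):
        kept = 0
        for seed in range(400):
            dag = random_dag(DagGenSpec(n_measured=4, n_latent=1, seed=seed))
            cov = sorted(dag.measured_covariates)
            if not bool(is_valid_adjustment_set(dag, cov)):
                continue
            run = forward_select(dag, cov)
            assert bool(is_valid_adjustment_set(dag, run.selected)), (seed, run)
            kept += 1
        assert kept >= 100

    def test_sample_mode_agrees_with_oracle_at_large_n(self):
        """Finite-sample backward selection converges on the oracle answer.

        Agreement tends to 1 only if the test level shrinks: at fixed alpha a
        residual alpha-sized false-retention rate remains no matter how large
        n is, so the large-n check runs at alpha = 0.01.
        """
        dag = fig3_with_isolated_covariate()
        sem = LinearSEM.with_unit_parameters(dag)
        oracle = backward_select(dag, ["C", "X"]).selected
        agree = 0
        reps = 200
        for rep in range(reps):
            df = sample_dataset(sem, n=100_000, seed=10_000 + rep)
            run = backward_select(df, ["C", "X"], alpha=0.01)
            agree += run.selected == oracle
        assert agree / reps >= 0.95


class TestChangeInEstimate:
    def test_strong_confounder_retained(self):
        sem = LinearSEM.with_unit_parameters(make_figure_dag("fig1"))
        df = sample_dataset(sem, n=100_000, seed=0)
        run = change_in_estimate_select(df, ["C"])
        assert run.selected == ("C",)

    def test_irrelevant_covariate_dropped(self):
        sem = LinearSEM.with_unit_parameters(make_figure_dag("fig1"))
        df = sample_dataset(sem, n=50_000, seed=1)
        df["X"] = np.random.default_rng(9).normal(size=len(df))
        run = change_in_estimate_select(df, ["C", "X"])
        assert run.selected == ("C",)

    def test_infinite_threshold_never_retains(self):
        sem = LinearSEM.with_unit_parameters(make_figure_dag("fig1"))
        df = sample_dataset(sem, n=5_000, seed=2)
        run = change_in_estimate_select(df, ["C"], threshold=math.inf)
        assert run.selected == ()

    def test_or_scale_flags_nonconfounder_difference_scale_does_not(self):
        """Non-collapsibility: in a randomized design with a strong logistic
        covariate the OR-scale rule keeps the covariate; the linear
        (risk-difference) scale drops it."""
        df = rct_binary_data()
        on_or = change_in_estimate_select(df, ["C"], scale="or")
        assert on_or.selected == ("C",)
        assert any(w[0] == "noncollapsibility" for w in on_or.warnings)
        on_rd = change_in_estimate_select(df, ["C"], scale="difference")
        assert on_rd.selected == ()


class TestHdps:
    @pytest.mark.parametrize(
        "p1, p0, rr, expected",
        [
            (0.3, 0.3, 5.0, 1.0),  # equal prevalence
            (0.6, 0.1, 1.0, 1.0),  # no outcome association
            (0.5, 0.2, 2.0, 1.25),  # hand arithmetic
        ],
    )
    def test_score_formula(self, p1, p0, rr, expected):
        assert hdps_score(p1, p0, rr) == pytest.approx(expected, abs=1e-12)

    def test_score_monotone_in_rr(self):
        scores = [hdps_score(0.5, 0.2, rr) for rr in (1.5, 2.0, 4.0, 8.0)]
        assert scores == sorted(scores)

    def test_ranking_and_selection(self):
        rng = np.random.default_rng(4)
        n = 20_000
        conf = rng.integers(0, 2, n)  # strong confounder
        noise = rng.integers(0, 2, n)  # unrelated
        a = (rng.random(n) < np.where(conf == 1, 0.7, 0.3)).astype(int)
        y = (rng.random(n) < np.where(conf == 1, 0.5, 0.1)).astype(int)
        df = pd.DataFrame({"A": a, "Y": y, "conf": conf, "noise": noise})
        rank = hdps_rank(df, ["noise", "conf"], fraction=0.5)
        assert rank.rows[0].covariate == "conf"
        assert rank.selected == ("conf",)

    def test_forced_in_appended(self):
        df = rct_binary_data(n=5_000, seed=8)
        rank = hdps_rank(df, ["C"], forced_in=["C", "age"])
        assert "age" in rank.selected

    def test_zero_cell_continuity_correction(self):
        df = pd.DataFrame(
            {"A": [0, 0, 1, 1], "Y": [0, 0, 1, 1], "C": [0, 0, 1, 1]}
        )
        rank = hdps_rank(df, ["C"], fraction=1.0)
        assert rank.rows[0].corrected
        assert math.isfinite(rank.rows[0].score)

    def test_ranking_invariant_to_relabeling(self):
        df = rct_binary_data(n=5_000, seed=12)
        df["D"] = df["C"]
        r1 = hdps_rank(df, ["C"], fraction=1.0)
        r2 = hdps_rank(df.rename(columns={"C": "Q", "D": "C"}), ["C"], fraction=1.0)
        assert r1.rows[0].score == pytest.approx(r2.rows[0].score)


class TestSplitSample:
    def selector(self, df):
        return backward_select(df, ["C", "X"]).selected

    def make_data(self, n, seed):
        dag = fig3_with_isolated_covariate()
        df = sample_dataset(LinearSEM.with_unit_parameters(dag), n=n, seed=seed)
        return df.rename(columns={"X": "X"})

    def test_determinism(self):
        df = self.make_data(2_000, 0)
        out1 = split_sample_estimate(df, self.selector, seed=5)
        out2 = split_sample_estimate(df, self.selector, seed=5)
        assert out1 == out2
        assert out1 != split_sample_estimate(df, self.selector, seed=6)

    def test_estimate_within_three_se_of_truth(self):
        dag = fig3_with_isolated_covariate()
        sem = LinearSEM.with_unit_parameters(dag)
        df = sample_dataset(sem, n=10_000, seed=21)
        selected, est, se = split_sample_estimate(df, self.selector, seed=1)
        assert "C" in selected
        assert abs(est - true_total_effect(sem)) < 3 * se

    def test_empty_selection_on_unconfounded_data(self):
        dag = CausalDAG({"A", "Y", "X"}, [("A", "Y")], "A", "Y")
        sem = LinearSEM.with_unit_parameters(dag)
        df = sample_dataset(sem, n=10_000, seed=2)
        selected, est, se = split_sample_estimate(
            df, lambda d: backward_select(d, ["X"]).selected, seed=3
        )
        assert selected == ()
        assert abs(est - 1.0) < 3 * se

    def test_small_sample_rejected(self):
        df = self.make_data(10, 0)
        with pytest.raises(InsufficientSampleError):
            split_sample_estimate(df, self.selector)
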