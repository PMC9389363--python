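import numpy as np
import pandas as pd
import pytest

from inflamnet import simulate as sim
from inflamnet import survival as surv


def breslow_loglik_bruteforce(beta, x, time, event):
    """Literal Breslow partial log-likelihood, double loop over samples."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def make_cohort(n, beta, seed=0, censor_rate=0.0005):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 1))
    table = sim.generate_survival(
        n, x, [beta], baseline_rate=0.001, censor_rate=censor_rate, seed=seed
    )
    expr = pd.Series(x.ravel(), index=table.index)
    return expr, table


class TestCoxUnivariate:
    def test_null_covariate_within_three_se(self):
        expr, table = make_cohort(500, 0.0, seed=1)
        res = surv.cox_univariate(expr, table)
        assert abs(res["beta"]) < 3 * res["se"]

    def test_simulated_beta_recovered(self):
        expr, table = make_cohort(1000, 0.7, seed=2)
        res = surv.cox_univariate(expr, table)
        assert abs(res["beta"] - 0.7) < 3 * res["se"]
        assert res["hr"] == pytest.approx(np.exp(res["beta"]))

    def test_standardization_invariance(self):
        expr, table = make_cohort(300, 0.5, seed=3)
        res1 = surv.cox_univariate(expr, table)
        res2 = surv.cox_univariate(expr * 2.0, table)
        assert res1["beta"] == pytest.approx(res2["beta"], abs=1e-8)

    def test_too_few_events_rejected(self):
        expr, table = make_cohort(30, 0.5, seed=4, censor_rate=0.1)
        table["event"] = 0
        with pytest.raises(ValueError, match="events"):
            surv.cox_univariate(expr, table)

    def test_constant_covariate_rejected(self):
        _, table = make_cohort(50, 0.0, seed=5)
        with pytest.raises(ValueError, match="constant"):
            surv.cox_univariate(pd.Series(1.0, index=table.index), table)

    def test_matches_grid_oracle_small_n(self):
        """Newton solution vs brute-force grid maximization of the Breslow
        partial likelihood, n <= 20, one covariate."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 21))
            x = rng.normal(size=n)
            time = rng.exponential(100, size=n)
            event = rng.random(n) < 0.8
            if event.sum() < 2:
                continue
            beta_hat, _ = surv.fit_cox(x[:, None], time, event.astype(int))
            grid = np.arange(-3.0, 3.0, 1e-3)
            lls = [breslow_loglik_bruteforce(b, x, time, event) for b in grid]
            beta_grid = grid[int(np.argmax(lls))]
            assert abs(beta_hat[0] - beta_grid) < 1e-3

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        expr, table = make_cohort(400, 0.6, seed=6)
        res = surv.cox_univariate(expr, table)
        df = table.copy()
        df["x"] = (expr - expr.mean()) / expr.std()
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        # lifelines stops at its own looser tolerance; agreement to ~2e-3
        assert res["beta"] == pytest.approx(cph.params_["x"], abs=2e-3)


class TestSelectRiskGenes:
    def _results(self, rows):
        return pd.DataFrame(rows).set_index("gene")

    def test_all_protective_empty(self):
        res = self._results(
            [
                {"gene": "A", "beta": -0.5, "hr": 0.6, "se": 0.1, "pvalue": 0.001},
                {"gene": "B", "beta": -0.2, "hr": 0.8, "se": 0.1, "pvalue": 0.01},
            ]
        )
        assert surv.select_risk_genes(res) == []

    def test_hr_exactly_one_excluded(self):
        res = self._results(
            [{"gene": "A", "beta": 0.0, "hr": 1.0, "se": 0.1, "pvalue": 0.001}]
        )
        assert surv.select_risk_genes(res) == []

    def test_planted_hazardous_genes_selected(self):
        """3 hazardous genes among 50 nulls, strong effect: exactly those 3."""
        rng = np.random.default_rng(10)
        n = 800
        x = rng.normal(size=(n, 53))
        betas = np.zeros(53)
        betas[:3] = 1.0
        table = sim.generate_survival(
            n, x, betas, baseline_rate=0.001, censor_rate=0.0002, seed=10
        )
        expr = pd.DataFrame(
            x.T, index=[f"G{i}" for i in range(53)], columns=table.index
        )
        screen = surv.screen_genes(expr, list(expr.index), table)
        selected = surv.select_risk_genes(screen, p_threshold=0.001)
        assert set(selected) == {"G0", "G1", "G2"}


class TestRiskModel:
    def test_single_gene_score_proportional(self):
        expr, table = make_cohort(300, 0.7, seed=11)
        mat = pd.DataFrame([expr], index=["G1"])
        model = surv.fit_risk_model(["G1"], mat, table)
        z = (expr - expr.mean()) / expr.std(ddof=0)
        np.testing.assert_allclose(
            model.scores.to_numpy(), model.betas[0] * z.to_numpy(), atol=1e-10
        )

    def test_three_gene_recovery_and_concordance(self):
        rng = np.random.default_rng(12)
        n = 1000
        x = rng.normal(size=(n, 3))
        betas = np.array([0.8, 0.5, -0.4])
        table = sim.generate_survival(
            n, x, betas, baseline_rate=0.001, censor_rate=0.0003, seed=12
        )
        expr = pd.DataFrame(x.T, index=["G1", "G2", "G3"], columns=table.index)
        model = surv.fit_risk_model(["G1", "G2", "G3"], expr, table)
        for b_hat, b_true, se in zip(model.betas, betas, model.se):
            assert abs(b_hat - b_true) < 3 * se
        assert model.concordance > 0.6

    def test_permuted_survival_null_concordance(self):
        rng = np.random.default_rng(13)
        expr, table = make_cohort(600, 0.8, seed=13)
        permuted = table.copy()
        permuted[["time", "event"]] = (
            table[["time", "event"]].sample(frac=1, random_state=0).to_numpy()
        )
        mat = pd.DataFrame([expr], index=["G1"])
        model = surv.fit_risk_model(["G1"], mat, permuted)
        assert abs(model.concordance - 0.5) < 0.05

    def test_antiprognostic_concordance_complement(self):
        from lifelines.utils import concordance_index

        expr, table = make_cohort(300, 0.7, seed=14)
        scores = expr
        c1 = concordance_index(table["time"], -scores, table["event"])
        c2 = concordance_index(table["time"], scores, table["event"])
        assert c1 == pytest.approx(1 - c2)


class TestStratifyAndCompare:
    def test_median_split_counts(self):
        _, table = make_cohort(4, 0.0, seed=15)
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=table.index)
        labels, _, _, _ = surv.stratify_and_compare(scores, table)
        assert (labels == "high").sum() == 2
        assert (labels == "low").sum() == 2

    def test_ties_go_low(self):
        _, table = make_cohort(6, 0.0, seed=16)
        scores = pd.Series([1.0, 1.0, 1.0, 1.0, 5.0, 6.0], index=table.index)
        labels, _, _, _ = surv.stratify_and_compare(scores, table)
        assert (labels.loc[scores[scores == 1.0].index] == "low").all()

    def test_identical_groups_null_logrank(self):
        rng = np.random.default_rng(17)
        n = 200
        table = pd.DataFrame(
            {
                "time": rng.exponential(100, n),
                "event": rng.random(n) < 0.7,
            },
            index=[f"P{i}" for i in range(n)],
        ).astype({"event": int})
        scores = pd.Series(rng.normal(size=n), index=table.index)
        _, _, p, _ = surv.stratify_and_compare(scores, table)
        assert p > 0.05

    def test_prognostic_score_separates_km(self):
        rng = np.random.default_rng(18)
        n = 400
        x = rng.normal(size=(n, 1))
        table = sim.generate_survival(
            n, x, [1.2], baseline_rate=0.001, censor_rate=0.0002, seed=18
        )
        scores = pd.Series(x.ravel(), index=table.index)
        labels, stat, p, km = surv.stratify_and_compare(scores, table)
        assert p < 0.05
        # high-risk curve sits below the low-risk curve at the end
        assert km["high"].iloc[-1] <= km["low"].iloc[-1]

    def test_all_equal_scores_rejected(self):
        _, table = make_cohort(10, 0.0, seed=19)
        scores = pd.Series(2.0, index=table.index)
        with pytest.raises(ValueError, match="split"):
            surv.stratify_and_compare(scores, table)

    def test_km_no_censoring_equals_empirical(self):
        rng = np.random.default_rng(20)
        n = 50
        table = pd.DataFrame(
            {"time": rng.exponential(50, n), "event": 1},
            index=[f"P{i}" for i in range(n)],
        )
        scores = pd.Series(rng.normal(size=n), index=table.index)
        _, _, _, km = surv.stratify_and_compare(scores, table)
        hi = table.loc[scores > scores.median()]
        times = np.sort(hi["time"].to_numpy())
        for t, s in km["high"].dropna().items():
            if t == 0:
                continue
            empirical = (times > t).mean()
            assert s == pytest.approx(empirical, abs=1e-10)
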