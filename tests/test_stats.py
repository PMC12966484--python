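"""Group-level inference: FDR, logistic model, directionality, sleep."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from corticoflow.stats import (
    class_contrasts,
    fdr_bh,
    fit_probability_model,
    participant_directionality,
    sleep_modulation,
)


class TestFdrBH:
    def test_matches_hand_computed_step_up(self):
        # independent oracle: the Benjamini-Hochberg step-up rule written out
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        m = p.size
        order = np.argsort(p)
        ranked = p[order]
        adj = ranked * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):  # enforce monotonicity from the largest rank down
            adj[i] = min(adj[i], adj[i + 1])
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        reject, p_adj = fdr_bh(p, alpha=0.05)
        assert np.allclose(p_adj, expected, atol=1e-12)
        k = max(np.nonzero(ranked <= 0.05 * np.arange(1, m + 1) / m)[0], default=-1)
        expected_reject = np.zeros(m, bool)
        if k >= 0:
            expected_reject[order[: k + 1]] = True
        assert np.array_equal(reject, expected_reject)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=25)
        _, p_adj = fdr_bh(p)
        assert (p_adj >= p - 1e-15).all()


def _binomial_table(rng, n_conn, beta0, beta2, n_stims=300):
    d = rng.uniform(26.0, 80.0, n_conn)
    regions = rng.choice(["regA", "regB"], size=(n_conn, 2))
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta2 * d)))
    n_sig = rng.binomial(n_stims, p)
    return pd.DataFrame(
        {
            "n_significant": n_sig,
            "n_stims": n_stims,
            "distance_mm": d,
            "stim_region": regions[:, 0],
            "resp_region": regions[:, 1],
        }
    )


class TestProbabilityModel:
    def test_distance_coefficient_recovery_coverage(self):
        # unbiased recovery: 2-SE coverage in >= 9 of 12 seeded replicates
        # and a near-zero mean standardized error
        zs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            table = _binomial_table(rng, 80, beta0=0.0, beta2=-0.05)
            model = fit_probability_model(table)
            zs.append((model.distance_coef - (-0.05)) / model.distance_se)
        zs = np.asarray(zs)
        assert (np.abs(zs) < 2).sum() >= 9
        assert abs(zs.mean()) < 3 / np.sqrt(zs.size)

    def test_null_distance_ci_covers_zero(self):
        hits = 0
        for seed in range(12):
            rng = np.random.default_rng(100 + seed)
            table = _binomial_table(rng, 80, beta0=-0.4, beta2=0.0)
            model = fit_probability_model(table)
            lo, hi = model.conf_int.loc["distance_mm"]
            hits += lo < 0.0 < hi
        assert hits >= 9

    def test_region_pair_effect_detected(self):
        # one region pair with doubled log-odds is flagged significant
        found = 0
        for seed in range(8):
            rng = np.random.default_rng(200 + seed)
            table = _binomial_table(rng, 80, beta0=0.0, beta2=-0.05)
            pair = (table.stim_region == "regA") & (table.resp_region == "regB")
            logit = -0.05 * table.distance_mm + np.where(pair, np.log(2) * 2, 0.0)
            table["n_significant"] = rng.binomial(
                table["n_stims"], 1.0 / (1.0 + np.exp(-logit))
            )
            model = fit_probability_model(table)
            found += model.pvalues["pair_regA:regB"] < 0.05
        assert found >= 6

    def test_pseudo_r2_in_unit_interval(self):
        rng = np.random.default_rng(0)
        model = fit_probability_model(_binomial_table(rng, 60, 0.0, -0.05))
        assert 0.0 <= model.pseudo_r2 <= 1.0

    def test_nonpositive_distance_rejected(self):
        rng = np.random.default_rng(0)
        table = _binomial_table(rng, 10, 0.0, -0.05)
        table.loc[0, "distance_mm"] = 0.0
        with pytest.raises(ValueError):
            fit_probability_model(table)


def _di_cohort(rng, n_participants, pairs, efferent_factor):
    rows = []
    for part in range(n_participants):
        for pair in pairs:
            for conn in range(3):
                p_ba = rng.uniform(0.2, 0.4)
                p_ab = min(p_ba * efferent_factor.get(pair, 1.0), 1.0)
                noise = rng.normal(0, 0.03, 2)
                rows.append(
                    {
                        "participant": f"p{part}",
                        "region_pair": pair,
                        "p_ab": float(np.clip(p_ab + noise[0], 0, 1)),
                        "p_ba": float(np.clip(p_ba + noise[1], 0, 1)),
                    }
                )
    return pd.DataFrame(rows)


class TestParticipantDirectionality:
    def test_doubled_efference_detected_with_expected_di(self):
        rng = np.random.default_rng(0)
        pairs = ["amygdala:dorsofrontal", "central:parietal", "occipital:cingulate"]
        table = _di_cohort(rng, 13, pairs, {"amygdala:dorsofrontal": 2.0})
        out = participant_directionality(table).set_index("region_pair")
        assert out.loc["amygdala:dorsofrontal", "significant"]
        assert 0.4 <= out.loc["amygdala:dorsofrontal", "mean_di"] <= 0.6
        assert not out.loc["central:parietal", "significant"]

    def test_symmetric_null_rarely_significant(self):
        n_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            table = _di_cohort(rng, 10, ["a:b", "c:d", "e:f"], {})
            out = participant_directionality(table)
            n_sig += int(out["significant"].sum())
        # 60 null pair-tests at FDR 0.05: a handful of false positives at most
        assert n_sig <= 7

    def test_single_participant_untested(self):
        rng = np.random.default_rng(0)
        table = _di_cohort(rng, 1, ["a:b"], {})
        out = participant_directionality(table)
        assert not out.loc[0, "tested"] and np.isnan(out.loc[0, "p_raw"])


class TestClassContrasts:
    def test_null_kw_pvalues_uniform(self):
        # 200 replicates of three classes drawn from one distribution
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            table = pd.DataFrame(
                {
                    "connection_class": np.repeat(["local", "long_short", "long_long"], 30),
                    "probability": rng.uniform(size=90),
                }
            )
            out = class_contrasts(table)
            pvals.append(
                out[(out.statistic == "kruskal_wallis") & (out.measure == "probability")][
                    "p_raw"
                ].iloc[0]
            )
        assert sstats.kstest(pvals, "uniform").pvalue > 0.01

    def test_shifted_medians_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(10):
            table = pd.DataFrame(
                {
                    "connection_class": np.repeat(["local", "long_short", "long_long"], 100),
                    "probability": np.clip(
                        np.concatenate(
                            [
                                rng.normal(0.9, 0.1, 100),
                                rng.normal(0.6, 0.1, 100),
                                rng.normal(0.2, 0.1, 100),
                            ]
                        ),
                        0,
                        1,
                    ),
                }
            )
            out = class_contrasts(table)
            kw = out[(out.statistic == "kruskal_wallis") & (out.measure == "probability")]
            hits += kw["p_raw"].iloc[0] < 0.001
        assert hits >= 10 * 0.95

    def test_single_class_emits_note(self):
        table = pd.DataFrame({"connection_class": ["local"] * 5, "probability": [0.5] * 5})
        out = class_contrasts(table)
        assert "fewer than two" in out["note"].iloc[0]

    def test_posthoc_pairs_present_and_adjusted(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "connection_class": np.repeat(["local", "long_short", "long_long"], 40),
                "probability": rng.uniform(size=120),
                "di": rng.uniform(-1, 1, 120),
            }
        )
        out = class_contrasts(table)
        posthoc = out[out.statistic == "mann_whitney"]
        assert len(posthoc) == 6  # 3 pairs x 2 measures
        assert (posthoc["p_adj"] >= posthoc["p_raw"] - 1e-12).all()


def _sleep_table(rng, n_participants, gain, pairs, n_conn=2, noise=0.02):
    rows = []
    for part in range(n_participants):
        for pair in pairs:
            stim_region = pair.split(":")[0]
            for conn in range(n_conn):
                cid = f"p{part}-{pair}-{conn}"
                base_mag = rng.uniform(0.8, 1.2)
                base_p = rng.uniform(0.5, 0.9)
                g = gain.get(pair, 1.0)
                for state, m, pr in [
                    ("W", base_mag, base_p),
                    ("NREM", base_mag * g, base_p),
                ]:
                    rows.append(
                        {
                            "participant": f"p{part}",
                            "region_pair": pair,
                            "connection": cid,
                            "state": state,
                            "stim_region": stim_region,
                            "probability": float(np.clip(pr + rng.normal(0, noise), 0, 1)),
                            "magnitude": m * float(np.exp(rng.normal(0, noise))),
                            "exi": float(np.clip(0.6 * m + rng.normal(0, noise), 0, 1)),
                        }
                    )
    return pd.DataFrame(rows)


class TestSleepModulation:
    PAIRS = ["hippocampus:dorsofrontal", "amygdala:dorsofrontal", "central:parietal"]

    def test_identical_states_give_perfect_agreement(self):
        rng = np.random.default_rng(0)
        table = _sleep_table(rng, 8, {}, self.PAIRS, noise=0.0)
        res = sleep_modulation(table)
        agree = res.agreement.set_index("state").loc["NREM"]
        assert agree["pearson_r"] == pytest.approx(1.0)
        assert agree["bland_altman_bias"] == pytest.approx(0.0, abs=1e-12)

    def test_reduced_hippocampal_magnitude_detected(self):
        rng = np.random.default_rng(1)
        table = _sleep_table(rng, 13, {"hippocampus:dorsofrontal": 0.75}, self.PAIRS)
        res = sleep_modulation(table)
        mag = res.pair_tests[(res.pair_tests.measure == "magnitude")].set_index("region_pair")
        row = mag.loc["hippocampus:dorsofrontal"]
        assert row["significant"] and row["mean_change_pct"] < 0
        assert row["mean_change_pct"] == pytest.approx(-25.0, abs=5.0)
        assert not mag.loc["central:parietal", "significant"]

    def test_mixed_model_reports_region_terms(self):
        rng = np.random.default_rng(2)
        table = _sleep_table(rng, 10, {"hippocampus:dorsofrontal": 0.7}, self.PAIRS)
        res = sleep_modulation(table)
        assert res.mixed_model is not None
        assert any("stim_region" in str(ix) for ix in res.mixed_model.index)

    def test_wake_required(self):
        rng = np.random.default_rng(3)
        table = _sleep_table(rng, 4, {}, self.PAIRS)
        with pytest.raises(ValueError):
            sleep_modulation(table[table.state != "W"])
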