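"""Group-level inference on connection metrics.

Covers the distance/region-pair logistic model for signaling probability,
participant-level directionality tests (Wilcoxon signed-rank with
Benjamini–Hochberg correction), connection-class contrasts
(Kruskal–Wallis with post-hoc Mann–Whitney), and sleep-modulation analyses
(percent changes with signed-rank tests, Pearson/Bland–Altman agreement of
probabilities between states, and a mixed-effects model of probability
changes with participant random intercepts).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionModel",
    "SleepModulationResult",
    "fdr_bh",
    "fit_probability_model",
    "participant_directionality",
    "class_contrasts",
    "sleep_modulation",
]

logger = logging.getLogger(__name__)


def fdr_bh(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns (reject, adjusted p-values); adjusted values are monotone and
    never below the raw ones.
    """
    p = np.asarray(pvalues, float)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# logistic model of signaling probability
# ---------------------------------------------------------------------------

@dataclass
class RegressionModel:
    """Binomial GLM of signaling probability on region pair and distance.

    logit(P) = β0 + β1(Region_stim : Region_resp) + β2·d, fitted on per-
    connection success counts; the region-pair interaction is coded as a
    single combined factor (reference cell = first pair alphabetically).
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    pseudo_r2: float
    n_observations: int
    dropped_levels: list[str]

    @property
    def distance_coef(self) -> float:
        return float(self.params["distance_mm"])

    @property
    def distance_se(self) -> float:
        return float(self.bse["distance_mm"])


def fit_probability_model(table: pd.DataFrame) -> RegressionModel:
    """Fit the probability model on a connection table.

    ``table`` needs columns n_significant, n_stims, distance_mm,
    stim_region, resp_region.  Observations are binomial counts (weighted by
    trials), not fractional probabilities.  Reports McFadden pseudo-R²
    against the intercept-only model.  Region-pair levels with no
    observations are simply absent; levels dropped for perfect separation
    are listed.
    """
    required = {"n_significant", "n_stims", "distance_mm", "stim_region", "resp_region"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    df = table.copy()
    if (df["distance_mm"] <= 0).any():
        raise ValueError("distances must be positive")
    df["region_pair"] = df["stim_region"].astype(str) + ":" + df["resp_region"].astype(str)
    if df["region_pair"].nunique() < 1 or df["stim_region"].nunique() + df["resp_region"].nunique() < 2:
        raise ValueError("need at least two regions")

    df = df.reset_index(drop=True)
    endog = np.column_stack(
        [df["n_significant"].to_numpy(float), (df["n_stims"] - df["n_significant"]).to_numpy(float)]
    )
    pair_dummies = pd.get_dummies(df["region_pair"], prefix="pair", dtype=float)
    reference = sorted(pair_dummies.columns)[0]
    pair_dummies = pair_dummies.drop(columns=[reference])
    exog = sm.add_constant(pd.concat([pair_dummies, df[["distance_mm"]]], axis=1))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        null_fit = sm.GLM(endog, np.ones((len(df), 1)), family=sm.families.Binomial()).fit()
    pseudo_r2 = float(1.0 - fit.llf / null_fit.llf) if null_fit.llf != 0 else float("nan")
    dropped = [name for name, se in fit.bse.items() if not np.isfinite(se) or se > 1e4]
    if dropped:
        logger.warning("levels with unstable estimates (possible separation): %s", dropped)
    return RegressionModel(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        conf_int=fit.conf_int(),
        pseudo_r2=pseudo_r2,
        n_observations=len(df),
        dropped_levels=dropped,
    )


# ---------------------------------------------------------------------------
# participant-level directionality
# ---------------------------------------------------------------------------

def _safe_wilcoxon(x: np.ndarray, y: np.ndarray | None = None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank robust to all-zero differences."""
    d = np.asarray(x, float) - (0.0 if y is None else np.asarray(y, float))
    d = d[np.isfinite(d)]
    if d.size == 0 or np.allclose(d, 0.0):
        return 0.0, 1.0
    try:
        res = sstats.wilcoxon(d, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    except ValueError:
        return 0.0, 1.0


def participant_directionality(
    di_table: pd.DataFrame,
    min_participants: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-pair directionality across participants.

    ``di_table`` has one row per connection: participant, region_pair,
    p_ab, p_ba.  Probabilities are averaged within participants first, then
    the paired P_AB vs P_BA difference is tested across participants with a
    two-sided Wilcoxon signed-rank test, Benjamini–Hochberg adjusted across
    region pairs.  Pairs with fewer than ``min_participants`` participants
    are reported untested.
    """
    from .metrics import directionality_index

    rows = []
    for pair, grp in di_table.groupby("region_pair"):
        per_part = grp.groupby("participant")[["p_ab", "p_ba"]].mean()
        n_part = len(per_part)
        dis = [
            directionality_index(r.p_ab, r.p_ba)
            for r in per_part.itertuples()
            if max(r.p_ab, r.p_ba) > 0
        ]
        mean_di = float(np.nanmean(dis)) if dis else float("nan")
        if n_part >= min_participants:
            stat, p = _safe_wilcoxon(per_part["p_ab"].to_numpy(), per_part["p_ba"].to_numpy())
            tested = True
        else:
            stat, p, tested = float("nan"), float("nan"), False
        rows.append(
            {
                "region_pair": pair,
                "n_participants": n_part,
                "mean_di": mean_di,
                "statistic": stat,
                "p_raw": p,
                "tested": tested,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    out["significant"] = False
    mask = out["tested"].to_numpy()
    if mask.any():
        reject, p_adj = fdr_bh(out.loc[mask, "p_raw"].to_numpy(), alpha)
        out.loc[mask, "p_adj"] = p_adj
        out.loc[mask, "significant"] = reject
    return out


# ---------------------------------------------------------------------------
# connection-class contrasts
# ---------------------------------------------------------------------------

def class_contrasts(metrics_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal–Wallis across connection classes for P and |DI|.

    ``metrics_table`` columns: connection_class, probability and (optionally)
    di.  Post-hoc pairwise two-sided Mann–Whitney tests are FDR-adjusted
    within each measure.  Empty classes are omitted with a note row.
    """
    measures = {"probability": metrics_table.get("probability")}
    if "di" in metrics_table.columns:
        measures["abs_di"] = metrics_table["di"].abs()
    rows = []
    for name, values in measures.items():
        if values is None:
            continue
        df = pd.DataFrame({"y": values, "cls": metrics_table["connection_class"]}).dropna()
        groups = {c: g["y"].to_numpy() for c, g in df.groupby("cls") if len(g) > 0}
        if len(groups) < 2:
            rows.append(
                {
                    "grouping": "all",
                    "measure": name,
                    "statistic": "kruskal_wallis",
                    "p_raw": np.nan,
                    "p_adj": np.nan,
                    "n": len(df),
                    "note": "fewer than two populated classes",
                }
            )
            continue
        h, p = sstats.kruskal(*groups.values())
        rows.append(
            {
                "grouping": "all",
                "measure": name,
                "statistic": "kruskal_wallis",
                "p_raw": float(p),
                "p_adj": np.nan,
                "n": len(df),
                "note": "",
            }
        )
        posthoc = []
        for a, b in combinations(sorted(groups), 2):
            u, pu = sstats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            posthoc.append(
                {
                    "grouping": f"{a} vs {b}",
                    "measure": name,
                    "statistic": "mann_whitney",
                    "p_raw": float(pu),
                    "n": len(groups[a]) + len(groups[b]),
                    "note": "",
                }
            )
        if posthoc:
            _, p_adj = fdr_bh([r["p_raw"] for r in posthoc], alpha)
            for r, pa in zip(posthoc, p_adj):
                r["p_adj"] = float(pa)
            rows.extend(posthoc)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sleep modulation
# ---------------------------------------------------------------------------

@dataclass
class SleepModulationResult:
    """Outputs of the sleep-vs-wake comparison."""

    pair_tests: pd.DataFrame  # state, measure, region_pair, mean change %, p, p_adj
    agreement: pd.DataFrame  # state, pearson_r, pearson_p, bland_altman_bias, n
    mixed_model: pd.DataFrame | None  # ΔP ~ stim region with participant intercepts
    n_state_incomplete: int


def sleep_modulation(
    table: pd.DataFrame,
    min_participants: int = 5,
    alpha: float = 0.05,
) -> SleepModulationResult:
    """Sleep-vs-wake modulation of magnitude, excitability, and probability.

    ``table`` has one row per connection × state with columns: participant,
    region_pair, connection, state ('W' plus 'NREM' and/or 'REM'),
    probability, and optionally magnitude, exi, stim_region.  Percent change
    is 100 × (sleep − wake)/wake on state-complete connections, averaged
    within participant × region pair, then tested across participants with a
    signed-rank test (BH-adjusted across region pairs, within each state and
    measure).  Probability agreement between states is summarized by Pearson
    correlation and Bland–Altman mean bias; probability changes are modelled
    with a mixed-effects linear model (stimulation region fixed, participant
    random intercept, REML).
    """
    if "W" not in set(table["state"]):
        raise ValueError("wake ('W') state required")
    sleep_states = [s for s in ("NREM", "REM") if s in set(table["state"])]
    if not sleep_states:
        raise ValueError("at least one sleep state (NREM/REM) required")

    wide_cols = [c for c in ("probability", "magnitude", "exi") if c in table.columns]
    idx_cols = ["participant", "region_pair", "connection"]
    keep = idx_cols + ["state"] + wide_cols
    if "stim_region" in table.columns:
        stim_lookup = table.drop_duplicates("connection").set_index("connection")["stim_region"]
    else:
        stim_lookup = None
    wide = table[keep].pivot_table(index=idx_cols, columns="state", values=wide_cols)

    pair_rows = []
    agree_rows = []
    delta_p_rows = []
    n_incomplete = 0
    for state in sleep_states:
        for measure in ("magnitude", "exi"):
            if measure not in wide_cols:
                continue
            w = wide[(measure, "W")]
            s = wide[(measure, state)]
            ok = np.isfinite(w) & np.isfinite(s) & (w != 0)
            n_incomplete += int((~ok).sum())
            pct = 100.0 * (s[ok] - w[ok]) / w[ok]
            per = pct.groupby(level=["participant", "region_pair"]).mean().reset_index()
            per.columns = ["participant", "region_pair", "pct_change"]
            for pair, grp in per.groupby("region_pair"):
                vals = grp["pct_change"].to_numpy()
                if len(vals) >= min_participants:
                    stat, p = _safe_wilcoxon(vals)
                    tested = True
                else:
                    stat, p, tested = float("nan"), float("nan"), False
                pair_rows.append(
                    {
                        "state": state,
                        "measure": measure,
                        "region_pair": pair,
                        "n_participants": len(vals),
                        "mean_change_pct": float(np.mean(vals)) if len(vals) else np.nan,
                        "p_raw": p,
                        "tested": tested,
                    }
                )
        # probability agreement across connections
        if "probability" in wide_cols:
            w = wide[("probability", "W")]
            s = wide[("probability", state)]
            ok = np.isfinite(w) & np.isfinite(s)
            if ok.sum() >= 3:
                r, pr = sstats.pearsonr(w[ok], s[ok])
            else:
                r, pr = float("nan"), float("nan")
            agree_rows.append(
                {
                    "state": state,
                    "pearson_r": float(r),
                    "pearson_p": float(pr),
                    "bland_altman_bias": float((s[ok] - w[ok]).mean()) if ok.any() else np.nan,
                    "n": int(ok.sum()),
                }
            )
            dp = (s[ok] - w[ok]).reset_index()
            dp.columns = idx_cols + ["delta_p"]
            dp["state"] = state
            delta_p_rows.append(dp)

    pair_tests = pd.DataFrame(pair_rows)
    if len(pair_tests):
        pair_tests["p_adj"] = np.nan
        pair_tests["significant"] = False
        for (state, measure), grp in pair_tests.groupby(["state", "measure"]):
            mask = grp["tested"]
            if mask.any():
                reject, p_adj = fdr_bh(grp.loc[mask, "p_raw"].to_numpy(), alpha)
                pair_tests.loc[grp.index[mask], "p_adj"] = p_adj
                pair_tests.loc[grp.index[mask], "significant"] = reject

    mixed = None
    if delta_p_rows and stim_lookup is not None:
        dp = pd.concat(delta_p_rows, ignore_index=True)
        dp["stim_region"] = dp["connection"].map(stim_lookup)
        if dp["stim_region"].nunique() >= 2 and dp["participant"].nunique() >= 2:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(
                        "delta_p ~ C(stim_region)", dp, groups=dp["participant"], re_formula="1"
                    )
                    fit = model.fit(reml=True)
                mixed = pd.DataFrame(
                    {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
                )
            except Exception as exc:  # singular fits on degenerate inputs
                logger.warning("mixed model failed: %s", exc)
    return SleepModulationResult(
        pair_tests=pair_tests,
        agreement=pd.DataFrame(agree_rows),
        mixed_model=mixed,
        n_state_incomplete=n_incomplete,
    )
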