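"""Field-plot canopy statistics.

Implements the permanent-plot side of the analysis: a DBH quality-control
rule based on the measurement-error model s = 0.9036 + 0.006214*DBH (cm),
log-log allometries for tree height and crown area with Duan smearing,
crown-area-weighted top-of-canopy height truncated at the 625 m^2 plot
area, basal-area mortality/growth decomposition between censuses, a
Beer-Lambert inversion of canopy openness to plant area index, and the two
plot-level ordinary-least-squares regressions linking canopy-height change
to stand dynamics.

Censuses are long DataFrames with columns plot_id, census_date, tree_id,
dbh_cm, height_m, crown_area_m2, alive (the schema produced by
``canopyedge.synthetic.generate_plot_inventory``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PLOT_AREA_M2",
    "AllometryFit",
    "dbh_error_sd",
    "clean_growth",
    "fit_allometry",
    "crown_weighted_tch",
    "basal_area_dynamics",
    "pai_from_openness",
    "plot_regressions",
]

PLOT_AREA_M2 = 625.0  # each permanent plot is 25 x 25 m


def dbh_error_sd(dbh_cm):
    """Standard deviation (cm) of the DBH measurement error, s = 0.9036 + 0.006214*DBH."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh < 0):
        raise ValueError("DBH must be non-negative")
    return 0.9036 + 0.006214 * dbh


def clean_growth(
    census_t0: pd.DataFrame,
    census_t1: pd.DataFrame,
    interval_yr: float,
    growth_threshold_cm_yr: float = 5.0,
    shrinkage_sd_multiple: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace implausible DBH changes with the expected growth of similar trees.

    A tree is flagged when its annualized growth is >= 5 cm/yr or its total
    shrinkage is >= 12*s (s evaluated at the initial DBH).  Flagged trees
    get DBH_t1 = DBH_t0 + interval * (mean annual increment of unflagged
    trees in the same plot and DBH quartile); if a quartile bin has no
    unflagged tree the whole-plot mean is used, and failing that the
    network-wide mean.  Returns the corrected t1 census and a table of
    flagged trees.
    """
    if interval_yr <= 0:
        raise ValueError("census interval must be positive")
    merged = census_t0.merge(
        census_t1, on=["plot_id", "tree_id"], suffixes=("_t0", "_t1"), how="inner"
    )
    growth = (merged["dbh_cm_t1"] - merged["dbh_cm_t0"]) / interval_yr
    shrinkage = merged["dbh_cm_t0"] - merged["dbh_cm_t1"]
    s = dbh_error_sd(merged["dbh_cm_t0"])
    flagged = (growth >= growth_threshold_cm_yr) | (shrinkage >= shrinkage_sd_multiple * s)
    merged["flagged"] = flagged.to_numpy()

    # per-plot DBH quartile bins at t0 (rank-based, robust to ties)
    def _bin(s: pd.Series) -> pd.Series:
        ranks = s.rank(method="first").to_numpy()
        return pd.Series(
            np.minimum((4 * (ranks - 1) / len(s)).astype(int), 3), index=s.index
        )

    merged["size_class"] = (
        merged.groupby("plot_id", group_keys=False)["dbh_cm_t0"].apply(_bin).astype(int)
    )
    ok = merged[~merged["flagged"]]
    bin_mean = ok.groupby(["plot_id", "size_class"]).apply(
        lambda g: ((g["dbh_cm_t1"] - g["dbh_cm_t0"]) / interval_yr).mean(),
        include_groups=False,
    )
    plot_mean = ok.groupby("plot_id").apply(
        lambda g: ((g["dbh_cm_t1"] - g["dbh_cm_t0"]) / interval_yr).mean(),
        include_groups=False,
    )
    network_mean = ((ok["dbh_cm_t1"] - ok["dbh_cm_t0"]) / interval_yr).mean()

    corrected = census_t1.copy()
    replacements = {}
    for _, row in merged[merged["flagged"]].iterrows():
        key = (row["plot_id"], row["size_class"])
        rate = bin_mean.get(key, np.nan)
        if not np.isfinite(rate):
            rate = plot_mean.get(row["plot_id"], np.nan)
        if not np.isfinite(rate):
            rate = network_mean if np.isfinite(network_mean) else 0.0
        replacements[(row["plot_id"], row["tree_id"])] = row["dbh_cm_t0"] + interval_yr * rate
    if replacements:
        idx = pd.MultiIndex.from_frame(corrected[["plot_id", "tree_id"]])
        new_dbh = corrected["dbh_cm"].to_numpy(float).copy()
        mapper = pd.Series(replacements)
        hits = idx.isin(mapper.index)
        new_dbh[hits] = mapper.loc[idx[hits]].to_numpy(float)
        corrected["dbh_cm"] = new_dbh
    flags = merged.loc[merged["flagged"], ["plot_id", "tree_id", "dbh_cm_t0", "dbh_cm_t1"]]
    return corrected, flags.reset_index(drop=True)


@dataclass
class AllometryFit:
    """Log-log power-law fits ln H = a_h + b_h ln DBH and ln CA = a_ca + b_ca ln DBH."""

    a_h: float
    b_h: float
    sd_h: float
    smear_h: float
    a_ca: float
    b_ca: float
    sd_ca: float
    smear_ca: float

    def predict_height(self, dbh_cm):
        return self.smear_h * np.exp(self.a_h + self.b_h * np.log(np.asarray(dbh_cm, float)))

    def predict_crown_area(self, dbh_cm):
        return self.smear_ca * np.exp(self.a_ca + self.b_ca * np.log(np.asarray(dbh_cm, float)))


def _loglog_fit(x, y):
    X = sm.add_constant(np.log(x))
    res = sm.OLS(np.log(y), X).fit()
    resid = res.resid
    return res.params[0], res.params[1], float(np.std(resid, ddof=2)), float(np.mean(np.exp(resid)))


def fit_allometry(trees: pd.DataFrame) -> AllometryFit:
    """Fit both allometries on trees with measured height and crown area.

    Back-transformed predictions carry the Duan smearing factor
    mean(exp(residual)) to undo the log-scale retransformation bias.
    """
    t = trees.dropna(subset=["dbh_cm", "height_m", "crown_area_m2"])
    if len(t) < 10:
        raise ValueError("need at least 10 trees with DBH, height and crown area")
    for col in ("dbh_cm", "height_m", "crown_area_m2"):
        if (t[col] <= 0).any():
            raise ValueError(f"{col} must be positive for the log-log fit")
    a_h, b_h, sd_h, sm_h = _loglog_fit(t["dbh_cm"].to_numpy(), t["height_m"].to_numpy())
    a_c, b_c, sd_c, sm_c = _loglog_fit(t["dbh_cm"].to_numpy(), t["crown_area_m2"].to_numpy())
    return AllometryFit(a_h, b_h, sd_h, sm_h, a_c, b_c, sd_c, sm_c)


def crown_weighted_tch(census: pd.DataFrame, plot_area_m2: float = PLOT_AREA_M2) -> float:
    """Crown-area-weighted height of the overstory trees of one plot census.

    Trees are ranked by crown area (descending; ties by larger DBH, then
    tree id) and selected down the list until the cumulative crown area
    first reaches the plot area; the crossing tree is included whole.  The
    result is sum(CA_i * H_i) / sum(CA_i) over the selected trees, the plot
    statistic comparable to LiDAR top-of-canopy height.
    """
    t = census[census["alive"].astype(bool)] if "alive" in census else census
    t = t.dropna(subset=["height_m", "crown_area_m2"])
    if len(t) == 0 or t["crown_area_m2"].sum() <= 0:
        raise ValueError("census has no trees with positive crown area")
    t = t.sort_values(
        ["crown_area_m2", "dbh_cm", "tree_id"], ascending=[False, False, True], kind="stable"
    )
    ca = t["crown_area_m2"].to_numpy(float)
    cum = np.cumsum(ca)
    n_sel = int(np.searchsorted(cum, plot_area_m2) + 1)
    n_sel = min(n_sel, len(t))
    sel_ca = ca[:n_sel]
    sel_h = t["height_m"].to_numpy(float)[:n_sel]
    return float(np.sum(sel_ca * sel_h) / np.sum(sel_ca))


def basal_area_dynamics(census_t0: pd.DataFrame, census_t1: pd.DataFrame) -> dict:
    """Basal-area loss to mortality and gain from survivor growth (m^2).

    BA per tree is pi*(DBH/200)^2.  Mortality sums BA_t0 over trees alive at
    t0 and dead at t1; growth sums BA_t1 - BA_t0 over survivors.  Recruits
    (ids absent at t0) are reported separately and excluded from both terms.
    """
    ba = lambda d: np.pi * (np.asarray(d, float) / 200.0) ** 2
    m = census_t0.merge(census_t1, on=["plot_id", "tree_id"], suffixes=("_t0", "_t1"), how="outer", indicator=True)
    both = m[m["_merge"] == "both"]
    revived = both[(~both["alive_t0"].astype(bool)) & both["alive_t1"].astype(bool)]
    if len(revived):
        raise ValueError("tree recorded dead at t0 but alive at t1")
    alive0 = both["alive_t0"].astype(bool)
    alive1 = both["alive_t1"].astype(bool)
    died = both[alive0 & ~alive1]
    survived = both[alive0 & alive1]
    recruits = m[(m["_merge"] == "right_only") & m["alive_t1"].astype(bool)]
    return {
        "ba_mortality_m2": float(ba(died["dbh_cm_t0"]).sum()),
        "ba_growth_m2": float((ba(survived["dbh_cm_t1"]) - ba(survived["dbh_cm_t0"])).sum()),
        "n_died": int(len(died)),
        "n_survived": int(len(survived)),
        "n_recruits": int(len(recruits)),
        "ba_recruits_m2": float(ba(recruits["dbh_cm_t1"]).sum()),
    }


def pai_from_openness(openness, k: float = 0.5):
    """Plant area index from canopy openness by Beer-Lambert inversion.

    PAI = -ln(openness)/k with extinction coefficient k (default 0.5).
    Openness must lie in (0, 1]; zero openness means a saturated canopy with
    no finite PAI.
    """
    o = np.asarray(openness, dtype=float)
    if k <= 0:
        raise ValueError("extinction coefficient k must be > 0")
    if np.any(o <= 0) or np.any(o > 1):
        raise ValueError("openness must lie in (0, 1]")
    return -np.log(o) / k


def plot_regressions(plot_table: pd.DataFrame) -> dict:
    """The two plot-level OLS fits.

    ``ba`` model: field-estimated dTCH ~ BA mortality + BA growth.
    ``lidar`` model: LiDAR dTCH ~ dPAI + field-estimated dTCH (fitted when
    the needed columns are present).  Each result carries coefficients,
    R^2 and a per-predictor F statistic (the squared t of a single-df
    predictor).
    """

    def _fit(y, X_cols):
        data = plot_table.dropna(subset=[y] + X_cols)
        if len(data) < len(X_cols) + 2:
            raise ValueError(f"need at least {len(X_cols) + 2} plots to fit {y} ~ {X_cols}")
        X = sm.add_constant(data[X_cols].to_numpy(float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        res = sm.OLS(data[y].to_numpy(float), X).fit()
        return {
            "params": dict(zip(["intercept"] + X_cols, res.params)),
            "r2": float(res.rsquared),
            "f_per_predictor": dict(zip(X_cols, (res.tvalues[1:] ** 2))),
            "p_per_predictor": dict(zip(X_cols, res.pvalues[1:])),
            "n": int(res.nobs),
        }

    out = {"ba": _fit("delta_tch_field", ["ba_mortality", "ba_growth"])}
    if {"delta_tch_lidar", "delta_pai"}.issubset(plot_table.columns):
        out["lidar"] = _fit("delta_tch_lidar", ["delta_pai", "delta_tch_field"])
    return out
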