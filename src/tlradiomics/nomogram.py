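"""Radiomics score, combined radiomics + clinical logistic model, and
point-based nomogram export.

The radiomics score of a patient is the weighted sum of the selected
features, ``r = sum_i F_i * W_i``, with the weights taken from the
feature selector's importance ranking.  The score is combined with the
clinically meaningful binary covariates (ER, PR, HER2) in a
maximum-likelihood logistic regression, and the fitted model is
rendered as a points-based nomogram: each variable's contribution is
mapped to a 0-100 point scale (the largest absolute effect spans 100
points), individual points are summed, and the total maps back to a
predicted pCR probability through the inverse logit.  The mapping is
affine, so the probability recovered from the points representation
equals the logistic model's probability exactly (to numerical
round-off).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

logger = logging.getLogger("tlradiomics")


# ---------------------------------------------------------------------------
# Radiomics score
# ---------------------------------------------------------------------------

def radiomics_score(table, features, weights) -> pd.Series:
    """Per-sample weighted sum of the selected features.

    ``table`` is a FeatureTable (or DataFrame of values); missing
    features raise a KeyError naming the first offender.
    """
    values = table.values if hasattr(table, "feature_ids") else table
    values = pd.DataFrame(values)
    features = list(features)
    weights = np.asarray(weights, dtype=float)
    if len(features) != weights.size:
        raise ValueError("features and weights must have equal length")
    missing = [f for f in features if f not in values.columns]
    if missing:
        raise KeyError(f"feature {missing[0]!r} missing from the table")
    score = values.loc[:, features].to_numpy(dtype=float) @ weights
    return pd.Series(score, index=values.index, name="r_score")


# ---------------------------------------------------------------------------
# Combined logistic model
# ---------------------------------------------------------------------------

@dataclass
class NomogramModel:
    """Logistic coefficients plus the affine point-scale mapping."""

    terms: list                                # predictor names, r_score first
    coef: pd.Series                            # includes "intercept"
    stderr: pd.Series
    zvalues: pd.Series
    predicted: pd.Series = field(repr=False)   # in-sample probabilities
    train_range: pd.DataFrame = field(repr=False)  # min/max per predictor
    separation_flag: bool = False

    def linear_predictor(self, data: pd.DataFrame) -> pd.Series:
        eta = np.full(len(data), self.coef["intercept"], dtype=float)
        for t in self.terms:
            eta += self.coef[t] * data[t].to_numpy(dtype=float)
        return pd.Series(eta, index=data.index, name="eta")

    def predict_proba(self, data: pd.DataFrame) -> pd.Series:
        return pd.Series(expit(self.linear_predictor(data)),
                         index=data.index, name="probability")


def fit_combined_model(r_score, clinical: pd.DataFrame, outcome
                       ) -> NomogramModel:
    """Maximum-likelihood logistic regression of pCR on the radiomics
    score and the clinical covariates.

    Perfect separation is detected (fitted probabilities all within
    1e-8 of the labels) and flagged with a warning rather than raised;
    the reported coefficients are then the last iterates.
    """
    r_score = pd.Series(r_score, name="r_score")
    clinical = pd.DataFrame(clinical)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    data = pd.concat([r_score, clinical.set_index(r_score.index)], axis=1)
    if data.isna().any().any():
        raise ValueError("missing values in predictors")

    x = sm.add_constant(data.to_numpy(dtype=float), has_constant="add")
    names = ["intercept"] + list(data.columns)
    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception:  # separation or a collinear (singular) design
        separation = True
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, x).fit(method="lbfgs", disp=0, maxiter=500)
    prob = np.asarray(fit.predict(x), dtype=float)
    if not separation and np.all(np.abs(prob - y) < 1e-8):
        separation = True
    if separation:
        logger.warning("combined model: (quasi-)perfect separation — "
                       "coefficients are unstable")

    coef = pd.Series(np.asarray(fit.params, dtype=float), index=names)
    try:
        se = pd.Series(np.asarray(fit.bse, dtype=float), index=names)
    except Exception:
        se = pd.Series(np.nan, index=names)
    with np.errstate(invalid="ignore", divide="ignore"):
        zv = coef / se
    rng = pd.DataFrame({"min": data.min(), "max": data.max()})
    return NomogramModel(terms=list(data.columns), coef=coef, stderr=se,
                         zvalues=zv,
                         predicted=pd.Series(prob, index=data.index),
                         train_range=rng, separation_flag=separation)


# ---------------------------------------------------------------------------
# Points-based nomogram export
# ---------------------------------------------------------------------------

@dataclass
class NomogramTable:
    """Machine-readable nomogram: per-variable point mappings plus the
    total-points -> probability transform."""

    variables: pd.DataFrame      # term, coef, ref (value at 0 points), points_per_unit, max_points
    points_scale: float          # points per unit of linear predictor
    eta_at_zero_points: float    # linear predictor when total points = 0
    dropped: list

    def total_points(self, data: pd.DataFrame) -> pd.Series:
        pts = np.zeros(len(data))
        for _, row in self.variables.iterrows():
            x = data[row["term"]].to_numpy(dtype=float)
            pts += (x - row["ref"]) * row["points_per_unit"]
        return pd.Series(pts, index=data.index, name="total_points")

    def probability(self, total_points) -> np.ndarray:
        eta = np.asarray(total_points, dtype=float) / self.points_scale \
            + self.eta_at_zero_points
        return expit(eta)

    def to_json(self, path) -> None:
        payload = {
            "points_scale": self.points_scale,
            "eta_at_zero_points": self.eta_at_zero_points,
            "dropped": list(self.dropped),
            "variables": self.variables.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def export_nomogram(model: NomogramModel, plot_path=None) -> NomogramTable:
    """Convert the fitted logistic model into a points table (0-100 per
    variable; the largest absolute effect spans exactly 100 points) and
    optionally render the familiar axis plot.

    Each variable earns ``coef * (value - ref)`` points after rescaling,
    where ``ref`` is the variable's end of least risk, so points are
    non-negative and monotone in the effect direction.  A zero-range
    variable carries no information and is excluded with a warning.
    """
    rows = []
    dropped = []
    for t in model.terms:
        lo = float(model.train_range.loc[t, "min"])
        hi = float(model.train_range.loc[t, "max"])
        beta = float(model.coef[t])
        span = beta * (hi - lo)
        if hi <= lo:
            dropped.append(t)
            logger.warning("nomogram: variable %s has zero range; excluded", t)
            continue
        rows.append({"term": t, "coef": beta, "min": lo, "max": hi,
                     "ref": lo if beta >= 0 else hi,
                     "effect_span": abs(span)})
    if not rows:
        raise ValueError("no variable with nonzero range to render")
    var = pd.DataFrame(rows)
    max_span = var["effect_span"].max()
    if max_span <= 0:
        # all coefficients zero: points are identically zero, probability
        # is the intercept-only constant
        scale = 1.0
    else:
        scale = 100.0 / max_span
    var["points_per_unit"] = var["coef"] * scale
    var["max_points"] = var["effect_span"] * scale

    # eta when every variable sits at its reference value
    eta0 = float(model.coef["intercept"])
    for _, row in var.iterrows():
        eta0 += row["coef"] * row["ref"]
    # dropped zero-range variables still contribute their constant value
    for t in dropped:
        eta0 += float(model.coef[t]) * float(model.train_range.loc[t, "min"])

    table = NomogramTable(variables=var, points_scale=scale,
                          eta_at_zero_points=eta0, dropped=dropped)
    if plot_path is not None:
        _render(table, plot_path)
    return table


def _render(table: NomogramTable, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    var = table.variables
    n = len(var)
    fig, ax = plt.subplots(figsize=(8, 1.2 * (n + 3)))
    ax.set_xlim(-5, 105)
    ax.set_ylim(-2.5, n + 1)
    ax.axis("off")

    ax.hlines(n, 0, 100, color="k")
    for p in range(0, 101, 10):
        ax.vlines(p, n - 0.08, n + 0.08, color="k")
        ax.text(p, n + 0.15, str(p), ha="center", fontsize=8)
    ax.text(-4, n, "Points", ha="right", va="center", fontsize=9)

    for i, (_, row) in enumerate(var.iterrows()):
        y = n - 1 - i
        ax.hlines(y, 0, row["max_points"], color="tab:blue")
        for frac in (0.0, 0.5, 1.0):
            p = frac * row["max_points"]
            val = row["ref"] + p / row["points_per_unit"] \
                if row["points_per_unit"] else row["ref"]
            ax.vlines(p, y - 0.08, y + 0.08, color="tab:blue")
            ax.text(p, y - 0.35, f"{val:.2g}", ha="center", fontsize=7)
        ax.text(-4, y, row["term"], ha="right", va="center", fontsize=9)

    total_max = float(var["max_points"].sum())
    ax.hlines(-1, 0, min(total_max, 100 * n), color="k")
    ax.text(-4, -1, "Total points", ha="right", va="center", fontsize=9)
    for frac in np.linspace(0, 1, 6):
        tp = frac * total_max
        prob = float(table.probability([tp])[0])
        ax.vlines(tp, -1.08, -0.92, color="k")
        ax.text(tp, -1.35, f"{tp:.0f}", ha="center", fontsize=7)
        ax.text(tp, -1.85, f"p={prob:.2f}", ha="center", fontsize=7,
                color="tab:red")
    ax.text(-4, -1.85, "pCR probability", ha="right", va="center",
            fontsize=9, color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
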