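"""Scanner batch-effect harmonization of feature tables.

Two methods are provided, both operating feature-wise on a samples x
features table with a batch label per sample:

* **ComBat** — parametric empirical-Bayes location/scale adjustment.
  Each feature is standardized by its grand mean and pooled SD; batch
  location and scale parameters are shrunk toward common priors (normal
  prior on location, inverse-gamma on scale, hyperparameters by method
  of moments) with the usual iterative conditional estimates; values
  are then re-scaled back.  Suitable for small per-batch sample sizes,
  which is exactly the multicenter radiomics situation.
* **Limma-style linear removal** — per feature, ordinary least squares
  of the value on batch indicators (sum-to-zero coding); the batch
  coefficients are subtracted so all batch means coincide, and the
  overall feature mean is preserved exactly.

Both return a fitted :class:`HarmonizationModel` so held-out samples
from batches seen at fit time can be adjusted without re-estimation
(leakage-safe mode).  Biological covariates (e.g. outcome, receptor
status) can optionally be protected: they enter the model design and
their fitted contribution is left untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .table import FeatureTable

logger = logging.getLogger("tlradiomics")

#: empirical-Bayes iteration controls (standard ComBat practice)
EB_CONV = 1e-4
EB_MAX_ITER = 100

METHODS = ("none", "combat", "limma")


@dataclass
class HarmonizationModel:
    """Fitted per-batch, per-feature adjustments.

    ``method="none"`` stores nothing and transforms as identity.
    For ComBat, ``location``/``scale`` hold the EB estimates
    (gamma*, delta*) on the standardized scale; for limma they hold the
    batch-mean offsets (and scale is all-ones).
    """

    method: str
    feature_ids: list = field(default_factory=list)
    batches: list = field(default_factory=list)
    grand_mean: pd.Series | None = None        # per-feature alpha
    pooled_sd: pd.Series | None = None         # per-feature pooled SD
    location: pd.DataFrame | None = None       # batch x feature
    scale: pd.DataFrame | None = None          # batch x feature (>0)
    protect: list = field(default_factory=list)
    covar_coef: pd.DataFrame | None = None     # protect-covariate x feature
    passthrough: list = field(default_factory=list)


def _check_batches(table: FeatureTable) -> pd.Series:
    batch = table.batch.astype(str)
    counts = batch.value_counts()
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"every batch needs >= 2 samples; offending: {bad}")
    return batch


def _covariate_matrix(table: FeatureTable, protect: list) -> np.ndarray:
    cols = []
    for c in protect:
        if c not in table.sample_meta:
            raise KeyError(f"protected covariate {c!r} not in sample_meta")
        cols.append(table.sample_meta[c].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((table.n_samples, 0))


def _fit_location_model(x, batch_codes, n_batches, mod):
    """OLS of features on [batch one-hot | covariates]; returns per-batch
    means (adjusted), covariate coefficients, and fitted values."""
    n = x.shape[0]
    onehot = np.zeros((n, n_batches))
    onehot[np.arange(n), batch_codes] = 1.0
    design = np.hstack([onehot, mod])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    batch_means = coef[:n_batches]          # (n_batches, p)
    covar_coef = coef[n_batches:]           # (n_mod, p)
    fitted = design @ coef
    return batch_means, covar_coef, fitted


def _eb_adjust(gamma_hat, delta_hat, s_batch):
    """One batch's iterative EB estimates (gamma*, delta*), vectorized
    over features.  Falls back to the raw estimates when the moment
    hyperpriors are degenerate (e.g. a single feature)."""
    n_b = s_batch.shape[0]
    gamma_bar = gamma_hat.mean()
    t2 = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 0.0
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1) if delta_hat.size > 1 else 0.0
    if not (np.isfinite(t2) and t2 > 0 and np.isfinite(s2) and s2 > 0):
        return gamma_hat.copy(), delta_hat.copy()
    a = (2.0 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2

    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(EB_MAX_ITER):
        g_new = (t2 * n_b * gamma_hat + d_old * gamma_bar) / (t2 * n_b + d_old)
        sum2 = ((s_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n_b / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-30)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-30)))
        g_old, d_old = g_new, d_new
        if change < EB_CONV:
            break
    return g_old, d_old


def combat_fit_transform(table: FeatureTable, protect: list | None = None
                         ) -> tuple[FeatureTable, HarmonizationModel]:
    """Fit parametric ComBat on ``table`` and return the adjusted table
    plus the fitted model.

    A single batch is returned unchanged (identity model, warning).  A
    feature that is constant within any batch cannot be standardized per
    batch; it passes through unadjusted and is logged.
    """
    protect = list(protect or [])
    batch = table.batch.astype(str)
    batches = list(dict.fromkeys(batch))
    if len(batches) < 2:
        logger.warning("ComBat: single batch — identity transform")
        return table, HarmonizationModel("none")
    _check_batches(table)
    mod = _covariate_matrix(table, protect)

    x = table.matrix()
    n, p = x.shape
    codes = np.array([batches.index(b) for b in batch])
    n_per = np.bincount(codes, minlength=len(batches)).astype(float)

    batch_means, covar_coef, fitted = _fit_location_model(
        x, codes, len(batches), mod)
    # grand mean = sample-size-weighted mean of the fitted batch means
    alpha = (n_per / n) @ batch_means                        # (p,)
    var_pooled = ((x - fitted) ** 2).mean(axis=0)            # denominator N

    # features constant within some batch, or with no residual variance,
    # cannot be adjusted — pass them through
    within_ok = np.ones(p, dtype=bool)
    for bi in range(len(batches)):
        sub = x[codes == bi]
        within_ok &= sub.std(axis=0) > 0
    adjustable = within_ok & (var_pooled > 0)
    if (~adjustable).any():
        logger.warning("ComBat: %d feature(s) constant within a batch — "
                       "passed through unadjusted", int((~adjustable).sum()))

    stand_mean = alpha[None, :] + mod @ covar_coef           # (n, p)
    sd = np.sqrt(var_pooled, where=adjustable, out=np.ones(p))
    s_data = (x - stand_mean) / sd[None, :]

    gamma_star = np.zeros((len(batches), p))
    delta_star = np.ones((len(batches), p))
    cols = np.flatnonzero(adjustable)
    for bi in range(len(batches)):
        s_b = s_data[codes == bi][:, cols]
        gamma_hat = s_b.mean(axis=0)
        delta_hat = s_b.var(axis=0, ddof=1)
        g, d = _eb_adjust(gamma_hat, delta_hat, s_b)
        gamma_star[bi, cols] = g
        delta_star[bi, cols] = np.maximum(d, 1e-30)

    adj = (s_data - gamma_star[codes]) / np.sqrt(delta_star[codes])
    out = adj * sd[None, :] + stand_mean
    out[:, ~adjustable] = x[:, ~adjustable]

    fids = list(table.feature_ids)
    model = HarmonizationModel(
        method="combat",
        feature_ids=fids,
        batches=batches,
        grand_mean=pd.Series(alpha, index=fids),
        pooled_sd=pd.Series(sd, index=fids),
        location=pd.DataFrame(gamma_star, index=batches, columns=fids),
        scale=pd.DataFrame(delta_star, index=batches, columns=fids),
        protect=protect,
        covar_coef=pd.DataFrame(covar_coef, index=protect, columns=fids),
        passthrough=list(table.feature_ids[~adjustable]),
    )
    return table.with_values(out, note="ComBat harmonized"), model


def limma_fit_transform(table: FeatureTable, protect: list | None = None
                        ) -> tuple[FeatureTable, HarmonizationModel]:
    """Remove batch effects by per-feature linear regression on batch.

    Equivalent to subtracting each batch's fitted mean offset from the
    sample-size-weighted grand mean: afterwards every batch mean equals
    the grand mean exactly (without protected covariates), and the
    overall feature mean is preserved exactly.
    """
    protect = list(protect or [])
    batch = table.batch.astype(str)
    batches = list(dict.fromkeys(batch))
    if len(batches) < 2:
        logger.warning("limma removal: single batch — identity transform")
        return table, HarmonizationModel("none")
    _check_batches(table)
    mod = _covariate_matrix(table, protect)

    x = table.matrix()
    n = x.shape[0]
    codes = np.array([batches.index(b) for b in batch])
    n_per = np.bincount(codes, minlength=len(batches)).astype(float)

    batch_means, covar_coef, _ = _fit_location_model(x, codes, len(batches), mod)
    grand = (n_per / n) @ batch_means
    offsets = batch_means - grand[None, :]   # weighted-mean-zero batch offsets
    out = x - offsets[codes]

    fids = list(table.feature_ids)
    model = HarmonizationModel(
        method="limma",
        feature_ids=fids,
        batches=batches,
        grand_mean=pd.Series(grand, index=fids),
        location=pd.DataFrame(offsets, index=batches, columns=fids),
        scale=pd.DataFrame(np.ones_like(offsets), index=batches, columns=fids),
        protect=protect,
        covar_coef=pd.DataFrame(covar_coef, index=protect, columns=fids),
    )
    return table.with_values(out, note="limma batch-removed"), model


def fit_transform(table: FeatureTable, method: str,
                  protect: list | None = None
                  ) -> tuple[FeatureTable, HarmonizationModel]:
    """Dispatch on ``method`` in {none, combat, limma}."""
    if method == "none":
        return table, HarmonizationModel("none")
    if method == "combat":
        return combat_fit_transform(table, protect)
    if method == "limma":
        return limma_fit_transform(table, protect)
    raise ValueError(f"unknown harmonization method {method!r}; "
                     f"choose from {METHODS}")


def batch_predictability_auc(table: FeatureTable, batch_a: str, batch_b: str,
                             method: str = "none", probe_seed: int = 0
                             ) -> float:
    """How well a linear classifier can tell two scanners apart.

    Diagnostic for residual batch leakage: samples of the two batches
    are split in half; harmonization (if any) is fitted on the probe
    training half only and frozen onto the probe test half, so the fit
    cannot couple the two halves; a logistic classifier trained on the
    training half is scored on the test half.  Returns the symmetric
    AUC ``max(a, 1 - a)`` — an anti-predicting classifier leaks batch
    information just as much as a predicting one.

    Note that fitting the harmonization on the *full* table instead
    would impose per-batch sum constraints that let a high-dimensional
    classifier anti-predict held-out samples; that artefact is exactly
    what the frozen-fit design here avoids.
    """
    from sklearn.linear_model import LogisticRegression

    sub = table.select_samples(
        table.sample_ids[table.batch.isin([batch_a, batch_b])])
    y = (sub.batch == batch_b).astype(int).to_numpy()
    rng = np.random.default_rng(probe_seed)
    idx = rng.permutation(sub.n_samples)
    half = sub.n_samples // 2
    tr, te = idx[:half], idx[half:]
    train = sub.select_samples(sub.sample_ids[tr])
    test = sub.select_samples(sub.sample_ids[te])

    if method != "none":
        train, model = fit_transform(train, method)
        test = apply_model(model, test)
    clf = LogisticRegression(max_iter=2000).fit(train.matrix(), y[tr])
    scores = clf.decision_function(test.matrix())
    from .stats import auc
    a = float(auc(scores, y[te]))
    return max(a, 1.0 - a)


def apply_model(model: HarmonizationModel, table: FeatureTable) -> FeatureTable:
    """Adjust ``table`` with a previously fitted model (no re-estimation).

    Every batch present must have been seen at fit time.
    """
    if model.method == "none":
        return table
    batch = table.batch.astype(str)
    unseen = sorted(set(batch) - set(model.batches))
    if unseen:
        raise ValueError(f"batch {unseen[0]!r} was not seen at fit time")
    missing = [f for f in model.feature_ids if f not in table.feature_ids]
    if missing:
        raise KeyError(f"table lacks fitted feature {missing[0]!r}")

    sub = table.values.loc[:, model.feature_ids]
    x = sub.to_numpy(dtype=float)
    codes = np.array([model.batches.index(b) for b in batch])
    mod = _covariate_matrix(table, model.protect)
    covar = mod @ model.covar_coef.to_numpy() if model.protect else 0.0

    if model.method == "limma":
        out = x - model.location.to_numpy()[codes]
    else:
        alpha = model.grand_mean.to_numpy()
        sd = model.pooled_sd.to_numpy()
        stand_mean = alpha[None, :] + covar
        z = (x - stand_mean) / sd[None, :]
        g = model.location.to_numpy()[codes]
        d = model.scale.to_numpy()[codes]
        out = (z - g) / np.sqrt(d) * sd[None, :] + stand_mean
        if model.passthrough:
            idx = [model.feature_ids.index(f) for f in model.passthrough]
            out[:, idx] = x[:, idx]

    values = table.values.copy()
    values.loc[:, model.feature_ids] = out
    return table.with_values(values, note=f"{model.method} applied (frozen fit)")
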