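"""Synthetic multi-scanner radiomic cohort generator with known ground truth.

Real multicenter PET/CT radiomics cohorts are private, so every pipeline
stage here is exercised on simulated feature tables whose generative
parameters are recorded and returned (``SyntheticCohort.truth``).  The
generator emulates the statistical structure of extracted features, not
the images:

* a positive, log-normal per-feature base level (SUV- and HU-derived
  features are positive, and tumor-to-liver ratios must never divide by
  zero by construction);
* an additive class effect on a known subset of informative features for
  pCR patients, expressed as a standardized mean difference;
* per-(scanner, feature) additive and multiplicative batch effects;
* a per-patient global multiplicative uptake factor on all PET
  *intensity* features of both tumor and liver (shape features are
  geometric and receive none) — the nuisance that tumor-to-liver ratios
  cancel;
* i.i.d. Gaussian residual noise;
* a binary pCR outcome with logistic dependence on ER/PR/HER2 status;
* three replicate tables (two readers, one reading twice) for ICC
  filtering, with a configurable subset of features given large
  replicate noise so the reproducibility filter has something to catch.

The value model, per sample i, feature f, batch b(i)::

    value = (base_f + delta_f * informative_f * pCR_i + shift_bf)
            * scale_bf * uptake_i**is_pet_intensity_f  +  eps_if

with ``delta_f = effect_size * noise_sd * sign_f`` and
``eps ~ N(0, noise_sd^2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .table import FeatureTable

logger = logging.getLogger("tlradiomics")

#: log-scale location/spread of tumor base levels and liver base levels
_TUMOR_BASE_LOG_MEAN, _TUMOR_BASE_LOG_SD = np.log(10.0), 0.5
_LIVER_BASE_LOG_MEAN, _LIVER_BASE_LOG_SD = np.log(5.0), 0.3

#: marginal prevalence of positive receptor status used for the clinical
#: covariates (typical of NAC-treated breast-cancer cohorts)
_COVARIATE_PREVALENCE = {"ER": 0.60, "PR": 0.55, "HER2": 0.30}


class DesignError(ValueError):
    """A SimulationDesign field is invalid; the message names the field."""


@dataclass
class SimulationDesign:
    """Parameters of the synthetic multicenter cohort.

    Defaults describe three scanners of 50 patients each, 200 radiomic
    features (half CT, half PET) of which 20 carry a standardized class
    effect of 0.8, moderate batch effects, and a per-patient PET uptake
    nuisance — a deliberately recoverable desk-scale stand-in for a
    ~150-patient three-scanner cohort.
    """

    n_per_batch: dict = field(
        default_factory=lambda: {"scanner1": 50, "scanner2": 50, "scanner3": 50})
    n_features_ct: int = 100
    n_features_pet: int = 100
    n_informative: int = 20
    effect_size: float = 0.8          # standardized mean difference, pCR vs non-pCR
    batch_shift_sd: float = 0.5       # SD of additive per-(batch,feature) shifts
    batch_scale_sd: float = 0.1       # SD of log multiplicative per-(batch,feature) factors
    uptake_sd: float = 0.3            # SD of log per-patient global PET uptake factor
    noise_sd: float = 1.0             # residual SD on the feature scale
    pcr_prevalence: float = 0.35      # ~52/147
    clinical_or: dict = field(
        default_factory=lambda: {"ER": 0.35, "PR": 0.5, "HER2": 2.8})
    pet_informative_fraction: float = 0.8  # share of informative features on PET
    replicate_noise_sd: float = 0.2   # replicate SD, relative to each feature's SD
    unstable_fraction: float = 0.1    # fraction of features with poor reproducibility
    unstable_noise_sd: float = 2.0    # replicate SD of unstable features (relative)
    shape_fraction: float = 0.1       # fraction of features per modality flagged shape
    seed: int = 7

    @property
    def n_features(self) -> int:
        return self.n_features_ct + self.n_features_pet

    @property
    def n_samples(self) -> int:
        return int(sum(self.n_per_batch.values()))

    def validate(self) -> None:
        if not self.n_per_batch:
            raise DesignError("n_per_batch: must name at least one batch")
        for b, n in self.n_per_batch.items():
            if int(n) <= 0:
                raise DesignError(f"n_per_batch[{b!r}]: counts must be positive")
        for name in ("n_features_ct", "n_features_pet"):
            if int(getattr(self, name)) <= 0:
                raise DesignError(f"{name}: must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise DesignError(
                "n_informative: must lie in [0, n_features_ct + n_features_pet]")
        if not 0.0 < self.pcr_prevalence < 1.0:
            raise DesignError("pcr_prevalence: must be strictly inside (0, 1)")
        for name in ("batch_shift_sd", "batch_scale_sd", "uptake_sd", "noise_sd",
                     "replicate_noise_sd", "unstable_noise_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name}: standard deviations must be >= 0")
        if not 0.0 <= self.unstable_fraction <= 1.0:
            raise DesignError("unstable_fraction: must lie in [0, 1]")
        if not 0.0 <= self.pet_informative_fraction <= 1.0:
            raise DesignError("pet_informative_fraction: must lie in [0, 1]")
        if not 0.0 <= self.shape_fraction < 1.0:
            raise DesignError("shape_fraction: must lie in [0, 1)")
        if self.effect_size < 0:
            raise DesignError("effect_size: must be >= 0")


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground truth used to generate them."""

    tumor_table: FeatureTable          # CT + PET tumor features
    liver_table: FeatureTable          # liver PET features, same samples
    replicates: dict                   # {"reader1a", "reader1b", "reader2"} -> FeatureTable
    truth: dict
    design: SimulationDesign


def _solve_intercept(log_or: dict, prevalence: float) -> float:
    """Intercept making the marginal pCR rate equal ``prevalence`` given
    independent Bernoulli covariates with the module's receptor prevalences."""
    names = list(log_or)
    probs = [_COVARIATE_PREVALENCE.get(n, 0.5) for n in names]

    def marginal(b0: float) -> float:
        total = 0.0
        for combo in product([0, 1], repeat=len(names)):
            w = np.prod([p if x else 1 - p for p, x in zip(probs, combo)])
            eta = b0 + sum(lo * x for lo, x in zip(log_or.values(), combo))
            total += w * expit(eta)
        return total - prevalence

    return brentq(marginal, -25.0, 25.0)


def _feature_meta(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for modality, n in (("CT", design.n_features_ct), ("PET", design.n_features_pet)):
        n_shape = int(round(design.shape_fraction * n))
        for j in range(n):
            rows.append({
                "feature_id": f"{modality}_f{j:03d}",
                "modality": modality,
                # shape/volume features are the first block of each modality
                "family": "shape" if j < n_shape else "intensity",
                "is_shape": int(j < n_shape),
            })
    return pd.DataFrame(rows).set_index("feature_id")


def simulate_cohort(design: SimulationDesign) -> SyntheticCohort:
    """Generate one multi-scanner cohort from ``design``.

    Deterministic: the same design (including ``seed``) yields a
    bit-identical cohort.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    batches = list(design.n_per_batch)
    batch_of = np.repeat(batches, [design.n_per_batch[b] for b in batches])
    n = len(batch_of)
    sample_ids = pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id")

    fmeta = _feature_meta(design, rng)
    fids = fmeta.index
    p = len(fids)
    is_pet = (fmeta["modality"] == "PET").to_numpy()
    is_shape = fmeta["is_shape"].to_numpy(dtype=bool)
    pet_intensity = is_pet & ~is_shape

    # ---- clinical covariates and outcome --------------------------------
    log_or = {k: float(np.log(v)) for k, v in design.clinical_or.items()}
    b0 = _solve_intercept(log_or, design.pcr_prevalence)
    clin = {k: (rng.random(n) < _COVARIATE_PREVALENCE.get(k, 0.5)).astype(int)
            for k in log_or}
    eta = b0 + sum(lo * clin[k] for k, lo in log_or.items())
    outcome = (rng.random(n) < expit(eta)).astype(int)

    # ---- ground-truth generative parameters -----------------------------
    base = np.exp(rng.normal(_TUMOR_BASE_LOG_MEAN, _TUMOR_BASE_LOG_SD, p))
    # informative features sit predominantly on PET intensity features:
    # in FDG-PET oncology the metabolic features carry the outcome signal,
    # which is also what makes liver normalization consequential
    eligible_pet = np.flatnonzero(pet_intensity)
    eligible_ct = np.flatnonzero(~is_shape & ~is_pet)
    if design.n_informative > len(eligible_pet) + len(eligible_ct):
        raise DesignError(
            "n_informative: exceeds the number of non-shape features")
    n_pet_inf = min(int(round(design.pet_informative_fraction
                              * design.n_informative)), len(eligible_pet))
    n_ct_inf = min(design.n_informative - n_pet_inf, len(eligible_ct))
    n_pet_inf = design.n_informative - n_ct_inf
    informative_idx = np.sort(np.concatenate([
        rng.choice(eligible_pet, n_pet_inf, replace=False),
        rng.choice(eligible_ct, n_ct_inf, replace=False)]).astype(int))
    signs = rng.choice([-1.0, 1.0], design.n_informative)
    delta = np.zeros(p)
    delta[informative_idx] = design.effect_size * design.noise_sd * signs

    shift = rng.normal(0.0, design.batch_shift_sd, (len(batches), p))
    scale = np.exp(rng.normal(0.0, design.batch_scale_sd, (len(batches), p)))
    uptake = np.exp(rng.normal(0.0, design.uptake_sd, n))

    b_idx = np.array([batches.index(b) for b in batch_of])
    y = outcome[:, None]
    uptake_exp = np.where(pet_intensity[None, :], uptake[:, None], 1.0)
    noise = rng.normal(0.0, design.noise_sd, (n, p))
    values = ((base[None, :] + delta[None, :] * y + shift[b_idx, :])
              * scale[b_idx, :] * uptake_exp + noise)

    sample_meta = pd.DataFrame(
        {"batch": batch_of, "outcome": outcome, **clin}, index=sample_ids)
    tumor = FeatureTable(
        pd.DataFrame(values, index=sample_ids, columns=fids),
        sample_meta, fmeta, provenance=["simulated tumor table"])

    # ---- liver table (PET intensity features only) ----------------------
    liver_fids = fids[pet_intensity]
    pl = len(liver_fids)
    liver_base = np.exp(rng.normal(_LIVER_BASE_LOG_MEAN, _LIVER_BASE_LOG_SD, pl))
    liver_shift = rng.normal(0.0, design.batch_shift_sd, (len(batches), pl))
    liver_scale = np.exp(rng.normal(0.0, design.batch_scale_sd, (len(batches), pl)))
    liver_noise = rng.normal(0.0, design.noise_sd, (n, pl))
    liver_values = ((liver_base[None, :] + liver_shift[b_idx, :])
                    * liver_scale[b_idx, :] * uptake[:, None] + liver_noise)
    liver = FeatureTable(
        pd.DataFrame(liver_values, index=sample_ids, columns=liver_fids),
        sample_meta.copy(), fmeta.loc[liver_fids].copy(),
        provenance=["simulated liver table"])

    # ---- segmentation replicates ----------------------------------------
    n_unstable = int(round(design.unstable_fraction * p))
    unstable_idx = np.sort(rng.choice(p, n_unstable, replace=False)) \
        if n_unstable else np.array([], dtype=int)
    feat_sd = values.std(axis=0, ddof=1) if n > 1 else np.ones(p)
    feat_sd = np.where(feat_sd > 0, feat_sd, 1.0)
    rep_sd = design.replicate_noise_sd * feat_sd
    rep_sd[unstable_idx] = design.unstable_noise_sd * feat_sd[unstable_idx]
    replicates = {}
    for name in ("reader1a", "reader1b", "reader2"):
        pert = rng.normal(0.0, 1.0, (n, p)) * rep_sd[None, :]
        replicates[name] = tumor.with_values(values + pert,
                                             note=f"replicate {name}")

    truth = {
        "informative_features": list(fids[informative_idx]),
        "class_effect": dict(zip(fids[informative_idx], delta[informative_idx])),
        "unstable_features": list(fids[unstable_idx]),
        "uptake_factor": pd.Series(uptake, index=sample_ids),
        "batch_shift": pd.DataFrame(shift, index=batches, columns=fids),
        "batch_scale": pd.DataFrame(scale, index=batches, columns=fids),
        "base_level": pd.Series(base, index=fids),
        "clinical_log_or": log_or,
        "clinical_intercept": b0,
    }
    logger.info("simulated cohort: %d samples, %d features (%d informative), "
                "%d batches", n, p, design.n_informative, len(batches))
    return SyntheticCohort(tumor, liver, replicates, truth, design)


def bayes_auc(design: SimulationDesign, n_draws: int = 100_000,
              seed: int | None = None) -> float:
    """Monte-Carlo AUC of the oracle score under ``design``.

    The oracle knows the informative-feature set, the class-effect signs
    and all nuisance parameters; its score for a sample is the
    sign-corrected sum of the nuisance-inverted informative features,
    leaving ``delta*y + eps/(scale*uptake)`` per feature.  This is the
    recovery ceiling no trained model can beat in expectation.
    """
    design.validate()
    if design.n_informative == 0 or design.effect_size == 0.0:
        return 0.5
    rng = np.random.default_rng(design.seed if seed is None else seed)
    m = design.n_informative
    batches = list(design.n_per_batch)
    probs = np.array([design.n_per_batch[b] for b in batches], dtype=float)
    probs /= probs.sum()

    delta = design.effect_size * design.noise_sd  # sign folded into the score
    # one realisation of the per-(batch,feature) scales, as in a real cohort
    scale = np.exp(rng.normal(0.0, design.batch_scale_sd, (len(batches), m)))
    # informative features are PET-weighted per the design
    is_pet = rng.random(m) < design.pet_informative_fraction

    y = (rng.random(n_draws) < design.pcr_prevalence).astype(float)
    b = rng.choice(len(batches), n_draws, p=probs)
    uptake = np.exp(rng.normal(0.0, design.uptake_sd, n_draws))
    eps = rng.normal(0.0, design.noise_sd, (n_draws, m))
    denom = scale[b, :] * np.where(is_pet[None, :], uptake[:, None], 1.0)
    score = (delta * y[:, None] + eps / denom).sum(axis=1)

    from .stats import auc  # local import to avoid a cycle at import time
    if y.min() == y.max():  # pathological prevalence draw at tiny n_draws
        return 0.5
    return float(auc(score, y.astype(int)))
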