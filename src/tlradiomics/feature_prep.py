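"""Reproducibility filtering, redundancy pruning, and OR/TLR assembly.

Radiomic features that are not stable under repeated segmentation are
removed first (ICC filter), highly collinear features are then pruned
(Pearson filter), and the two candidate feature sets are assembled:

* **OR** ("origin radiomics") — raw CT + PET tumor features;
* **TLR** (tumor-to-liver ratio) — each PET tumor *intensity* feature
  divided elementwise by its same-named liver counterpart, cancelling
  the per-patient global uptake nuisance; shape/volume features are
  geometric and pass through unchanged, as do all CT features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import AlignmentError, FeatureTable, check_same_grid

logger = logging.getLogger("tlradiomics")


# ---------------------------------------------------------------------------
# ICC(2,1) reproducibility filter
# ---------------------------------------------------------------------------

@dataclass
class ICCReport:
    """Per-feature minimum pairwise ICC and the retained feature list."""

    icc_min: pd.Series              # feature_id -> min pairwise ICC (NaN if undefined)
    icc_pairs: pd.DataFrame         # feature_id x pair-label matrix of ICCs
    retained: list                  # feature ids with all pairwise ICCs > threshold
    threshold: float


def _icc21_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) — two-way random effects, absolute agreement,
    single rater — for two raters over columns of (n_subjects, n_features)
    arrays.  Returns NaN where the feature has no variance in the pair."""
    n = x.shape[0]
    k = 2
    grand = (x + y) / 2.0
    m = grand.mean(axis=0)
    row_mean = grand                       # per-subject mean of the two raters
    col_mean = np.stack([x.mean(axis=0), y.mean(axis=0)])   # (2, p)

    msr = k * ((row_mean - m) ** 2).sum(axis=0) / (n - 1)
    msc = n * ((col_mean - m) ** 2).sum(axis=0) / (k - 1)
    resid = np.stack([x, y]) - row_mean[None, :, :] \
        - col_mean[:, None, :] + m[None, None, :]
    mse = (resid ** 2).sum(axis=(0, 1)) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (msr - mse) / denom
    icc[np.isclose(denom, 0.0)] = np.nan
    return icc


def icc_filter(rep_a: FeatureTable, rep_b: FeatureTable, rep_c: FeatureTable,
               threshold: float = 0.75) -> ICCReport:
    """Retain features whose ICC(2,1) exceeds ``threshold`` in *every*
    pairwise comparison of the three replicate segmentations.

    The three tables must share identical samples and features.  A
    feature with zero variance in any pair has an undefined ICC; it is
    recorded as NaN and dropped, with a logged warning.  The result is
    symmetric in the order of the replicates.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    try:
        check_same_grid(rep_a, rep_b, rep_c)
    except AlignmentError as err:
        raise AlignmentError(f"replicate tables misaligned: {err}") from err

    mats = [t.matrix() for t in (rep_a, rep_b, rep_c)]
    pairs = {"ab": (0, 1), "ac": (0, 2), "bc": (1, 2)}
    icc = pd.DataFrame(
        {label: _icc21_pair(mats[i], mats[j]) for label, (i, j) in pairs.items()},
        index=rep_a.feature_ids)
    icc_min = icc.min(axis=1)
    undefined = icc.isna().any(axis=1)
    if undefined.any():
        logger.warning("ICC undefined (zero variance) for %d feature(s); dropped",
                       int(undefined.sum()))
    retained = list(icc_min.index[(icc > threshold).all(axis=1) & ~undefined])
    logger.info("ICC filter: %d/%d features retained at threshold %.2f",
                len(retained), len(icc_min), threshold)
    return ICCReport(icc_min=icc_min, icc_pairs=icc, retained=retained,
                     threshold=threshold)


# ---------------------------------------------------------------------------
# Pearson redundancy pruning
# ---------------------------------------------------------------------------

def correlation_prune(table: FeatureTable, r_max: float = 0.9) -> FeatureTable:
    """Greedy redundancy pruning in deterministic column order.

    Features are visited left to right; a feature is dropped if its
    absolute Pearson correlation with any already-kept feature exceeds
    ``r_max``.  A constant feature has undefined correlation; it is
    treated as correlation 0 (never pruned *for correlation*) and logged.
    """
    if not 0.0 < r_max < 1.0:
        raise ValueError("r_max must lie in (0, 1)")
    if table.n_samples < 2:
        raise ValueError("correlation pruning needs at least 2 samples")

    x = table.matrix()
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("correlation undefined for %d constant feature(s); "
                       "treated as r=0", int(constant.sum()))
    # z-score non-constant columns once; constants correlate 0 with everything
    z = np.zeros_like(x)
    ok = ~constant
    z[:, ok] = (x[:, ok] - x[:, ok].mean(axis=0)) / sd[ok]
    denom = table.n_samples - 1

    kept: list[int] = []
    for j in range(table.n_features):
        if kept:
            r = np.abs(z[:, kept].T @ z[:, j]) / denom
            if np.any(r > r_max):
                continue
        kept.append(j)
    out = table.select_features(table.feature_ids[kept],
                                note=f"pruned |r|>{r_max}")
    logger.info("correlation pruning: %d/%d features kept at |r| <= %.2f",
                out.n_features, table.n_features, r_max)
    return out


# ---------------------------------------------------------------------------
# OR / TLR assembly
# ---------------------------------------------------------------------------

def assemble_or(ct_pet_tumor: FeatureTable) -> FeatureTable:
    """Tag the combined CT + PET tumor table as the OR feature set.

    Identity on the values; raises if either modality is missing, since
    the OR set is by definition the union of both.
    """
    modalities = set(ct_pet_tumor.feature_meta["modality"])
    missing = {"CT", "PET"} - modalities
    if missing:
        raise ValueError(f"OR assembly requires both modalities; missing {sorted(missing)}")
    return ct_pet_tumor.tagged("OR", note="assembled OR feature set")


def assemble_tlr(tumor: FeatureTable, liver: FeatureTable,
                 eps: float = 1e-12) -> FeatureTable:
    """Build the tumor-to-liver-ratio feature set.

    Every PET non-shape tumor feature is divided elementwise by its
    same-named liver feature; PET shape/volume features and all CT
    features pass through unchanged.  A feature whose liver denominator
    is smaller than ``eps`` in magnitude for any sample is excluded from
    the TLR set entirely (logged with a count); a missing liver
    counterpart is an error naming the feature.
    """
    fmeta = tumor.feature_meta
    pet_intensity = ((fmeta["modality"] == "PET")
                     & (fmeta.get("is_shape", 0) == 0))
    ratio_ids = list(fmeta.index[pet_intensity])
    missing = [f for f in ratio_ids if f not in liver.feature_ids]
    if missing:
        raise KeyError(f"liver table lacks counterpart for PET feature "
                       f"{missing[0]!r} ({len(missing)} missing in total)")
    if not tumor.sample_ids.equals(liver.sample_ids):
        raise AlignmentError("tumor and liver tables do not share samples")

    values = tumor.values.copy()
    denom = liver.values.loc[:, ratio_ids]
    degenerate = (denom.abs() < eps).any(axis=0)
    bad = list(degenerate.index[degenerate])
    if bad:
        logger.warning("TLR: %d feature(s) dropped for near-zero liver "
                       "denominator", len(bad))
    good = [f for f in ratio_ids if f not in set(bad)]
    values.loc[:, good] = tumor.values.loc[:, good] / denom.loc[:, good]
    if bad:
        values = values.drop(columns=bad)

    out = FeatureTable(values, tumor.sample_meta.copy(),
                       tumor.feature_meta.loc[values.columns].copy(),
                       provenance=list(tumor.provenance))
    return out.tagged("TLR", note="assembled TLR feature set "
                                  f"({len(good)} PET features ratioed)")
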