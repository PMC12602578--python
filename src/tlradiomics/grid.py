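"""The 630-configuration model-evaluation grid.

A configuration is one choice from each of five closed factors —
feature type (OR/TLR) x batch-effect method (none/ComBat/Limma) x
discretization (none/FBN32/FBN64/FBW32/FBW64) x tree-based feature
selector (DT/RF/XGB) x classifier (DT/ET/KNN/RF/SVM/XGB/SGD) — giving
2 * 3 * 5 * 3 * 7 = 630 models.

Each configuration is scored by the repeated down-sampled protocol:
patients from the training scanners are balanced by down-sampling the
majority outcome class to the minority count, split 80/20 into training
and validation sets, the selector keeps the top ten most important
features, the classifier is fitted, and AUCs are computed on the
validation set and on the held-out test scanner; the two AUCs averaged
over repeats — and the mean of those two means — summarise the
configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from . import discretization, harmonization
from .feature_prep import assemble_or, assemble_tlr, correlation_prune, icc_filter
from .stats import auc
from .table import FeatureTable

logger = logging.getLogger("tlradiomics")

FEATURE_TYPES = ("OR", "TLR")
BATCH_METHODS = ("none", "combat", "limma")
DISCRETIZATIONS = ("none", "FBN32", "FBN64", "FBW32", "FBW64")
SELECTORS = ("DT", "RF", "XGB")
CLASSIFIERS = ("DT", "ET", "KNN", "RF", "SVM", "XGB", "SGD")

#: number of features kept by the selector
TOP_K = 10


@dataclass(frozen=True)
class PipelineConfig:
    """One cell of the factorial grid."""

    feature_type: str
    batch_method: str
    discretization: str
    selector: str
    classifier: str

    def __post_init__(self) -> None:
        for name, value, valid in (
                ("feature_type", self.feature_type, FEATURE_TYPES),
                ("batch_method", self.batch_method, BATCH_METHODS),
                ("discretization", self.discretization, DISCRETIZATIONS),
                ("selector", self.selector, SELECTORS),
                ("classifier", self.classifier, CLASSIFIERS)):
            if value not in valid:
                raise ValueError(f"{name}={value!r} not in {valid}")

    def label(self) -> str:
        return "/".join((self.feature_type, self.batch_method,
                         self.discretization, self.selector, self.classifier))


def enumerate_grid() -> list[PipelineConfig]:
    """Full factorial grid in deterministic lexicographic factor order."""
    return [PipelineConfig(*combo) for combo in
            product(FEATURE_TYPES, BATCH_METHODS, DISCRETIZATIONS,
                    SELECTORS, CLASSIFIERS)]


# ---------------------------------------------------------------------------
# Down-sampled stratified splitting
# ---------------------------------------------------------------------------

def downsample_split(table: FeatureTable, train_fraction: float = 0.8,
                     rng_seed: int = 0) -> tuple[FeatureTable, FeatureTable]:
    """Balance the outcome classes by down-sampling, then split.

    The majority class is down-sampled without replacement to the
    minority count; each class is then split ``train_fraction`` /
    ``1 - train_fraction`` (train size per class is the floor).  All
    sampling is driven solely by ``rng_seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = table.outcome
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("both outcome classes must be present")
    if (counts < 2).any():
        raise ValueError("each outcome class needs >= 2 samples")
    n_min = int(counts.min())
    rng = np.random.default_rng(rng_seed)

    train_ids: list = []
    val_ids: list = []
    for cls in sorted(counts.index):
        ids = np.asarray(table.sample_ids[y == cls])
        ids = rng.permutation(ids)[:n_min]          # down-sample majority
        n_train = int(np.floor(train_fraction * n_min))
        train_ids.extend(ids[:n_train])
        val_ids.extend(ids[n_train:])
    return (table.select_samples(train_ids, note="train split"),
            table.select_samples(val_ids, note="validation split"))


# ---------------------------------------------------------------------------
# Model factories
# ---------------------------------------------------------------------------

def _make_selector(name: str, seed: int, params: dict | None = None):
    params = dict(params or {})
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "XGB":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", **params)
    raise ValueError(f"unknown selector {name!r}; valid: {SELECTORS}")


def _make_classifier(name: str, seed: int, params: dict | None = None):
    params = dict(params or {})
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "ET":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    if name == "KNN":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier(**params))])
    if name == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "SVM":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(random_state=seed, **params))])
    if name == "XGB":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", **params)
    if name == "SGD":
        # log loss so a probability score exists for the AUC
        params.setdefault("loss", "log_loss")
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SGDClassifier(random_state=seed, **params))])
    raise ValueError(f"unknown classifier {name!r}; valid: {CLASSIFIERS}")


def _ranking_scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(x)[:, 1]
        except AttributeError:
            pass
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(x), dtype=float)
    raise TypeError(f"{type(model).__name__} exposes neither predict_proba "
                    "nor decision_function")


@dataclass
class SelectedFeatures:
    """Top-k features with the selector's importance scores (used later
    as the radiomics-score weights)."""

    features: list
    weights: pd.Series          # importance, indexed by feature_id

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)


def select_features(train: FeatureTable, selector: str, k: int = TOP_K,
                    rng_seed: int = 0,
                    selector_params: dict | None = None) -> SelectedFeatures:
    """Rank features by a tree-based model's impurity/gain importance and
    keep the top ``k``; ties broken by feature (column) order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    model = _make_selector(selector, rng_seed, selector_params)
    x, y = train.matrix(), train.outcome.to_numpy()
    model.fit(x, y)
    imp = np.asarray(model.feature_importances_, dtype=float)
    order = np.lexsort((np.arange(imp.size), -imp))   # stable: importance desc
    top = order[:min(k, imp.size)]
    fids = [train.feature_ids[i] for i in top]
    return SelectedFeatures(features=fids,
                            weights=pd.Series(imp[top], index=fids))


# ---------------------------------------------------------------------------
# Preprocessing shared across configurations
# ---------------------------------------------------------------------------

def prepare_inputs(cohort, icc_threshold: float = 0.75, r_max: float = 0.9,
                   apply_icc: bool = True, apply_prune: bool = True) -> dict:
    """Assemble the OR and TLR tables from a synthetic cohort, applying
    the ICC reproducibility filter and the Pearson redundancy pruning
    once to the full dataset (the workflow's ordering; per-split modes
    exist on the individual operations)."""
    tumor = cohort.tumor_table
    if apply_icc:
        report = icc_filter(*[cohort.replicates[k] for k in
                              ("reader1a", "reader1b", "reader2")],
                            threshold=icc_threshold)
        tumor = tumor.select_features(report.retained, note="ICC filtered")
    or_table = assemble_or(tumor)
    tlr_table = assemble_tlr(tumor, cohort.liver_table)
    if apply_prune:
        or_table = correlation_prune(or_table, r_max)
        tlr_table = correlation_prune(tlr_table, r_max)
    return {"OR": or_table, "TLR": tlr_table}


def _preprocess(table: FeatureTable, batch_method: str, disc: str,
                leakage_safe_batches: list | None = None) -> FeatureTable:
    """Harmonize then discretize one assembled table.

    Default mode fits both steps on the full table (train + validation +
    test scanners together).  In leakage-safe mode the fits use only the
    given source batches and are frozen onto the rest.
    """
    if leakage_safe_batches is None:
        table, _ = harmonization.fit_transform(table, batch_method)
        method, bins = _parse_disc(disc)
        table, _ = discretization.fit_transform(table, method, bins)
        return table
    src_ids = table.sample_ids[table.batch.isin(leakage_safe_batches)]
    rest_ids = table.sample_ids.difference(src_ids, sort=False)
    src = table.select_samples(src_ids)
    rest = table.select_samples(rest_ids)
    src_h, _hmodel = harmonization.fit_transform(src, batch_method)
    # the held-out scanner is harmonized separately in this mode; alone it
    # constitutes a single batch, so there is nothing to adjust
    rest_h = rest
    method, bins = _parse_disc(disc)
    src_d, dmodel = discretization.fit_transform(src_h, method, bins)
    rest_d = discretization.discretize_apply(dmodel, rest_h)
    merged = pd.concat([src_d.values, rest_d.values]).loc[table.sample_ids]
    return table.with_values(merged, note="leakage-safe preprocessing")


def _parse_disc(disc: str) -> tuple[str, int]:
    if disc == "none":
        return "none", 0
    return disc[:3].lower(), int(disc[3:])


# ---------------------------------------------------------------------------
# Per-configuration evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Averaged AUCs of one configuration under the repeated protocol."""

    config: PipelineConfig
    repeats: int
    auc_validation: float
    auc_test: float
    auc_mean: float
    auc_validation_per_repeat: np.ndarray = field(repr=False)
    auc_test_per_repeat: np.ndarray = field(repr=False)
    feature_frequency: pd.Series = field(repr=False)
    seed: int = 0
    error: str | None = None

    def as_row(self) -> dict:
        row = asdict(self.config)
        row.update(n_repeats=self.repeats, auc_validation=self.auc_validation,
                   auc_test=self.auc_test, auc_mean=self.auc_mean,
                   seed=self.seed, error=self.error)
        return row


def _repeat_seeds(seed: int, repeats: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return np.array([int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(repeats)])


def evaluate_config(config: PipelineConfig, tables: dict,
                    train_batches: list, test_batch: str,
                    repeats: int = 100, seed: int = 0, k: int = TOP_K,
                    model_params: dict | None = None,
                    preprocessed: FeatureTable | None = None,
                    leakage_safe: bool = False) -> EvaluationResult:
    """Run the repeated down-sampled protocol for one configuration.

    ``tables`` maps feature type to the assembled (ICC-filtered, pruned)
    full table; samples of ``train_batches`` form the train/validation
    source, ``test_batch`` is held out entirely.  ``model_params`` may
    override estimator keyword arguments per model name (applied to both
    selectors and classifiers); anything not overridden keeps library
    defaults.  Deterministic given ``seed``.
    """
    if test_batch in train_batches:
        raise ValueError("test batch must be disjoint from training batches")
    model_params = model_params or {}
    if preprocessed is None:
        preprocessed = _preprocess(
            tables[config.feature_type], config.batch_method,
            config.discretization,
            leakage_safe_batches=list(train_batches) if leakage_safe
            else None)
    src = preprocessed.select_samples(
        preprocessed.sample_ids[preprocessed.batch.isin(train_batches)])
    test = preprocessed.select_samples(
        preprocessed.sample_ids[preprocessed.batch == test_batch])
    y_test = test.outcome.to_numpy()

    seeds = _repeat_seeds(seed, repeats)
    auc_val = np.empty(repeats)
    auc_tst = np.empty(repeats)
    freq: dict = {}
    for r in range(repeats):
        s = int(seeds[r])
        train, val = downsample_split(src, 0.8, rng_seed=s)
        sel = select_features(train, config.selector, k=k, rng_seed=s,
                              selector_params=model_params.get(config.selector))
        for f in sel.features:
            freq[f] = freq.get(f, 0) + 1
        clf = _make_classifier(config.classifier, s,
                               model_params.get(config.classifier))
        clf.fit(train.values.loc[:, sel.features].to_numpy(),
                train.outcome.to_numpy())
        auc_val[r] = auc(_ranking_scores(
            clf, val.values.loc[:, sel.features].to_numpy()),
            val.outcome.to_numpy())
        auc_tst[r] = auc(_ranking_scores(
            clf, test.values.loc[:, sel.features].to_numpy()), y_test)

    mv, mt = float(auc_val.mean()), float(auc_tst.mean())
    return EvaluationResult(
        config=config, repeats=repeats, auc_validation=mv, auc_test=mt,
        auc_mean=(mv + mt) / 2.0, auc_validation_per_repeat=auc_val,
        auc_test_per_repeat=auc_tst,
        feature_frequency=pd.Series(freq).sort_values(ascending=False),
        seed=seed)


def run_grid(tables: dict, train_batches: list, test_batch: str,
             configs: list | None = None, repeats: int = 100, seed: int = 0,
             k: int = TOP_K, model_params: dict | None = None,
             leakage_safe: bool = False) -> list[EvaluationResult]:
    """Evaluate every configuration (or a subset), caching the shared
    harmonization + discretization preprocessing across the selector x
    classifier combinations that reuse it.  One configuration's failure
    is recorded on its result and does not abort the rest."""
    configs = list(configs) if configs is not None else enumerate_grid()
    cache: dict = {}
    results: list[EvaluationResult] = []
    for cfg in configs:
        key = (cfg.feature_type, cfg.batch_method, cfg.discretization)
        if key not in cache:
            cache[key] = _preprocess(
                tables[cfg.feature_type], cfg.batch_method,
                cfg.discretization,
                leakage_safe_batches=list(train_batches) if leakage_safe
                else None)
        try:
            results.append(evaluate_config(
                cfg, tables, train_batches, test_batch, repeats=repeats,
                seed=seed, k=k, model_params=model_params,
                preprocessed=cache[key]))
        except Exception as err:          # noqa: BLE001 — per-config isolation
            logger.error("config %s failed: %s", cfg.label(), err)
            results.append(EvaluationResult(
                config=cfg, repeats=0, auc_validation=np.nan, auc_test=np.nan,
                auc_mean=np.nan, auc_validation_per_repeat=np.empty(0),
                auc_test_per_repeat=np.empty(0),
                feature_frequency=pd.Series(dtype=float), seed=seed,
                error=str(err)))
    results.sort(key=lambda r: (-(r.auc_mean if np.isfinite(r.auc_mean)
                                  else -np.inf), r.config.label()))
    return results


def results_to_frame(results: list[EvaluationResult]) -> pd.DataFrame:
    """Tidy one-row-per-configuration frame, ranked by mean AUC."""
    return pd.DataFrame([r.as_row() for r in results])


def with_clinical(table: FeatureTable, cols=("ER", "PR", "HER2")
                  ) -> FeatureTable:
    """Append clinical covariates as additional feature columns (modality
    tag CLIN) so a combined radiomics + clinical model can be evaluated
    with the same classifier protocol."""
    extra = {}
    for c in cols:
        if c not in table.sample_meta:
            raise KeyError(f"clinical column {c!r} not in sample_meta")
        extra[f"CLIN_{c}"] = table.sample_meta[c].astype(float).to_numpy()
    values = table.values.copy()
    for name, col in extra.items():
        values[name] = col
    fmeta = table.feature_meta.copy()
    add = pd.DataFrame({"modality": "CLIN", "family": "clinical",
                        "is_shape": 0}, index=list(extra))
    fmeta = pd.concat([fmeta, add])
    return FeatureTable(values, table.sample_meta.copy(), fmeta,
                        feature_type=table.feature_type,
                        provenance=list(table.provenance) + ["clinical appended"])
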