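"""Feature-table container shared by every pipeline stage.

A :class:`FeatureTable` bundles a samples x features value matrix with
per-sample metadata (scanner batch, pCR outcome, hormone-receptor status)
and per-feature metadata (imaging modality, feature family, shape flag).
All pipeline operations consume and return this container so that sample
and feature alignment is checked once, here, instead of in every stage.

On-disk convention
------------------
values          CSV, ``sample_id`` as first column, one column per feature
samples.csv     sample_id, batch, outcome, ER, PR, HER2 (outcome/receptors
                may be absent for unlabeled tables)
features.csv    feature_id, modality in {CT, PET}, family, is_shape in {0,1}
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tlradiomics")

#: modality labels recognised in feature metadata
MODALITIES = ("CT", "PET")


class AlignmentError(ValueError):
    """Sample or feature sets of two tables do not line up."""


@dataclass
class FeatureTable:
    """Samples x features matrix plus sample and feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by ``sample_id`` with one column per feature.
    sample_meta
        DataFrame indexed by ``sample_id`` in the same row order as
        ``values``; expected columns include ``batch`` and optionally
        ``outcome`` (1 = pCR, 0 = non-pCR), ``ER``, ``PR``, ``HER2``.
    feature_meta
        DataFrame indexed by ``feature_id`` in the same column order as
        ``values``; expected columns ``modality`` and ``is_shape``.
    feature_type
        Provenance tag, e.g. ``"OR"`` or ``"TLR"`` once assembled.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    feature_type: str | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.sample_meta = pd.DataFrame(self.sample_meta)
        self.feature_meta = pd.DataFrame(self.feature_meta)
        self._validate()

    # -- invariants -------------------------------------------------------
    def _validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample_ids in value matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature_ids in value matrix")
        if not self.values.index.equals(self.sample_meta.index):
            raise AlignmentError("sample_meta index does not match value rows")
        if not self.values.columns.equals(self.feature_meta.index):
            raise AlignmentError("feature_meta index does not match value columns")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("value matrix contains non-finite entries")

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def batch(self) -> pd.Series:
        return self.sample_meta["batch"]

    @property
    def outcome(self) -> pd.Series:
        """Binary pCR outcome (1 = pCR); raises if the table is unlabeled."""
        if "outcome" not in self.sample_meta:
            raise KeyError("table has no outcome column in sample_meta")
        return self.sample_meta["outcome"].astype(int)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    # -- derived tables ---------------------------------------------------
    def with_values(self, values: pd.DataFrame | np.ndarray,
                    note: str | None = None) -> "FeatureTable":
        """Same metadata, new values (shape must match)."""
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(values, index=self.values.index,
                                  columns=self.values.columns)
        out = replace(self, values=values,
                      provenance=list(self.provenance))
        if note:
            out.provenance.append(note)
        return out

    def select_features(self, feature_ids, note: str | None = None) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        missing = ids.difference(self.values.columns)
        if len(missing):
            raise KeyError(f"unknown feature ids: {list(missing[:5])}")
        out = replace(
            self,
            values=self.values.loc[:, ids],
            feature_meta=self.feature_meta.loc[ids],
            provenance=list(self.provenance),
        )
        if note:
            out.provenance.append(note)
        return out

    def select_samples(self, sample_ids, note: str | None = None) -> "FeatureTable":
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.values.index)
        if len(missing):
            raise KeyError(f"unknown sample ids: {list(missing[:5])}")
        out = replace(
            self,
            values=self.values.loc[ids],
            sample_meta=self.sample_meta.loc[ids],
            provenance=list(self.provenance),
        )
        if note:
            out.provenance.append(note)
        return out

    def tagged(self, feature_type: str, note: str | None = None) -> "FeatureTable":
        out = replace(self, feature_type=feature_type,
                      provenance=list(self.provenance))
        if note:
            out.provenance.append(note)
        return out

    # -- I/O --------------------------------------------------------------
    def to_csv(self, values_path, samples_path=None, features_path=None) -> None:
        values_path = Path(values_path)
        self.values.rename_axis("sample_id").to_csv(values_path)
        if samples_path is not None:
            self.sample_meta.rename_axis("sample_id").to_csv(samples_path)
        if features_path is not None:
            self.feature_meta.rename_axis("feature_id").to_csv(features_path)

    @classmethod
    def from_csv(cls, values_path, samples_path=None, features_path=None,
                 feature_type: str | None = None) -> "FeatureTable":
        values = pd.read_csv(values_path, index_col="sample_id")
        values.columns = values.columns.astype(str)
        if samples_path is not None:
            sample_meta = pd.read_csv(samples_path, index_col="sample_id")
            sample_meta = sample_meta.loc[values.index]
        else:
            sample_meta = pd.DataFrame(index=values.index)
        if features_path is not None:
            feature_meta = pd.read_csv(features_path, index_col="feature_id")
            feature_meta.index = feature_meta.index.astype(str)
            feature_meta = feature_meta.loc[values.columns]
        else:
            feature_meta = pd.DataFrame(index=values.columns)
        return cls(values, sample_meta, feature_meta, feature_type=feature_type)


def check_same_grid(*tables: FeatureTable) -> None:
    """Raise :class:`AlignmentError` unless all tables share identical
    sample ids (same order) and feature ids (same order)."""
    first = tables[0]
    for t in tables[1:]:
        if not first.values.index.equals(t.values.index):
            raise AlignmentError("tables do not share the same samples")
        if not first.values.columns.equals(t.values.columns):
            raise AlignmentError("tables do not share the same features")
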