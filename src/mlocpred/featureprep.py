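"""Feature cleansing, normalization and the PCA alternative.

Two mutually exclusive reduction paths are supported per run:

* filtering path (default): drop constant columns, drop one member of
  every pair with |Pearson r| above the collinearity threshold (0.98),
  then z-score with training statistics;
* PCA path: drop constant columns, z-score, then keep the smallest
  number of leading principal components reaching the target cumulative
  explained variance (default 95%).

Collinearity pruning scans columns in their fixed input order and drops
a column the first time it exceeds the threshold against an earlier
*kept* column, so the earlier column in the canonical group order always
survives.  Selection is fully deterministic given the column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from mlocpred.encoders import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Record of dropped and kept features from the cleansing stage."""

    dropped_constant: list[str] = field(default_factory=list)
    dropped_collinear: list[tuple[str, str, float]] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    threshold: float = 0.98

    @property
    def dropped_names(self) -> list[str]:
        return self.dropped_constant + [d for d, _, _ in self.dropped_collinear]

    def write_tsv(self, path: str | Path) -> None:
        rows = [("constant", name, "", "") for name in self.dropped_constant]
        rows += [
            ("collinear", d, kept, f"{r:.6f}")
            for d, kept, r in self.dropped_collinear
        ]
        rows += [("kept", name, "", "") for name in self.kept]
        pd.DataFrame(
            rows, columns=["status", "feature", "partner", "correlation"]
        ).to_csv(path, sep="\t", index=False)

    def write_kept_list(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.kept) + "\n")


def drop_constant_features(m: FeatureMatrix) -> tuple[FeatureMatrix, SelectionReport]:
    """Remove columns whose value is identical across all rows."""
    if m.n_samples == 0:
        raise ValueError("empty matrix")
    if m.n_samples == 1:
        raise ValueError("cannot assess constancy with n=1")
    constant = np.all(m.values == m.values[0, :], axis=0)
    dropped = [n for n, c in zip(m.feature_names, constant) if c]
    kept = [n for n, c in zip(m.feature_names, constant) if not c]
    logger.info("constant-column drop: %d of %d", len(dropped), m.n_features)
    report = SelectionReport(dropped_constant=dropped, kept=kept)
    return m.select_columns(kept), report


def drop_collinear_features(
    m: FeatureMatrix, threshold: float = 0.98
) -> tuple[FeatureMatrix, SelectionReport]:
    """Greedy collinearity pruning at |Pearson r| > ``threshold``.

    Requires constant columns to be removed first (their correlation is
    undefined).  Absolute correlation is used: strongly negatively
    correlated pairs are pruned the same as positive ones.
    """
    X = m.values
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [n for n, s in zip(m.feature_names, sds) if s == 0]
        raise ValueError(
            f"constant columns present ({bad[:3]}...); "
            "run drop_constant_features first"
        )
    p = m.n_features
    Z = (X - X.mean(axis=0)) / sds
    corr = np.clip((Z.T @ Z) / X.shape[0], -1.0, 1.0)

    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(p):
        if kept_idx:
            against = np.abs(corr[j, kept_idx])
            worst = int(np.argmax(against))
            if against[worst] > threshold:
                dropped.append(
                    (
                        m.feature_names[j],
                        m.feature_names[kept_idx[worst]],
                        float(corr[j, kept_idx[worst]]),
                    )
                )
                continue
        kept_idx.append(j)
    kept = [m.feature_names[j] for j in kept_idx]
    logger.info("collinearity drop (|r| > %.2f): %d of %d", threshold, len(dropped), p)
    report = SelectionReport(
        dropped_collinear=dropped, kept=kept, threshold=threshold
    )
    return m.select_columns(kept), report


def merge_reports(
    constant: SelectionReport, collinear: SelectionReport
) -> SelectionReport:
    return SelectionReport(
        dropped_constant=list(constant.dropped_constant),
        dropped_collinear=list(collinear.dropped_collinear),
        kept=list(collinear.kept),
        threshold=collinear.threshold,
    )


@dataclass
class Normalizer:
    """Per-feature z-score statistics, fitted on training rows only.

    Uses the sample standard deviation (ddof=1).
    """

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def transform(self, m: FeatureMatrix) -> FeatureMatrix:
        return apply_normalizer(self, m)


def fit_normalizer(m: FeatureMatrix) -> Normalizer:
    if m.n_samples < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    means = m.values.mean(axis=0)
    sds = m.values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [n for n, s in zip(m.feature_names, sds) if s == 0]
        raise ValueError(
            f"zero standard deviation for {bad[:3]}...; "
            "a constant column leaked through cleansing"
        )
    return Normalizer(feature_names=list(m.feature_names), means=means, sds=sds)


def apply_normalizer(nz: Normalizer, m: FeatureMatrix) -> FeatureMatrix:
    if list(m.feature_names) != list(nz.feature_names):
        raise ValueError("feature-name mismatch between normalizer and matrix")
    return FeatureMatrix(
        sample_ids=list(m.sample_ids),
        feature_names=list(m.feature_names),
        feature_groups=list(m.feature_groups),
        values=(m.values - nz.means) / nz.sds,
    )


@dataclass
class PCAReduction:
    """Retained components, loadings and the explained-variance curve."""

    n_components: int
    reduced: FeatureMatrix
    loadings: np.ndarray  # components x features
    explained_variance_ratio: np.ndarray  # full curve, all fitted components
    pca: PCA


def pca_reduce(
    m: FeatureMatrix, variance_target: float = 0.95
) -> PCAReduction:
    """Keep the smallest number of leading components whose cumulative
    explained-variance ratio reaches ``variance_target``.

    Expects a normalized matrix; with target 1.0 all min(n-1, p)
    components are kept.
    """
    if not 0 < variance_target <= 1:
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    if m.n_samples < 2:
        raise ValueError("need at least 2 rows for PCA")
    max_comp = min(m.n_samples - 1, m.n_features)
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(m.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = min(n_keep, max_comp)
    reduced = FeatureMatrix(
        sample_ids=list(m.sample_ids),
        feature_names=[f"PC{i + 1}" for i in range(n_keep)],
        feature_groups=["PCA"] * n_keep,
        values=scores[:, :n_keep],
    )
    return PCAReduction(
        n_components=n_keep,
        reduced=reduced,
        loadings=pca.components_[:n_keep],
        explained_variance_ratio=pca.explained_variance_ratio_,
        pca=pca,
    )
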