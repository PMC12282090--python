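"""Expression containers, log-TPM transform, reference centering, PCA QC.

The central container is :class:`ExpressionMatrix`: a genes × samples
log-TPM matrix (log2 scale) with a per-sample metadata table attached
(strain, fermentation phase, medium, time, replicate pairing, OD600).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

METADATA_COLUMNS = ["strain", "phase", "medium", "time_h", "replicate_pair", "od600"]


@dataclass
class SampleContrast:
    """Two disjoint, non-empty sample groups to compare (b minus a)."""

    group_a: frozenset
    group_b: frozenset
    label: str = ""

    def __post_init__(self):
        self.group_a = frozenset(self.group_a)
        self.group_b = frozenset(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError("contrast groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError("contrast groups must be disjoint")

    def swapped(self) -> "SampleContrast":
        return SampleContrast(self.group_b, self.group_a, label=self.label)


class ExpressionMatrix:
    """Genes × samples expression values (log-TPM) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns. All
        values must be finite.
    metadata
        DataFrame indexed by sample id; must cover every sample in
        ``values``. Conventional columns are strain, phase, medium,
        time_h, replicate_pair, od600, but extra columns are kept.
    """

    def __init__(self, values: pd.DataFrame, metadata: pd.DataFrame):
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        missing = set(values.columns) - set(metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        self.values = values
        self.metadata = metadata.loc[values.columns]

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_where(self, **query) -> list:
        """Sample ids whose metadata matches all ``column=value`` pairs."""
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in query.items():
            mask &= self.metadata[col] == val
        return list(self.metadata.index[mask])

    def replicate_pairs(self) -> list[tuple]:
        """(sample, sample) tuples sharing a replicate_pair id, in id order."""
        pairs = []
        for _, grp in self.metadata.groupby("replicate_pair", sort=True):
            ids = sorted(grp.index)
            if len(ids) == 2:
                pairs.append(tuple(ids))
        return pairs

    # -- IO -------------------------------------------------------------

    def to_tsv(self, values_path, metadata_path) -> None:
        self.values.rename_axis("gene_id").to_csv(
            values_path, sep="\t", float_format="%.10g"
        )
        self.metadata.rename_axis("sample").to_csv(
            metadata_path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, values_path, metadata_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(values, metadata)


def compute_log_tpm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Counts → log2(TPM + 1).

    Per sample: rate_g = count_g / length_g (length in base pairs),
    TPM_g = 1e6 · rate_g / Σ rate, value = log2(TPM + 1).

    Raises if any gene length is non-positive or a sample has no reads
    (the error names the offending sample).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    dead = totals[totals == 0]
    if len(dead):
        raise ValueError(f"all-zero sample(s): {sorted(dead.index)}")
    tpm = rates.div(totals, axis=1) * 1e6
    values = np.log2(tpm + 1.0)
    if metadata is None:
        metadata = pd.DataFrame(index=counts.columns)
    return ExpressionMatrix(values, metadata)


def tpm_from_log(values: pd.DataFrame) -> pd.DataFrame:
    """Invert the log2(TPM+1) transform (QC helper)."""
    return 2.0**values - 1.0


def center_to_reference(X: ExpressionMatrix, reference_samples) -> ExpressionMatrix:
    """Subtract from each gene its mean over a reference sample set.

    Mirrors the convention of reporting expression and activities relative
    to a reference condition (e.g. the batch phase). Idempotent for a fixed
    reference set.
    """
    ref = list(reference_samples)
    if not ref:
        raise ValueError("reference sample set is empty")
    unknown = set(ref) - set(X.sample_ids)
    if unknown:
        raise ValueError(f"reference samples not in matrix: {sorted(unknown)}")
    means = X.values[ref].mean(axis=1)
    return ExpressionMatrix(X.values.sub(means, axis=0), X.metadata)


def pca_variance_summary(X: ExpressionMatrix, n_components: int) -> np.ndarray:
    """Explained-variance fractions of the leading principal components.

    PCA is run on gene-centered data with samples as observations — the
    standard QC view in which the first components separate fermentation
    phases and strains. Fractions are of the total variance, so they are
    non-increasing and sum to 1 over all components.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X.values.to_numpy().T)  # samples as observations, genes as features
    return pca.explained_variance_ratio_
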