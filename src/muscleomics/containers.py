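"""Core data carriers shared across the pipeline.

The central object is :class:`OmicsMatrix`, a features x samples table of
log2 intensities together with per-sample metadata (sex, genotype,
timepoint, replicate).  All downstream stages (filtering, normalization,
model fitting) operate on this container.  Tables round-trip through
tab-separated text so that every pipeline artifact stays human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Metadata columns every sample table must carry.
SAMPLE_COLUMNS = ("sex", "genotype", "timepoint", "replicate")


@dataclass
class OmicsMatrix:
    """Features x samples matrix of log2 intensities plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        Entries are log2 intensities; NaN marks a missing measurement.
    samples
        DataFrame indexed by sample id with columns ``sex``, ``genotype``,
        ``timepoint`` and ``replicate``.  Row order must match the column
        order of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)[:5]}")
        if not self.values.columns.equals(self.samples.index):
            # allow same set in different order: realign metadata to values
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("sample metadata does not cover the value columns")
            self.samples = self.samples.loc[self.values.columns]

    # -- convenience ---------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def group_labels(self) -> pd.Series:
        """Genotype x timepoint cell label per sample (e.g. ``KI.SED``)."""
        return (
            self.samples["genotype"].astype(str)
            + "."
            + self.samples["timepoint"].astype(str)
        )

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values.loc[:, list(sample_ids)], self.samples.loc[list(sample_ids)]
        )

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), self.samples.copy())

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, values_path, samples_path=None) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(values_path, sep="\t", float_format="%.10g")
        if samples_path is not None:
            meta = self.samples.copy()
            meta.index.name = "sample_id"
            meta.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, samples_path=None) -> "OmicsMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = None
        if samples_path is not None and Path(samples_path).exists():
            samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values, samples)
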