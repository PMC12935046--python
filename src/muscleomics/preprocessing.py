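"""Normalization, complete-case filtering and peptide-to-protein assignment.

Each sex is quantified in its own isobaric-label plex, so sexes are
processed as independent datasets: features with any missing sample
within a sex are removed (complete-case filtering), samples are
median-normalized to remove loading differences, and each feature is
median-centered.  Shared peptides are resolved to a single protein by
parsimony — the candidate protein with the most total peptide
identifications wins — and phosphosites additionally give absolute
priority to proteins already detected in the global proteome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .containers import OmicsMatrix


def filter_complete_features(matrix: OmicsMatrix) -> OmicsMatrix:
    """Drop features that are not measured in every sample.

    Intended for a matrix holding the samples of a single sex (one plex);
    a feature missing in any of them is removed entirely.
    """
    complete = matrix.values.notna().all(axis=1)
    if not complete.any():
        warnings.warn("no feature is complete in all samples", stacklevel=2)
    return OmicsMatrix(matrix.values.loc[complete].copy(), matrix.samples.copy())


def _require_complete(matrix: OmicsMatrix, op: str) -> None:
    if matrix.has_missing():
        raise ValueError(f"{op} requires a complete matrix; run filter_complete_features first")


def normalize_sample_medians(matrix: OmicsMatrix) -> OmicsMatrix:
    """Subtract each sample's median intensity (column-wise centering)."""
    _require_complete(matrix, "normalize_sample_medians")
    values = matrix.values - matrix.values.median(axis=0)
    return OmicsMatrix(values, matrix.samples.copy())


def center_features(matrix: OmicsMatrix) -> OmicsMatrix:
    """Subtract each feature's median across samples (row-wise centering)."""
    _require_complete(matrix, "center_features")
    values = matrix.values.sub(matrix.values.median(axis=1), axis=0)
    return OmicsMatrix(values, matrix.samples.copy())


@dataclass
class PeptideProteinMap:
    """Candidate proteins per peptide plus per-protein evidence counts.

    ``candidates`` maps a peptide (or phosphosite) id to its candidate
    protein accessions; ``peptide_counts`` gives, per protein, the total
    number of peptide identifications supporting that protein.
    """

    candidates: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    peptide_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pep, cands in self.candidates.items():
            if len(cands) == 0:
                raise ValueError(f"peptide {pep!r} has no candidate protein")
        for acc, cnt in self.peptide_counts.items():
            if cnt < 1:
                raise ValueError(f"protein {acc!r} has non-positive peptide count {cnt}")

    @classmethod
    def from_tsv(cls, path) -> "PeptideProteinMap":
        """Read a (peptide_id, accession, accession_total_peptides) TSV."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        pep_col, acc_col, cnt_col = df.columns[:3]
        candidates: dict[str, tuple[str, ...]] = {}
        counts: dict[str, int] = {}
        for pep, grp in df.groupby(pep_col, sort=False):
            candidates[str(pep)] = tuple(str(a) for a in grp[acc_col])
        for _, row in df.iterrows():
            counts[str(row[acc_col])] = int(row[cnt_col])
        return cls(candidates, counts)


def _best_candidate(cands: Iterable[str], counts: Mapping[str, int]) -> str:
    # highest evidence count; ties go to the lexicographically smallest
    # accession so the assignment is order-independent
    return min(cands, key=lambda acc: (-counts.get(acc, 0), acc))


def assign_parsimonious(pep_map: PeptideProteinMap) -> dict[str, str]:
    """Assign each peptide to the candidate with the most peptide evidence."""
    return {
        pep: _best_candidate(cands, pep_map.peptide_counts)
        for pep, cands in pep_map.candidates.items()
    }


def map_phosphosites_to_proteins(
    pep_map: PeptideProteinMap, global_proteins: Iterable[str]
) -> dict[str, str]:
    """Assign phosphosites to proteins, preferring globally detected ones.

    Candidates present in the global proteomics results take absolute
    priority; among the surviving pool the parsimony rule (most total
    peptide identifications, lexicographic tie-break) applies.
    """
    detected = set(global_proteins)
    assignment: dict[str, str] = {}
    for pep, cands in pep_map.candidates.items():
        pool = [c for c in cands if c in detected] or list(cands)
        assignment[pep] = _best_candidate(pool, pep_map.peptide_counts)
    return assignment


def preprocess_matrix(matrix: OmicsMatrix) -> OmicsMatrix:
    """Complete-case filter, sample-median normalize, then feature-center."""
    return center_features(normalize_sample_medians(filter_complete_features(matrix)))
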