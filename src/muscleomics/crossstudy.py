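"""Cross-study signature comparison: quadrant plots and intersections.

Effect directions from two differential studies (e.g. mouse knock-in vs
human type 2 diabetes muscle) are compared by placing each shared
identifier in one of four quadrants — q1 (+,+), q2 (-,+), q3 (-,-),
q4 (+,-) — with an exactly-zero effect on either axis left unclassified.
A multi-study intersection extracts identifiers present in every
signature, optionally restricted to significant rows and to
sign-concordant effects.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

QUADRANTS = ("q1", "q2", "q3", "q4", "unclassified")


def _check_signature(table: pd.DataFrame, name: str) -> pd.DataFrame:
    if "identifier" not in table.columns or "effect" not in table.columns:
        raise ValueError(f"{name} needs columns 'identifier' and 'effect'")
    if table["identifier"].duplicated().any():
        dups = table.loc[table["identifier"].duplicated(), "identifier"].tolist()[:5]
        raise ValueError(f"{name} has duplicate identifiers: {dups}")
    if not np.isfinite(table["effect"].to_numpy(dtype=float)).all():
        raise ValueError(f"{name} has non-finite effects")
    return table.set_index("identifier")


def assign_quadrants(x: pd.DataFrame, y: pd.DataFrame) -> pd.DataFrame:
    """Classify identifiers shared by two signatures into sign quadrants.

    ``x`` and ``y`` are SignatureTables (columns ``identifier``,
    ``effect``, optional ``significant``); x is the reference study
    (horizontal axis).  Returns a QuadrantTable with columns
    ``identifier, x_effect, y_effect, quadrant`` covering the shared
    identifiers, sorted lexicographically.
    """
    xt = _check_signature(x, "x")
    yt = _check_signature(y, "y")
    shared = sorted(set(xt.index) & set(yt.index))
    rows = []
    for ident in shared:
        xe = float(xt.at[ident, "effect"])
        ye = float(yt.at[ident, "effect"])
        if xe > 0 and ye > 0:
            quad = "q1"
        elif xe < 0 and ye > 0:
            quad = "q2"
        elif xe < 0 and ye < 0:
            quad = "q3"
        elif xe > 0 and ye < 0:
            quad = "q4"
        else:
            quad = "unclassified"
        rows.append({"identifier": ident, "x_effect": xe, "y_effect": ye, "quadrant": quad})
    return pd.DataFrame(rows, columns=["identifier", "x_effect", "y_effect", "quadrant"])


def quadrant_counts(table: pd.DataFrame) -> pd.Series:
    counts = table["quadrant"].value_counts()
    return pd.Series({q: int(counts.get(q, 0)) for q in QUADRANTS})


def intersect_signatures(
    tables: Sequence[pd.DataFrame],
    require_significant: bool = False,
    require_same_sign: bool = False,
) -> list[str]:
    """Identifiers present in all signatures, with optional filters.

    ``require_significant`` keeps only rows flagged significant in every
    table; ``require_same_sign`` additionally demands a consistent,
    nonzero effect direction across all tables.  Output is sorted.
    """
    if len(tables) < 2:
        raise ValueError("need at least two signature tables")
    indexed = []
    for i, t in enumerate(tables):
        ti = _check_signature(t, f"table {i}")
        if require_significant:
            if "significant" not in t.columns:
                raise ValueError(f"table {i} lacks a 'significant' column")
            ti = ti[ti["significant"].astype(bool)]
        indexed.append(ti)
    common = set(indexed[0].index)
    for ti in indexed[1:]:
        common &= set(ti.index)
    if require_same_sign:
        kept = []
        for ident in common:
            signs = {np.sign(float(ti.at[ident, "effect"])) for ti in indexed}
            if len(signs) == 1 and 0.0 not in signs:
                kept.append(ident)
        common = set(kept)
    return sorted(common)
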