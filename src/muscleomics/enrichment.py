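"""Competitive set enrichment on z-score matrices.

Moderated t-statistics from the differential stage are mapped to normal
z-scores, features sharing an identifier (e.g. multiple proteins per gene
symbol) are collapsed to the most extreme z per contrast, near-duplicate
annotation sets are merged by Jaccard clustering with a deterministic
representative cascade, and each surviving set is tested per contrast
with the parametric correlation-adjusted competitive test (CAMERA-PR): a
two-sample t-test of set vs background z-scores whose set variance is
inflated by VIF = 1 + (m - 1) * rho to account for inter-feature
correlation within sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats


# ---------------------------------------------------------------------------
# z-scores


def t_to_z(t, df):
    """Map t-statistics to standard-normal z-scores of equal tail area.

    Uses log-scale tail probabilities (``stats.t.logsf`` +
    ``special.ndtri_exp``) so |z| stays accurate far into the tails where
    naive CDF round-tripping saturates.  Vectorized over ``t`` and ``df``.
    """
    t = np.asarray(t, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(df <= 0):
        raise ValueError("degrees of freedom must be positive")
    log_tail = stats.t.logsf(np.abs(t), df)
    z_abs = -special.ndtri_exp(log_tail)
    z = np.sign(t) * z_abs
    return z if z.shape else float(z)


def collapse_features(
    stats_table: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse per-feature z-scores to one row per identifier.

    ``stats_table`` has columns ``feature, contrast, z``.  Each feature is
    renamed through ``mapping`` (features absent from the mapping keep
    their own id, so unannotated proteins are not discarded).  When
    several features share an identifier, each contrast column
    independently takes the z of the feature with maximal |z| for that
    contrast; |z| ties go to the lexicographically smallest feature id.

    Returns a StatMatrix: identifiers x contrasts DataFrame of z-scores.
    """
    tbl = stats_table.copy()
    tbl["identifier"] = [
        mapping.get(f, f) for f in tbl["feature"].astype(str)
    ]
    # deterministic tie-break: sort so the first row per (id, contrast)
    # has max |z|, then smallest feature id
    tbl["_absz"] = tbl["z"].abs()
    tbl = tbl.sort_values(
        ["identifier", "contrast", "_absz", "feature"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = tbl.groupby(["identifier", "contrast"], sort=True).first().reset_index()
    mat = best.pivot(index="identifier", columns="contrast", values="z")
    mat.index.name = "identifier"
    return mat


# ---------------------------------------------------------------------------
# set collections (GMT)


@dataclass
class SetCollection:
    """Named annotation sets with descriptions and original sizes."""

    members: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)
    original_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mem in self.members.items():
            if len(mem) == 0:
                raise ValueError(f"set {name!r} has no members")
        for name in self.members:
            self.descriptions.setdefault(name, "")
            self.original_sizes.setdefault(name, len(self.members[name]))

    @property
    def names(self) -> list[str]:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_gmt(cls, path) -> "SetCollection":
        members: dict[str, tuple[str, ...]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:60]!r}")
                name, desc, mem = parts[0], parts[1], tuple(p for p in parts[2:] if p)
                if name in members:
                    raise ValueError(f"duplicate set name {name!r}")
                members[name] = mem
                descriptions[name] = desc
        return cls(members, descriptions)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, mem in self.members.items():
                fh.write("\t".join([name, self.descriptions.get(name, "")] + list(mem)) + "\n")


def read_kinase_substrate_tsv(path) -> SetCollection:
    """Build kinase-substrate sets from a (kinase, substrate gene, site) TSV.

    Site ids are formed as GENE-SITE (e.g. ``PRKAA2-S377``) and grouped by
    kinase into one set per kinase.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    kin_col, gene_col, site_col = df.columns[:3]
    members: dict[str, tuple[str, ...]] = {}
    for kinase, grp in df.groupby(kin_col, sort=True):
        sites = tuple(dict.fromkeys(grp[gene_col] + "-" + grp[site_col]))
        members[str(kinase)] = sites
    return SetCollection(members)


def filter_sets(
    collection: SetCollection, universe: Iterable[str], min_overlap: int
) -> SetCollection:
    """Keep sets with >= ``min_overlap`` members in the universe.

    Surviving memberships are replaced by their intersection with the
    universe (preserving input member order); the pre-intersection size is
    retained as the original size for the representative cascade.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    members, descriptions, original = {}, {}, {}
    for name, mem in collection.members.items():
        inter = tuple(x for x in mem if x in uni)
        if len(inter) >= min_overlap:
            members[name] = inter
            descriptions[name] = collection.descriptions.get(name, "")
            original[name] = collection.original_sizes.get(name, len(mem))
    return SetCollection(members, descriptions, original)


# ---------------------------------------------------------------------------
# redundancy clustering


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


@dataclass
class ClusterResult:
    """Partition of set names into clusters of near-duplicates."""

    clusters: list[list[str]]
    similarities: pd.DataFrame  # pairwise Jaccard coefficients

    def cluster_of(self, name: str) -> list[str]:
        for cl in self.clusters:
            if name in cl:
                return cl
        raise KeyError(name)


def cluster_sets(collection: SetCollection, cutoff: float = 0.85) -> ClusterResult:
    """Cluster sets whose pairwise Jaccard similarity reaches ``cutoff``.

    Clusters are the connected components of the graph with an edge
    between two sets when Jaccard >= cutoff.  Memberships are used as
    stored (apply :func:`filter_sets` first to cluster on
    universe-intersected memberships).
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    names = collection.names
    graph = nx.Graph()
    graph.add_nodes_from(names)
    sim = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            j = jaccard(collection.members[a], collection.members[b])
            sim.loc[a, b] = sim.loc[b, a] = j
            if j >= cutoff:
                graph.add_edge(a, b)
    clusters = [sorted(c) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: c[0])
    return ClusterResult(clusters=clusters, similarities=sim)


def _normalized_description_length(desc: str) -> int:
    return len(re.sub(r"\s+", " ", desc.strip()))


def select_representatives(
    clusters: ClusterResult, collection: SetCollection
) -> SetCollection:
    """Keep one representative set per cluster.

    Cascade, in order: (1) largest universe-intersected membership,
    (2) highest proportion of original members retained, (3) shortest
    whitespace-normalized description, (4) first name alphabetically.
    """
    members, descriptions, original = {}, {}, {}
    for cl in clusters.clusters:
        def rank(name: str):
            size = len(collection.members[name])
            orig = collection.original_sizes.get(name, size)
            prop = size / orig if orig else 0.0
            desc_len = _normalized_description_length(collection.descriptions.get(name, ""))
            return (-size, -prop, desc_len, name)

        rep = min(cl, key=rank)
        members[rep] = collection.members[rep]
        descriptions[rep] = collection.descriptions.get(rep, "")
        original[rep] = collection.original_sizes.get(rep, len(members[rep]))
    return SetCollection(members, descriptions, original)


# ---------------------------------------------------------------------------
# CAMERA-PR


def camera_pr(
    stats_column: pd.Series,
    collection: SetCollection,
    rho: float = 0.01,
) -> pd.DataFrame:
    """Parametric correlation-adjusted competitive set test, one contrast.

    For a set of ``m`` members among ``G`` scored identifiers the
    statistic compares the set's mean z against the background mean with
    a pooled-variance two-sample t whose set term carries the variance
    inflation factor ``VIF = 1 + (m - 1) * rho``:

        T = (mean(z_set) - mean(z_rest))
            / sqrt(s_p^2 * (VIF / m + 1 / (G - m)))

    with ``s_p^2`` the classical pooled within-group variance and
    ``G - 2`` degrees of freedom.  At ``rho = 0`` this is exactly the
    ordinary equal-variance two-sample t-test.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    z = stats_column.astype(float)
    if z.isna().any():
        raise ValueError("stat column contains missing values")
    ids = set(z.index)
    G = len(z)
    z_all = z.to_numpy()
    mean_all = z_all.mean()
    var_all = z_all.var(ddof=1)

    rows = []
    for name, mem in collection.members.items():
        mem_set = set(mem)
        if not mem_set <= ids:
            missing = sorted(mem_set - ids)[:3]
            raise ValueError(f"set {name!r} has members outside the stat rows: {missing}")
        m = len(mem_set)
        if m + 2 > G:
            raise ValueError(f"set {name!r} too large for universe of {G}")
        m2 = G - m
        mean_set = z.loc[sorted(mem_set)].to_numpy().mean()
        delta = G / m2 * (mean_set - mean_all)  # = mean_set - mean_rest
        # classical pooled within-group variance via the overall variance
        var_pooled = ((G - 1) * var_all - delta**2 * m * m2 / G) / (G - 2)
        var_pooled = max(var_pooled, 0.0)
        vif = 1.0 + (m - 1) * rho
        se = np.sqrt(var_pooled * (vif / m + 1.0 / m2))
        t_stat = delta / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t_stat), G - 2)
        rows.append(
            {
                "set": name,
                "n_members": m,
                "direction": "Up" if delta > 0 else "Down",
                "delta": delta,
                "t": t_stat,
                "p": min(max(p, np.nextafter(0.0, 1.0)), 1.0),
            }
        )
    return pd.DataFrame(rows, columns=["set", "n_members", "direction", "delta", "t", "p"])


def enrich(
    stat_matrix: pd.DataFrame,
    collection: SetCollection,
    min_overlap: int = 10,
    jaccard_cutoff: float = 0.85,
    rho: float = 0.01,
) -> pd.DataFrame:
    """Full enrichment stage over every contrast column of a StatMatrix.

    Filters sets against the matrix's identifiers, collapses redundant
    sets, runs CAMERA-PR per contrast and BH-adjusts p-values across all
    set/contrast pairs (single family).
    """
    from .differential import adjust_bh_grouped

    filtered = filter_sets(collection, stat_matrix.index, min_overlap)
    if len(filtered) == 0:
        return pd.DataFrame(
            columns=["set", "contrast", "n_members", "direction", "delta", "t", "p", "adj_p"]
        )
    reps = select_representatives(cluster_sets(filtered, jaccard_cutoff), filtered)
    tables = []
    for contrast in stat_matrix.columns:
        tbl = camera_pr(stat_matrix[contrast], reps, rho=rho)
        tbl.insert(1, "contrast", contrast)
        tables.append(tbl)
    table = pd.concat(tables, ignore_index=True)
    table["family"] = "enrichment"
    table = adjust_bh_grouped(table.rename(columns={"p": "p"}))
    return table.drop(columns=["family"])
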