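"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here so the full
stack is testable without any external download:

* a two-plex multi-omics experiment (one plex per sex; 2 genotypes x
  3 timepoints x n replicates) whose feature variances are drawn from a
  scaled inverse-chi-square prior — exactly the assumption under which
  empirical-Bayes variance moderation is calibrated — with planted
  log2 effects, optional per-sample variance inflation and
  whole-feature-within-sex missingness;
* phosphosite 15-mer windows constructed to hit a requested motif tier
  (verified against the classifier at generation time);
* set collections made of families of near-duplicate sets with a known
  intended representative, to exercise Jaccard redundancy collapsing;
* linear force-flow respirometry assays on the standard dG_ATP grid.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bioenergetics import DELTA_G_BY_PCR, DELTA_G_MAX, RespirometryAssay, RespState
from .containers import OmicsMatrix
from .differential import DEFAULT_LEVELS, GENOTYPES, TIMEPOINTS, default_contrasts
from .enrichment import SetCollection
from .motif import (
    CENTER_INDEX,
    MINUS3_RESIDUES,
    MINUS5_RESIDUES,
    PLUS4_RESIDUES,
    POS_MINUS3,
    POS_MINUS5,
    POS_PLUS4,
    WINDOW_LENGTH,
    PhosphoWindow,
    classify_motif,
)

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

SEXES = ("M", "F")


# ---------------------------------------------------------------------------
# omics experiment


@dataclass
class SimConfig:
    """Parameters of the simulated two-plex multi-omics experiment.

    ``effect_table`` plants additive log2 effects per
    ``(feature_id, genotype, timepoint)`` cell.  ``var_prior_df`` /
    ``var_prior_scale`` are the true scaled-inverse-chi-square prior
    parameters (d0, s0^2) from which per-feature noise variances are
    drawn.  ``inflated_samples`` multiplies the noise variance of chosen
    samples, emulating low-quality TMT channels.  ``missing_fraction`` of
    features are blanked for all samples of a sex (independently per
    sex), matching a plex in which a feature was simply not quantified.
    """

    n_features: int = 2000
    n_replicates: int = 3
    genotypes: tuple[str, ...] = GENOTYPES
    timepoints: tuple[str, ...] = TIMEPOINTS
    sexes: tuple[str, ...] = SEXES
    effect_table: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    var_prior_df: float = 4.0
    var_prior_scale: float = 0.09
    inflated_samples: tuple[tuple[str, float], ...] = ()
    missing_fraction: float = 0.0
    noise_sd_override: float | None = None  # fixed noise sd for every feature (0 allowed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per cell")
        if self.var_prior_df <= 0 or self.var_prior_scale <= 0:
            raise ValueError("variance prior parameters must be positive")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        for sample, mult in self.inflated_samples:
            if mult <= 0:
                raise ValueError(f"variance multiplier for {sample!r} must be positive")

    def feature_ids(self) -> list[str]:
        width = len(str(self.n_features - 1))
        return [f"F{i:0{width}d}" for i in range(self.n_features)]

    def sample_ids(self, sex: str) -> list[str]:
        return [
            f"{sex}_{g}_{t}_r{r + 1}"
            for g in self.genotypes
            for t in self.timepoints
            for r in range(self.n_replicates)
        ]


@dataclass
class SimulatedExperiment:
    """Simulated matrices (one per sex) plus the ground-truth table."""

    matrices: dict[str, OmicsMatrix]
    truth: pd.DataFrame


def simulate_omics_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate one log2-intensity matrix per sex with known ground truth.

    The truth table records, per feature, the drawn noise variance, the
    planted effect of every default contrast and an ``is_null`` flag
    (True when all planted cell effects are zero).
    """
    rng = np.random.default_rng(config.seed)
    features = config.feature_ids()
    n = config.n_features

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    if config.noise_sd_override is not None:
        if config.noise_sd_override < 0:
            raise ValueError("noise_sd_override must be non-negative")
        variances = np.full(n, config.noise_sd_override**2)
    else:
        # sigma_i^2 ~ s0^2 * d0 / chi^2(d0): the scaled inverse-chi-square prior
        chi2 = rng.chisquare(config.var_prior_df, size=n)
        variances = config.var_prior_scale * config.var_prior_df / chi2

    # planted cell effects: features x (genotype, timepoint)
    cells = [(g, t) for g in config.genotypes for t in config.timepoints]
    effect = np.zeros((n, len(cells)))
    feat_index = {f: i for i, f in enumerate(features)}
    for (feat, g, t), value in config.effect_table.items():
        if feat not in feat_index:
            raise ValueError(f"effect_table references unknown feature {feat!r}")
        effect[feat_index[feat], cells.index((g, t))] = value

    inflation = dict(config.inflated_samples)
    matrices: dict[str, OmicsMatrix] = {}
    for sex in config.sexes:
        sample_ids = config.sample_ids(sex)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        cell_of_sample = [
            cells.index((g, t))
            for g in config.genotypes
            for t in config.timepoints
            for _ in range(config.n_replicates)
        ]
        mean = baselines[:, None] + effect[:, cell_of_sample]
        sds = np.sqrt(variances)[:, None] * np.sqrt(
            np.array([inflation.get(s, 1.0) for s in sample_ids])
        )[None, :]
        values = mean + rng.normal(size=mean.shape) * sds
        if config.missing_fraction > 0:
            n_missing = int(np.floor(config.missing_fraction * n))
            missing_rows = rng.choice(n, size=n_missing, replace=False)
            values[missing_rows, :] = np.nan
        meta = pd.DataFrame(
            {
                "sex": sex,
                "genotype": [s.split("_")[1] for s in sample_ids],
                "timepoint": [s.split("_")[2] for s in sample_ids],
                "replicate": [int(s.split("_")[3][1:]) for s in sample_ids],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        matrices[sex] = OmicsMatrix(
            pd.DataFrame(values, index=pd.Index(features, name="feature_id"), columns=sample_ids),
            meta,
        )

    truth = pd.DataFrame({"feature": features, "true_variance": variances})
    levels = [f"{g}.{t}" for g, t in cells]
    for contrast in default_contrasts(tuple(levels)):
        c = contrast.vector(levels)
        truth[contrast.name] = effect @ c
    contrast_cols = [c.name for c in default_contrasts(tuple(levels))]
    truth["is_null"] = (effect == 0).all(axis=1)
    truth = truth[["feature", "true_variance", "is_null"] + contrast_cols]
    return SimulatedExperiment(matrices=matrices, truth=truth)


def default_experiment_config(
    seed: int = 0,
    planted_fraction: float = 0.05,
    planted_log2fc: float = 1.0,
    n_features: int = 2000,
) -> SimConfig:
    """The reference simulation: 2000 features, variance prior
    (d0=4, s0^2=0.09), 3 replicates per cell, and a log2 effect of 1
    planted on 5% of features in the KI sedentary cell (so the KI.SED
    vs WT.SED contrast carries the signal).

    Set ``planted_fraction=0`` for a global-null experiment.
    """
    width = len(str(n_features - 1))
    n_planted = int(round(planted_fraction * n_features))
    effects = {
        (f"F{i:0{width}d}", "KI", "SED"): planted_log2fc for i in range(n_planted)
    }
    return SimConfig(n_features=n_features, effect_table=effects, seed=seed)


# ---------------------------------------------------------------------------
# phosphosite windows

WINDOW_CLASSES = ("strict", "relaxed_only", "minimal_only", "none")

_NOT_MINUS5 = tuple(sorted(set(AMINO_ACIDS) - MINUS5_RESIDUES))
_NOT_MINUS3 = tuple(sorted(set(AMINO_ACIDS) - MINUS3_RESIDUES))
_NOT_PLUS4 = tuple(sorted(set(AMINO_ACIDS) - PLUS4_RESIDUES))


def allocate_class_counts(n: int, class_fractions: Mapping[str, float]) -> dict[str, int]:
    """Exact integer allocation of ``n`` windows to motif classes.

    Uses floor allocation plus largest-remainder distribution so counts
    always sum to ``n``; fractions must sum to 1 within 1e-9.
    """
    fractions = {k: float(class_fractions.get(k, 0.0)) for k in WINDOW_CLASSES}
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, expected 1")
    raw = {k: n * v for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(WINDOW_CLASSES, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def _build_window(rng: np.random.Generator, cls: str) -> str:
    chars = list(rng.choice(AMINO_ACIDS, size=WINDOW_LENGTH))
    chars[CENTER_INDEX] = str(rng.choice(("S", "T")))
    if cls == "strict":
        chars[POS_MINUS5] = str(rng.choice(tuple(sorted(MINUS5_RESIDUES))))
        chars[POS_MINUS3] = str(rng.choice(tuple(sorted(MINUS3_RESIDUES))))
        chars[POS_PLUS4] = str(rng.choice(tuple(sorted(PLUS4_RESIDUES))))
    elif cls == "relaxed_only":
        chars[POS_MINUS5] = str(rng.choice(_NOT_MINUS5))
        chars[POS_MINUS3] = str(rng.choice(tuple(sorted(MINUS3_RESIDUES))))
        chars[POS_PLUS4] = str(rng.choice(tuple(sorted(PLUS4_RESIDUES))))
    elif cls == "minimal_only":
        chars[POS_MINUS3] = str(rng.choice(tuple(sorted(MINUS3_RESIDUES))))
        chars[POS_PLUS4] = str(rng.choice(_NOT_PLUS4))
    elif cls == "none":
        chars[POS_MINUS3] = str(rng.choice(_NOT_MINUS3))
    else:
        raise ValueError(f"unknown window class {cls!r}")
    return "".join(chars)


def simulate_phospho_windows(
    n: int, class_fractions: Mapping[str, float], seed: int = 0
) -> list[PhosphoWindow]:
    """Construct ``n`` 15-mer windows hitting the requested motif classes.

    Class keys: ``strict``, ``relaxed_only``, ``minimal_only``, ``none``.
    Allocation is exact (construction, not sampling), and every window is
    re-classified at generation time to guarantee it satisfies precisely
    the requested tier.
    """
    counts = allocate_class_counts(n, class_fractions)
    rng = np.random.default_rng(seed)
    windows: list[PhosphoWindow] = []
    i = 0
    for cls in WINDOW_CLASSES:
        for _ in range(counts[cls]):
            seq = _build_window(rng, cls)
            call = classify_motif(seq)
            observed = (
                "strict"
                if call.strict
                else "relaxed_only"
                if call.relaxed
                else "minimal_only"
                if call.minimal
                else "none"
            )
            if observed != cls:  # pragma: no cover - constructive guarantee
                raise AssertionError(f"constructed window misclassified: {seq} -> {observed}")
            windows.append(PhosphoWindow(site_id=f"SYN-{i:05d}-{cls}", sequence=seq))
            i += 1
    return windows


def write_windows_tsv(windows: Sequence[PhosphoWindow], path) -> None:
    pd.DataFrame(
        {"site_id": [w.site_id for w in windows], "sequence": [w.sequence for w in windows]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# redundant set collections


def simulate_set_collection(
    n_true_sets: int,
    duplicates_per_set: int,
    jitter: int,
    universe: Sequence[str],
    seed: int = 0,
    set_size: int = 20,
) -> tuple[SetCollection, dict[str, str]]:
    """Build families of near-duplicate sets with a known representative.

    Each of ``n_true_sets`` families contains one hub set plus
    ``duplicates_per_set`` variants obtained by swapping ``jitter``
    members for fresh universe items (so all family members share size
    ``set_size`` and pairwise Jaccard ``(set_size - jitter) /
    (set_size + jitter)`` with the hub).  Families draw from disjoint
    slices of the universe, so cross-family similarity is zero.  The hub
    carries the shortest description, making it the intended winner of
    the representative cascade; the returned dict maps family hub names
    to themselves (family name -> expected representative).
    """
    if jitter < 0 or jitter > set_size:
        raise ValueError("jitter must be between 0 and the set size")
    per_family = set_size + duplicates_per_set * jitter
    needed = n_true_sets * per_family
    if len(universe) < needed:
        raise ValueError(
            f"universe of {len(universe)} too small: need {needed} distinct members"
        )
    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(np.asarray(universe, dtype=object)))
    members: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    expected: dict[str, str] = {}
    cursor = 0
    for fam in range(n_true_sets):
        slice_ = pool[cursor : cursor + per_family]
        cursor += per_family
        hub = [str(x) for x in slice_[:set_size]]
        spare = [str(x) for x in slice_[set_size:]]
        hub_name = f"FAM{fam:03d}_HUB"
        members[hub_name] = tuple(hub)
        descriptions[hub_name] = f"family {fam}"
        expected[hub_name] = hub_name
        for k in range(duplicates_per_set):
            dup = list(hub)
            if jitter > 0:
                drop = rng.choice(set_size, size=jitter, replace=False)
                for j, d in enumerate(sorted(drop)):
                    dup[d] = spare[k * jitter + j]
            name = f"FAM{fam:03d}_DUP{k}"
            members[name] = tuple(dup)
            descriptions[name] = f"family {fam} near-duplicate variant number {k}"
    return SetCollection(members, descriptions), expected


# ---------------------------------------------------------------------------
# respirometry


def simulate_respirometry(
    true_slope: float,
    intercept: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    include_leak: bool = True,
    genotype: str = "",
    sex: str = "",
) -> RespirometryAssay:
    """Generate a CK-clamp assay with a linear force-flow relationship.

    Titration states are placed on the standard dG_ATP grid
    (-13.38, -13.71, -14.12, -14.45 kcal/mol for 1/2/4/6 mM PCr) with
    ``JO2 = intercept + true_slope * dG_ATP + noise``; the maximal state
    sits on the same line at -12.94 kcal/mol.  JO2 is floored at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    def jo2_at(dg: float) -> float:
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        return max(0.0, intercept + true_slope * dg + noise)

    states: list[RespState] = []
    max_jo2 = jo2_at(DELTA_G_MAX)
    if include_leak:
        states.append(RespState(label="leak", jo2=0.2 * max_jo2))
    states.append(RespState(label="max", jo2=max_jo2, pcr_mm=1.0, delta_g_atp=DELTA_G_MAX))
    for pcr in sorted(DELTA_G_BY_PCR):
        dg = DELTA_G_BY_PCR[pcr]
        states.append(
            RespState(label="titration", jo2=jo2_at(dg), pcr_mm=pcr, delta_g_atp=dg)
        )
    return RespirometryAssay(states=states, genotype=genotype, sex=sex)
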