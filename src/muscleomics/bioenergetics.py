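"""Creatine-kinase-clamp respirometry analysis.

The CK clamp holds the free energy of ATP hydrolysis (dG_ATP, kcal/mol)
at set values via phosphocreatine titrations while oxygen flux (JO2,
pmol/s) is recorded by high-resolution respirometry.  Across the clamp's
linear force-flow range, the slope of JO2 versus dG_ATP is the
mitochondrial "conductance" — by analogy with Ohm's law, the inverse
resistance of oxidative phosphorylation to energetic demand.  dG_ATP
values for the standard PCr levels are fixed constants computed for
37 degC, 170 mM ionic strength, 5 mM creatine and 10 mM phosphate
(pH 7.1); no interpolation between levels is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: dG_ATP (kcal/mol) at each PCr titration level (mM).
DELTA_G_BY_PCR = {1.0: -13.38, 2.0: -13.71, 4.0: -14.12, 6.0: -14.45}
#: dG_ATP during maximal phosphorylating respiration (1 mM PCr bolus with CK/ATP).
DELTA_G_MAX = -12.94

#: Cytochrome-c integrity threshold: a JO2 rise above 15% fails QC.
CYTC_THRESHOLD = 0.15

STATE_LABELS = ("leak", "max", "titration", "cytc_check")


def assign_delta_g(pcr_mm: float | None = None, label: str | None = None) -> float:
    """Look up dG_ATP (kcal/mol) for a PCr level or the 'max' state."""
    if label == "max":
        return DELTA_G_MAX
    if pcr_mm is None:
        raise ValueError("need a PCr concentration or label='max'")
    key = float(pcr_mm)
    if key not in DELTA_G_BY_PCR:
        raise ValueError(
            f"no tabulated dG_ATP for PCr={pcr_mm} mM "
            f"(known levels: {sorted(DELTA_G_BY_PCR)}); interpolation is not supported"
        )
    return DELTA_G_BY_PCR[key]


def qc_cytochrome_c(jo2_before: float, jo2_after: float) -> tuple[bool, float]:
    """Outer-membrane integrity check after exogenous cytochrome c.

    Returns ``(passed, fractional_change)``.  A rise strictly greater
    than 15% indicates membrane damage and fails the assay.
    """
    if jo2_before <= 0:
        raise ValueError("baseline JO2 must be positive")
    change = (jo2_after - jo2_before) / jo2_before
    return change <= CYTC_THRESHOLD, change


@dataclass(frozen=True)
class RespState:
    """One respirometry state: label, PCr level, dG_ATP and oxygen flux."""

    label: str
    jo2: float
    pcr_mm: float | None = None
    delta_g_atp: float | None = None

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")
        if self.jo2 < 0:
            raise ValueError("JO2 cannot be negative")


@dataclass
class RespirometryAssay:
    """Ordered CK-clamp states for one subject."""

    states: list[RespState]
    genotype: str = ""
    sex: str = ""

    def with_delta_g(self) -> "RespirometryAssay":
        """Fill in tabulated dG_ATP for titration and max states."""
        filled = []
        for st in self.states:
            if st.delta_g_atp is None and st.label in ("titration", "max"):
                dg = assign_delta_g(st.pcr_mm, label="max" if st.label == "max" else None)
                st = RespState(st.label, st.jo2, st.pcr_mm, dg)
            filled.append(st)
        return RespirometryAssay(filled, self.genotype, self.sex)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "label": s.label,
                    "pcr_mm": s.pcr_mm,
                    "delta_g_atp": s.delta_g_atp,
                    "jo2": s.jo2,
                }
                for s in self.states
            ]
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, genotype: str = "", sex: str = "") -> "RespirometryAssay":
        df = pd.read_csv(path, sep="\t")
        states = [
            RespState(
                label=str(r["label"]),
                jo2=float(r["jo2"]),
                pcr_mm=None if pd.isna(r.get("pcr_mm")) else float(r["pcr_mm"]),
                delta_g_atp=None
                if pd.isna(r.get("delta_g_atp"))
                else float(r["delta_g_atp"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(states, genotype, sex)


@dataclass(frozen=True)
class ConductanceResult:
    """Force-flow fit: JO2 regressed on dG_ATP over the titration states."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def conductance(self) -> float:
        return abs(self.slope)


def compute_conductance(
    assay: RespirometryAssay, include_max: bool = False
) -> ConductanceResult:
    """Ordinary least-squares fit of JO2 on dG_ATP.

    Uses the titration states (plus the max state when ``include_max``);
    states without an assigned dG_ATP are filled from the lookup table.
    """
    assay = assay.with_delta_g()
    wanted = ("titration", "max") if include_max else ("titration",)
    pts = [
        (s.delta_g_atp, s.jo2)
        for s in assay.states
        if s.label in wanted and s.delta_g_atp is not None
    ]
    if len(pts) < 2:
        raise ValueError("need at least 2 states with assigned dG_ATP")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("all dG_ATP values identical; slope undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float((xc @ yc) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(((y - intercept - slope * x) ** 2).sum())
    ss_tot = float((yc**2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ConductanceResult(
        slope=slope, intercept=intercept, r_squared=max(0.0, min(1.0, r2)), n_points=len(pts)
    )


def compare_conductance(
    slopes_a: Iterable[float], slopes_b: Iterable[float]
) -> tuple[float, float]:
    """Two-sample t-test of per-subject conductance slopes (e.g. WT vs KI)."""
    from scipy import stats as _st

    a = np.asarray(list(slopes_a), dtype=float)
    b = np.asarray(list(slopes_b), dtype=float)
    t, p = _st.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
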