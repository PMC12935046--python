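"""AMPK consensus-motif classification of phosphosite sequence windows.

AMPK (AMP-activated protein kinase) phosphorylates serine/threonine
residues embedded in a characteristic sequence context.  Substrate
candidates are screened with a fixed-width window of 15 residues centered
on the phosphosite (position 0), scored at three stringency tiers:

* **strict** — hydrophobic [I/V/L/M] at -5, basic [R/K] at -3, S/T at the
  center, and hydrophobic [I/F/L/M] at +4;
* **relaxed** — drops the -5 requirement;
* **minimal** — only the basic residue at -3 (plus S/T at the center).

The tiers are nested: every strict match is a relaxed match, and every
relaxed match is a minimal match.  Matching is case-insensitive
(lower-case letters conventionally mark the phosphorylated residue), and
the padding character ``_`` used for windows that run off a protein
terminus fails every positional test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

WINDOW_LENGTH = 15
CENTER_INDEX = 7  # 0-based index of position 0 in the 15-mer
PAD_CHAR = "_"

#: Residue classes at each constrained position (upper-case alphabet).
MINUS5_RESIDUES = frozenset("IVLM")
MINUS3_RESIDUES = frozenset("RK")
CENTER_RESIDUES = frozenset("ST")
PLUS4_RESIDUES = frozenset("IFLM")

# Offsets relative to the center, as 0-based window indices.
POS_MINUS5 = CENTER_INDEX - 5
POS_MINUS3 = CENTER_INDEX - 3
POS_PLUS4 = CENTER_INDEX + 4


@dataclass(frozen=True)
class PhosphoWindow:
    """A 15-mer sequence window centered on a phosphosite."""

    site_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"{self.site_id}: window must be {WINDOW_LENGTH} residues, "
                f"got {len(self.sequence)}"
            )


@dataclass(frozen=True)
class MotifCall:
    """Tiered classification of one window plus the residues inspected."""

    site_id: str
    sequence: str
    res_minus5: str
    res_minus3: str
    res_center: str
    res_plus4: str
    strict: bool
    relaxed: bool
    minimal: bool


def extract_window(protein_sequence: str, position: int, site_id: str = "") -> PhosphoWindow:
    """Cut the 15-mer window around a phosphosite of a protein sequence.

    ``position`` is the 1-based residue index of the phosphosite.  Window
    positions that fall outside the protein are padded with ``_``.
    """
    n = len(protein_sequence)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside protein of length {n}")
    center = protein_sequence[position - 1]
    if center.upper() not in CENTER_RESIDUES:
        raise ValueError(
            f"residue at position {position} is {center!r}, expected S or T"
        )
    chars = []
    for offset in range(-7, 8):
        idx = position - 1 + offset
        chars.append(protein_sequence[idx] if 0 <= idx < n else PAD_CHAR)
    return PhosphoWindow(site_id=site_id, sequence="".join(chars))


def classify_motif(window: PhosphoWindow | str) -> MotifCall:
    """Classify one 15-mer window against the three motif tiers."""
    if isinstance(window, str):
        window = PhosphoWindow(site_id="", sequence=window)
    seq = window.sequence.upper()
    r5, r3, rc, r4 = seq[POS_MINUS5], seq[POS_MINUS3], seq[CENTER_INDEX], seq[POS_PLUS4]
    minimal = rc in CENTER_RESIDUES and r3 in MINUS3_RESIDUES
    relaxed = minimal and r4 in PLUS4_RESIDUES
    strict = relaxed and r5 in MINUS5_RESIDUES
    raw = window.sequence
    return MotifCall(
        site_id=window.site_id,
        sequence=raw,
        res_minus5=raw[POS_MINUS5],
        res_minus3=raw[POS_MINUS3],
        res_center=raw[CENTER_INDEX],
        res_plus4=raw[POS_PLUS4],
        strict=strict,
        relaxed=relaxed,
        minimal=minimal,
    )


@dataclass
class MotifSummary:
    """Per-window motif calls with tier totals (and any per-row errors)."""

    calls: pd.DataFrame
    errors: pd.DataFrame
    n_strict: int
    n_relaxed: int
    n_minimal: int

    @property
    def n_windows(self) -> int:
        return len(self.calls)


def scan_sites(windows: Iterable[PhosphoWindow | Sequence[str]]) -> MotifSummary:
    """Classify a batch of windows and tally matches per stringency tier.

    Accepts :class:`PhosphoWindow` objects or ``(site_id, sequence)``
    pairs.  Malformed windows are collected as error records rather than
    aborting the scan.
    """
    rows, errors = [], []
    for item in windows:
        if isinstance(item, PhosphoWindow):
            site_id, seq = item.site_id, item.sequence
        else:
            site_id, seq = item
        try:
            call = classify_motif(PhosphoWindow(site_id=site_id, sequence=seq))
        except ValueError as exc:
            errors.append({"site_id": site_id, "sequence": seq, "error": str(exc)})
            continue
        rows.append(
            {
                "site_id": call.site_id,
                "sequence": call.sequence,
                "res_minus5": call.res_minus5,
                "res_minus3": call.res_minus3,
                "res_center": call.res_center,
                "res_plus4": call.res_plus4,
                "strict": call.strict,
                "relaxed": call.relaxed,
                "minimal": call.minimal,
            }
        )
    columns = [
        "site_id", "sequence", "res_minus5", "res_minus3", "res_center",
        "res_plus4", "strict", "relaxed", "minimal",
    ]
    calls = pd.DataFrame(rows, columns=columns)
    err = pd.DataFrame(errors, columns=["site_id", "sequence", "error"])
    return MotifSummary(
        calls=calls,
        errors=err,
        n_strict=int(calls["strict"].sum()) if len(calls) else 0,
        n_relaxed=int(calls["relaxed"].sum()) if len(calls) else 0,
        n_minimal=int(calls["minimal"].sum()) if len(calls) else 0,
    )


def read_windows_tsv(path) -> list[PhosphoWindow]:
    """Read a two-column (site_id, sequence) TSV of phosphosite windows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("windows TSV needs at least two columns (site_id, sequence)")
    id_col, seq_col = df.columns[:2]
    return [
        PhosphoWindow(site_id=str(r[id_col]), sequence=str(r[seq_col]))
        for _, r in df.iterrows()
    ]


def write_summary_tsv(summary: MotifSummary, path) -> None:
    summary.calls.to_csv(path, sep="\t", index=False)
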