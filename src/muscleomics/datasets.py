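"""Bundled reference data.

``AMPK_CANDIDATE_WINDOWS`` is a curated panel of 18 phosphosite sequence
windows from mouse skeletal-muscle exercise phosphoproteomics: every
exercise-regulated site whose 15-mer context fits the AMPK consensus at
the strict or relaxed tier, together with the published residue
annotations at the -5/-3/+4 positions and the published strict/relaxed
calls.  The panel serves as a ground-truth fixture for the motif scanner:
re-classification must reproduce every annotation.
"""

from __future__ import annotations

import pandas as pd

# columns: protein, site, sequence, res-5, res-3, res0, res+4, strict, relaxed
_ROWS = [
    ("Ankrd11", "S1070", "HSKDRKAsFDQLREK", "K", "R", "S", "L", False, True),
    ("C2cd2",   "S54",   "DELRRREsDTLLSWI", "L", "R", "S", "L", True,  True),
    ("Cog3",    "S655",  "PRFFRLNsNNALIEF", "F", "R", "S", "L", False, True),
    ("Crtc2",   "S612",  "THCSRHGsGPNIILT", "C", "R", "S", "I", False, True),
    ("Dst",     "S7186", "SKMLRSEsNSSITAT", "M", "R", "S", "I", True,  True),
    ("Ehbp1l1", "S1074", "LGVQKPGsWGALKYE", "V", "K", "S", "L", True,  True),
    ("Map4k5",  "S335",  "SRAERTAsEINFDKL", "A", "R", "S", "F", False, True),
    ("Mylk4",   "S100",  "MVMAKHAsVDNLYTV", "M", "K", "S", "L", True,  True),
    ("Ppp1r12b","S446",  "LGLRKTGsHNMLSEV", "L", "K", "S", "L", True,  True),
    ("Ppp1r3a", "S837",  "TGNQKATsKLDLHLG", "N", "K", "S", "L", False, True),
    ("Prep",    "S667",  "VGRSRKQsNPLLIHV", "R", "R", "S", "L", False, True),
    ("Prob1",   "S494",  "VGLSRDSsLPALLPR", "L", "R", "S", "L", True,  True),
    ("Prxl2b",  "S110",  "LGFKRYNsLSILPAA", "F", "R", "S", "L", False, True),
    ("Ptpn2",   "S293",  "QKRWKELsKEDLSPI", "R", "K", "S", "L", False, True),
    ("Rbm14",   "S618",  "LSDYRRLsESQLSFR", "D", "R", "S", "L", False, True),
    ("Smtnl2",  "S119",  "LGTARFSsHATFSLS", "T", "R", "S", "F", False, True),
    ("Sorbs2",  "S27",   "TSVKRVQsSPNLLAA", "V", "R", "S", "L", True,  True),
    ("Ulk2",    "S528",  "LLGARLQsAPTLTDI", "G", "R", "S", "L", False, True),
]


def ampk_candidate_windows() -> pd.DataFrame:
    """Return the reference panel of AMPK substrate-candidate windows.

    Columns: ``site_id`` (GENE-SITE), ``protein``, ``site``, ``sequence``
    (15-mer, lower-case phosphoresidue at the center), ``res_minus5``,
    ``res_minus3``, ``res_center``, ``res_plus4``, ``strict``, ``relaxed``.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "protein", "site", "sequence", "res_minus5", "res_minus3",
            "res_center", "res_plus4", "strict", "relaxed",
        ],
    )
    df.insert(0, "site_id", df["protein"] + "-" + df["site"])
    return df
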