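"""Published differential-expression table of the grapevine cold-stress
two-library experiment (control NCT at 25 degC vs cold-treated CT at 4 degC).

Each row carries the printed per-library TPM pair, the printed log2
fold-change and p-value.  Fused row labels denote identical-sequence family
members reported as one row: a slash lists members (``vvi-miR171a/i`` is two
miRNAs) and a dash spans a letter range (``vvi-miR395a-m`` is thirteen).
These printed values serve as worked-example inputs for the fold-change and
classification machinery; they are data, not code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List


@dataclass(frozen=True)
class PublishedDEMRow:
    name: str
    tpm_nct: float
    tpm_ct: float
    fc_printed: float
    p_printed: float


DEM_TABLE: List[PublishedDEMRow] = [
    PublishedDEMRow("vvi-miR3640*", 2.76, 51.63, 4.22, 2.22e-265),
    PublishedDEMRow("vvi-miR3640", 27.25, 83.23, 1.61, 9.18e-151),
    PublishedDEMRow("vvi-miR3624", 85.36, 244.18, 1.52, 0.0),
    PublishedDEMRow("vvi-miR3636", 414.93, 1090.49, 1.39, 0.0),
    PublishedDEMRow("vvi-miR3637*", 7.5859, 18.0585, 1.25, 7.30e-24),
    PublishedDEMRow("vvi-miR3634", 14.56, 31.80, 1.13, 7.97e-35),
    PublishedDEMRow("novel_mir_65", 15.97, 52.36, 1.71, 4.33e-104),
    PublishedDEMRow("novel_mir_44", 0.01, 13.20, 10.37, 5.85e-90),
    PublishedDEMRow("novel_mir_45", 0.01, 20.10, 10.97, 1.10e-136),
    PublishedDEMRow("novel_mir_42", 0.01, 111.79, 13.45, 0.0),
    PublishedDEMRow("novel_mir_39", 0.01, 151.10, 13.88, 0.0),
    PublishedDEMRow("vvi-miR171a/i", 24.44, 12.04, -1.02, 6.02e-24),
    PublishedDEMRow("vvi-miR171c/d", 27.96, 13.74, -1.03, 2.71e-27),
    PublishedDEMRow("vvi-miR156d", 11590.51, 5547.77, -1.06, 0.0),
    PublishedDEMRow("vvi-miR156b", 11569.63, 5527.86, -1.07, 0.0),
    PublishedDEMRow("vvi-miR156c", 11422.59, 5431.93, -1.07, 0.0),
    PublishedDEMRow("vvi-miR172d", 55.02, 24.77, -1.15, 1.41e-62),
    PublishedDEMRow("vvi-miR397a", 208.71, 84.39, -1.31, 4.20e-283),
    PublishedDEMRow("vvi-miR3633b*", 13.25, 5.29, -1.33, 5.23e-20),
    PublishedDEMRow("vvi-miR398b/c", 11.99, 4.67, -1.36, 6.36e-19),
    PublishedDEMRow("vvi-miR3633b", 10.68, 3.47, -1.62, 1.18e-21),
    PublishedDEMRow("vvi-miR395a-m", 276.56, 46.38, -2.58, 0.0),
    PublishedDEMRow("novel_mir_29", 16.06, 5.02, -1.68, 2.29e-33),
    PublishedDEMRow("novel_mir_13", 55.96, 25.51, -1.13, 4.42e-62),
    PublishedDEMRow("novel_mir_30", 89.44, 44.61, -1.00, 1.09e-80),
    PublishedDEMRow("novel_mir_6", 200.79, 0.01, -14.29, 0.0),
    PublishedDEMRow("novel_mir_4", 161.32, 0.01, -13.98, 0.0),
    PublishedDEMRow("novel_mir_27", 76.09, 0.01, -13.89, 0.0),
    PublishedDEMRow("novel_mir_24", 10.21, 0.01, -10.00, 5.33e-76),
]

_FUSED_RE = re.compile(r"^(?P<base>.*?miR\d+)(?P<suffix>[a-z](?:[/-][a-z])+)\*?$")


def n_members(name: str) -> int:
    """Number of family members a (possibly fused) row label stands for.

    ``a/i`` lists members explicitly; ``a-m`` spans the letter range.
    Plain and star-strand labels stand for one miRNA.
    """
    m = _FUSED_RE.match(name)
    if not m:
        return 1
    suffix = m.group("suffix")
    if "/" in suffix:
        return len(suffix.split("/"))
    lo, hi = suffix.split("-")
    return ord(hi) - ord(lo) + 1
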