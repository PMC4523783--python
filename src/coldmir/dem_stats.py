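"""Two-library differential expression of miRNA counts.

Expression is normalised to transcripts per million (TPM = count / total
clean reads x 1e6); a zero count is substituted with TPM = 0.01 so the
log2 fold-change log2(CT/NCT) stays finite.  miRNAs with TPM < 10 in both
libraries are set aside as low-expression.  A miRNA is upregulated when
FC > 1 and p <= 0.001, downregulated when FC < -1 and p <= 0.001.

The replicate-free two-library p-value follows the Audic-Claverie model for
tag counts: given x reads out of N1 and y out of N2, with r = N2/N1,

    P(y | x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)),

a negative-binomial mass in y.  The default test conditions this model on
the observed total (the renormalised mass at fixed x+y is
Binomial(x+y, N1/(N1+N2))) and computes the exact minimum-likelihood
two-sided p, which is symmetric under swapping the libraries.  The literal
tail form (twice the smaller nbinom tail) is available as ``method="ac_tail"``
and a two-proportion normal approximation as ``method="normal"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

TPM_ZERO_SUBSTITUTE = 0.01
LOW_TPM_THRESHOLD = 10.0
FC_THRESHOLD = 1.0
P_THRESHOLD = 0.001

TIMEPOINTS_H = (0, 2, 4, 8, 24, 48)


@dataclass
class DEMThresholds:
    low_tpm: float = LOW_TPM_THRESHOLD
    fc: float = FC_THRESHOLD
    p: float = P_THRESHOLD
    zero_substitute: float = TPM_ZERO_SUBSTITUTE


@dataclass
class ExpressionRecord:
    mirna_name: str
    count_NCT: int
    count_CT: int
    total_NCT: int
    total_CT: int


@dataclass
class DEMResult:
    mirna_name: str
    tpm_NCT: float
    tpm_CT: float
    log2_fold_change: float
    p_value: float
    dem_class: str  # up | down | unchanged | filtered_low


def tpm(count: float, total_clean_reads: float,
        zero_substitute: float = TPM_ZERO_SUBSTITUTE) -> float:
    """Transcripts per million; a zero count maps to the 0.01 floor."""
    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return zero_substitute
    return count / total_clean_reads * 1e6


def fold_change(tpm_ct: float, tpm_nct: float) -> float:
    """log2(CT/NCT); inputs must already be zero-substituted (positive)."""
    if tpm_ct <= 0 or tpm_nct <= 0:
        raise ValueError("TPM inputs must be positive (missed zero substitution?)")
    return math.log2(tpm_ct / tpm_nct)


def ac_logpmf(y, x: int, n1: float, n2: float) -> np.ndarray:
    """log P(y|x) of the AC mass in log space (nbinom parameterisation)."""
    r = n2 / n1
    return stats.nbinom.logpmf(np.asarray(y), x + 1, 1.0 / (1.0 + r))


def ac_pmf_direct(y: int, x: int, n1: float, n2: float) -> float:
    """Direct (non-log) evaluation of the AC mass P(y|x) for small counts."""
    r = n2 / n1
    # (x+y)! / (x! y!) written as a binomial coefficient to avoid overflow
    return math.comb(x + y, y) * r ** y / (1.0 + r) ** (x + y + 1)


def pvalue_two_library(
    x: int, y: int, n1: float, n2: float, method: str = "ac"
) -> float:
    """Two-sided p-value for a tag observed x/N1 vs y/N2 times.

    method="ac": exact conditional test of the Audic-Claverie model
    (minimum-likelihood binomial on x out of x+y at q = N1/(N1+N2));
    symmetric under swapping (x, N1) with (y, N2).
    method="ac_tail": twice the smaller tail of the AC negative-binomial
    mass in y, capped at 1.
    method="normal": two-proportion z-test.
    """
    if x < 0 or y < 0 or x > n1 or y > n2:
        raise ValueError("counts must satisfy 0 <= count <= library total")
    if method == "ac":
        if x + y == 0:
            return 1.0
        q = n1 / (n1 + n2)
        return float(stats.binomtest(x, x + y, q, alternative="two-sided").pvalue)
    if method == "ac_tail":
        r = n2 / n1
        dist = stats.nbinom(x + 1, 1.0 / (1.0 + r))
        lower = dist.cdf(y)
        upper = dist.sf(y - 1)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "normal":
        p1, p2 = x / n1, y / n2
        pooled = (x + y) / (n1 + n2)
        if pooled in (0.0, 1.0):
            return 1.0
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = (p2 - p1) / se
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown p-value method: {method!r}")


def classify_from_tpm(
    tpm_nct: float,
    tpm_ct: float,
    p_value: float,
    thresholds: Optional[DEMThresholds] = None,
) -> Tuple[float, str]:
    """(log2 fold-change, class) from a zero-substituted TPM pair and p-value."""
    t = thresholds or DEMThresholds()
    fc = fold_change(tpm_ct, tpm_nct)
    if tpm_nct < t.low_tpm and tpm_ct < t.low_tpm:
        return fc, "filtered_low"
    if fc > t.fc and p_value <= t.p:
        return fc, "up"
    if fc < -t.fc and p_value <= t.p:
        return fc, "down"
    return fc, "unchanged"


def classify_dem(
    record: ExpressionRecord,
    thresholds: Optional[DEMThresholds] = None,
    method: str = "ac",
) -> DEMResult:
    """Full DEM classification of one miRNA from raw counts and totals."""
    t = thresholds or DEMThresholds()
    tpm_nct = tpm(record.count_NCT, record.total_NCT, t.zero_substitute)
    tpm_ct = tpm(record.count_CT, record.total_CT, t.zero_substitute)
    p = pvalue_two_library(
        record.count_NCT, record.count_CT, record.total_NCT, record.total_CT, method
    )
    fc, cls = classify_from_tpm(tpm_nct, tpm_ct, p, t)
    return DEMResult(
        mirna_name=record.mirna_name,
        tpm_NCT=tpm_nct,
        tpm_CT=tpm_ct,
        log2_fold_change=fc,
        p_value=p,
        dem_class=cls,
    )


def dem_table(results: Sequence[DEMResult]) -> "pd.DataFrame":
    """DEM table with 2-decimal TPM and fold-change reporting columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "miRNA_name": r.mirna_name,
                "NCT_TPM": round(r.tpm_NCT, 2),
                "CT_TPM": round(r.tpm_CT, 2),
                "log2_fold_change": round(r.log2_fold_change, 2),
                "p_value": r.p_value,
                "class": r.dem_class,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# qPCR validation time-series patterns
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """Relative expression over the cold time course, normalised to 1 at 0 h."""

    mirna_name: str
    timepoints: Tuple[int, ...] = TIMEPOINTS_H
    relative_expression: Tuple[float, ...] = ()

    def validate(self) -> None:
        if tuple(self.timepoints) != TIMEPOINTS_H:
            raise ValueError(f"expected timepoints {TIMEPOINTS_H}")
        if len(self.relative_expression) != len(TIMEPOINTS_H):
            raise ValueError("need one value per timepoint")
        if abs(self.relative_expression[0] - 1.0) > 1e-9:
            raise ValueError("series must be normalised to 1 at 0 h")
        if any(v <= 0 for v in self.relative_expression):
            raise ValueError("relative expression must be positive")


def classify_time_pattern(series: TimeSeries) -> str:
    """Assign a cold-response expression pattern group (I-IV).

    I:   minimum at 4 or 8 h with mean stress-phase expression < 1
         (rapid repression, gradual recovery)
    II:  transient rise at 2 h, fallen by 8 h, stress mean < 1
    III: interior maximum > 1 followed by decline, elevated around 4 h
    IV:  declining through 8 h but recovering to >= 2-fold at 48 h

    Series matching no rule (e.g. flat controls) are 'unclassified'.
    """
    series.validate()
    v = list(series.relative_expression)
    stress = v[1:]
    stress_mean = sum(stress) / len(stress)
    argmin = min(range(len(v)), key=v.__getitem__)
    argmax = max(range(len(v)), key=v.__getitem__)
    # Group I: falls immediately, minimum at 4 or 8 h, overall repression
    if v[1] < v[0] and argmin in (2, 3) and stress_mean < 1.0 and v[argmin] < 1.0:
        return "I"
    # Group II: up at 2 h, down by 8 h, overall repression
    if v[1] > v[0] and v[3] < v[1] and stress_mean < 1.0:
        return "II"
    # Group III: interior peak above control, elevated around 4 h
    early_mean = sum(v[1:4]) / 3.0
    if argmax in (1, 2, 3) and v[argmax] > 1.0 and v[-1] < v[argmax] and early_mean > 1.0:
        return "III"
    # Group IV: repressed through 8 h, >= 2-fold by 48 h
    declining = all(v[i + 1] <= v[i] for i in range(3))
    if declining and v[3] < 1.0 and v[-1] >= 2.0:
        return "IV"
    return "unclassified"


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values (emitted as an extra column only;
    classification uses raw p-values)."""
    from statsmodels.stats.multitest import multipletests

    if len(pvalues) == 0:
        return []
    return list(multipletests(list(pvalues), method="fdr_bh")[1])
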