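"""Inter-method agreement statistics: Cohen's kappa, multiclass MCC, FDR, bands.

Two identification methods applied to the same individuals are compared via
a square confusion table over the union of their categories (species names
plus outcome categories such as ``putative_hybrid`` or ``no_match`` that
only one method can emit).  Agreement is summarised by

* Cohen's kappa, kappa = (po - pe) / (1 - pe), with the large-sample
  standard error se = sqrt(po (1 - po) / (n (1 - pe)^2)) and the 95 %
  interval kappa +/- 1.96 se;
* a one-sided p-value for kappa > 0 from the normal test with the
  null-hypothesis (Fleiss) standard error;
* the multiclass Matthews correlation coefficient (Gorodkin's R_K), which
  reduces to the classical MCC on 2x2 tables;
* the Landis–Koch verbal band for kappa.

p-values across a family of method pairs are adjusted by Benjamini–Hochberg
step-up (via statsmodels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests


@dataclass
class ConfusionTable:
    """Cross-tabulation of two categorical call sets over the same individuals."""

    categories: list[str]
    counts: np.ndarray  # rows: method 1, columns: method 2

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the category union")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.categories, columns=self.categories)


def confusion_table(
    calls1: Mapping[str, str], calls2: Mapping[str, str]
) -> ConfusionTable:
    """Build the confusion table of two call mappings over identical id sets.

    The category axis is the sorted union of both methods' categories, so a
    category only one method emits appears with zero marginal for the other.
    """
    if set(calls1) != set(calls2):
        raise ValueError("the two call sets cover different ids")
    if not calls1:
        raise ValueError("empty id set")
    cats = sorted(set(calls1.values()) | set(calls2.values()))
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)))
    for rid in calls1:
        counts[idx[calls1[rid]], idx[calls2[rid]]] += 1
    return ConfusionTable(categories=cats, counts=counts)


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    p_raw: float
    po: float
    pe: float
    undefined: bool = False


def cohen_kappa(t: ConfusionTable) -> KappaResult:
    """Cohen's kappa with large-sample SE, 95 % CI and one-sided p-value.

    When both methods are constant on the same category (pe = 1), kappa is
    undefined and reported as NaN with the ``undefined`` flag.
    """
    n = t.n
    if n < 2:
        raise ValueError("kappa needs at least 2 individuals")
    po = float(np.trace(t.counts)) / n
    rows = t.counts.sum(axis=1) / n
    cols = t.counts.sum(axis=0) / n
    pe = float(rows @ cols)
    if pe >= 1.0 - 1e-15:
        return KappaResult(math.nan, math.nan, (math.nan, math.nan),
                           math.nan, po, pe, undefined=True)
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    # one-sided normal test of kappa > 0 with the Fleiss null-hypothesis SE
    var0 = pe + pe**2 - float((rows * cols * (rows + cols)).sum())
    se0 = math.sqrt(max(var0, 0.0)) / ((1.0 - pe) * math.sqrt(n))
    if se0 > 0:
        p_raw = float(norm.sf(kappa / se0))
    else:
        # degenerate null (a marginal is empty): no evidence either way
        p_raw = 0.5 if kappa == 0 else math.nan
    return KappaResult(kappa, se, ci, p_raw, po, pe)


def mcc_multiclass(t: ConfusionTable) -> float:
    """Gorodkin's R_K: the Matthews correlation generalized to K categories.

    R_K = (c s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    with c the diagonal total, s = n, p_k row sums and t_k column sums.
    Degenerate tables (zero denominator) yield 0.
    """
    c = float(np.trace(t.counts))
    s = t.n
    p = t.counts.sum(axis=1)
    q = t.counts.sum(axis=0)
    num = c * s - float(p @ q)
    den = math.sqrt((s**2 - float(p @ p)) * (s**2 - float(q @ q)))
    if den == 0.0:
        return 0.0
    return num / den


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


#: Landis–Koch interpretation bands for kappa.
_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def agreement_band(kappa: float) -> str:
    """Landis–Koch verbal band; kappa = 1 exactly is reported as 'perfect'."""
    if math.isnan(kappa):
        return "undefined"
    if kappa < 0:
        return "poor"
    if kappa >= 1.0:
        return "perfect"
    for upper, label in _BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


@dataclass
class AgreementResult:
    """Full agreement summary for one ordered method pair."""

    method1: str
    method2: str
    kappa: float
    se: float
    ci95: tuple[float, float]
    p_raw: float
    p_fdr: float
    mcc: float
    band: str
    n: int


def agreement_matrix(
    calls_by_method: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Pairwise agreement over all unordered method pairs, with BH-FDR.

    ``calls_by_method`` maps a method name to its id -> call mapping; all
    methods must cover the same ids.  Returns a tidy DataFrame with one row
    per pair: kappa, SE, CI bounds, raw and FDR-adjusted p, MCC and band.
    """
    methods = list(calls_by_method)
    rows = []
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            t = confusion_table(calls_by_method[m1], calls_by_method[m2])
            k = cohen_kappa(t)
            rows.append(
                AgreementResult(
                    method1=m1,
                    method2=m2,
                    kappa=k.kappa,
                    se=k.se,
                    ci95=k.ci95,
                    p_raw=k.p_raw,
                    p_fdr=math.nan,
                    mcc=mcc_multiclass(t),
                    band=agreement_band(k.kappa),
                    n=int(t.n),
                )
            )
    finite = [r for r in rows if not math.isnan(r.p_raw)]
    if finite:
        adjusted = bh_fdr([r.p_raw for r in finite])
        for r, p in zip(finite, adjusted):
            r.p_fdr = p
    return pd.DataFrame(
        {
            "method1": [r.method1 for r in rows],
            "method2": [r.method2 for r in rows],
            "n": [r.n for r in rows],
            "kappa": [r.kappa for r in rows],
            "se": [r.se for r in rows],
            "ci_low": [r.ci95[0] for r in rows],
            "ci_high": [r.ci95[1] for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_fdr": [r.p_fdr for r in rows],
            "mcc": [r.mcc for r in rows],
            "band": [r.band for r in rows],
        }
    )
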