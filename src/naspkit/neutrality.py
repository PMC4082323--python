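"""Neutrality-deviation tests on composition statistics.

Under neutral (mutation-driven) evolution, the frequency of GC-rich amino
acids (G, A, P, W) should rise, and that of GC-poor amino acids
(F, Y, M, I, N, K) fall, with the genomic GC content — approximated here by
the GC fraction at fourfold-degenerate third codon positions (GC4f).
Likewise the purine (G+A) content at first codon positions of selected
residues should match that at fourfold-degenerate sites.  Selection on
amino-acid composition breaks both expectations: correlations vanish while
first-position composition decouples from the neutral proxy.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from scipy import stats

from naspkit.composition import CompositionReport, ga_first_vs_fourfold
from naspkit.seqio import GeneticCode, SequenceSet

#: Largest n for which the permutation p-value is computed exhaustively.
EXACT_PERMUTATION_MAX_N = 9


@dataclasses.dataclass
class CorrelationResult:
    r_s: float
    p_value: float
    n: int
    method: str  # exact-permutation | t-approximation
    label: str = ""


@dataclasses.dataclass
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_1: float
    sd_1: float
    mean_2: float
    sd_2: float
    paired: bool
    alternative: str
    n: int


def _midranks(x: TypingSequence[float]) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x: TypingSequence[float], y: TypingSequence[float]
) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    For n <= 9 the p-value is the exact two-sided permutation probability
    (all n! orderings of one variable); for larger n the usual t
    approximation with n - 2 degrees of freedom is used.  Constant input is
    rejected (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rx, ry = _midranks(x), _midranks(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r_perm = float((rx_c[list(perm)] * ry_c).sum()) / denom
            total += 1
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                hits += 1
        return CorrelationResult(r_obs, hits / total, n, "exact-permutation")
    t = r_obs * math.sqrt((n - 2) / max(1.0 - r_obs**2, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r_obs, min(p, 1.0), n, "t-approximation")


def neutrality_correlations(
    reports: Iterable[CompositionReport],
) -> list[CorrelationResult]:
    """Spearman correlations of GAPW/FYMINK/Ala/Lys frequencies with GC4f.

    One row per comparison; sequences without a defined GC4f are dropped.
    """
    usable = [r for r in reports if r.gc4f is not None]
    if len(usable) < 3:
        raise ValueError("need at least 3 sequences with defined fourfold-site GC")
    gc4f = [r.gc4f for r in usable]
    rows = []
    for label, values in (
        ("GC4f vs GAPW", [r.gapw for r in usable]),
        ("GC4f vs FYMINK", [r.fymink for r in usable]),
        ("GC4f vs Alanine", [r.alanine for r in usable]),
        ("GC4f vs Lysine", [r.lysine for r in usable]),
    ):
        res = spearman(gc4f, values)
        res.label = label
        rows.append(res)
    return rows


def ga_position_test(
    cds_set: SequenceSet,
    code: GeneticCode | None = None,
    paired: bool = True,
    restrict_to: Iterable[str] | None = None,
    alternative: str = "greater",
) -> TTestResult:
    """t-test of first-position G+A content against fourfold-site G+A content.

    Per sequence, (GA1, GA4f) form a pair; the default is a paired t-test of
    GA1 > GA4f (one-tailed), with Welch's unpaired test available.  Sequences
    lacking either quantity are dropped.
    """
    if alternative not in ("greater", "two-sided", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    code = code or GeneticCode.standard()
    ga1s, ga4s = [], []
    for seq in cds_set:
        ga1, ga4f = ga_first_vs_fourfold(seq, code, restrict_to)
        if ga1 is None or ga4f is None:
            continue
        ga1s.append(ga1)
        ga4s.append(ga4f)
    n = len(ga1s)
    if n < 2:
        raise ValueError("fewer than 2 sequences with defined GA1 and GA4f")
    a = np.asarray(ga1s)
    b = np.asarray(ga4s)
    if paired:
        d = a - b
        if float(d.std(ddof=1)) == 0.0:
            t, p, df = 0.0, (0.5 if alternative != "two-sided" else 1.0), n - 1
        else:
            res = stats.ttest_rel(a, b, alternative=alternative)
            t, p, df = float(res.statistic), float(res.pvalue), n - 1
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        if math.isnan(t):
            t, p = 0.0, (0.5 if alternative != "two-sided" else 1.0)
    return TTestResult(
        t=t, df=float(df), p_value=p,
        mean_1=float(a.mean()), sd_1=float(a.std(ddof=1)),
        mean_2=float(b.mean()), sd_2=float(b.std(ddof=1)),
        paired=paired, alternative=alternative, n=n,
    )
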