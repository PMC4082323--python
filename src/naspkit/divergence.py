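"""Distances, modified Nei-Gojobori counting and the codon-based Z-test of selection.

Divergence is measured as uncorrected proportions of differing sites
(p-distances) because of their small variance for deeply diverged taxa.
Synonymous (pS) and non-synonymous (pN) differences per site follow the
modified Nei-Gojobori method: the potential-site count of each codon weights
a transition 2R against each transversion 1, where R is the
transition/transversion ratio (transition rate over *total* transversion
rate), so R = 0.5 is the equal-per-change baseline and reproduces the
unweighted 1986 counts.  Observed differences between two codons are averaged
over all orderings of the differing positions, excluding any pathway that
passes through a stop codon.

Purifying selection is tested with a codon-based Z-test on (pS - pN), with
variances obtained by bootstrap over codon sites and a one-tailed standard
normal p-value for the alternative pN < pS.
"""

from __future__ import annotations

import dataclasses
import itertools
from functools import lru_cache
from typing import Iterable

import numpy as np
from scipy import stats

from naspkit.seqio import (
    AlignmentError,
    CodonAlignment,
    GeneticCode,
    NUCLEOTIDES,
    RegionMap,
    SequenceSet,
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

_CODES: dict[int, GeneticCode] = {}


def _code(table_id: int) -> GeneticCode:
    if table_id not in _CODES:
        _CODES[table_id] = GeneticCode(table_id)
    return _CODES[table_id]


def is_transition(b1: str, b2: str) -> bool:
    return (b1, b2) in _TRANSITIONS


def _step_weight(b1: str, b2: str, r: float) -> float:
    return 2.0 * r if is_transition(b1, b2) else 1.0


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, r: float, table_id: int) -> tuple[float, float]:
    code = _code(table_id)
    aa = code.amino_acid(codon)
    full_w = 2.0 * r + 2.0  # one transition + two transversions per position
    s = n = 0.0
    for pos in range(3):
        syn_w = non_w = 0.0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if code.is_stop(mutant):
                continue  # paths to stops count as neither syn nor non-syn sites
            w = _step_weight(codon[pos], base, r)
            if code.amino_acid(mutant) == aa:
                syn_w += w
            else:
                non_w += w
        s += syn_w / full_w
        n += non_w / full_w
    return s, n


def ng_site_counts(
    codon: str, r: float = 0.5, code: GeneticCode | None = None
) -> tuple[float, float]:
    """Synonymous and non-synonymous potential sites (s, n) of one sense codon.

    Each position contributes the transition/transversion-weighted fraction of
    its non-stop single-nucleotide mutants that are synonymous; mutational
    paths to stop codons are removed from numerator and denominator, so
    s + n <= 3 with equality unless a position's every change hits a stop.
    """
    code = code or GeneticCode.standard()
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if r <= 0:
        raise ValueError("transition/transversion ratio R must be positive")
    return _site_counts_cached(codon, float(r), code.table_id)


@lru_cache(maxsize=None)
def _pair_diffs_cached(
    c1: str, c2: str, r: float, table_id: int
) -> tuple[float, float]:
    code = _code(table_id)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_w = 0.0
    sd = nd = 0.0
    for order in itertools.permutations(diff_pos):
        current = c1
        weight = 1.0
        syn = nsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                break
            weight *= _step_weight(current[pos], c2[pos], r)
            if code.amino_acid(nxt) == code.amino_acid(current):
                syn += 1
            else:
                nsyn += 1
            current = nxt
        if blocked:
            continue
        total_w += weight
        sd += weight * syn
        nd += weight * nsyn
    if total_w > 0.0:
        return sd / total_w, nd / total_w
    # Every ordering passes through a stop codon: fall back to classifying each
    # differing position independently on whichever background avoids a stop.
    sd = nd = 0.0
    for pos in diff_pos:
        for base_codon, other in ((c1, c2), (c2, c1)):
            mutant = base_codon[:pos] + other[pos] + base_codon[pos + 1 :]
            if not code.is_stop(mutant):
                if code.amino_acid(mutant) == code.amino_acid(base_codon):
                    sd += 1.0
                else:
                    nd += 1.0
                break
    return sd, nd


def ng_pairwise_differences(
    c1: str, c2: str, r: float = 0.5, code: GeneticCode | None = None
) -> tuple[float, float]:
    """Synonymous and non-synonymous differences (Sd, Nd) between two sense codons.

    Averaged over all orderings of the differing positions with per-step
    transition/transversion weights; orderings passing through a stop codon
    are excluded.  Sd + Nd equals the number of differing positions whenever
    at least one ordering is admissible.
    """
    code = code or GeneticCode.standard()
    for c in (c1, c2):
        if code.is_stop(c):
            raise ValueError(f"stop codon {c!r} not allowed")
    return _pair_diffs_cached(c1, c2, float(r), code.table_id)


@dataclasses.dataclass
class DistanceEstimate:
    """A mean proportion of differing sites with its bootstrap standard error."""

    value: float
    se: float
    n_boot: int
    method: str  # aa | nt | syn | nonsyn
    scope: str  # pairwise | group-mean
    n_sites: float = 0.0


@dataclasses.dataclass
class SelectionZTest:
    """Result of the codon-based Z-test of selection on (pS - pN)."""

    ps: float
    pn: float
    var_ps: float
    var_pn: float
    z: float | None
    p_value: float
    alternative: str  # purifying | neutral | positive
    n_boot: int
    seed: int
    flags: tuple[str, ...] = ()


@dataclasses.dataclass
class WindowProfile:
    """Sliding-window nucleotide diversity along a codon alignment."""

    window: int
    step: int
    starts: list[int]
    pi_total: list[float]
    pi_syn: list[float]
    pi_nonsyn: list[float]


def _pairs(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _site_matrix(rows: list[str]) -> np.ndarray:
    return np.array([list(r) for r in rows])


def _pair_diff_matrix(mat: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """(n_pairs, n_sites) boolean matrix of per-site differences."""
    return np.array([mat[i] != mat[j] for i, j in pairs])


def p_distance(
    aln: SequenceSet | CodonAlignment,
    level: str = "aa",
    n_boot: int = 1000,
    seed: int = 0,
) -> DistanceEstimate:
    """Mean pairwise proportion of differing sites, SE by site-resampling bootstrap.

    ``level='aa'`` expects a protein :class:`SequenceSet` (or a codon alignment,
    which is translated); ``level='nt'`` compares nucleotide columns.
    Complete deletion is assumed to have been applied already.
    """
    if level not in ("aa", "nt"):
        raise ValueError("level must be 'aa' or 'nt'")
    if isinstance(aln, CodonAlignment):
        seqs = aln.translate_rows() if level == "aa" else aln.rows
    else:
        seqs = aln
        if level == "nt" and seqs.kind != "nucleotide":
            raise AlignmentError("nt-level distance needs nucleotide sequences")
        if level == "aa" and seqs.kind != "protein":
            raise AlignmentError("aa-level distance needs protein sequences")
    if len(seqs) < 2:
        raise AlignmentError("p_distance requires at least 2 sequences")
    if not seqs.is_aligned():
        raise AlignmentError("p_distance requires aligned sequences")
    mat = _site_matrix([s.residues for s in seqs])
    n_sites = mat.shape[1]
    if n_sites == 0:
        raise AlignmentError("zero sites")
    pairs = _pairs(len(seqs))
    diffs = _pair_diff_matrix(mat, pairs)
    value = float(diffs.mean(axis=1).mean())
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_sites, size=n_sites)
        reps[b] = diffs[:, idx].mean(axis=1).mean()
    se = float(reps.std(ddof=1)) if n_boot > 1 else 0.0
    scope = "pairwise" if len(seqs) == 2 else "group-mean"
    return DistanceEstimate(value=value, se=se, n_boot=n_boot, method=level,
                            scope=scope, n_sites=n_sites)


def _codon_site_arrays(
    aln: CodonAlignment, r: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per-pair, per-codon-site arrays (S, N, Sd, Nd); gap/ambiguous sites zeroed."""
    code = aln.genetic_code
    rows = [s.residues for s in aln.rows]
    n_rows, n_cod = len(rows), aln.n_codons
    pairs = _pairs(n_rows)
    codons = [[rows[i][3 * j : 3 * j + 3] for j in range(n_cod)] for i in range(n_rows)]
    usable = [
        [all(b in NUCLEOTIDES for b in c) and not code.is_stop(c) for c in row]
        for row in codons
    ]
    site_s = np.zeros((n_rows, n_cod))
    site_n = np.zeros((n_rows, n_cod))
    for i in range(n_rows):
        for j in range(n_cod):
            if usable[i][j]:
                s, n = ng_site_counts(codons[i][j], r, code)
                site_s[i, j], site_n[i, j] = s, n
    S = np.zeros((len(pairs), n_cod))
    N = np.zeros((len(pairs), n_cod))
    SD = np.zeros((len(pairs), n_cod))
    ND = np.zeros((len(pairs), n_cod))
    for p, (i, k) in enumerate(pairs):
        for j in range(n_cod):
            if not (usable[i][j] and usable[k][j]):
                continue
            S[p, j] = 0.5 * (site_s[i, j] + site_s[k, j])
            N[p, j] = 0.5 * (site_n[i, j] + site_n[k, j])
            sd, nd = ng_pairwise_differences(codons[i][j], codons[k][j], r, code)
            SD[p, j], ND[p, j] = sd, nd
    return S, N, SD, ND, pairs


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def ps_pn(
    aln: CodonAlignment,
    r: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[DistanceEstimate, DistanceEstimate]:
    """Per-site synonymous and non-synonymous difference proportions (pS, pN).

    For each pair, pS = sum(Sd)/sum(S) and pN = sum(Nd)/sum(N) over codon
    sites, with S and N averaged between the two sequences; group values are
    means over all pairs.  Standard errors come from a bootstrap over codon
    sites (the same resampling drives both estimates).
    """
    S, N, SD, ND, pairs = _codon_site_arrays(aln, r)
    if float(S.sum()) == 0.0 or float(N.sum()) == 0.0:
        raise AlignmentError("no synonymous or no non-synonymous sites available")
    ps_val = float(_ratio(SD.sum(axis=1), S.sum(axis=1)).mean())
    pn_val = float(_ratio(ND.sum(axis=1), N.sum(axis=1)).mean())
    rng = np.random.default_rng(seed)
    n_cod = S.shape[1]
    ps_reps = np.empty(n_boot)
    pn_reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_cod, size=n_cod)
        ps_reps[b] = _ratio(SD[:, idx].sum(axis=1), S[:, idx].sum(axis=1)).mean()
        pn_reps[b] = _ratio(ND[:, idx].sum(axis=1), N[:, idx].sum(axis=1)).mean()
    scope = "pairwise" if len(pairs) == 1 else "group-mean"
    ps_est = DistanceEstimate(ps_val, float(ps_reps.std(ddof=1)), n_boot, "syn",
                              scope, n_sites=float(S.sum(axis=1).mean()))
    pn_est = DistanceEstimate(pn_val, float(pn_reps.std(ddof=1)), n_boot, "nonsyn",
                              scope, n_sites=float(N.sum(axis=1).mean()))
    return ps_est, pn_est


def z_test_selection(
    aln: CodonAlignment,
    r: float = 0.5,
    alternative: str = "purifying",
    n_boot: int = 1000,
    seed: int = 0,
) -> SelectionZTest:
    """Codon-based Z-test of selection.

    Z = (pS - pN) / sqrt(var(pS) + var(pN)) with bootstrap variances; the
    p-value is one-tailed normal for the purifying (pN < pS) and positive
    (pN > pS) alternatives and two-tailed for the neutral alternative.
    A degenerate comparison (zero variance, e.g. identical sequences) reports
    p = 1 with an explicit flag instead of NaN.
    """
    if alternative not in ("purifying", "neutral", "positive"):
        raise ValueError(f"unknown alternative {alternative!r}")
    S, N, SD, ND, pairs = _codon_site_arrays(aln, r)
    flags: list[str] = []
    variable = int(((SD + ND).sum(axis=0) > 0).sum())
    if variable < 10:
        flags.append("low_power")
    ps_val = float(_ratio(SD.sum(axis=1), S.sum(axis=1)).mean())
    pn_val = float(_ratio(ND.sum(axis=1), N.sum(axis=1)).mean())
    rng = np.random.default_rng(seed)
    n_cod = S.shape[1]
    ps_reps = np.empty(n_boot)
    pn_reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_cod, size=n_cod)
        ps_reps[b] = _ratio(SD[:, idx].sum(axis=1), S[:, idx].sum(axis=1)).mean()
        pn_reps[b] = _ratio(ND[:, idx].sum(axis=1), N[:, idx].sum(axis=1)).mean()
    var_ps = float(ps_reps.var(ddof=1))
    var_pn = float(pn_reps.var(ddof=1))
    denom = var_ps + var_pn
    if denom <= 0.0:
        flags.append("degenerate")
        return SelectionZTest(ps_val, pn_val, var_ps, var_pn, None, 1.0,
                              alternative, n_boot, seed, tuple(flags))
    z = (ps_val - pn_val) / np.sqrt(denom)
    if alternative == "purifying":
        p = float(stats.norm.sf(z))
    elif alternative == "positive":
        p = float(stats.norm.cdf(z))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return SelectionZTest(ps_val, pn_val, var_ps, var_pn, float(z), min(p, 1.0),
                          alternative, n_boot, seed, tuple(flags))


@dataclasses.dataclass
class RegionResult:
    """Region-stratified distances and selection test (one table row)."""

    label: str
    n_codons: int
    p_aa: DistanceEstimate
    p_nt: DistanceEstimate
    ps: DistanceEstimate
    pn: DistanceEstimate
    ztest: SelectionZTest


def region_report(
    aln: CodonAlignment,
    regions: RegionMap,
    r: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
    alternative: str = "purifying",
    min_codons: int = 5,
) -> list[RegionResult]:
    """Distances and Z-tests stratified by named regions (TPR1-4, ACIDIC, ...).

    Produces one row per region, a REMAINDER row for unassigned columns (when
    any) and an ALL row for the whole alignment.  Region coordinates are
    1-based inclusive codon columns.
    """
    regions.validate_against(aln.n_codons)
    jobs: list[tuple[str, CodonAlignment]] = []
    for label, (start, end) in regions:
        if end - start + 1 < min_codons:
            raise ValueError(
                f"region {label!r} spans {end - start + 1} codons "
                f"(minimum {min_codons})"
            )
        jobs.append((label, aln.region_slice(start, end)))
    remainder = regions.complement(aln.n_codons)
    if len(remainder) >= min_codons:
        jobs.append(("REMAINDER", aln.subset_columns(remainder)))
    jobs.append(("ALL", aln))
    out = []
    for label, sub in jobs:
        p_aa = p_distance(sub, "aa", n_boot=n_boot, seed=seed)
        p_nt = p_distance(sub, "nt", n_boot=n_boot, seed=seed)
        ps, pn = ps_pn(sub, r, n_boot=n_boot, seed=seed)
        zt = z_test_selection(sub, r, alternative, n_boot=n_boot, seed=seed)
        out.append(RegionResult(label, sub.n_codons, p_aa, p_nt, ps, pn, zt))
    return out


def sliding_window_pi(
    aln: CodonAlignment, window: int = 50, step: int = 10, r: float = 0.5
) -> WindowProfile:
    """Nucleotide diversity (Pi) in sliding windows of nucleotide coordinates.

    Pi is the mean pairwise proportion of differing nucleotide positions in
    the window (window length 50 and step 10 by default).  Synonymous and
    non-synonymous per-site diversity are computed over codons lying fully
    inside the window; codons straddling a boundary count toward total Pi
    only.
    """
    length = aln.rows.alignment_length
    if window > length:
        raise AlignmentError(
            f"window {window} exceeds alignment length {length}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    mat = _site_matrix([s.residues for s in aln.rows])
    pairs = _pairs(len(aln))
    nt_diffs = _pair_diff_matrix(mat, pairs)
    S, N, SD, ND, _ = _codon_site_arrays(aln, r)
    n_windows = (length - window) // step + 1
    starts, pi_tot, pi_syn, pi_non = [], [], [], []
    for w in range(n_windows):
        start = 1 + w * step  # 1-based nt coordinate
        stop = start + window - 1
        starts.append(start)
        cols = slice(start - 1, stop)
        pi_tot.append(float(nt_diffs[:, cols].sum(axis=1).mean() / window))
        # codon c occupies nt 3c-2 .. 3c; fully inside iff 3c-2 >= start, 3c <= stop
        c_lo = (start + 2 + 2) // 3  # smallest c with 3c-2 >= start
        c_hi = stop // 3  # largest c with 3c <= stop
        if c_hi >= c_lo:
            csl = slice(c_lo - 1, c_hi)
            ps_w = _ratio(SD[:, csl].sum(axis=1), S[:, csl].sum(axis=1)).mean()
            pn_w = _ratio(ND[:, csl].sum(axis=1), N[:, csl].sum(axis=1)).mean()
        else:
            ps_w = pn_w = float("nan")
        pi_syn.append(float(ps_w))
        pi_non.append(float(pn_w))
    return WindowProfile(window, step, starts, pi_tot, pi_syn, pi_non)


def estimate_r(aln: CodonAlignment) -> float:
    """Crude transition/(total transversion) ratio from observed pair differences.

    Convenience only; the analysis functions take R explicitly (default 0.5).
    """
    mat = _site_matrix([s.residues for s in aln.rows])
    ts = tv = 0
    for i, j in _pairs(len(aln)):
        for a, b in zip(mat[i], mat[j]):
            if a == b or a not in NUCLEOTIDES or b not in NUCLEOTIDES:
                continue
            if is_transition(a, b):
                ts += 1
            else:
                tv += 1
    if tv == 0:
        return 0.5 if ts == 0 else float("inf")
    return ts / tv
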