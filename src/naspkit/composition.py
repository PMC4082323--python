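"""Codon-usage and composition statistics.

Implements the composition layer of the analysis: positional GC content,
fourfold-degenerate-site GC (the operational proxy for genomic GC), Wright's
effective number of codons (ENC), relative synonymous codon usage (RSCU),
amino-acid class frequencies (GC-rich GAPW vs GC-poor FYMINK), first-position
vs fourfold-site purine content, acidic-residue counts and theoretical pI.

ENC follows Wright (1990): for each synonymous family the codon homozygosity
is estimated as F = (n * sum(p_i^2) - 1) / (n - 1) with n the family's codon
count; homozygosities are averaged within each degeneracy class k and

    ENC = n_single + sum_k  m_k / Fbar_k

where m_k is the number of k-fold families and n_single the number of
single-codon families (standard code: 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6).
The family structure is always derived from the active genetic code, so the
ciliate nuclear table (TAA/TAG = Gln) changes the class counts accordingly.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence as TypingSequence

from naspkit.seqio import (
    GeneticCode,
    NUCLEOTIDES,
    Sequence,
    SequenceError,
    iter_codons,
)

GC = frozenset("GC")
GA = frozenset("GA")
GAPW = frozenset("GAPW")
FYMINK = frozenset("FYMINK")
ACIDIC_RESIDUES = frozenset("DE")

#: EMBOSS pKa values for ionizable groups (iep defaults).
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclasses.dataclass
class CodonUsageTable:
    """Counts of sense codons in a CDS (stops excluded from the total)."""

    counts: dict[str, int]
    total: int
    n_ambiguous: int
    n_stop: int
    genetic_code: GeneticCode

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        if other.genetic_code.table_id != self.genetic_code.table_id:
            raise ValueError("cannot merge usage tables under different genetic codes")
        merged = dict(self.counts)
        for codon, k in other.counts.items():
            merged[codon] = merged.get(codon, 0) + k
        return CodonUsageTable(
            counts=merged,
            total=self.total + other.total,
            n_ambiguous=self.n_ambiguous + other.n_ambiguous,
            n_stop=self.n_stop + other.n_stop,
            genetic_code=self.genetic_code,
        )


@dataclasses.dataclass
class CodonUsageStats:
    """ENC and per-degeneracy-class mean homozygosities for one usage table."""

    enc: float
    fbar: dict[int, float]
    imputed_classes: tuple[int, ...] = ()


def codon_usage(cds: Sequence, code: GeneticCode | None = None) -> CodonUsageTable:
    """Count sense codons in an in-frame CDS.

    Stop codons and codons containing ambiguity characters are excluded from
    the counts and tallied separately.
    """
    code = code or GeneticCode.standard()
    if cds.kind != "nucleotide":
        raise SequenceError("codon_usage expects a nucleotide CDS")
    counts: dict[str, int] = {}
    n_ambiguous = n_stop = 0
    for codon in iter_codons(cds.residues):
        if any(b not in NUCLEOTIDES for b in codon):
            n_ambiguous += 1
            continue
        if code.is_stop(codon):
            n_stop += 1
            continue
        counts[codon] = counts.get(codon, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise SequenceError(f"sequence {cds.id!r}: no countable sense codons")
    return CodonUsageTable(counts, total, n_ambiguous, n_stop, code)


def gc_by_position(
    cds: Sequence, code: GeneticCode | None = None
) -> tuple[float, float, float]:
    """GC fraction at codon positions 1, 2 and 3 (stop codons excluded)."""
    code = code or GeneticCode.standard()
    hits = [0, 0, 0]
    n = 0
    for codon in iter_codons(cds.residues):
        if any(b not in NUCLEOTIDES for b in codon) or code.is_stop(codon):
            continue
        n += 1
        for j, base in enumerate(codon):
            if base in GC:
                hits[j] += 1
    if n == 0:
        raise SequenceError(f"sequence {cds.id!r}: no countable codons")
    return tuple(h / n for h in hits)  # type: ignore[return-value]


def fourfold_gc(cds: Sequence, code: GeneticCode | None = None) -> float | None:
    """GC fraction at third positions of fourfold-degenerate codons.

    This quantity stands in for the genomic GC content of the region housing
    the gene.  Returns None when the CDS contains no fourfold codon.
    """
    code = code or GeneticCode.standard()
    hits = n = 0
    for codon in iter_codons(cds.residues):
        if any(b not in NUCLEOTIDES for b in codon):
            continue
        if code.is_fourfold(codon):
            n += 1
            if codon[2] in GC:
                hits += 1
    if n == 0:
        return None
    return hits / n


def _family_homozygosity(counts: TypingSequence[int]) -> float | None:
    """Wright's bias-corrected homozygosity F for one synonymous family.

    Requires at least 2 observed codons in the family; returns None otherwise.
    """
    n = sum(counts)
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in counts)
    return (n * s - 1) / (n - 1)


def wright_enc(
    fbar: Mapping[int, float],
    class_sizes: Mapping[int, int],
    n_single: int,
    cap: int = 61,
) -> float:
    """Evaluate Wright's ENC formula from mean homozygosities per class.

    ``fbar`` maps degeneracy k to the mean family homozygosity, ``class_sizes``
    maps k to the number of k-fold families, ``n_single`` counts single-codon
    families.  The result is capped at ``cap`` (61 sense codons under the
    standard code).
    """
    enc = float(n_single)
    for k, m in class_sizes.items():
        f = fbar[k]
        if f <= 0:
            raise ValueError(f"non-positive mean homozygosity for class {k}")
        enc += m / f
    return min(enc, float(cap))


def enc(usage: CodonUsageTable) -> CodonUsageStats:
    """Effective number of codons for a codon-usage table.

    Families with fewer than 2 observed codons are excluded from their class
    mean; a degeneracy class with no usable family has its mean homozygosity
    imputed as 1/k (the no-bias value), and the affected classes are reported.
    """
    code = usage.genetic_code
    families = code.families()
    by_class: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    n_single = 0
    for _aa, codons in families.items():
        k = len(codons)
        if k == 1:
            n_single += 1
            continue
        class_sizes[k] = class_sizes.get(k, 0) + 1
        f = _family_homozygosity([usage[c] for c in codons])
        if f is not None and f > 0:
            by_class.setdefault(k, []).append(f)
    if not by_class:
        raise ValueError("no synonymous family has enough codons to estimate ENC")
    fbar: dict[int, float] = {}
    imputed = []
    for k in class_sizes:
        if by_class.get(k):
            fbar[k] = sum(by_class[k]) / len(by_class[k])
        else:
            fbar[k] = 1.0 / k
            imputed.append(k)
    cap = len(code.sense_codons)
    value = wright_enc(fbar, class_sizes, n_single, cap=cap)
    return CodonUsageStats(enc=value, fbar=fbar, imputed_classes=tuple(sorted(imputed)))


def rscu(usage: CodonUsageTable) -> dict[str, float | None]:
    """Relative synonymous codon usage for every sense codon.

    RSCU = observed count / (family total / family size); 1 means no bias,
    >1 over-use, <1 under-use.  Codons of families never observed map to
    None; single-codon families report 1.0 whenever observed.
    """
    out: dict[str, float | None] = {}
    for _aa, codons in usage.genetic_code.families().items():
        family_total = sum(usage[c] for c in codons)
        size = len(codons)
        for c in codons:
            if family_total == 0:
                out[c] = None
            else:
                out[c] = usage[c] / (family_total / size)
    return out


@dataclasses.dataclass
class CompositionReport:
    """Per-sequence composition summary used by the neutrality tests."""

    seq_id: str
    aa_frequencies: dict[str, float]
    gapw: float
    fymink: float
    alanine: float
    lysine: float
    acidic_count: int
    net_charge_ph7: float
    theoretical_pi: float
    gc1: float | None = None
    gc2: float | None = None
    gc3: float | None = None
    gc4f: float | None = None
    ga1: float | None = None
    ga4f: float | None = None
    enc: float | None = None


def aa_class_frequencies(protein: Sequence) -> dict[str, float]:
    """Frequencies of the GAPW and FYMINK classes, alanine and lysine.

    Computed over the ungapped length; gaps and 'X' are ignored.
    """
    if protein.kind != "protein":
        raise SequenceError("aa_class_frequencies expects a protein sequence")
    residues = [r for r in protein.residues if r not in "-X"]
    if not residues:
        raise SequenceError(f"sequence {protein.id!r}: empty after removing gaps")
    n = len(residues)
    freqs: dict[str, float] = {}
    for aa in set(residues):
        freqs[aa] = residues.count(aa) / n
    return {
        "GAPW": sum(freqs.get(a, 0.0) for a in GAPW),
        "FYMINK": sum(freqs.get(a, 0.0) for a in FYMINK),
        "A": freqs.get("A", 0.0),
        "K": freqs.get("K", 0.0),
    }


def ga_first_vs_fourfold(
    cds: Sequence,
    code: GeneticCode | None = None,
    restrict_to: Iterable[str] | None = None,
) -> tuple[float | None, float | None]:
    """Purine (G+A) fraction at first codon positions and at fourfold sites.

    Under neutrality the two should match; selection for particular residues
    (alanine/lysine and the acidic pair share G or A first bases) decouples
    them.  ``restrict_to`` limits the first-position count to codons encoding
    the given residues (e.g. {"A", "K"}).  Either value is None when its
    denominator is empty.
    """
    code = code or GeneticCode.standard()
    restrict = set(restrict_to) if restrict_to is not None else None
    ga1_hits = ga1_n = ga4_hits = ga4_n = 0
    for codon in iter_codons(cds.residues):
        if any(b not in NUCLEOTIDES for b in codon) or code.is_stop(codon):
            continue
        aa = code.amino_acid(codon)
        if restrict is None or aa in restrict:
            ga1_n += 1
            if codon[0] in GA:
                ga1_hits += 1
        if code.is_fourfold(codon):
            ga4_n += 1
            if codon[2] in GA:
                ga4_hits += 1
    ga1 = ga1_hits / ga1_n if ga1_n else None
    ga4f = ga4_hits / ga4_n if ga4_n else None
    return ga1, ga4f


def protein_charge(protein_residues: str, ph: float,
                   pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Net charge at a given pH by Henderson-Hasselbalch over ionizable groups."""
    residues = [r for r in protein_residues if r not in "-X"]
    if not residues:
        raise SequenceError("empty protein")
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _POSITIVE:
        charge += residues.count(aa) / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        charge -= residues.count(aa) / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def acidic_stats(
    protein: Sequence,
    pka: Mapping[str, float] = EMBOSS_PKA,
    tol: float = 1e-4,
) -> tuple[int, float, float]:
    """(acidic D+E count, net charge at pH 7, theoretical pI).

    The pI is located by bisection on the monotone charge-vs-pH curve until
    the absolute net charge falls below ``tol``.
    """
    if protein.kind != "protein":
        raise SequenceError("acidic_stats expects a protein sequence")
    residues = protein.ungapped()
    if not residues:
        raise SequenceError(f"sequence {protein.id!r}: empty protein")
    acidic_count = sum(residues.count(a) for a in ACIDIC_RESIDUES)
    charge7 = protein_charge(residues, 7.0, pka)
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = protein_charge(residues, mid, pka)
        if abs(c) < tol:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    else:
        mid = (lo + hi) / 2.0
    return acidic_count, charge7, mid


def composition_report(
    cds: Sequence,
    code: GeneticCode | None = None,
) -> CompositionReport:
    """Full composition summary for one coding sequence."""
    code = code or GeneticCode.standard()
    from naspkit.seqio import translate  # local import avoids cycle at module load

    prot = translate(cds.with_residues(cds.residues.replace("---", "")), code)
    classes = aa_class_frequencies(prot)
    gc1, gc2, gc3 = gc_by_position(cds, code)
    gc4f = fourfold_gc(cds, code)
    ga1, ga4f = ga_first_vs_fourfold(cds, code)
    acidic_count, charge7, pi = acidic_stats(prot)
    usage = codon_usage(cds, code)
    try:
        enc_value: float | None = enc(usage).enc
    except ValueError:
        enc_value = None
    residues = prot.ungapped()
    n = len(residues)
    return CompositionReport(
        seq_id=cds.id,
        aa_frequencies={aa: residues.count(aa) / n for aa in set(residues)},
        gapw=classes["GAPW"],
        fymink=classes["FYMINK"],
        alanine=classes["A"],
        lysine=classes["K"],
        acidic_count=acidic_count,
        net_charge_ph7=charge7,
        theoretical_pi=pi,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc4f=gc4f,
        ga1=ga1,
        ga4f=ga4f,
        enc=enc_value,
    )
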