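"""Sequence I/O, genetic codes, codon alignments and the complete-deletion filter.

Coding sequences and their protein translations are the raw material of every
downstream statistic.  Alignments of coding sequences are represented as
:class:`CodonAlignment` objects built by threading each CDS onto its aligned
protein (`back_translate_alignment`), which guarantees the reading frame is
preserved through alignment gaps.  Distance and selection statistics assume
`complete_deletion` has removed every column touched by a gap or ambiguity.

Coordinates are 1-based inclusive throughout (alignment residue/codon columns),
matching the conventions of the comparative literature on TPR proteins.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
NT_ALPHABET = frozenset("ACGTN-")
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_ALPHABET = frozenset(AA20 + "X-")
GAP_CODON = "---"

REGION_LABELS = ("TPR1", "TPR2", "TPR3", "TPR4", "ACIDIC", "NTERM", "CTERM", "LINKER")


class SequenceError(ValueError):
    """Invalid sequence content or identifier."""


class TranslationError(ValueError):
    """Codon-level translation failure (internal stop, frame, ambiguity)."""


class AlignmentError(ValueError):
    """Inconsistent alignment (lengths, frames, empty after filtering)."""


@dataclasses.dataclass(frozen=True)
class Sequence:
    """A single named nucleotide or protein sequence.

    ``residues`` is upper-case text over the declared alphabet; ``kind`` is
    ``"nucleotide"`` or ``"protein"``.  ``description`` keeps the full FASTA
    header (the id is the token before the first whitespace).
    """

    id: str
    residues: str
    kind: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: residues must be non-empty")
        if self.kind not in ("nucleotide", "protein"):
            raise SequenceError(f"sequence {self.id!r}: unknown kind {self.kind!r}")
        alphabet = NT_ALPHABET if self.kind == "nucleotide" else AA_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise SequenceError(
                f"sequence {self.id!r}: characters {sorted(bad)} outside the "
                f"{self.kind} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def with_residues(self, residues: str) -> "Sequence":
        return dataclasses.replace(self, residues=residues)


class SequenceSet:
    """An ordered collection of same-kind sequences with unique ids."""

    def __init__(self, sequences: Iterable[Sequence]):
        self._seqs: list[Sequence] = []
        self._index: dict[str, int] = {}
        for seq in sequences:
            self.append(seq)
        if not self._seqs:
            raise SequenceError("SequenceSet must contain at least one sequence")

    def append(self, seq: Sequence) -> None:
        if self._seqs and seq.kind != self.kind:
            raise SequenceError(
                f"mixed kinds: set is {self.kind}, sequence {seq.id!r} is {seq.kind}"
            )
        if seq.id in self._index:
            raise SequenceError(f"duplicate sequence id {seq.id!r}")
        self._index[seq.id] = len(self._seqs)
        self._seqs.append(seq)

    @property
    def kind(self) -> str:
        return self._seqs[0].kind

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self._seqs]

    def is_aligned(self) -> bool:
        return len({len(s) for s in self._seqs}) == 1

    @property
    def alignment_length(self) -> int:
        if not self.is_aligned():
            raise AlignmentError("sequences have unequal lengths")
        return len(self._seqs[0])

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self._seqs)

    def __getitem__(self, key: int | str) -> Sequence:
        if isinstance(key, str):
            try:
                return self._seqs[self._index[key]]
            except KeyError:
                raise KeyError(f"no sequence with id {key!r}") from None
        return self._seqs[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def map_residues(self, fn) -> "SequenceSet":
        return SequenceSet(s.with_residues(fn(s.residues)) for s in self._seqs)


class GeneticCode:
    """A codon -> amino-acid table (NCBI numbering), including stop codons.

    Table 1 is the standard code; table 6 is the ciliate/dasycladacean nuclear
    code in which TAA and TAG encode glutamine -- required because the family
    under study spans ciliates such as *Tetrahymena thermophila*.
    """

    def __init__(self, table_id: int):
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError:
            raise ValueError(f"unknown genetic-code table id {table_id}") from None
        self.table_id = table_id
        self.name = table.names[0]
        self.forward: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.forward[stop] = "*"
        if len(self.forward) != 64:
            raise ValueError(f"table {table_id} does not map all 64 codons")
        self.stop_codons = frozenset(table.stop_codons)
        self.sense_codons = tuple(
            c for c in sorted(self.forward) if c not in self.stop_codons
        )

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls(1)

    @classmethod
    def ciliate(cls) -> "GeneticCode":
        return cls(6)

    def amino_acid(self, codon: str) -> str:
        """Amino acid for an unambiguous codon; '*' for stop."""
        try:
            return self.forward[codon]
        except KeyError:
            raise TranslationError(f"ambiguous or invalid codon {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid -> its sense codons, from this table."""
        fams: dict[str, list[str]] = {}
        for codon in self.sense_codons:
            fams.setdefault(self.forward[codon], []).append(codon)
        return {aa: tuple(codons) for aa, codons in fams.items()}

    def is_fourfold(self, codon: str) -> bool:
        """True if every third-position variant of the codon encodes the same residue."""
        if self.is_stop(codon):
            return False
        aa = self.forward[codon]
        return all(self.forward[codon[:2] + b] == aa for b in NUCLEOTIDES)

    def __repr__(self) -> str:
        return f"GeneticCode(table_id={self.table_id}, name={self.name!r})"


def read_fasta(path: str | Path, kind: str) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` of the given kind."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise SequenceError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise SequenceError(f"{path}: empty FASTA file")
    seqs = []
    for record in SeqIO.parse(str(path), "fasta"):
        seqs.append(
            Sequence(
                id=record.id,
                residues=str(record.seq).upper(),
                kind=kind,
                description=record.description,
            )
        )
    if not seqs:
        raise SequenceError(f"{path}: no FASTA records found")
    try:
        return SequenceSet(seqs)
    except SequenceError as exc:
        raise SequenceError(f"{path}: {exc}") from None


def write_fasta(seqs: SequenceSet | Iterable[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def iter_codons(residues: str) -> Iterator[str]:
    if len(residues) % 3:
        raise TranslationError(
            f"sequence length {len(residues)} is not a multiple of 3"
        )
    for i in range(0, len(residues), 3):
        yield residues[i : i + 3]


def translate(cds: Sequence, code: GeneticCode | None = None) -> Sequence:
    """Translate an in-frame CDS; gap triplets map to '-'.

    A terminal stop codon is dropped; an internal stop raises
    :class:`TranslationError` naming the codon index (1-based).
    """
    code = code or GeneticCode.standard()
    if cds.kind != "nucleotide":
        raise TranslationError("translate expects a nucleotide sequence")
    codons = list(iter_codons(cds.residues))
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    if not codons:
        raise TranslationError(f"sequence {cds.id!r}: nothing to translate")
    out = []
    for i, codon in enumerate(codons, start=1):
        if codon == GAP_CODON:
            out.append("-")
            continue
        if "-" in codon:
            raise TranslationError(
                f"sequence {cds.id!r}: partial gap in codon {i} ({codon!r})"
            )
        if "N" in codon:
            raise TranslationError(
                f"sequence {cds.id!r}: ambiguous base in codon {i} ({codon!r})"
            )
        aa = code.amino_acid(codon)
        if aa == "*":
            raise TranslationError(
                f"sequence {cds.id!r}: internal stop codon at codon {i} ({codon!r})"
            )
        out.append(aa)
    return Sequence(id=cds.id, residues="".join(out), kind="protein",
                    description=cds.description)


class CodonAlignment:
    """An in-frame nucleotide alignment whose gaps are whole codons.

    Translating any row (gaps ignored) yields no internal stop, so every
    codon column is comparable across rows under the attached genetic code.
    """

    def __init__(self, rows: SequenceSet, genetic_code: GeneticCode | None = None):
        if rows.kind != "nucleotide":
            raise AlignmentError("CodonAlignment rows must be nucleotide sequences")
        if not rows.is_aligned():
            raise AlignmentError("CodonAlignment rows must have equal lengths")
        if rows.alignment_length % 3:
            raise AlignmentError(
                f"aligned length {rows.alignment_length} is not a multiple of 3"
            )
        code = genetic_code or GeneticCode.standard()
        n_codons = rows.alignment_length // 3
        for seq in rows:
            codons = list(iter_codons(seq.residues))
            for i, codon in enumerate(codons, start=1):
                if "-" in codon and codon != GAP_CODON:
                    raise AlignmentError(
                        f"row {seq.id!r}: partial gap codon {codon!r} at codon column {i}"
                    )
                # ambiguous codons are tolerated here (complete deletion
                # removes them); unambiguous internal stops are not
                if (i < n_codons and "N" not in codon and codon != GAP_CODON
                        and code.is_stop(codon)):
                    raise TranslationError(
                        f"row {seq.id!r}: internal stop codon at codon column {i}"
                    )
        self.rows = rows
        self.genetic_code = code

    @property
    def n_codons(self) -> int:
        return self.rows.alignment_length // 3

    @property
    def ids(self) -> list[str]:
        return self.rows.ids

    def __len__(self) -> int:
        return len(self.rows)

    def codon(self, row: int | str, column: int) -> str:
        """Codon at 1-based codon column ``column`` of a row."""
        seq = self.rows[row]
        return seq.residues[3 * (column - 1) : 3 * column]

    def codon_columns(self) -> Iterator[tuple[str, ...]]:
        for j in range(1, self.n_codons + 1):
            yield tuple(self.codon(i, j) for i in range(len(self.rows)))

    def translate_rows(self) -> SequenceSet:
        return SequenceSet(translate(s, self.genetic_code) for s in self.rows)

    def subset_columns(self, columns: Iterable[int]) -> "CodonAlignment":
        """New alignment keeping the given 1-based codon columns, in order."""
        cols = list(columns)
        if not cols:
            raise AlignmentError("cannot build an alignment with zero codon columns")
        rows = SequenceSet(
            s.with_residues(
                "".join(s.residues[3 * (c - 1) : 3 * c] for c in cols)
            )
            for s in self.rows
        )
        return CodonAlignment(rows, self.genetic_code)

    def region_slice(self, start: int, end: int) -> "CodonAlignment":
        """Sub-alignment over codon columns start..end (1-based inclusive)."""
        return self.subset_columns(range(start, end + 1))


class RegionMap:
    """Named 1-based inclusive intervals over alignment residue/codon columns.

    Labels are unique; standard labels are TPR1-4 (34 columns each by
    convention), ACIDIC, NTERM, CTERM and LINKER, but arbitrary labels are
    accepted.
    """

    def __init__(self, intervals: Mapping[str, tuple[int, int]]):
        self._intervals: dict[str, tuple[int, int]] = {}
        for label, (start, end) in intervals.items():
            if not label:
                raise ValueError("region label must be non-empty")
            if label in self._intervals:
                raise ValueError(f"duplicate region label {label!r}")
            if start < 1 or end < start:
                raise ValueError(
                    f"region {label!r}: invalid interval [{start}, {end}]"
                )
            self._intervals[label] = (int(start), int(end))
        if not self._intervals:
            raise ValueError("RegionMap must contain at least one region")

    @property
    def labels(self) -> list[str]:
        return list(self._intervals)

    def __getitem__(self, label: str) -> tuple[int, int]:
        return self._intervals[label]

    def __contains__(self, label: str) -> bool:
        return label in self._intervals

    def __iter__(self):
        return iter(self._intervals.items())

    def __len__(self) -> int:
        return len(self._intervals)

    def length(self, label: str) -> int:
        start, end = self._intervals[label]
        return end - start + 1

    def validate_against(self, n_columns: int) -> None:
        for label, (start, end) in self._intervals.items():
            if end > n_columns:
                raise ValueError(
                    f"region {label!r} [{start}, {end}] exceeds alignment "
                    f"length {n_columns}"
                )

    def complement(self, n_columns: int) -> list[int]:
        """1-based columns covered by no region (the 'remainder')."""
        covered = set()
        for _, (start, end) in self._intervals.items():
            covered.update(range(start, end + 1))
        return [c for c in range(1, n_columns + 1) if c not in covered]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMap":
        intervals: dict[str, tuple[int, int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 3 tab-separated fields "
                        f"(label, start, end)"
                    )
                label, start, end = parts
                if label in intervals:
                    raise ValueError(f"{path}: line {lineno}: duplicate label {label!r}")
                intervals[label] = (int(start), int(end))
        return cls(intervals)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# label\tstart\tend (1-based inclusive residue columns)\n")
            for label, (start, end) in self._intervals.items():
                fh.write(f"{label}\t{start}\t{end}\n")


def back_translate_alignment(
    protein_alignment: SequenceSet,
    cds_set: SequenceSet,
    code: GeneticCode | None = None,
) -> CodonAlignment:
    """Thread each CDS onto its aligned protein, expanding gaps to '---'.

    Every aligned protein row must, after removing gaps, equal the translation
    of the same-id CDS (terminal stop codons on the CDS are tolerated).
    """
    code = code or GeneticCode.standard()
    if protein_alignment.kind != "protein":
        raise AlignmentError("protein_alignment must contain protein sequences")
    if not protein_alignment.is_aligned():
        raise AlignmentError("protein rows have unequal aligned lengths")
    rows = []
    for prot in protein_alignment:
        if prot.id not in cds_set:
            raise AlignmentError(f"no CDS provided for protein row {prot.id!r}")
        cds = cds_set[prot.id]
        codons = list(iter_codons(cds.residues))
        if codons and code.is_stop(codons[-1]):
            codons = codons[:-1]
        translated = translate(cds, code).residues
        ungapped = prot.ungapped()
        if translated != ungapped:
            n = min(len(translated), len(ungapped))
            pos = next(
                (k + 1 for k in range(n) if translated[k] != ungapped[k]), n + 1
            )
            raise AlignmentError(
                f"row {prot.id!r}: CDS translation disagrees with the aligned "
                f"protein at residue {pos}"
            )
        out, k = [], 0
        for aa in prot.residues:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(codons[k])
                k += 1
        rows.append(Sequence(id=prot.id, residues="".join(out), kind="nucleotide",
                             description=prot.description))
    return CodonAlignment(SequenceSet(rows), code)


def complete_deletion(aln: CodonAlignment | SequenceSet):
    """Drop every column containing a gap or ambiguity character in any row.

    For a :class:`CodonAlignment` whole codon columns are dropped when any row
    carries '-' or 'N' in that codon; for a protein :class:`SequenceSet`,
    residue columns with '-' or 'X'.  Ambiguities are treated like gaps,
    following MEGA's complete-deletion semantics.  Idempotent.
    """
    if isinstance(aln, CodonAlignment):
        keep = []
        for j in range(1, aln.n_codons + 1):
            column = (aln.codon(i, j) for i in range(len(aln)))
            if all("-" not in c and "N" not in c for c in column):
                keep.append(j)
        if not keep:
            raise AlignmentError("complete deletion removed every codon column")
        return aln.subset_columns(keep)
    if not isinstance(aln, SequenceSet):
        raise TypeError("complete_deletion expects a CodonAlignment or SequenceSet")
    if not aln.is_aligned():
        raise AlignmentError("complete deletion requires an aligned input")
    bad_chars = "-X" if aln.kind == "protein" else "-N"
    length = aln.alignment_length
    rows = [s.residues for s in aln]
    keep_idx = [
        j for j in range(length)
        if all(r[j] not in bad_chars for r in rows)
    ]
    if not keep_idx:
        raise AlignmentError("complete deletion removed every column")
    return aln.map_residues(lambda r: "".join(r[j] for j in keep_idx))
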