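"""Motif and region analyses: NNR scanning, conservation profiles, acidic tracts.

The NNR (NASP N-terminal Region) motif characteristic of fish NASP2 paralogs
is the 14-residue pattern S-X(5)-E-E-X-P-C-S-S-(S/T), where X is any amino
acid.  Acidic tracts -- the D/E-rich stretches that interrupt TPR2 in most
family members -- are located as maximal windows satisfying a length and
D+E-fraction threshold.
"""

from __future__ import annotations

import dataclasses
import re
from collections import Counter

from naspkit.seqio import RegionMap, Sequence, SequenceSet

NNR_PATTERN = "S-X(5)-E-E-X-P-C-S-S-(S/T)"
NNR_LENGTH = 14
_NNR_RE = re.compile(r"(?=(S.{5}EE.PCSS[ST]))")

#: Residue property classes (ClustalX-style coloring, fixed here).
RESIDUE_CLASSES = {
    "hydrophobic": frozenset("AVLIMFWC"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
}
RESIDUE_CLASSES["polar"] = frozenset("ACDEFGHIKLMNPQRSTVWY") - (
    RESIDUE_CLASSES["hydrophobic"] | RESIDUE_CLASSES["acidic"] | RESIDUE_CLASSES["basic"]
)


@dataclasses.dataclass
class MotifHit:
    seq_id: str
    start: int  # 1-based ungapped residue position
    span: str


def scan_nnr(protein: Sequence) -> list[MotifHit]:
    """All (possibly overlapping) NNR motif matches in a protein.

    Gaps are removed before scanning, so positions refer to the ungapped
    sequence of each row.
    """
    if protein.kind != "protein":
        raise ValueError("scan_nnr expects a protein sequence")
    residues = protein.ungapped()
    return [
        MotifHit(protein.id, m.start() + 1, m.group(1))
        for m in _NNR_RE.finditer(residues)
    ]


@dataclasses.dataclass
class ProfileColumn:
    column: int  # 1-based index within the region
    consensus: str
    identity: float
    class_fractions: dict[str, float]


@dataclasses.dataclass
class ConservationProfile:
    label: str
    columns: list[ProfileColumn]

    def __len__(self) -> int:
        return len(self.columns)


def conservation_profile(
    aln: SequenceSet, region: tuple[str, tuple[int, int]] | None = None
) -> ConservationProfile:
    """Per-column consensus, identity and property-class fractions.

    ``region`` is a (label, (start, end)) entry of a :class:`RegionMap`
    in 1-based inclusive alignment columns; by default the whole alignment is
    profiled.  Gap characters are excluded from the denominators; the modal
    residue breaks ties alphabetically.
    """
    if aln.kind != "protein":
        raise ValueError("conservation_profile expects protein sequences")
    if not aln.is_aligned():
        raise ValueError("conservation_profile requires aligned sequences")
    length = aln.alignment_length
    if region is None:
        label, (start, end) = "ALL", (1, length)
    else:
        label, (start, end) = region
    if start < 1 or end > length:
        raise ValueError(f"region {label!r} [{start}, {end}] outside alignment")
    rows = [s.residues for s in aln]
    columns = []
    for idx, col in enumerate(range(start - 1, end), start=1):
        residues = [r[col] for r in rows if r[col] not in "-X"]
        if not residues:
            columns.append(ProfileColumn(idx, "-", 0.0,
                                         {k: 0.0 for k in RESIDUE_CLASSES}))
            continue
        counts = Counter(residues)
        top = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        consensus = min(aa for aa, k in counts.items() if k == top[1])
        identity = counts[consensus] / len(residues)
        fractions = {
            name: sum(counts[aa] for aa in members) / len(residues)
            for name, members in RESIDUE_CLASSES.items()
        }
        columns.append(ProfileColumn(idx, consensus, identity, fractions))
    return ConservationProfile(label, columns)


def find_acidic_tract(
    protein: Sequence, min_len: int = 10, min_de_frac: float = 0.5
) -> list[tuple[int, int]]:
    """Maximal intervals of length >= min_len with D+E fraction >= min_de_frac.

    Every window of length ``min_len`` meeting the threshold is marked and
    overlapping or adjacent windows are merged, so the returned 1-based
    inclusive intervals never overlap.  Defaults (10 residues, half acidic)
    capture even the shortest TPR2 interruptions seen in divergent family
    members.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not 0.0 < min_de_frac <= 1.0:
        raise ValueError("min_de_frac must be in (0, 1]")
    residues = protein.ungapped()
    n = len(residues)
    if n < min_len:
        return []
    is_acidic = [r in "DE" for r in residues]
    prefix = [0]
    for flag in is_acidic:
        prefix.append(prefix[-1] + flag)
    hits = [
        i for i in range(n - min_len + 1)
        if prefix[i + min_len] - prefix[i] >= min_de_frac * min_len
    ]
    if not hits:
        return []
    intervals: list[list[int]] = []
    for i in hits:
        start, end = i + 1, i + min_len  # 1-based inclusive
        if intervals and start <= intervals[-1][1] + 1:
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([start, end])
    return [(s, e) for s, e in intervals]
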