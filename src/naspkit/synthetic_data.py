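"""Codon-family simulator with the domain architecture of NASP-like proteins.

Generates coding-sequence families whose statistical structure matches the
assumptions of the analysis modules, with full ground truth: a root protein
with four 34-codon TPR blocks, a D/E-rich acidic tract interrupting the TPR2
neighbourhood, linkers and termini, and an optional N-terminal NNR motif
block; region-specific dN/dS (omega); transition/transversion bias (kappa,
per-change rate ratio); and per-lineage third-position GC targets.

The substitution process is a continuous-time single-nucleotide codon model
simulated exactly (Gillespie): the rate of each of the nine single-base
changes of a codon is proportional to kappa for transitions and 1 for
transversions, multiplied by omega for non-synonymous changes, and by a GC
acceptance factor 2g (toward G/C) or 2(1-g) (toward A/T) at third positions
(at all positions in ``mutation-bias`` mode, which also forces omega = 1 so
amino-acid composition drifts with the mutational bias).  Changes creating a
stop codon have rate zero, so no simulated sequence ever contains an internal
stop.  Rates are normalised so that a branch length of 1 corresponds to one
expected substitution per codon site for an unconstrained site.

No indel process is simulated: sequences are born aligned, which keeps
alignment error out of every parameter-recovery test.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from naspkit.seqio import (
    CodonAlignment,
    GeneticCode,
    NUCLEOTIDES,
    RegionMap,
    Sequence,
    SequenceSet,
    write_fasta,
)
from naspkit.trees import read_newick
from skbio import TreeNode

#: Default region lengths (codons).  TPR blocks are 34 codons, the canonical
#: TPR repeat length; the acidic tract sits between the TPR2 block and TPR3,
#: modelling the interruption of TPR2.
DEFAULT_ARCHITECTURE = {
    "NTERM": 25,
    "TPR1": 34,
    "LINKER": 8,
    "TPR2": 34,
    "ACIDIC": 20,
    "TPR3": 34,
    "TPR4": 34,
    "CTERM": 25,
}

#: Region-specific dN/dS defaults: TPR2/TPR3 under the strongest purifying
#: selection, TPR1/TPR4 faster, termini and linkers fastest.
DEFAULT_OMEGA_BY_REGION = {
    "TPR1": 0.3,
    "TPR2": 0.1,
    "TPR3": 0.1,
    "TPR4": 0.3,
    "ACIDIC": 0.15,
}

#: Protein segment realising the NNR pattern S-X(5)-E-E-X-P-C-S-S-(S/T).
NNR_PROTEIN = "SAKDLQEEVPCSST"

#: dN/dS ceiling applied to the NNR block when present: the motif is modelled
#: as a conserved functional unit of the paralog that carries it.
NNR_OMEGA = 0.02

HYDROPHOBIC = "AVLIMFWC"
_AA_POOL = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass
class Architecture:
    """Root protein scaffold plus the region map describing it."""

    scaffold: str  # root amino-acid sequence
    regions: RegionMap
    acidic_sites: tuple[int, ...]  # 1-based codon columns restricted to D/E
    nnr_span: tuple[int, int] | None  # 1-based codon columns of the NNR block

    @property
    def n_codons(self) -> int:
        return len(self.scaffold)


@dataclasses.dataclass
class SimulationParams:
    """Ground-truth parameters of one simulated family.

    ``tree`` is a newick string with branch lengths in expected substitutions
    per codon site; alternatively the star-tree shortcut (``n_leaves`` leaves
    at distance ``radius`` from the root) is used.  ``gc3_target`` is either a
    global fraction or a per-leaf mapping; ``mode`` selects purifying-type
    evolution (``selection``) or neutral GC-driven evolution
    (``mutation-bias``).
    """

    seed: int = 0
    tree: str | None = None
    n_leaves: int = 12
    radius: float = 0.3
    kappa: float = 2.0
    omega: float = 0.5
    omega_by_region: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_OMEGA_BY_REGION)
    )
    gc3_target: float | Mapping[str, float] = 0.5
    mode: str = "selection"
    acidic_de_frac: float = 0.7

    def __post_init__(self) -> None:
        if self.mode not in ("selection", "mutation-bias"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        targets = (
            [self.gc3_target]
            if isinstance(self.gc3_target, (int, float))
            else list(self.gc3_target.values())
        )
        for g in targets:
            if not 0.0 < g < 1.0:
                raise ValueError("gc3_target must lie strictly inside (0, 1)")
        omegas = [self.omega] + list(self.omega_by_region.values())
        if any(w < 0 for w in omegas):
            raise ValueError("omega must be non-negative")


@dataclasses.dataclass
class SimulatedFamily:
    """A simulated CDS family plus its generating truth."""

    cds: SequenceSet
    alignment: CodonAlignment
    regions: RegionMap
    params: SimulationParams
    architecture: Architecture
    region_events: dict[str, dict[str, int]]  # region -> {'syn': n, 'nonsyn': n}
    leaf_gc3: dict[str, float]
    paralog_of: dict[str, str] | None = None  # leaf id -> '1' | '2'

    def save(self, outdir: str | Path) -> None:
        """Write CDS FASTA, region-map TSV and a truth JSON to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.cds, outdir / "family.fasta")
        self.regions.to_tsv(outdir / "regions.tsv")
        truth = {
            "seed": self.params.seed,
            "kappa": self.params.kappa,
            "omega": self.params.omega,
            "omega_by_region": dict(self.params.omega_by_region),
            "mode": self.params.mode,
            "gc3_target": (
                self.params.gc3_target
                if isinstance(self.params.gc3_target, (int, float))
                else dict(self.params.gc3_target)
            ),
            "n_leaves": len(self.cds),
            "n_codons": self.alignment.n_codons,
            "region_events": self.region_events,
            "leaf_gc3": self.leaf_gc3,
            "paralog_of": self.paralog_of,
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def make_architecture(
    region_lengths: Mapping[str, int] | None = None,
    nnr: bool = False,
    seed: int = 0,
    acidic_de_frac: float = 0.7,
) -> Architecture:
    """Build a root protein scaffold and its region map.

    Regions appear in the order given (default: NTERM, TPR1, LINKER, TPR2,
    ACIDIC, TPR3, TPR4, CTERM).  TPR blocks are enriched for hydrophobic
    residues; the acidic tract has a D/E codon fraction of at least
    ``acidic_de_frac`` by construction (those sites stay restricted to D/E in
    selection-mode simulations).  With ``nnr=True`` the NNR motif block is
    embedded near the start of NTERM.
    """
    lengths = dict(region_lengths or DEFAULT_ARCHITECTURE)
    for label, ln in lengths.items():
        if ln < 1:
            raise ValueError(f"region {label!r} has non-positive length {ln}")
    if nnr and lengths.get("NTERM", 0) < len(NNR_PROTEIN) + 2:
        raise ValueError(
            f"NTERM must span at least {len(NNR_PROTEIN) + 2} codons to host the NNR block"
        )
    rng = np.random.default_rng(seed)
    intervals: dict[str, tuple[int, int]] = {}
    scaffold: list[str] = []
    acidic_sites: list[int] = []
    nnr_span: tuple[int, int] | None = None
    pos = 1
    for label, ln in lengths.items():
        intervals[label] = (pos, pos + ln - 1)
        if label.startswith("TPR"):
            block = rng.choice(list(HYDROPHOBIC), size=ln).tolist()
            loose = rng.random(ln) < 0.5  # half the positions are generic
            generic = rng.choice(list(_AA_POOL), size=ln)
            residues = [g if f else b for b, f, g in zip(block, loose, generic)]
        elif label == "ACIDIC":
            n_de = int(np.ceil(acidic_de_frac * ln))
            de_local = rng.choice(ln, size=n_de, replace=False)
            residues = rng.choice(list(_AA_POOL), size=ln).tolist()
            for i in sorted(de_local):
                residues[i] = rng.choice(["D", "E"])
                acidic_sites.append(pos + int(i))
        else:
            residues = rng.choice(list(_AA_POOL), size=ln).tolist()
        if label == "NTERM" and nnr:
            start_local = 1  # motif begins at residue 2 of NTERM
            for k, aa in enumerate(NNR_PROTEIN):
                residues[start_local + k] = aa
            nnr_span = (pos + start_local, pos + start_local + len(NNR_PROTEIN) - 1)
        scaffold.extend(residues)
        pos += ln
    return Architecture(
        scaffold="".join(scaffold),
        regions=RegionMap(intervals),
        acidic_sites=tuple(acidic_sites),
        nnr_span=nnr_span,
    )


def calibrate_gc3_bias(scaffold: str, target: float) -> float:
    """Internal third-position G/C acceptance bias hitting a realized GC3 target.

    At stationarity, every synonymous family whose third position offers a
    balanced G/C vs A/T choice settles at GC fraction g, but Met and Trp are
    fixed at G and the three-codon Ile family equilibrates at g/(2-g); the
    realized whole-sequence GC3 is therefore

        GC3(g) = f_MW + f_I * g / (2 - g) + (1 - f_MW - f_I) * g,

    with f_MW and f_I the Met+Trp and Ile fractions of the (selection-mode)
    amino-acid composition.  This solves GC3(g) = target by bisection on the
    monotone curve; unreachable targets clamp to the admissible boundary.
    """
    n = len(scaffold)
    f_mw = (scaffold.count("M") + scaffold.count("W")) / n
    f_i = scaffold.count("I") / n

    def realized(g: float) -> float:
        return f_mw + f_i * g / (2.0 - g) + (1.0 - f_mw - f_i) * g

    lo, hi = 1e-3, 1.0 - 1e-3
    if target <= realized(lo):
        return lo
    if target >= realized(hi):
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# codon mutation tables (built once per genetic code)


class _CodonTables:
    def __init__(self, code: GeneticCode):
        self.code = code
        self.codons = ["".join((a, b, c)) for a in NUCLEOTIDES
                       for b in NUCLEOTIDES for c in NUCLEOTIDES]
        self.index = {c: i for i, c in enumerate(self.codons)}
        n = 64
        self.target = np.zeros((n, 9), dtype=np.int64)
        self.is_ts = np.zeros((n, 9), dtype=bool)
        self.is_syn = np.zeros((n, 9), dtype=bool)
        self.is_stop = np.zeros((n, 9), dtype=bool)
        self.pos = np.zeros((n, 9), dtype=np.int64)
        self.new_is_gc = np.zeros((n, 9), dtype=bool)
        self.target_is_de = np.zeros((n, 9), dtype=bool)
        self.codon_is_stop = np.array([code.is_stop(c) for c in self.codons])
        transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
        for i, codon in enumerate(self.codons):
            m = 0
            for p in range(3):
                for b in NUCLEOTIDES:
                    if b == codon[p]:
                        continue
                    tgt = codon[:p] + b + codon[p + 1 :]
                    self.target[i, m] = self.index[tgt]
                    self.is_ts[i, m] = transitions[codon[p]] == b
                    self.pos[i, m] = p
                    self.new_is_gc[i, m] = b in "GC"
                    stop = code.is_stop(tgt)
                    self.is_stop[i, m] = stop
                    if not stop and not code.is_stop(codon):
                        aa_t = code.amino_acid(tgt)
                        self.is_syn[i, m] = aa_t == code.amino_acid(codon)
                        self.target_is_de[i, m] = aa_t in "DE"
                    m += 1


_TABLES: dict[int, _CodonTables] = {}


def _tables(code: GeneticCode) -> _CodonTables:
    if code.table_id not in _TABLES:
        _TABLES[code.table_id] = _CodonTables(code)
    return _TABLES[code.table_id]


def _mutation_weights(
    codon_idx: np.ndarray,
    tables: _CodonTables,
    kappa: float,
    omega_sites: np.ndarray,
    g: float,
    mode: str,
    de_only: np.ndarray,
) -> np.ndarray:
    """(L, 9) rate matrix for the current sequence."""
    t = tables
    ts = t.is_ts[codon_idx]
    syn = t.is_syn[codon_idx]
    stop = t.is_stop[codon_idx]
    pos = t.pos[codon_idx]
    gc = t.new_is_gc[codon_idx]
    w = np.where(ts, kappa, 1.0) / (3.0 * (kappa + 2.0))
    if mode == "mutation-bias":
        w = w * np.where(gc, 2.0 * g, 2.0 * (1.0 - g))
        # neutral at the protein level: omega == 1
    else:
        third = pos == 2
        w = w * np.where(third & gc, 2.0 * g, 1.0)
        w = np.where(third & ~gc, w * 2.0 * (1.0 - g), w)
        w = np.where(syn, w, w * omega_sites[:, None])
        allowed = syn | t.target_is_de[codon_idx]
        w = np.where(de_only[:, None] & ~allowed, 0.0, w)
    return np.where(stop, 0.0, w)


def _evolve_branch(
    codon_idx: np.ndarray,
    branch_len: float,
    tables: _CodonTables,
    kappa: float,
    omega_sites: np.ndarray,
    g: float,
    mode: str,
    de_only: np.ndarray,
    rng: np.random.Generator,
    site_region: list[str],
    events: dict[str, dict[str, int]],
) -> np.ndarray:
    """Gillespie simulation of one branch; returns the new codon-index array."""
    seq = codon_idx.copy()
    if branch_len <= 0:
        return seq
    w = _mutation_weights(seq, tables, kappa, omega_sites, g, mode, de_only)
    site_rates = w.sum(axis=1)
    total = float(site_rates.sum())
    t = 0.0
    while total > 0:
        t += rng.exponential(1.0 / total)
        if t >= branch_len:
            break
        cum = np.cumsum(site_rates)
        u = rng.random() * cum[-1]
        site = int(np.searchsorted(cum, u, side="right"))
        row = w[site]
        mcum = np.cumsum(row)
        mu = rng.random() * mcum[-1]
        m = int(np.searchsorted(mcum, mu, side="right"))
        syn = bool(tables.is_syn[seq[site], m])
        seq[site] = tables.target[seq[site], m]
        label = site_region[site]
        bucket = events.setdefault(label, {"syn": 0, "nonsyn": 0})
        bucket["syn" if syn else "nonsyn"] += 1
        w[site] = _mutation_weights(
            seq[site : site + 1], tables, kappa,
            omega_sites[site : site + 1], g, mode, de_only[site : site + 1]
        )[0]
        old = site_rates[site]
        site_rates[site] = w[site].sum()
        total += float(site_rates[site] - old)
    return seq


def _root_codons(
    scaffold: str,
    code: GeneticCode,
    g: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Root codon indices: synonymous choice weighted by the GC3 target."""
    tables = _tables(code)
    families = code.families()
    out = np.zeros(len(scaffold), dtype=np.int64)
    for i, aa in enumerate(scaffold):
        codons = families[aa]
        weights = np.array(
            [g if c[2] in "GC" else (1.0 - g) for c in codons]
        )
        weights = weights / weights.sum()
        out[i] = tables.index[codons[rng.choice(len(codons), p=weights)]]
    return out


def _site_labels(regions: RegionMap, n_codons: int) -> list[str]:
    labels = ["UNASSIGNED"] * n_codons
    for label, (start, end) in regions:
        for c in range(start, end + 1):
            labels[c - 1] = label
    return labels


def _omega_sites(
    arch: Architecture, params: SimulationParams
) -> np.ndarray:
    omega = np.full(arch.n_codons, float(params.omega))
    for label, w in params.omega_by_region.items():
        if label in arch.regions:
            start, end = arch.regions[label]
            omega[start - 1 : end] = float(w)
    if arch.nnr_span is not None:
        # the NNR motif block is treated as a conserved functional unit
        lo, hi = arch.nnr_span
        omega[lo - 1 : hi] = np.minimum(omega[lo - 1 : hi], NNR_OMEGA)
    return omega


def _build_tree(params: SimulationParams) -> TreeNode:
    if params.tree is not None:
        tree = read_newick(params.tree)
        for node in tree.postorder(include_self=False):
            if node.length is None:
                raise ValueError("every branch of the simulation tree needs a length")
            if node.length < 0:
                raise ValueError("negative branch length in simulation tree")
        return tree
    if params.n_leaves < 2:
        raise ValueError("star-tree shortcut needs at least 2 leaves")
    root = TreeNode()
    width = max(2, len(str(params.n_leaves)))
    for i in range(1, params.n_leaves + 1):
        leaf = TreeNode(name=f"L{i:0{width}d}")
        leaf.length = params.radius
        root.append(leaf)
    return root


def _leaf_gc(params: SimulationParams, leaf_names: list[str]) -> dict[str, float]:
    if isinstance(params.gc3_target, (int, float)):
        return {name: float(params.gc3_target) for name in leaf_names}
    missing = [n for n in leaf_names if n not in params.gc3_target]
    if missing:
        raise ValueError(f"gc3_target missing leaves: {missing}")
    return {n: float(params.gc3_target[n]) for n in leaf_names}


def simulate_family(
    params: SimulationParams,
    architecture: Architecture | None = None,
    code: GeneticCode | None = None,
) -> SimulatedFamily:
    """Simulate a codon family along a tree with region-specific selection.

    The branch to each leaf uses that leaf's GC3 target; internal branches
    use the mean target of their descendant leaves.  Identical seeds yield
    byte-identical families.
    """
    code = code or GeneticCode.standard()
    arch = architecture or make_architecture(seed=params.seed)
    tables = _tables(code)
    rng = np.random.default_rng(params.seed)
    tree = _build_tree(params)
    leaf_names = [t.name for t in tree.tips()]
    leaf_gc = _leaf_gc(params, leaf_names)
    omega_sites = _omega_sites(arch, params)
    de_only = np.zeros(arch.n_codons, dtype=bool)
    if params.mode == "selection":
        for c in arch.acidic_sites:
            de_only[c - 1] = True
    site_region = _site_labels(arch.regions, arch.n_codons)
    events: dict[str, dict[str, int]] = {}
    if params.mode == "selection":
        eff_gc = {k: calibrate_gc3_bias(arch.scaffold, v) for k, v in leaf_gc.items()}
    else:
        eff_gc = dict(leaf_gc)
    root_g = float(np.mean(list(eff_gc.values())))
    root_seq = _root_codons(arch.scaffold, code, root_g, rng)

    leaves: dict[str, np.ndarray] = {}

    def branch_g(node: TreeNode) -> float:
        names = [t.name for t in node.tips()] or [node.name]
        return float(np.mean([eff_gc[n] for n in names]))

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            g = branch_g(child)
            child_seq = _evolve_branch(
                seq, float(child.length), tables, params.kappa, omega_sites,
                g, params.mode, de_only, rng, site_region, events,
            )
            if child.is_tip():
                leaves[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    seqs = SequenceSet(
        Sequence(
            id=name,
            residues="".join(tables.codons[i] for i in leaves[name]),
            kind="nucleotide",
        )
        for name in leaf_names
    )
    aln = CodonAlignment(seqs, code)
    return SimulatedFamily(
        cds=seqs,
        alignment=aln,
        regions=arch.regions,
        params=params,
        architecture=arch,
        region_events=events,
        leaf_gc3=leaf_gc,
    )


def _resample_synonymous(
    seq: np.ndarray, code: GeneticCode, g: float, rng: np.random.Generator
) -> np.ndarray:
    """Re-equilibrate synonymous codon choice to a new GC3 target."""
    tables = _tables(code)
    families = code.families()
    out = seq.copy()
    for i, idx in enumerate(seq):
        aa = code.amino_acid(tables.codons[idx])
        codons = families[aa]
        weights = np.array([g if c[2] in "GC" else (1.0 - g) for c in codons])
        weights = weights / weights.sum()
        out[i] = tables.index[codons[rng.choice(len(codons), p=weights)]]
    return out


def simulate_duplication(
    params: SimulationParams,
    architecture: Architecture | None = None,
    duplication: str = "root",
    divergence_boost: float = 1.0,
    nnr_in_paralog2: bool = True,
    gc3_paralogs: tuple[float, float] | None = None,
    code: GeneticCode | None = None,
) -> SimulatedFamily:
    """Simulate a gene duplication: two paralog sets per species.

    The species tree (from ``params``) is duplicated at the named node
    (``"root"`` or an internal node label); each copy's leaves are suffixed
    ``_1``/``_2``.  The two paralog stem branches have length
    ``divergence_boost`` x the mean root-to-leaf distance of the duplicated
    subtree.  ``gc3_paralogs`` gives each paralog its own GC3 target, applied
    by synonymous re-equilibration at the duplication point and during all
    subsequent branches -- the duplicate relocating into a different genomic
    GC environment.  The NNR block (when the architecture carries one) is
    kept in paralog 2 and randomised in paralog 1, mimicking N-terminal loss.
    """
    code = code or GeneticCode.standard()
    arch = architecture or make_architecture(nnr=nnr_in_paralog2, seed=params.seed)
    species_tree = _build_tree(params)
    if duplication == "root":
        dup_node = species_tree
    else:
        matches = [n for n in species_tree.traverse() if n.name == duplication]
        if not matches:
            raise ValueError(f"duplication node {duplication!r} not found in tree")
        dup_node = matches[0]

    depths = [sum(a.length or 0.0 for a in t.ancestors() if a.length is not None)
              + (t.length or 0.0)
              for t in dup_node.tips()]
    stem = divergence_boost * float(np.mean(depths)) if depths else params.radius

    def _suffixed(node: TreeNode, suffix: str) -> TreeNode:
        clone = node.copy()
        for tip in clone.tips():
            tip.name = f"{tip.name}{suffix}"
        return clone

    dup_parent = TreeNode()
    for suffix in ("_1", "_2"):
        sub = _suffixed(dup_node, suffix)
        sub.length = stem
        sub.name = f"paralog{suffix}"
        dup_parent.append(sub)
    if dup_node.is_root():
        gene_tree = dup_parent
    else:
        gene_tree = species_tree.copy()
        matches = [n for n in gene_tree.traverse() if n.name == duplication]
        target = matches[0]
        dup_parent.length = target.length
        parent = target.parent
        parent.remove(target)
        parent.append(dup_parent)

    leaf_names = [t.name for t in gene_tree.tips()]
    g1, g2 = gc3_paralogs if gc3_paralogs else (None, None)
    base_gc = _leaf_gc(params, [n[:-2] for n in leaf_names])
    leaf_gc = {}
    for name in leaf_names:
        if name.endswith("_1") and g1 is not None:
            leaf_gc[name] = g1
        elif name.endswith("_2") and g2 is not None:
            leaf_gc[name] = g2
        else:
            leaf_gc[name] = base_gc[name[:-2]]

    dup_params = dataclasses.replace(
        params,
        tree=None,  # placeholder; we drive the simulation manually below
        gc3_target={n: leaf_gc[n] for n in leaf_names},
    )
    tables = _tables(code)
    rng = np.random.default_rng(params.seed)
    omega_sites = _omega_sites(arch, params)
    de_only = np.zeros(arch.n_codons, dtype=bool)
    if params.mode == "selection":
        for c in arch.acidic_sites:
            de_only[c - 1] = True
    site_region = _site_labels(arch.regions, arch.n_codons)
    events: dict[str, dict[str, int]] = {}
    if params.mode == "selection":
        eff_gc = {k: calibrate_gc3_bias(arch.scaffold, v) for k, v in leaf_gc.items()}
        eff_g1 = calibrate_gc3_bias(arch.scaffold, g1) if g1 is not None else None
        eff_g2 = calibrate_gc3_bias(arch.scaffold, g2) if g2 is not None else None
    else:
        eff_gc = dict(leaf_gc)
        eff_g1, eff_g2 = g1, g2
    root_g = float(np.mean(list(eff_gc.values())))
    root_seq = _root_codons(arch.scaffold, code, root_g, rng)

    leaves: dict[str, np.ndarray] = {}

    def branch_g(node: TreeNode) -> float:
        names = [t.name for t in node.tips()] or [node.name]
        return float(np.mean([eff_gc[n] for n in names]))

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            start_seq = seq
            if child.name == "paralog_1" and arch.nnr_span is not None:
                start_seq = start_seq.copy()
                lo, hi = arch.nnr_span
                sense = [tables.index[c] for c in code.sense_codons]
                for cpos in range(lo - 1, hi):
                    start_seq[cpos] = sense[rng.integers(len(sense))]
            if child.name == "paralog_1" and eff_g1 is not None:
                start_seq = _resample_synonymous(start_seq, code, eff_g1, rng)
            if child.name == "paralog_2" and eff_g2 is not None:
                start_seq = _resample_synonymous(start_seq, code, eff_g2, rng)
            child_seq = _evolve_branch(
                start_seq, float(child.length), tables, params.kappa, omega_sites,
                branch_g(child), params.mode, de_only, rng, site_region, events,
            )
            if child.is_tip():
                leaves[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(gene_tree, root_seq)
    seqs = SequenceSet(
        Sequence(
            id=name,
            residues="".join(tables.codons[i] for i in leaves[name]),
            kind="nucleotide",
        )
        for name in leaf_names
    )
    aln = CodonAlignment(seqs, code)
    return SimulatedFamily(
        cds=seqs,
        alignment=aln,
        regions=arch.regions,
        params=dup_params,
        architecture=arch,
        region_events=events,
        leaf_gc3=leaf_gc,
        paralog_of={n: n[-1] for n in leaf_names},
    )
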