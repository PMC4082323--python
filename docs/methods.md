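# Methods

`naspkit` implements the comparative-sequence statistics used to characterise
the molecular evolution of the NASP (N1/N2) family of histone H3/H4
chaperones — proteins built from four 34-residue tetratricopeptide repeats
(TPRs), with the TPR2 neighbourhood interrupted by a large acidic (D/E-rich)
tract, conserved from excavates to vertebrates.  This note records the models
and conventions behind each module, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Distances and selection statistics

**p-distances.**  Divergence is measured as the uncorrected proportion of
differing sites (amino-acid or nucleotide).  For deeply diverged families the
p-distance has smaller variance than model-corrected distances, which is why
it is the working statistic here.  Group values are arithmetic means over all
pairs.  Standard errors come from a bootstrap over sites (codon sites for the
codon statistics), 1000 replicates by default.  All distance functions assume
*complete deletion* has been applied: every alignment column containing a gap
**or ambiguity character** (N/X) in any row is removed first.  Ambiguities
are treated like gaps because a partially observed column cannot enter a
difference count symmetrically.

**Modified Nei–Gojobori counting.**  Synonymous (pS) and non-synonymous (pN)
differences per site are computed by codon-level counting with
transition/transversion weighting.  The ratio R is the transition rate over
the *total* transversion rate; per single-base change a transition carries
weight 2R and each transversion weight 1, so R = 0.5 reproduces the
unweighted 1986 counts.  Potential sites of a codon: each position
contributes the weighted fraction of its single-nucleotide mutants that are
synonymous, with the denominator fixed at the full positional weight
(2R + 2).  Mutational paths that reach a stop codon count as neither
synonymous nor non-synonymous sites, so S + N < 3 × (codon count) whenever a
codon borders stop space.  This convention (rather than renormalising the
surviving mutants to a full site) makes the site counts exactly proportional
to the mutational opportunity of a process that never creates stops, and
therefore leaves pS and pN unbiased against the package's own simulator.

Observed differences between two codons are averaged over all orderings of
the differing positions, excluding orderings that pass through a stop codon.
Step weights are applied as above; note that because every ordering performs
the same multiset of base changes, the pathway weights cancel and the result
equals the unweighted pathway average except where stop exclusions differ.
In the (never observed for sense codons of the standard code) case that every
ordering is blocked, each differing position is classified independently on
whichever background avoids a stop.

For a sequence pair, S and N are the means of the two sequences' site counts
summed over codon sites; pS = ΣSd/ΣS, pN = ΣNd/ΣN; group values are means
over pairs.

**Codon-based Z-test of selection.**  Z = (pS − pN) / √(var pS + var pN),
with both variances from the same codon-site bootstrap resampling.  The
p-value is one-tailed standard normal for the purifying (pN < pS) and
positive (pN > pS) alternatives and two-tailed for the neutral alternative.
A comparison with zero bootstrap variance (e.g. identical sequences) reports
p = 1 with a `degenerate` flag rather than NaN; fewer than 10 variable codon
sites adds a `low_power` flag but the test still runs.  The normal
approximation, not the bootstrap distribution itself, supplies the p-value;
the bootstrap only feeds the variance.

**Region stratification.**  A `RegionMap` (1-based inclusive codon-column
intervals: TPR1–4, ACIDIC, termini, linkers) stratifies every statistic.
`region_report` emits one row per region plus a REMAINDER row for unassigned
columns and an ALL row.  Regions must span at least 5 codons; note that
stochastic orderings such as "pS ≥ pN in every region" are only reliable for
regions of ~20 codons and up — an 8-codon linker can invert by sampling noise
even under genuinely purifying conditions.

**Sliding-window diversity.**  Pi per window is the mean pairwise proportion
of differing nucleotide positions, windows of 50 nt advancing by 10 nt
(defaults).  Synonymous/non-synonymous per-site diversity is computed over
codons lying fully inside the window; codons straddling a boundary contribute
to total Pi only.

## Codon-usage and composition statistics

**ENC.**  Wright's effective number of codons.  Per synonymous family the
homozygosity is the bias-corrected F = (nΣp² − 1)/(n − 1); class means F̄_k
are taken over families with at least 2 observed codons, and

    ENC = n₁ + Σ_k m_k / F̄_k

with m_k the number of k-fold families and n₁ the single-codon families
(standard code: 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆).  A class with no usable
family is imputed at its no-bias value 1/k and flagged.  ENC is capped at the
number of sense codons (61 for the standard code).  The family structure is
always derived from the active genetic code, so under the ciliate nuclear
table (TAA/TAG = Gln) the class counts shift accordingly — necessary because
the family under study includes *Tetrahymena*.  The default code is the
standard table; the ciliate table is selectable per sequence set.

**RSCU.**  Observed count over (family total / family size); 1 = no bias.
Families never observed report undefined (None); single-codon families report
1.0 when observed.

**GC and purine composition.**  GC1/GC2/GC3 are positional GC fractions with
stop codons excluded.  GC at fourfold-degenerate third positions (GC4f)
serves throughout as the operational proxy for the genomic GC environment of
the gene; no genome files are read.  GA1/GA4f are the purine (G+A) fractions
at first codon positions (optionally restricted to codons of selected
residues, e.g. Ala/Lys whose codons carry G/A first bases) and at
fourfold-degenerate third positions.

**Acidic statistics.**  The acidic count is #D + #E.  Net charge and
theoretical pI use Henderson–Hasselbalch sums over ionizable groups with the
EMBOSS pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1), pI located by bisection to |charge| < 1e-4.  The pKa set is
a declared constant; swapping it changes pI values by up to ~0.5 pH units.

## Neutrality-deviation tests

Under mutation-driven evolution the frequency of GC-rich amino acids
(G, A, P, W) should correlate positively, and that of GC-poor amino acids
(F, Y, M, I, N, K) negatively, with the genomic GC proxy (GC4f); selection on
amino-acid composition destroys these correlations while leaving GC3 free.
`neutrality_correlations` computes Spearman coefficients of GAPW, FYMINK,
Ala and Lys frequencies against GC4f.  Spearman uses midranks for ties; for
n ≤ 9 the p-value is the exact permutation probability over all n! orderings,
otherwise the t approximation with n − 2 df (the method used is recorded in
the result).  `ga_position_test` compares GA1 with GA4f per sequence — a
paired t-test by default (the two quantities are paired observations on the
same gene), Welch's unpaired test as an option, one-tailed for GA1 > GA4f.
Both GA1 modes (all codons, or restricted to chosen residues) are offered
because either reading is defensible; the mode is logged in the output.

## Motif and region analyses

The NNR (NASP N-terminal Region) motif of fish NASP2 paralogs is the
14-residue pattern S-X(5)-E-E-X-P-C-S-S-(S/T), scanned with overlapping
matches on ungapped coordinates (gaps removed per sequence before scanning).
Conservation profiles report per-column consensus (modal residue, ties broken
alphabetically), identity fraction, and property-class fractions with a fixed
table: hydrophobic {A,V,L,I,M,F,W,C}, acidic {D,E}, basic {K,R,H}, remainder
polar.  Acidic tracts are found by marking every window of `min_len` residues
whose D+E fraction meets `min_de_frac` and merging touching windows; defaults
(10 residues, fraction 0.5) are chosen so that even the shortest TPR2
interruptions described in divergent family members are detected.  A merged
interval is therefore guaranteed to contain a qualifying window, though the
union itself may dip below the fraction threshold.

## Neighbor joining

A minimal Saitou–Nei implementation over `DistanceMatrix` (typically aa-level
p-distances), used for cluster-pattern checks such as "paralogs group by
subtype, not species".  Ties in the Q criterion resolve to the lowest
taxon-index pair, making output deterministic.  Negative branch-length
estimates are clamped to zero with the deficit moved to the sibling branch.
Trees are `skbio.TreeNode` objects; newick serialisation round-trips through
standard parsers.  No bootstrap supports are attached.

## The synthetic-data generator

`synthetic_data` produces codon families with full ground truth so that every
statistic above can be tested against known parameters.

*Architecture.*  The default root protein is 214 codons: NTERM(25), TPR1(34),
LINKER(8), TPR2(34), ACIDIC(20), TPR3(34), TPR4(34), CTERM(25).  TPR blocks
are hydrophobic-enriched; the acidic tract has ≥ 70% D/E by construction (the
D/E positions stay restricted to {D,E} during selection-mode evolution,
modelling selection for negative charge rather than for a specific residue).
Because region labels are unique intervals, the acidic tract is modelled as a
region adjacent to a contiguous 34-codon TPR2 rather than physically
splitting it.  An optional NNR block near the start of NTERM encodes the
motif; it carries a dN/dS ceiling of 0.02, treating the motif as a conserved
functional unit.

*Substitution process.*  Continuous-time, single-nucleotide codon changes
simulated exactly (Gillespie) along a newick tree or a star tree (n leaves at
a given radius).  Rates: transition κ vs transversion 1 (per change, so
κ = 2R), × ω for non-synonymous changes (per region), × a GC acceptance
factor 2g toward G/C and 2(1−g) toward A/T at third positions.  Changes
creating stops have rate zero.  Rates are normalised so a branch length of 1
equals one expected substitution per codon site for an unconstrained site;
under selection the realised rate is lower, as in real data.  In
`mutation-bias` mode the GC factor applies at **all** positions and ω is 1:
amino-acid composition then drifts with the mutational bias, realising the
neutral expectation that the GAPW/FYMINK classes track genomic GC.

*GC3 calibration.*  The raw bias g is not the realised GC3: Met/Trp third
positions are fixed at G and the three-codon Ile family equilibrates at
g/(2−g).  In selection mode the generator therefore solves the closed-form
stationary composition for the internal g that makes realised GC3 equal the
requested target (bisection); recovery is within ±0.02 at 3000 codons.
Per-leaf targets are supported; internal branches use the mean of descendant
leaf targets.

*Duplication scenarios.*  `simulate_duplication` duplicates the species tree
at a named node, suffixes leaves `_1`/`_2`, and adds paralog stem branches of
length `divergence_boost` × the subtree's mean root-to-leaf depth.  Each
paralog may receive its own GC3 target, applied by synonymous
re-equilibration at the duplication point (the duplicate relocating into a
different genomic GC environment) and during subsequent evolution.  The NNR
block is kept in paralog 2 and randomised in paralog 1, mimicking N-terminal
loss.

*What the generator does not emulate.*  No indels — sequences are born
aligned, so all recovery tests exclude alignment error entirely; real
analyses inherit additional error from the alignment step.  No rate
heterogeneity beyond the region map, no empirical codon frequencies (F3x4
etc.), no recombination, no splice isoforms.  Passing tests therefore show
that the statistics recover the parameters of this idealised process, not
that they are robust to misalignment or model violation on real data.

## Numerical choices and determinism

- One named, seeded `numpy.random.Generator` per simulation; identical seeds
  give byte-identical FASTA output.  Every pipeline stage consumes the config
  seed, so a fixed config reproduces the report bundle byte for byte.
- Bootstrap default 1000 replicates; SEs stabilise to within ~10% of the
  4000-replicate value at that setting.
- pI bisection to |charge| < 1e-4 on pH ∈ [0, 14]; verified against a 1e-5
  pH-grid search.
- Degenerate statistics return flagged sentinel results (p = 1, None
  coefficients) instead of NaN.
- Problem sizes in the test suite were chosen for statistical resolution at
  desk scale: 500-codon families for Z-test calibration (200 neutral
  families) and power (20 purifying families), 3000–10 000-codon single-region
  families for GC3 and event-ratio recovery, 30-lineage families for the
  neutrality correlations (100 replicates in the selection arm), 214-codon
  default architecture for end-to-end runs.

## Known limitations

- pS saturates near 0.7–0.8 for deeply diverged pairs (uncorrected counting);
  no multiple-hit correction is applied, by design.
- The Z-test variance ignores the bootstrap covariance of pS and pN (the
  variances are summed), which is slightly conservative when the two are
  positively correlated.
- The NJ utility has no support values; it exists for topology checks, not
  for publication-grade phylogenies (likelihood/Bayesian reconstruction is
  out of scope).
- Per-codon maximum-likelihood selection scans and ancestral-state
  reconstruction are out of scope; the Z-test operates on pairwise averages
  and will miss selection confined to a few codons.
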