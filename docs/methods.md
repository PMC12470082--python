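# Methods

## Scope and model

`cpgphylo` quantifies methylation-driven CpG erosion in orthologous CpG
islands and asks how much phylogenetic signal survives in CpG
presence/absence alone. The underlying biological model: 5-methylcytosine
deaminates to thymine far more often than unmethylated cytosine, the
resulting T·G mismatch is repaired inefficiently, and the palindromic CpG
therefore decays to TpG (sense strand) or CpA (antisense strand) at an
elevated rate — empirically 10–50× the background transition rate. Islands
that stay unmethylated are protected; lineage-specific methylation episodes
leave lineage-specific CpG losses. The pipeline measures the footprint of
that process; it makes no attempt to infer methylation states themselves.

## Island detection

Islands are called with the standard triple criterion: GC fraction ≥ 0.50,
observed/expected CpG ≥ 0.60, length ≥ 200 bp, where
obs/exp = n(CG)·L / (n(C)·n(G)) over the scored interval. The GC threshold
is the defining property of a CpG island; the obs/exp and length thresholds
are required to make detection well-posed and follow the classic
Gardiner-Garden-style convention. All three are configurable. The
algorithm slides 200-bp windows at step 1, merges overlapping passing
windows, then trims each merged interval one base at a time (right end
first, then left) until the interval as a whole passes — so every reported
island re-scores above the thresholds it was called with. `N` counts as
non-C/non-G and never forms part of a CpG; an all-N sequence yields an
empty result with a warning. Coordinates are 0-based half-open everywhere.

## Dinucleotide annotation

The alignment is tiled into non-overlapping column pairs anchored at
column 0; a trailing odd column is ignored. Overlapping (sliding)
dinucleotides are deliberately not used: the position count of roughly
half the alignment length is what makes "orthologous dinucleotide
position" well-defined across species.

Evaluability rules, applied uniformly to every per-position analysis:

* a species with a gap or `N` in either column is not evaluable at that
  position (it simply drops out; `n_evaluable` decreases);
* if any species has a gap run of length ≥ 2 touching either column, the
  position is excluded outright — long gap runs are alignment artifacts or
  indels, not point-substitution information;
* positions with fewer than two evaluable species are excluded.

Classes: conserved-CpG (all evaluable states CG), variable-CpG (at least
one CG and one non-CG), non-CpG conserved/variable, excluded. The classes
partition the positions on every input.

The substitution spectrum counts **unique (position, alternative state)
pairs**: at a variable-CpG position, each distinct evaluable non-CG state
adds one to its CG→XY bin regardless of how many species share it. This
counting unit keeps a bin total interpretable as "number of distinct
alternative alleles observed" rather than being inflated by clade size.

Clade markers (mode `cpg`) are variable-CpG positions where every
evaluable member of one clade is CG and every evaluable member of the
other is not, in either polarity; the marker set is invariant under
swapping the clade names. Mode `snv` reports single alignment columns in
non-CpG positions where the two clades are each internally uniform and
carry disjoint bases.

Guanine-context counts compare one species pair: for each column where the
two differ (gap/N columns skipped), the reference base is tallied under the
dinucleotide context formed by its nearest left non-gap reference neighbor
plus itself, split into guanine vs non-guanine changes; altered adenines in
CpA context are exposed separately as the antisense deamination signature.
Placing the altered base second in the context string matches the
convention in which CpG, GpG, ApG and TpG all name a changed G.

## Recoding

Every position with a CpG in at least one evaluable species becomes one
character: `A` where a species' state is CG, `T` for any other evaluable
state, `-` where the species is not evaluable. Constant-`A` columns
(fully conserved CpGs) are retained: they carry no distance signal but keep
the character set equal to "all orthologous CpG positions", which is the
object of interest. A stricter column-constant rule (conserved positions
all-`A`, variable positions all-`T`) is available via `rule="column"`, but
it is species-invariant by construction and therefore useless for
between-species distances; the per-species rule is the default because it
is the only reading that yields a non-degenerate presence/absence tree.

## Distances, UPGMA, calibration

Percent identity is Clustal-style: 100 × matches / co-ungapped columns.
p-distance is mismatches over comparable positions; for nucleotide
alignments an optional indel mode scores each gap-vs-base column as one
mismatch (gap-vs-gap excluded) for the "all changes" tree. On gap-free
alignments pid/100 + p = 1.

UPGMA merges the cluster pair with minimal average-linkage distance
(weighted by cluster sizes, i.e. the arithmetic mean over all original
pairs); the new node sits at height d_min/2, so the result is exactly
ultrametric. Ties are broken by the lexicographically smallest member
label of the candidate pair — arbitrary, but deterministic, which the
reproducibility contract requires. Distances must be finite and
non-negative; NaN is rejected.

Calibration multiplies every node height by t/h(MRCA(pair)), pinning the
anchor pair's divergence to the supplied age (default chimp–bonobo at
1.7 Ma); it is idempotent up to scale. Newick branch lengths are parent
height minus child height; reading Newick reconstructs heights as distance
to the deepest descendant leaf (exact for ultrametric input). Tree
comparison is plain Robinson–Foulds on non-trivial unrooted bipartitions.

## The erosion simulator

An exact event-driven (Gillespie) simulation on the plus strand with no
indels, so leaf sequences are aligned by construction and annotation can
be tested independently of any aligner. Context dependence makes sites
non-independent, which rules out per-branch matrix exponentiation; instead
each branch is simulated event by event and the two neighboring sites'
rates are updated after every event. Per site: background rate μ split
κ:1:1 between the transition and the two transversions; every C followed
by G carries an extra C→T rate μ(λ−1) and every G preceded by C an extra
G→A rate μ(λ−1) — the strand-symmetric deamination channels, implemented
without reverse-complement bookkeeping. Events record branch, site, time,
bases, the trinucleotide context, and whether the draw came from the
background or the deamination channel; replaying the log from the root
reproduces every leaf exactly, which the tests assert bitwise.

Root sequences are built from frame-0 dinucleotide units:
round(cpg_fraction · length) units are `CG`, the rest drawn from GC-rich
fillers (`CC, CT, AC, TC, CA`, weighted to ~0.7 GC) that neither contain
CG nor start with G, so the CpG count is exact, no CpG spans a unit
boundary, and cpg_fraction 0 really means zero CpGs.

### Default study conditions

The default dataset emulates a 12-taxon primate-style design: three island
loci (1700 + 1600 + 1700 bases, even lengths so concatenation preserves
the tiling frame) evolved on a fixed clock tree with a hominid clade
(human, two archaic humans, chimp, bonobo, gorilla, orangutan) and an Old
World monkey clade (two macaques, baboon, green monkey, snub-nosed
monkey); node ages in Ma (root 29, orangutan 14, human–chimp 6,
chimp–bonobo 1.7, Colobinae split 16.2). Defaults: λ = 25 (mid-range of
the empirical 10–50×), κ = 2, cpg_fraction = 0.085 (≈17% of tiled
dinucleotides are CpG, an island-like density), and μ = 0.00015 per site
per Ma, chosen so that the deepest pairwise divergence — background plus
CpG erosion — stays below ~5%, i.e. all pairs remain ≥95% identical as the
design requires. Every random stream derives from the single user seed
(locus j uses seed+j; replicate r uses independent streams keyed by
[seed, tag, r]).

What the simulator does **not** model: indels, selection, rate variation
among non-CpG sites, methylation-state dynamics, back-biased repair, or
alignment error. Passing tests on simulated data therefore validate the
counting, recoding and tree machinery under a clean clock-like erosion
process; they do not establish that real island alignments are free of
alignment artifacts or selection effects.

### A known identifiability limit

With μ bounded by the ≥95%-identity condition, the shortest internal
branches of the default tree (the 0.2–0.45 Ma archaic-human splits) carry
fewer than one expected CpG-character change across the ~426 recoded
characters. Exact recovery of the archaic trio's branching order from
CpG presence/absence is therefore not statistically guaranteed at 5000
sites: for some seeds the simulated characters genuinely support a wrong
grouping (e.g. zero character differences between one archaic genome and
the modern human, one difference to the other archaic), and every
distance- or parsimony-based method will follow the data. Deeper splits —
both clades, all inter-genus relationships — are recovered reliably, and
recovery of the full topology approaches certainty as sequence length
grows.

## Numerical and degenerate-input choices

* Tie-breaks: UPGMA merges and recoded/spectrum orderings are all
  deterministic (lexicographic) so identical configs give byte-identical
  outputs; the run manifest carries a config hash and no timestamps.
* Calibration on a zero-height MRCA (identical sequences) is an error, not
  a silent division by zero.
* A species pair with no co-ungapped columns (percent identity) or no
  comparable positions (p-distance) is an error naming the pair.
* Newick round trips preserve topology and heights to 1e-9 (heights are
  written with 12 significant digits).
* An empty recoded matrix (no CpG anywhere) cannot be written to FASTA;
  the error says so explicitly.

## Problem sizes in the test suite

Unit and acceptance tests run on 12 × 5000 simulated alignments (seconds),
100-instance randomized oracle sweeps for the combinatorial operations,
200 replicates for the neutral-λ chi-square control and 500 for the
deamination-expectation check, and 100 random ultrametric trees (5–15
taxa) for exact UPGMA reconstruction. These sizes give stable statistics
for every stochastic check while keeping the full suite and the
acceptance script in the seconds-to-minutes range.
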