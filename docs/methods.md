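# Methods

This note documents the model behind `probekit`, the defaults and why they
were chosen, the numerical choices, what the synthetic test scenarios do and
do not emulate, and known limitations.

## Model overview

A probe set is modeled as a closed, well-mixed chemical system at
equilibrium. The species are: free probes, probe self-hairpins, probe–probe
cross-dimers, free target binding sites, and probe·site duplexes. Binding
sites on the same transcript are treated as independent (no cooperativity,
no partial overlap, no strand displacement), which is what makes the
bound-count distribution per transcript exactly Poisson-Binomial.

### Hybridization sites

An antisense DNA probe can bind an RNA wherever it has sufficient
complementarity. Sites are found by exact 7-mer seeding against the reverse
complement of each transcript followed by affine-gap local alignment with
BLAST-equivalent scoring (reward +1, mismatch −3, gap open 5, gap extend 2;
a length-k gap costs 5 + 2k). Alignments with fewer than 15 matched
nucleotides are discarded: shorter complementarity does not contribute
meaningfully to hybridization under FISH conditions. Retention is on
*matched nucleotides*, not score — an optimal local alignment can have
score below its match count once mismatches are crossed, and filtering on
score would silently drop such hits. No E-value or low-complexity filter is
applied. Overlapping retained hits on one transcript are clustered by
single-linkage interval overlap into non-overlapping sites; each hit is one
duplex configuration of its site. Only RNA is searched; genomic DNA and
intronic/nascent RNA are out of scope.

### Thermodynamics

Duplex ΔH/ΔS are summed from the unified DNA/DNA nearest-neighbor stack
table (shipped as `data/nn_dna_unified.csv`), with one initiation
contribution per terminal base pair (A·T and G·C flavors) and the entropic
salt correction ΔS′ = ΔS + 0.368·N_stacks·ln[Na⁺]. Mismatched and gapped
columns split the alignment into independent perfectly matched segments;
only segments of ≥ 2 bp contribute stacks, and no mismatch, loop, or
dangling-end terms are applied. This deliberately underestimates off-target
affinity where mismatches would stack favorably; a mismatch-aware model is
out of scope. The self-complementary symmetry correction is omitted —
probe–target duplexes here always involve distinct molecules, and the rare
self-complementary homodimer case is not worth a special branch.

The configurations of one interaction (the alternative duplex geometries of
a probe at a site, a probe's hairpin stems, a pair's two dimer
orientations) are aggregated as a bound-state partition function,
Ka = Σ_l exp(−ΔG_l/RT), and Kd = 1/Ka — molar for bimolecular reactions
(1 M standard state), dimensionless for unimolecular hairpins. Stronger
binding therefore always means smaller Kd, and absence of any stable
configuration means Kd = +∞ (the interaction simply drops out of the mass
balances).

Hairpin stems are enumerated by brute force as maximal complementary
antiparallel substring pairs with stems ≥ 3 bp and loops ≥ 3 nt (the
steric minimum); the top 5 stems by length become configurations. No loop
entropy is charged, so hairpin stability is overestimated — conservative
for design, since it penalizes structured probes. Cross-dimers get exactly
two configurations: the best local alignment in the antiparallel and in the
parallel orientation. Parallel duplexes have no proper antiparallel NN
parameters; their matched stacks are evaluated on the canonical
(id-ordered) strand, which also makes cross(i,j) ≡ cross(j,i) exact.

### Equilibrium

Expression (nTPM) is read as RNA copies per cell and converted to molar by
the volume of a 10 µm-radius sphere (a Jurkat-sized cell): one copy per
cell ≈ 0.40 pM. Each site of a transcript gets the transcript's
concentration. Probes default to 5 nM each — vendor protocols dilute
stocks by ratio rather than stating molarity, so this is a package choice,
config-overridable and recorded in every run's resolved config.

Free-site concentrations are eliminated analytically, leaving one
fixed-point equation per probe (see README). The solver is damped Picard
iteration (damping 0.5) from the all-free starting point, relative
tolerance 1e-12, at most 10,000 iterations, with a log-space Newton-type
fallback (`scipy.optimize.root`) if 1,000 iterations pass without
convergence. Non-convergence raises with the residual — it is never
silently accepted. On convergence the complex concentrations are
back-substituted from the elementary mass-action relations, so probe and
site conservation close to ≤ 1e-8 relative by construction; the test suite
checks the full solution against an independent root finder on the raw
mass balances (unknowns: free probes *and* free sites) to 1e-9 relative.

### Statistics

P(site bound) = S/(S+1) with S = Σ_i C_i^free/K_d(i,s). The per-transcript
bound-count pmf is computed by iterative convolution of (1−p, p) kernels —
numerically stable and exactly equal to expanding the probability
generating function, which the tests verify symbolically. N_on(n)/N_off(n)
weight each transcript's pmf by its expression in copies per cell (the
spherical-volume prefactor cancels against the copies-per-cell reading, so
these are molecule counts per cell; under equal expression they are
per-copy rates). Specificity load = Σ n·N_off(n) divided by the mean
probes bound per on-target molecule. A site's expected occupancy is
attributed to probes proportionally to their C_free/K_d share of its
binding — the model gives no other natural decomposition. The leave-one-out
"multi-site off-target" ranking removes a probe's binding terms while
holding free concentrations fixed (first-order approximation; full
re-equilibration would couple a diagnostic to solver cost without changing
orderings in any scenario we generate).

### Selection

Candidates are totally ordered by (off-target site count ascending, energy
gap ascending, start ascending). The energy gap is ΔG_on − (Σ ΔG_off +
ΔG_self + accrued ΔG_cross), using each interaction's most favorable
configuration; off-target counting is site-resolved (a transcript with two
sites counts twice) and optionally expression-weighted (off by default —
design under the equal-expression assumption). Selection runs in two
phases (zero-off-target candidates first), each pick permanently removing
candidates closer than the 3 nt minimum spacing and folding cross-dimer ΔG
against the new pick into the remaining candidates' gaps before re-ranking.
Tie-breaking by start coordinate makes selection fully deterministic;
identical inputs give byte-identical outputs. `max_probes` defaults to 48,
a typical full smFISH set for a ~1.5 kb transcript.

### Expression processing

TPM matrices are TMM-normalized: reference column = the one whose upper
quartile (over nonzero values) is closest to the mean upper quartile;
per-column factors are the doubly trimmed (30% M-values, 5% A-values)
weighted mean of M-values with delta-method variance weights; scaled
columns are rescaled to sum to 1e6. Gene-level tables are imputed to
transcripts by dividing by the annotation's isoform count, conserving gene
totals. Transcripts absent from a table are treated as unexpressed (0
nTPM) with a logged warning.

## Synthetic scenarios

`fixtures.generate_fixture` builds random transcriptomes (50% GC by
default, configurable) around one or more targets and plants exact
complementary blocks of known length into chosen decoys, so every
recoverable off-target site is known in advance. Plants are contiguous
exact-identity blocks with five forced-mismatch bases on each flank: a
20-nt probe overhangs a ≥ 15-nt block by at most 5 nt, so flank mismatches
make any alignment extension strictly score-losing and the manifest stays
exact down to coordinates. Random sequence is screened for accidental
15-mer sharing with the target (and targets for internal repeats) and
re-rolled on collision. The canned `arf4_like_scenario` miniaturizes a
hard design case — ~1.5 kb mRNA, a second isoform (internal deletion), 30
decoys, one rRNA decoy carrying a 16-nt planted homology, eight 15–20 nt
planted off-targets, log-normal expression (ln-mean 3, ln-sigma 1.5;
median ≈ 20 nTPM) with the rRNA boosted 100×.

What these fixtures do *not* emulate: real transcriptome k-mer statistics
and repeat families, biased base composition, isoform splice graphs,
partially complementary (mismatch-stabilized) off-targets, and
genome-scale search sizes. Passing tests demonstrate the algorithms'
correctness and the model's internal consistency, not background levels in
any real cell line; at desk scale the problem sizes are a ~1.5 kb target
against a few-tens-of-kb transcriptome rather than a genome-wide search.

## Numerical and degenerate-input choices

- Coordinates: 0-based half-open internally and in BED; 1-based closed in
  the human-readable probe table.
- Duplicate (probe, target, span) hits keep the maximum-score alignment.
- A candidate with no stable on-target duplex ranks on its penalty terms
  alone (ΔG_on := 0); windows containing N are skipped at tiling.
- Empty configuration lists mean Kd = +∞ everywhere, never 0 or NaN.
- All randomness is owned by the caller-supplied seed; reruns are
  byte-identical.

## Known limitations

Mismatch and loop thermodynamics are not modeled (off-target affinity is
underestimated, hairpin stability overestimated); RNA secondary structure,
RNA–protein occlusion, compartmentalization, toehold displacement,
formamide, and kinetics (time courses) are out of scope — the model is
strictly an equilibrium description of fully spliced transcripts in one
well-mixed volume.
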