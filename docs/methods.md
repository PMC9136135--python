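# Methods

## Problem setting

Proteins secreted through LC3-dependent secretory autophagy carry no
known export signal. The approach implemented here is a cohort-contrast
census: enumerate every short motif, measure per-protein prevalence in a
positive cohort (LC3-mediated, unconventionally secreted) and a negative
cohort (conventionally secreted), and test candidate motif classes —
the triacidic class (three consecutive D/E residues) and the di-lysine
class KKX — together with their sequence and structural context
(LC3-interacting regions, phosphorylatable flanking residues).

## Motif space and scanning

- Alphabet: the 20 standard amino acids. Ambiguity and rare codes
  (B, J, O, U, X, Z) are retained in sequences with their positions
  flagged, but match no motif position, fixed or wildcard. Treating
  selenocysteine as nonstandard keeps the motif space exactly 20^k.
- Motifs are literal k-mers, k ∈ {2, 3, 4}. Mirror symmetry identifies
  m with reverse(m); the canonical representative is the lexicographic
  minimum of the pair. Class counts are (20^k + 20^⌈k/2⌉)/2: 210, 4200
  and 80200 for k = 2, 3, 4. The differential analysis defaults to
  literal (uncollapsed) motifs, with collapsing available as a flag.
- Patterns extend motifs with single-position wildcards (`X`): KKX,
  WXXL, and the extended LIR consensus [W/F/Y]XX[L/I/V] expressed as a
  union of nine patterns. A wildcard matches only standard residues.
  KKX requires a third residue: a C-terminal `...KK` is not a hit.
- All hits, including overlapping ones, are reported as 0-based
  half-open spans. Scanning is implemented with compiled lookahead
  regular expressions; the test suite verifies exact agreement with a
  character-by-character brute-force scanner.

## Prevalence and tests

- Prevalence is presence-based: a protein contributes at most once per
  motif regardless of its number of occurrences.
- A motif is a differential candidate when f_pos ≥ 1.3 · f_neg and
  f_pos > 0. The 30% constraint is read as a relative ratio of
  protein proportions, not a 30-percentage-point difference. Motifs
  absent from the negative cohort pass with an infinite ratio (the
  limiting case of the constraint). Candidates are ranked by the
  prevalence difference f_pos − f_neg, ties broken lexicographically so
  the ranking is deterministic.
- The class-level test is the pooled two-proportion Z-test, two-sided,
  without continuity correction — the textbook form appropriate for
  cohort sizes in the hundreds. The statistic is undefined (and raises
  a dedicated error) when the pooled proportion is 0 or 1. `log10_p` is
  computed from the normal log-survival function so far-tail results
  remain finite after `p` underflows double precision.
- No multiple-testing correction is applied by default, matching the
  census character of the analysis; a Bonferroni column over the
  enumerated motif count can be requested.
- The class report covers triacidic, KKX, their disjunction (either
  class as "the signal"), and each class restricted to hits with a
  phosphorylatable flank.

## Sequence proximity

- The gap between two spans is the number of residues strictly between
  them; overlapping or adjacent spans have gap 0. "Within 3 residues"
  therefore measures nearest edges, and the same rule serves the
  5-residue validation threshold. Motif-start to motif-start distance
  was the plausible alternative; nearest edges was chosen because it is
  symmetric in the two motifs and independent of their lengths.
- The S/T/Y context window covers `[start − w, start)` and
  `[end, end + w)` (default w = 3), clipped at the termini. Residues
  inside the motif are excluded — so the serine of a KKS hit does not by
  itself satisfy the criterion; the criterion asks about the motif's
  surroundings, not its composition.
- LIR scanning defaults to the core WXXL consensus; the extended
  [W/F/Y]XX[L/I/V] alphabet of the LIR literature is available as a
  mode.

## Structural proximity

- One PDB chain per protein, first model only, first alternate location
  kept, hydrogens excluded. Parsing is delegated to Biopython's PDB
  parser; parsed coordinates are rounded back to the three decimals the
  PDB format carries, which keeps fixture distances exact in double
  precision.
- Sequence-to-structure mapping assumes author numbering is 1-based
  along the sequence and accepts a residue only when its identity
  matches; if fewer than half the chain residues map this way, an
  ungapped sliding match of the chain's residue string within the
  sequence is attempted. Below 50% coverage the structure is rejected as
  unusable rather than silently half-mapped.
- The distance between two motif instances is the minimum Euclidean
  distance over atom pairs drawn one from each instance's mapped
  residues; `all_heavy` (default, the most permissive reading of a
  distance threshold between motifs) or `ca_only`. Class-level proximity
  is the minimum over all hit pairs, flagged against configurable
  thresholds (defaults 10 and 15 Å). Which PDB entries the original
  structural observations used is not recorded anywhere, so structural
  results are exercised on user-supplied chains and synthetic fixtures,
  not reproduced.

## Synthetic data

The generator emulates the statistical design of the real study: two
cohorts, constructs present in a controlled fraction of each.

- Defaults mirror the study conditions: cohort sizes 202/1576 in the
  CLI, residue background uniform over the 20 standard amino acids,
  protein length 300, triacidic planted at 0.8/0.4, KKX at 0.9/0.5,
  WXXL at 0.9/0.9. An average-vertebrate composition table is available
  because triacidic/KKX base rates depend strongly on D/E/K abundance;
  uniform remains the default for analysable arithmetic.
- Prevalence is controlled exactly: background draws are rejected until
  they contain no spontaneous hit of any planted construct's detection
  class, so presence ⇔ planted and per-cohort counts are Binomial(n, p).
  Without suppression, spontaneous triacidic hits (≈ 26% of uniform
  300-mers) would make planted rates unrecoverable.
- Plants overwrite background residues (lengths stay exact), never
  overlap or touch each other (adjacency could fuse two plants of the
  same class into extra windows), draw wildcards from the background,
  and satisfy co-location (gap ≤ g to a partner plant) and S/T/Y-flank
  rules by bounded rejection sampling (500 attempts, then a generation
  error).
- Reproducibility: each protein has its own PCG64 substream keyed by
  (root seed, cohort offset + index), so resizing one cohort never
  changes the other.
- What the generator does **not** emulate: real proteome composition
  biases, domain structure, disorder, homology between cohort members,
  or correlated motif occurrences. Passing parameter-recovery tests
  shows the pipeline measures what was planted under a clean null
  background — not that the real cohorts' contrasts are free of
  compositional confounding.
- `straight_chain_pdb` writes a single-CA-per-residue chain along the
  x-axis at 3.8 Å spacing (the canonical Cα–Cα virtual bond length), so
  every inter-residue distance is known in closed form.

## Numerical and degenerate-input conventions

- Coordinates 0-based half-open throughout; spans must be non-empty.
- Empty cohorts, empty motif classes and empty sequences raise
  argument/validation errors rather than returning silent zeros.
- Duplicate FASTA identifiers receive deterministic numeric suffixes
  with a logged warning; an entry with no sequence aborts the read and
  names the offending header.
- All pipeline tables have fixed column orders and deterministic row
  orders; reruns with identical config and inputs are byte-identical
  (timestamps appear only in the log file).

## Problem sizes used in the checks

The packaged checks run synthetic studies of 500 proteins per arm at
length 300 for parameter recovery and ranking, 200 replicates of the
same design for the power check of the class test at α = 2×10⁻⁴
(50 replicates in the acceptance script), and 1000-instance brute-force
oracle comparisons for each scanner and for the distance code. These
sizes give binomial standard errors of ~2 percentage points on recovered
prevalences and leave the power check with effectively no sampling
slack (the planted effect yields |z| ≈ 13).

## Known limitations

- Prevalence-based counting discards occurrence counts and positions
  within the protein (by design, following the presence/absence rule).
- The Z-test treats proteins as independent; homologous cohort members
  violate this and would narrow the nominal error rate.
- Structural proximity handles a single chain; inter-chain contacts and
  quaternary context are out of scope.
- The LIR scanner is presence-only; no position-specific scoring or
  disorder context is applied.
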