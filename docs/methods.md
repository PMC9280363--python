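# Methods

## Problem setting and model

Conserved plant miRNA families can be discovered without a reference
genome by scanning expressed-sequence-tag (EST) collections for
near-exact copies of known mature miRNAs, then requiring that the
surrounding sequence folds back into a pre-miRNA hairpin. The approach
rests on two empirical regularities: mature plant miRNAs are strongly
conserved across species, and plant miRNA–target duplexes are close to
perfectly complementary, which also makes rule-based target prediction
effective. `guarmir` implements this workflow end to end, with every
stage an importable function and every threshold explicit.

## Homology scan

The scan is exhaustive and ungapped: each reference mature (19–25 nt;
anything shorter than the 18-nt floor or outside the range is skipped
with a warning) is slid across every plus-strand EST window, counting
Hamming mismatches on a canonical alphabet (U≡T, so RNA references
compare directly to DNA ESTs; N matches only N). A hit is any window
with at most `max_mismatch` mismatches.

- `max_mismatch` — default 4, with a `PipelineConfig.strict()` preset at
  3. Both budgets circulate in this literature; the criteria-style
  statement (four) is the default and the tighter one is a preset
  rather than a silent choice.
- Per (EST, family) the hit with fewest mismatches (earliest window,
  then smallest reference id, on ties) is flagged `best` and is the one
  carried into folding.
- BLAST is deliberately not used: exhaustive scanning of ≤25-mers at
  desk scale is fast (the implementation is a vectorised
  sliding-window comparison) and exactly matches its own brute-force
  oracle, which a heuristic seeded search would not.

Reverse-complement matches are never reported; minus-strand discovery
is out of scope, as is protein-coding/Rfam screening, which is replaced
by a pluggable exclusion list of EST ids applied after cleaning.

## Folding engine

The built-in engine is a pair-energy dynamic program of the Nussinov
form: every admissible pair contributes a fixed energy (G:C −3, A:U −2,
G:U −1 kcal/mol; N never pairs), and the program minimises total energy
subject to a minimum hairpin loop of 3 unpaired bases and a maximum
pair span (default 3,000 nt). Traceback is deterministic: pairing is
preferred over leaving a base unpaired, with the leftmost admissible
partner. Because all pair energies are negative, MFE = 0 exactly when
the structure has no pairs. The O(n³) kernel is JIT-compiled, keeping
600-nt windows well under a second.

This is a simplified thermodynamic model — no stacking, loop penalties,
dangles or temperature dependence — chosen so that folding is exactly
reproducible and dependency-free, and so that the structure level the
validator needs (which bases pair, where the loop is) is available
without a full energy model. A ViennaRNA-backed engine
(`viennarna_engine`, 37 °C by default) plugs in behind the same
`sequence -> (structure, MFE)` contract when the bindings are
installed. All published-value comparisons in this package rest on the
shipped descriptor tables, not on either engine, so the engine choice
is isolated from acceptance.

## Window extraction and hairpin validation

Around each best hit, nested windows are enumerated largest-first:
flank sizes on the two sides of the mature vary independently over a
grid (default: from 300 nt down in 25-nt steps, plus a 10-nt minimum
pad), clipped to the EST. Asymmetric windows matter because the mature
may sit on either precursor arm. Each window is folded and validated:

- **Arm placement** is read off the mature's own pairing pattern: the
  mature is on the 5′ arm when every paired mature base has its partner
  downstream of the mature, on the 3′ arm when every partner is
  upstream. Mature bases pairing with other mature bases, or partners
  on both sides, mean the mature straddles a terminal loop
  (`loop_overlap`). This mature-centred reading is robust to decorative
  structure elsewhere in large windows — in particular to small
  hairpins that random flanking sequence or the terminal loop itself
  forms, which would derail a "largest stem in the window" rule.
- **Duplex budget**: a mature base counts against
  `max_duplex_mismatch` (default 5) when it is unpaired or its pair is
  not Watson–Crick. G:U wobbles therefore count toward this budget —
  the mature:star comparison treats a wobble as a mismatch even though
  the folding model pairs it. This is the convention under which a
  6-wobble star is rejected at budget 5, matching how the mature/star
  criterion is exercised throughout the package.
- **Bulge size**: along the mature:star ladder, no gap between
  consecutive pairs may exceed `max_bulge` (default 30 nt). The limit
  is enforced as a post-fold check rather than inside the dynamic
  program, keeping the DP simple while filtering the same structures.
- A+U richness is reported as a descriptor, never used as a hard
  filter: no defensible threshold exists (accepted reference rows run
  from ~40% to ~83% AU).

Among valid windows for a hit, the selected precursor minimises energy
density (MFE/length), with shorter-then-leftmost tie-breaks. Hits with
no valid window are dropped and logged.

## Descriptors, MFEI and the filter cascade

For each precursor: base counts (U and T pooled), AU% and GC% computed
with N excluded from numerators and the shared denominator — the one
convention under which AU% + GC% always closes to 100, including rows
with N bases — A/U and C/G ratios (reported missing on zero
denominators), MFE, and

    MFEI = ((MFE / length) × 100) / GC%,

undefined (missing, never a crash) at GC% = 0. Energies are stored
signed; magnitudes appear only at report time, matching the common
"−kcal/mol" display convention. Candidates pass at |MFEI| ≥ 0.6 and are
additionally flagged `strict` at |MFEI| ≥ 0.85, the stronger
hairpin-vs-other-RNA criterion. Duplicate mature sequences within a
family collapse to one representative (fewest mismatches against the
reference, then lowest MFE). Summaries keep exact means and round only
for display (MFE 1 dp, MFEI 2 dp, length integer, half away from
zero); the mature-length mode breaks ties toward the smaller length.

### Reference fixtures

Two published descriptor tables for cluster bean ship in
`guarmir/data/`: the 57-family precursor table (AU%, GC%, counts,
length, MFE, MFEI) and the 49-row known/predicted mature table. They
were transcribed verbatim from the source, including its quirks: two
rows (miR5565, miR2628) print AU% and GC% transposed relative to their
own base counts (their printed MFEI values are consistent with the
counts-derived GC, which is how the transposition is detectable), and a
handful of MFEI cells round differently than their printed inputs
imply. `verify_fixtures()` therefore recomputes the statistics that are
arithmetically well-defined from the tables — the per-row AU+GC
closure, composition from counts, the MFEI cells whose inputs reproduce
them exactly, column summaries, and the mature-length mode — and
reports each computed-vs-published comparison. Fixture comparisons use
absolute tolerance 0.01 (0.1 on the MFE mean) because the source mixes
rounding and truncation.

## Target prediction

Plant-style rule-based scanning, exhaustive over every transcript
window, antiparallel and ungapped: position *i* from the miRNA 5′ end
faces window base *L−1−i*. Classes are Watson–Crick `match`, `gu`
wobble, or `mismatch` (N is always a mismatch). A window is a site when
mismatches ≤ 4, wobbles ≤ 4 (separate budgets — a wobble is never
double-counted as a mismatch) and positions 10–11 (1-based, 5′
numbering; the cleavage site) are Watson–Crick. All qualifying sites
are reported, with a `best` flag per (miRNA, transcript) on fewest
mismatches+wobbles, leftmost on ties. Gapped duplexes and bulges are
out of scope: the rules speak only of mismatches and wobbles.

## Phylogeny

Precursor relationships use a self-contained distance pipeline:
Needleman–Wunsch global alignment (match +1, mismatch −1, linear gap
−2; deterministic traceback diagonal > up > left), p-distance
(mismatch fraction over gap-free columns; 0 with a warning when no
columns are comparable), and Saitou–Nei neighbor joining with the
lexicographically-smallest-label-pair tie-break on the Q-criterion and
negative branch lengths clamped to zero. On additive matrices the
implementation recovers the generating tree exactly (topology and path
metric), and it agrees with an independent NJ implementation in tests.

Bootstrapping resamples the columns of a progressive multiple
alignment: sequences are added in NJ guide-tree leaf order, each
aligned against the majority consensus of the growing alignment
(gaps, once introduced, are kept). Supports are the percentage of
`n_reps` (default 1,000) replicate NJ trees containing each internal
bipartition of the reference tree; a fixed seed makes supports exactly
reproducible. The consensus-based progressive scheme is a minimal
stand-in for profile–profile aligners: adequate for the short, related
precursors this pipeline compares, and pluggable where it is not.

## Synthetic data

`generate_est_set` emulates the pipeline's discovery inputs: i.i.d.
uniform {A,C,G,T} background ESTs (GC bias is a parameter, default 0.5
— AU-rich compositions can be emulated but are not hard-wired), with a
chosen fraction carrying one planted hairpin at a uniform random
offset. Hairpins are mature + random loop (8 nt) + reverse-complement
star, with optional G:U wobbles in the star and either arm placement;
planted matures are perturbed by substitutions only (consistent with
the ungapped scan), either per-base at `mutation_rate` or an exact
count. `generate_transcript_set` plants reverse-complement target
sites with exact mismatch/wobble counts at random non-protected
positions. Every planted feature is recorded in a truth manifest
(coordinates, sequences, perturbations, parameters, seed), outputs are
byte-identical for a fixed seed, and recovery is scored against the
manifest: a planted precursor counts as recovered when a best hit on
its EST yields a valid hairpin candidate.

Default generator conditions used by the tests and examples: 30–40
ESTs of 300 nt with half carrying plants, against ~12 real reference
matures taken from the packaged table. These sizes keep an end-to-end
run in seconds while leaving every stage non-trivially populated; with
no mutations recovery is 100%, with 5 substitutions per mature nothing
survives the 4-mismatch scan. What the generator does not emulate:
sequencing error, vector contamination, protein-coding content,
expression structure, and real EST length distributions — so passing
tests demonstrate correctness of the machinery under its stated model,
not discovery performance on real dbEST data.

## Numerical and engineering choices

- All internal coordinates are 0-based half-open; written tables are
  1-based inclusive, the reporting convention of this field's tables.
- Rounding is half-away-from-zero at the precision of the column being
  reported.
- Energies are exact in floating point (sums of −1/−2/−3), so DP
  equality comparisons in traceback are safe.
- Determinism is a contract everywhere: same inputs, config and seed
  give byte-identical tables, structures, trees and supports.
- Degenerate inputs: empty EST input or an all-rejected cleaning stage
  abort the pipeline with a stage-named error; an empty reference set
  is a contract error; a miRNA longer than a transcript yields no
  sites; sequences too short to fold return an all-dot structure at
  MFE 0.

## Known limitations

The pair-energy folder ranks structures differently than a full
thermodynamic model, so built-in MFE/MFEI values are not comparable to
published UNAFold/ViennaRNA numbers (use the ViennaRNA engine for
that); the homology scan is plus-strand and substitution-only; target
scanning has no expectation score or translational-inhibition
classification; the progressive aligner has no iterative refinement;
and the published headline discovery counts from full-scale EST sets
depend on database snapshots and are intentionally out of scope — the
fixtures carry the published statistics instead.
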