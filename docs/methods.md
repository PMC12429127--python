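# Methods

## Problem and approach

A protease of unknown specificity is characterised by digesting a diverse
protein mixture and identifying the resulting peptides by tandem mass
spectrometry. Each confidently identified peptide witnesses up to two
cleavage events — one at each boundary — and pooling the residues around
all unique cleavage positions yields a position-specific picture of what
the enzyme prefers at each subsite. `cleavemap` implements that analysis
chain and a generative simulator that inverts it, so every stage can be
validated against a known ground truth.

## From peptides to cleavage sites

Records carry 1-based inclusive coordinates and are validated against the
parent sequence (the stated peptide must equal the protein substring);
inconsistent records are dropped with a logged reason. The confidence
filter keeps records with ion score ≥ 20 (inclusive). The default of 20
reflects the score region where specificity profiles typically stabilise
for small sample sets; it is a parameter, not a constant. Sequence-level
deduplication keeps the highest-scoring occurrence of each peptide:
duplicate identifications are repeated observations of the same molecule,
and the score is the only principled tiebreak for which record's metadata
to keep. Peptides containing non-canonical residues (B, Z, X, U, O) are
excluded from counting, since they have no column in a 20-residue matrix.

Boundary rules for site inference:

* no N-boundary site for a peptide starting at position 1, or at position 2
  of a Met-initiated protein — the latter is attributed to co-translational
  initiator-Met removal, not proteolysis. A methionine anywhere else before
  a peptide is a legitimate P1 (Met specificity is real and must not be
  suppressed);
* no C-boundary site for a peptide ending at the protein's last residue
  (the natural terminus is not a cut);
* sites are deduplicated by (accession, position), ignoring which boundary
  witnessed them — a cleaved bond is one observation.

Windows default to 6 upstream + 5 downstream subsites (P6…P1 ‖ P1′…P5′).
Both spans are parameters. Subsites falling outside the protein are padded
with `-`; padded slots are absence of data, not observations, and are
excluded from every denominator.

## Specificity matrices

With `c_rs` the count of residue *r* at subsite *s* and `n_s` the number of
defined (non-padded, canonical) observations at *s*:

* frequency: `f_rs = c_rs / n_s` (each subsite column sums to 1);
* enrichment ratio: `f_rs / q_r` against a background composition `q`;
* Z-score: `(f_rs − q_r) / sqrt(q_r (1 − q_r) / n_s)`.

The Z-score is the one-sample binomial-proportion statistic: under the
null, the residue at a subsite is a Bernoulli(q_r) draw per site, so the
observed proportion has standard error `sqrt(q(1−q)/n)`. It uses only
quantities the pipeline defines, treats subsites independently, and is the
standard choice for residue-enrichment heatmaps. Degenerate backgrounds
(q = 0 or 1) have zero sampling variance: Z is 0 when the observation
matches the certain outcome and signed infinity (flagged, excluded from
colour scaling) otherwise. A residue observed in windows but absent from
the background is an error for the ratio layer — the background does not
cover the data.

Backgrounds come from an external two-column TSV (e.g. a database
composition snapshot; such tables are user-supplied, never bundled, because
database composition drifts between releases) or from the identified
proteins themselves, each unique protein pooled once regardless of peptide
multiplicity. The identified-protein background is the recommended default:
it is the composition actually exposed to the enzyme. Dipeptide backgrounds
count ordered adjacent pairs within each sequence; pairs never span protein
boundaries. Compositions are compared with Pearson and Spearman
coefficients over the 20 paired frequencies; zero variance makes them
undefined and NaN is reported.

Printed percentages round half-up at one decimal, matching how such tables
are conventionally typeset (banker's rounding would print 14.75 % as 14.7).

## Motif statistics

P2–P1 pair counts use only windows with both subsites defined; pair
Z-scores apply the same binomial-proportion form against the ordered-
dipeptide background, for internal consistency with the single-residue
layer. The conditional-P1 analysis partitions defined-P2 windows into
those with a chosen residue (default proline) at P2 and all others, and
reports both P1 frequency vectors with their event counts; an empty
partition is flagged rather than silently zero.

Triplet analysis counts concrete P3–P2–P1 triples plus user-declared
generalized templates (`X` wildcard, `[LMP]` or `[L/M/P]` residue classes),
ranked by count descending with alphabetical ties. Site-level matrices run
on unique (accession, position) sites, whereas motif statistics follow the
window list they are given — the caller chooses the dedupe universe, and
the two keys (unique site vs unique peptide) are both available upstream.

## Length and missed-cleavage statistics

All length statistics run on unique peptide sequences. SD is the sample
(n−1) estimator — the convention behind "mean ± sd" in this literature;
mode ties break to the smallest length and even-count medians average the
central pair (both otherwise arbitrary). The histogram covers every
observed length and sums to 100 %; the five named bins (5–8, 9–12, 13–16,
17–20, >21) partition lengths ≥ 5, with the last bin including 21 so no
length is unassigned; shorter peptides are counted separately.

A missed cleavage is an internal peptide residue in the enzyme's
cleavage-residue set. The final residue is never a miss (it is the realized
cut or the protein terminus); the first residue is eligible. Adding a
residue to the rule set can only increase per-peptide counts (monotone),
but the *fraction of peptides* with ≥ 1 miss is not monotone — a broader
rule also cuts more, producing different peptides — so only the per-peptide
property is asserted.

## Logos and reports

The percent-difference logo is `100·(f_rs − q_r)` per cell, so each
subsite's differences cancel to zero. Per-cell significance is a two-sided
exact binomial test of `c_rs` against `q_r` at `n_s`; cells with p ≥ α
(default 0.05) are masked. No multiple-testing correction is applied — the
logo is a descriptive display, and the mask is a visual de-noising
threshold, not an inference procedure. Because p-values can equal 1
exactly, α ≥ 1 is treated as the degenerate mask-nothing threshold.
Masking is monotone in α by construction.

Rendering is deterministic: a fixed SVG hash salt and suppressed date
metadata make re-rendered SVGs byte-identical. The report bundle writes
every artifact as TSV/JSON plus images, and a manifest with SHA-256
checksums keyed by kind (`data` vs `image`), so reruns are comparable
checksum by checksum.

## The simulator

The generator emulates a diverse substrate pool: by default several
hundred proteins with lognormal lengths (μ = 6.0, σ = 0.5 on the log scale,
truncated to 50–2000 residues — median ≈ 400, the realistic span from
single-domain proteins to large multi-domain ones) and uniform residue
composition, the neutral choice when no organism is being imitated.
Digestion draws an independent Bernoulli per peptide bond, left to right:
the cut probability is the P1 residue's rule probability times an optional
multiplicative factor for the P2 residue of the *original* sequence,
clamped to [0, 1]. A position-1 methionine is never a realized cut P1,
mirroring the biology the initiator-Met exclusion rule is meant to handle,
so that rule has a clean ground truth. The identification layer keeps
fragments of 5–40 residues (the typical LC–MS/MS detectability window),
scores true hits from U[30, 80] and decoys from U[0, 15] — cleanly on
either side of the default score threshold of 20 — and draws decoys as
random substrings of real proteins, so their coordinates are internally
consistent and filtering is meaningfully exercised.

What the simulator does *not* model: spectra or m/z (no peak lists),
retention or ionization behaviour, sequence-dependent detectability,
homologous/shared peptides, non-canonical residues, or any kinetic
mechanism behind missed cleavages (the Bernoulli model is a stand-in, not
a claim about any real enzyme's kinetics). Passing recovery tests
therefore shows the pipeline is a correct inverse of this generative
model, not that any particular biological conclusion is right.

## Validation scale and results computed

The parameter-recovery checks simulate 300 proteins per run over 20-seed
grids — large enough that a 0.9/0.5 two-residue rule is recovered in rank
order essentially always, small enough that the whole suite runs in tens
of seconds on one CPU. `scripts/acceptance.py` recomputes, from scratch:
the P1 percentages implied by the published cleavage counts of the
broad-specificity protease (478/344/291/239/259 over 3231 events), the
P1-rule and proline-at-P2 recovery rates, the missed-cleavage fraction of
a fully specific digest (exactly 0 by construction of the rules), and the
identified-vs-pool composition correlations.

## Known limitations

* The binomial model treats sites as independent; correlated cleavage
  (e.g. processive digestion) would understate the Z-score variance.
* Peptide-to-protein ambiguity is resolved by the reported parent only;
  shared peptides are not re-assigned.
* External database Z values computed with other (unstated) formulas are
  not comparable number-for-number to this package's Z layer, though rank
  orders agree for strong preferences.
* The Mascot XML reader targets the generic export fields (accession,
  prot_seq, pep_seq, pep_start, pep_end, pep_score) and ignores unknown
  elements; exotic schema dialects may need the TSV route.
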