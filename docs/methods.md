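# Methods

This document specifies the models and procedures implemented by
`cistress`, the parameter defaults and why they were chosen, and the known
limitations. Coordinates are 0-based half-open internally; GFF3 input and
output use 1-based closed coordinates, BED6 output 0-based half-open.

## Promoter extraction

A gene model contributes one promoter: the `window` bases (default
**1000 bp**, the conventional proximal-promoter window for plant
cis-element surveys) immediately upstream of the TSS, read 5'→3' on the
gene's strand. For a plus-strand gene with TSS at 0-based position `t`,
the window is `[t − window, t)`; for a minus-strand gene it is the reverse
complement of `[t + 1, t + 1 + window)`. Windows are clipped at contig
ends and flagged `truncated`. Promoter position `i` maps to TSS offset
`i − window`, so offsets run from `−window` (distal) to `−1` (the base
adjacent to the TSS). Sequences are uppercased, `U` is mapped to `T`, and
characters outside `ACGTN` are replaced by `N` with a warning.

## Motif scanning

Motifs are declarative specs of three kinds:

- **exact** — a literal sequence (e.g. `pUPRE`, `ATTGGTCCACGTCATC`);
- **degenerate** — IUPAC ambiguity codes, compiled to character classes
  (e.g. `ERSE-II`, `ATTGGNCCACG`);
- **gapped** — two parts with a spacer-length range (e.g. `pERSE`,
  `CCAAT` + N₁₀ + `CACG`, spacer fixed at 10..10). Each realized spacer
  length yields a separate match carrying `spacer_len`.

Semantics:

- **`N` asymmetry.** `N` in a *motif* matches any of `A/C/G/T`; `N` in the
  *scanned sequence* matches nothing. An undetermined base is never
  evidence for an element.
- **Both strands, overlapping hits.** The minus strand is scanned on the
  reverse complement and coordinates are mapped back
  (`[n − e, n − s)`). Overlapping occurrences are all reported.
- **Palindromic dedup.** When a hit occupies the identical interval (and
  spacer) on both strands, one match is reported with strand `+`, so a
  palindromic box is not double-counted.
- Reported offsets are TSS-relative (`tss_offset = start − window`).

The built-in ER-UPR catalogue: `pERSE` (gapped, spacer 10), `ERSE-II`
(degenerate), `pUPRE` (exact), `UPRE-I` (`CAGCGTG`), `UPRE-II` (`TACGTG`),
`UPRE-III` (`TCATCG`), and the bZIP core `BZIP_CORE` (`CACGT`; its
reverse-complement reading `ACGTG` arises as a minus-strand hit). A rice
`UPRE-II` variant (`GATGACGCGTAC`) ships disabled by default because it is
a species-specific alternative, not part of the core consensus set.
Catalogues can be replaced by a JSON motif file.

## HSE grammar

A pentamer is classified (mode `paper`, the default) as

- **forward** iff position 1 is `G` and position 2 *or* 3 is `A`
  (0-based) — i.e. it matches `nGANn` or `nGNAn`;
- **reverse** iff its reverse complement is forward;
- **none** otherwise, and *always* `none` if it contains `N`.

"Forward and reverse simultaneously" is impossible (it would require
position 1 to be both `G` and `T`), so orientation is well defined. The
relaxed rule is exactly the pentamer decomposition of the functional 8-mer
constraint `GAAnnTTC` with one tolerated mismatch position per half-site;
the test suite proves this equivalence exhaustively over all 1024
pentamers. Mode `perfect` restricts to the strict consensus
`nGAAn`/`nTTCn`; every perfect-mode run lies inside a paper-mode run.

An HSE is a **maximal run of ≥ `min_units` (default 3) consecutive,
non-overlapping pentamers with strictly alternating orientation**, at
stride 5. All five phase offsets are scanned; a repeated orientation ends
the run (and may start a new one). The grammar is self-reverse-
complementary, so scanning one strand suffices; matches on the reverse
complement are the coordinate mirror of matches on the sequence (tested).

## Positional summary and enrichment

Element maps aggregate per-promoter matches sorted by TSS offset. The
proximal/distal split uses `proximal_bp = 500` by default (half the
window, the conventional "proximal promoter" cut); the boundary is
**inclusive on the proximal side**: an element starting exactly at −500 is
proximal.

Enrichment per element class uses a **mononucleotide shuffle** null: the
promoter sequence is permuted (preserving base composition, destroying
order), rescanned, and the proximal count compared with the observed one.
The p-value is `(1 + #{shuffles ≥ observed}) / (n + 1)` (add-one, so p is
never 0); at least 100 shuffles are required for a meaningful resolution.
A class whose minimum motif length exceeds the promoter length is
reported as NaN. A mononucleotide (rather than dinucleotide) null was
chosen because the generator's background model is i.i.d.; with real
promoters this overstates enrichment of CpG-like motifs (see
Limitations).

## qPCR statistics

**Livak 2^−ΔΔCt.** Technical replicates are collapsed to their mean Ct
per (group, biological replicate, gene); wells with technical SD > 0.5
cycles are flagged. Then per biological replicate
`ΔCt = Ct_target − Ct_reference`, `ΔΔCt = ΔCt − mean ΔCt` of the
calibrator group, `rq = 2^−ΔΔCt`, and `neg_ddct = −ΔΔCt = log2 rq`. Group
summaries report mean rq and SEM (SD/√n over biological replicates).

**One-way ANOVA** by direct sum-of-squares decomposition; the F p-value
from the F survival function. Degenerate inputs (all groups identical)
return F = 0, p = 1.

**Duncan's multiple range test** (default α = 0.05): groups ordered by
mean; for a range spanning `p` ordered means the protection level is
`α_p = 1 − (1 − α)^(p−1)` and the critical range
`R_p = q(1 − α_p; p; df_error) · √(MSE / n_h)` with the harmonic mean
`n_h` for unequal group sizes. Testing is step-down, widest span first; a
non-significant span blocks all pairs it contains. Studentized-range
quantiles come from `scipy.stats.studentized_range.ppf` (cached); the
test suite cross-checks them against an independent double-quadrature
CDF and the exact identity `q(α; 2; df) = t(1 − α/2; df)·√2`.

**Compact letter display** by insert-and-absorb: groups sharing no letter
differ significantly, groups sharing a letter do not; letters are ordered
by descending group mean. Both soundness conditions are asserted inside
the function and property-tested on random decision sets.

**Two-sample t-test**: Student (pooled) or Welch, via
`scipy.stats.ttest_ind`.

## Simulators

**Promoters.** Backgrounds are i.i.d. with GC fraction **0.4** by default
(typical AT-rich plant promoter composition; configurable). Plantings are
specified as (element, TSS offset, strand, and for HSEs a unit count);
overlap and out-of-window plantings are rejected before any sequence is
generated. Planted HSE units are sampled uniformly from the valid
pentamer set for the requested mode and re-verified by the classifier.
Each promoter is embedded in a synthetic contig with a **60-bp** gene
body (long enough to exercise both-strand extraction while keeping
fixtures small); genes alternate between the plus and minus strand so GFF
round-trips exercise both code paths. Outputs: promoter FASTA, genome
FASTA, GFF3 gene models, and a TSV truth table.

**Ct tables.** For planted fold `f` relative to the calibrator: reference
Ct = `base_ct` (default **20.0**, a typical housekeeping Ct) plus
biological noise; target Ct = `base_ct + target_offset − log2 f` plus
biological noise, with `target_offset` = **2.0** cycles (targets
typically less abundant than the reference). Technical replicates add
independent technical noise. Defaults `noise_sd_bio = 0.2` and
`noise_sd_tech = 0.1` cycles reflect the usual ordering (biological >
technical variability) at magnitudes common for SYBR assays. The design
defaults mirror a standard experiment: 3 biological × 3 technical
replicates. With zero noise the pipeline returns rq exactly equal to the
planted fold — the identity anchoring the ΔΔCt acceptance test.

All randomness flows from a single `numpy.random.default_rng(seed)` per
simulation; repeated seeded runs are byte-identical (tested end to end
through the CLI).

## Problem sizes in the test suite

Suite sizes (200 random 2-kb sequences for oracle agreement, 50 seeded
promoter configurations for recall, 500 simulations for noisy ΔΔCt
recovery, 1000 random decision sets for CLD soundness) are package
choices balancing statistical power against the test-time budget; they
were fixed before running the suites and are not tuned to outcomes.

## Limitations

- The background model is i.i.d. mononucleotide; real promoters have
  dinucleotide structure and the enrichment null inherits this
  simplification.
- TSS positions are taken from the 5' end of the annotated feature
  (default `gene`); if annotations start at the ATG, "promoters" include
  the 5' UTR.
- The HSE grammar scores presence/absence only; no affinity or spacing
  penalties beyond strict 5-bp periodicity, and gapped HSE variants
  (e.g. step-type elements) are out of scope.
- Duncan's MRT is anti-conservative relative to Tukey's HSD; it is
  provided because it is the convention in the target literature, not as
  a recommendation.
- 2^−ΔΔCt assumes ~100% amplification efficiency for both target and
  reference; efficiency-corrected models (Pfaffl) are not implemented.
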