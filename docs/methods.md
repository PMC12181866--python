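# Methods

This note documents the models, rules, and numerical choices behind
`varconcord`, and what its green tests do and do not establish.

## Curation chain

A ClinVar-style VCF is reduced to a benchmark set by six filters applied
in a fixed order, with each excluded record attributed to the *first*
failing filter (the retained set is order-independent; only the
attribution depends on the order):

| order | filter | default |
|---|---|---|
| 1 | indel size | excluded when `max(len(ref), len(alt)) − 1 ≥ 50` bases |
| 2 | review stars | retained at ≥ 2 stars |
| 3 | assertion | only P / LP / B / LB retained (VUS, conflicting, other excluded) |
| 4 | chromosome | mitochondrial (MT) records excluded |
| 5 | MC present | records lacking molecular-consequence information excluded |
| 6 | multi-MC | more than one SO term on a single transcript excluded |

Star tiers follow ClinVar's published review-status table
(practice guideline → 4, expert panel → 3, multiple submitters no
conflicts → 2, single submitter or conflicting → 1, no assertion → 0) and
are configurable. Combined assertion tokens
(`Pathogenic/Likely_pathogenic`) map to the weaker class (LP). The indel
size reading `max(len) − 1 ≥ 50` is the standard small-variant/SV
boundary. Deduplication is exact on (chrom, pos, ref, alt) after
normalization, keeping the first record.

Allele normalization is VCF-convention parsimony plus left alignment: the
shared suffix is trimmed (rotating reference bases in from the left when
one allele would empty — this is exactly the left-shift across repeats),
then the shared prefix, keeping at least one base per allele. Degenerate
(non-ACGT) alleles and `ref == alt` remnants are rejected with typed
reasons. A 1,000-case fuzz test checks idempotence and that the
normalized representation splices to the same edited sequence as the
input representation.

## SO normalization and functional categories

Each tool's raw vocabulary is mapped onto canonical SO terms by a shipped
TSV (`data/so_synonyms.tsv`); the severity order (`data/so_severity.tsv`)
is the published Ensembl/VEP consequence ranking. Both files are editable
so an alternative table can be slotted in without code changes. The order
is a strict total order, so "most severe" needs no tie-breaking. Unknown
raw terms map to an `unmapped` sentinel and are counted, never dropped.

One mapping deserves a flag: ANNOVAR's bare `splicing` region label does
not distinguish donor from acceptor, so it maps to
`splice_region_variant`. This under-calls LoF for ANNOVAR splice
annotations; resolving it would require exon context ANNOVAR does not
provide in the term itself.

Functional categories (the ACMG-facing bins): LoF = frameshift, splice
donor, splice acceptor, nonsense; Missense; ProteinLengthChange = inframe
insertion/deletion, stop-loss, initiator-codon (`start_lost` is placed
here, *not* in LoF, although some classifiers treat initiator-codon loss
as LoF); Synonymous (including stop/start-retained); everything else
Other.

## HGVS parsing, canonicalization, equivalence

The parser accepts coding/non-coding/genomic/protein expressions with
optional accession prefixes: substitutions, del/dup/ins/delins/inv,
identity (`=`), intron offsets (`c.310+3`), UTR zones (`c.-12`, `c.*5`),
one- and three-letter amino-acid codes, `Ter`/`X`/`*` stops,
parenthesized protein forms, short and long frameshifts, extensions, and
repeat `UNIT[N]` tokens (parsed and recognized; repeat notation is *not*
normalized — it only resolves at the sequence level when an explicit
range is given, mirroring the unsettled status of repeat descriptions in
the nomenclature).

Protein canonicalization renders three-letter codes, `Ter` for stops, and
`=` for synonymous changes; short frameshifts are not expanded (that
would require the sequence), and the longest stated information is kept.

Equivalence levels:

* **strict** — raw identity after whitespace/case normalization;
* **canonical** — identity of canonical renders; plus notation-only
  equivalences: short-form frameshift vs any long form sharing the
  reference residue and position (two long forms that disagree in the new
  residue or stop offset are mismatches), dup-vs-ins when the insertion
  sits immediately 3′ of the duplicated interval *and* both alleles are
  stated and equal (anything weaker needs the sequence), and del/dup with
  vs without a stated allele;
* **full** — additionally, equality of `apply_edit` outputs on the
  transcript; `shift3` implements the 3′ rule (maximal right placement,
  insertion collapsing onto duplication when the rotated unit matches the
  segment 5′ of the insertion point).

Verdicts: `missing` (absent query — a missing annotation counts against
the tool), `exact`, `equivalent` (cause `non_preferred`), `mismatch`
(cause `position_or_type`, or `unknown` reserved for parse failures).
Transcript accessions compare version-blind whenever either side lacks a
version (ANNOVAR never states one); for protein comparisons without a
protein accession the coding accession stands in.

The comparator is validated against the sequence oracle: on ≥ 1,000
fuzzed (transcript, edit) cases, `compare_hgvs(..., "full")` returns a
match exactly when the two descriptions edit the transcript identically,
and `shift3` lands on the brute-force-maximal 3′ placement.

## ACMG engine

Criteria evaluated from evidence: PVS1 ⇔ LoF category; PP3 ⇔ not PVS1 and
(CADD ≥ 25.3 or SpliceAI ≥ 0.5); BP4 ⇔ CADD < 22.7 and SpliceAI absent or
< 0.5; PP5/BP6 from the ClinVar assertion with star-scaled strength
(2 stars → PP5 moderate / BP6 strong; ≥ 3 stars → very strong); PM4 ⇔
ProteinLengthChange; BP7 ⇔ Synonymous with no splice signal. PS4, PM3,
PP4, BP2, BP5 are disabled (they need cohort/phasing/gene–disease data).
All other criteria are pass-through boolean flags at their default
strengths — no hidden evaluators are invented for them.

Combining transcribes the 2015 table over strength counts per direction:
Pathogenic = 1 VS & (≥1 S | ≥2 M | 1 M+1 P | ≥2 P) | ≥2 VS | ≥2 S |
1 S & (≥3 M | 2 M+≥2 P | 1 M+≥4 P); Likely pathogenic = 1 VS+1 M |
1 S+1–2 M | 1 S+≥2 P | ≥3 M | 2 M+≥2 P | 1 M+≥4 P; Benign = standalone |
≥2 strong-benign; Likely benign = 1 strong+1 supporting | ≥2 supporting;
otherwise VUS, and both directions met → VUS. Two choices the 2015 table
leaves open: ≥2 very-strong is Pathogenic, and one benign *very-strong*
(BP6 at ≥3 stars, a slot the benign table lacks) suffices for Benign,
mirroring the pathogenic side's weighting; both are configurable. The
engine is checked by exhaustive enumeration (4,096 subsets of a
12-criterion pool) against an independently coded transcription of the
table, plus fuzzing with modified strengths.

## Delta analysis

For each (reference category, tool category) pair: PVS1 loss ⇔ reference
LoF and tool not; gain ⇔ the converse. For reassessment, the two evidence
inputs differ *only* in functional category; classification direction
uses the order B < LB < VUS < LP < P. By default only "no conflict"
variants are reassessed — those whose reference-side automatic class
agrees with the ClinVar assertion at the P/LP-vs-B/LB group level (class
equality would be stricter than the stated pre-filter and would drop
LP-classified P variants). PP5/BP6 strengths are re-derived from stars on
both sides of the reassessment.

## Synthetic world

The generator's defaults are the stated world, chosen once:

* class mix P/LP/B/LB = 0.2326 / 0.0369 / 0.3469 / 0.3836 (the curated
  test-set composition at paper scale);
* class-conditional consequence mixes: the pathogenic side is LoF- and
  indel-heavy (55% LoF mass), the benign side dominated by synonymous and
  other SNVs — the "PLP is more diverse" structure;
* per-tool corruption defaults echo the real tools' relative behavior:
  ANNOVAR strips versions, misses HGVS most (missing 0.05, non-preferred
  0.20), SnpEff lacks the most transcripts (transcript-absent 0.08), VEP
  is cleanest; all three confuse LoF terms at 2–3% toward their typical
  neighbors (nonsense → missense, splice → intron, frameshift → inframe);
* CADD ~ Normal(30, 4) for P/LP truth and Normal(12, 5) for B/LB,
  truncated at 0 — deliberately arbitrary, chosen so both the PP3 and BP4
  thresholds are exercised; SpliceAI ~ U(0.6, 1) for splice truth,
  U(0, 0.2) otherwise; stars 2/3/4 at 0.85/0.12/0.03.

Transcripts are synthetic 60–300 nt cDNA windows with planted homopolymer
runs so 3′-shifting is exercised under full control. What the generator
does **not** emulate: real RefSeq sequences, genomic-to-cDNA projection
across exons (all emitted HGVSc are exonic; splice/intronic consequences
are conveyed by the SO term only, though intron-offset syntax is fully
parsed), reverse-strand complementation, population allele frequencies,
and multi-transcript genes (one transcript per variant). A green
recovery test therefore establishes that the pipeline measures the
corruption process correctly — not that it reproduces any real tool's
behavior on the real genome.

Non-preferred corruption draws uniformly from the known equivalent-form
set of the true HGVS (one-letter amino acids, X-for-Ter,
substitution-style synonymous, short frameshift, ins-for-dup, left-shifted
placement, allele-bearing del/dup, delins-style substitution); every form
is equivalence-resolvable at the full comparison level by construction,
which is what makes the closed-form expectations exact:
match = (1 − missing)(1 − transcript-absent), strict
match = that × (1 − non-preferred), term match = presence × the
confusion diagonal averaged over truth mass, PVS1 loss/gain = LoF (resp.
non-LoF) truth mass × off-category confusion mass. Corruption labels are
stored with the truth and are sufficient to regenerate every emission
byte-identically (tested).

## Numerical conventions

Fractions are reported to 4 decimals, percentages to 2. Positions are
1-based inclusive (VCF convention) everywhere; no 0-based representation
exists internally. Probability vectors must sum to 1 within 1e−9.
Recovery tolerances are 3 binomial standard deviations at the realized
denominator (coding-only for HGVSp; present-annotation pairs for PVS1
rates).

## Known limitations

* ANNOVAR ingestion targets the tab-delimited multianno table (the tool's
  canonical output); its VCF-output mode is not parsed. A `column_map`
  makes non-default layouts usable.
* Repeat `[N]` notation is recognized but never normalized; comparisons
  involving it resolve only at the full level with an explicit range.
* The microsatellite (MS) variant-type label cannot be derived
  computationally and is taken from input metadata when present.
* `ext` (extension) protein forms parse but carry no equivalence
  semantics beyond render identity.
* Venn figures are not drawn (no plotting dependency); the region counts
  are emitted as JSON.
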