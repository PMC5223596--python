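# Methods

This note records the models and procedures the package implements,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions, so results
can be interpreted without reading the source.

## Database curation

A prolamin sequence database is curated in three logged passes, in
order: fragment removal, taxon whitelisting, exact-sequence
deduplication. Each pass records every removed accession with the
triggering rule, and survivors keep input order, so curation is
idempotent and auditable.

The *fragment* rule is a disjunction of three independently toggleable
sub-rules: a "Fragment" token in the header, a missing initiator
methionine, or length below 120 residues. Public annotation rarely
says what "fragment" means; the 120-residue floor is our
operationalisation, chosen because full-length gluten storage proteins
run from roughly 250 (α-gliadins) to 800+ residues (HMW glutenins), so
anything below 120 is a partial cDNA in practice. The *taxon* rule
parses the organism from the UniProt-style `OS=` header field (falling
back to the description) and keeps genus-prefix matches ("Triticum" by
default). *Duplicate* means byte-identical sequence; the first
occurrence wins. Near-identity is deliberately not collapsed —
near-identical isoforms are the object of study, not noise.

## Pairwise identity and trees

Percent identity comes from a global pairwise alignment (BLOSUM62,
gap open 10, gap extend 0.5 — the ubiquitous defaults) with identity
counted over columns where both sequences place a residue; gap columns
are excluded from the denominator, matching the convention most
aligners use when they print "percent identity". Because repeat-count
differences align as gaps, two alleles differing mainly by repeat
number can still show high identity; identity is a column statistic,
not an edit distance.

Trees are neighbor joining on distances 1 − identity. The NJ
agglomeration is delegated to scikit-bio; this package owns input
validation (symmetry, range, unit diagonal), the distance transform
and the clamping of negative branch lengths to zero. Determinism
follows from scikit-bio's fixed agglomeration order. On any additive
distance matrix NJ provably recovers the generating topology, which is
what the tree tests check (200 random 4–6-taxon additive matrices,
recovered bipartition sets compared exactly).

## Digestion model

Cleavage is positional: position *p* is a site iff residue *p* is in
the rule's cleave-after set and the following residue is not blocking;
the terminal residue is never a site. Two chymotrypsin presets exist
because practice is split: `chymotrypsin-search` (after F/Y/W/L, not
before P — the common search-engine setting for gluten) and
`chymotrypsin-expasy` (after F/Y/W/M/L, not before P — the ExPASy
convention, which adds methionine). The colloquial phrase "unless
preceded by a proline" is ambiguous; we implement blocking by the
*following* residue, the standard chymotrypsin convention and the
literal reading of "not before P". A peptide with *k* missed cleavages
is the concatenation of *k* + 1 adjacent fragments; with *f* fragments
and budget *k* the digest yields Σ_{j=0..min(k,f−1)} (f − j) spans.
The implementation is verified against two independent oracles: a
brute-force enumeration of boundary-valid substrings, and
`pyteomics.parser.cleave` with the equivalent regex.

Masses are monoisotopic by default (pyteomics residue tables; water
18.0105647 Da, proton 1.0072765 Da), average masses by flag.
Modification shifts: carbamidomethyl-C +57.02146 (fixed), oxidation-M
+15.99491, deamidation-N/Q +0.98402 (variable). Peptides containing X
have undefined mass and are excluded from m/z matching.

## Diagnostic peptides

Within an isoform family, a peptide is diagnostic for a member iff it
occurs in that member's digest and no other member's. Comparison is on
exact strings; I and L are distinct by default (search engines report
sequences as written), with an opt-in collapse for the
mass-indistinguishable I/L case. Variant classification aligns the
diagnostic locally against each non-owner: an equal-length gapless
counterpart with mismatches is a *substitution*; a gapped alignment is
*insertion_or_deletion*; a verbatim substring match (uniqueness arose
purely from cleavage-boundary or missed-cleavage context) is
*unclassified*. The `repeat_variation` label is reserved for generator
annotations — distinguishing a repeat-unit indel from a generic indel
by alignment alone is not reliable, so the classifier does not attempt
it. Matching diagnostics against observed evidence ignores
modification state, since deamidated forms carry the same sequence.

## Evidence filtering and inference

Rows are validated against the CSV schema and the modification grammar
(`Name@P` or `Name@{P1|P2|…}`, 1-based), then filtered by three
conjunctive criteria — score ≥ 5 (inclusive: reported score ranges
start at exactly 5), precursor error ≤ 10 ppm against the
modification-aware theoretical m/z, and membership in the database
digest with ≤ 2 missed cleavages. The retained set is criterion-order
independent; only the rejection tag (first failing criterion) depends
on the fixed order score → ppm → digest. A 20 ppm fragment tolerance
is accepted in the config for completeness but inert: no fragment-ion
data is ingested.

Rows collapse into peptide *entities*. In `sequence_with_mods` mode
the key is (sequence, multiset of modification names): positions are
ignored entirely, so deamidation-position isomers with equal count are
one entity (the site cannot be localised in Q runs) while different
deamidation counts stay distinct. `sequence_only` keys on the bare
sequence.

The replicate criterion is evaluated per extract and per entity: an
entity is reliable in an extract iff ≥ 2 seeds each contribute ≥ 2
distinct replicate observations there. Replicates are pooled across
platforms by default (a replicate is a distinct (platform, tech-rep)
pair); a strict per-platform mode is available. Reliability was a
genuinely open design point — "the same unique peptide(s)" could be
read per peptide or per protein — and we evaluate it per peptide,
which is the stricter and more mechanical reading.

A protein is reported when its count of unique entities reliable in at
least one extract reaches the threshold (1 or 3; both tallies are
computed in one pass, and raising the threshold can only shrink the
set). Entities matching no protein are flagged orphans and reported,
never silently dropped; entities matching several proteins keep the
full accession set, and byte-identical parent sequences trigger a
skipped-curation warning. Coverage is the union of all matching spans
of all supporting entities (multi-copy peptides contribute every
occurrence), with per-residue platform bitmasks retained for
shared/exclusive rendering.

## Quantification

Entity intensity is the arithmetic mean over the runs where the entity
was observed (median by flag); zeros are not imputed for missing runs.
T3PQ is the mean of the three largest unique-entity intensities;
proteins with one or two quantifiable entities get the mean of what
exists and a `partial` flag. Only unique entities contribute — shared
peptides would double-count signal across isoforms. Hi3 calibration is
the single-point ratio to a spiked standard (default 100 fmol) and is
skipped with a warning when the standard is absent or partial. T3PQ is
exactly scale-equivariant, so calibrated amounts are invariant under
global intensity rescaling; both properties are tested to machine
precision. Modification prevalence is reported over exclusive classes
(none / deamidated / oxidized / both), which sum to one;
carbamidomethylation is fixed chemistry and reported separately.

## Synthetic data: what it emulates, and what it does not

The family generator builds base sequences as signal peptide (~20
hydrophobic residues), an N-terminal domain, a repetitive core of
prolamin motifs (defaults PQQPFPQ / QQPFP / LQPFP / QQQFP, 25–40
units) and a C-terminal domain, over a Q/P-dominated background
composition with K+R capped at 3 %. Isoforms apply independent
per-residue substitutions (default 0.01) and whole-repeat-unit indels
(default probability 0.3), all annotated. A deterministic HMW-like
allelic pair (`make_hmw_like_pair`) plants the classic discriminators
— an S→C substitution after the repetitive-domain start, one repeat
insertion, one deletion, scattered substitutions — over ~900 residues
of HMW-type motifs (PGQGQQ / GYYPTSLQQ / GQQ).

The evidence simulator covers a 2-platform (QTOF ×3 reps, LTQ ×2) ×
3-extract × 3-seed design. Detection probability is base (default
0.9) × a logistic length bias favouring long peptides on the QTOF
(floor 0.55, midpoint 14 residues, scale 4 — chosen so the QTOF
length distribution is visibly right-shifted, not to reproduce any
particular percentage) × a missed-cleavage emission factor (1 / 0.4 /
0.15 for 0/1/2). Intensities are log-normal around a per-protein
abundance (σ = 1) times a fixed per-peptide ionisation efficiency
(σ = 0.8) times run noise (σ = 0.3). Each Q deamidates independently
(default 0.4 — stated as a per-glutamine probability; peptide-level
prevalence is consequently higher in Q-rich peptides), with ambiguity
sets spanning runs of adjacent glutamines; each M oxidises at 0.03,
matching the few-percent methionine oxidation typical of sample
handling; every C is carbamidomethylated. Observed m/z carries
Gaussian ppm error (σ = 3) clipped at ±9.5 ppm, so the 10 ppm filter
sees near-boundary values on both sides while every matched row
remains retainable. Matched scores are 5 + Gamma(2, 8); noise rows
(2 % of matched, random sequences with database composition, verified
absent from the digest) score Exponential(1), so the score filter
alone removes ≥ 99 % of them.

Not emulated: raw spectra, fragment ions, ion mobility,
chromatography and retention-time structure, inter-run alignment
artifacts, shared contaminant proteins, and search-engine scoring
behaviour. Passing the closed-loop tests therefore demonstrates that
the bookkeeping — digestion, matching, collapse, reliability,
inference, quantification — is correct under the stated generative
assumptions; it does not validate identification performance on real
instrument output.

## Problem sizes and determinism

The default closed-loop benchmark uses 20 true proteins (10 families ×
2 isoforms, all present) and the full replicate design, giving roughly
35–40 k evidence rows and >100 k glutamine sites; the digestion oracle
runs 500 random sequences ≤ 60 aa at 0–2 missed cleavages; tree
recovery uses 200 random 4–6-taxon additive matrices. These sizes keep
the whole suite and the acceptance script in the seconds-to-a-minute
range while leaving the statistical checks well-powered (the per-Q
deamidation estimate, for instance, is tested against its 95 %
binomial interval at n > 100 000 sites). Every stochastic component
takes a single integer seed through `numpy.random.default_rng`;
identical seeds give byte-identical FASTA and CSV outputs.

## Known limitations

* Identity is alignment-convention dependent; other gap penalties or
  denominator conventions shift the value by a few points on
  repeat-variable pairs.
* The `repeat_variation` class is annotated by the generator but not
  inferred by the classifier (see above).
* The missed-cleavage budget used for diagnostic discovery defaults to
  0; diagnostic counts grow quickly with the budget because every
  variant then appears in multiple overlapping spans.
* Reliability pooled across platforms is a modelling choice; the
  strict per-platform mode can only reduce identifications.
* No false-discovery-rate machinery: score thresholds are applied to
  already-scored evidence, and decoy searching is out of scope.
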