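# Methods

This note documents the models, conventions and design choices behind
`sh3prm`. It describes what each component computes and under which
assumptions; every number quoted here is produced by the package's own tests
or scripts.

## The recognition model

SH3 domains bind proline-rich motifs (PRMs) through a conserved hydrophobic
groove; canonical class-II ligands follow the register
x(-1)P(0)x(1)x(2)P(3)x(4)+(5), with the anchor prolines at positions 0 and 3
and a positive residue (K/R) at position 5. Typical class-II interactions
are weak (Kd ~20–200 uM) and position 2 usually carries a hydrophobic
residue. The atypical high-affinity mode this package analyzes is the
"Px+P" motif, xPx(K/R)Px(K/R): a positive residue *inside* the PxxP core at
position 2. It is read by SH3 domains of the ASAP/GRAF/SKAP families
("AGS"), whose RT-loop carries a diagnostic Cxx(D/E) sequence — a small
cysteine at the groove-center site (where most SH3 domains have an aromatic
residue, e.g. F165 of SEM5) opens room for the long position-2 lysine, and
the acidic residue three positions later pins its charged tip (C1096/D1099
in ASAP1 numbering). The resulting complexes bind in the ~0.3–10 uM range.

## Motif scanning (`motifs`)

* Windows are 7 residues; all overlapping windows are reported;
  deduplication only for identical (start, class) pairs.
* "+" means K or R only; histidine is not counted as positive.
* Any window containing `X` is voided individually; other windows of the
  sequence are unaffected. Input is case-normalized; characters outside the
  20 standard codes plus `X` are rejected with the offending position.
* Register indices are 1-based; biological numbering is obtained by adding
  an explicit per-sequence offset (`offset=<int>` on FASTA headers).
  Position −2 is included whenever a preceding residue exists.
* Class-I motifs (+xxPxxP) carry no published register subscripts; as a
  package convention the register is anchored on the two prolines (0 and 3)
  and the positive residue is reported at position −3.
* Position-2 hydrophobicity is annotated with the set {A,V,L,I,M,F,W,P}
  (Kyte–Doolittle-positive residues plus proline). It never affects
  match/no-match.
* `classify_window` returns the most specific class
  (Px+P > class-II > class-I > NONE). In *variant mode* it additionally
  recognizes windows matching a class-II/Px+P pattern except for one
  substituted anchor proline (e.g. the APC-like P3→S motif) and reports the
  intact-motif class with the missing anchor flagged — this is what the
  pair-rule engine consumes for substituted variants.

## RT-loop classification (`sh3`)

Diagnostic sites are located by global pairwise alignment to an annotated
reference (BLOSUM62, gap open 11 / extend 1, end gaps free — standard
protein-alignment defaults; end-gap freedom makes the call invariant to
flanking padding). A query scoring below 0.25× the reference self-score is
declared unalignable (UNKNOWN) so that non-SH3 input fails loudly rather
than being classified. AGS requires, on the query side, groove-center C,
acidic-site D or E, and spacing exactly 3 (strict Cxx(D/E); insertions
inside the motif disqualify). H is not accepted at the acidic site. The
four conserved groove aromatics are reported per site; losing two or more
flags a "degenerate groove".

The bundled default reference is a **synthetic SH3-like scaffold**, not a
database sequence: it places the diagnostic C/D at biological numbers
1096/1099 under an ASAP1-style offset (domain span 1087–1147) and annotates
four groove aromatics. All classifier logic is relative to the annotation,
so a user-supplied annotated reference (TSV) substitutes transparently; the
scaffold exists so that the package is testable without downloads.

## Pair rules (`pairs`)

Affinity is categorical (HIGH / TYPICAL / NONE) because the underlying
evidence is class-level: mutational outcomes and per-pair Kd values, not a
continuous response surface. Kd bands are annotations only: HIGH 0.3–10 uM
(upper bound 10 chosen to cover the measured ~0.3–8 uM with margin),
TYPICAL 20–200 uM. The rule order is fixed — terminal charge-reversal rules
first (acidic at position 5; acidic at position 2 against AGS), then the
base label from the class pairing (AGS×Px+P → HIGH, with an "enhanced"
annotation for R at position 2; other class-II/Px+P pairings → TYPICAL),
then a one-level downgrade for a missing anchor proline. Deliberate
conventions where the evidence is silent: the pos2-acidic × canonical cell
stays TYPICAL (flagged untested, since only the AGS pairing was probed);
class-I motifs are assigned TYPICAL under either SH3 class and annotated
untested. An UNKNOWN SH3 classification produces an explicit
"unclassifiable" result, never a default label.

## Complex geometry (`geometry`)

* Contacts: heavy-atom pairs across two chains within 4.5 Å (exact
  Euclidean; configurable). Salt bridges: Lys NZ / Arg NE,NH1,NH2 within
  4.0 Å of Asp OD1,OD2 / Glu OE1,OE2 — common literature conventions.
  Histidine is excluded as a donor because its protonation is unknown.
* PDB input is parsed with gemmi; hydrogens are dropped, alternate
  locations resolve to highest occupancy (first seen wins ties), insertion
  codes are preserved, and malformed ATOM records raise with the line
  number.
* PPII assignment: both dihedrals defined and within ±30° (angular
  distance) of (φ, ψ) = (−75°, +145°) — the standard PPII region; no
  numeric criterion is canonical, so the tolerance is configurable.
* Structure-derived register: the two peptide prolines with the largest
  heavy-atom contact counts to the annotated groove aromatics become
  P0/P3, cross-checked against the sequence register; on mismatch (or when
  the peptide sequence carries no class-II motif) a warning is raised and
  the sequence register wins when one exists.
* All outputs are functions of interatomic distances and torsions, hence
  invariant under rigid-body transforms (verified to 1e-6 Å / 1e-4°).

## Screen (`screen`)

The candidate unit is a protein with at least one Px+P match; the motif
scan therefore always runs, and the three downstream filters
(localization, PPII, conservation) are individually switchable. A config
"motif" flag is accepted for symmetry with the four-stage cascade but does
not change candidacy — with every filter disabled the screen reduces
exactly to the scanner.

* Localization: the protein's label set must intersect the configured
  cytoplasmic labels (default {cytoplasm, cytosol}, case-insensitive).
* PPII: a match passes if register positions −1..5 are all PPII-true under
  user-provided per-residue dihedrals (e.g. from predicted structures);
  running a structure predictor is out of scope by design.
* Conservation: fraction of orthologs whose residues at the match's
  register positions −1..5 are identical to the source, threshold 0.8.
  Orthologs are compared at equal indices (the generator produces
  substitution-only orthologs); a length-mismatched ortholog counts
  against the fraction.
* Missing data fails the corresponding filter (fail-closed) with a
  config switch to fail-open.
* Audit: each candidate records per-stage flags and, if eliminated, the
  first enabled stage that failed; final passes plus eliminations
  partition the candidates.

Enrichment is the exact hypergeometric upper tail per term with
Benjamini–Hochberg q-values across tested terms; a term passes at
p < 0.01, count ≥ 3 and enrichment factor (k/n)/(K/N) > 1.5. The
background is the screened universe (the input proteome), not an external
annotation database — a deliberate, documented divergence from web-service
enrichment tools. The network summary (connected components, degrees,
cross-class edge count) consumes a user-supplied edge list; no external
interaction database is queried.

## One-site ITC (`itc`)

Forward model and fitting as documented in the module docstring: perfusion
dilution with factor (1 − v/V0) per injection, one-site quadratic for the
bound concentration, heats normalized per mole of injectant with a fitted
constant baseline offset (blank-titration handling is instrument-specific,
so a constant is the neutral choice). Defaults follow the measurement
protocol the package is anchored to: 400 uM syringe, 40 uM cell, 19 × 3 uL
injections; the 200 uL cell volume is the instrument-typical value and is
configurable.

A subtlety of the displacement model: liquid pushed out of the cell before
saturation carries unbound titrand away, so the cumulative heat is a few
percent below N·M0·V0·ΔH even in the tight-binding limit (about 5% under
the default protocol). The tight-binding tests therefore check against an
independent mole-tracking oracle rather than the naive total.

Fitting is bounded nonlinear least squares over (N, log Kd, ΔH, offset);
the log-parameterization enforces Kd > 0 and gives scale-invariant steps.
Initialization: N = 1, ΔH = first-injection heat, Kd = M0/10. Standard
errors come from the Jacobian at the optimum (delta method for Kd);
singular Jacobians and non-convergence are flagged, never silent. A
c-value N·M0/Kd below 1 flags the fit "low-c" with a protocol suggestion.
Under the default protocol with 1% relative heat noise, the median fitted
Kd over 20 seeded replicates stays within 10% of truth for generating Kd
from 0.3 to 100 uM (the 100 uM case is low-c and visibly noisier).

## Synthetic data (`synthetic`)

The generators define the conditions under which the pipeline is tested:

* Proteomes: background residues i.i.d. from a uniform table by default
  (maximally transparent tests) with a Swiss-Prot-like composition switch
  (stresses false-positive behavior); motifs planted at interior positions
  with the full register recorded. Final sequences are re-scanned so
  spontaneous background matches enter the truth table; an optional
  rejection-resampling mode removes spontaneous Px+P matches when exact
  per-class counts are needed (the screen fixture uses it).
* The screen fixture plants the nested cascade 50 proteins → 12 with
  motifs → 8 cytoplasmic → 6 PPII → 5 conserved, with mixed flags off the
  nested chain so all 16 filter subsets have informative expectations.
* Annotations: enriched terms are planted among motif-positive proteins at
  probability min(ratio × base, 0.95) vs base 0.1 in the background; the
  power/null simulations use a 200-protein universe with 30 selected and
  ratio 5, which gives the planted term >95% detection at the standard
  thresholds while null terms pass ≤2% of the time.
* Orthologs: i.i.d. substitutions at a configurable rate; motif windows
  held invariant when conserved, or forced to carry ≥1 substitution per
  ortholog otherwise.
* Structures: ideal-geometry backbones (N–CA 1.458 Å, CA–C 1.525 Å,
  C–N 1.329 Å, standard angles, ω = 180°) built by sequential internal-
  coordinate placement at uniform (φ, ψ); dihedrals recomputed from the
  coordinates match the generating angles within 1°. The pseudo-SH3 chain
  is a minimal marker cloud, not a folded domain: PHE pseudo-ring atoms
  within 4.0 Å of the anchor-proline sidechains and ASP carboxylates
  within 3.5 Å of the position-2/5 terminal amines — contact, salt-bridge
  and register logic need distances, not a fold, and markers keep fixtures
  exact and tiny.
* One global seed fans out to per-generator streams via
  `default_rng([stream_id, seed])`, so each data type is independently
  reproducible.

What the synthetic data does *not* emulate: realistic domain folds, motif
sequence context (real PRMs sit in disordered proline-rich regions),
phylogenetically structured ortholog divergence, annotation noise, or
instrument-specific ITC baselines. Passing tests therefore demonstrate
correctness of the algorithms under controlled truth, not performance on
real proteomes or thermograms.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the checks
exact and quick: 1,000 random 200-mers for scanner/oracle equivalence, a
50-protein planted proteome for the screen, a 200-protein universe × 100
replicates for enrichment simulations, 20 seeded structures for register
recovery, and 20 titration replicates per affinity regime.

## Known limitations

* The classifier maps diagnostic sites through a single pairwise
  alignment; highly divergent but genuine SH3 domains may be declared
  UNKNOWN (by design, loudly).
* The rule engine is qualitative; it does not interpolate Kd within bands
  and encodes untested cells by convention (flagged in rationales).
* The conservation filter assumes positionally aligned orthologs; indels
  require pre-alignment upstream.
* The ITC model is strictly one-site; multi-site or sequential binding,
  raw-thermogram integration and instrument-file parsing are out of scope.
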