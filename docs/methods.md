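# Methods

`cglrkit` implements the desk-scale computational pipeline behind a
kingdom-wide cGAS-like receptor (cGLR) discovery and biochemical screen:
motif-based curation of candidate enzymes, isoelectric-point classification
of their predicted ligand preference, combinatorial identification of
cyclic dinucleotide (CDN) products from orthogonal assay readouts, binding
isotherm analysis of STING–ligand titrations, and family-level census
summaries. This note documents the models, the defaults and why they were
chosen, and what the synthetic-data generators do and do not emulate.

## Motif grammar and curation

The active-site signature of catalytically competent cGLR/CD-NTase enzymes
is written in a degenerate mini-language:

    h[QT]GS [X8-20] [DE]h [DE]h [X50-90] h[DE]h      (active site)
    G[S/G]                                            (activation loop)
    [E/D]h[E/D] [X50-90] [E/D]                        (catalytic triad)

Uppercase letters are fixed residues, brackets enclose residue classes
(`/` is cosmetic), lowercase letters reference named classes, and `[Xm-n]`
is a spacer of m..n residues (inclusive) strictly between the flanking
anchors. The hydrophobic class `h` is not universally standardized; the
shipped default is the Kyte–Doolittle-positive set {A, C, F, I, L, M, V,
W, Y}, configurable in `data/patterns.yaml`.

The scanner enumerates **every distinct anchor placement** by depth-first
search over gap lengths, deduplicating placements that differ only in how
an anchor-free spacer is apportioned. Coordinates are 0-based half-open.
Non-standard residue codes (B, J, O, U, X, Z, `*`) never satisfy an anchor
— not even a class listing all 20 standard residues — but do count toward
spacer lengths; this is the conservative choice for curation, where an
ambiguous residue should not certify an active site. The test suite pins
the scanner to an independent oracle that expands every gap combination
into a concrete regular expression.

Curation retains a sequence iff (1) all three motifs each place at least
once, and (2) two externally supplied boolean flags — NTase-core/helix-
bundle homology and predicted structural homology — are true. Those two
criteria depend on profile alignment and structure prediction tools that
are deliberately out of scope, so they are consumed as annotation columns
and never defaulted: a missing flag is an error naming the record. Whether
the activation loop and triad are separate criteria or facets of the
active-site criterion is ambiguous in practice; the strict reading (all
three required) is the default and `required_motifs` relaxes it.

Redundancy removal mirrors the published thresholds (minimum identity
0.95, minimum coverage 1) with a deterministic greedy centroid scheme:
sequences sorted by descending length (ties by id) join the first
representative within threshold, computed from a global alignment with
unit match score, zero mismatch, and affine gap penalties open=5/extend=1.
Identity is exact matches over alignment columns; mutual coverage is
min(len)/max(len), so full coverage restricts merging to equal-length
pairs, matching the intent of full-coverage clustering.

## Isoelectric point

Net charge is the Henderson–Hasselbalch sum over side chains of D, E, C, Y
(acidic), H, K, R (basic), one N- and one C-terminus; it is strictly
decreasing in pH and composition-only. pI is found by bisection on
[0, 14] to a bracket width of 1e-3 pH units (the termini guarantee a sign
change). The pKa constants of the cited pI implementation are not
published; the shipped default is the EMBOSS table, named and versioned in
`data/pka_tables.yaml` and swappable, because common tables disagree by up
to ~0.3 pH units — reported pI values are therefore meaningful only
together with the table name, and the classifier thresholds (basic > 8.5
= nucleic-acid-sensor-like, < 7.0 = acidic, strict inequalities) are
parameters, not constants of nature.

## CDN space, masses and screen inference

Candidates are unordered pairs of (base, 2'/3'-donor) units joined
cyclically: 4 linkage isomers per heterodimer base pair, 3 per homodimer,
36 molecules over {A, C, G, U} with 10 distinct formulas. Free-acid
formulas are NMP + NMP − 2 H2O; linkage isomers are constitutional
isomers with identical formulas. Average and monoisotopic masses use
atomic constants pinned in `data/atomic_masses.yaml` (IUPAC 2021 weights,
AME2020 isotope masses) so that two-decimal agreement with reported
molecular weights is reproducible; for cyclic UMP–AMP this gives
C19H23N7O14P2, 635.38 g/mol, [M−H]− at nominal m/z 634 and [M−2H+Na]− at
656. Nominal m/z rounds half away from zero; rounded monoisotopic and
nominal coincide for these compositions, so both readings of integer ESI
values are satisfied.

Screen inference applies four bond rules: the α-phosphate of base X sits
on X's 5' carbon (inside the bond donated by its ring partner); a bond
whose donor is a 3' hydroxyl is nuclease-P1-cleavable while a 2' donor
bond is protected; P1 cleavage exposes a terminal 5'-phosphate that CIP
removes; a base's radiolabel survives P1+CIP iff at least one of its
α-phosphates sits in a protected bond. The α-phosphate convention is fixed
by the unambiguous chemical nomenclature c[U(2′,5′)pA(3′,5′)p] for
2′3′-cUA: under it the **adenosine** phosphate sits in the protected 2′–5′
bond (A retained, U lost). Narrative descriptions of which base's
phosphate occupies which bond sometimes invert this assignment; the
chemical name is authoritative here and the discrepancy is noted rather
than resolved by guesswork.

With a binary per-base retained/lost readout, the 2′2′ and 2′3′ homodimers
of a base are provably indistinguishable by the full panel (same base set,
both CIP-resistant, same formula, and both retain the label — the mixed
homodimer keeps one of its two identical phosphates). Inference therefore
guarantees *containment* (the true product is always in the consistent
set) and *singleton recovery exactly for the 28 non-degenerate candidates*;
`distinguishability_report` names the four degenerate pairs explicitly, and
adding evidence fields never enlarges a consistent set. Partial
observations constrain only the fields they provide; mass matching
defaults to ±0.5 Da for integer (nominal) observations and ±0.02 Da for
decimal ones.

## Binding isotherms

EMSA titrations are fit to the single-site isotherm f(c) = c/(c + Kd)
under the trace-ligand approximation (probe at tens of nM against protein
up to tens of µM, so free ≈ total protein); no Hill coefficient, no
depletion correction. Kd is estimated by deterministic least squares on
log10 Kd — a 400-point grid spanning [min conc/100, max conc×100] followed
by bounded scalar refinement (xatol 1e-12) — which enforces positivity and
makes the estimate exactly equivariant under rescaling of the
concentration axis. Degenerate curves (all-zero, saturated, flat) return a
non-converged fit with a diagnostic instead of raising. Published
affinities in this setting are qualitative preference rankings rather than
printed Kd values, so correctness is established by parameter recovery:
noiseless curves recover Kd to <1e-6 relative error, and at Gaussian noise
sd 0.05 the median relative error over 100 seeded replicates is about 10%.

## Census summaries

Copy-number tables count curated cGLR/STING records per species over an
explicit roster (zero rows preserved; off-roster records are errors) and
reduce to a frequency matrix over (n_cGLR, n_STING) pairs whose total
always equals the roster size. Architecture prevalence reports percentage
shares within a family and folds every architecture strictly below the
threshold (default 0.5%) into "Other", so retained shares plus "Other"
sum to 100. Architectures are consumed as labels; domain detection, and
the database-snapshot-dependent headline counts (thousands of receptors
across hundreds of species), are out of scope — an `exclude_families`
parameter supports dropping Mab21-like records where a figure calls for it.

## Synthetic data

Every generator is a pure function of its parameters and an integer seed
(NumPy `default_rng`, one stream per generator): identical calls give
byte-identical output.

* **Proteomes** plant one motif realization (gap lengths uniform in
  bounds) at a uniform offset in uniform-composition background of
  250–450 residues (the typical single-domain receptor length range) and
  record the anchor spans; decoys are composition-matched shuffles
  rejection-resampled until the scanner finds nothing, so specificity on
  decoys is 1 by construction. Real proteomes have biased composition,
  homologous near-motifs and domain structure; passing here certifies the
  scanner's combinatorics, not discovery performance on real data.
* **Screen observations** are a product's predicted signature restricted
  to a field subset, optionally with Gaussian m/z jitter.
* **Binding curves** sample f(c) + N(0, sd) truncated to [0, 1] (flagged)
  on 8 half-log-spaced concentrations spanning 0.5 nM–50 µM, the titration
  range used in the assay this emulates; the default noise sd of 0.05 is a
  typical gel-quantification error scale.
* **Census tables** draw per-species copy numbers and per-record
  architectures from explicit normalized distributions and record the
  realized truth exactly.

## Numerical choices and limitations

* Scanning is exponential in principle but bounded in practice by anchor
  pruning; patterns with enormous joint gap spaces on long sequences are
  the user's responsibility.
* Bisection tolerance 1e-3 pH; the grid oracle in the tests certifies
  agreement to tol + grid resolution.
* Ties in clustering are broken by length-then-id ordering; the scheme is
  order-deterministic but, like all greedy clusterings, not globally
  optimal.
* `fraction_bound` values outside [0, 1] are clipped with a flag rather
  than rejected, since over-range densitometry is routine.
* Reproduction of the published acidic-receptor pI (5.0) requires the
  synthesized-sequence supplementary table, which is not redistributed;
  the corresponding check activates when that FASTA is placed at
  `data/sd3_synthesized_sequences.fasta`, and the value is table-dependent
  (computed with the shipped default pKa set, one-decimal rounding).
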