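# Methods

This note documents the models and numerical choices behind `modmt`,
what the synthetic-data generators do and do not emulate, and the known
limitations.

## Sequence statistics and the MT screen

A metallothionein candidate is screened on two composition rules: the
cysteine fraction must reach `min_cys_fraction` (default 0.15, well
below the 23–27% of real fungal MTs, so true positives are not lost to
length effects) and the sequence must contain no aromatic residues
(F/W/Y). Histidine and methionine are counted separately: His is a
potential metal ligand and Met feeds the sulfur budget for ICP
quantitation; neither disqualifies an MT. A Cys is "in a CXC motif"
when either neighbor two positions away is also Cys; X may itself be
Cys (in `CCC` the window (1,3) exists), and each Cys counts once even
when shared by two windows. Percentages are reported to one decimal
with no rounding adjustments.

Average masses use one pinned atomic-weight table (IUPAC 2005 vintage:
H 1.00794, C 12.0107, N 14.0067, O 15.9994, S 32.065) applied to
standard residue formulas, plus one water per peptide; the zero-residue
limit is water, 18.02 Da. Two independent routes — a frozen numeric
residue-mass table, and element-wise formula accumulation — agree to
well under 0.01 Da and are cross-checked against pyteomics in the test
suite. Monoisotopic masses, isotope envelopes and post-translational
modifications are out of scope.

## Cys-box decomposition

The tandem building block of long fungal MTs is modelled as a *gap
signature*: the ordered inter-Cys spacings of the consensus
`CXCX3CSCPPGXCXCAXCP`, i.e. [1,3,1,4,1,2]. Matching is
spacing-based rather than regex-based because homologous boxes vary in
spacing (the 26-mer paradigm MT carries [1,5,1,3,1,2]); the per-gap
tolerance of ±2 admits exactly that variation while rejecting unrelated
Cys runs. Scores are in base units: one per mandatory Cys placed (7 for
a full box), plus conserved-residue bonuses of weight 1 for the Ser of
the central CSC, the Pro-Pro-Gly after the second CXC, the Ala in the
penultimate gap and the Pro after the last Cys, and weight 0.5 for
charged residues (K/R/E/D) flanking the box. A degenerate 6-Cys box is
the same profile with exactly one mandatory Cys unmatched (base 6 — a
one-unit penalty); no separate 6-Cys consensus exists, so this is the
least-assumption model. Gaps disturbed by the missing Cys are not
bonus-scored, since their internal geometry is ambiguous.

Segmentation maximizes total box score over non-overlapping candidates
by weighted-interval dynamic programming; the test suite checks the DP
total against exhaustive subset enumeration on short proteins. Ties
break deterministically: leftmost start, then higher score, then
shorter box. Box coordinates are 1-based inclusive and anchored on the
first and last matched Cys (box termini are unscored); converters to
0-based half-open are provided. The Cys-conservation invariant — box
Cys plus unassigned Cys equals total Cys — holds on every input because
candidate windows are consecutive runs in the Cys list. A consensus
instance whose X position happens to be Cys would break the window's
gap vector and be matched differently; this is a known, accepted
limitation of spacing-based matching.

## Spliced alignment and gene models

Alignment is seed-and-chain: exact k-mer anchors (default k = 15) are
grouped by diagonal (genome offset − cDNA offset), merged into runs
while consecutive anchor starts are within 3k (the shadow of a couple
of mismatches), and chained collinearly. A zero diagonal jump continues
the same exon; a positive jump is a candidate intron and must lie
within [`min_intron`, `max_intron`] (defaults 40/5000 bp, bracketing
plausible fungal introns). Keeping distant same-diagonal anchor runs as
separate blocks matters on modular proteins: tandem repeats produce
occasional spurious k-mer collisions between boxes, and folding them
into one span would corrupt the chain.

The exact exon boundary inside each junction's ambiguity window (one
seed length to each side) is resolved by scanning split points left to
right and taking the first placement that yields a GT donor and AG
acceptor with the minimum local mismatch count; with enforcement off,
the leftmost minimum-mismatch split wins regardless of dinucleotides.
This rule is deterministic, recovers planted boundaries exactly in
canonical cases, and raises an explicit non-canonical-splice error
naming the junction otherwise. `max_mismatch_rate` defaults to 2%,
comfortably above the ~1.25% polymorphism observed between
independently sequenced strains of the same fungus. N bases never seed
anchors and are mismatch-neutral in extension. Both strands are
searched; minus-strand hits are reported on the forward scaffold axis
with donor/acceptor given on the transcribed strand. Coordinates are
0-based half-open internally and 1-based inclusive in GFF3 (re-import
round-trips through gffutils).

Coding validation finds the first ATG with an in-frame stop and checks
coding length = 3·(aa+1); missing ATG, missing stop and frame
violations each produce an explicit diagnostic — these are precisely
the symptoms by which a 5'-truncated gene annotation is recognized.
Promoter scanning matches IUPAC-degenerate motifs on both strands with
offsets counted from the A of the ATG as +1 (no position 0): a motif
whose first base lies 38 bases upstream has offset −38. The default
motifs, TATAWAW (TATA box) and TGCRCNC (metal-response-element core),
are standard consensus choices and config-overridable; reported
offsets are therefore consensus-dependent.

Ab initio gene prediction, branch-point modelling and multi-gene
scaffolds are out of scope (one locus per run).

## Metal stoichiometry and ICP quantitation

Holo-species masses follow native-MS neutral-mass bookkeeping: each
bound ion displaces protons equal to its charge, so Zn(II)/Cd(II) add
A − 2·1.00794 and Cu(I) adds A − 1.00794 Da (increments 63.364,
110.398 and 62.538 Da respectively). Acid-labile sulfide ligands are an
opt-in extra dimension adding 32.065 Da with no proton displacement.
Assignment enumerates all stoichiometries inside explicit bounds
(default cap: ⌈Cys·5/7⌉ + 10 total metals, from the densest relevant
cluster packing Cu₅S₇) — species here carry at most a few tens of
ions, so brute force is exact and fast — and keeps candidates within a
relative tolerance of 0.1%, the stated instrument error class.

Zn and Cu increments differ by 0.826 Da per ion. When both metals are
in play and the best candidate's combined Zn+Cu loading n satisfies
n·0.826 ≤ tolerance, the species is reported as the composite "Mₙ"
with `ambiguous_ZnCu` set; at a 25.4-kDa apo mass this fires for
n ≲ 30 and not at the Cu₄₁/Cu₄₂ loadings, matching how practitioners
report such spectra. Peaks are assumed already deconvoluted to neutral
masses; charge-state deconvolution and isotope fitting are out of
scope.

ICP-AES protein quantitation assumes every measured S atom comes from
the construct's Cys + Met (for a recombinant GS-extended peptide, the
extension counts): [protein] = [S]/s_atoms, metal ratios by division.
The Met count is an explicit input, never assumed.

## Cu(I) capacity and the loading series

The capacity model is additive: each 7-Cys box folds an independent
Cu₅ cluster, each 6-Cys box a Cu₄ cluster ([Cu₄S₆] and [Cu₅S₇] are the
classic stable Cu-thiolate model cores), and each box-unassigned Cys
contributes between 0 and 1 Cu — one per Cys being the loosest bound
consistent with Cu:S ≤ 1 in those cores. The six-plus-two architecture
with three spare Cys thus predicts majors in [38, 41]; consistency
reports accept observations up to max+1 to allow the ubiquitous one-Cu
satellite. The titration loading series is modelled as
architecture-independent — doublets (4k, 4k+1) for k ≤ 3, then +5 per
step — because the doublet-to-box mapping (4 ↔ 6-Cys filling, 5 ↔
7-Cys filling) is an interpretation, not a measurement. The
experimental series lists a lone Cu₃₃ where the +5 rule gives (32,33);
the generator follows the rule and the discrepancy is noted in the
series docstring. Thermodynamics, cooperativity and divalent-metal
stoichiometry prediction are explicitly out of scope: Zn/Cd loading
produces unfavored species mixtures that resist a capacity model.

## Growth normalization

Each (strain, dose) condition is summarized by the replicate mean and
SD; percent of control is 100·mean(dose)/mean(control) with the control
defined as the strain's zero-Cu condition, and percent SD propagates
the treated condition's replicate spread against the control mean (the
usual error-bar convention, not a ratio-distribution correction).
Concentration units are carried verbatim. Dose–response fitting (IC50,
4PL) is out of scope.

## Synthetic data: what it emulates, and what it does not

Generator defaults are the reference conditions of the system being
modelled: architecture 6×7-Cys +
2×6-Cys + 3 prefix Cys (57 Cys); box X-positions drawn from small/polar
residues weighted toward Gly/Ala; Cys-free linkers of 4–8 residues;
genes with 9 GT..AG introns of 48–204 bp splitting the transcript into
exons of 63–105 bp; a 69-bp 5'UTR; spectra at 0.02% relative mass
error (5× below the assignment tolerance); triplicate growth readings.
Reverse translation draws synonymous codons seeded-uniform (no
species-specific codon-usage table is claimed); scaffold flanks are
uniform-random at 50% GC, with promoter plants overwriting flank/UTR
bases at the requested ATG-relative offsets (a plant may not overlap
the CDS). Two generator-side constraints keep round trips exact by
construction rather than by tuning: 5'UTRs are drawn ATG-free (an
upstream ATG would shift coding-span detection), and intron termini are
re-drawn until every junction has a unique zero-mismatch GT..AG split
(otherwise boundary sliding is genuinely ambiguous and the aligner's
leftmost rule could legitimately disagree with the plant). Planted
cDNA polymorphisms spare the start/stop codons and a ±4 window around
junctions.

Passing parameter-recovery tests therefore shows that each analysis
stage exactly inverts its generator under the stated noise — it does
not show robustness to features real data have and the generators lack:
repetitive or GC-skewed intergenic sequence, non-canonical splice
sites, RNA editing, overlapping genes, peak-intensity baselines, or
adduct chemistry in spectra.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic or
printed inputs: 200 architecture round trips, 100 gene round trips
(~3.5-kb scaffolds), 1000 simulated peaks, 500 dual-route mass checks,
and exhaustive DP-vs-enumeration checks on proteins ≤ 80 aa with ≤ 16
candidate boxes — sizes chosen so the full battery completes in
seconds while exercising every code path at the default conditions.

## Known limitations

- Box matching is anchored on Cys spacing; boxes whose X positions
  contain Cys, or families with different gap signatures, need their
  own `BoxProfile`.
- The aligner assumes one collinear locus; paralogs or tandem gene
  copies on one scaffold can distract the chain.
- The Zn/Cu ambiguity rule compares whole-content swaps; partial-swap
  ambiguity (e.g. Zn₁₀Cu₅ vs Zn₉Cu₆, 0.826 Da apart) is intrinsic to
  the mass measurement and always below tolerance — candidates are
  ranked, not uniquely resolved.
- Accession-derived validation (the real 257-aa protein, its cDNA and
  scaffold) requires fetching database records; the suite's
  accession test documents the required snapshot files and fails
  cleanly when they are absent.
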