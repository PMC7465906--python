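# Methods

This note documents the models and procedures implemented in
`regionstrat`, the defaults they use, and the choices made where the
design was genuinely open.

## Age model

Ages are discrete strata on a nested taxonomy ladder, youngest first:
Mammalia ⊂ Vertebrata ⊂ Eumetazoa ⊂ Opisthokonta. Raw node labels
(e.g. "Sarcopterygii", "Bilateria", "Amniota") resolve to strata through
an extensible label map; an unknown label is a hard error rather than a
guess, because silently mis-binning a clade shifts ages by whole strata.

*Gene age* is the stratum of the gene-tree root. *Region age* is the
stratum of the deepest last common ancestor (LCA) of the human reference
leaf and any homolog whose conservation verdict is positive. "Most
distant conserved relative" is operationalized as deepest LCA rather than
the raw taxonomy of the hit species: this makes ortholog and paralog
evidence uniform — a conserved paralog that split at an ancient
duplication node pushes the region's age to that node. Two safeguards
replace manual curation: a stratum attained by a single supporting leaf
is flagged `single-witness`, and a region with no conserved homolog at
all is scored at the youngest stratum with a `reference-only` flag.
Because every LCA with the reference lies on the reference's root path,
region age can never exceed gene age, and adding a conserved verdict can
only deepen it (both are property-tested).

## Conservation call

For each homolog the region is read off the alignment columns of the
reference interval (gap columns recorded, never skipped). A position is
*similar* when the BLOSUM62 score between reference and homolog residue
is non-negative; gaps and ambiguity codes (X) are never similar. The
region is *conserved in that homolog* when similar positions carry
strictly more than 50 % of the region's missense mutations — an exact
50/50 split is not conserved, and a region with zero missense weight
returns not-conserved with an explicit `no_weight` flag instead of
dividing by zero. Mutation weighting is the point of the statistic:
heavily mutated residues are the ones whose conservation matters.

Region-level summary curves use a per-position conservation defined as
the fraction of homolog rows similar (or, in identity mode, identical)
to the reference at that column. The average runs over positions with at
least `min_mutations` missense counts (tiers 1, 15, 25); positions are
thresholded, not weighted, by default — weighting is available behind a
flag (`weight_by_mutations`) since the summary definition admits either
reading. When no position qualifies the summary is marked empty rather
than zero. Because the BLOSUM62 diagonal is strictly positive, identity
implies similarity, so the identity-mode average can never exceed the
similarity-mode average (property-tested on random alignments).

Dataset filters mirror the curation rules of the packaged region set:
regions with fewer than 15 missense mutations are dropped, as are regions
whose in-frame indel count strictly exceeds their missense count
("primarily indel-mutated" read as strict majority). The packaged fixture
already encodes the upstream exclusions (the CDKN2A-ARF isoform, mixed
ordered/disordered proteins, histone merging), so they are not
recomputed.

## Alignment

The built-in aligner is a progressive profile–profile
Needleman–Wunsch–Gotoh: global, affine gaps, sum-of-pairs column scoring
against BLOSUM62, profiles merged in post-order of the gene tree used as
guide. Defaults are gap open 11, extend 1 (a gap of length L costs
11 + L·1); terminal gaps are charged like internal ones. The guide tree
is the gene tree's topology rather than a distance-based re-estimate —
the tree is always present in this pipeline and reusing it removes a
stochastic stage. Dynamic-program ties break deterministically in the
order match > delete > insert, so alignments are byte-stable. Direct
transitions between the two gap states are disallowed (standard Gotoh).
Gap characters inside a profile column contribute nothing to the match
score and are not re-penalized when merging.

Externally produced alignments (aligned FASTA, e.g. from MAFFT) can be
imported and take precedence over the built-in aligner; the built-in
path exists so that the pipeline has no external-binary dependency. No
attempt is made at iterative refinement or local alignment.

## Profile scan

Alignment of disordered sequence is unreliable, so every conservation
call is corroborated by an alignment-free check: a gapless log-odds
profile built from the region instances of the reference and of
conserved homologs whose divergence from the reference is within the
Vertebrata stratum, scanned exhaustively along each homolog. Column
scores are `log2(((count_a + pc·bg_a)/(N + pc))/bg_a)` with pseudocount
weight 1 and uniform background; columns gapped in a majority of training
instances are dropped, minority gaps reduce the column's N. The hit
threshold is calibrated per profile as 60 % of the minimum training
self-score — a deliberate, documented substitute for an external
profile-HMM engine's E-value, which this package does not reimplement
(the scanned unit is short and fixed-length, so a PSSM without indel
states suffices for corroboration; an HMMER3 text profile can be plugged
in through the JSON serialization if desired). Scan ties go to the
smallest offset. When fewer than two training instances exist the scan
is skipped and the conservation call stands alone.

Agreement between the two evidences yields the verdict; disagreement
yields `conflict`, which downstream aging treats as not conserved but
reports per region — the deterministic replacement for manual review.
This AND-combination is what keeps false-positive conservation calls on
pre-birth lineages (which occur at an appreciable rate, since a single
heavily-weighted position being coincidentally similar can tip the
weighted fraction) from inflating region ages: a random region scores
far below the calibrated profile threshold.

## Emergence classification

Classification uses only leaf presence verdicts; ancestral states are
never imputed (no Fitch-style reconstruction, by design). With the
emergence node E (from region aging):

* no duplication node anywhere in the family → **singleton**;
* carriers outside E's clade → **ambiguous** (inconsistent with a single
  birth; left for review, mirroring uncategorizable real cases);
* E itself a duplication with carriers in both child clades, or a
  duplication below E on carrier lineages with carriers in both child
  clades → **de novo, pre-duplication** (the region predates the
  duplication);
* nearest duplication ancestor D of E with presence confined to E's side:
  zero intervening speciation nodes → **neofunctionalization**; one or
  more → **de novo, post-duplication** (the intervening count is
  reported);
* carriers on both sides of D while E lies strictly below it →
  **ambiguous**;
* otherwise → **de novo, no duplication context**.

"Directly after a duplication" needs a window; zero intervening
speciations is the strictest reading and is what the synthetic scenarios
encode. Fate looks strictly below E: no duplication on carrying lineages
→ *not duplicated*; otherwise *spread_all* if every leaf under every
post-emergence duplication carries the region, else *partial_loss* (the
losers are listed). Note a speciation-level loss under a post-emergence
duplication also reads as partial loss — with leaf-only evidence the two
are indistinguishable, which is a documented limitation.

## Synthetic families

The generator emulates the data structure the pipeline consumes in the
wild: a ladder species tree (defaults: 3 mammals, 2 extra vertebrates,
2 eumetazoans, 1 opisthokont — human, mouse, dog, chicken, zebrafish,
fly, hydra, yeast), optional whole-clade duplications, and a planted
region. Scenario presets pin the ground truth: neofunctionalization
(vertebrate-clade duplication, region born on one copy's crown branch),
de novo pre-duplication (birth at the vertebrate crown, mammal clade
duplicated later), de novo post-duplication (eumetazoan duplication,
birth later inside one copy), singleton (no duplication); `loss_branches`
degrades the region on chosen branches to create partial-loss fates.

Sequence evolution is i.i.d. per site per edge: substitution probability
0.08 in flanks and 0.01 in the region (the conserved island; the config
rejects the reverse ordering), replacement residues drawn proportional
to exp(BLOSUM62/2) so substitutions favour similar residues. Indels
(rate 0.02 per flank per edge, lengths 1–3) occur only in flanks,
keeping the region's reference coordinates exact by construction while
still stressing the aligner. Pre-birth lineages carry ancestral random
content at the region columns, evolving at the flank rate — unrelated to
the planted region, so profile scans have a clean negative class.
Mutation tables place exact missense counts at three hotspot offsets
(25/18/16 by default, comfortably above the 15-mutation floor) plus
Poisson(0.5) background. One RNG stream per family, keyed by
(seed, family id), makes every family independently reproducible.

These defaults were chosen once as a plausible desk-scale analogue of a
deeply conserved disordered region in a ~280-species supertree: roughly
6–8 edges root-to-leaf, ≈ 60–95 % pairwise flank identity and ≥ 94 %
region identity across carriers. What the simulations do **not** model:
codon-level evolution and selection (dN/dS), region-internal indels,
alignment ambiguity of low-complexity sequence, gene-tree reconstruction
error, and COSMIC's mutation-count heterogeneity. Passing the recovery
tests therefore shows the inference chain is correct under its stated
assumptions, not that real supertrees are this clean.

## Numerical and interface choices

* Coordinates are 1-based inclusive everywhere user-visible; only
  alignment internals use half-open indices.
* Single-residue hotspots are widened by ±7 residues (clamped) unless
  the functional-unit annotation carries explicit motif bounds, which
  win.
* Selection sites are kept at posterior strictly greater than 0.9;
  interval membership is inclusive on both ends (the VHL site at 141,
  between regions 54–136 and 144–193, pins this convention and is a
  regression test). "Highly mutated residue" defaults to ≥ 15 missense
  mutations, reusing the dataset floor, and is a flag.
* Pipeline reports serialize with sorted keys and no timestamps;
  identical config + seed gives identical bytes.
* Cohort sizes in the acceptance script (50 families per scenario) give
  recovery-rate estimates with a binomial standard error of about 1.4
  percentage points per scenario at the observed rates.

## Known limitations

Beyond the simulation gaps above: the profile threshold is a calibration,
not a statistical significance level; conservation averaging is
reference-anchored (a deeply diverged homolog set drags every position
equally); duplication/speciation events are taken from the input NHX
annotations at face value, with no reconciliation against a species
tree; and ambiguous emergence calls are terminal — no probabilistic
model attempts to resolve them.
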