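# Methods

## Problem and model

Given m protein kinases, n small-molecule inhibitors and an m x n binary
binding matrix from an ATP-site competition screen, the toolkit predicts
whether an unseen (kinase, inhibitor) pair binds.  Each pair is an instance
whose feature vector is the concatenation of a kinase feature row and an
inhibitor feature row; a standard classifier (pruned decision tree, or SVM
with linear / quadratic / RBF kernel) is trained on labelled pairs.  The
interesting statistical question is not the classifier but the evaluation
geometry: how much information about the two test molecules is allowed into
training.  The framework implements four leave-one-out variants over the
matrix — hard ((m-1)(n-1) training pairs sharing neither molecule with the
test pair), soft (all mn-1 other pairs), and mixed / mixed-mixed (hard-case
training plus r_k pairs pairing other kinases with the test inhibitor and
r_i pairs pairing the test kinase with other inhibitors) — plus a
restricted-training probe that keeps only the (m-1)+(n-1) pairs containing
a test molecule.

## Kinase features

* **STTK / PC** — nominal annotations: Ser/Thr-vs-Tyr class, phylogenetic
  group, family.
* **PRO** — presence bitvectors of user-supplied PROSITE-syntax patterns.
  The supported subset is residue letters, `x`, `[..]`, `{..}`,
  `elem(n)` / `elem(n,m)` and the `< >` anchors; anything else is rejected
  loudly rather than silently mis-matched.
* **Apri** — frequent contiguous residue patterns mined level-wise with
  pattern merging.  Up to two single-residue wildcards are allowed, never at
  the ends; support counts each sequence once.  The candidate space
  internally admits end wildcards because the suffix/prefix merge otherwise
  cannot reach interior-wildcard patterns (A?C needs intermediates A? and
  ?C); support remains anti-monotone in that space and end-wildcard
  patterns are filtered from the output.  The solution set is reduced to
  *border elements*: patterns with no frequent proper super-pattern.
  Defaults: minimum support 50% of the corpus, minimum size 3, maximum
  length 10 — the source screen reports only its final feature counts, so
  these are configuration keys, not claims.
* **glAli / locAli** — per-kinase vectors of alignment scores against every
  kinase.  glAli is full-length Needleman-Wunsch under a linear gap model
  ("uniform costs for gap opening and extension" is read as opening =
  extension); default gaps are -8 with PAM120 and -4 with BLOSUM62.  locAli
  scores only *frames*: windows of +-5 columns around MSA columns that are
  both highly conserved (one residue in more than ~88.5% of rows, the
  113-row rule "more than 100 of 113" generalized to a fraction) and marked
  active-site; overlapping windows merge.  Column-wise scoring charges the
  gap penalty when exactly one row has a gap and 0 for gap-gap, which keeps
  self-scores maximal; optionally each frame pair is degapped and
  re-aligned globally instead.
* **PSF / abPSF** — the residue (or its physico-chemical class) at each
  active-site MSA column, as nominal features; a gap is its own category.
  The default 5-class map (hydrophobic AVLIMC, aromatic FWY, polar STNQGP,
  positive KRH, negative DE) is overridable by file.

## Inhibitor features

* **PT / MS** — nominal primary-target and 2D-structure-cluster annotations.
* **FTs** — maximal frequent free trees: connected acyclic substructures
  matched by element and bond order via subgraph monomorphism, support
  counted once per molecule, default minimum frequency 10%.  Mining is
  level-wise with occurrence-based one-leaf extensions; a pattern is maximal
  iff no one-leaf extension is frequent (any larger frequent supertree would
  contain one).  Canonical forms are centroid-rooted sorted encodings
  (lexicographic minimum over the 1-2 centroids), so isomorphic trees
  deduplicate.  A maximum pattern size (default 12 atoms, 6 in the
  recovery pipeline) bounds the search.
* **KNN** — each inhibitor's binding-profile similarity to its k=3 nearest
  other inhibitors (common-binding count or Tanimoto c/(a+b-c)),
  represented as an n-vector with non-neighbor entries zeroed, ties at the
  k-th rank broken by index.  These features read the label matrix, so the
  evaluation loop recomputes them per split from a matrix in which every
  non-training label is zeroed; in the hard case the test inhibitor's
  profile is empty and its features are all zero (with a warning).
* **CF** — molecular weight, logP, H-bond donor/acceptor counts, rotatable
  bonds, tautomer count and TPSA, computed with RDKit.  Values are pinned to
  this engine; agreement with any other descriptor engine is out of scope.
* **GF** — topological diameter, principal-axis 2D length and width (PCA
  bounding box; a deterministic RDKit layout supplies coordinates when the
  input has none), their ratio, and atom count.
* **P** — 3-point pharmacophores over atom roles HBD (N/O with >= 1 H),
  HBA (N, or non-nitro O, uncharged), POS/NEG (formal charge), with
  priority NEG > POS > HBD > HBA when several apply.  Pairwise distances
  are topological shortest paths binned at edges {<=2, <=4, <=6, >6};
  triplet keys sort roles and distances, making them order-invariant.
  Feature columns are the corpus-wide top-50 keys by frequency.

## Classification and preprocessing

Nominal columns become binary indicators (k=2 -> one column, k>2 -> k
indicators; unseen categories encode as all-zero with a warning).  Numeric
columns are min-max scaled to [0,1] with statistics from training rows
only; test values clip.  The tree wrapper uses a CART learner with
min_samples_leaf=2 and cost-complexity pruning (ccp_alpha=0.01) as the
open-source stand-in for C4.5/C5 confidence-factor pruning at CF=25%: the
intended behavior — noise splits collapse, strong splits survive — is what
the null-signal calibration below exercises.  The quadratic SVM kernel is
polynomial degree 2 with coef0=1; scores are signed decision values with
label threshold 0.  All learners are deterministic under a fixed seed.

## Evaluation mechanics

Fractional insertion amounts are converted with round-half-up (0.5 x 113 ->
57, 0.5 x 20 -> 10) and clipped to the m-1 / n-1 available partners, so
fraction 1.0 approaches the soft case; absolute counts above the maximum
raise instead.  Inserted pairs are sampled uniformly without replacement,
re-sampled per test split, and mixed-case runs average 10 seeded repeats.
The probability-product baseline predicts binding iff p_kin(b) * p_inh(b)
strictly exceeds theta, with theta grid-searched (0 to 1, step 0.01,
smallest tie wins) on training information; the majority baseline breaks
exact ties toward no-binding.  Undefined metric ratios (zero denominator)
are reported as absent, never as 0.  A leakage guard raises if the test
pair reaches the training set or the masked matrix.

## Synthetic data

The generator emulates the screen's shape (defaults m=113, n=20, positive
rate 26.4%) with a recoverable rule.  Kinase sequences are drawn
pre-aligned from one consensus — no indels, since no tested computation
depends on them beyond gap handling, which has dedicated hand-built
fixtures.  Twelve active-site columns are fully conserved (recoverable by
the conservation rule and usable as frame anchors); three further *signal*
columns carry one of two archetype residue patterns (55/45 split).
Inhibitors are random acyclic molecules over {C,N,O,S} grown under valence
constraints; half carry a planted amide-like fragment N-C(=O), and the
builder provably never creates that adjacency elsewhere.  Pair (i,j) binds
with probability s * rule(i,j) + (1-s) * pi where rule = archetype-1 AND
fragment; a minimal set of random flips rebalances the matrix to pi +- 2%.
The recovery check runs the full pipeline (phylogeny + PSF + mined free
trees + nominal inhibitor features + per-split KNN) at 40 x 10 — sized so
the 400-split soft LOOCV stays fast — and verifies that the planted
fragment is contained in a mined border element and the planted columns
are recovered.  What passing shows: the pipeline can carry a clean
feature -> label signal end to end without leakage, and stays at the
majority rate when none exists.  What it does not show: performance on real
kinome data, whose phylogenetic correlation structure, indel patterns and
drug-like chemistry the generator deliberately does not model.

## Known limitations

* The tree learner approximates, not replicates, C5; bit-exact agreement
  with the commercial tool (and with JOELib2 descriptors) is a non-goal.
* locAli is frame-restricted MSA scoring, not Smith-Waterman local
  alignment; the group name follows the source convention.
* Free-tree and sequence-pattern mining are exponential in the worst case;
  the size caps above are the intended guard rails.
* Affinity regression, k-fold generalizations of the dyadic splits, and
  significance testing between classifiers are out of scope.
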