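# Methods

## Data model

A dataset is a set of proteins, each a `GlycoProteinRecord`: an
uppercase amino-acid sequence (the 20 standard letters; X/U/B/Z are
accepted but can never be candidate sites), a list of per-site
annotations (1-based position, residue S or T, glycan type among
GalNAc / GlcNAc / Gal / Xyl / Fuc / Glc / HexNAc / Hex, status
positive or negative), and optionally a per-residue segmentation into
structural domains (`DOMAIN`) and intrinsically disordered regions
(`ID`) that must tile `[1, len]` without gaps or overlaps.  All file
coordinates are 1-based inclusive, the UniProt convention.  Site tables
may list only positives; every unannotated Ser/Thr is then a negative,
matching how curated glycosylation sets are defined (annotation absence
= assumed unmodified).

## Clustered vs isolated typing

For each positive site the nearest Ser/Thr position on the left and on
the right are found, skipping all other residues and with no distance
cap — the rule is about the Ser/Thr lattice, not a fixed window.  The
site is **clustered** iff at least one of those neighbors is itself
positive (OR semantics), otherwise **isolated**.  A terminal site with
a Ser/Thr neighbor on only one side is judged on that side; a protein's
sole Ser/Thr is isolated.

OR was chosen over AND because it makes two adjacent positives mutually
clustered, which is what "densely clustered" runs in mucin repeats
mean, while still leaving a glycosylated Thr in a TGDS repeat (whose
nearest Ser/Thr neighbors are unmodified Ser) isolated.  The stricter
AND reading is available as `require_both_sides=True` everywhere the
typing is computed.

## Window encodings

Windows of odd length *W*ₛ are excised around a candidate Ser/Thr;
positions beyond the termini carry a null symbol.  The encoding
alphabet is the 20 amino acids in alphabetical one-letter order plus
null as the 21st symbol (non-standard residues share the null bin,
keeping the alphabet closed).

* **sparse**: each non-center position is a 21-bit one-hot block,
  ordered left to right; the center is appended as 2 bits [S, T].
  Length 21(*W*ₛ−1)+2, exactly *W*ₛ set bits, losslessly decodable.
* **composition**: the frequency vector of all *W*ₛ window symbols
  (center and null padding included), normalized to sum to 1 so vectors
  are comparable across window sizes.
* **ica** (*W*ₛ = 7 only): the six flank positions sparse-coded to 126
  bits with the center omitted entirely, so Ser- and Thr-centered
  windows with identical flanks encode identically.

Block sums of the sparse encoding plus the center one-hot, divided by
*W*ₛ, equal the composition encoding exactly; tests use this as a
cross-encoder consistency oracle.

## SVM prediction protocol

One `SVC(kernel="rbf")` per site type.  Balancing: all positives of the
type plus an equal-size uniform sample (without replacement) of
negatives, so accuracy has chance level 0.5 and is reported as plain
fraction correct with no threshold tuning.  Cross-validation groups by
protein: proteins are dealt into 10 folds (sizes differing by at most
one), every site of a protein inherits its protein's fold, and each
fold's negatives are sampled once, from that fold's own proteins — so
train and validation negatives always come from disjoint proteins and
no window overlaps between train and test.  Grid search uses
logarithmic grids C ∈ {0.1, 1, 10, 100} and γ ∈ {1e-4 … 1} spanning the
conventional ranges; for each grid point the SVM is trained on nine
folds' balanced sets and scored on the held-out balanced set, and the
grid point with the best fold-averaged accuracy is reported together
with its per-fold accuracies.  Folds with no positives of the requested
type are skipped with a warning.

## Positional existence-ratio profiles

For a site class, `ratios[a, p]` is the fraction of the class's
windows carrying amino acid `a` at offset `p` from the center (default
*W*ₛ = 31, offsets −15…+15).  The 21 symbols partition every position,
so each column sums to 1.  The center column is kept (it is the class's
S/T split); null is counted where windows overrun the termini, making
the denominator the site count for every column.  Profiles are computed
over *all* sites of a class, not a balanced subsample, since each class
carries its own denominator.  Class contrasts are plain elementwise
differences.

## PCA→ICA decomposition

The n×126 binary flank matrix is mean-centered and reduced to its top
10 principal components by exact (full-SVD) PCA — the exact solver
matters: the default randomized solver is unseeded and makes the
downstream fixed-point ICA trajectory, and even its convergence,
irreproducible.  FastICA with symmetric decorrelation then unmixes the
10 scores (whitening is part of this step).  The contrast function is
the kurtosis-based negentropy approximation (`cube`): on the strongly
non-Gaussian score distributions of sparse-coded windows it converges
in tens to hundreds of iterations, whereas `logcosh` (available as an
option) can oscillate indefinitely between symmetric solutions on the
same data while producing numerically identical subspaces.  Tolerance
is 5e-3 on the fixed-point update with a 2000-iteration budget;
convergence failures are init-dependent, so the pipeline retries up to
5 deterministic restarts before raising.  Isotropic Gaussian input —
where independent components are not identifiable — fails every
restart and raises a convergence error by design.

Each independent component is mapped back through the PCA loadings
into the 126-dim input space, reshaped to 6 positions × 21 symbols,
sign-fixed so its largest-magnitude element is positive, and summarized
by that arg-max (symbol, offset).  Strictly, ICA mixing directions are
not existence ratios; decoded maps are therefore presented as signed
magnitudes under the positivity convention.  A component is called
dominated by a single element when its largest element carries more
than 0.9 of its L2 norm (>81% of the energy); planted single-position
signals decode at ≈0.97 while purely composition-biased windows stay
below ≈0.85.

## Disorder enrichment

Counting is an exhaustive scan: every residue, every Ser/Thr, and every
positive site is assigned DOMAIN or ID by interval lookup in the
segmentation.  The site-type table reports (in-ID, total, percent) for
clustered, isolated, and all positive sites plus the Ser/Thr and
all-residue denominators; the glycan-type table reports, per glycan
type, the same over the proteins carrying that type.  Derived densities
are sites per ID / overall / domain residue and the same over Ser/Thr
denominators, with the two ID-over-overall fold changes.  Percentages
are rounded half-up to one decimal; densities near 1% to two decimals
and the ID-Ser/Thr density (order 10%) to one; folds to one decimal —
the precisions such survey tables conventionally print.  Zero
denominators yield "undefined" (None), never an exception.

The reference count tables packaged in `oglysite.synthetic` are the
printed counts of a published curated survey (107 mucin-type proteins
with clustered/isolated breakdown; 83 non-mucin-type proteins by glycan
type, DICHOT-segmented).  The underlying per-protein segmentations are
not printed anywhere, so the package carries the counts — the full
pipeline is exercised end-to-end on synthetic segmentations instead.

## Synthetic generator

The generator's defaults are the study conditions of such a survey;
they are fixed once and the tests measure recovery against them.

* **Proteins**: 98, lengths ~N(430, 120²) clipped at 150.
* **Segmentation**: alternating DOMAIN/ID segments, means 160/70
  residues (min 25), first class fair-coin — expected disordered
  fraction ≈ 0.30.
* **Composition**: domain segments draw from average globular
  frequencies; ID segments apply a disorder-promoting tilt (P ×2.2,
  S ×1.6, T ×1.5, G ×1.4, A/E/Q ×1.3 up; C ×0.15, W ×0.3, F ×0.4,
  I/Y ×0.5 down; renormalized).  This gives composition-based
  classifiers a realistic signal and a measurable ID-vs-domain KL
  divergence.
* **Clustered sites**: 102 runs of 3 adjacent positive Ser/Thr
  (Thr with probability 0.6), ≈306 sites; each run placed inside an ID
  segment with probability 0.91, else in a domain segment.  Run
  members' nearest Ser/Thr neighbors are their positive run mates, so
  nearest-neighbor typing recovers the planted label exactly.
* **Isolated sites**: 145 single positives centered in a reserved
  21-residue span whose edges are non-glycosylated Ser sentinels and
  whose interior contains no other Ser/Thr — the nearest Ser/Thr
  neighbors are always the negative sentinels, again giving exact label
  recovery.  ID placement probability 0.75.  Flank motifs are drawn
  independently per site: Pro@−1 0.30, Pro@+3 0.25, Val@−3 0.16,
  Val@+8 0.16, Ala@−6 0.15, Ala@+5 0.15 (the Val values are the one
  peak height such surveys print; the others are plausible magnitudes
  chosen once).  At a motif offset the background filler never uses the
  motif residue, so the planted probability is exact rather than a
  lower bound.
* **Exclusive-motif mode** (for separability experiments): background
  fillers inside reserved spans exclude all motif residues, and a
  post-pass removes motif residues at motif offsets of every negative
  Ser/Thr outside reserved spans.  With a single motif at probability
  1.0 this makes positives and negatives linearly separable in the
  sparse encoding by construction.
* Placement reserves non-overlapping intervals (gap ≥ 2) inside
  segments of the drawn class, proteins weighted by length; clearly
  infeasible configurations (demand above 80% of generated ID
  capacity, runs longer than the minimum segment) raise before any
  output is emitted.  Everything derives from one seeded generator, so
  a fixed config + seed reproduces outputs byte-identically.

What the generator does **not** emulate: homologous protein families
and redundancy, real mucin tandem-repeat grammar, glycan-structure
heterogeneity, position-specific signals around *clustered* sites, and
any correlation between motifs and disorder beyond placement.  Passing
recovery tests therefore demonstrates that the pipeline measures what
was planted at realistic scales — not that real glycosylation attains
any particular prediction accuracy.  Published survey-specific numbers
(e.g. headline CV accuracies of 74%/79%, profile peak heights) depend
on curated datasets that are not printed and are deliberately not
asserted anywhere; the packaged count-table arithmetic is asserted
exactly.

## Problem sizes used in validation

Checks run at the scales the statistics need: motif-probability
recovery at 2,000 isolated sites (binomial tolerance 3·√(p(1−p)/n)),
ICA recovery at 2,000 windows (|r| > 0.95 up to permutation/sign),
end-to-end ID-placement recovery at 1,000 clustered sites planted at
90% (±3 points; placement is drawn per run, so runs of length 2 give
1,000 sites from 500 independent draws), typing vs a brute-force
oracle on 500 random sequences, and chance-level CV pooled over three
uninformative datasets with the tolerance set from the pooled fold
standard error (grouped CV adds protein-level variance beyond the
binomial floor).

## Known limitations

* Site typing assumes complete positive annotation; missing
  annotations can only flip clustered → isolated (the OR rule is
  monotone in added positives).
* The ID/DOMAIN segmentation is consumed as given; the package does not
  judge disorder, and segmentations must fully tile each protein.
* Negative re-sampling happens once per fold per run, not per grid
  point; grid comparisons therefore share negatives, which is the
  deterministic choice.
* Evidence qualifiers on annotations (e.g. "by similarity") are
  assumed to be resolved upstream; the site-table format carries no
  evidence column.
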