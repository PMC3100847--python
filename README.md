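# oglysite

Analysis toolkit for mucin-type (*O*-GalNAc) and other *O*-linked
glycosylation sites on Ser/Thr residues of mammalian proteins:

* **Site typing.** A glycosylated (positive) Ser/Thr is *clustered* when
  its nearest Ser/Thr neighbor on at least one side — at any distance
  along the chain — is also glycosylated, and *isolated* otherwise.
  Mucin runs make mutually clustered sites; a glycosylated Thr inside
  Thr-Gly-Asp-Ser repeats with unmodified Ser neighbors stays isolated.
* **SVM prediction.** One RBF-kernel SVM per site type on fixed windows
  of odd size *W*ₛ ∈ [3, 55] centered on the candidate site, encoded
  either as a sparse 21(*W*ₛ−1)+2-bit one-hot vector (20 amino acids +
  null beyond the termini, 2 bits for the Ser/Thr center) or as the
  21-dim amino-acid composition of the window.  Training is balanced
  (all positives + an equal uniform sample of negatives), evaluation is
  protein-grouped 10-fold cross-validation with (C, γ) grid search, so
  chance level is 0.5 and nothing leaks between folds.
* **Positional profiles.** Existence ratios of each amino acid at each
  relative position around clustered-positive, isolated-positive, and
  negative Ser/Thr (default *W*ₛ = 31), the representation in which
  flank preferences such as Pro at −1/+3 or Val at −3/+8 appear.
* **PCA→ICA motif decomposition.** The six flanks of *W*ₛ = 7 windows
  sparse-coded to 126 dims, reduced to 10 principal components, and
  unmixed by fixed-point ICA; each component is decoded back into a
  6-position × 21-symbol map whose dominant element names a
  position-specific, statistically independent residue preference.
* **Disorder enrichment.** Given per-residue DOMAIN/ID segmentations
  (DICHOT-style), counts and densities of glycosylation sites inside
  intrinsically disordered regions, per site type and per glycan type,
  including the ID-over-overall fold enrichment.
* **Synthetic data.** A generator that emits FASTA + site table +
  region table with planted, parameterized structure (clustered runs,
  isolated sites with flank motifs, disorder-skewed composition,
  configurable ID placement), plus the packaged reference count tables
  of a curated survey of 107 mucin-type and 83 non-mucin-type
  glycoproteins.

## Worked example

```sh
$ oglysite simulate --seed 11 --out demo
wrote demo/proteins.fasta, demo/sites.tsv, demo/regions.tsv, demo/ground_truth.tsv

$ oglysite classify --fasta demo/proteins.fasta --sites demo/sites.tsv --out demo/typing.tsv
$ head -5 demo/typing.tsv
# oglysite v0.1.0
protein_id      position        residue site_type
SYN0001 3       T       clustered
SYN0001 4       T       clustered
SYN0001 5       S       clustered

$ oglysite enrich --fasta demo/proteins.fasta --sites demo/sites.tsv --regions demo/regions.tsv
category        n_in_ID n_total percent_in_ID
clustered       273     306     89.2
isolated        108     145     74.5
total           381     451     84.5
ser_thr 2317    5786    40.0
residues        12316   42875   28.7
# sites_per_id_residue=3.09
# sites_per_residue=1.05
# fold_id_over_all_residue=2.9
...
```

The default generator emulates a curated mucin-type glycoprotein set
(98 proteins, ~300 clustered + 145 isolated positives, ~30% disordered
residues, 91%/75% of clustered/isolated sites placed in ID regions), so
the enrichment table above reads like the real survey: nearly 9 in 10
clustered sites fall in disordered regions, a ~3-fold density
enrichment over the proteome background.

Cross-validated prediction on the same dataset shows the type
specialization the window encodings are designed for:

```sh
$ oglysite cv --fasta demo/proteins.fasta --sites demo/sites.tsv \
      --type isolated --encoding sparse --ws 7 --seed 11 --out demo/cv_iso.tsv
mean accuracy 0.709 (C=10.0, gamma=0.1); wrote demo/cv_iso.tsv
$ oglysite cv --fasta demo/proteins.fasta --sites demo/sites.tsv \
      --type clustered --encoding composition --ws 31 --seed 11 --out demo/cv_clu.tsv
mean accuracy 0.744 (C=10.0, gamma=1.0); wrote demo/cv_clu.tsv
```

The packaged reference counts are available without any input files:

```sh
$ oglysite enrich --fixtures site_type
category        n_in_ID n_total percent_in_ID
clustered       283     311     91.0
isolated        116     154     75.3
total           399     465     85.8
ser_thr 2779    7228    38.4
residues        14028   45962   30.5
# sites_per_id_residue=2.84
# sites_per_id_st=14.4
# fold_id_over_all_residue=2.8
# fold_id_over_all_st=2.2
...
```

Other subcommands: `featurize`, `train`, `predict`, `profile`, `ica`,
`track`; every stochastic one takes `--seed` and echoes it in a `#`
header of its outputs.

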