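# rnasnap

Per-nucleotide prediction of RNA **solvent-accessible surface area (ASA)**
from sequence alone, for structural bioinformaticians who need tertiary
structural information about RNAs that have no solved 3D structure — to
flag candidate protein-binding surfaces, buried structural cores, or to
relate accessibility to functional genomics signals (chemical probing,
variant frequencies, transcript architecture).

## The model

Most RNA structures are unsolved, but accessibility is learnable from
sequence.  The package trains an **ε-support-vector regression with an RBF
kernel** mapping a window of sequence context to the normalized ASA of the
central nucleotide:

* **Ground truth.**  Residue ASA is computed from 3D coordinates by the
  Shrake–Rupley method with solvent probe radius 0.75 Å (probe diameter
  1.5 Å) and normalized by a single constant, `asa / 400 Å²`.  A residue
  enters training only if it and its two sequence neighbours have no
  missing heavy atoms.
* **Features (seq mode).**  Each position is a ±1 one-hot 4-vector over
  A,C,G,U; the feature row for position *i* concatenates positions
  *i−w … i+w* (default *w* = 40), giving 4×(2*w*+1) = **324 features**, with
  (−1,−1,−1,−1) padding beyond the chain ends.  (For comparison, a 20-letter
  protein alphabet at *w* = 8 gives 20×17 = 340.)
* **Features (prof mode).**  The 4-vector is replaced by a multiple-
  alignment profile: per-column base counts *N<sub>ij</sub>* receive
  pseudocounts (+9.0 at the query base, +0.3 elsewhere), become
  *P<sub>ij</sub>* = −log(*N<sub>ij</sub>* / Σ<sub>j</sub>*N<sub>ij</sub>*),
  and are min–max mapped onto (−1, 1) with bounds persisted in the model.
* **Validation.**  Chain-level *k*-fold cross-validation (all positions of a
  chain share a fold) with the pooled Pearson *r* over held-out positions as
  the headline metric; (C, γ) chosen by exhaustive grid search.

Downstream analyses operate on the predictions: DMS reactivity
normalization (per-mRNA max scaling, 50-base fragment averaging,
denature-ratio correction), equal-occupancy binning of SNVs by predicted
ASA against mean log₁₀(minor allele frequency), and mean accessibility
profiles ±50 nt around transcript region boundaries
(5′UTR|CDS, CDS|intron, intron|CDS, CDS|3′UTR).

## Worked example

All inputs can be generated synthetically (`rnasnap fixtures`), so the full
pipeline runs without downloads:

```sh
$ rnasnap fixtures --what chains --seed 11 --out fx
$ rnasnap asa --structure fx/chain0.pdb --chain A --inventory simple --out asa.tsv
8 residues -> asa.tsv
$ head -5 asa.tsv
chain   residue_index   base    asa_A2    asa_norm  valid
A       0               A       89.0163   0.2225    1
A       1               A       154.0910  0.3852    1
A       2               U       145.9465  0.3649    1
A       3               C       151.2421  0.3781    1
```

`asa_A2` is the Shrake–Rupley accessible area in Å², `asa_norm` the
regression target (area / 400 Å²), `valid` the missing-atom completeness
flag.  A profile from an alignment:

```sh
$ rnasnap fixtures --what alignments --seed 11 --out fx
$ rnasnap profile --alignment fx/alignment.fasta --out prof.tsv
profile of 60 positions -> prof.tsv
$ head -2 prof.tsv | cut -c1-100
position  base  P_A       P_C       P_G       P_U       norm_A     norm_C    norm_G    norm_U
0         A     0.245394  2.517208  4.915103  2.043423  -0.929773  0.009061  1.000000  -0.186732
```

Low `P` means high observed frequency (here the query base A), and `norm_*`
are the (−1,1)-scaled feature values.  Training and prediction chain
together with `rnasnap encode`, `rnasnap train --cv 5`, `rnasnap predict`
and `rnasnap eval`; the downstream analyses are `rnasnap dms-norm`,
`rnasnap maf-bin` and `rnasnap boundary-profile`.

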