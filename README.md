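# zygopeak

Transgene zygosity genotyping from log-phase PCR capillary-electrophoresis
peak tables.

## The problem

Crop transformation programmes constantly need to know whether a transgenic
plant carries its insertion on both homologous chromosomes (**homozygous**,
2 copies), on one (**hemizygous**, 1 copy), or on neither (**null**).
Direct assays (qPCR, ddPCR, sequencing across the insertion site) are
accurate but expensive, low-throughput, or require knowing the insertion
site.  An alternative is ordinary endpoint PCR stopped early: run only ~10
cycles after touchdown and the reaction is still in its logarithmic phase,
so the amount of product measured by capillary electrophoresis remains
proportional to the starting template — a homozygote yields about twice the
product of a hemizygote, while by 20–40 cycles every reaction has hit the
plateau and the signal is uninformative.

zygopeak turns the tabular peak export of a fragment analyzer (one row per
sample × marker with amplicon size, peak height, peak area) into zygosity
calls for segregating populations.  It is aimed at plant molecular-breeding
labs genotyping backcross/self progeny (e.g. BC₁S₁ populations) for a
single-locus transgene with a marker panel of conserved construct elements
(by default 35S promoter, OCS terminator, NPTII) and a single-copy native
reference gene (GhUBC1 for cotton).

## The method

1. **Presence calling.** A sample is *transgenic* when every transgene
   marker and the reference amplified, *null* when only the reference
   amplified, and *missing* otherwise.
2. **Normalization.** Each trait value X (height or area of a transgene
   peak) is rescaled against the same sample's reference peak Y and the
   population median reference value Z:

   `T = (X / Y) · Z`

   X/Y removes per-sample template and injection effects (including any
   pre-electrophoresis dilution); Z restores the original trait scale.  The
   median is used because segregating populations are not normal.
3. **Zygosity splitting.** Within each population the transgenic samples'
   normalized values form a two-component mixture (homozygous mean ≈ 2×
   hemizygous mean).  Two splits are computed:
   - the **pit**: the valley of minimum kernel density between the two
     modes of the distribution (Gaussian KDE, Silverman bandwidth);
   - exact **1-D K-means** (k = 2) by exhaustive threshold search, with
     cluster support scored by Sarle's Cubic Clustering Criterion
     (CCC ≥ 2 = well-supported) and the Tukey–Kramer HSD test between
     cluster means.  The cluster with the larger centroid is homozygous
     (AA), the other hemizygous (AB).  Populations whose distribution does
     not support a split (unimodal line, CCC < 2) are left unresolved
     rather than forced into two classes.
4. **Segregation testing.** Pearson χ² and likelihood-ratio G tests of the
   3:1 transgenic:null and 1:2:1 homozygous:hemizygous:null ratios
   (df = classes − 1, no continuity correction; "fits" requires both tests
   to accept).
5. **Family confirmation.** Parents predicted homozygous must breed true on
   selfing (no nulls, no detectable hemizygous class); parents predicted
   hemizygous must throw 1:2:1 progeny.

A built-in simulator generates ground-truthed peak tables from a logistic
amplification model (P₀ = copies·A₀; P_{i+1} = P_i + e·P_i(1 − P_i/K)), so
every stage of the pipeline is testable without lab data.

## Worked example

Simulate two 240-plant segregating populations, call zygosity, and test
the Mendelian ratios:

```sh
$ zygopeak simulate --populations 2 --n 240 --seed 7 \
    --out peaks.tsv --truth truth.tsv --sheet sheet.tsv
wrote 1546 peak records for 480 samples to peaks.tsv

$ zygopeak call --peaks peaks.tsv --sheet sheet.tsv --method both \
    --out calls.tsv --report report.json
called 480 samples; pit/K-means disagreement 0 of 342
  pop1: transgenic=165 null=66 missing=9 hom=57 hem=108
  pop2: transgenic=177 null=52 missing=11 hom=57 hem=120
  Total: transgenic=342 null=118 missing=20 hom=114 hem=228

$ zygopeak segregate --calls calls.tsv --ratio 1:2:1
pop1: observed=[57, 108, 66] chi2=1.675 G=1.634 df=2 p=0.4327 fits
pop2: observed=[57, 120, 52] chi2=0.747 G=0.758 df=2 p=0.6845 fits

$ zygopeak segregate --calls calls.tsv --ratio 3:1
pop1: observed=[165, 66] chi2=1.571 G=1.525 df=1 p=0.2100 fits
pop2: observed=[177, 52] chi2=0.642 G=0.656 df=1 p=0.4181 fits
```

Reading the output: in pop1, 165 plants amplified all four markers
(transgenic), 66 only the reference (null), 9 had failed reactions.  The
K-means split of normalized OCS peak heights put 57 plants in the
high cluster (homozygous) and 108 in the low cluster (hemizygous); the
report records the cluster means (pop1: 788.8 vs 386.1 RFU — the expected
2:1 dosage signal) and a CCC of 10.7, well above the ≥ 2 support
threshold.  Both populations fit 3:1 and 1:2:1, i.e. the construct
segregates as a single locus.  The pit and K-means methods agreed on all
342 transgenic samples.

The same analysis is available as a library call:

```python
from zygopeak import run_pipeline
calls, report = run_pipeline("peaks.tsv", "sheet.tsv")
```

`zygopeak confirm --calls calls.tsv --sheet sheet.tsv` additionally scores
selfed BC₁S₂ families against their parents' predicted genotypes.

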