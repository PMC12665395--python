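# nbsupport — Net Bootstrap Support for phylogenomic superalignments

`nbsupport` measures clade confidence in phylogenies inferred from
*superalignments* (the concatenation of hundreds or thousands of gene
alignments).  The standard Felsenstein bootstrap applied to a superalignment
converges to 100% for nearly every clade as loci accumulate — including
clades that are wrong, because concatenation averages away genuine
phylogenetic heterogeneity across the genome (incomplete lineage sorting,
rogue or paralogous loci, data errors).  `nbsupport` implements the **Net
Bootstrap Support (NBS)** approach, which detects and corrects this
overconfidence using the *little bootstraps* resampling scheme, without
requiring any knowledge of gene boundaries.

It is intended for molecular systematists who have a concatenated DNA or
protein alignment (FASTA or relaxed PHYLIP) and want heterogeneity-aware
support values — on a desktop, without rerunning a full bootstrap of the
whole matrix.

## The method

1. Draw a subsample of `l = ⌊L^g⌋` sites (default `g = 0.7`) without
   replacement from the `L`-site superalignment.
2. Build `R` **upsampled replicates**: each contains `L` sites drawn *with
   replacement from the subsample*, so a replicate carries as many
   substitutions as the full matrix while holding only `l/L` of its
   distinct site patterns (≈1.6% for `L = 10⁶` — hence the speed and
   memory savings).
3. Infer a tree per replicate (built-in weighted-distance + neighbor
   joining, or any external ML program via an adapter), and record each
   clade's frequency among the `R` trees: its **bcl** (bootstrap confidence
   limit) for that subsample, on a `100/R` grid.
4. Repeat over `S` subsamples.  For each clade the bcl values form a
   distribution, and

   ```
   NBS  = mean{bcl}            net bootstrap support
   FBS  ≈ fbs = median{bcl}    estimate of the classic full-data bootstrap
   OC   = FBS − NBS            overconfidence of the standard bootstrap
   ```

   `OC = (1/S) Σᵢ (FBS − bclᵢ)` is zero when the bcl distribution is
   symmetric around FBS; a clade contradicted by part of the genome piles
   bcl mass at both 0 and 100, leaving FBS ≈ 100 but NBS near the clade's
   true genomic frequency.
5. `S` grows adaptively (start 5, add one at a time) until the root mean
   squared deviation of per-clade NBS between successive iterations falls
   below 0.05 (proportion scale, i.e. 5 support points) twice in a row.
6. Each clade's bcl distribution is tested for unimodality (Hartigan's dip
   with 2,000-sample Monte Carlo calibration; Silverman's critical-bandwidth
   test counts the modes).  A bimodal bcl distribution is the signature of
   a clade affected by phylogenetic heterogeneity.

## Worked example

Simulate a 10-taxon dataset of 60 genes (1,000 bp each) in which half the
genes follow one topology and half follow its nearest-neighbor-interchange
variant — a 50/50 conflict over a single branch — then analyze it:

```
$ nbsupport simulate --spec demo_spec.json --outdir demo_data
wrote 10 taxa x 60000 sites to demo_data

$ nbsupport run --input demo_data/alignment.fasta --s0 15 --seed 4 --outdir demo_out
$ cat demo_out/clades.tsv
clade                     NBS      FBS_est  OC       S   R   dip_p   n_modes modality    converged
t10|t9                    100.0    100.0    0.0      17  20  1.0     1       unimodal    True
t10|t8|t9                 100.0    100.0    0.0      17  20  1.0     1       unimodal    True
t10|t7|t8|t9              100.0    100.0    0.0      17  20  1.0     1       unimodal    True
t10|t5|t6|t7|t8|t9        100.0    100.0    0.0      17  20  1.0     1       unimodal    True
t10|t4|t5|t6|t7|t8|t9     100.0    100.0    0.0      17  20  1.0     1       unimodal    True
t10|t3|t4|t5|t6|t7|t8|t9  100.0    100.0    0.0      17  20  1.0     1       unimodal    True
t10|t5|t7|t8|t9           51.4706  55.0     3.5294   17  20  0.0005  2       multimodal  True
t10|t6|t7|t8|t9           48.5294  45.0     -3.5294  17  20  0.0005  2       multimodal  True
```

Each row is one bipartition (the side of the split not containing the
reference taxon, `t1`).  The six branches shared by both gene-tree classes
earn `NBS = 100` with unimodal bcl distributions.  The two mutually
exclusive resolutions of the contested branch sit near `NBS ≈ 50` — their
true frequency in the genome — and their bcl distributions are flagged
bimodal (dip p = 0.0005, 2 modes): every subsample resolves the branch
decisively one way or the other, so a standard bootstrap of the
concatenation would have reported a confidently wrong ~100%.  The adaptive
loop sampled `S = 17` subsamples of `l = 2,211` sites (of 60,000) and
converged (`manifest.json` records the RMSD trace: 0.0151, 0.0161).

The same analysis is available as a library:

```python
from nbsupport import EngineConfig, adaptive_nbs_run, read_alignment

aln = read_alignment("demo_data/alignment.fasta")
result = adaptive_nbs_run(aln, EngineConfig(), seed=4)
for rec in result.records:
    print(rec.clade.taxa(result.taxon_order), rec.NBS, rec.FBS_est, rec.OC)
```

`nbsupport modality` runs the dip/Silverman tests on an externally computed
bcl table, and `nbsupport support-map` transfers NBS values from a finished
run onto any reference Newick tree.

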