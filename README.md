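# refstab

Reference-gene selection and validation for RT-qPCR, driven by RNA-seq.

Relative quantification by RT-qPCR stands or falls with the reference
("housekeeping") genes used for normalization: a reference that itself
responds to the experimental treatment silently distorts every fold change
computed against it. `refstab` implements the complete two-stage workflow
used to find and validate trustworthy references in plants (developed here
around rice, *Oryza sativa*, under salt and drought stress, but generic in
its inputs):

1. **Screening** — mine multi-dataset RNA-seq FPKM matrices for candidate
   reference genes with a filter cascade applied per dataset:
   * abundance: gene mean FPKM > 70% of the dataset's grand-average FPKM;
   * ratio window: every condition group's mean / the gene's dataset mean
     within [0.75, 1.25];
   * one-way ANOVA across condition groups with p > 0.05 (the filter keeps
     genes that do *not* respond);
   * presence in ≥ 2 datasets;
   * Pearson-correlation selection among the kept genes (profiles of mean
     log₂(FPKM+1) per dataset × tissue × treatment cell; best positive
     partner r² > 0.95 at p < 0.01).
2. **Stability ranking** — evaluate candidates on Cq data per tissue with
   the four classical algorithms, combined RefFinder-style:
   * geNorm: M_j = mean over partners k of SD_samples[log₂(Q_j/Q_k)], with
     the iterative worst-gene exclusion ranking;
   * NormFinder: variance-components model on sample-centered log
     quantities combining intra-group variance and shrunken inter-group
     bias;
   * BestKeeper: SD (and CV%) of raw Cq plus correlation with the
     geometric-mean index — the one method deliberately sensitive to
     sample-loading differences;
   * comparative ΔCt: mean over partners of SD_samples[Cq_j − Cq_k]
     (identical to geNorm's M when all efficiencies are 2);
   * comprehensive rank: geometric mean of the per-method ranks.
3. **Quantification** — standard-curve efficiency fitting
   (E = 10^(−1/slope)) and efficiency-corrected relative expression
   2^(−ΔΔCq) against a mock (CK) calibrator, under single or combined
   (geometric-mean) reference schemes, including a divergence summary that
   quantifies how much a bad reference distorts a target's response.

Because studies of this kind rarely deposit raw matrices, the package
includes a first-class synthetic-data generator (`refstab.simulate`) that
emulates the target experimental design — six RNA-seq datasets over varieties, organs and
treatments; a 2-variety × 3-tissue × 3-treatment Cq experiment with 3
biological × 3 technical replicates; serial dilutions — with planted,
ground-truthed stable and unstable genes, so every stage is testable end
to end.

## Worked example

```sh
python examples/02_rank_stability.py
```

prints, for the leaf tissue (3 planted stable genes STB01–03, 9 planted
unstable genes with ≥ 1-cycle condition shifts):

```
=== leaf ===
       genorm_m  normfinder_rho  bestkeeper_sd  deltact_meansd  comprehensive_rank
gene
STB02     0.701           0.091          0.314           0.701               1.316
STB01     0.703           0.134          0.285           0.703               1.732
STB03     0.721           0.114          0.357           0.721               2.711
UNS06     0.795           0.246          0.505           0.795               4.000
...
UNS05     1.396           0.862          1.043           1.396              12.000
recommended references for leaf: STB02, STB01, STB03
```

Each column is one stability statistic (lower = more stable): geNorm's M
and the ΔCt statistic coincide because all efficiencies default to 2;
NormFinder's value is small for genes whose sample-centered expression has
neither group bias nor excess variance; BestKeeper's SD is raw Cq scatter.
The comprehensive rank (geometric mean of the four ranks) recovers the
planted stable trio ahead of all planted unstable genes.

The other examples cover screening (`01`), standard curves (`03`) and the
consequence of normalizing with a bad reference (`04`). The same
functionality is available from the shell:

```sh
refstab simulate --seed 1 --out fixtures/
refstab screen --expression fixtures/expression.tsv --meta fixtures/samples.csv --out screen.tsv
refstab stability --cq fixtures/cq.csv --tissue leaf --out leaf_stability.tsv
refstab quantify --cq fixtures/cq.csv --target UNS01 --refs STB01,STB02,STB03 --tissue leaf --out fc.tsv
refstab run --seed 1 --out run_out/   # full pipeline + manifest
```

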