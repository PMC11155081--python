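# ldstack

LD-consistency prioritization of GWAS association signals.

Small case-control genome scans — a few dozen cases against a few hundred
population controls — produce two very different kinds of "significant" hits:
**stacked** regions, where many SNPs in mutual linkage disequilibrium (LD)
reach comparable significance because they tag the same underlying signal, and
**isolated spikes** with no LD support, the typical signature of genotyping or
sequencing artifacts. `ldstack` separates the two directly from summary
statistics plus a genotype panel, and ships the minimal upstream (QC, additive
logistic association, LD) and downstream (inflation factor, gene annotation)
machinery to run end-to-end.

## The method

1. **Chain** significant SNPs (p < 0.05) into non-overlapping regions:
   consecutive significant SNPs ≤ 5 kb apart join the same region, and only
   regions with ≥ 10 significant SNPs are kept.
2. **Group** each region's significant SNPs by direction of effect
   (OR > 1 vs OR < 1) and LD: the strongest unassigned SNP anchors a group
   containing every same-direction SNP with r² > 0.4 to it, iterating until
   all SNPs are assigned. Independent signals are thereby scored separately.
3. **Score** each group's p-value consistency against the prediction

       ŝ = s_max · r²        MAE = Σₖ |sₖ − ŝₖ| / K

   where s = −log₁₀(p), s_max is the top SNP's value, and r² is each member's
   LD with the top SNP. Under an additive model, the expected association
   chi-square of a SNP in LD r² with a causal variant scales by r², so
   genuinely linked SNPs track the line ŝ = s_max·r², while artifacts do not.
4. **Prioritize** regions containing at least one multi-SNP group with
   MAE < 3.0.

r² is the squared Pearson correlation of unphased additive dosages
(PLINK-style allele-count r²), computed on demand from a VCF or dosage table,
or taken from a precomputed PLINK `.ld` file.

## Worked example

Simulate a cohort (136 cases / 1,864 controls) with one causal haplotype
block (OR 3) and eight isolated artifact spikes, run the association test,
then prioritize:

```
$ ldstack simulate --out-prefix demo --seed 11 \
    --set n_cases=136 --set n_controls=1864 --set n_blocks=6 --set n_spike_snps=8
$ ldstack assoc --dosages demo.dosages.tsv --phenotype demo.phenotype.tsv --out demo.assoc
$ ldstack cluster --assoc demo.assoc --dosages demo.dosages.tsv --out-prefix demo
INFO ldstack: thresholds: p<0.05, gap<=5000 bp, >=10 significant, r2>0.4, MAE<3
INFO ldstack.cluster: prioritized 1/1 regions containing 20 SNPs
```

`demo.regions.tsv` then contains one row — the causal block's region:

```
chrom  start_bp  end_bp   n_snps_total  n_snps_significant  n_signal_groups  best_mae             top_snp_id  top_snp_p              prioritized
1      1000666   1017906  20            20                  7                0.04520167689871668  blk0_10     1.824937838526414e-13  1
```

All 20 SNPs of the causal block are significant, the best signal group sits
essentially on the consistency line (MAE 0.045 ≪ 3), and the region is
prioritized. None of the eight artifact spikes appears: each is a single
isolated significant SNP and cannot meet the 10-significant-SNP minimum.
`demo.prioritized.assoc` holds the 20 member SNPs in PLINK layout, and

```
$ ldstack plotdata --assoc demo.assoc --out-prefix demo
genomic inflation factor lambda = 2.004
```

exports Manhattan/QQ coordinates and the genomic inflation factor
λ = median(χ²_observed)/median(χ²_null).

The same operations are available as library functions
(`ldstack.run_cluster_analysis`, `ldstack.logistic_assoc_additive`,
`ldstack.simulate_dataset`, ...); see `docs/methods.md` for the model and its
assumptions.

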