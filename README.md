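# riverepi

Population-epigenetics analysis for riverine landscapes: does the
epigenetic structure of wild populations track their **genetic** structure,
their **environment**, or simple **isolation by distance**?

`riverepi` is aimed at molecular ecologists working with anonymous
methylation markers (MS-AFLP) alongside neutral genetic markers
(microsatellites, pooled-sequencing SNPs) across a set of sampling sites —
typically two sympatric fish species sampled at the same sites of a river
basin. It implements the full inference chain:

1. **MS-AFLP four-state scoring.** Two isoschizomer digests (MspI, HpaII)
   of the CCGG motif differ in methylation sensitivity; presence/absence
   of a fragment in each profile classifies every locus into Condition
   I (unmethylated), II (internal-cytosine methylation), III
   (external-cytosine hemimethylation) or IV (uninformative). Peaks are
   called at an inclusive RFU threshold (default 750) inside an inclusive
   size window (default 150–500 bp), and loci whose Condition-IV fraction
   exceeds 95% of individuals (strictly) are dropped. All four states are
   kept as informative throughout.
2. **Pairwise differentiation on one scale.** The standardised measure

   G″<sub>ST</sub> = k(H<sub>T</sub> − H<sub>S</sub>) / [(kH<sub>T</sub> − H<sub>S</sub>)(1 − H<sub>S</sub>)],  k = 2 for pairs,

   with H<sub>S</sub> the mean within-population gene diversity 1 − Σp²
   and H<sub>T</sub> the pooled-frequency diversity, both averaged over
   loci before the ratio. One engine serves epiloci (haploid four-allele),
   microsatellites (codominant diploid) and SNP pools (frequency-only), so
   marker systems are directly comparable.
3. **Distance-based AMOVA.** Squared inter-individual mismatch distances
   are partitioned into among-/within-population components; Φ<sub>ST</sub>
   = σ²<sub>a</sub>/(σ²<sub>a</sub> + σ²<sub>w</sub>) is tested by permuting
   individual labels (1000 permutations by default). Pooled SNPs carry no
   within-population component and are excluded by type.
4. **Environmental ordination.** PCA (correlation matrix by default) of a
   14-variable site panel; each retained axis (3 by default) yields a
   one-dimensional Euclidean site-distance matrix.
5. **Mantel & MRM inference.** Simple Mantel tests relate marker
   differentiation to each other and to environmental/riparian distances;
   multiple regression on distance matrices (MRM) then asks whether an
   epigenetics–environment association survives once genetic
   differentiation is controlled for — the test that separates genuine
   environmental induction from structure merely inherited through
   genetics. Permutation nulls are exact (full enumeration) for ≤7 sites.
6. **Synthetic riverscape generator.** A first-class module that emulates
   the whole study design — correlated environmental gradients on a random
   river tree, an F-model for allele frequencies, and tunable
   environment→genetics, genetics→epigenetics and environment→epigenetics
   couplings — so every stage, including the spurious-association logic,
   is testable without any field data.

## Worked example

```python
from riverepi import (SimConfig, simulate_dataset, dataset_to_inputs,
                      analyse_dataset)

ds = simulate_dataset(SimConfig(), seed=42)   # 13 sites x 24 fish x 2 species
bundle = analyse_dataset(dataset_to_inputs(ds), ds.env, ds.riparian,
                         seed=42, n_perm=999)

sp = "gudgeon"
for marker in ("msaflp", "microsat"):
    r = bundle.amova[(sp, marker)]
    print(marker, f"among-population variation = {r.pct_variation_among:.2f}%",
          f"Phi_st = {r.phi_st:.3f}, p = {r.p_value:.3f}")
print(bundle.mrm[sp].round(4))
```

prints (seed 42):

```
msaflp among-population variation = 16.09% Phi_st = 0.161, p = 0.001
microsat among-population variation = 9.42% Phi_st = 0.094, p = 0.001
        term  coefficient  p_value  r_squared  r_squared_p
0  intercept       0.0923    0.986     0.1674        0.066
1    env_pc1       0.0241    0.089     0.1674        0.066
2    env_pc2       0.0066    0.800     0.1674        0.066
3    env_pc3      -0.0110    0.502     0.1674        0.066
4   riparian       0.0005    0.121     0.1674        0.066
5    snp_gst       0.9355    0.055     0.1674        0.066
```

Read: epigenetic markers discriminate populations about twice as sharply
as microsatellites (16.1% vs 9.4% among-population variance, both highly
significant), and in the MRM neither the environmental axes nor riparian
distance explain epigenetic differentiation once SNP differentiation is in
the model — the genetic predictor carries the association (b = 0.94,
p = 0.055). Mean pairwise G″<sub>ST</sub> in this run is 0.364 (epiloci),
0.339 (microsatellites) and 0.124 (SNPs).

The same pipeline runs from the shell on CSV inputs:

```bash
riverepi simulate --seed 42 --out-dir data/
riverepi run --config config.yaml --out-dir report/
riverepi mantel report/gst_gudgeon_msaflp.csv report/gst_gudgeon_snp.csv
```

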