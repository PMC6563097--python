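# kinmeth

Kinship-aware differential DNA methylation analysis for reduced
representation bisulfite sequencing (RRBS) count data.

## The problem

Split-family rearing experiments — for example, families of steelhead trout
divided between a hatchery and a simulated stream environment — ask whether
the environment leaves a methylation signature. But siblings resemble each
other epigenetically for genetic reasons, so when families are unevenly
represented across treatments, naive per-site tests confound family with
environment and report spurious differentially methylated cytosines (DMCs).
`kinmeth` implements the analysis stack for this setting: site filtering,
C/T-SNP masking, a per-CG binomial mixed model with a genetic-relatedness
random effect, Storey q-value FDR, windowed DMR calling, gene annotation
and Fisher enrichment, global-pattern statistics (clustering, PCA, ANOSIM),
SNP-panel parentage assignment and relatedness estimation, and a synthetic
data generator that emulates the split-family design with known ground
truth.

## The model

For each CG site, with `y_i` methylated reads of `r_i` total in sample `i`:

```
y_i ~ Binomial(r_i, pi_i)
logit(pi_i) = W_i a + x_i b + g_i + e_i
g ~ MVN(0, sigma_g^2 K),   e_i ~ N(0, sigma_e^2)
```

where `x` is the treatment indicator, `K` the genetic relatedness matrix
(pedigree numerator matrix or SNP-based GRM), `g` the heritable random
effect and `e` independent overdispersion (the marginal counts are
beta-binomial-like). Estimation is by Laplace-approximated REML with the
fixed effects refined on the Laplace profile; inference on `b` is a Wald
t-test with Satterthwaite degrees of freedom. A site is a DMC at q < 0.10
(Storey). DMRs require either two or more CGs at p <= 0.001 in a 2 kb
window centered on a DMC, or three or more CGs at p < 0.001 spanning at
most 2 kb. See `docs/methods.md` for the full account.

## Worked example

Simulate a 6-family split design (24 offspring, 300 CG sites, 10% of sites
carrying a true logit-scale effect of 1.5), assign parentage from the
95-SNP panel, estimate relatedness, and run the age-1 rearing-group
contrast end to end:

```python
import kinmeth as km

cfg = km.SimulationConfig(n_families=6, offspring_per_family=4, n_sites=300,
                          frac_effect_sites=0.1, beta_effect=1.5, seed=42)
data = km.simulate_dataset(cfg)
ped, mat, truth = data["pedigree"], data["matrix"], data["truth"]

geno = data["genotypes"]
assign = km.assign_parentage(geno.loc[ped.offspring], geno.loc[ped.dams],
                             geno.loc[ped.sires], genotyping_error_rate=0.01)
K = km.kinship_from_genotypes(geno.loc[ped.offspring])

config = km.ContrastConfig.canonical("immediate", n_perm=199)
bundle = km.run_contrast(config, mat, K)
print(bundle.filter_report.to_tsv())
print(f"DMCs (q<0.10): {len(bundle.dmcs)}   DMRs: {len(bundle.dmrs)}")
print(f"ANOSIM by rearing group: R={bundle.anosim.R:.3f} p={bundle.anosim.p_value:.3g}")
```

Output:

```
step	threshold	CG_remaining
input	-	300
coverage	>=11x in >=0.5 of each group	300
low_variance	lowest 0.05 quantile	285
hypo_methylation	mean <= 0.1	215
hyper_methylation	mean >= 0.9	159
cg_snps	site or site+1 in SNP set	159

DMCs (q<0.10): 15   DMRs: 0
ANOSIM by rearing group: R=0.131 p=0.01
```

Reading this: the cascade drops the invariant and extreme-methylation
sites typical of a bimodal liver methylome (300 -> 159 analyzable CGs); 15
sites pass the 10% FDR — in this run all 15 are true effect sites from the
generator's truth table, and parentage was assigned correctly for all 24
offspring. The ANOSIM R of 0.13 at p = 0.01 says rearing group explains a
modest but significant share of the global methylome distance structure.
No DMR is called because the simulator places effects on independent
sites, so clusters of low-p CGs within 2 kb are rare at this size.

The same pipeline is available from the shell:

```
kinmeth simulate --config sim.yaml --out dataset/
kinmeth run-contrast --config contrast.yaml --data dataset/ --out results/
kinmeth compare --a results_a/ --b results_b/
```

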