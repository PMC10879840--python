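# owlmhc

Tools for asking whether the immune-gene makeup of breeding partners
predicts their reproductive success, in the way long-term studies of
biparental birds (the motivating system is a barn-owl population) do it:

1. **Amplicon MHC genotyping** — call alleles per individual and locus
   from unique-sequence read-depth spectra with two complementary
   methods, the *Degree-of-Change* inflection statistic and a
   per-amplicon frequency *Threshold*, plus chimera and
   stop-codon/frameshift screening and replicate reproducibility.
   The class-I amplicon co-amplifies two genes, so up to four alleles
   are called jointly; each class-IIβ gene (DAB1, DAB2) carries up to
   two.
2. **Functional divergence** — per-individual MHC diversity as the mean
   pairwise Grantham distance between an individual's alleles,
   D(a,b) = ρ·[α(Δc)² + β(Δp)² + γ(Δv)²]^½ over composition, polarity
   and volume (α = 1.833, β = 0.1018, γ = 0.000399; ρ normalises the
   mean over the 190 residue pairs to 100), alongside the amino-acid
   p-distance.
3. **Supertypes** — alleles clustered by the five z-scale descriptors of
   their positively selected residues (k-means; k by BIC or silhouette;
   DAPC-style PCA + discriminant re-assignment), with population
   frequencies and per-individual presence/absence.
4. **Association models** — Poisson GLMMs for clutch size and binomial
   GLMMs for fledging success (fledged of clutch), with crossed random
   intercepts for parental identities and year, fitted by a Laplace
   approximation. Divergence effects are inferred by AICc multimodel
   selection (all marginality-respecting sub-models, ΔAICc ≤ 2 set,
   full averaging with unconditional SEs); supertype effects by one
   presence/absence model per common supertype with Benjamini–Hochberg
   correction and Tukey-adjusted estimated-marginal-mean contrasts.
   On cross-fostered clutches the models carry the genetic *and* the
   social parents' MHC side by side, separating inherited from rearing
   effects.

A synthetic-data module generates allele pools with built-in supertype
motifs, Hardy–Weinberg genotypes, noisy amplicon spectra (PCR point
errors, single-breakpoint chimeras, amplification imbalance, replicates)
and cross-fostered nest records with known injected effects, so the
entire chain runs and validates itself without any external data.

## Worked example

```python
from owlmhc.io import RunConfig
from owlmhc.pipeline import run_pipeline

cfg = RunConfig(seed=7, outdir="owlmhc_run", n_individuals=150, n_nests=120,
                noise={"replicate_fraction": 0.15},
                effects={"beta_div_genetic_father": -0.46})
report = run_pipeline(cfg)
print(report["genotype"]["replicate_concordance"])   # 1.0
print(report["supertype"]["DAB2"]["k"])              # 10
print(report["associate"]["averaged_significant"])   # ['f_div']
```

This simulates 150 genotyped adults and 120 breeding attempts in which
the genetic father's class-I functional divergence lowers the fledging
logit by 0.46 per two standard deviations of divergence. The run report
shows: the noisy amplicons genotyped back with perfect replicate
concordance (`1.0`); the ten binding motifs built into the DAB2 pool
were recovered as ten supertypes (`10`); and the model-averaged analysis
flagged exactly the injected term — the father's divergence `f_div` —
as significant (negative), out of the 13 candidate sub-models.

The same stages are available from the shell:

```bash
owlmhc run-all --config config.yaml
owlmhc simulate --seed 7 --outdir owlmhc_run
```

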