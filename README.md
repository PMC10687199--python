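# breedpanel

Selection of breed-informative SNP panels from multi-population diploid
genotypes, with the population-genetic groundwork that motivates the panel:
within-breed diversity, Hardy–Weinberg testing, between-breed
differentiation, and an F_ST-outlier scan.

The package is aimed at animal-genetics practitioners who genotype a few
hundred individuals from a handful of breeds or lines on a SNP panel and
want to (i) characterize diversity and structure and (ii) distil the panel
down to the markers that actually discriminate the breeds, for traceability
and assignment applications.

## What it computes

Given an `n × L` matrix of alt-allele dosages with population labels
(read from PLINK text `.ped/.map` or VCF):

* **QC** — SNP call rate, pooled MAF, sample call rate, and identity-by-state
  (IBS) duplicate pruning, in a fixed single pass.
* **Diversity** — per-locus allele frequencies; observed/expected
  heterozygosity (Nei gene diversity, H_E = 2p(1−p)); the fixation index
  F_IS = 1 − H_O/H_E (multilocus value as a ratio of sums); and Hill-number
  profiles ^qD = (Σᵢ pᵢ^q)^{1/(1−q)} for q = 0 (richness), 1 (exp Shannon),
  2 (inverse Simpson).
* **Exact HWE tests** — enumeration of all heterozygote counts compatible
  with the observed allele counts, p = Σ P(h) over outcomes no more probable
  than the observed one (mid-p optional), plus de Finetti ternary coordinates
  and the HWE parabola.
* **Differentiation** — Weir–Cockerham variance components (a, b, c) and
  θ = a/(a+b+c) per locus and multilocus per population pair; Nei
  G_ST = (H_T − H_S)/H_T; Euclidean distance between allele-frequency
  vectors.
* **F_ST-outlier scan** — fits a scaled χ²(df) to the trimmed distribution
  of per-locus uncorrected θ and flags loci in the fitted right tail.
* **DAPC** — PCA (mean-imputed, centered) followed by linear discriminant
  analysis on retained PCs; the number of PCs is chosen by the permutation
  a-score; per-SNP squared contributions to the discriminant axes are
  thresholded (default 0.01) to select the informative panel; assignment
  uses Gaussian posteriors in discriminant space. `compare_panels` refits
  on the reduced panel and reports both assignment accuracies.
* **Simulator** — Balding–Nichols populations (p_k ~ Beta around an
  ancestral frequency with spread F·p(1−p)) with inbreeding-adjusted
  genotype draws (F_IS, including heterozygote excess), MAF spectrum and
  missingness controls; defaults emulate a 3-breed × 100-animal × 300-SNP
  design with F_ST ≈ 0.04 and F_IS ≈ −0.03.

## Worked example

```python
import breedpanel as bp

table, truth = bp.simulate(bp.SimulationConfig(seed=1))

print(bp.pairwise_fst(table).round(3))
#        POP1   POP2   POP3
# POP1  0.000  0.039  0.045
# POP2  0.039  0.000  0.037
# POP3  0.045  0.037  0.000

het, overall = bp.fis(table, by_population=True)
print({k: round(v, 3) for k, v in overall.items()})
# {'POP1': -0.037, 'POP2': -0.033, 'POP3': -0.028}

cmp = bp.compare_panels(table, threshold=0.01, seed=1)
print(len(cmp.panel), cmp.full.overall, cmp.reduced.overall)
# 48 1.0 0.99
```

The three pairwise θ values sit at the simulated drift level (0.04); the
negative multilocus F_IS reproduces the built-in heterozygote excess; and
the DAPC chain selects a 48-SNP informative panel that assigns 99% of
individuals back to their breed, versus 100% with all 300 SNPs.

The same stages are available from the shell:

```sh
breedpanel simulate --pops 3 --n 100 --loci 300 --fst 0.04 --fis -0.03 --seed 42 --out sim
breedpanel qc --ped sim.ped --map sim.map --out sim_qc
breedpanel distances --in sim_qc
breedpanel dapc --in sim_qc --threshold 0.01 --seed 42 --out dapc_out
breedpanel run --config run.cfg      # the whole pipeline
```

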