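# foodwebs

Topology analysis of dichotomous (presence/absence) food webs for
studies of **non-trophic facilitation by foundation species** —
habitat-forming organisms such as seagrasses, mussel beds, marram grass
or Spanish moss that enlarge the niche space available to the rest of
the community.

The package is aimed at community ecologists comparing trophic networks
sampled from foundation-species-dominated areas (FS webs) with paired
nearby bare areas (BA webs), and asking whether the foundation species
facilitates associated species *at random* throughout the web or
*targets* particular trophic levels or feeding guilds.

## What it does

1. **Web construction** (`foodwebs.core`, `foodwebs.reconstruct`) —
   webs are directed networks with links oriented prey → predator,
   stored as edge-list or adjacency CSV (rows = prey, columns =
   predators). A maximized literature-based candidate web is constrained
   by (i) removing rare species (< 3 individuals), (ii) removing
   expert-flagged implausible links, and (iii) dropping links whose prey
   contributes **< 5%** to the consumer's diet, as estimated by a
   Bayesian stable-isotope mixing model.
2. **Isotope mixing model** (`foodwebs.mixing`) — the standard
   two-tracer (δ¹³C, δ¹⁵N) diet mixture
   `X_j = Σ_k p_k (s_jk + c_jk) + ε_j` with a flat Dirichlet prior on the
   diet proportions `p`, Gaussian source and trophic-enrichment
   uncertainty, and MCMC posterior sampling (deterministic per seed).
3. **The 19-metric topology suite** (`foodwebs.metrics`) — species
   number S; link density Z = L/S; connectance C = L/S²; mean
   vulnerability, generality and links per species;
   top/intermediate/basal fractions; herbivore/omnivore/
   carnivore/cannibal fractions; mean shortest chain length to a basal
   species; mean prey-averaged trophic level (TL = 1 for basal species,
   otherwise 1 + mean TL of prey, solved as a linear system); mean
   maximum trophic similarity; clustering; mean path length; and
   compartmentalization (mean pairwise neighbour overlap).
4. **Random-removal null model** (`foodwebs.nullmodel`) — each FS web is
   pruned by uniformly random species removal, cascading away species
   left without links, until its richness matches the 95% confidence
   interval of the paired bare webs. If facilitation is random, these
   RR webs should be statistically indistinguishable from the real bare
   webs; metrics on which BA and RR diverge flag targeted facilitation.
5. **Comparison statistics** (`foodwebs.stats`) — per-metric linear
   mixed models `metric ~ web_type + (1 | ecosystem)` with Satterthwaite
   denominator degrees of freedom, Tukey all-pairs letters, and a
   covariance PCA of the metric panel with a mixed-model contrast on PC1.
6. **Synthetic studies** (`foodwebs.synth`) — a full study generator
   (niche-model webs, a weakly linked basal foundation species, paired
   bare subsamples in *random* or *targeted* facilitation mode, species
   counts, isotope samples with known true diets) so the entire pipeline
   is testable end to end with ground truth.

## Worked example

```python
import pandas as pd
from foodwebs.synth import SynthConfig, generate_study
from foodwebs.metrics import metrics_table
from foodwebs.nullmodel import null_ensemble
from foodwebs.stats import lme_summary_table, pca_metrics, pc1_contrast

study = generate_study(SynthConfig(seed=11, reps_per_ecosystem=(5, 4, 4, 4, 4, 4, 4)))
real = metrics_table(study.design.webs())            # 29 FS + 29 BA webs
rr, _ = null_ensemble(study.design, reps_per_fs_web=1, seed=7)
table = pd.concat([real, rr], ignore_index=True)

print(lme_summary_table(table, metrics=["species_number", "link_density", "connectance"]))
pca = pca_metrics(table)
pc1 = pc1_contrast(pca, table)
```

which prints (abridged):

```
        metric  FS_mean  BA_mean  RR_mean     F       p signif  letters
species_number    24.83    11.52    11.90 494.0 5.7e-45    ***  b, a, a
  link_density     3.68     1.97     1.82 103.8   1e-22    ***  b, a, a
   connectance     0.15     0.17     0.15   3.5   0.034      * a, b, ab
PC1 explains 95.9% of total variation 50.4
PC1 web-type contrast: F_2,77.9 = 462.5, p = 6e-44
```

Reading this: foundation-dominated webs hold roughly twice as many
species (24.8 vs 11.5) and almost double the link density, while
connectance moves the other way; the Tukey letters show FS (`b`) apart
from BA and RR (`a`), i.e. uniformly random pruning of the FS webs
reproduces the bare webs for size and complexity. The PCA condenses the
metric panel onto one axis that separates web types the same way.

A command-line interface mirrors the stages:

```bash
foodweb simulate --seed 1 --out-dir study/
foodweb metrics --design study/ --out metrics.csv
foodweb nullmodel --design study/ --reps 10 --seed 2 --out rr.csv
foodweb run-all --seed 1 --out-dir results/
```

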