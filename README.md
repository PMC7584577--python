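# introquant

Quantify introgression between closely related species from shotgun
sequencing reads, and test whether two groups of species differ in how much
genetic material they exchange.

The motivating system is dove feather lice: *wing lice* (*Columbicola*)
disperse between host individuals phoretically on hippoboscid flies, while
*body lice* (*Physconelloides*) do not. Higher dispersal should mean more
contact between louse species on shared hosts, and therefore more
hybridization and introgression. `introquant` implements the two analyses
used to test this prediction, together with a synthetic-data generator so
the whole pipeline is testable without any sequencing data:

1. **Competitive read mapping.** For each genus, a combined reference is
   built from the nuclear loci of one representative individual per species.
   Every read of a sample is assigned to the species it matches best
   (k-mer-seeded, ungapped match-count scoring); only reads whose best score
   beats every other species by a margin (the mapping-quality proxy,
   default ≥ 2) are kept. The per-sample **introgression score** is

   *score* = Σ<sub>s ≠ focal</sub> cov̄(s) / cov̄(focal)

   where cov̄(s) is the mean fold-coverage of species *s*'s reference
   (zeros included). For read-level admixture fraction α from a single
   donor, the expected score is α/(1−α).

2. **Contamination-aware GLM.** Index swapping between multiplexed samples
   (reportedly 1–9% of reads) can mimic introgression. The pipeline
   repeatedly subtracts a random allocation of up to 9% of each sample's
   non-focal coverage, recomputes scores, fits a Gaussian identity-link GLM
   (score ~ genus) per iteration (default 100), and reports a headline GLM
   on each sample's mean adjusted score. On *n* = 71 samples the genus-only
   model has residual df = 69.

3. **Reticulation proportion test.** Phylogenetic networks (extended Newick,
   `#H` hybrid tags) are summarized to leaf and reticulation counts; the two
   genera are compared by a continuity-corrected two-proportion χ² test of
   reticulations per leaf pair (one- or two-sided), plus AIC ranking of
   candidate networks from their log pseudo-likelihoods.

## Worked example

```python
from introquant import (ContamSimConfig, NetworkSummary, generate_study,
                        paper71_config, reticulation_comparison, run_simulation)
from introquant.pipeline import score_bundle

# 71 louse individuals: 5 wing-louse species (higher admixture, lower
# interspecific divergence) and 7 body-louse species; reduced loci for speed
bundle = generate_study(paper71_config(seed=7, n_loci=(100, 100),
                                       locus_length_mean=300.0))
scores, coverage = score_bundle(bundle)
print(scores.groupby("genus")["score"].mean())
# Columbicola        0.175499
# Physconelloides    0.050540

sim = run_simulation(coverage, ContamSimConfig(max_fraction=0.09,
                                               n_iter=100, seed=7))
h = sim.headline
print(f"F={h.F:.2f} df=({h.df1},{h.df2}) p={h.p:.3g} r2={h.r2:.3f}")
# F=91.66 df=(1,69) p=2.72e-14 r2=0.571

wing = NetworkSummary("wing", n_leaves=6, n_reticulations=7)
body = NetworkSummary("body", n_leaves=8, n_reticulations=4)
res = reticulation_comparison(wing, body, alternative="greater")
print(f"chi2={res.chi2:.4f} p={res.p:.3f} CI=({res.conf_int[0]:.2f}, {res.conf_int[1]:.0f})")
# chi2=3.8132 p=0.025 CI=(0.03, 1)
```

The wing genus scores ~3.5× higher than the body genus (its simulated
admixture is higher), the genus effect survives the contamination
subtraction, and 7 reticulations among 15 wing leaf pairs versus 4 among 28
body pairs is significant under the one-sided test.

The same stages are available as CLI subcommands (`introquant simulate`,
`map`, `score`, `contam-sim`, `glm`, `nettest`, `run-all`); `run-all` takes
a JSON config and emits TSV/JSON outputs stamped with a configuration hash,
plus a provenance record.

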