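# commphylo

Decoupled phylogenetic–functional analysis of community assembly along
environmental gradients.

## The problem

Communities under strong abiotic stress (the motivating system is dung-beetle
assemblages along a semiarid-to-Saharan aridity transect) are shaped by a
balance of *environmental filtering* — which selects phylogenetically and
functionally similar species, producing clustering — and *limiting
similarity* — competition that selects dissimilar species, producing
overdispersion. Because trait variation and phylogenetic relatedness are
correlated, analysing them in parallel double-counts the conserved part of
trait variation. `commphylo` separates the two signals and quantifies both
facets of community structure against randomization null models.

The workflow:

1. **Decoupling.** Species trait distances (mixed quantitative/categorical,
   Euclidean-embeddable by construction) and cophenetic phylogenetic
   distances are embedded by principal coordinates; the functional
   coordinates are regressed on the leading phylogenetic axes. The residual
   distances are the *decoupled functional distance* (dcFdist); the
   explained share is the *shared fraction* (jointFPdist ∈ [0, 1]); the
   phylogenetic distance (Pdist) is kept whole, giving preeminence to
   phylogeny as a proxy for unmeasured conserved traits.
2. **Alpha structure.** Abundance-weighted MPD (volume of occupied
   phylo/trait space) and MNTD (packing of that space) per site,
   standardized as SES = (obs − null mean)/null sd against *random tips*
   (permute tip names on the pool tree) and *random traits* (permute species
   names on the trait distances) nulls, 100 draws each; the community
   matrix is never altered, so richness and abundance structure are held
   fixed.
3. **Beta structure.** Pairwise Sørensen-family dissimilarity partitioned
   into turnover (β_sim) and nestedness-resultant (β_sne = β_sor − β_sim)
   components: branch-length based on the UPGMA back-transformation of
   Pdist for the phylogenetic side, convex-hull volume overlap on the first
   min(4, min richness − 1) synthetic-trait (PCoA) axes for the functional
   side. Transect summaries: n mean-pairwise values and n − 1
   consecutive-pair values.
4. **Gradient statistics.** Spearman Mantel tests against aridity distances,
   paired t tests between seasons, OLS of SES on centred log₁₀ aridity, its
   square, season and interactions (HC3 robust errors on
   heteroscedasticity, Bonferroni thresholds), MANOVA of component scores
   on aridity, and (sparse) independent principal component analysis of
   community weighted means — PCA loadings unmixed by deflationary
   fixed-point ICA, components ordered by |excess kurtosis|, `keep_x`
   traits retained per sparse component.
5. **Synthetic gradients.** A generator with known ground truth (pure-birth
   two-clade trees, Brownian-vs-independent trait mixtures, neutral /
   filtering / repulsion assembly along a 10-site gradient, two seasons ×
   two years) closes the loop: every stage is validated by parameter
   recovery, not by fixtures.

## Worked example

```python
import numpy as np
import commphylo as cp

scenario = cp.Scenario(assembly="filtering", filter_strength=0.5,
                       signal=0.8, seed=42)
tree, traits, campaigns = cp.simulate_scenario(scenario)
wet = campaigns[0]

fdist = cp.trait_distance(traits)
pdm = cp.cophenetic_distance(tree).submatrix(fdist.ids)
dec = cp.decouple_distances(fdist, pdm)
print(f"shared phylogeny-trait fraction (jointFPdist): {dec.joint_fp:.2f}")

pool = wet.species_sampled()
rng = np.random.default_rng(0)
ses_raw = cp.ses_per_site(wet, fdist, pool, "mpd", n_null=100, rng=rng)
print("raw functional SES MPD:", np.round(ses_raw, 2))
ses_dc = cp.ses_per_site(wet, dec.dc_fdist, pool, "mpd", n_null=100,
                         rng=np.random.default_rng(0))
print("decoupled functional SES MPD:", np.round(ses_dc, 2))
```

prints

```
shared phylogeny-trait fraction (jointFPdist): 0.38
raw functional SES MPD: [-4.5  -2.93 -3.58 -3.18 -1.03 -0.33 -0.04 -2.57 -3.15 -4.01]
decoupled functional SES MPD: [-0.97 -0.53 -0.9  -1.24  0.38  2.1   1.23  0.36 -0.74 -1.65]
```

The scenario filters communities on a trait with 80% Brownian signal, so
raw functional MPD is strongly clustered (negative SES) at every site —
but most of that signal is phylogenetically conserved: once the shared
fraction (38% here) is removed, the purely functional clustering largely
disappears. That contrast is exactly what the decoupling is for.

A thin CLI mirrors the library
(`commphylo simulate|validate|decouple|alpha|ses|beta|cwm|stats`), reading
CSV/TSV tables and Newick trees and writing tidy CSV results plus a run
manifest; see `commphylo --help`.

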