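# pandiverge

Comparative-genomics toolkit for studying the divergence of a bacterial
clade — the kind of analysis run on a genus like *Acidithiobacillus*, where
a handful of named species and a pile of unclassified isolates must be
sorted out from genome sequence alone. It bundles the standard stages of
such a study into one tested, scriptable pipeline:

- **Marker-gene phylogeny** — 16S-style length/redundancy filtering,
  Tamura–Nei (TN93) pairwise distances, an explicit substitution-saturation
  diagnostic (transitions vs. transversions against TN93 distance),
  neighbor-joining tree building and outgroup rooting.
- **ANI species delineation** — ANIb-style average nucleotide identity:
  1,020 bp query fragments, seeded local alignment, acceptance at ≥30%
  identity over ≥70% of the fragment, and the conventional 95% same-species
  threshold.
- **Ortholog clustering** — keyword-based exclusion of mobile genetic
  elements, greedy centroid clustering of proteomes at a 50% identity
  cutoff, and the core / accessory / strain-specific partition of the
  resulting gene-family matrix.
- **Pan-genome models** — rarefaction over random genome-addition orders
  (medians over permutations) fitted with Heaps' law *Ps(n) = κnᵞ* for the
  pan-genome and *Fc(n) = κ_c e^(−n/τ_c) + Ω* for the core genome;
  0 < γ < 1 calls the pan-genome open.
- **Gene turnover** — Wagner-parsimony reconstruction of ancestral
  gene-family counts on a rooted reference tree, with per-branch gain/loss
  events and per-branch turnover rates.
- **Composition-vector phylogeny** — alignment-free whole-proteome trees
  from K-tuple (K = 6) frequency deviations against a (K−2)-order Markov
  background, compared by cosine distance.

A synthetic-data module generates whole clades with known ground truth
(species tree, gain/loss history, substitution parameters), so every stage
can be validated end to end without downloading anything.

## Worked example

```python
import pandiverge as pv

cfg = pv.SimulationConfig(n_genomes=10, seed=7)
result = pv.simulate(cfg)

groups = pv.cluster_orthogroups(result.proteomes)
pan = pv.build_pan_matrix(groups, sorted(result.proteomes))
part = pv.partition_pangenome(pan)

series = pv.rarefaction_curves(pan, n_permutations=100, seed=1)
fit = pv.fit_power_law(series)
turnover = pv.wagner_ancestral_counts(result.tree, pan)
sat = pv.saturation_assessment(result.marker_alignment)
```

Output:

```
simulated 10 genomes, 357 true families
clustered: 357 families (127 core, 157 accessory, 73 unique)
Heaps' law: Ps(n) = 228.5 n^0.1965 -> pan-genome open
Wagner parsimony: 244 gain/loss events across 18 branches
marker saturation: not_saturated (0% of pairs with v >= s)
```

Reading the numbers: clustering recovered exactly the 357 simulated
families; 127 of them are present in all ten genomes (the core), 73 in just
one (strain-specific). The fitted Heaps exponent γ ≈ 0.20 lies in (0, 1),
so each added genome keeps contributing new families — an open pan-genome,
as expected for a gain-driven simulation. The marker alignment shows
transitions well in excess of transversions, i.e. usable phylogenetic
signal.

The same stages are available from the shell:

```bash
pandiverge simulate --n-genomes 10 --seed 7 --outdir sim
pandiverge marker  --aln sim/marker.fasta --outgroup G01 --outdir out
pandiverge ani     --genomes sim/genomes --out ani.tsv
pandiverge cluster --proteomes sim/proteomes --annotations sim/annotations.tsv
pandiverge pangenome --matrix pan_matrix.tsv --permutations 100 --seed 7
pandiverge turnover  --matrix sim/pan_matrix.tsv --tree sim/tree.nwk
pandiverge cvtree    --proteomes sim/proteomes -k 6 --outgroup G01
```

## Documentation

`docs/methods.md` describes the models, the numerical choices, what the
synthetic data does and does not emulate, and known limitations.
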