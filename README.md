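# serpintools

A toolkit for superfamily-scale evolutionary analysis of proteins,
modeled on the workflow used to survey the serpin (serine protease
inhibitor) superfamily: sequence-similarity-network (SSN) clustering,
structure-seeded profile alignment with consensus-representative
selection, molecular-marker screening for horizontal gene transfer (HGT),
phylogenetic tree utilities, and rigid-body structural comparison.  It is
written for molecular evolution researchers who want each stage of that
workflow as a tested, scriptable library rather than a chain of external
tools, and it ships seeded synthetic-data generators so the entire
pipeline runs and is verified end to end without any downloads.

## What it computes

- **SSN**: near-identical sequences collapse into nodes at 75% pairwise
  identity; edges connect representatives sharing >40% identity, where
  identity comes from an optimal global BLOSUM62 alignment (affine gaps
  10/0.5, terminal gap columns excluded from the denominator).  Markov
  clustering (MCL) partitions the network by alternating expansion
  (M ← M²) and inflation (M ← M^∘r, columns renormalized, r = 2 by
  default); clusters are attractor basins.  A discrete power-law fit
  P(k) ∝ k^−α (MLE α, KS-selected x_min, semiparametric bootstrap) checks
  whether the degree distribution is scale-free, and annotation coverage
  is reported over clusters of ≥4 unique sequences.
- **Profile alignment**: position-specific profiles (match/insert/delete
  states, pseudocounted emissions, shared transitions) built from a seed
  alignment, Viterbi log-odds scoring and alignment, per-cluster
  consensus-representative selection, and the five-stage superfamily
  alignment (seed → global profile → cluster profiles/representatives →
  enriched profile → final alignment).
- **HGT markers**: gene/genome GC ratios flagged outside (0.8, 1.2); the
  codon class (ACY vs TCN by default) at a conserved aligned site; Fitch
  small parsimony of that character on a phylogeny — min changes, per-node
  optimal state sets, and one optimal labeling.
- **Trees**: Newick I/O with supports as internal labels, midpoint
  rooting, collapse of edges with support ≤90, clade extraction,
  taxonomic annotation.
- **Structures**: Kabsch superposition (SVD, reflection-corrected) and
  min/mean/max RMSD statistics over coordinate ensembles.
- **Hinge motif**: scan for the inhibitory-serpin RCL hinge
  P17–P9 = ExGTEAAAA (x ∈ {E, K, R}).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate_data.py
python analysis/02_build_ssn.py
python analysis/03_align_superfamily.py
python analysis/04_screen_hgt.py
python analysis/05_tree_and_structure.py
```

Output (seed 101):

```
superfamily: 15 records in 3 families, 8 hinge carriers -> results/data/superfamily
genomes: 500 genes across 50 genomes, 100 planted transfers (donor GC 0.65) -> results/data/genomes
15 records -> 3 nodes, 0 edges, 3 MCL clusters; ARI vs planted families = 1.000
power-law degrees (true alpha 2.5, 10 draws): alpha = 2.49 +/- 0.02, 90% labeled plausible; Poissonian graph: p=0.00 (implausible)
18 sequences aligned over 200 match columns; representatives: ['F2_t6', 'F0_t2', 'F1_t6']
column-homology recovery: 0.961 over 8 near-consensus sequences (0.966 over all records)
500 genes screened: 100 flagged anomalous, 100 planted transfers
sensitivity 1.000, specificity 1.000, verdict: non-systematic
codon-class character on a 16-leaf tree: true changes 3, parsimony minimum 3
midpoint rooting: two deepest leaves at 0.860000 and 0.860000 (gap 0.00e+00)
ensemble RMSD over 5 perturbed copies: 0.9-3.6 A, mean 2.1 A
```

Reading this: the three planted families collapse to three nodes with no
between-family edges and MCL recovers them exactly (adjusted Rand index
1.0); the power-law exponent of a known scale-free degree sequence is
recovered (2.49 ± 0.02 vs a true 2.5) while a Poissonian graph is
rejected; the structure-seeded alignment places 96% of residues of
near-consensus sequences into their true homology columns; every planted
compositionally anomalous gene — and nothing else — is flagged by the GC
ratio screen; and midpoint rooting leaves the two deepest leaves exactly
equidistant.

The same stages are available as a single command over a YAML config
(`serpintools pipeline run config.yaml`), and each module has its own
subcommand group (`serpintools ssn|profile|align|markers|tree|rmsd|simulate`).

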