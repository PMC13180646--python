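# dunefly

Courtship-display structure and population-genetic divergence analysis for
the dancing dune fly *Apotropina ornatipennis* (Diptera: Chloropidae) — a
beach-dwelling fly whose males and females negotiate mating through long,
elaborate visual displays.  The package asks how the *choreography* of such
a display relates to neutral genetic divergence among isolated populations:
are the display's elements, tempo and sequence structure stable across
demes that barely exchange migrants?

It provides, as importable library code plus numbered analysis drivers:

* **Ethogram analysis** — validated behavior-bout event logs; overlay of
  simultaneous behaviors into *composite behavioral states*; proportional
  courtship metrics per courting pair (mean bout duration, frequency, and
  inter-bout interval, each as a fraction of the interaction);
  behavior-occurrence tables and a prevalence filter for quantitative
  comparison.
* **Markov sequence structure** — transition-count matrices over composite
  states; a permutation screen (within-sequence order shuffles,
  `p = (1 + #{permuted ≥ observed}) / (B + 1)`) isolating the nonrandom
  display backbone; Kullback–Leibler divergence between Dirichlet-smoothed
  vectorized transition matrices,
  `KL(y1, y2) = Σ_i p̂_i ln(p̂_i/q̂_i)` with `p̂_i = (y1_i + a)/(n1 + aS)`
  and pseudocount `a = 1`, as the inter-individual courtship distance.
* **Population genetics** — sequential SNP filtering (reproducibility ≥
  0.98, call rate ≥ 0.95, minor-allele frequency ≥ 0.02); observed and
  expected heterozygosity with
  `Hs = n/(n−1)·(1 − Σp² − H_O/2n)` and `F_IS = 1 − H_O/H_E`;
  Weir–Cockerham pairwise F_ST with bootstrap-over-loci p-values;
  Weir–Goudet population-specific F_ST; three-stratum AMOVA with a
  label-permutation test; Nei (1972) distances; Kosman inter-individual
  distances; private-allele counts; dosage PCA; Mantel isolation by
  distance on linearized F_ST vs great-circle km.
* **Divergence link** — population-pair means of courtship KL vs Kosman
  genetic distance, with an OLS R².
* **Synthetic data** — a semi-Markov courtship simulator (per-population
  transition matrices `(1−ε)·P_base + ε·P_perturb`, gamma bout durations)
  and a Balding–Nichols SNP-panel simulator with assay metadata, so the
  whole pipeline is testable end to end without any downloads.

## Worked example

```sh
python analysis/01_simulate_field_study.py   # writes data/synthetic/
python analysis/03_popgen_structure.py
```

prints (seed 1):

```
pairwise F_ST range: 0.056 - 0.240
AMOVA: 14.7% among populations, 0.1% among individuals within,
       85.2% within individuals (Phi_ST = 0.1468, p = 0.001)
Mantel isolation by distance: r = 0.757, p = 0.0005
PCA: first two components explain 20.1% of variance
```

i.e. the seven simulated beach populations are clearly differentiated
(about 15% of dosage variance lies among populations; permutation p at its
floor of 1/1000), and because drift was accumulated serially along the
coastline, genetic distance tracks geography (Mantel r ≈ 0.76).  Continuing,

```sh
python analysis/05_transition_networks.py
python analysis/06_courtship_vs_genetics.py
```

summarizes the display networks (~35–46 nonrandom transitions per
population at α = 0.05 among 41 composite states) and ends with

```
OLS: R^2 = 0.799 over 3 population pairs (small-n caveat: True)
```

— with only three population pairs the R² of courtship distance on genetic
distance is essentially unconstrained, which is exactly the caveat the
`small_n_caveat` flag encodes.

A `dunefly` console script exposes the same stages
(`dunefly run --seed 1 --out-dir out/` runs everything and writes a
checksummed run manifest; `dunefly filter/popgen/ethogram/transitions/
divergence` operate on your own CSV or VCF inputs).

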