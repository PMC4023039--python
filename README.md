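# retrodict

Structural phylogenomics of RNA molecules: from conformational statistics
of secondary-structure ensembles to rooted trees and a geological timeline.

## The problem

Transfer RNA is among the oldest molecules of the cell, but its history
cannot be read from sequence alignments — tRNAs are short, saturated, and
heavily recruited into new functions. An alternative is to treat
*structure* as the heritable trait: fold each molecule, summarise the
Boltzmann ensemble of its secondary structures with a few conformational
statistics, code those statistics as linearly ordered phylogenetic
characters, and let maximum parsimony reconstruct the history of
molecules, of their substructures (acceptor stem, D arm, anticodon arm,
variable loop, T arm), and — from genomic abundance censuses — of the
protein domains they interact with. Because protein-domain history follows
a global molecular clock of fold structures, RNA substructure ages can be
anchored to the geological record through the domains they bind: the age
of an interaction bounds the age of its components.

`retrodict` implements that whole chain as a reproducible pipeline with
synthetic generators supplying every input with known ground truth.

## The model in brief

For a sequence of length *n* with ensemble pairing probabilities
*p<sub>ij</sub>* and unpaired probabilities *q<sub>i</sub>*, the three
morphospace statistics are

- **Q** = −(1/n) [ Σ<sub>i&lt;j</sub> p<sub>ij</sub> log₂ p<sub>ij</sub> +
  Σ<sub>i</sub> q<sub>i</sub> log₂ q<sub>i</sub> ] — Shannon entropy of the
  base-pairing probability matrix (bits/nt), a measure of conformational
  disorder;
- **P** — base-pairing propensity, the fraction of nucleotides paired in
  the minimum-free-energy structure;
- **S** — mean stem length, pairs per helix of the MFE structure.

Statistics are discretized into k = 24 ordered states (Wagner parsimony,
cost |i−j|). Trees are rooted by attaching a hypothetical ancestor (ANC)
that carries the polarized states — maximal disorder, minimal order —
operationalising the assumption that conformational order increases as
structures canalise in evolution. Tree fit is reported as length *s*,
consistency index CI = M/s, retention index RI = (G−s)/(G−M), rescaled
consistency index RC = CI·RI, and g1, the skewness of the tree-length
distribution over random topologies. Node distances nd (internal nodes
from the root) become relative ages 1 − nd/nd<sub>max</sub>, converted to
Gy by an OLS clock and cross-anchored through domain–RNA interaction maps.

## Worked example

```python
>>> import retrodict as rd
>>> st = rd.morphospace_stats("GGGAAACCC")
>>> round(st.Q, 4), round(st.P, 4), st.S
(0.1952, 0.6667, 3.0)
```

The nine-nucleotide hairpin folds into a single dominant stem of three
stacked pairs: six of nine positions are paired (P = 0.667), the lone
helix has length 3 (S = 3.0), and the ensemble entropy is low
(Q = 0.195 bits/nt) because the hairpin dominates the Boltzmann ensemble.

End-to-end on a synthetic eight-molecule family:

```
retrodict run --seed 17 --out demo_run
```

produces, among other artifacts, `tom.nwk` — a rooted tree of molecules
with ANC basal:

```
(ANC,((((((T001,T008),(T004,T005)),T002),T007),T006),T003));
```

`tom_fitstats.json` with the fit report
(`length 561, CI 0.533, RI 0.441, RC 0.235, g1 -0.272`; RC = CI·RI and
the negative g1 indicates phylogenetic signal in the character matrix),
and `timeline_substructures.tsv`:

```
unit	kind	age_gy	provenance	flags
acceptor	substructure	2.76535	interaction-anchor	-
anticodon_arm	substructure	0.975368	interaction-anchor	-
d_arm	substructure	1.51236	interaction-anchor	-
t_arm	substructure	2.58635	interaction-anchor	-
variable_loop	substructure	2.40735	interaction-anchor	-
```

The acceptor stem anchors as the oldest substructure and the anticodon
arm as the youngest — the ordering the underlying accretion simulation
encoded in its domain–substructure interaction map, dated through the
clock fitted on the reconstructed domain tree.

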