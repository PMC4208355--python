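# eqmotif

Analytic equilibrium (stationary) distributions for Markov jump-process
models of biochemical reaction networks — and their use in speeding up
stochastic simulation by quasi-steady-state (QSSA) averaging.

The package is a catalogue of state-space topologies for which the
equilibrium of the chemical master equation has a closed form, together
with general solvers and the machinery to verify every closed form against
a brute-force nullspace oracle:

| module | contents |
| --- | --- |
| `eqmotif.network` | reaction networks, mass-action propensities, stoichiometry, conservation laws, compatibility-class enumeration, rate matrices, mass-cutoff truncation |
| `eqmotif.solvers` | nullspace oracle (GTH elimination), finite-path detailed-balance formula with Horner normalization, circular-chain formula, Kirchhoff spanning-tree method, one-vertex gluing rule |
| `eqmotif.motifs` | named motifs: birth–death (Poisson), isomerization (binomial), TF binding to gene copies, dimerization, single-gene Bernoulli (Hill coefficient 1), sequential/independent two-site binding, hypercube compounding, glued three-site models |
| `eqmotif.crnt` | chemical reaction network theory: complex graph, linkage classes, weak reversibility, deficiency, complex-balanced steady states, product-form (conditional Poisson) equilibria |
| `eqmotif.dimer_tf` | gene regulated by dimer TFs on a ladder state space: exact product-form equilibrium, saddle-point asymptotic binding probability, ODE dimer count |
| `eqmotif.qssa` | Gillespie SSA (direct method, Philox counter-based RNG), time-weighted occupancy estimation, averaged propensities, slow-scale SSA |
| `eqmotif.compare` | full-occupancy curves of four gene-regulation mechanisms, 1/T series expansions, the sequential/independent structural equivalence |
| `eqmotif.io`, `eqmotif.fixtures`, `eqmotif.cli` | plain-text reaction format, serialization, seeded fixture generator, command line |

## Conventions (read this first)

* **Generator**: `dP/dt = Q P` with column-based `Q` (`Q[to, from]` is a
  rate; columns sum to zero). Equilibria are right nullvectors.
* **Homogeneous bimolecular propensity** is `kappa * X * (X - 1)` with
  **no factor 1/2**. Rate constants from sources using the halved
  convention must be doubled.
* Rate constants are stochastic (volume factors already absorbed).

## CLI

A network is a plain-text file, one reaction per line, with an `init:`
line fixing the compatibility class (see `examples/`):

```text
2 M <-> D ; kf=1.0 ; kr=1.0
G + D <-> Gs ; kf=1.0 ; kr=1.0
init: M=8 D=0 G=1 Gs=0
```

```sh
# equilibrium distribution (auto = catalogued closed form, else
# product-form when deficiency zero + weakly reversible, else nullspace)
eqmotif equilibrium examples/dimer_tf_ladder.rxn --method auto --out tsv

# complexes / linkage classes / deficiency / weak reversibility
eqmotif crnt-report examples/dimer_tf_ladder.rxn

# build a catalogued motif directly
eqmotif motif tf-binding -p N=2 -p T=5 -p kappa_b=1.0 -p kappa_u=2.0

# stochastic simulation; --slow-scale runs the QSSA-reduced mRNA model
eqmotif simulate examples/isomerization.rxn --t-end 1000 --seed 1
eqmotif simulate examples/single_gene_tf.rxn --t-end 1000 --seed 1 \
    --slow-scale a_u=3.0,a_b=0.5,kappa_d=1.0

# occupancy comparison of the four regulation mechanisms
eqmotif compare --mechanisms monomer,dimer,sequential,independent --T 2:512
```

Exit codes: 0 on success, 2 on validation errors.

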