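# allomap

Allosteric landscape mapping from deep mutational scanning.

`allomap` infers the causal energetic effects of mutations on an enzyme —
how much each substitution changes fold stability and how much it changes
catalytic activity beyond abundance — from paired activity/abundance
fitness data of a tiled double-mutant library, and provides the
downstream analytics that turn those energies into an allosteric map:
mutation classification, allosteric-site calling, exponential
distance-decay and directional (anisotropic) decay fitting, contact-
dynamics classification across conformational states, druggable-pocket
prioritisation, feature-based ddGa prediction, and the comparison of
regulatory-domain constructs.  It is aimed at groups running (or
simulating) multiplexed assays of enzyme variants who want energy-level
interpretation rather than raw fitness.

## Model

A molecule occupies one of three states — unfolded-inactive, folded-
inactive, folded-active — with folding energy ΔG_f and activation energy
ΔG_a (kcal/mol).  The fraction folded and the fraction folded-and-active
follow the Boltzmann distribution:

    p_f  = 1 / (1 + e^{ΔG_f/RT})
    p_fa = 1 / (1 + e^{ΔG_a/RT} (1 + e^{ΔG_f/RT}))

Mutational effects ΔΔG_f, ΔΔG_a are additive over the substitutions in a
genotype; each experiment observes an affine transform of the relevant
state probability.  Fitting the model jointly to both phenotypes across
many genetic backgrounds disentangles stability effects from genuine
activity (allosteric) effects.  Downstream, inhibitory allosteric effects
decay with minimum heavy-atom distance d from the active site as
a·e^{k·d}, summarised by the half-decay distance d_1/2 = ln2/|k|.

Everything is exercised end-to-end on synthetic studies with known
ground truth (`allomap.synth`): a 5-tile library with ~10 genetic
backgrounds per tile, planted spatial effect structure, a toy 3-D
structure, state-specific contact tables and overlapping pocket sets.

## Worked example

`examples/01_simulate_and_fit.py` simulates a small two-tile study at 10%
measurement noise and refits the model:

    $ python examples/01_simulate_and_fit.py
    library: 4146 fitness observations (380 mutations, 2 assays)
    weighted loss after fit: 3408.1 (n_obs = 4146)
    Pearson r, true vs inferred ddGf: 0.963
    Pearson r, true vs inferred ddGa: 0.960
    wild-type energies: dGf = -0.94 (true -1.00), dGa = -0.04 (true 0.00) kcal/mol

The correlations say that, despite the nonlinear genotype–fitness map and
the noise, the two-phenotype multi-background design pins down both
energies per mutation; on noiseless data the fit is exact to machine
precision.  `examples/03_distance_decay.py` fits the spatial decay of the
planted activity effects:

    fitted decay: |ddGa|0 = 1.38 kcal/mol, k = -0.064 +- 0.011 1/A (planted -0.07)
    half-decay distance d_1/2 = 10.8 A
    matched-subsample test: median inactivating k = -0.087, p = 0.0000

i.e. inhibitory effects halve roughly every 11 Å from the active site,
and the decay is significantly steeper than that of effect-matched
activating mutations — the directional asymmetry the map is designed to
expose.  The other examples cover classification and site calling (02),
contact dynamics and pocket ranking (04), and the regulatory-domain
comparison (05).

A thin CLI wraps the same library calls:

    allomap generate --seed 1 --out-dir study/
    allomap fit --fitness study/fitness.tsv --folds 10 --out energies.tsv
    allomap spatial --pdb study/structure.pdb --energies energies.tsv \
        --refs residue:23,residue:24 --out decay.json

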