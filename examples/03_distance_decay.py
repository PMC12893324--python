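"""Quantify the distance dependence of allosteric effects.

Takes the planted ground-truth activity energies of a synthetic study,
computes each residue's minimum heavy-atom distance to the active site,
fits the exponential decay |ddGa| = a * exp(k * d), and reports the decay
rate and half-decay distance, plus the effect-size-matched comparison of
inhibitory vs activating mutations.
"""

import numpy as np

from allomap.spatial import (
    fit_exponential_decay,
    matched_subsample_decay_test,
    min_distance_to_active_site,
)
from allomap.synth import GeneratorConfig, generate_study

cfg = GeneratorConfig(n_positions=80, n_tiles=4, backgrounds_per_tile=6,
                      frac_allosteric=0.4, decay_rate=-0.07)
study = generate_study(cfg, seed=2)
truth = study.truth
dist = min_distance_to_active_site(
    study.structure, [("residue", r) for r in truth.active_site]
)

# per-site mean |ddGa| vs distance, over sites carrying activity effects
sites = sorted({m.position for m, v in truth.ddGa.items() if v != 0})
d = np.array([dist[p] for p in sites])
y = np.array([np.mean([abs(truth.ddGa[m]) for m in truth.ddGa
                       if m.position == p]) for p in sites])
decay = fit_exponential_decay(d, y)
print(f"fitted decay: |ddGa|0 = {decay.amplitude:.2f} kcal/mol, "
      f"k = {decay.rate:.3f} +- {decay.ci95_k:.3f} 1/A "
      f"(planted {cfg.decay_rate})")
print(f"half-decay distance d_1/2 = {decay.d_half:.1f} A")

# inhibitory effects decay with distance; activating effects do not
# (magnitudes below 0.1 kcal/mol carry no usable signal and are dropped)
inact = [(dist[m.position], v) for m, v in truth.ddGa.items() if v > 0.1]
act = [(dist[m.position], v) for m, v in truth.ddGa.items() if v < -0.1]
p, med_k = matched_subsample_decay_test(
    tuple(np.array(z) for z in zip(*inact)),
    tuple(np.array(z) for z in zip(*act)),
    n_subsamples=2000, seed=0,
)
print(f"matched-subsample test: median inactivating k = {med_k:.3f}, "
      f"p = {p:.4f}")
# small p: effect-matched inhibitory mutations decay more steeply with
# distance than activating ones, the hallmark asymmetry of the map
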