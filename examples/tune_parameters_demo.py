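"""Grid-search fusion coefficients on a pair of training phantoms.

Mimics leave-one-out parameter tuning at desk scale: every grid point is
scored by the mean similarity index over training targets with known truth,
and the best point is returned (first-in-grid wins ties).
"""

from malsf import (
    AtlasEnsemble,
    AtlasPerturbSpec,
    FusionParams,
    PhantomSpec,
    make_atlas_ensemble,
    make_phantom,
    tune_parameters,
)

targets = []
for seed in (0, 1):
    img, truth = make_phantom(PhantomSpec(seed=seed))
    ensemble = make_atlas_ensemble(truth, AtlasPerturbSpec(n_atlases=5, seed=seed + 10))
    targets.append((img, truth, ensemble))

base = FusionParams(max_iters=40)
grid = {"alpha": [0.05, 0.1, 0.2], "upsilon": [0.01, 0.05]}
best = tune_parameters(targets, grid, base_params=base)
print(f"best alpha   : {best.alpha}")
print(f"best upsilon : {best.upsilon}")
# alpha weighs the atlas shape prior, upsilon the curvature (smoothing) flow;
# the selected pair maximizes mean Dice over the training targets.
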