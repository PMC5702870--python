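"""Simulate numerosity-tuned voxels and recover their tuning by grid search.

Voxels respond with a Gaussian tuned to log10 numerosity, convolved with
the HRF, plus white noise at amplitude/noise-SD = 2. The grid fit should
place the preferred numerosity close to truth.
"""

import numpy as np

import numpref as npf
from numpref.features import FeatureTimecourse
from numpref.prf import GridSpec

design = npf.build_default_design(cycles=20)  # 200 time points at TR = 2 s
track = FeatureTimecourse(
    "numerosity", "any", design.numerosities().astype(float), "log10"
)

truth = npf.make_numerosity_map(30, seed=1)
voxels = npf.simulate_voxels(truth, design, track, ("run",), noise_sd=0.5, seed=1)

grid = GridSpec.from_tracks(track)
errors, r2s = [], []
for i in range(len(truth)):
    fit = npf.fit_grid(voxels.data["run"][i], track, design, grid=grid)
    errors.append(abs(fit.tuning.preferred - truth.preferred.iloc[i]))
    r2s.append(fit.r2)

print(f"median |preferred error| : {np.median(errors):.3f} log10 units")
print(f"median variance explained: {np.median(r2s):.3f}")
print(
    "\nAn error of ~0.04 log10 units at preferred numerosity 4 is roughly a\n"
    "third of an item; R^2 near 0.6 is the expected ceiling at this noise level."
)
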