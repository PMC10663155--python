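"""Run the preprocessing chain: intra-run matching (50 ppm), scattered-ion
filtering (< 9 eight-connected pixels), inter-run matching (20 ppm),
consensus filtering, median scaling and run-wise batch correction.
"""

import warnings

import numpy as np

from ioncoloc.peakflow import preprocess_runs
from ioncoloc.synthio import SynthConfig, generate_biclonal_runs

warnings.filterwarnings("ignore")

runs, truth = generate_biclonal_runs(SynthConfig(grid_w=32, grid_h=32, seed=7))
ft = preprocess_runs(runs)

print(f"feature table: {ft.n_pixels} tissue pixels x {ft.n_features} consensus features")
planted = truth.features.query("kind == 'module'")
hits = sum((np.abs(ft.mz - m) / m * 1e6 < 20).any() for m in planted["mz"])
print(f"planted module features recovered: {hits}/{len(planted)}")
noise = truth.features.query("kind == 'noise'")
leaks = sum((np.abs(ft.mz - m) / m * 1e6 < 20).any() for m in noise["mz"])
print(f"scattered noise ions surviving the spatial filter: {leaks}/{len(noise)}")
dropped = sum(len(v) for v in ft.provenance["dropped_features"].values())
print(f"features dropped by the scatter/off-tissue filter across runs: {dropped}")
# Every planted ion should map to one consensus mass within 20 ppm and
# every scattered noise ion should be gone.
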