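"""Store and reload contact matrices as single-resolution .cool files.

Writes a simulated matrix to the cooler HDF5 layout (chroms/bins/pixels
tables), reads it back, and shows balanced reading against a weight
column added to the bin table.
"""

import os

import h5py
import numpy as np

from hicvst import SynthConfig, read_cool, simulate_pair, write_cool

OUT = os.path.join(os.path.dirname(__file__), "..", "scratch")
os.makedirs(OUT, exist_ok=True)
path = os.path.join(OUT, "example.cool")

rep1, _, _ = simulate_pair(SynthConfig(seed=1, n_bins=120))
write_cool(rep1, path)

back = read_cool(path, rep1.chrom1, rep1.chrom2)
assert back.pixel_set() == rep1.pixel_set()
print(f"round trip ok: {back.n_pixels} pixels, bin_size {back.bin_size}")

# Attach a toy balancing weight column and read the balanced matrix:
# each pixel value is multiplied by weight[i] * weight[j].
with h5py.File(path, "r+") as fh:
    n = fh["bins/start"].shape[0]
    rng = np.random.default_rng(0)
    fh["bins"].create_dataset("weight", data=rng.uniform(0.5, 2.0, n))

balanced = read_cool(path, rep1.chrom1, rep1.chrom2, balanced=True)
print(f"balanced values: min {balanced.value.min():.3f}, "
      f"max {balanced.value.max():.3f} (raw max {rep1.value.max():.0f})")
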