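"""Quantize one tile with K-Means and Mean-Shift colour clustering.

Each pixel is treated as a point in normalized RGB space; the transform
replaces it with its cluster-centre colour.  K-Means fixes the palette
size (K = 8 here); Mean-Shift discovers the number of colour modes from
the bandwidth (0.2 here).
"""

import numpy as np

from histoclust import (
    ClusterParams,
    SyntheticParams,
    generate_synthetic_dataset,
    quantize_image,
)

tile = generate_synthetic_dataset(SyntheticParams(n_images=1, seed=4)).images[0]
print(f"original distinct colours: {len(np.unique(tile.reshape(-1, 3), axis=0))}")

km = quantize_image(tile, ClusterParams(method="km", k=8, seed=0))
print(f"K-Means (K=8): palette of {len(km.palette)} colours, "
      f"{len(np.unique(km.pixels.reshape(-1, 3), axis=0))} distinct in output")

ms = quantize_image(tile, ClusterParams(method="ms", bandwidth=0.2))
print(f"Mean-Shift (BW=0.2): {len(ms.palette)} colour modes found")
print("-> the transform exposes each tile's colour structure to the networks")
print("   while discarding pixel-level stain noise.")
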