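"""Encode keypoints as Gaussian heatmaps and decode them back to sub-pixel.

Shows the representation the network is trained on: per-keypoint Gaussian
confidence maps (peak 1 at the landmark) plus the pseudo-line channel, and
the sub-pixel decoder that inverts them.
"""

import numpy as np

from echolv import KeypointName, decode_heatmap, encode_keypoints, generate_phantom
from echolv.phantom import PhantomSpec

frame, image, truth = generate_phantom(PhantomSpec(), seed=3)
stack = encode_keypoints(truth, frame, working_size=(320, 320), sigma_px=15.0)

print("channel   truth (x, y)          decoded (x, y)        error px  conf")
for i, name in enumerate(KeypointName):
    tx, ty = truth.points[name]
    x, y, conf = decode_heatmap(stack.planes[i])
    err = np.hypot(x - tx, y - ty)
    print(f"{name.name:9s} ({tx:7.2f}, {ty:7.2f})  ({x:7.2f}, {y:7.2f})  "
          f"{err:8.5f}  {conf:.3f}")
print("\nDecoding error is ~1e-6 px on exact Gaussians: the log-quadratic")
print("refinement is exact for Gaussian-shaped peaks. The pseudo-line channel")
print(f"(max {stack.planes[4].max():.2f}) ties the four landmarks to a line.")
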