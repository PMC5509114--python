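"""From a silhouette image to homologous landmarks.

Renders a molar-like outline as a black-on-white mask (what a crowd
worker submits), extracts its boundary, fits 10 elliptical Fourier
harmonics and regenerates 150 canonical-start landmarks — the step
that makes tracings of the same tooth directly comparable.
"""

import numpy as np

from occlumorph import (binarize, canonicalize, cumulative_power,
                        efa_forward, extract_contour, rasterize,
                        riemann_distance, tooth_outline)
from occlumorph.contours import mask_to_image

outline = tooth_outline(aspect=1.6, waist=0.12)
mask = rasterize(outline, image_size=512)
image = np.asarray(mask_to_image(mask))
contour = extract_contour(binarize(image))
print(f"extracted boundary: {len(contour)} vertices, "
      f"area {abs(contour.signed_area()):.0f} px^2")

landmarks = canonicalize(contour.points, H=10, K=150)
print(f"regenerated {len(landmarks)} landmarks from the canonical start")

power = cumulative_power(efa_forward(contour.points, H=20))
print(f"harmonic power captured by H=10: {100 * power[9]:.2f}%")

err = riemann_distance(landmarks, canonicalize(outline))
print(f"shape distance to the original outline: {err:.4f}")
print("-> small (< 0.05): rasterizing at 512 px and re-extracting barely "
      "perturbs the shape")
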