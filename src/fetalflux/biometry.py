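"""Volumetry: label-map volumes and volume-to-weight conversion.

The brain label lies inside the fetal body, so fetal volume counts both
labels.  Conversion factors (g/mL tissue densities) are required
configuration; the shipped defaults are provisional.
"""

from __future__ import annotations

import numpy as np

from .types import ConversionFactors, ValidationError, VolumeSegmentation

__all__ = ["measure_volumes", "volumes_to_weights"]


def measure_volumes(seg: VolumeSegmentation) -> tuple[float, float]:
    """(fetal_ml, brain_ml) from a 0/1/2 label map."""
    labels = seg.label_map
    n_brain = int(np.count_nonzero(labels == 2))
    n_fetal = int(np.count_nonzero(labels == 1)) + n_brain
    to_ml = seg.voxel_size_mm3 / 1000.0
    return n_fetal * to_ml, n_brain * to_ml


def volumes_to_weights(fetal_ml: float, brain_ml: float,
                       factors: ConversionFactors,
                       ) -> tuple[float, float, float]:
    """(fetal_g, brain_g, brain % of body weight)."""
    fetal_g = fetal_ml * factors.fetal_g_per_ml
    brain_g = brain_ml * factors.brain_g_per_ml
    if fetal_g == 0:
        if brain_g > 0:
            raise ValidationError("brain weight positive with zero fetal weight")
        return 0.0, 0.0, 0.0
    return fetal_g, brain_g, brain_g / fetal_g * 100.0
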