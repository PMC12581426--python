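"""The five linear sella turcica measurements.

Every measure is a 3D Euclidean distance between two named landmarks placed
by the operator and verified in orthogonal views:

============  =======================================================
st_length     length_ant ↔ length_post (median-sagittal sella extent)
st_width      interclinoid_left ↔ interclinoid_right
st_height     height_sup ↔ height_inf (caudo-cranial extent)
st_diameter   dorsum_posterior_cranial ↔ tuberculum
cb            sella_mid ↔ nasofrontal_suture (cranial-base length)
============  =======================================================

No projection onto an estimated mid-sagittal plane is performed; the
measurements are taken three-dimensionally.
"""
from __future__ import annotations

import numpy as np

from .types import LandmarkSet, STMeasurements

__all__ = ["distance", "measure_st", "MEASUREMENT_ENDPOINTS"]

#: measure name -> (landmark, landmark)
MEASUREMENT_ENDPOINTS: dict[str, tuple[str, str]] = {
    "st_length": ("length_ant", "length_post"),
    "st_width": ("interclinoid_left", "interclinoid_right"),
    "st_height": ("height_sup", "height_inf"),
    "st_diameter": ("dorsum_posterior_cranial", "tuberculum"),
    "cb": ("sella_mid", "nasofrontal_suture"),
}


def distance(p, q) -> float:
    """Euclidean distance in mm."""
    p = np.asarray(p, dtype=float).reshape(3)
    q = np.asarray(q, dtype=float).reshape(3)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("points must be finite")
    return float(np.linalg.norm(p - q))


def measure_st(lm: LandmarkSet) -> STMeasurements:
    """Compute the five linear measures; volumes are left NaN.

    Raises :class:`~sella3d.types.MissingLandmarkError` naming the first
    absent landmark.
    """
    values = {
        name: distance(*lm.require(a, b))
        for name, (a, b) in MEASUREMENT_ENDPOINTS.items()
    }
    return STMeasurements(**values)
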