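"""Shared geometric conventions.

All pose coordinates live in the image frame: x to the right, y *down*
(row-major pixels, origin at the top-left). In this frame a rotation from
+x toward +y appears **clockwise** to someone looking at the image, and the
whole package uses clockwise-positive signed angles. The trajectory
generator, the commutation controller and the stage simulator all import
from here so the sign convention cannot drift between them.

Angles are degrees throughout unless a name says otherwise.
"""

from __future__ import annotations

import numpy as np

#: heading angle of a vector in the image frame, CW-positive.
#: atan2(y, x) increases from +x toward +y, which is clockwise on screen.


def heading_angle_deg(vec: np.ndarray) -> float:
    """Angle of a heading vector in degrees, clockwise-positive in image view."""
    return float(np.degrees(np.arctan2(vec[..., 1], vec[..., 0])))


def unit(vec: np.ndarray) -> np.ndarray:
    """Normalise to unit length. Raises on (near-)zero vectors."""
    n = np.linalg.norm(vec)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero-length vector")
    return np.asarray(vec, dtype=float) / n


def wrap_deg(angle: float | np.ndarray):
    """Wrap an angle (deg) into (-180, +180], mapping -180 to +180."""
    return 180.0 - ((180.0 - np.asarray(angle)) % 360.0)


def heading_from_angle_deg(angle_deg: float | np.ndarray) -> np.ndarray:
    """Unit heading vector(s) for CW-positive image-frame angle(s) in degrees."""
    a = np.radians(np.asarray(angle_deg, dtype=float))
    return np.stack([np.cos(a), np.sin(a)], axis=-1)
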