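"""Intrinsic- and extrinsic-frame class labelings for the 8-target task.

At elbow angle 0 deg the two frames coincide: target k requires finger
movement k.  Rotating the elbow by 90 deg rotates the mapping between
target direction (extrinsic, world-referenced) and finger movement
(intrinsic, body-referenced) by two steps of the 45-deg target grid:
target 8 cues finger extension at 0 deg but adduction at 90 deg, and
target 2 cues adduction at 0 deg but flexion at 90 deg.  Both printed
correspondences are reproduced by a single cyclic shift of +2 at 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LabelError

#: Cyclic shift (in 45-deg steps) between target and movement at elbow 90 deg.
INTRINSIC_SHIFT_90 = 2


def _validate(target, angle):
    target = np.asarray(target, dtype=int)
    angle = np.asarray(angle, dtype=int)
    if np.any((target < 1) | (target > 8)):
        raise LabelError("target must be in 1..8")
    if np.any((angle != 0) & (angle != 90)):
        raise LabelError("elbow angle must be 0 or 90")
    return target, angle


def ext_label(target, angle):
    """Extrinsic (target-direction) class: the target id, angle ignored."""
    target, angle = _validate(target, angle)
    out = target.copy()
    return int(out) if out.ndim == 0 else out


def int_label(target, angle, shift: int = INTRINSIC_SHIFT_90):
    """Intrinsic (finger-movement) class.

    Identity at elbow 0 deg; at 90 deg the movement class is the target
    cyclically shifted by ``shift`` steps on the 45-deg grid.
    """
    target, angle = _validate(target, angle)
    out = np.where(angle == 90, ((target - 1 + shift) % 8) + 1, target)
    return int(out) if out.ndim == 0 else out


def direction_angle(label) -> np.ndarray:
    """Direction angle theta in radians for a class label on the 45-deg grid."""
    label = np.asarray(label, dtype=int)
    return (label - 1) * (np.pi / 4.0)


@dataclass(frozen=True)
class LabelScheme:
    """A named (target, angle) -> class mapping: ``ext`` or ``int``."""

    name: str
    shift: int = INTRINSIC_SHIFT_90

    def __post_init__(self):
        if self.name not in ("ext", "int"):
            raise LabelError("scheme name must be 'ext' or 'int'")

    def apply(self, target, angle):
        if self.name == "ext":
            return ext_label(target, angle)
        return int_label(target, angle, shift=self.shift)


EXT = LabelScheme("ext")
INT = LabelScheme("int")
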