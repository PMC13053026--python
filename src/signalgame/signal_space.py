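"""Trackpad signal space: pad coordinates, CIELAB colors, and dot signals.

The sender produces every signal by placing a finger on a rectangular
trackpad.  The normalized finger position is the *underlying* signal in
all conditions; what each player actually sees depends on the condition:

* ``high``      — both players see the color the position maps to;
* ``low``       — both players see a black dot at the position;
* ``one_sided`` — the sender sees the color, the receiver sees the dot.

The color mapping places the pad on a surface through CIELAB space:
``a*`` runs red→green left to right, ``b*`` runs yellow→blue bottom to
top, and lightness ``L*`` is held at 75 on the bottom half of the pad and
falls linearly from 75 to 30 on the top half.  The bottom-left corner is
therefore a saturated red, the bottom edge sweeps red→orange→yellow→green,
and the top edge carries dark blues and purples.

Coordinates are normalized to the unit square with ``v = 0`` at the
*bottom* edge; this is the only orientation under which the lightness
rule is continuous at mid-pad and stays within [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "CONDITIONS",
    "ROLES",
    "PadPoint",
    "LabColor",
    "DotSignal",
    "SignalView",
    "pad_to_lab",
    "lab_to_rgb",
    "render_view",
    "colorspace_image",
]

CONDITIONS = ("high", "low", "one_sided")
ROLES = ("sender", "receiver")

Condition = Literal["high", "low", "one_sided"]
Role = Literal["sender", "receiver"]


@dataclass(frozen=True)
class PadPoint:
    """Normalized finger position on the trackpad.

    ``u`` runs left (0) to right (1); ``v`` runs bottom (0) to top (1).
    """

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValueError(
                f"pad coordinates must lie in [0, 1]^2, got ({self.u}, {self.v})"
            )


@dataclass(frozen=True)
class LabColor:
    """A CIELAB color with L* in [0, 100] and a*, b* in [-128, 128]."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 100.0):
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")
        if not (-128.0 <= self.a <= 128.0 and -128.0 <= self.b <= 128.0):
            raise ValueError(f"a*, b* must lie in [-128, 128], got ({self.a}, {self.b})")


@dataclass(frozen=True)
class DotSignal:
    """Dot position on the message panel; equals the generating pad point."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValueError(
                f"dot coordinates must lie in [0, 1]^2, got ({self.u}, {self.v})"
            )


@dataclass(frozen=True)
class SignalView:
    """What one role sees on the message panel for a sent point.

    ``kind`` is ``"color"``, ``"dot"`` or ``"blank"`` (nothing sent yet);
    the payload type must match the kind.
    """

    kind: Literal["color", "dot", "blank"]
    payload: Optional[Union[LabColor, DotSignal]] = None

    def __post_init__(self) -> None:
        if self.kind == "color" and not isinstance(self.payload, LabColor):
            raise ValueError("color view requires a LabColor payload")
        if self.kind == "dot" and not isinstance(self.payload, DotSignal):
            raise ValueError("dot view requires a DotSignal payload")
        if self.kind == "blank" and self.payload is not None:
            raise ValueError("blank view carries no payload")


BLANK_VIEW = SignalView("blank", None)


def pad_to_lab(p: PadPoint) -> LabColor:
    """Map a pad position to its CIELAB color.

    ``a* = -128 + (1 - u) * 256`` and ``b* = -128 + (1 - v) * 256``, so the
    left edge is maximally red and the bottom edge maximally yellow.  L* is
    75 for ``v <= 0.5`` and ``120 - 90 v`` above, which is continuous at
    mid-pad and reaches its minimum of 30 at the top edge.
    """
    a = -128.0 + (1.0 - p.u) * 256.0
    b = -128.0 + (1.0 - p.v) * 256.0
    L = 75.0 if p.v <= 0.5 else 120.0 - 90.0 * p.v
    return LabColor(L, a, b)


def lab_to_rgb(c: LabColor) -> tuple[float, float, float]:
    """Convert a CIELAB color to sRGB in [0, 1]^3 (D65, 2° observer).

    Much of the pad maps outside the sRGB gamut; out-of-range channels are
    clamped to [0, 1], so the conversion never fails.
    """
    arr = np.array([[c.L, c.a, c.b]], dtype=float)
    with warnings.catch_warnings():
        # out-of-gamut Lab values are clamped, not treated as errors
        warnings.simplefilter("ignore")
        rgb = _skcolor.lab2rgb(arr)
    r, g, b = np.clip(rgb[0], 0.0, 1.0)
    return float(r), float(g), float(b)


def render_view(condition: str, role: str, p: Optional[PadPoint]) -> SignalView:
    """Render what ``role`` sees in ``condition`` for sent point ``p``.

    ``p=None`` (nothing sent) renders as the blank gray panel.  In the
    one-sided condition the sender's view equals the high-condition view and
    the receiver's view equals the low-condition view, built from the same
    pad point.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    if p is None:
        return BLANK_VIEW
    sees_color = condition == "high" or (condition == "one_sided" and role == "sender")
    if sees_color:
        return SignalView("color", pad_to_lab(p))
    return SignalView("dot", DotSignal(p.u, p.v))


def colorspace_image(n: int = 256) -> np.ndarray:
    """Sample the pad→sRGB map on an ``n × n`` grid.

    Returns an array of shape ``(n, n, 3)``; row index increases with ``v``
    (bottom row first), column index with ``u``.  Useful for rendering the
    underlying colorspace as an image (use ``origin='lower'``).
    """
    u = np.linspace(0.0, 1.0, n)
    v = np.linspace(0.0, 1.0, n)
    uu, vv = np.meshgrid(u, v)
    a = -128.0 + (1.0 - uu) * 256.0
    b = -128.0 + (1.0 - vv) * 256.0
    L = np.where(vv <= 0.5, 75.0, 120.0 - 90.0 * vv)
    lab = np.dstack([L, a, b])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rgb = _skcolor.lab2rgb(lab)
    return np.clip(rgb, 0.0, 1.0)
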