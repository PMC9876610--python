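"""Screen and area-of-interest (AOI) geometry.

All gaze coordinates are screen pixels, origin at the top-left corner of a
1920 x 1080 display. Angular quantities (fixation dispersion thresholds,
stimulus sizes) are converted to pixels from the physical viewing set-up:
a 24-inch 16:9 panel (531 x 299 mm active area) viewed at 60 cm. These
constants are configurable because they are properties of the recording
set-up, not of the analysis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

SCREEN_W_PX = 1920
SCREEN_H_PX = 1080
SCREEN_W_MM = 531.0
SCREEN_H_MM = 299.0
VIEW_DIST_MM = 600.0


def px_per_degree(
    view_dist_mm: float = VIEW_DIST_MM,
    screen_w_mm: float = SCREEN_W_MM,
    screen_w_px: int = SCREEN_W_PX,
) -> float:
    """Pixels subtended by one degree of visual angle at screen centre."""
    mm_per_deg = 2.0 * view_dist_mm * math.tan(math.radians(0.5))
    return mm_per_deg / (screen_w_mm / screen_w_px)


def degrees_to_px(deg: float, ppd: float | None = None) -> float:
    return deg * (ppd if ppd is not None else px_per_degree())


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with half-open membership [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle: {self}")

    def contains(self, x: float, y: float) -> bool:
        return (self.x0 <= x < self.x1) and (self.y0 <= y < self.y1)

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0


def default_face_rect(face_deg: float = 20.0, ppd: float | None = None) -> Rect:
    """Centred square face stimulus subtending ``face_deg`` degrees."""
    side = degrees_to_px(face_deg, ppd)
    cx, cy = SCREEN_W_PX / 2.0, SCREEN_H_PX / 2.0
    return Rect(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)


def default_eyes_rect(face: Rect, top_frac: float = 0.25, bottom_frac: float = 0.45) -> Rect:
    """Eyes band: full face width, from ``top_frac`` to ``bottom_frac`` of face height.

    Both eyes are covered by a single joint region; fixations on either eye
    count as eye-looking.
    """
    return Rect(
        face.x0,
        face.y0 + top_frac * face.height,
        face.x1,
        face.y0 + bottom_frac * face.height,
    )


@dataclass(frozen=True)
class AOISet:
    """The two analysis regions: an eyes band nested inside the face."""

    eyes_rect: Rect
    face_rect: Rect
    screen_w: int = SCREEN_W_PX
    screen_h: int = SCREEN_H_PX

    def __post_init__(self) -> None:
        e, f = self.eyes_rect, self.face_rect
        inside = f.x0 <= e.x0 and e.x1 <= f.x1 and f.y0 <= e.y0 and e.y1 <= f.y1
        if not inside:
            raise ValueError("eyes_rect must lie fully inside face_rect")

    @classmethod
    def default(cls) -> "AOISet":
        face = default_face_rect()
        return cls(eyes_rect=default_eyes_rect(face), face_rect=face)

    def label(self, x: float, y: float) -> str:
        """Classify a point: 'eyes', 'face' (rest of face) or 'off'.

        Rectangle edges follow the half-open convention, so a point exactly
        on the right or bottom edge of the eyes band falls to 'face'.
        """
        if self.eyes_rect.contains(x, y):
            return "eyes"
        if self.face_rect.contains(x, y):
            return "face"
        return "off"
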