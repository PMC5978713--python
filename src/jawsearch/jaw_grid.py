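"""Conformal jaw placement and the X-jaw search grid.

Jaw coordinates are signed millimetres at the isocenter plane (IEC-style:
x1 <= x2, bank 1 on the negative side; isocenter at the target centroid).
The conformal baseline places the X jaws exactly on the target's
beam's-eye-view border with no margin, and retracts the Y jaws outward by
one adjacent MLC leaf width to capture scatter.

The search grid closes each X jaw inward from conformal in fixed steps:
with ``n`` offsets per bank (0, step, ..., (n-1)*step) the Cartesian
product yields n^2 candidate settings, indexed row-major from 1 with the
conformal setting first.  Settings whose residual field width falls below a
minimum are emitted flagged invalid rather than dropped, so grid indexing
stays dense and the n x n heat map is complete.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BEVExtent",
    "JawSetting",
    "GridError",
    "conformal_jaws",
    "generate_grid",
    "DEFAULT_MIN_WIDTH_MM",
]

DEFAULT_MIN_WIDTH_MM = 20.0


class GridError(ValueError):
    """Invalid jaw geometry or empty search space."""


@dataclass(frozen=True)
class BEVExtent:
    """Target projection bounds (mm) in the beam's-eye-view at isocenter."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise GridError("degenerate BEV extent (min must be < max)")


@dataclass(frozen=True)
class JawSetting:
    """One candidate jaw configuration.

    ``offset1``/``offset2`` record the inward X-jaw travel (mm, >= 0) from
    the conformal position of bank 1/bank 2, so heat-map axes can be
    labeled by travel rather than absolute coordinate.  ``index`` is the
    1-based row-major grid index (conformal = 1); ``valid`` is False when
    the residual field width violates the configured minimum.
    """

    x1: float
    x2: float
    y1: float
    y2: float
    offset1: float = 0.0
    offset2: float = 0.0
    index: int = 1
    valid: bool = True

    def __post_init__(self) -> None:
        if self.x2 - self.x1 <= 0:
            raise GridError(f"setting {self.index}: non-positive field width")
        if self.offset1 < 0 or self.offset2 < 0:
            raise GridError(f"setting {self.index}: offsets must be >= 0")

    @property
    def field_width(self) -> float:
        return self.x2 - self.x1

    @property
    def is_conformal(self) -> bool:
        return self.offset1 == 0.0 and self.offset2 == 0.0

    @property
    def plan_id(self) -> str:
        return f"plan_{self.index:03d}"


def conformal_jaws(extent: BEVExtent, leaf_width: float) -> JawSetting:
    """Conformal baseline: X jaws on the BEV border, Y jaws out one leaf.

    ``leaf_width`` (mm, >= 0) is the adjacent-leaf retraction applied to
    both Y jaws for scatter contribution.
    """
    if leaf_width < 0:
        raise GridError("leaf_width must be >= 0")
    return JawSetting(
        x1=extent.x_min,
        x2=extent.x_max,
        y1=extent.y_min - leaf_width,
        y2=extent.y_max + leaf_width,
        offset1=0.0,
        offset2=0.0,
        index=1,
        valid=True,
    )


def generate_grid(
    conformal: JawSetting,
    step: float,
    n_steps_per_bank: int,
    min_width: float = DEFAULT_MIN_WIDTH_MM,
) -> list[JawSetting]:
    """All n^2 jaw settings from the per-bank offset grid 0..(n-1)*step.

    Ordering is row-major in (offset1, offset2) with consecutive 1-based
    indices; the conformal setting is index 1.  Settings with residual
    width below ``min_width`` carry ``valid=False``.  Raises
    :class:`GridError` when even the conformal width is at or below
    ``min_width`` (no search space).
    """
    if step <= 0:
        raise GridError("step must be positive")
    if n_steps_per_bank < 1:
        raise GridError("need at least one offset position per bank")
    if min_width <= 0:
        raise GridError("min_width must be positive")
    w0 = conformal.field_width
    if w0 <= min_width:
        raise GridError(
            f"conformal field width {w0:g} mm <= min_width {min_width:g} mm: no search space"
        )
    settings: list[JawSetting] = []
    idx = 1
    for i in range(n_steps_per_bank):
        off1 = i * step
        for j in range(n_steps_per_bank):
            off2 = j * step
            width = w0 - off1 - off2
            valid = width >= min_width
            if width <= 0:
                # geometrically impossible aperture: clamp to a thin sliver so
                # the record keeps real coordinates; always flagged invalid
                x1 = conformal.x1 + off1
                x2 = x1 + 1e-6
                valid = False
            else:
                x1 = conformal.x1 + off1
                x2 = conformal.x2 - off2
            settings.append(
                JawSetting(
                    x1=x1,
                    x2=x2,
                    y1=conformal.y1,
                    y2=conformal.y2,
                    offset1=off1,
                    offset2=off2,
                    index=idx,
                    valid=valid,
                )
            )
            idx += 1
    return settings
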