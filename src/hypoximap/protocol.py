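"""Acquisition protocol constants for the small-animal 7 T study.

The diffusion series uses 11 b-values spanning 0-2000 s/mm² (dense
low-b sampling to resolve the perfusion compartment, three high-b
points for the tissue compartment).  The multi-echo gradient-echo
series uses 16 evenly spaced echoes from 3.4 to 92.1 ms.  In-plane
geometry is a 25.6 mm field of view on a 96x96 matrix (0.2667 mm
pixels) with 1 mm slices.
"""

from __future__ import annotations

from pydantic import BaseModel, field_validator

#: Diffusion weightings, s/mm².
B_VALUES: tuple[float, ...] = (
    0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 1000.0, 1500.0, 2000.0,
)

#: Gradient-echo echo times, milliseconds.
ECHO_TIMES_MS: tuple[float, ...] = (
    3.4, 9.3, 15.2, 21.2, 27.1, 33.0, 38.9, 44.8,
    50.7, 56.6, 62.5, 68.5, 74.4, 80.3, 86.2, 92.1,
)

FOV_MM: float = 25.6
MATRIX_SIZE: int = 96
SLICE_THICKNESS_MM: float = 1.0


class AcquisitionProtocol(BaseModel):
    """MR protocol: b-value list, echo times and slice geometry."""

    b_values: tuple[float, ...] = B_VALUES
    echo_times_ms: tuple[float, ...] = ECHO_TIMES_MS
    fov_mm: float = FOV_MM
    matrix_size: int = MATRIX_SIZE
    slice_thickness_mm: float = SLICE_THICKNESS_MM

    @field_validator("b_values")
    @classmethod
    def _b_nonneg_with_zero(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(b < 0 for b in v):
            raise ValueError("b-values must be non-negative")
        if 0.0 not in v:
            raise ValueError("a b=0 acquisition is required")
        return v

    @field_validator("echo_times_ms")
    @classmethod
    def _te_increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(t <= 0 for t in v):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("echo times must be strictly increasing")
        return v

    @property
    def in_plane_voxel_mm(self) -> float:
        return self.fov_mm / self.matrix_size

    @property
    def echo_times_s(self) -> tuple[float, ...]:
        return tuple(t / 1000.0 for t in self.echo_times_ms)
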