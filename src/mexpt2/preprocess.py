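"""Effective-echo selection and background-noise subtraction.

The first acquired echo of the alternating-refocusing multi-echo train is
unreliable and is dropped (not extrapolated).  The residual baseline offset of
the magnitude images is estimated as the mean signal of a signal-free (air)
region at every effective echo and subtracted from each voxel before fitting;
negative post-subtraction values are retained so that the fit objective stays
unbiased in the noise-dominated tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "NoiseProfile",
    "select_effective_echoes",
    "estimate_background_noise",
    "subtract_noise",
    "eligible_voxel_mask",
]


@dataclass(frozen=True)
class NoiseProfile:
    """Mean background magnitude per effective echo (a.u.)."""

    e: np.ndarray
    n_background_voxels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "e", np.asarray(self.e, dtype=float))
        if self.e.ndim != 1:
            raise ValueError("noise profile must be a vector")

    def to_dict(self) -> dict:
        return {"e": self.e.tolist(), "n_background_voxels": self.n_background_voxels}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseProfile":
        return cls(e=np.asarray(d["e"], dtype=float),
                   n_background_voxels=int(d["n_background_voxels"]))


def select_effective_echoes(
    stack: np.ndarray, protocol: AcquisitionProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Drop the first acquired echo from an (H, W, K_acq) stack.

    Returns the restricted stack and the matching effective echo times.
    Voxel values at retained echoes are untouched.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected an (H, W, n_echoes) stack")
    if stack.shape[2] != protocol.n_acquired:
        raise ValueError(
            f"stack has {stack.shape[2]} echoes but protocol lists "
            f"{protocol.n_acquired}"
        )
    return stack[:, :, 1:], protocol.effective_tes


def estimate_background_noise(
    stack: np.ndarray, background_mask: np.ndarray
) -> NoiseProfile:
    """Mean background signal at each effective echo.

    Parameters
    ----------
    stack : (H, W, K) array
        Effective-echo stack.
    background_mask : (H, W) bool array
        Signal-free voxels; must be nonempty and disjoint from tissue ROIs.
    """
    stack = np.asarray(stack, dtype=float)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != stack.shape[:2]:
        raise ValueError("background mask and stack grids differ")
    n = int(background_mask.sum())
    if n == 0:
        raise ValueError("background mask is empty")
    e = stack[background_mask, :].mean(axis=0)
    return NoiseProfile(e=e, n_background_voxels=n)


def subtract_noise(signal: np.ndarray, profile: NoiseProfile) -> np.ndarray:
    """Elementwise signal - e; negative results are retained, not clipped."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != profile.e.size:
        raise ValueError("signal and noise profile lengths differ")
    return signal - profile.e


def eligible_voxel_mask(
    stack: np.ndarray,
    profile: NoiseProfile,
    tissue_mask: np.ndarray,
    factor: float = 2.0,
    n_lead_echoes: int = 3,
) -> np.ndarray:
    """Flag voxels with enough early signal to be worth fitting.

    A voxel is eligible when its mean noise-corrected signal over the first
    ``n_lead_echoes`` effective echoes exceeds ``factor * mean(e)``.  With a
    zero-mean (gaussian) background this floor is effectively "positive early
    signal".
    """
    corrected = stack[..., :n_lead_echoes] - profile.e[:n_lead_echoes]
    lead = corrected.mean(axis=-1)
    floor = factor * float(profile.e.mean())
    return np.asarray(tissue_mask, dtype=bool) & (lead > floor)
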