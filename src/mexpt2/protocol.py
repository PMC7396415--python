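"""Multi-echo acquisition protocol: echo-time vector and effective-echo subset.

The reference acquisition is a single-slice CPMG multi-echo spin-echo train with
25 equidistant echoes (first TE 13.4 ms, spacing 13.4 ms, last TE 335 ms).  The
first acquired echo is systematically biased by B1 inhomogeneity in alternating
refocusing schemes and is excluded rather than corrected, so the first
*effective* echo is the second acquired one at 26.8 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionProtocol", "DEFAULT_N_ECHOES", "DEFAULT_ECHO_SPACING_MS"]

DEFAULT_N_ECHOES = 25
DEFAULT_ECHO_SPACING_MS = 13.4


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Echo times of a multi-echo acquisition.

    Parameters
    ----------
    acquired_tes : tuple of float
        Strictly increasing, positive echo times in ms, one per acquired echo.
    repetition_time : float
        TR in ms; metadata only, not used in fitting.
    """

    acquired_tes: tuple[float, ...]
    repetition_time: float = 2500.0

    def __post_init__(self) -> None:
        tes = np.asarray(self.acquired_tes, dtype=float)
        if tes.ndim != 1 or tes.size < 2:
            raise ValueError("protocol needs at least two acquired echoes")
        if np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("acquired_tes must be positive and strictly increasing")
        object.__setattr__(self, "acquired_tes", tuple(float(t) for t in tes))

    @classmethod
    def default(cls) -> "AcquisitionProtocol":
        """25 equidistant echoes, 13.4 ... 335 ms."""
        tes = DEFAULT_ECHO_SPACING_MS * np.arange(1, DEFAULT_N_ECHOES + 1)
        return cls(acquired_tes=tuple(np.round(tes, 10)))

    @property
    def effective_tes(self) -> np.ndarray:
        """Echo times after first-echo exclusion (K = K_acq - 1 values, ms)."""
        return np.asarray(self.acquired_tes[1:], dtype=float)

    @property
    def n_acquired(self) -> int:
        return len(self.acquired_tes)

    @property
    def n_effective(self) -> int:
        return len(self.acquired_tes) - 1

    def to_dict(self) -> dict:
        return {
            "acquired_tes_ms": list(self.acquired_tes),
            "effective_tes_ms": self.effective_tes.tolist(),
            "repetition_time_ms": self.repetition_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(
            acquired_tes=tuple(d["acquired_tes_ms"]),
            repetition_time=float(d.get("repetition_time_ms", 2500.0)),
        )
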