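"""Synthetic multi-echo phantom generator with per-voxel ground truth.

Builds single-slice multi-echo magnitude image stacks whose tissue voxels decay
as known mono- or biexponential curves, so that every downstream stage
(preprocessing, fitting, model selection, ROI statistics, classification) can
be validated against exact truth.  Tissue-class presets carry the published
per-class fit statistics of benign and malignant adipocytic tissue: the
fraction of voxels behaving monoexponentially and the amplitude / T2 of the
short (lipid-bound) and long (free-water) pools.

Per-voxel biological variation is emulated by jittering the class parameters:
normal multiplicative jitter on amplitudes (clipped at 0) and log-normal
multiplicative jitter on T2s (median-preserving, always positive).  Background
voxels contain pure noise.  Noise is additive gaussian by default (signed;
consistent with linear mean-background subtraction); a Rician option models
true magnitude statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "TissueClassSpec",
    "Region",
    "PhantomSpec",
    "GroundTruth",
    "simulate_decay",
    "generate_phantom",
    "TISSUE_PRESETS",
]


@dataclass(frozen=True)
class TissueClassSpec:
    """Decay-parameter distribution of one tissue class.

    ``mono_fraction`` is the probability that a voxel of this class decays
    monoexponentially; the remaining voxels are biexponential.  ``dispersion``
    maps parameter names (``mono_A``, ``mono_T2``, ``bi_A1``, ``bi_T2_1``,
    ``bi_A2``, ``bi_T2_2``) to relative voxel-to-voxel SDs.
    """

    label: str
    mono_fraction: float
    mono_A: float
    mono_T2: float
    bi_A1: float
    bi_T2_1: float
    bi_A2: float
    bi_T2_2: float
    dispersion: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mono_fraction <= 1.0:
            raise ValueError("mono_fraction must lie in [0, 1]")
        for a in (self.mono_A, self.bi_A1, self.bi_A2):
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
        for t in (self.mono_T2, self.bi_T2_1, self.bi_T2_2):
            if t <= 0:
                raise ValueError("T2 values must be positive")
        if not self.bi_T2_1 < self.bi_T2_2:
            raise ValueError("short T2 must be below long T2")

    def with_dispersion(self, scale: float) -> "TissueClassSpec":
        """Copy with every dispersion entry multiplied by ``scale``."""
        return replace(
            self, dispersion={k: v * scale for k, v in self.dispersion.items()}
        )


def _preset(label, mono_frac, mono, bi, disp) -> TissueClassSpec:
    return TissueClassSpec(
        label=label, mono_fraction=mono_frac,
        mono_A=mono[0], mono_T2=mono[1],
        bi_A1=bi[0], bi_T2_1=bi[1], bi_A2=bi[2], bi_T2_2=bi[3],
        dispersion=disp,
    )


def _rel(sd, mean):
    return round(sd / mean, 4)


# Published per-class summary statistics (mean, SD over fitted voxels).
# Classes with (near-)zero monoexponential prevalence report no mono
# parameters; their preset mono_A/mono_T2 fall back to the amplitude-weighted
# biexponential values so that a rare mono draw remains plausible.
TISSUE_PRESETS: dict[str, TissueClassSpec] = {
    "lipoma": _preset(
        "lipoma", 0.003,
        mono=(319 + 630, (319 * 41 + 630 * 205) / (319 + 630)),
        bi=(319, 41, 630, 205),
        disp={"mono_A": 0.2, "mono_T2": 0.2,
              "bi_A1": _rel(183, 319), "bi_T2_1": _rel(13, 41),
              "bi_A2": _rel(195, 630), "bi_T2_2": _rel(64, 205)},
    ),
    "well_differentiated": _preset(
        "well_differentiated", 0.177,
        mono=(205, 322), bi=(279, 42, 757, 220),
        disp={"mono_A": _rel(95, 205), "mono_T2": _rel(139, 322),
              "bi_A1": _rel(160, 279), "bi_T2_1": _rel(19, 42),
              "bi_A2": _rel(260, 757), "bi_T2_2": _rel(112, 220)},
    ),
    "myxoid": _preset(
        "myxoid", 0.478,
        mono=(910, 439), bi=(237, 60, 793, 469),
        disp={"mono_A": _rel(134, 910), "mono_T2": _rel(79, 439),
              "bi_A1": _rel(129, 237), "bi_T2_1": _rel(37, 60),
              "bi_A2": _rel(190, 793), "bi_T2_2": _rel(148, 469)},
    ),
    "poorly_differentiated": _preset(
        "poorly_differentiated", 0.530,
        mono=(469, 152), bi=(242, 48, 525, 223),
        disp={"mono_A": _rel(237, 469), "mono_T2": _rel(102, 152),
              "bi_A1": _rel(156, 242), "bi_T2_1": _rel(25, 48),
              "bi_A2": _rel(378, 525), "bi_T2_2": _rel(121, 223)},
    ),
    "pleomorphic": _preset(
        "pleomorphic", 0.25,
        mono=(583, 441), bi=(285, 38, 678, 263),
        disp={"mono_A": _rel(99, 583), "mono_T2": _rel(154, 441),
              "bi_A1": _rel(95, 285), "bi_T2_1": _rel(19, 38),
              "bi_A2": _rel(109, 678), "bi_T2_2": _rel(153, 263)},
    ),
    "adipose": _preset(
        "adipose", 0.0,
        mono=(504 + 751, (504 * 45 + 751 * 191) / (504 + 751)),
        bi=(504, 45, 751, 191),
        disp={"mono_A": 0.2, "mono_T2": 0.2,
              "bi_A1": _rel(69, 504), "bi_T2_1": _rel(13, 45),
              "bi_A2": _rel(147, 751), "bi_T2_2": _rel(21, 191)},
    ),
}


@dataclass(frozen=True)
class Region:
    """Rectangle or disc placed on the phantom grid (voxel coordinates).

    Rectangle: ``params = (row0, col0, height, width)``.
    Disc: ``params = (center_row, center_col, radius)``.
    """

    shape: str
    params: tuple

    def mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        if self.shape == "rect":
            r0, c0, h, w = (int(v) for v in self.params)
            if r0 < 0 or c0 < 0 or r0 + h > grid_shape[0] or c0 + w > grid_shape[1]:
                raise ValueError("rectangle extends outside the grid")
            m[r0:r0 + h, c0:c0 + w] = True
        elif self.shape == "disc":
            cr, cc, rad = self.params
            if cr - rad < 0 or cc - rad < 0 or cr + rad >= grid_shape[0] or cc + rad >= grid_shape[1]:
                raise ValueError("disc extends outside the grid")
            rr, cc_idx = np.ogrid[: grid_shape[0], : grid_shape[1]]
            m[(rr - cr) ** 2 + (cc_idx - cc) ** 2 <= rad**2] = True
        else:
            raise ValueError(f"unknown region shape {self.shape!r}")
        if not m.any():
            raise ValueError("region covers no voxels")
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic slice."""

    grid_shape: tuple[int, int]
    regions: tuple[tuple[TissueClassSpec, Region], ...]
    background_sigma: float = 5.0
    noise_model: str = "gaussian"
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol.default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_sigma < 0:
            raise ValueError("background_sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass
class GroundTruth:
    """Per-voxel generative truth of a phantom slice.

    ``model`` holds 0 (background), 1 (mono) or 2 (bi); component arrays are
    NaN where the component does not exist.  ``label_map`` indexes into
    ``labels`` (0 = background).
    """

    model: np.ndarray
    A1: np.ndarray
    T2_1: np.ndarray
    A2: np.ndarray
    T2_2: np.ndarray
    label_map: np.ndarray
    labels: list[str]

    def to_dataframe(self):
        import pandas as pd

        rows, cols = np.nonzero(self.model > 0)
        lab = np.asarray(self.labels)
        return pd.DataFrame({
            "row": rows, "col": cols,
            "label": lab[self.label_map[rows, cols]],
            "model": self.model[rows, cols],
            "A1": self.A1[rows, cols], "T2_1": self.T2_1[rows, cols],
            "A2": self.A2[rows, cols], "T2_2": self.T2_2[rows, cols],
        })


def simulate_decay(
    A1: float,
    T2_1: float,
    A2: float | None = None,
    T2_2: float | None = None,
    tes: np.ndarray | None = None,
) -> np.ndarray:
    """Noiseless decay S(TE_k) = Σ A_i exp(-TE_k / T2_i) for one or two pools."""
    if tes is None:
        raise ValueError("echo-time vector required")
    tes = np.asarray(tes, dtype=float)
    if np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be positive and strictly increasing")
    if T2_1 <= 0 or (T2_2 is not None and T2_2 <= 0):
        raise ValueError("T2 values must be positive")
    s = A1 * np.exp(-tes / T2_1)
    if A2 is not None:
        if T2_2 is None:
            raise ValueError("A2 given without T2_2")
        s = s + A2 * np.exp(-tes / T2_2)
    return s


def _jitter_amp(rng, base, rel_sd):
    if rel_sd <= 0:
        return base
    return max(0.0, rng.normal(base, rel_sd * base))


def _jitter_t2(rng, base, rel_sd):
    # median-preserving log-normal: exp(sigma_ln * z) with sigma_ln from the
    # relative SD of the matching log-normal
    if rel_sd <= 0:
        return base
    sigma_ln = np.sqrt(np.log1p(rel_sd**2))
    return base * np.exp(sigma_ln * rng.standard_normal())


def _draw_voxel(rng, cls: TissueClassSpec) -> tuple[int, float, float, float, float]:
    d = cls.dispersion
    mono = rng.random() < cls.mono_fraction
    if mono:
        A = _jitter_amp(rng, cls.mono_A, d.get("mono_A", 0.0))
        T2 = _jitter_t2(rng, cls.mono_T2, d.get("mono_T2", 0.0))
        return 1, A, T2, np.nan, np.nan
    for _ in range(100):  # rejection keeps the pools ordered
        a1 = _jitter_amp(rng, cls.bi_A1, d.get("bi_A1", 0.0))
        t1 = _jitter_t2(rng, cls.bi_T2_1, d.get("bi_T2_1", 0.0))
        a2 = _jitter_amp(rng, cls.bi_A2, d.get("bi_A2", 0.0))
        t2 = _jitter_t2(rng, cls.bi_T2_2, d.get("bi_T2_2", 0.0))
        if t1 < t2:
            return 2, a1, t1, a2, t2
    raise RuntimeError("could not draw ordered T2 pair; dispersion too large")


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, GroundTruth, np.ndarray, np.ndarray]:
    """Render a phantom slice.

    Returns
    -------
    stack : (H, W, K_acq) float array
        One magnitude image per *acquired* echo (the first echo is included so
        preprocessing can drop it).
    truth : GroundTruth
    region_labels : (H, W) int array
        0 = background, i = i-th region (1-based).
    background_mask : (H, W) bool array
        Complement of all regions.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.grid_shape
    tes = np.asarray(spec.protocol.acquired_tes, dtype=float)
    K = tes.size

    region_labels = np.zeros((H, W), dtype=np.int16)
    labels = ["background"]
    masks = []
    for idx, (cls, region) in enumerate(spec.regions, start=1):
        m = region.mask((H, W))
        if np.any(region_labels[m] != 0):
            raise ValueError(f"region {idx} ({cls.label}) overlaps a previous region")
        region_labels[m] = idx
        labels.append(cls.label)
        masks.append(m)

    truth = GroundTruth(
        model=np.zeros((H, W), dtype=np.int16),
        A1=np.full((H, W), np.nan), T2_1=np.full((H, W), np.nan),
        A2=np.full((H, W), np.nan), T2_2=np.full((H, W), np.nan),
        label_map=region_labels.copy(), labels=labels,
    )

    clean = np.zeros((H, W, K))
    for (cls, _), m in zip(spec.regions, masks):
        for r, c in zip(*np.nonzero(m)):
            order, a1, t1, a2, t2 = _draw_voxel(rng, cls)
            truth.model[r, c] = order
            truth.A1[r, c], truth.T2_1[r, c] = a1, t1
            truth.A2[r, c], truth.T2_2[r, c] = a2, t2
            if order == 1:
                clean[r, c, :] = simulate_decay(a1, t1, tes=tes)
            else:
                clean[r, c, :] = simulate_decay(a1, t1, a2, t2, tes=tes)

    sigma = spec.background_sigma
    if sigma == 0:
        stack = clean
    elif spec.noise_model == "gaussian":
        stack = clean + rng.normal(0.0, sigma, clean.shape)
    else:  # rician: magnitude of a complex gaussian around the clean signal
        re = clean + rng.normal(0.0, sigma, clean.shape)
        im = rng.normal(0.0, sigma, clean.shape)
        stack = np.sqrt(re**2 + im**2)

    background_mask = region_labels == 0
    return stack, truth, region_labels, background_mask
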