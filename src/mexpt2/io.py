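"""NIfTI / CSV / JSON readers and writers.

Multi-echo stacks are stored as 3-D NIfTI volumes with the echo train along
the last axis; there is no standard NIfTI field for an echo-time train, so the
TE vector (and other provenance: seed, version) lives in a JSON sidecar next
to the image (same stem, ``.json`` extension).  Masks are integer label
images on the same grid.  Parametric maps are written one NIfTI per map plus a
sidecar recording the protocol, search space and tie-break rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .fitting import ParametricMaps, SearchSpace
from .protocol import AcquisitionProtocol

__all__ = [
    "write_stack", "read_stack", "write_mask", "read_mask",
    "write_maps", "read_maps", "write_json", "read_json",
]

_AFFINE = np.eye(4)


def write_json(obj: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())


def _sidecar(path: Path) -> Path:
    path = Path(path)
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.with_name(stem + ".json")


def write_stack(
    stack: np.ndarray, protocol: AcquisitionProtocol, path: Path,
    extra_meta: dict | None = None,
) -> None:
    """Write an (H, W, K) echo stack as NIfTI plus a TE sidecar."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected an (H, W, n_echoes) stack")
    if stack.shape[2] != protocol.n_acquired and stack.shape[2] != protocol.n_effective:
        raise ValueError("echo axis length matches neither acquired nor "
                         "effective echo count")
    nib.save(nib.Nifti1Image(stack.astype(np.float64), _AFFINE), str(path))
    meta = {"protocol": protocol.to_dict(), "version": __version__}
    if extra_meta:
        meta.update(extra_meta)
    write_json(meta, _sidecar(path))


def read_stack(path: Path) -> tuple[np.ndarray, AcquisitionProtocol]:
    """Read an echo stack and its protocol; validates the sidecar TE vector."""
    img = nib.load(str(path))
    stack = np.asarray(img.dataobj, dtype=np.float64)
    meta = read_json(_sidecar(path))
    protocol = AcquisitionProtocol.from_dict(meta["protocol"])
    n = stack.shape[-1]
    if n not in (protocol.n_acquired, protocol.n_effective):
        raise ValueError(
            f"sidecar TE vector ({protocol.n_acquired} acquired) does not "
            f"match echo axis length {n}")
    return stack, protocol


def write_mask(mask: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), _AFFINE), str(path))


def read_mask(path: Path, grid_shape: tuple[int, int] | None = None) -> np.ndarray:
    mask = np.asarray(nib.load(str(path)).dataobj)
    if grid_shape is not None and mask.shape != tuple(grid_shape):
        raise ValueError(f"mask grid {mask.shape} does not match stack grid "
                         f"{tuple(grid_shape)}")
    return mask


def write_maps(
    maps: ParametricMaps, out_dir: Path,
    protocol: AcquisitionProtocol | None = None,
    space: SearchSpace | None = None,
    extra_meta: dict | None = None,
) -> None:
    """One NIfTI per parametric map plus a provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in maps.map_names():
        arr = getattr(maps, name)
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), _AFFINE),
                 str(out_dir / f"{name}.nii.gz"))
    meta = {
        "version": __version__,
        "tie_break": "equal adjusted R^2 resolves to monoexponential",
    }
    if protocol is not None:
        meta["protocol"] = protocol.to_dict()
    if space is not None:
        meta["search_space"] = space.to_dict()
    if extra_meta:
        meta.update(extra_meta)
    write_json(meta, out_dir / "maps.json")


def read_maps(out_dir: Path) -> ParametricMaps:
    out_dir = Path(out_dir)
    arrays = {}
    for name in ParametricMaps.empty((1, 1)).map_names():
        arr = np.asarray(nib.load(str(out_dir / f"{name}.nii.gz")).dataobj,
                         dtype=np.float64)
        arrays[name] = arr.astype(np.int16) if name == "model_map" else arr
    return ParametricMaps(**arrays)
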