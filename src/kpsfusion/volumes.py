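"""Segmented label volumes: I/O, per-slice tumor area, slice-window selection.

Volumes are 3D integer label maps produced by an upstream tumor-segmentation
model, with classes 0 = background, 1 = brain parenchyma, 2 = peritumoral
edema / non-enhancing tumor, 3 = lesion core (enhancing tumor, necrosis,
cysts). The slice axis is axis 0. From each volume a fixed window of
``WINDOW`` axial slices is chosen so the largest-tumor slice sits as close to
the window centre as the volume boundaries allow, and the window is split
into lesion channels (core, edema) and a brain-mask channel for the two VAEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

VALID_LABELS = (0, 1, 2, 3)
CORE, EDEMA, BRAIN = 3, 2, 1
WINDOW = 24


@dataclass
class LabelVolume:
    """One patient's segmentation at one timepoint."""

    labels: np.ndarray  # (slices, H, W) integer array
    spacing: tuple[float, float, float]  # mm per axis (slice, row, col)
    patient_id: str = ""
    timepoint: str = "pre"  # {"pre", "post"}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if not np.isin(self.labels, VALID_LABELS).all():
            raise ValueError("labels must be in {0,1,2,3}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")


@dataclass
class SliceStack:
    """The selected slice window, split for the VAEs.

    ``lesion``: (WINDOW, H, W, 2) binary — channel 0 core (class 3),
    channel 1 edema (class 2). ``brain_mask``: (WINDOW, H, W, 1) binary —
    classes 1, 2 and 3 combined.
    """

    lesion: np.ndarray
    brain_mask: np.ndarray
    window_start: int
    patient_id: str = ""
    timepoint: str = "pre"


def tumor_area_per_slice(volume: LabelVolume) -> np.ndarray:
    """Lesion-core area (mm^2) of every axial slice.

    Area is the class-3 voxel count times the in-plane voxel area; edema is
    excluded from the measurement.
    """
    if volume.labels.size == 0:
        raise ValueError("empty volume")
    voxel_area = volume.spacing[1] * volume.spacing[2]
    return (volume.labels == CORE).sum(axis=(1, 2)) * voxel_area


def select_slice_window(areas: np.ndarray, window: int = WINDOW) -> int:
    """Start index of the slice window that best centres the largest-tumor slice.

    Among all feasible starts ``s`` (``0 <= s``, ``s + window <= n``), the one
    minimising ``|argmax - (s + (window-1)/2)|`` is chosen; ties break toward
    the earlier start. If the volume has fewer slices than the window it is
    treated as symmetrically zero-padded and the returned start indexes the
    padded stack. An all-zero area vector falls back to centring on the
    middle slice.
    """
    areas = np.asarray(areas, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(areas)
    if n == 0:
        raise ValueError("empty area vector")
    if n < window:
        pad_lo = (window - n) // 2
        padded = np.concatenate([np.zeros(pad_lo), areas, np.zeros(window - n - pad_lo)])
        return select_slice_window(padded, window)
    m = int(np.argmax(areas)) if areas.any() else (n - 1) // 2
    centre_off = (window - 1) / 2.0
    best_s, best_cost = 0, np.inf
    for s in range(n - window + 1):
        cost = abs(m - (s + centre_off))
        if cost < best_cost - 1e-12:
            best_s, best_cost = s, cost
    return best_s


def _windowed(labels: np.ndarray, start: int, window: int) -> np.ndarray:
    """Extract [start, start+window) along axis 0, honouring the padding rule."""
    n = labels.shape[0]
    if n >= window:
        if start < 0 or start + window > n:
            raise ValueError("window does not fit the volume")
        return labels[start:start + window]
    pad_lo = (window - n) // 2
    out = np.zeros((window,) + labels.shape[1:], dtype=labels.dtype)
    out[pad_lo:pad_lo + n] = labels
    return out[start:start + window] if window == out.shape[0] else out


def split_channels(volume: LabelVolume, window_start: int,
                   window: int = WINDOW) -> SliceStack:
    """Split the slice window into lesion channels and the brain-mask channel."""
    lab = _windowed(volume.labels, window_start if volume.labels.shape[0] >= window else 0,
                    window)
    lesion = np.stack([(lab == CORE), (lab == EDEMA)], axis=-1).astype(np.float32)
    brain_mask = (lab >= BRAIN).astype(np.float32)[..., None]
    return SliceStack(lesion=lesion, brain_mask=brain_mask,
                      window_start=window_start,
                      patient_id=volume.patient_id, timepoint=volume.timepoint)


def make_slice_stack(volume: LabelVolume, window: int = WINDOW) -> SliceStack:
    """Measure areas, pick the window, and split channels in one step."""
    areas = tumor_area_per_slice(volume)
    start = select_slice_window(areas, window)
    return split_channels(volume, start, window)


def make_patient_stacks(pre: LabelVolume, post: LabelVolume,
                        window: int = WINDOW) -> tuple[SliceStack, SliceStack]:
    """One shared slice window per patient, defined on the preoperative tumor.

    The window is selected from the preoperative core areas and applied to
    both timepoints, keeping the pre- and post-op stacks anatomically aligned
    (selecting a fresh window on the post-op volume would shift with the
    resection and leak residual-tumor information into the brain-mask stack).
    """
    start = select_slice_window(tumor_area_per_slice(pre), window)
    return (split_channels(pre, start, window),
            split_channels(post, start, window))


def write_label_volume(volume: LabelVolume, path) -> None:
    """Write as NIfTI-1 with the spacing encoded in a diagonal affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_label_volume(path, patient_id: str = "", timepoint: str = "pre") -> LabelVolume:
    """Read a NIfTI-1 label map; rejects non-integer data."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: voxel values are not integer labels")
    labels = np.round(data).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels=labels, spacing=spacing,
                       patient_id=patient_id, timepoint=timepoint)
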