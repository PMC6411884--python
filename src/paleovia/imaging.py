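"""DNA Damage Index (DDI) from two-channel 3D time-lapse stacks.

A nucleus's DDI is its integrated, background-subtracted gammaH2A.X signal
divided by its integrated H2B signal (the injection-volume normalizer),
rescaled so the median of a designated reference cohort (fresh sperm) equals
exactly 1.  Nuclei with DDI above a threshold (default 2) are classified as
developmentally incompetent.

Segmentation runs on the H2B channel — the chromatin probe common to every
injected nucleus — with Otsu thresholding and 26-connected 3D components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "NucleusMeasurement",
    "segment_nuclei",
    "measure_nucleus_signal",
    "measure_stack",
    "compute_ddi",
    "classify_competence",
    "ddi_timecourse",
    "track_nuclei",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ImageStack:
    """Two-channel 3D+t stack: voxels indexed (t, channel, z, y, x), a.u."""

    voxels: np.ndarray
    channel_map: dict[str, int]  # {"h2b": idx, "gamma_h2ax": idx}
    voxel_size: tuple[float, float, float]  # um per axis (z, y, x)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 5:
            raise ValueError("expected a 5-D (t, c, z, y, x) array")
        if set(self.channel_map) != {"h2b", "gamma_h2ax"}:
            raise ValueError("channel_map must name exactly 'h2b' and 'gamma_h2ax'")
        if self.voxels.shape[1] != 2:
            raise ValueError("expected exactly 2 channels")
        if (self.voxels < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    def channel(self, name: str, frame: int) -> np.ndarray:
        return self.voxels[frame, self.channel_map[name]]


@dataclass
class NucleusMeasurement:
    label: int
    frame: int
    volume: int  # voxels
    h2b_signal: float
    gamma_signal: float
    background_h2b: float  # per-voxel
    background_gamma: float
    centroid: tuple[float, float, float]  # voxel coordinates (z, y, x)


def segment_nuclei(stack: ImageStack, frame: int, min_volume: int = 20) -> list[np.ndarray]:
    """Label nuclei in one frame of the H2B channel.

    Otsu threshold, 26-connected 3D components, components smaller than
    ``min_volume`` voxels discarded.  Returns a list of disjoint boolean
    masks; an all-constant image yields no masks (with a warning).
    """
    if not 0 <= frame < stack.n_frames:
        raise IndexError(f"frame {frame} out of range")
    img = stack.channel("h2b", frame)
    if np.ptp(img) == 0:
        warnings.warn("constant H2B image: no nuclei segmented", stacklevel=2)
        return []
    thresh = threshold_otsu(img)
    labels, n = ndimage.label(img > thresh, structure=_STRUCT_26)
    masks = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if int(mask.sum()) >= min_volume:
            masks.append(mask)
    return masks


def _histogram_mode(values: np.ndarray, bins: int = 256) -> float:
    counts, edges = np.histogram(values, bins=bins)
    i = int(np.argmax(counts))
    return float((edges[i] + edges[i + 1]) / 2)


def measure_nucleus_signal(
    stack: ImageStack, mask: np.ndarray, frame: int, label: int = 0,
    shell_voxels: int = 2, exclude: np.ndarray | None = None,
) -> NucleusMeasurement:
    """Integrated background-subtracted channel signals for one nucleus.

    Per channel, background is the median intensity in a shell obtained by
    dilating the mask by ``shell_voxels`` and removing the mask itself (and
    any voxels in ``exclude``, e.g. neighbouring nuclei).  The signal is
    sum(voxel - background) over the mask, clipped at zero.  An empty shell
    (mask flooding the frame) falls back to the whole-frame histogram mode.
    """
    if not mask.any():
        raise ValueError("empty mask")
    shell = ndimage.binary_dilation(mask, structure=_STRUCT_26, iterations=shell_voxels) & ~mask
    if exclude is not None:
        shell &= ~exclude
    signals, backgrounds = {}, {}
    for name in ("h2b", "gamma_h2ax"):
        img = stack.channel(name, frame)
        if shell.any():
            bg = float(np.median(img[shell]))
        else:
            warnings.warn("empty background shell; falling back to whole-frame mode", stacklevel=2)
            bg = _histogram_mode(img.ravel())
        signals[name] = max(float((img[mask] - bg).sum()), 0.0)
        backgrounds[name] = bg
    centroid = tuple(float(c) for c in ndimage.center_of_mass(mask))
    return NucleusMeasurement(
        label=label, frame=frame, volume=int(mask.sum()),
        h2b_signal=signals["h2b"], gamma_signal=signals["gamma_h2ax"],
        background_h2b=backgrounds["h2b"], background_gamma=backgrounds["gamma_h2ax"],
        centroid=centroid,
    )


def measure_stack(
    stack: ImageStack, frames: list[int] | None = None, min_volume: int = 20
) -> pd.DataFrame:
    """Segment and measure every nucleus in the given frames (default: all)."""
    if frames is None:
        frames = list(range(stack.n_frames))
    rows = []
    for frame in frames:
        masks = segment_nuclei(stack, frame, min_volume=min_volume)
        union = np.zeros(stack.voxels.shape[2:], dtype=bool)
        for m in masks:
            union |= m
        for lab, mask in enumerate(masks, start=1):
            m = measure_nucleus_signal(stack, mask, frame, label=lab, exclude=union & ~mask)
            rows.append(
                {"frame": frame, "label": m.label, "volume": m.volume,
                 "h2b_signal": m.h2b_signal, "gamma_signal": m.gamma_signal,
                 "background_h2b": m.background_h2b, "background_gamma": m.background_gamma,
                 "centroid_z": m.centroid[0], "centroid_y": m.centroid[1],
                 "centroid_x": m.centroid[2]}
            )
    return pd.DataFrame(
        rows, columns=["frame", "label", "volume", "h2b_signal", "gamma_signal",
                       "background_h2b", "background_gamma",
                       "centroid_z", "centroid_y", "centroid_x"],
    )


def compute_ddi(
    measurements: pd.DataFrame, reference_group: str, threshold: float = 2.0
) -> pd.DataFrame:
    """Normalize gamma/H2B ratios so the reference group's median DDI is 1.

    Input needs columns ``group``, ``gamma_signal`` and ``h2b_signal``.
    Rows with non-positive H2B are rejected (logged).  The median is the
    conventional interpolated median (mean of the central pair for even n),
    so the reference group's post-normalization median is exactly 1.
    """
    df = measurements.copy()
    if reference_group not in set(df["group"]):
        raise ValueError(f"reference group {reference_group!r} not present")
    bad = df["h2b_signal"] <= 0
    if bad.any():
        logger.warning("rejecting %d records with non-positive H2B signal", int(bad.sum()))
        df = df.loc[~bad].copy()
    if not (df["group"] == reference_group).any():
        raise ValueError("reference group empty after H2B filtering")
    df["raw_ratio"] = df["gamma_signal"] / df["h2b_signal"]
    ref_median = float(df.loc[df["group"] == reference_group, "raw_ratio"].median())
    if ref_median <= 0:
        raise ValueError("reference-group median ratio is not positive; cannot normalize")
    ddi = df["raw_ratio"].to_numpy(float) / ref_median
    is_ref = (df["group"] == reference_group).to_numpy()
    # interpolated even-n medians can land 1 ulp off after division; renormalize
    # to the fixed point so the reference median is exactly 1 in float
    for _ in range(8):
        m = float(np.median(ddi[is_ref]))
        if m == 1.0:
            break
        ddi = ddi / m
    df["ddi"] = ddi
    df["competent"] = df["ddi"].map(lambda d: classify_competence(d, threshold))
    return df


def classify_competence(ddi: float, threshold: float = 2.0) -> bool:
    """Developmental competence call: incompetent iff DDI strictly exceeds the threshold."""
    if ddi < 0:
        raise ValueError("DDI must be non-negative")
    return not ddi > threshold


def ddi_timecourse(records: pd.DataFrame, nucleus_col: str = "nucleus",
                   time_col: str = "time", value_col: str = "ddi") -> pd.DataFrame:
    """Per-nucleus DDI series summary: initial, final, delta = final - initial.

    A declining series (delta < 0) is flagged repair-consistent — the
    signature of damage being resolved by the host ooplasm.  Single-frame
    nuclei get an undefined delta and a flag.
    """
    rows = []
    for nucleus, grp in records.groupby(nucleus_col, sort=True):
        grp = grp.sort_values(time_col)
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 2:
            rows.append({nucleus_col: nucleus, "n_frames": int(vals.size),
                         "initial": float(vals[0]), "final": float(vals[-1]),
                         "delta": float("nan"), "repair_consistent": False,
                         "single_frame": True})
            continue
        delta = float(vals[-1] - vals[0])
        rows.append({nucleus_col: nucleus, "n_frames": int(vals.size),
                     "initial": float(vals[0]), "final": float(vals[-1]),
                     "delta": delta, "repair_consistent": delta < 0,
                     "single_frame": False})
    return pd.DataFrame(rows)


def track_nuclei(
    stack: ImageStack, min_volume: int = 20, max_displacement_um: float = 5.0
) -> pd.DataFrame:
    """Per-frame segmentation with nearest-centroid linking across frames.

    Matches each nucleus to the closest centroid in the previous frame
    within ``max_displacement_um`` (um per frame); unmatched detections open
    new tracks.  Returns measure_stack output plus a ``nucleus`` track id.
    """
    vz, vy, vx = stack.voxel_size
    scale = np.array([vz, vy, vx])
    meas = measure_stack(stack, min_volume=min_volume)
    if meas.empty:
        meas["nucleus"] = pd.Series(dtype=int)
        return meas
    meas = meas.sort_values(["frame", "label"]).reset_index(drop=True)
    track_ids = np.full(len(meas), -1, dtype=int)
    next_id = 0
    prev: list[tuple[int, np.ndarray]] = []  # (track id, centroid um)
    for frame, grp in meas.groupby("frame", sort=True):
        current = []
        taken = set()
        for i in grp.index:
            c = meas.loc[i, ["centroid_z", "centroid_y", "centroid_x"]].to_numpy(float) * scale
            best, best_d = None, max_displacement_um
            for j, (tid, pc) in enumerate(prev):
                if tid in taken:
                    continue
                d = float(np.linalg.norm(c - pc))
                if d <= best_d:
                    best, best_d = tid, d
            if best is None:
                best = next_id
                next_id += 1
            taken.add(best)
            track_ids[i] = best
            current.append((best, c))
        prev = current
    meas["nucleus"] = track_ids
    return meas
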