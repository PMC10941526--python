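"""Assembly of the six-channel microstructural feature volume.

The pipeline expects diffusion-tensor metrics (FA, MD, AD, RD) and NODDI
metrics (NDI, ODI, ISO) already fitted and co-registered on one grid.  The
isotropic water fraction gives the tissue fraction ``1 - ISO``, which
modulates NDI and ODI; the six resulting channels (FA, MD, AD, RD,
NDI_mod, ODI_mod) are each z-scored over the tissue mask of the subject and
stacked, so that every masked voxel carries a standardized 6-vector.

Z-scoring is per subject and per channel, with the population SD (ddof 0);
the normalisation population is whatever mask is passed in (whole brain or
cortex-only).  ISO itself is not a channel: exactly six channels enter the
downstream homogeneity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import CHANNEL_NAMES, FeatureVolume

UNIT_INTERVAL_METRICS = {"FA", "NDI", "ODI", "ISO"}
DIFFUSIVITY_METRICS = {"MD", "AD", "RD"}  # mm^2/s
VALID_METRICS = UNIT_INTERVAL_METRICS | DIFFUSIVITY_METRICS | {"NDI_mod", "ODI_mod", "TF"}


@dataclass(frozen=True)
class MetricMap:
    """One scalar metric on a 3D grid."""

    name: str
    data: np.ndarray          # (X, Y, Z)
    affine: np.ndarray

    def __post_init__(self):
        if self.name not in VALID_METRICS:
            raise ValueError(f"unknown metric name {self.name!r}")
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    def validate_range(self, mask: np.ndarray) -> None:
        vals = self.data[mask]
        if self.name in UNIT_INTERVAL_METRICS:
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                worst = vals[bad][np.argmax(np.abs(vals[bad] - 0.5))]
                raise ValueError(
                    f"{self.name} outside [0, 1] at {int(bad.sum())} masked "
                    f"voxels (extreme value {worst:g})")
        elif self.name in DIFFUSIVITY_METRICS and (vals < 0).any():
            raise ValueError(f"{self.name} negative at masked voxels")


def tissue_fraction(iso: MetricMap, mask: np.ndarray) -> MetricMap:
    """Tissue fraction ``1 - ISO``; requires ISO in [0, 1] within the mask."""
    if iso.name != "ISO":
        raise ValueError("tissue_fraction expects the ISO map")
    iso.validate_range(mask)
    return MetricMap(name="TF", data=1.0 - iso.data, affine=iso.affine)


def modulate(metric: MetricMap, tf: MetricMap) -> MetricMap:
    """Voxel-wise product of NDI or ODI with the tissue fraction."""
    if metric.name not in ("NDI", "ODI"):
        raise ValueError("modulate applies to NDI or ODI only")
    if metric.data.shape != tf.data.shape or not np.allclose(
            metric.affine, tf.affine, atol=1e-4):
        raise ValueError("metric and tissue-fraction grids do not match")
    return MetricMap(name=metric.name + "_mod", data=metric.data * tf.data,
                     affine=metric.affine)


def zscore_channel(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize one channel over masked voxels: (x - mean) / SD, ddof 0.

    Outside-mask voxels are set to NaN.  Raises on a constant channel.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = data[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 masked voxels to z-score")
    mu = vals.mean()
    sd = vals.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant channel: zero variance within mask")
    out = np.full(data.shape, np.nan)
    out[mask] = (vals - mu) / sd
    return out


def build_feature_volume(data: np.ndarray, mask: np.ndarray,
                         affine: np.ndarray, zscore: bool = True) -> FeatureVolume:
    """Wrap a pre-stacked (X, Y, Z, C) array, optionally z-scoring channels."""
    data = np.asarray(data, dtype=float)
    if zscore:
        data = np.stack([zscore_channel(data[..., c], mask)
                         for c in range(data.shape[-1])], axis=-1)
        data = np.where(np.isnan(data), 0.0, data)  # outside-mask filler
    return FeatureVolume(data=data, affine=affine, mask=mask)


def stack_channels(maps, mask, affine=None, zscore: bool = True) -> FeatureVolume:
    """Stack the six metric maps in the fixed channel order and z-score each.

    ``maps`` may be a sequence of :class:`MetricMap` (any order; re-sorted by
    name into FA, MD, AD, RD, NDI_mod, ODI_mod) or a pre-stacked 4D array, in
    which case ``affine`` is required.
    """
    if isinstance(maps, np.ndarray):
        if affine is None:
            raise ValueError("affine required when passing a raw array")
        return build_feature_volume(maps, mask, affine, zscore=zscore)
    by_name = {m.name: m for m in maps}
    if len(by_name) != len(list(maps)):
        raise ValueError("duplicate metric names")
    missing = [n for n in CHANNEL_NAMES if n not in by_name]
    if missing:
        raise ValueError(f"missing channels: {missing} "
                         f"(expected exactly {list(CHANNEL_NAMES)})")
    extra = set(by_name) - set(CHANNEL_NAMES)
    if extra:
        raise ValueError(f"unexpected channels: {sorted(extra)}")
    ordered = [by_name[n] for n in CHANNEL_NAMES]
    ref = ordered[0]
    for m in ordered[1:]:
        if m.data.shape != ref.data.shape or not np.allclose(
                m.affine, ref.affine, atol=1e-4):
            raise ValueError(f"grid/affine mismatch for channel {m.name}")
    data = np.stack([m.data for m in ordered], axis=-1)
    return build_feature_volume(data, mask, ref.affine, zscore=zscore)
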