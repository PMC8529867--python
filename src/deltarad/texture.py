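"""Filtration-histogram texture core.

The technique has two steps.  First a Laplacian-of-Gaussian (LoG) band-pass
filter enhances image structure at a chosen *spatial scale filter* (SSF, in
mm): SSF = 2 highlights fine texture, 3–5 medium, 6 coarse, and SSF = 0
means no filtration.  Second, the filtered (or raw) values inside the lesion
ROI are rounded to integers ("integer binning") and summarised by six
histogram statistics: mean, standard deviation, entropy, mean of positive
pixels (MPP), skewness and kurtosis.

The sigma of the Gaussian is tied to the SSF by ``sigma = SSF / (2*sqrt(2))``
so that the LoG zero-crossing diameter ``2*sqrt(2)*sigma`` equals the SSF:
objects of roughly that size produce the strongest response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .imaging import ImageSlice, LesionRecord

#: The six histogram statistics, in canonical order.
STATISTICS = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")

#: Spatial scale filters in mm; 0 denotes the unfiltered map.
SCALES_MM = (0, 2, 3, 4, 5, 6)

#: sigma(mm) = SSF(mm) * SIGMA_PER_SSF
SIGMA_PER_SSF = 1.0 / (2.0 * math.sqrt(2.0))

#: Below this sigma in pixels the kernel is undersampled by the pixel grid.
MIN_SIGMA_PX = 0.3


class TextureError(ValueError):
    pass


def feature_name(stat: str, ssf: float) -> str:
    """Canonical feature column name, e.g. ``kurtosis_ssf2``."""
    return f"{stat}_ssf{int(ssf)}"


def delta_feature_name(stat: str, ssf: float) -> str:
    """Column name of the percentage-change (delta) feature, e.g. ``perc_entropy_ssf4``."""
    return f"perc_{feature_name(stat, ssf)}"


BASELINE_FEATURES = tuple(feature_name(s, k) for s in STATISTICS for k in SCALES_MM)
DELTA_FEATURES = tuple(delta_feature_name(s, k) for s in STATISTICS for k in SCALES_MM)


def log_sigma_px(ssf_mm: float, spacing_mm: float | tuple[float, float]) -> tuple[float, float]:
    """Gaussian sigma in pixel units along (row, col) for a given SSF."""
    if np.isscalar(spacing_mm):
        spacing_mm = (float(spacing_mm), float(spacing_mm))
    sigma_mm = ssf_mm * SIGMA_PER_SSF
    return sigma_mm / spacing_mm[0], sigma_mm / spacing_mm[1]


def build_log_kernel(ssf_mm: float, spacing_mm: float | tuple[float, float]) -> np.ndarray:
    """Discrete 2D LoG kernel for one spatial scale.

    The kernel is sampled at pixel centers in physical (mm) coordinates and
    then mean-subtracted so its coefficients sum to exactly zero: a constant
    image yields zero response (zero-DC / band-pass contract).
    """
    if ssf_mm <= 0:
        raise TextureError("SSF must be positive; SSF=0 means no filtration")
    if np.isscalar(spacing_mm):
        spacing_mm = (float(spacing_mm), float(spacing_mm))
    sig_r, sig_c = log_sigma_px(ssf_mm, spacing_mm)
    if min(sig_r, sig_c) < MIN_SIGMA_PX:
        raise TextureError(
            f"sigma of {min(sig_r, sig_c):.3f} px is below the grid resolution "
            f"({MIN_SIGMA_PX} px); use a larger SSF or finer pixel spacing"
        )
    rad_r = math.ceil(4.0 * sig_r)
    rad_c = math.ceil(4.0 * sig_c)
    y = (np.arange(-rad_r, rad_r + 1) * spacing_mm[0])[:, None]
    x = (np.arange(-rad_c, rad_c + 1) * spacing_mm[1])[None, :]
    r2 = x * x + y * y
    s2 = (ssf_mm * SIGMA_PER_SSF) ** 2
    kernel = (r2 - 2.0 * s2) / (s2 * s2) * np.exp(-r2 / (2.0 * s2))
    kernel -= kernel.mean()
    return kernel


def filter_slice(image: ImageSlice, ssf_mm: float) -> np.ndarray:
    """Convolve the whole slice with the LoG kernel (mirror padding).

    SSF = 0 returns the HU values unchanged (as floats).  Masking is applied
    only afterwards, at sampling time, so the convolution sees true
    surrounding tissue rather than a masked edge.
    """
    if ssf_mm == 0:
        return image.pixels.astype(np.float64)
    kernel = build_log_kernel(ssf_mm, image.pixel_spacing_mm)
    if image.shape[0] < kernel.shape[0] or image.shape[1] < kernel.shape[1]:
        raise TextureError(
            f"image {image.shape} is smaller than the SSF={ssf_mm} kernel support "
            f"{kernel.shape}"
        )
    return ndimage.convolve(image.pixels.astype(np.float64), kernel, mode="mirror")


def integer_bin(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Round to the nearest integer, ties to even (CT integer-binning rule)."""
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise TextureError("cannot integer-bin non-finite values")
    return np.rint(arr).astype(np.int64)


@dataclass
class TextureStats:
    """The six histogram statistics of one integer-binned sample.

    Undefined entries are NaN: MPP when no value is positive, skewness and
    kurtosis when the standard deviation is zero.  ``kurtosis`` is excess
    kurtosis by default (Gaussian → 0).
    """

    mean: float
    sd: float
    entropy: float
    mpp: float
    skewness: float
    kurtosis: float
    n_pixels: int

    def as_dict(self) -> dict[str, float]:
        return {stat: getattr(self, stat) for stat in STATISTICS}


def compute_stats(
    binned: np.ndarray | Sequence[int],
    entropy_base: float = 2.0,
    kurtosis_convention: str = "excess",
) -> TextureStats:
    """Histogram statistics over the empirical distribution of integer values.

    mean and SD are population moments (divide by n); entropy is
    ``-sum(p_i * log_base(p_i))`` over distinct integer values; MPP averages
    strictly positive values; skewness is ``m3/sd**3``; kurtosis is
    ``m4/sd**4`` minus 3 under the default ``"excess"`` convention
    (``"pearson"`` keeps the +3).
    """
    x = np.asarray(binned)
    if x.size == 0:
        raise TextureError("cannot compute statistics of an empty sample")
    if not np.issubdtype(x.dtype, np.integer):
        raise TextureError("compute_stats expects integer-binned values")
    if kurtosis_convention not in ("excess", "pearson"):
        raise TextureError(f"unknown kurtosis convention {kurtosis_convention!r}")
    xf = x.astype(np.float64)
    n = x.size
    mean = float(xf.mean())
    centered = xf - mean
    m2 = float((centered**2).mean())
    sd = math.sqrt(m2)

    _, counts = np.unique(x, return_counts=True)
    p = counts / n
    entropy = float(-(p * (np.log(p) / math.log(entropy_base))).sum())
    entropy = max(entropy, 0.0)  # clamp -0.0 from the single-level histogram

    positive = xf[xf > 0]
    mpp = float(positive.mean()) if positive.size else math.nan

    if sd > 0:
        skewness = float((centered**3).mean()) / sd**3
        kurtosis = float((centered**4).mean()) / sd**4
        if kurtosis_convention == "excess":
            kurtosis -= 3.0
    else:
        skewness = math.nan
        kurtosis = math.nan

    return TextureStats(
        mean=mean,
        sd=sd,
        entropy=entropy,
        mpp=mpp,
        skewness=skewness,
        kurtosis=kurtosis,
        n_pixels=int(n),
    )


@dataclass
class FeatureVector:
    """All statistics × spatial scales for one lesion at one timepoint."""

    lesion_id: str
    patient_id: str
    timepoint: str
    values: dict[str, float] = field(default_factory=dict)
    n_pixels: int = 0

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def extract_features(
    lesion: LesionRecord,
    scales_mm: Iterable[float] = SCALES_MM,
    entropy_base: float = 2.0,
    kurtosis_convention: str = "excess",
    bin_before_stats: bool = True,
) -> FeatureVector:
    """Run the full filtration-histogram extraction for one lesion.

    For each scale the whole slice is filtered, in-mask values are sampled,
    integer-binned (unless ``bin_before_stats`` is disabled, in which case
    binning is still applied for the entropy histogram only) and summarised.
    """
    values: dict[str, float] = {}
    n_pixels = int(lesion.mask.sum())
    for ssf in scales_mm:
        try:
            fmap = filter_slice(lesion.image, ssf)
            sampled = fmap[lesion.mask]
            binned = integer_bin(sampled)
            stats = compute_stats(
                binned,
                entropy_base=entropy_base,
                kurtosis_convention=kurtosis_convention,
            )
            per_scale = stats.as_dict()
            if not bin_before_stats:
                raw = compute_moment_stats_raw(
                    sampled, kurtosis_convention=kurtosis_convention
                )
                per_scale.update(raw)
        except TextureError as exc:
            raise TextureError(f"lesion {lesion.lesion_id}: {exc}") from exc
        for stat, value in per_scale.items():
            values[feature_name(stat, ssf)] = value
    return FeatureVector(
        lesion_id=lesion.lesion_id,
        patient_id=lesion.patient_id,
        timepoint=lesion.timepoint,
        values=values,
        n_pixels=n_pixels,
    )


def compute_moment_stats_raw(
    sampled: np.ndarray, kurtosis_convention: str = "excess"
) -> dict[str, float]:
    """Moment statistics on raw (un-binned) filter responses.

    Used when ``bin_before_stats=False``: entropy always comes from the
    integer histogram, the other five statistics from the raw responses.
    """
    x = np.asarray(sampled, dtype=np.float64)
    mean = float(x.mean())
    centered = x - mean
    sd = math.sqrt(float((centered**2).mean()))
    positive = x[x > 0]
    out = {
        "mean": mean,
        "sd": sd,
        "mpp": float(positive.mean()) if positive.size else math.nan,
    }
    if sd > 0:
        out["skewness"] = float((centered**3).mean()) / sd**3
        kurt = float((centered**4).mean()) / sd**4
        out["kurtosis"] = kurt - 3.0 if kurtosis_convention == "excess" else kurt
    else:
        out["skewness"] = math.nan
        out["kurtosis"] = math.nan
    return out
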