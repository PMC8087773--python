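"""Quantification of synaptic-protein puncta in two-channel confocal stacks.

The reference channel (mGluR6) marks ON-bipolar dendritic tips in the
outer plexiform layer (OPL); the target channel carries the protein of
interest (RGS7, Gβ5, ...).  Every stack is first normalized by the mean
non-specific signal in the outer nuclear layer (ONL), so all intensities
are expressed in units of that background.  The pipeline then

1. measures a background-thresholded mean intensity over the OPL ROI,
2. locates the strict 26-neighbour local maxima of the reference channel
   inside the ROI volume,
3. restricts them with a 2-D dendritic-tip mask built from the z-averaged
   reference image,
4. classifies each tip as rod (mask extends ≤ 0.5 µm each side of the
   centre) or cone (extends > 1.1 µm including the centre), and
5. sums the background-subtracted target intensity over a 1.1 × 1.1 µm
   window centred on each maximum.

Coordinates are 0-based ``(z, y, x)``; ROI rectangles are half-open in
pixel space; physical ↔ pixel conversion goes through the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_objects

__all__ = [
    "VoxelSize",
    "ImageStack",
    "PunctaRecord",
    "SectionQuant",
    "normalize_to_onl",
    "opl_mean_intensity",
    "find_local_maxima_3d",
    "build_tip_mask",
    "classify_and_sum",
    "quantify_section",
    "ROD_MAX_EXTENT_UM",
    "CONE_MIN_EXTENT_UM",
    "WINDOW_UM",
]

#: rod tip: mask extends no more than this far each side of the centre (µm)
ROD_MAX_EXTENT_UM = 0.5
#: cone tip: mask extends more than this, including the centre (µm)
CONE_MIN_EXTENT_UM = 1.1
#: per-punctum summation window edge (µm)
WINDOW_UM = 1.1


@dataclass(frozen=True)
class VoxelSize:
    """Voxel dimensions in µm: lateral (x, y) pixel size and slice spacing z."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass
class ImageStack:
    """Multichannel confocal z-stack with OPL/ONL annotations.

    ``data`` has shape (channels, z, y, x).  ``opl_roi`` and ``onl_region``
    are half-open pixel rectangles ``(y0, y1, x0, x1)`` applying to every
    slice.  ``channels`` names each channel; index 0 is the reference
    (mGluR6 proxy) unless ``reference`` says otherwise.
    """

    data: np.ndarray
    voxel_size: VoxelSize
    opl_roi: tuple[int, int, int, int]
    onl_region: tuple[int, int, int, int]
    channels: list[str] = field(default_factory=list)
    reference: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (channels, z, y, x)")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names do not match data")
        if not self.reference:
            self.reference = self.channels[0]
        _, _, ny, nx = self.data.shape
        for name, (y0, y1, x0, x1) in (("opl_roi", self.opl_roi),
                                       ("onl_region", self.onl_region)):
            if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
                raise ValueError(f"{name} {y0, y1, x0, x1} outside stack bounds")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def um_to_px(self, um: float, axis: str = "x") -> int:
        return round(um / getattr(self.voxel_size, axis))


@dataclass
class PunctaRecord:
    """One detected dendritic-tip punctum."""

    center: tuple[int, int, int]  # (z, y, x)
    klass: str  # 'rod' | 'cone' | 'excluded'
    extent_left_um: float
    extent_right_um: float
    window_sums: dict = field(default_factory=dict)  # channel -> background-subtracted sum
    flag: str = ""


@dataclass
class SectionQuant:
    """Per-section quantification: OPL means and per-class punctal averages.

    ``opl_means``/``opl_flags`` are per channel; ``opl_mean`` is the
    reference-channel value for convenience.
    """

    opl_mean: float
    opl_flag: bool
    opl_means: dict = field(default_factory=dict)
    opl_flags: dict = field(default_factory=dict)
    n_rod: int = 0
    n_cone: int = 0
    n_excluded: int = 0
    #: (class, channel) -> mean window sum, present only when n > 0
    class_means: dict = field(default_factory=dict)
    records: list = field(default_factory=list)
    sample_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": self.sample_id, "z": r.center[0], "y": r.center[1],
             "x": r.center[2], "class": r.klass,
             "extent_left_um": r.extent_left_um,
             "extent_right_um": r.extent_right_um, "flag": r.flag,
             **{f"sum_{c}": v for c, v in r.window_sums.items()}}
            for r in self.records
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def normalize_to_onl(stack: ImageStack) -> ImageStack:
    """Divide every channel by its mean intensity over the ONL region.

    After normalization the ONL mean of each channel is exactly 1, so all
    intensities are in units of the non-specific background; any global
    scale factor of the acquisition cancels.
    """
    y0, y1, x0, x1 = stack.onl_region
    out = stack.data.copy()
    for c in range(out.shape[0]):
        m = out[c, :, y0:y1, x0:x1].mean()
        if m == 0:
            raise ZeroDivisionError(f"channel {stack.channels[c]!r} has zero ONL mean")
        out[c] /= m
    return ImageStack(out, stack.voxel_size, stack.opl_roi, stack.onl_region,
                      list(stack.channels), stack.reference, dict(stack.meta))


def opl_mean_intensity(stack: ImageStack, channel: str | None = None,
                       threshold: float = 1.0,
                       subtract_background: bool = True) -> tuple[float, bool]:
    """Background-thresholded mean intensity of the OPL ROI.

    Operates on the z-averaged, ONL-normalized image: pixels at or below
    the threshold (the ONL mean, i.e. 1) contribute zero; the rest
    contribute ``value - 1`` (units of background above background) when
    ``subtract_background`` or the raw value otherwise.  The mean is over
    all ROI pixels, zeros included.  Returns ``(mean, flagged)`` with
    ``flagged=True`` when every pixel fell below threshold.
    """
    ch = channel or stack.reference
    y0, y1, x0, x1 = stack.opl_roi
    img = stack.channel(ch).mean(axis=0)[y0:y1, x0:x1]
    above = img > threshold
    if not above.any():
        return 0.0, True
    vals = np.where(above, img - (1.0 if subtract_background else 0.0), 0.0)
    return float(vals.mean()), False


def find_local_maxima_3d(volume: np.ndarray) -> list[tuple[int, int, int]]:
    """Strict 26-neighbour local maxima of a 3-D volume.

    A voxel qualifies only if it is strictly greater than all 26
    neighbours (volume boundaries pad with −inf); plateaus therefore
    yield no maximum.  Returned sorted by intensity descending, with
    (z, y, x) lexicographic order breaking exact ties.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3-D")
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(vol, footprint=footprint,
                                       mode="constant", cval=-np.inf)
    zz, yy, xx = np.nonzero(vol > neigh_max)
    order = np.lexsort((xx, yy, zz, -vol[zz, yy, xx]))
    return [(int(zz[i]), int(yy[i]), int(xx[i])) for i in order]


def build_tip_mask(image: np.ndarray, threshold: float = 1.0,
                   min_size: int = 4) -> np.ndarray:
    """Binary 2-D mask of candidate dendritic-tip areas.

    ``image`` is the z-averaged, ONL-normalized reference image.  Pixels
    strictly above ``threshold`` (× the ONL background) are kept;
    connected components smaller than ``min_size`` pixels (default 2×2)
    are removed as speckle.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    mask = img > threshold
    if min_size > 1:
        # drop components with fewer than min_size pixels
        mask = remove_small_objects(mask, max_size=min_size - 1)
    return mask


def _row_extent(mask_row: np.ndarray, x: int) -> tuple[int, int]:
    """Contiguous mask run through column ``x``: pixels to the left/right."""
    left = 0
    while x - left - 1 >= 0 and mask_row[x - left - 1]:
        left += 1
    right = 0
    while x + right + 1 < mask_row.size and mask_row[x + right + 1]:
        right += 1
    return left, right


def classify_and_sum(
    maxima: list[tuple[int, int, int]],
    mask: np.ndarray,
    stack: ImageStack,
    window_um: float = WINDOW_UM,
    rod_max_um: float = ROD_MAX_EXTENT_UM,
    cone_min_um: float = CONE_MIN_EXTENT_UM,
    clip_negative: bool = False,
) -> list[PunctaRecord]:
    """Classify each maximum by its mask extent and sum target windows.

    The extent is measured along the horizontal (OPL-parallel) axis of
    the tip-mask component through the maximum's row: rod tips extend at
    most ``rod_max_um`` each side of the centre; cone patches extend more
    than ``cone_min_um`` from the centre, the centre pixel included with
    the longer arm; anything in between is excluded.  ``window_sums`` hold, per channel, the sum of
    ``(normalized value − 1)`` over the ``window_um``-square window
    (nearest odd pixel count) of the z-averaged image centred on the
    maximum — i.e. background-subtracted intensity in ONL-background
    units.  Maxima whose window exceeds the image bounds are flagged and
    excluded; maxima outside the mask are dropped.
    """
    px = stack.voxel_size.x
    py = stack.voxel_size.y

    def _odd_px(um: float, size: float) -> int:
        n = max(1, round(um / size))
        if n % 2 == 0:
            n += 1 if abs((n + 1) * size - um) <= abs((n - 1) * size - um) else -1
        return n

    half = _odd_px(window_um, px) // 2
    half_y = _odd_px(window_um, py) // 2

    zavg = {c: stack.channel(c).mean(axis=0) for c in stack.channels}
    ny, nx = mask.shape
    records: list[PunctaRecord] = []
    for (z, y, x) in maxima:
        if not mask[y, x]:
            continue
        left, right = _row_extent(mask[y], x)
        lum, rum = left * px, right * px
        # cone criterion counts the centre pixel with the longer arm
        extent_incl_center = (max(left, right) + 1) * px
        if lum <= rod_max_um and rum <= rod_max_um:
            klass = "rod"
        elif extent_incl_center > cone_min_um:
            klass = "cone"
        else:
            klass = "excluded"
        rec = PunctaRecord((z, y, x), klass, lum, rum)
        if y - half_y < 0 or y + half_y >= ny or x - half < 0 or x + half >= nx:
            rec.klass = "excluded"
            rec.flag = "window-out-of-bounds"
        else:
            for c in stack.channels:
                win = zavg[c][y - half_y : y + half_y + 1, x - half : x + half + 1] - 1.0
                if clip_negative:
                    win = np.clip(win, 0.0, None)
                rec.window_sums[c] = float(win.sum())
        records.append(rec)
    return records


def quantify_section(
    stack: ImageStack,
    sample_id: str = "",
    maxima_threshold: float = 1.0,
    mask_threshold: float = 1.0,
    min_mask_size: int = 4,
    window_um: float = WINDOW_UM,
    already_normalized: bool = False,
) -> SectionQuant:
    """Full per-section pipeline: normalize → OPL mean → maxima → mask →
    classify/sum → per-class averages."""
    norm = stack if already_normalized else normalize_to_onl(stack)
    opl_means, opl_flags = {}, {}
    for c in norm.channels:
        opl_means[c], opl_flags[c] = opl_mean_intensity(norm, channel=c)

    y0, y1, x0, x1 = norm.opl_roi
    ref = norm.channel(norm.reference)
    roi_vol = ref[:, y0:y1, x0:x1]
    maxima = [
        (z, y + y0, x + x0)
        for (z, y, x) in find_local_maxima_3d(roi_vol)
        if roi_vol[z, y, x] > maxima_threshold
    ]
    mask = build_tip_mask(ref.mean(axis=0), threshold=mask_threshold,
                          min_size=min_mask_size)
    records = classify_and_sum(maxima, mask, norm, window_um=window_um)

    class_means: dict = {}
    counts = {"rod": 0, "cone": 0, "excluded": 0}
    for klass in ("rod", "cone"):
        sums = [r.window_sums for r in records if r.klass == klass and r.window_sums]
        counts[klass] = len(sums)
        if sums:
            for c in norm.channels:
                class_means[(klass, c)] = float(np.mean([s[c] for s in sums]))
    counts["excluded"] = sum(1 for r in records if r.klass == "excluded")
    return SectionQuant(
        opl_mean=opl_means[norm.reference], opl_flag=opl_flags[norm.reference],
        opl_means=opl_means, opl_flags=opl_flags,
        n_rod=counts["rod"], n_cone=counts["cone"],
        n_excluded=counts["excluded"],
        class_means=class_means, records=records, sample_id=sample_id,
    )
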