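"""Fluorescence micrograph quantification for myogenic cultures and muscle sections.

Implements the segmentation-and-counting pipeline used to score myogenesis
and marker staining in two-channel immunofluorescence images (a nuclear
stain such as DAPI plus a marker channel: MyHC, laminin, elastase or Ly6G):

1. split an RGB or multi-channel raster into nuclei and marker channels;
2. threshold each channel with the Li (minimum cross-entropy) or Triangle
   histogram method;
3. separate touching nuclei by watershed on the negated Euclidean distance
   transform, seeded from smoothed distance-transform maxima;
4. remove large inseparable nuclear clumps (maximum size cutoff, default
   900 px);
5. count objects and compute marker-positive area, marker-positive cell
   counts, myotube area, differentiation index and fusion index by mask
   logic.

Conventions: coordinates are 0-based ``(row, col)``; areas are in pixels;
foreground is *strictly above* the threshold; a myotube is a marker-positive
connected component containing at least two nuclei; the fusion index counts
"cells" by their nuclei (nucleus-as-cell convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import imageio.v3 as iio
import tifffile
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

#: default channel mapping for RGB micrographs: DAPI in blue, marker in green
DEFAULT_RGB_MAPPING = {"nuclei": 2, "marker": 1}
#: default mapping for 2-plane stacks written by the simulator
DEFAULT_STACK_MAPPING = {"nuclei": 0, "marker": 1}

DEFAULT_MAX_AREA_PX = 900


class ChannelConfigError(ValueError):
    """A requested channel role cannot be mapped onto the input raster."""


class DimensionError(ValueError):
    """Two rasters that must share a pixel grid do not."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelImage:
    """A single fluorescence channel on a 2-D pixel grid.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities.
    channel_role
        ``"nuclei"`` or ``"marker"``.
    bit_depth
        Bits per sample of the source raster (metadata only).
    """

    pixels: np.ndarray
    channel_role: str
    bit_depth: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("ChannelImage requires a non-empty 2-D array")
        if np.issubdtype(px.dtype, np.floating) and (px < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ThresholdResult:
    """A thresholded channel: binary mask plus provenance."""

    mask: np.ndarray            # 2-D bool, same grid as the source channel
    threshold: float | None     # threshold in source intensity units
    method: str
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class MyogenesisIndices:
    """Per-image quantification record.

    ``differentiation_index`` is the fraction of all nuclei lying in
    marker-positive cells; ``fusion_index`` is the fraction of
    marker-positive cells (counted via their nuclei) that lie in myotubes.
    ``myotube_area_px`` follows the total-marker-area convention (total
    marker-positive area per image) and therefore equals ``marker_area_px``
    when both are computed from the same mask.
    """

    total_nuclei: int
    nuclei_in_marker: int
    myotube_nuclei: int
    marker_positive_cell_count: int
    myotube_count: int
    myotube_area_px: int
    marker_area_px: int
    marker_area_fraction: float
    differentiation_index: float
    fusion_index: float
    flags: tuple[str, ...] = ()
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not (self.nuclei_in_marker <= self.total_nuclei):
            raise ValueError("nuclei_in_marker exceeds total_nuclei")
        if not (self.myotube_nuclei <= self.nuclei_in_marker):
            raise ValueError("myotube_nuclei exceeds nuclei_in_marker")
        for name in ("differentiation_index", "fusion_index",
                     "marker_area_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QuantConfig:
    """Parameters for :func:`quantify_image`."""

    channel_map: dict[str, int] | None = None
    nuclei_method: str = "li"
    marker_method: str = "triangle"
    max_area_px: int = DEFAULT_MAX_AREA_PX
    watershed_sigma: float = 1.0
    min_seed_distance: int = 5
    assignment: str = "centroid"          # or "overlap"
    min_nuclei_per_myotube: int = 2


# ---------------------------------------------------------------------------
# Channel splitting and I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG micrograph into an array (channels first or last)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(str(path))
    return iio.imread(str(path))


def split_channels(
    image: np.ndarray,
    mapping: Mapping[str, int] | None = None,
) -> dict[str, ChannelImage]:
    """Split a multi-channel raster into role-named channels.

    Parameters
    ----------
    image
        ``(H, W, C)`` or ``(C, H, W)`` array with ``C <= 4`` channels
        (an RGB micrograph or a 2-plane stack). A 2-D array is treated as a
        single plane.
    mapping
        ``role -> channel index``; defaults to blue=nuclei / green=marker
        for 3- or 4-channel input and plane0=nuclei / plane1=marker for
        2-plane stacks.

    Returns
    -------
    dict mapping each requested role to the *unmodified* plane as a
    :class:`ChannelImage`.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        planes = image[None]
    elif image.ndim == 3:
        if image.shape[-1] <= 4 < image.shape[0]:
            planes = np.moveaxis(image, -1, 0)
        elif image.shape[0] <= 4:
            planes = image
        else:
            raise ChannelConfigError(
                f"cannot locate a channel axis in shape {image.shape}")
    else:
        raise ChannelConfigError(f"expected 2-D or 3-D raster, got {image.ndim}-D")

    if mapping is None:
        mapping = (DEFAULT_STACK_MAPPING if planes.shape[0] == 2
                   else DEFAULT_RGB_MAPPING)

    bit_depth = image.dtype.itemsize * 8
    out: dict[str, ChannelImage] = {}
    for role, idx in mapping.items():
        if not (0 <= idx < planes.shape[0]):
            raise ChannelConfigError(
                f"channel index {idx} for role {role!r} does not exist "
                f"(input has {planes.shape[0]} plane(s))")
        out[role] = ChannelImage(planes[idx], channel_role=role,
                                 bit_depth=bit_depth)
    return out


# ---------------------------------------------------------------------------
# Histogram thresholding
# ---------------------------------------------------------------------------

def li_threshold_bin(counts: np.ndarray) -> int | None:
    """Li minimum cross-entropy threshold on a 256-bin histogram.

    Scans every candidate bin ``t`` (foreground = bins strictly above
    ``t``) and minimises the cross entropy between the image and its
    two-level (class-mean) reconstruction.  With class sums
    ``s0 = sum_{g<=t} h(g)·g`` and ``s1 = sum_{g>t} h(g)·g`` and class means
    ``mu0, mu1`` the criterion reduces to ``-s0·ln(mu0) - s1·ln(mu1)`` (the
    pixel-entropy term is constant in ``t``).  Ties break to the lowest bin.
    Returns ``None`` when no candidate leaves both classes non-empty.
    """
    counts = np.asarray(counts, dtype=float)
    g = np.arange(counts.size, dtype=float)
    w = counts * g
    m0 = np.cumsum(counts)
    s0 = np.cumsum(w)
    m1 = m0[-1] - m0
    s1 = s0[-1] - s0
    valid = (m0 > 0) & (m1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # 0·ln(0) := 0 for the all-zero-intensity lower class
        term0 = np.where(s0 > 0, -s0 * np.log(s0 / m0), 0.0)
        term1 = np.where(s1 > 0, -s1 * np.log(s1 / m1), 0.0)
    eta = np.where(valid, term0 + term1, np.inf)
    if not np.isfinite(eta).any():
        return None
    return int(np.argmin(eta))


def triangle_threshold_bin(counts: np.ndarray) -> int | None:
    """Triangle threshold on a 256-bin histogram.

    Draws the line joining the histogram peak to the last nonzero bin and
    picks the bin whose (normalised) histogram point is farthest from that
    line.  Axes are normalised so the peak height is 1 and the peak-to-end
    span is 1, making the selection invariant to histogram scale.  When the
    peak *is* the last nonzero bin (bright-dominated histogram) the mirror
    side — peak to first nonzero bin — is used instead.  Ties break to the
    bin nearest the peak.
    """
    counts = np.asarray(counts, dtype=float)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        return None
    peak = int(np.argmax(counts))
    first, last = int(nz[0]), int(nz[-1])
    if last > peak:
        lo, hi = peak, last
    elif first < peak:
        lo, hi = peak, first          # mirrored: scan towards the left tail
    else:
        return None                   # single occupied bin
    span = hi - lo                    # may be negative on the mirror side
    y_end = counts[hi] / counts[peak]
    bins = lo + np.sign(span) * np.arange(abs(span) + 1)
    u = (bins - lo) / span            # in [0, 1] along the chord
    y = counts[bins] / counts[peak]
    # perpendicular distance to the chord from (0,1) to (1, y_end), up to a
    # constant factor
    dist = np.abs((y_end - 1.0) * u - (y - 1.0))
    t = int(bins[int(np.argmax(dist))])
    return t


def _histogram_256(pixels: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin histogram with the bin->intensity affine map ``(lo, step)``.

    8-bit integer input is binned on its native 0..255 grid; anything else
    is min-max scaled onto 256 bins so the method is reproducible across
    bit depths.
    """
    if pixels.dtype == np.uint8:
        counts = np.bincount(pixels.ravel(), minlength=256)
        return counts, 0.0, 1.0
    lo = float(pixels.min())
    hi = float(pixels.max())
    if hi == lo:
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = pixels.size
        return counts, lo, 0.0
    scaled = np.rint((pixels.astype(np.float64) - lo) / (hi - lo) * 255.0)
    counts = np.bincount(scaled.astype(np.intp).ravel(), minlength=256)
    return counts, lo, (hi - lo) / 255.0


def threshold(channel: ChannelImage | np.ndarray, method: str = "li") -> ThresholdResult:
    """Threshold a channel with the Li or Triangle method.

    Foreground is strictly above the selected threshold.  A constant
    channel yields an empty mask with a ``"constant_channel"`` warning
    rather than an error, so batch runs survive blank fields.
    """
    px = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    if method not in ("li", "triangle"):
        raise ValueError(f"unknown threshold method {method!r}")
    counts, lo, step = _histogram_256(px)

    if step == 0.0 and px.dtype != np.uint8:
        return ThresholdResult(np.zeros(px.shape, bool), None, method,
                               ("constant_channel",))

    t = li_threshold_bin(counts) if method == "li" else triangle_threshold_bin(counts)
    if t is None:
        return ThresholdResult(np.zeros(px.shape, bool), None, method,
                               ("constant_channel",))

    if px.dtype == np.uint8:
        value = float(t)
        mask = px > t
    else:
        # compare in bin space so mask semantics match the histogram exactly
        scaled = np.rint((px.astype(np.float64) - lo) / (step * 255.0) * 255.0)
        mask = scaled > t
        value = lo + t * step
    logger.debug("threshold(%s): t=%s", method, value)
    return ThresholdResult(mask, value, method)


# ---------------------------------------------------------------------------
# Nucleus separation and filtering
# ---------------------------------------------------------------------------

def separate_nuclei(
    mask: np.ndarray,
    sigma: float = 1.0,
    min_seed_distance: int = 5,
) -> np.ndarray:
    """Split touching nuclei by watershed on the distance transform.

    Seeds are local maxima of the Gaussian-smoothed Euclidean distance
    transform (``sigma`` px), at least ``min_seed_distance`` px apart; the
    watershed floods the *negated* unsmoothed distance transform restricted
    to the mask.  Any connected component that receives no seed (possible
    for tiny specks) is kept as a single object, so the union of output
    labels always equals the input foreground pixel-for-pixel.

    Returns an int32 label map with labels 1..N (0 = background).
    """
    mask = np.asarray(mask, bool)
    labels_out = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels_out

    dist = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(dist, sigma) if sigma > 0 else dist
    coords = peak_local_max(smoothed, min_distance=min_seed_distance,
                            labels=mask, exclude_border=False)

    markers = np.zeros(mask.shape, dtype=np.int32)
    n = 0
    for r, c in coords:
        n += 1
        markers[r, c] = n

    # guarantee one seed per connected component
    comp, n_comp = ndi.label(mask)
    seeded = set(np.unique(comp[markers > 0])) - {0}
    for cid in range(1, n_comp + 1):
        if cid not in seeded:
            inside = np.where(comp == cid)
            best = int(np.argmax(dist[inside]))
            n += 1
            markers[inside[0][best], inside[1][best]] = n

    labels_out = watershed(-dist, markers, mask=mask).astype(np.int32)
    return _relabel_contiguous(labels_out)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Re-index labels to 1..N preserving order of first appearance by id."""
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return lut[labels]


def filter_large_objects(
    labels: np.ndarray,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
) -> np.ndarray:
    """Remove objects with area strictly greater than ``max_area_px``.

    The printed cutoff is read as the largest *retained* size: an object of
    exactly ``max_area_px`` pixels survives.  Surviving labels are
    re-indexed 1..M.
    """
    labels = np.asarray(labels)
    if labels.size == 0 or labels.max() == 0:
        return labels.astype(np.int32, copy=True)
    areas = np.bincount(labels.ravel())
    too_big = np.flatnonzero(areas > max_area_px)
    too_big = too_big[too_big > 0]
    if too_big.size:
        logger.info("filter_large_objects: removed %d object(s) > %d px",
                    too_big.size, max_area_px)
    out = labels.copy()
    out[np.isin(labels, too_big)] = 0
    return _relabel_contiguous(out)


def count_objects(labels: np.ndarray) -> int:
    """Number of distinct nonzero labels."""
    labels = np.asarray(labels)
    return int(np.unique(labels[labels > 0]).size)


def label_centroids(labels: np.ndarray) -> np.ndarray:
    """``(N, 2)`` array of (row, col) centroids for labels 1..N."""
    n = int(labels.max())
    if n == 0:
        return np.empty((0, 2))
    return np.asarray(ndi.center_of_mass(np.ones_like(labels, dtype=np.uint8),
                                         labels, index=np.arange(1, n + 1)))


# ---------------------------------------------------------------------------
# Mask-logic quantification
# ---------------------------------------------------------------------------

def marker_area(mask: np.ndarray) -> tuple[int, float]:
    """Marker-positive area: ``(pixels, fraction of the image)``."""
    mask = np.asarray(mask, bool)
    area = int(mask.sum())
    return area, area / mask.size


def count_marker_positive_cells(nuclei: np.ndarray, marker: np.ndarray) -> int:
    """Count nuclear objects whose centroid pixel lies in the marker mask."""
    nuclei = np.asarray(nuclei)
    marker = np.asarray(marker, bool)
    if nuclei.shape != marker.shape:
        raise DimensionError(
            f"grid mismatch: nuclei {nuclei.shape} vs marker {marker.shape}")
    cents = label_centroids(nuclei)
    if cents.size == 0:
        return 0
    rr = np.clip(np.rint(cents[:, 0]).astype(int), 0, marker.shape[0] - 1)
    cc = np.clip(np.rint(cents[:, 1]).astype(int), 0, marker.shape[1] - 1)
    return int(marker[rr, cc].sum())


def _assign_nuclei_to_components(
    nuclei: np.ndarray,
    components: np.ndarray,
    rule: str,
) -> np.ndarray:
    """Component id (0 = none) for each nuclear label 1..N."""
    n = int(nuclei.max())
    if n == 0:
        return np.zeros(0, dtype=int)
    if rule == "centroid":
        cents = label_centroids(nuclei)
        rr = np.clip(np.rint(cents[:, 0]).astype(int), 0, components.shape[0] - 1)
        cc = np.clip(np.rint(cents[:, 1]).astype(int), 0, components.shape[1] - 1)
        return components[rr, cc]
    if rule == "overlap":
        assign = np.zeros(n, dtype=int)
        for i in range(1, n + 1):
            overlap = components[nuclei == i]
            overlap = overlap[overlap > 0]
            if overlap.size:
                vals, cnt = np.unique(overlap, return_counts=True)
                assign[i - 1] = int(vals[np.argmax(cnt)])
        return assign
    raise ValueError(f"unknown assignment rule {rule!r}")


def compute_indices(
    nuclei: np.ndarray,
    marker: np.ndarray,
    min_nuclei_per_myotube: int = 2,
    assignment: str = "centroid",
    provenance: dict | None = None,
) -> MyogenesisIndices:
    """Differentiation and fusion indices by mask logic.

    The marker foreground is partitioned into connected components
    (8-connectivity); each nucleus is assigned to the component containing
    its centroid (or, with ``assignment="overlap"``, the component covering
    most of its pixels).  A myotube is a component holding at least
    ``min_nuclei_per_myotube`` nuclei.  Degenerate denominators give an
    index of 0 with the corresponding flag (``no_nuclei`` /
    ``no_marker_cells``) instead of raising.
    """
    nuclei = np.asarray(nuclei)
    marker = np.asarray(marker, bool)
    if nuclei.shape != marker.shape:
        raise DimensionError(
            f"grid mismatch: nuclei {nuclei.shape} vs marker {marker.shape}")

    components = measure.label(marker, connectivity=2)
    assign = _assign_nuclei_to_components(nuclei, components, assignment)

    total = int(nuclei.max())
    flags: list[str] = []
    in_marker = assign[assign > 0]
    nuclei_in_marker = int(in_marker.size)
    if components.max() > 0 and nuclei_in_marker:
        per_comp = np.bincount(in_marker, minlength=components.max() + 1)
        myotube_ids = np.flatnonzero(per_comp >= min_nuclei_per_myotube)
        myotube_ids = myotube_ids[myotube_ids > 0]
        myotube_nuclei = int(per_comp[myotube_ids].sum())
        myotube_count = int(myotube_ids.size)
    else:
        myotube_nuclei = 0
        myotube_count = 0

    if total == 0:
        flags.append("no_nuclei")
        di = 0.0
    else:
        di = nuclei_in_marker / total
    if nuclei_in_marker == 0:
        flags.append("no_marker_cells")
        fi = 0.0
    else:
        fi = myotube_nuclei / nuclei_in_marker

    area_px, area_frac = marker_area(marker)
    return MyogenesisIndices(
        total_nuclei=total,
        nuclei_in_marker=nuclei_in_marker,
        myotube_nuclei=myotube_nuclei,
        marker_positive_cell_count=nuclei_in_marker,
        myotube_count=myotube_count,
        myotube_area_px=area_px,
        marker_area_px=area_px,
        marker_area_fraction=area_frac,
        differentiation_index=di,
        fusion_index=fi,
        flags=tuple(flags),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# End-to-end quantification
# ---------------------------------------------------------------------------

def quantify_image(
    image: np.ndarray | str | Path,
    config: QuantConfig | None = None,
) -> MyogenesisIndices:
    """Full pipeline: split -> threshold x2 -> watershed -> size filter -> indices.

    ``image`` may be an array or a path to a TIFF/PNG file.  The returned
    record carries a provenance dict with the thresholds used, the number
    of size-filtered objects and the resolved configuration.
    """
    cfg = config or QuantConfig()
    if isinstance(image, (str, Path)):
        image = load_image(image)

    channels = split_channels(image, cfg.channel_map)
    if "nuclei" not in channels or "marker" not in channels:
        raise ChannelConfigError("channel map must provide 'nuclei' and 'marker'")

    th_nuc = threshold(channels["nuclei"], cfg.nuclei_method)
    th_mar = threshold(channels["marker"], cfg.marker_method)

    nuc_labels = separate_nuclei(th_nuc.mask, sigma=cfg.watershed_sigma,
                                 min_seed_distance=cfg.min_seed_distance)
    n_before = count_objects(nuc_labels)
    nuc_labels = filter_large_objects(nuc_labels, cfg.max_area_px)
    removed = n_before - count_objects(nuc_labels)

    prov = {
        "nuclei_threshold": th_nuc.threshold,
        "marker_threshold": th_mar.threshold,
        "nuclei_method": cfg.nuclei_method,
        "marker_method": cfg.marker_method,
        "objects_removed_by_size_filter": removed,
        "config": asdict(cfg),
        "warnings": list(th_nuc.warnings) + list(th_mar.warnings),
    }
    return compute_indices(
        nuc_labels, th_mar.mask,
        min_nuclei_per_myotube=cfg.min_nuclei_per_myotube,
        assignment=cfg.assignment,
        provenance=prov,
    )
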