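"""Two-channel movie I/O, rigid registration and ROI trace extraction.

Movies are multi-page TIFF stacks holding a functional (GCaMP) and an
anatomical (static red fluorophore) channel, either interleaved in one file
or in two per-channel files.  Registration is pure-translation, estimated by
cross-correlation on the anatomical channel and applied identically to both
channels.  ROI fluorescence is the per-frame mean over mask pixels; neuropil
contamination is removed by scaled subtraction of a median-centred annulus
trace.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.morphology import dilation, disk
from skimage.registration import phase_cross_correlation


@dataclass
class TwoChannelMovie:
    """Time-ordered stack of paired functional/anatomical frames."""

    functional: np.ndarray   # (n_frames, h, w)
    anatomical: np.ndarray   # (n_frames, h, w)
    frame_rate_hz: float
    pixel_size_um: float | None = None

    def __post_init__(self):
        if self.functional.shape != self.anatomical.shape:
            raise ValueError("functional and anatomical channels must have the "
                             f"same shape, got {self.functional.shape} vs "
                             f"{self.anatomical.shape}")
        if self.functional.ndim != 3:
            raise ValueError("movie channels must be (n_frames, h, w) stacks")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.functional.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.functional.shape[1:]


@dataclass
class RoiSet:
    """Pixel-coordinate ROI masks with optional neuropil annuli."""

    masks: list                      # per ROI, (k, 2) int array of (y, x)
    roi_ids: list
    neuropil_masks: list | None = None

    def __post_init__(self):
        if len(self.masks) != len(self.roi_ids):
            raise ValueError("masks and roi_ids length mismatch")
        for rid, m in zip(self.roi_ids, self.masks):
            if len(m) == 0:
                raise ValueError(f"ROI {rid} has an empty mask")

    def __len__(self):
        return len(self.masks)


@dataclass
class RawTraceSet:
    """Per-ROI mean fluorescence (and neuropil) time series."""

    traces: np.ndarray            # (n_rois, n_frames)
    neuropil_traces: np.ndarray | None
    frame_rate_hz: float
    roi_ids: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")


def read_movie(path, channel_layout: str = "interleaved",
               anatomical_path=None, frame_rate_hz: float = 10.0,
               pixel_size_um: float | None = None) -> TwoChannelMovie:
    """Read a two-channel movie from multi-page TIFF.

    ``channel_layout`` is ``"interleaved"`` (even pages functional, odd pages
    anatomical) or ``"separate"`` (``path`` functional, ``anatomical_path``
    anatomical).
    """
    stack = np.asarray(tifffile.imread(path))
    if stack.ndim == 2:
        stack = stack[None]
    if channel_layout == "interleaved":
        if stack.shape[0] % 2 != 0:
            raise ValueError(
                f"interleaved layout requires an even page count; file has "
                f"{stack.shape[0]} pages (offending page index "
                f"{stack.shape[0] - 1})")
        func, anat = stack[0::2], stack[1::2]
    elif channel_layout == "separate":
        if anatomical_path is None:
            raise ValueError("separate layout requires anatomical_path")
        anat = tifffile.imread(anatomical_path)
        if anat.ndim == 2:
            anat = anat[None]
        func = stack
        if func.shape[0] != anat.shape[0]:
            raise ValueError(
                f"channel page counts differ: {func.shape[0]} functional vs "
                f"{anat.shape[0]} anatomical")
    else:
        raise ValueError(f"unknown channel_layout {channel_layout!r}")
    return TwoChannelMovie(functional=np.asarray(func),
                           anatomical=np.asarray(anat),
                           frame_rate_hz=frame_rate_hz,
                           pixel_size_um=pixel_size_um)


def write_movie(movie: TwoChannelMovie, path, channel_layout: str = "interleaved",
                anatomical_path=None) -> None:
    """Write a movie to TIFF in the layout understood by :func:`read_movie`."""
    if channel_layout == "interleaved":
        n, h, w = movie.functional.shape
        inter = np.empty((2 * n, h, w), dtype=movie.functional.dtype)
        inter[0::2] = movie.functional
        inter[1::2] = movie.anatomical
        tifffile.imwrite(path, inter)
    elif channel_layout == "separate":
        if anatomical_path is None:
            raise ValueError("separate layout requires anatomical_path")
        tifffile.imwrite(path, movie.functional)
        tifffile.imwrite(anatomical_path, movie.anatomical)
    else:
        raise ValueError(f"unknown channel_layout {channel_layout!r}")


def read_rois(path, frame_shape=None) -> RoiSet:
    """Read ROI definitions.

    ``.tif``/``.tiff``: labelled mask image (0 = background, k = ROI k).
    ``.json``: ``{"rois": [{"id": k, "vertices": [[y, x], ...]}, ...]}``
    polygon list filled on the pixel grid (``frame_shape`` required).
    """
    p = str(path)
    if p.endswith((".tif", ".tiff")):
        labels = tifffile.imread(p)
        ids = sorted(int(v) for v in np.unique(labels) if v != 0)
        masks = [np.argwhere(labels == k) for k in ids]
        return RoiSet(masks=masks, roi_ids=ids)
    if p.endswith(".json"):
        if frame_shape is None:
            raise ValueError("frame_shape required for polygon ROIs")
        with open(p) as fh:
            data = json.load(fh)
        masks, ids = [], []
        for roi in data["rois"]:
            m = polygon2mask(frame_shape, np.asarray(roi["vertices"], dtype=float))
            masks.append(np.argwhere(m))
            ids.append(int(roi["id"]))
        return RoiSet(masks=masks, roi_ids=ids)
    raise ValueError(f"unsupported ROI file format: {p}")


def write_label_image(roi_set: RoiSet, shape, path) -> None:
    """Write ROI masks as a 16-bit labelled TIFF."""
    labels = np.zeros(shape, dtype=np.uint16)
    for rid, m in zip(roi_set.roi_ids, roi_set.masks):
        labels[m[:, 0], m[:, 1]] = rid
    tifffile.imwrite(path, labels)


def roi_masks_from_centroids(centroids, shape, radius_px: float = 3.0) -> RoiSet:
    """Disc masks around rendered-spot centroids (for synthetic movies)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    masks = []
    for cy, cx in np.asarray(centroids, dtype=float):
        m = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
        masks.append(np.argwhere(m))
    return RoiSet(masks=masks, roi_ids=list(range(1, len(masks) + 1)))


def register_frames(movie: TwoChannelMovie, reference="mean",
                    upsample_factor: int = 10, apply: bool = True,
                    subpixel_apply: bool = False):
    """Estimate and correct rigid per-frame translation on the anatomical channel.

    Returns ``(registered_movie, shifts)`` where ``shifts[f] = (dy, dx)`` is
    the estimated displacement of frame ``f`` relative to the reference (the
    translation the frame content has undergone; its negation maps the frame
    onto the reference).  The same correction is applied to both channels.
    Integer application (default) fills vacated border pixels with the frame
    median; ``subpixel_apply`` uses linear interpolation instead.
    """
    anat = np.asarray(movie.anatomical, dtype=float)
    if reference == "mean":
        ref = anat.mean(axis=0)
    else:
        ref = anat[int(reference)]
    n = movie.n_frames
    shifts = np.zeros((n, 2))
    if ref.std() == 0:
        warnings.warn("degenerate registration: constant reference frame; "
                      "returning zero shifts")
        return movie, shifts
    for f in range(n):
        frame = anat[f]
        if frame.std() == 0:
            warnings.warn(f"degenerate registration: constant frame {f}")
            continue
        est, _, _ = phase_cross_correlation(ref, frame,
                                            upsample_factor=upsample_factor,
                                            normalization=None)
        # est is the shift registering the frame onto the reference
        shifts[f] = -est
    if not apply:
        return movie, shifts
    func_r = np.empty_like(np.asarray(movie.functional, dtype=float))
    anat_r = np.empty_like(anat)
    for f in range(n):
        corr = -shifts[f]
        if not subpixel_apply:
            corr = np.round(corr)
        for src, dst in ((np.asarray(movie.functional[f], dtype=float), func_r),
                         (anat[f], anat_r)):
            if corr[0] == 0 and corr[1] == 0:
                dst[f] = src
            else:
                order = 0 if not subpixel_apply else 1
                dst[f] = ndimage.shift(src, corr, order=order, mode="constant",
                                       cval=float(np.median(src)))
    reg = TwoChannelMovie(functional=func_r, anatomical=anat_r,
                          frame_rate_hz=movie.frame_rate_hz,
                          pixel_size_um=movie.pixel_size_um)
    return reg, shifts


def derive_neuropil_masks(roi_set: RoiSet, frame_shape,
                          annulus_inner_px: int = 2,
                          annulus_outer_px: int = 6) -> RoiSet:
    """Per-ROI neuropil annulus between two dilation radii, excluding every
    ROI's pixels.  Empty annuli are flagged with a warning."""
    if annulus_outer_px <= annulus_inner_px:
        raise ValueError("annulus_outer_px must exceed annulus_inner_px")
    union = np.zeros(frame_shape, dtype=bool)
    imgs = []
    for m in roi_set.masks:
        img = np.zeros(frame_shape, dtype=bool)
        img[m[:, 0], m[:, 1]] = True
        imgs.append(img)
        union |= img
    npil = []
    for rid, img in zip(roi_set.roi_ids, imgs):
        outer = dilation(img, disk(annulus_outer_px))
        inner = dilation(img, disk(annulus_inner_px))
        ann = outer & ~inner & ~union
        if not ann.any():
            warnings.warn(f"empty neuropil annulus for ROI {rid}")
        npil.append(np.argwhere(ann))
    return RoiSet(masks=roi_set.masks, roi_ids=roi_set.roi_ids,
                  neuropil_masks=npil)


def extract_traces(movie: TwoChannelMovie, roi_set: RoiSet) -> RawTraceSet:
    """Per-frame arithmetic mean of functional-channel pixels per ROI (and
    per neuropil annulus, when defined)."""
    h, w = movie.frame_shape
    func = np.asarray(movie.functional, dtype=float)
    traces = np.empty((len(roi_set), movie.n_frames))
    for i, (rid, m) in enumerate(zip(roi_set.roi_ids, roi_set.masks)):
        if m[:, 0].min() < 0 or m[:, 0].max() >= h or \
           m[:, 1].min() < 0 or m[:, 1].max() >= w:
            raise ValueError(f"ROI {rid} mask out of frame bounds")
        traces[i] = func[:, m[:, 0], m[:, 1]].mean(axis=1)
    npil_traces = None
    if roi_set.neuropil_masks is not None:
        npil_traces = np.full((len(roi_set), movie.n_frames), np.nan)
        for i, (rid, m) in enumerate(zip(roi_set.roi_ids,
                                         roi_set.neuropil_masks)):
            if len(m) == 0:
                warnings.warn(f"ROI {rid}: empty neuropil mask, trace is NaN")
                continue
            npil_traces[i] = func[:, m[:, 0], m[:, 1]].mean(axis=1)
    return RawTraceSet(traces=traces, neuropil_traces=npil_traces,
                       frame_rate_hz=movie.frame_rate_hz,
                       roi_ids=list(roi_set.roi_ids))


def neuropil_correct(raw: RawTraceSet, r: float = 0.7) -> RawTraceSet:
    """Subtract the median-centred neuropil trace scaled by ``r``.

    ``corrected(t) = roi(t) - r * (neuropil(t) - median(neuropil))`` — the
    median-centring removes neuropil fluctuations without destroying the
    baseline that F0 estimation divides by.  ``r = 0`` is the identity.
    """
    if not (0 <= r < 1):
        raise ValueError("neuropil coefficient r must be in [0, 1)")
    if r == 0 or raw.neuropil_traces is None:
        corrected = raw.traces.copy()
    else:
        npil = raw.neuropil_traces
        centred = npil - np.nanmedian(npil, axis=1, keepdims=True)
        centred = np.nan_to_num(centred, nan=0.0)
        corrected = raw.traces - r * centred
    params = dict(raw.params)
    params["neuropil_r"] = r
    return RawTraceSet(traces=corrected, neuropil_traces=raw.neuropil_traces,
                       frame_rate_hz=raw.frame_rate_hz, roi_ids=raw.roi_ids,
                       params=params)
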