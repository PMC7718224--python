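"""Volumetric immunoblot analysis pipeline.

Turns a 3D fluorescence stack of separated protein bands into per-lane
quantifications: per-slice segmentation of protein spots, centroid linking
through z to form one lane track per microwell, background-subtracted
z-intensity profiles in a square ROI around each track, Gaussian peak fits
with R^2/SNR quality control, lateral (xy) band-width fits at the
migration peak, gel-level summaries, live-cell-to-band correspondence, and
lysis-kinetics extraction from time-lapse movies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.optimize import linear_sum_assignment
from skimage import filters, measure, morphology, segmentation

from .stack import ImageStack

# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_slices(
    stack: ImageStack,
    threshold: float | Literal["otsu"] = "otsu",
    min_area_um2: float = 50.0,
    opening_radius_px: int = 1,
    smooth_sigma_px: float = 2.0,
) -> pd.DataFrame:
    """Segment protein spots in every z-slice of the summed-channel image.

    Per slice: lateral Gaussian pre-smoothing (protein bands are tens of
    pixels wide, so smoothing suppresses voxel noise without moving
    centroids), intensity thresholding (global Otsu over the volume by
    default, or a fixed value), morphological open/close, hole filling,
    removal of small objects (below ``min_area_um2``) and of objects
    touching the image border; intensity-weighted centroids of the
    surviving objects are returned.

    Returns a DataFrame with columns z_index, x_um, y_um, area_px.
    """
    work = stack.summed_channels()
    if work.size == 0:
        raise ValueError("empty stack")
    dz, dy, dx = stack.voxel_size_um
    if work.max() <= 0:
        return pd.DataFrame(columns=["z_index", "x_um", "y_um", "area_px"])
    if smooth_sigma_px > 0:
        work = ndimage.gaussian_filter(
            work.astype(float), (0.0, smooth_sigma_px, smooth_sigma_px)
        )
    if threshold == "otsu":
        # Otsu over a sparse-foreground volume can land inside the noise
        # distribution; clamp it above a robust background + noise floor
        sub = work.ravel()[:: max(1, work.size // 4_000_000)]
        med = float(np.median(sub))
        mad = 1.4826 * float(np.median(np.abs(sub - med)))
        thr = max(filters.threshold_otsu(work), med + 5.0 * mad)
    else:
        thr = float(threshold)

    selem = morphology.disk(opening_radius_px)
    min_px = max(1, int(round(min_area_um2 / (dx * dy))))
    rows = []
    for zi in range(work.shape[0]):
        mask = work[zi] > thr
        if not mask.any():
            continue
        mask = morphology.opening(mask, selem)
        mask = morphology.closing(mask, selem)
        mask = ndimage.binary_fill_holes(mask)
        mask = segmentation.clear_border(mask)
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
        if not mask.any():
            continue
        labels = measure.label(mask)
        for prop in measure.regionprops(labels, intensity_image=work[zi]):
            cy, cx = prop.centroid_weighted
            rows.append(
                {
                    "z_index": zi,
                    "x_um": (cx + 0.5) * dx,
                    "y_um": (cy + 0.5) * dy,
                    "area_px": int(prop.area),
                }
            )
    return pd.DataFrame(rows, columns=["z_index", "x_um", "y_um", "area_px"])


# ---------------------------------------------------------------------------
# lane linking
# ---------------------------------------------------------------------------


@dataclass
class LaneTrack:
    """One microwell's separation lane tracked through the z depth."""

    lane_id: int
    anchor_x_um: float
    anchor_y_um: float
    slices: pd.DataFrame  # z_index, x_um, y_um
    span_fraction: float
    ambiguous: bool = False


def link_lanes(
    centroids: pd.DataFrame,
    n_slices: int,
    max_step_um: float = 15.0,
    min_span_fraction: float = 0.1,
    merge_radius_um: float = 40.0,
) -> list[LaneTrack]:
    """Link per-slice centroids into one track per microwell.

    Slice-to-slice assignment minimizes total displacement (Hungarian
    algorithm) with a hard gate of ``max_step_um``. A pair of assignments
    that could be swapped while staying inside the gate (crossing drift
    between nearby lanes) marks both tracks ambiguous rather than being
    silently merged. Tracks persist through slices with no detection
    (bands of different species in one lane are separated by dark gaps).
    Because one microwell must yield one lane, tracks whose median
    positions fall within ``merge_radius_um`` are merged (threshold-edge
    blob splitting otherwise spawns satellite fragments); finally, tracks
    spanning less than ``min_span_fraction`` of the stack depth are
    discarded.
    """
    z_levels = sorted(centroids["z_index"].unique()) if len(centroids) else []
    if len(z_levels) < 2:
        raise ValueError("centroids from at least two slices are required")

    tracks: list[dict] = []  # {'pts': [(z, x, y)], 'last': (x, y), 'amb': bool}
    for zi in z_levels:
        pts = centroids[centroids["z_index"] == zi][["x_um", "y_um"]].to_numpy()
        if not tracks:
            for x, y in pts:
                tracks.append({"pts": [(zi, x, y)], "last": (x, y), "amb": False})
            continue
        last = np.array([t["last"] for t in tracks])
        dist = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
        big = 1e9
        cost = np.where(dist <= max_step_um, dist, big)
        rows, cols = linear_sum_assignment(cost)
        pairs = [(r, c) for r, c in zip(rows, cols) if cost[r, c] < big]
        # crossing ambiguity: swapping two assignments also fits the gate
        for i, (r1, c1) in enumerate(pairs):
            for r2, c2 in pairs[i + 1 :]:
                if dist[r1, c2] <= max_step_um and dist[r2, c1] <= max_step_um:
                    tracks[r1]["amb"] = True
                    tracks[r2]["amb"] = True
        claimed = {c for _, c in pairs}
        for r, c in pairs:
            x, y = pts[c]
            tracks[r]["pts"].append((zi, x, y))
            tracks[r]["last"] = (x, y)
        for c in range(len(pts)):
            if c not in claimed:
                x, y = pts[c]
                tracks.append({"pts": [(zi, x, y)], "last": (x, y), "amb": False})

    # merge co-located tracks (largest first) into one lane per microwell
    tracks.sort(key=lambda t: -len(t["pts"]))
    merged: list[dict] = []
    for t in tracks:
        pts = np.array([(p[1], p[2]) for p in t["pts"]])
        med = np.median(pts, axis=0)
        for m in merged:
            if np.hypot(*(med - m["anchor"])) <= merge_radius_um:
                m["pts"].extend(t["pts"])
                m["amb"] = m["amb"] or t["amb"]
                break
        else:
            merged.append({"pts": list(t["pts"]), "anchor": med, "amb": t["amb"]})

    out = []
    lane_id = 0
    for t in sorted(merged, key=lambda t: (t["anchor"][1], t["anchor"][0])):
        df = pd.DataFrame(t["pts"], columns=["z_index", "x_um", "y_um"])
        # keep one detection per slice: the one nearest the lane anchor
        d = np.hypot(df["x_um"] - t["anchor"][0], df["y_um"] - t["anchor"][1])
        df = (
            df.assign(_d=d)
            .sort_values(["z_index", "_d"])
            .drop_duplicates("z_index")
            .drop(columns="_d")
            .reset_index(drop=True)
        )
        span = (df["z_index"].max() - df["z_index"].min() + 1) / n_slices
        if span < min_span_fraction:
            continue
        out.append(
            LaneTrack(
                lane_id=lane_id,
                anchor_x_um=float(df["x_um"].median()),
                anchor_y_um=float(df["y_um"].median()),
                slices=df,
                span_fraction=float(span),
                ambiguous=t["amb"],
            )
        )
        lane_id += 1
    return out


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------


@dataclass
class ZProfile:
    """Background-subtracted summed-intensity profile along z for one lane."""

    z_um: np.ndarray
    intensity: np.ndarray
    noise: np.ndarray  # background-subtracted noise-region trace (ROI scale)
    roi_side_um: float
    background_per_z: np.ndarray
    clipped: bool = False


def _roi_bounds(center_px: float, half_px: int, size: int) -> tuple[int, int, bool]:
    lo = int(round(center_px)) - half_px
    hi = int(round(center_px)) + half_px
    clipped = lo < 0 or hi > size
    return max(lo, 0), min(hi, size), clipped


def extract_profile(
    stack: ImageStack,
    track: LaneTrack,
    channel: str | int = 0,
    roi_side_um: float = 102.0,
    background: Literal["border", "plane"] = "border",
    background_border_px: int = 5,
    noise_border_px: int = 5,
    plane_z_um: float | None = None,
    plane_exclude_um: float = 34.0,
) -> ZProfile:
    """Summed ROI intensity vs z, background subtracted.

    ``border`` mode subtracts, at each z, the mean intensity of a
    ``background_border_px``-wide frame surrounding the ROI (outside a
    thin noise-assessment ring). ``plane`` mode subtracts one scalar: the
    mean far-field intensity of the slice nearest ``plane_z_um``, away
    from any bright spots. The noise trace is the background-subtracted
    mean of the thin ring, scaled to the ROI pixel count, and feeds the
    SNR quality-control metric.
    """
    img = stack.channel(channel)
    nz, ny, nx = img.shape
    dz, dy, dx = stack.voxel_size_um
    half = max(1, int(round(roi_side_um / 2.0 / dx)))

    # per-z anchor: per-slice centroid where detected, else nearest detection
    sl = track.slices.set_index("z_index").sort_index()
    all_z = np.arange(nz)
    x_px = np.interp(all_z, sl.index, sl["x_um"] / dx - 0.5)
    y_px = np.interp(all_z, sl.index, sl["y_um"] / dy - 0.5)

    bg_scalar = None
    if background == "plane":
        if plane_z_um is None:
            raise ValueError("plane background mode needs plane_z_um")
        zi = int(np.clip(round(plane_z_um / dz - 0.5), 0, nz - 1))
        plane = img[zi]
        thr = plane.mean() + 2.0 * plane.std()
        far = plane < thr
        # also stay clear of bright spots by an exclusion margin
        if (~far).any():
            margin = int(round(plane_exclude_um / dx))
            far = ~morphology.dilation(~far, morphology.disk(min(margin, 50)))
        bg_scalar = float(plane[far].mean()) if far.any() else float(plane.mean())
    elif background != "border":
        raise ValueError("background must be 'border' or 'plane'")

    n_roi_px = (2 * half) ** 2
    intensity = np.zeros(nz)
    noise = np.zeros(nz)
    bg_per_z = np.zeros(nz)
    any_clip = False
    fully_outside = 0
    for zi in range(nz):
        x0, x1, cx = _roi_bounds(x_px[zi], half, nx)
        y0, y1, cy = _roi_bounds(y_px[zi], half, ny)
        if x0 >= x1 or y0 >= y1:
            fully_outside += 1
            continue
        any_clip = any_clip or cx or cy
        roi = img[zi, y0:y1, x0:x1]

        nb = noise_border_px
        bb = background_border_px
        ny0, ny1 = max(y0 - nb, 0), min(y1 + nb, ny)
        nx0, nx1 = max(x0 - nb, 0), min(x1 + nb, nx)
        by0, by1 = max(ny0 - bb, 0), min(ny1 + bb, ny)
        bx0, bx1 = max(nx0 - bb, 0), min(nx1 + bb, nx)

        outer = img[zi, by0:by1, bx0:bx1]
        mask_bg = np.ones(outer.shape, dtype=bool)
        mask_bg[ny0 - by0 : ny1 - by0, nx0 - bx0 : nx1 - bx0] = False
        ring = img[zi, ny0:ny1, nx0:nx1]
        mask_ring = np.ones(ring.shape, dtype=bool)
        mask_ring[y0 - ny0 : y1 - ny0, x0 - nx0 : x1 - nx0] = False

        if bg_scalar is not None:
            bg = bg_scalar
        else:
            bg = float(outer[mask_bg].mean()) if mask_bg.any() else 0.0
        bg_per_z[zi] = bg
        intensity[zi] = float(roi.sum() - bg * roi.size)
        if mask_ring.any():
            noise[zi] = float((ring[mask_ring].mean() - bg) * n_roi_px)
    if fully_outside == nz:
        raise ValueError("ROI lies fully outside the stack")
    return ZProfile(
        z_um=stack.z_coords_um(),
        intensity=intensity,
        noise=noise,
        roi_side_um=2 * half * dx,
        background_per_z=bg_per_z,
        clipped=any_clip,
    )


# ---------------------------------------------------------------------------
# Gaussian peak fitting and QC
# ---------------------------------------------------------------------------


@dataclass
class PeakFit:
    """Gaussian fit of one z-intensity peak with quality-control flags."""

    amplitude: float
    mu_um: float
    sigma_um: float
    r_squared: float
    snr: float
    qc_pass: bool
    reason: str = ""
    window_um: tuple[float, float] | None = None

    @property
    def auc(self) -> float:
        return self.amplitude * self.sigma_um * np.sqrt(2.0 * np.pi)


def _gaussian(z, a, mu, sigma):
    return a * np.exp(-0.5 * ((z - mu) / sigma) ** 2)


def fit_peak(
    profile: ZProfile,
    window_um: tuple[float, float] | None = None,
    r2_threshold: float = 0.7,
    snr_threshold: float = 3.0,
    min_points: int = 5,
) -> PeakFit:
    """Nonlinear least-squares Gaussian fit of a z-profile peak.

    Initialization is moment-based; R^2 is computed over the fit window;
    SNR is the fitted amplitude divided by twice the standard deviation of
    the background-subtracted noise trace over the peak's z-range. Both QC
    thresholds are strict inequalities. Non-convergence yields
    ``qc_pass=False`` with a reason code, never an exception.
    """
    z = profile.z_um
    y = profile.intensity
    if window_um is not None:
        sel = (z >= window_um[0]) & (z <= window_um[1])
        z, y = z[sel], y[sel]
    if z.size < min_points:
        raise ValueError(f"need at least {min_points} points in the fit window")

    def failed(reason: str) -> PeakFit:
        return PeakFit(
            amplitude=np.nan, mu_um=np.nan, sigma_um=np.nan,
            r_squared=np.nan, snr=np.nan, qc_pass=False,
            reason=reason, window_um=window_um,
        )

    if not np.any(y > 0):
        return failed("no_signal")
    yp = np.clip(y, 0.0, None)
    mu0 = float((z * yp).sum() / yp.sum())
    var0 = float((yp * (z - mu0) ** 2).sum() / yp.sum())
    sigma0 = max(np.sqrt(var0), (z[1] - z[0]) / 2.0)
    a0 = float(y.max())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _gaussian, z, y,
                p0=[a0, mu0, sigma0],
                bounds=([0.0, z.min(), (z[1] - z[0]) / 10.0],
                        [np.inf, z.max(), z.max() - z.min() + 1.0]),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return failed("no_convergence")
    a, mu, sigma = popt
    resid = y - _gaussian(z, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0

    peak_sel = (profile.z_um >= mu - 2 * sigma) & (profile.z_um <= mu + 2 * sigma)
    noise_sd = float(np.std(profile.noise[peak_sel])) if peak_sel.any() else 0.0
    snr = a / (2.0 * noise_sd) if noise_sd > 0 else np.inf

    qc = (r2 > r2_threshold) and (snr > snr_threshold)
    reason = "" if qc else ("low_r2" if r2 <= r2_threshold else "low_snr")
    return PeakFit(
        amplitude=float(a), mu_um=float(mu), sigma_um=float(sigma),
        r_squared=r2, snr=float(snr), qc_pass=qc, reason=reason,
        window_um=window_um,
    )


@dataclass
class XYWidth:
    sigma_x_um: float
    sigma_y_um: float
    z_index: int
    failed: bool = False

    @property
    def sigma_xy_um(self) -> float:
        return 0.5 * (self.sigma_x_um + self.sigma_y_um)

    @property
    def anisotropy(self) -> float:
        lo = min(self.sigma_x_um, self.sigma_y_um)
        return max(self.sigma_x_um, self.sigma_y_um) / lo if lo > 0 else np.inf


def fit_xy_width(
    stack: ImageStack,
    track: LaneTrack,
    channel: str | int = 0,
    z_peak_um: float | None = None,
    roi_side_um: float = 102.0,
) -> XYWidth:
    """Lateral band width at the migration peak.

    At the slice where the lane's summed ROI intensity is maximal (or at
    ``z_peak_um``), the summed 1D x- and y-profiles of the
    minimum-subtracted ROI are Gaussian-fitted; the reported sigma_xy is
    the mean of sigma_x and sigma_y.
    """
    img = stack.channel(channel)
    nz, ny, nx = img.shape
    dz, dy, dx = stack.voxel_size_um
    half = max(1, int(round(roi_side_um / 2.0 / dx)))
    sl = track.slices.set_index("z_index").sort_index()
    all_z = np.arange(nz)
    x_px = np.interp(all_z, sl.index, sl["x_um"] / dx - 0.5)
    y_px = np.interp(all_z, sl.index, sl["y_um"] / dy - 0.5)

    if z_peak_um is not None:
        zi = int(np.clip(round((z_peak_um - stack.z0_offset_um) / dz - 0.5), 0, nz - 1))
    else:
        sums = np.full(nz, -np.inf)
        for k in range(nz):
            x0, x1, _ = _roi_bounds(x_px[k], half, nx)
            y0, y1, _ = _roi_bounds(y_px[k], half, ny)
            if x0 < x1 and y0 < y1:
                sums[k] = img[k, y0:y1, x0:x1].sum()
        zi = int(np.argmax(sums))

    x0, x1, _ = _roi_bounds(x_px[zi], half, nx)
    y0, y1, _ = _roi_bounds(y_px[zi], half, ny)
    roi = img[zi, y0:y1, x0:x1].astype(float)
    roi = roi - roi.min()

    def gauss_offset(x, a, mu, sigma, c):
        return _gaussian(x, a, mu, sigma) + c

    def fit_1d(profile: np.ndarray, pitch: float, origin_px: int) -> float:
        coords = (np.arange(profile.size) + origin_px + 0.5) * pitch
        if not np.any(profile > 0):
            return np.nan
        mu0 = float((coords * profile).sum() / profile.sum())
        s0 = max(
            np.sqrt(float((profile * (coords - mu0) ** 2).sum() / profile.sum())),
            pitch / 2.0,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # free offset absorbs the in-ROI tail baseline left by
                # min-subtraction, which otherwise biases sigma low
                popt, _ = optimize.curve_fit(
                    gauss_offset, coords, profile,
                    p0=[float(profile.max()), mu0, s0, 0.0], maxfev=5000,
                )
            return abs(float(popt[2]))
        except (RuntimeError, ValueError):
            return np.nan

    sx = fit_1d(roi.sum(axis=0), dx, x0)
    sy = fit_1d(roi.sum(axis=1), dy, y0)
    failed = not (np.isfinite(sx) and np.isfinite(sy))
    return XYWidth(sigma_x_um=sx, sigma_y_um=sy, z_index=zi, failed=failed)


# ---------------------------------------------------------------------------
# per-gel orchestration and summaries
# ---------------------------------------------------------------------------


def analyze_stack(
    stack: ImageStack,
    threshold: float | Literal["otsu"] = "otsu",
    max_step_um: float = 15.0,
    min_span_fraction: float = 0.1,
    roi_side_um: float = 102.0,
    background: Literal["border", "plane"] = "border",
    background_border_px: int = 5,
    plane_z_um: float | None = None,
    channel_windows_um: dict[str, tuple[float, float]] | None = None,
    r2_threshold: float = 0.7,
    snr_threshold: float = 3.0,
) -> tuple[pd.DataFrame, list[LaneTrack]]:
    """Full pipeline: segmentation -> linking -> profiles -> fits -> records.

    Returns one record per (lane, channel) with columns lane_id, x_um,
    y_um, channel, mu_um, sigma_z_um, sigma_xy_um, amplitude, auc, r2,
    snr, qc_pass, ambiguous.
    """
    cents = segment_slices(stack, threshold=threshold)
    columns = [
        "lane_id", "x_um", "y_um", "channel", "mu_um", "sigma_z_um",
        "sigma_xy_um", "amplitude", "auc", "r2", "snr", "qc_pass", "ambiguous",
    ]
    if cents.empty or cents["z_index"].nunique() < 2:
        return pd.DataFrame(columns=columns), []
    tracks = link_lanes(
        cents, n_slices=stack.shape_zyx[0],
        max_step_um=max_step_um, min_span_fraction=min_span_fraction,
    )
    channels = list(stack.channels) if stack.voxels.ndim == 4 else [0]
    rows = []
    for track in tracks:
        for ch in channels:
            prof = extract_profile(
                stack, track, channel=ch, roi_side_um=roi_side_um,
                background=background,
                background_border_px=background_border_px,
                plane_z_um=plane_z_um,
            )
            window = None
            if channel_windows_um and isinstance(ch, str):
                window = channel_windows_um.get(ch)
            peak = fit_peak(
                prof, window_um=window,
                r2_threshold=r2_threshold, snr_threshold=snr_threshold,
            )
            if peak.qc_pass:
                xy = fit_xy_width(
                    stack, track, channel=ch,
                    z_peak_um=peak.mu_um, roi_side_um=roi_side_um,
                )
                sigma_xy = xy.sigma_xy_um
            else:
                sigma_xy = np.nan
            rows.append(
                {
                    "lane_id": track.lane_id,
                    "x_um": track.anchor_x_um,
                    "y_um": track.anchor_y_um,
                    "channel": ch if isinstance(ch, str) else f"ch{ch}",
                    "mu_um": peak.mu_um,
                    "sigma_z_um": peak.sigma_um,
                    "sigma_xy_um": sigma_xy,
                    "amplitude": peak.amplitude,
                    "auc": peak.auc,
                    "r2": peak.r_squared,
                    "snr": peak.snr,
                    "qc_pass": peak.qc_pass,
                    "ambiguous": track.ambiguous,
                }
            )
    return pd.DataFrame(rows, columns=columns), tracks


def summarize_gel(
    records: pd.DataFrame,
    channel_pairs: Sequence[tuple[str, str]] | None = None,
) -> dict:
    """Gel-level summary of QC-passing lanes.

    Per channel: count passing QC, median/sd/CV of migration, median
    sigma_z; per requested channel pair: the median migration difference
    delta_z. A migration heat map (x, y, mu) per channel supports spotting
    spatial field/temperature nonuniformity.
    """
    out: dict = {"channels": {}, "pairs": {}, "maps": {}}
    passing = records[records["qc_pass"] == True]  # noqa: E712
    if passing.empty:
        warnings.warn("no lanes passed quality control")
        return out
    for ch, grp in passing.groupby("channel"):
        mu = grp["mu_um"]
        out["channels"][ch] = {
            "n_pass": int(len(grp)),
            "migration_median_um": float(mu.median()),
            "migration_sd_um": float(mu.std(ddof=1)) if len(grp) > 1 else 0.0,
            "migration_cv": float(mu.std(ddof=1) / mu.mean())
            if len(grp) > 1 and mu.mean() != 0
            else 0.0,
            "sigma_z_median_um": float(grp["sigma_z_um"].median()),
            "sigma_xy_median_um": float(grp["sigma_xy_um"].median()),
        }
        out["maps"][ch] = grp[["x_um", "y_um", "mu_um"]].reset_index(drop=True)
    if channel_pairs:
        for a, b in channel_pairs:
            if a in out["channels"] and b in out["channels"]:
                out["pairs"][f"{a}-{b}"] = abs(
                    out["channels"][a]["migration_median_um"]
                    - out["channels"][b]["migration_median_um"]
                )
    return out


def match_cells_to_bands(
    livecell: np.ndarray,
    band_projection: np.ndarray,
    well_centers: pd.DataFrame,
    pixel_um: float,
    window_um: float = 60.0,
    threshold: float | Literal["otsu"] = "otsu",
) -> dict:
    """Well-by-well correspondence of live cells and probed bands.

    Both images must be registered to the same microwell grid (same shape
    and pixel size). Presence is decided by thresholding a square window
    around each well center in each image.
    """
    if livecell.shape != band_projection.shape:
        raise ValueError("live-cell and band images are not registered")
    half = max(1, int(round(window_um / 2.0 / pixel_um)))

    def thr_of(img):
        if threshold != "otsu":
            return float(threshold)
        return filters.threshold_otsu(img) if img.max() > 0 else np.inf

    t_cell, t_band = thr_of(livecell), thr_of(band_projection)
    rows = []
    for _, w in well_centers.iterrows():
        cx = int(round(w["x_um"] / pixel_um))
        cy = int(round(w["y_um"] / pixel_um))
        sl = np.s_[
            max(cy - half, 0) : cy + half, max(cx - half, 0) : cx + half
        ]
        rows.append(
            {
                "well_i": w.get("well_i", np.nan),
                "well_j": w.get("well_j", np.nan),
                "cell": bool(livecell[sl].max() > t_cell),
                "band": bool(band_projection[sl].max() > t_band),
            }
        )
    df = pd.DataFrame(rows)
    n_cells = int(df["cell"].sum())
    n_bands = int(df["band"].sum())
    both = int((df["cell"] & df["band"]).sum())
    return {
        "per_well": df,
        "n_cells": n_cells,
        "n_bands": n_bands,
        "pct_cells_with_bands": 100.0 * both / n_cells if n_cells else 0.0,
        "pct_cells_without_bands": 100.0 * (n_cells - both) / n_cells
        if n_cells
        else 0.0,
        "pct_bands_without_cells": 100.0 * (n_bands - both) / n_bands
        if n_bands
        else 0.0,
    }


def lysis_kinetics(
    frames: np.ndarray,
    times_s: np.ndarray,
    pixel_um: float,
    drop_fraction: float = 0.5,
    window_s: float = 5.0,
    circle_diameter_um: float = 100.0,
    metric: Literal["max", "total"] = "max",
    adaptive_block_px: int = 25,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell lysis onset times from a wide-field time-lapse.

    Cells are segmented in the first frame by adaptive thresholding of the
    median-filtered image; the maximum and total background-subtracted
    intensity in a circle around each centroid are tracked over time.
    Onset is the first time the tracked metric drops below
    ``drop_fraction`` of its initial value; the summary reports the
    fraction of cells lysing within ``window_s``.
    """
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (t, y, x) movie with at least two frames")
    first = ndimage.median_filter(frames[0], size=3)
    block = adaptive_block_px | 1  # must be odd
    local = filters.threshold_local(first, block_size=block, offset=0.0)
    mask = first > np.maximum(local, first.max() * 0.05)
    mask = morphology.opening(mask, morphology.disk(1))
    mask = morphology.closing(mask, morphology.disk(1))
    labels = measure.label(mask)
    props = measure.regionprops(labels, intensity_image=first)
    if not props:
        return pd.DataFrame(columns=["cell_id", "x_um", "y_um", "onset_s"]), {
            "n_cells": 0,
            "fraction_within_window": 0.0,
        }

    ny, nx = frames.shape[1:]
    yy, xx = np.mgrid[0:ny, 0:nx]
    radius_px = circle_diameter_um / 2.0 / pixel_um
    bg_clear = morphology.dilation(
        mask, morphology.disk(int(round(30.0 / pixel_um)))
    )

    rows = []
    for cid, prop in enumerate(props):
        cy, cx = prop.centroid
        circ = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        trace_max = np.empty(frames.shape[0])
        trace_tot = np.empty(frames.shape[0])
        for f in range(frames.shape[0]):
            bg_px = frames[f][~bg_clear]
            bg = float(bg_px.mean()) if bg_px.size else 0.0
            vals = frames[f][circ] - bg
            trace_max[f] = vals.max()
            trace_tot[f] = vals.sum()
        trace = trace_max if metric == "max" else trace_tot
        init = trace[0]
        onset = np.nan
        if init > 0:
            thr = drop_fraction * init
            below = np.flatnonzero(trace < thr)
            if below.size:
                i = int(below[0])
                if i > 0 and trace[i - 1] > trace[i]:
                    # linear interpolation of the threshold crossing
                    frac = (trace[i - 1] - thr) / (trace[i - 1] - trace[i])
                    onset = float(
                        times_s[i - 1] + frac * (times_s[i] - times_s[i - 1])
                    )
                else:
                    onset = float(times_s[i])
        rows.append(
            {
                "cell_id": cid,
                "x_um": (cx + 0.5) * pixel_um,
                "y_um": (cy + 0.5) * pixel_um,
                "onset_s": onset,
            }
        )
    df = pd.DataFrame(rows)
    lysed_in_window = (df["onset_s"] <= window_s).sum()
    summary = {
        "n_cells": int(len(df)),
        "n_within_window": int(lysed_in_window),
        "fraction_within_window": float(lysed_in_window / len(df)),
        "window_s": window_s,
    }
    return df, summary
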