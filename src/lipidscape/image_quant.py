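"""Relative plasma-membrane fluorescence from line profiles.

Quantifies how strongly a fluorescent reporter is enriched at the plasma
membrane relative to the cytosol. Three line profiles are taken on a
single-cell grayscale image — one crossing the cell, one inside it, one
fully outside — and five statistics are computed:

    F_in   = mean intensity of the inside line
    F_out  = mean intensity of the outside line (background)
    F_cross = mean of the two outer peaks of the crossing line, each
              averaged with the sample one pixel in front and behind
    F_cyto = F_in − F_out
    F_PM   = F_cross − F_out
    relative F_PM = F_PM / F_cyto = (F_cross − F_out) / (F_in − F_out)

The ratio is invariant under affine intensity transforms I → αI + β of the
source image because all five statistics are affine-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu


@dataclass
class LineProfile:
    positions: np.ndarray  # pixels along the line
    intensities: np.ndarray
    role: str = "cross"  # cross | inside | outside

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.intensities) < 5:
            raise ValueError("profile needs at least 5 samples")
        if not np.isfinite(self.intensities).all():
            raise ValueError("profile intensities must be finite")


@dataclass
class CellQuant:
    f_in: float
    f_out: float
    f_cross: float
    f_cyto: float
    f_pm: float
    relative_f_pm: float
    peak_indices: tuple[int, int]


def extract_line_profile(image: np.ndarray, start, end, role: str = "cross") -> LineProfile:
    """Sample the image along a segment at unit-pixel spacing (bilinear).

    ``start`` and ``end`` are (x, y) pixel coordinates inside the image.
    """
    image = np.asarray(image, dtype=float)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    ny, nx = image.shape
    for p in (start, end):
        if not (0 <= p[0] <= nx - 1 and 0 <= p[1] <= ny - 1):
            raise ValueError("line endpoints must lie inside the image")
    length = float(np.hypot(*(end - start)))
    if length == 0:
        raise ValueError("line endpoints coincide")
    n = int(np.floor(length)) + 1
    t = np.linspace(0.0, length, n)
    xs = start[0] + (end[0] - start[0]) * t / length
    ys = start[1] + (end[1] - start[1]) * t / length
    vals = ndimage.map_coordinates(image, np.stack([ys, xs]), order=1, mode="nearest")
    return LineProfile(t, vals, role)


def find_outer_peaks(profile: LineProfile, min_prominence: float = 0.1) -> tuple[int, int]:
    """First and last local maxima with prominence ≥ a fraction of the range.

    ``min_prominence`` is expressed as a fraction of the profile's intensity
    range. A single broad flat maximum (a membrane indistinguishable from
    the cytosol) degenerates to coincident peaks at the plateau midpoint;
    otherwise fewer than two qualifying maxima is an error, as is a flat
    profile.
    """
    y = profile.intensities
    rng = float(y.max() - y.min())
    if rng <= 0:
        raise ValueError("profile is flat: no peaks")
    peaks, props = signal.find_peaks(y, prominence=min_prominence * rng,
                                     plateau_size=0)
    if len(peaks) >= 2:
        return int(peaks[0]), int(peaks[-1])
    if len(peaks) == 1 and props["plateau_sizes"][0] >= 3:
        mid = int(peaks[0])
        return mid, mid
    raise ValueError("fewer than two qualifying intensity peaks")


def relative_fpm(
    cross: LineProfile,
    inside: LineProfile,
    outside: LineProfile,
    min_prominence: float = 0.1,
) -> CellQuant:
    """Compute the five line-profile statistics and relative F_PM.

    F_cross averages exactly six samples: each outer peak of the crossing
    profile together with its neighbours one pixel in front and behind.
    """
    left, right = find_outer_peaks(cross, min_prominence)
    y = cross.intensities
    samples = []
    for p in (left, right):
        lo, hi = max(p - 1, 0), min(p + 1, len(y) - 1)
        samples.extend(y[lo : hi + 1])
    f_cross = float(np.mean(samples))
    f_in = float(inside.intensities.mean())
    f_out = float(outside.intensities.mean())
    f_cyto = f_in - f_out
    f_pm = f_cross - f_out
    if abs(f_cyto) < 1e-12:
        raise ValueError("F_cyto is zero: relative F_PM undefined")
    return CellQuant(f_in, f_out, f_cross, f_cyto, f_pm, f_pm / f_cyto, (left, right))


def _segment_cell(image: np.ndarray):
    """Otsu threshold + largest connected component; returns (mask, centroid,
    equivalent radius)."""
    thr = threshold_otsu(image)
    mask = image > thr
    if not mask.any():
        raise ValueError("no foreground object found")
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    cy, cx = ndimage.center_of_mass(mask)
    radius = float(np.sqrt(mask.sum() / np.pi))
    return mask, (cx, cy), radius


def auto_quantify_cell(
    image: np.ndarray, min_prominence: float = 0.1, margin: float = 2.0
) -> CellQuant:
    """Place the three lines automatically on a single-cell image.

    The cell is located by intensity thresholding; the crossing line runs
    through the centroid along the image's longer axis (maximal profile
    length), the inside line is a short chord within half a radius of the
    centroid, and the outside line lies fully in the background.
    """
    image = np.asarray(image, dtype=float)
    if np.ptp(image) == 0:
        raise ValueError("no foreground object found")
    mask, (cx, cy), radius = _segment_cell(image)
    ny, nx = image.shape

    if nx >= ny:
        cross = extract_line_profile(image, (margin, cy), (nx - 1 - margin, cy), "cross")
    else:
        cross = extract_line_profile(image, (cx, margin), (cx, ny - 1 - margin), "cross")

    half = 0.5 * radius
    inside = extract_line_profile(image, (cx - half, cy), (cx + half, cy), "inside")

    # outside line: along the image edge farthest from the cell centre
    edge_y = margin if cy > ny / 2 else ny - 1 - margin
    seg = min(2 * radius, nx - 2 * margin - 1)
    x0 = margin if cx > nx / 2 else nx - 1 - margin - seg
    outside = extract_line_profile(image, (x0, edge_y), (x0 + seg, edge_y), "outside")

    return relative_fpm(cross, inside, outside, min_prominence)
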