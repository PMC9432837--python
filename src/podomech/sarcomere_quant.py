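"""Sarcomere-like-structure (SLS) periodicity from multichannel images.

Workflow, mirroring manual line-profile analysis: a polyline is drawn along
a striated stress fiber, intensity is sampled along it (averaged across a
perpendicular width), same-channel peaks are detected with sub-sample
parabolic refinement, and successive peak-to-peak distances give the
sarcomeric spacing.  Spacings are summarised two ways, both used in
practice and deliberately kept distinct:

* pooled — every spacing from every fiber in a group counts once
  (n = total number of spacings);
* per-fiber — one mean spacing per fiber, restricted to fibers of at
  least ``min_fiber_length`` (default 6 um) with at least two peaks
  (n = number of eligible fibers).

A two-channel alternation index quantifies how strictly e.g. myosin IIA
bands interleave with synaptopodin bands (1.0 = perfect alternation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .synthgen import BoundsError, StriationImage, _polyline_arclength

MIN_FIBER_LENGTH_UM = 6.0


@dataclass
class FiberProfile:
    """Per-channel intensity vs arclength along a fiber polyline."""

    arclength: np.ndarray               # um, strictly increasing
    intensity: dict                     # channel -> values
    source_polyline: np.ndarray         # (n, 2) um
    sampling_step: float                # um

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")
        for ch, vals in self.intensity.items():
            self.intensity[ch] = np.asarray(vals, dtype=float)
            if len(self.intensity[ch]) != len(self.arclength):
                raise ValueError(f"channel {ch!r} length mismatch")

    @property
    def length(self) -> float:
        return float(self.arclength[-1] - self.arclength[0])


@dataclass
class SpacingSet:
    """Detected band positions and spacings for one fiber and channel."""

    peak_positions: np.ndarray          # um along the fiber
    spacings: np.ndarray                # successive differences, um
    fiber_length: float                 # um
    per_fiber_mean: float | None       # None = fiber ineligible

    @property
    def eligible(self) -> bool:
        return self.per_fiber_mean is not None


def extract_profile(image: StriationImage, polyline: np.ndarray,
                    width: float = 0.0, step: float = 0.05) -> FiberProfile:
    """Sample intensity along a polyline, averaged across a normal width.

    Samples every ``step`` um along the polyline.  At each sample the
    intensity is the mean of bilinear interpolations at offsets spanning
    ``width`` perpendicular to the local fiber direction (``width`` 0 =
    single line).  All coordinates are microns; the polyline must stay
    inside the image.
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[1] != 2 or len(polyline) < 2:
        raise ValueError("polyline must be (n>=2, 2) micron points")
    if width < 0 or step <= 0:
        raise ValueError("width >= 0 and step > 0 required")
    seg_len, cum = _polyline_arclength(polyline)
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length polyline")

    h, w = image.shape
    px = image.pixel_size
    xmax, ymax = (w - 1) * px, (h - 1) * px
    if (polyline[:, 0].min() < 0 or polyline[:, 1].min() < 0
            or polyline[:, 0].max() > xmax or polyline[:, 1].max() > ymax):
        raise BoundsError("polyline extends outside the image")

    s = np.arange(0.0, total + 0.5 * step, step)
    s[-1] = min(s[-1], total)
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1,
                      0, len(seg_len) - 1)
    t = (s - cum[seg_idx]) / seg_len[seg_idx]
    dirs = (polyline[seg_idx + 1] - polyline[seg_idx]) / seg_len[seg_idx, None]
    pts = polyline[seg_idx] + t[:, None] * (polyline[seg_idx + 1]
                                            - polyline[seg_idx])
    normals = np.column_stack([-dirs[:, 1], dirs[:, 0]])

    if width > 0:
        n_off = max(3, int(np.ceil(width / px)) + 1)
        offsets = np.linspace(-width / 2.0, width / 2.0, n_off)
    else:
        offsets = np.array([0.0])
    sample_xy = pts[None] + offsets[:, None, None] * normals[None]
    if (sample_xy[..., 0].min() < 0 or sample_xy[..., 1].min() < 0
            or sample_xy[..., 0].max() > xmax
            or sample_xy[..., 1].max() > ymax):
        raise BoundsError("averaging width extends outside the image")

    rows = sample_xy[..., 1] / px
    cols = sample_xy[..., 0] / px
    intensity = {}
    for ch in image.channels:
        vals = ndimage.map_coordinates(
            image.channel(ch), [rows.ravel(), cols.ravel()], order=1)
        intensity[ch] = vals.reshape(len(offsets), len(s)).mean(axis=0)
    return FiberProfile(arclength=s, intensity=intensity,
                        source_polyline=polyline, sampling_step=step)


def detect_peaks(profile: FiberProfile, channel: str,
                 min_prominence: float = 0.2,
                 min_separation: float = 0.4) -> np.ndarray:
    """Peak positions (um) along the fiber with sub-sample refinement.

    ``min_prominence`` is a fraction of the channel's intensity range, so
    detection is invariant to constant offsets and uniform rescaling; peaks
    closer than ``min_separation`` um are suppressed (keep the higher one).
    Each surviving sample-level maximum is refined by a 3-point parabolic
    fit.  A flat or empty profile yields an empty array.
    """
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    y = profile.intensity[channel]
    if len(y) < 3:
        return np.empty(0)
    rng_y = float(y.max() - y.min())
    if rng_y <= 0:
        return np.empty(0)
    step = float(np.mean(np.diff(profile.arclength)))
    distance = max(1, int(round(min_separation / step)))
    prom = min_prominence * rng_y
    idx, _ = signal.find_peaks(y, prominence=prom, distance=distance)
    idx = list(idx)
    # find_peaks cannot flag maxima at the profile ends; admit an endpoint
    # if it dominates its neighbour, clears the same range-relative
    # prominence above the profile minimum, and respects the separation
    if y[0] >= y[1] and y[0] - y.min() >= prom and \
            (not idx or profile.arclength[idx[0]]
             - profile.arclength[0] >= min_separation):
        idx.insert(0, 0)
    if y[-1] >= y[-2] and y[-1] - y.min() >= prom and \
            (not idx or profile.arclength[-1]
             - profile.arclength[idx[-1]] >= min_separation):
        idx.append(len(y) - 1)
    idx = np.asarray(idx, dtype=int)
    if len(idx) == 0:
        return np.empty(0)
    # parabolic sub-sample refinement on interior peaks
    pos = profile.arclength[idx].astype(float)
    interior = (idx > 0) & (idx < len(y) - 1)
    ii = idx[interior]
    denom = y[ii - 1] - 2.0 * y[ii] + y[ii + 1]
    delta = np.zeros(len(ii))
    nz = denom != 0
    delta[nz] = 0.5 * (y[ii - 1] - y[ii + 1])[nz] / denom[nz]
    delta = np.clip(delta, -0.5, 0.5)
    pos[interior] = profile.arclength[ii] + delta * step
    return pos


def compute_spacings(peaks: np.ndarray, fiber_length: float,
                     min_fiber_length: float = MIN_FIBER_LENGTH_UM
                     ) -> SpacingSet:
    """Successive peak differences; per-fiber mean only for eligible fibers.

    A fiber contributes a per-fiber mean only if it is at least
    ``min_fiber_length`` um long and has at least two peaks; otherwise the
    mean is None and the fiber is excluded from per-fiber statistics (its
    pooled spacings, if any, still count).
    """
    peaks = np.asarray(peaks, dtype=float)
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be sorted strictly increasing")
    spacings = np.diff(peaks)
    eligible = fiber_length >= min_fiber_length and len(peaks) >= 2
    mean = float(np.mean(spacings)) if eligible else None
    return SpacingSet(peak_positions=peaks, spacings=spacings,
                      fiber_length=float(fiber_length), per_fiber_mean=mean)


def alternation_index(peaks_a: np.ndarray, peaks_b: np.ndarray):
    """Fraction of consecutive a-peak intervals containing exactly one b peak.

    1.0 means the b channel alternates perfectly with the a channel (one b
    band strictly between every pair of neighbouring a bands).  Undefined
    (None) with fewer than two a peaks.
    """
    a = np.asarray(peaks_a, dtype=float)
    b = np.asarray(peaks_b, dtype=float)
    if np.any(np.diff(a) <= 0) or np.any(np.diff(b) <= 0):
        raise ValueError("peak lists must be sorted strictly increasing")
    if len(a) < 2:
        return None
    hits = 0
    for lo, hi in zip(a[:-1], a[1:]):
        if np.sum((b > lo) & (b < hi)) == 1:
            hits += 1
    return hits / (len(a) - 1)


def spacing_statistics(spacing_sets, group_labels,
                       bins=None) -> dict:
    """Per-group pooled and per-fiber spacing summaries.

    Returns a dict with:

    * ``pooled`` — DataFrame (group, n = total spacing count, mean_um,
      sd_um): every spacing counts once;
    * ``per_fiber`` — DataFrame (group, n = eligible fiber count, mean_um,
      sd_um) over per-fiber mean spacings;
    * ``histograms`` — group -> (counts, bin_edges) of pooled spacings.

    Groups with no spacings (or no eligible fibers) are excluded from the
    corresponding table with a warning.
    """
    group_labels = list(group_labels)
    if len(group_labels) != len(spacing_sets):
        raise ValueError("one group label per spacing set required")
    if not spacing_sets:
        raise ValueError("need at least one spacing set")

    groups = pd.unique(pd.Series(group_labels))
    pooled_rows, fiber_rows, histograms = [], [], {}
    all_spacings = np.concatenate(
        [s.spacings for s in spacing_sets if len(s.spacings)] or [[np.nan]])
    if bins is None:
        finite = all_spacings[np.isfinite(all_spacings)]
        bins = (np.histogram_bin_edges(finite, bins=20)
                if len(finite) else 10)

    for g in groups:
        sets = [s for s, lab in zip(spacing_sets, group_labels) if lab == g]
        pooled = np.concatenate([s.spacings for s in sets]
                                ) if sets else np.empty(0)
        if len(pooled) == 0:
            warnings.warn(f"group {g!r} has no spacings; excluded")
        else:
            pooled_rows.append((g, len(pooled), pooled.mean(),
                                pooled.std(ddof=1) if len(pooled) > 1 else 0.0))
            histograms[g] = np.histogram(pooled, bins=bins)
        fiber_means = np.array([s.per_fiber_mean for s in sets
                                if s.eligible])
        if len(fiber_means) == 0:
            warnings.warn(f"group {g!r} has no eligible fibers; excluded "
                          "from per-fiber statistics")
        else:
            fiber_rows.append((g, len(fiber_means), fiber_means.mean(),
                               fiber_means.std(ddof=1)
                               if len(fiber_means) > 1 else 0.0))

    cols = ["group", "n", "mean_um", "sd_um"]
    return {
        "pooled": pd.DataFrame(pooled_rows, columns=cols),
        "per_fiber": pd.DataFrame(fiber_rows, columns=cols),
        "histograms": histograms,
    }


def measure_image(image: StriationImage, polylines, channels=None,
                  width: float = 0.3, step: float = 0.05,
                  min_prominence: float = 0.2,
                  min_separation: float = 0.4) -> pd.DataFrame:
    """Convenience: profiles + peaks + spacings for many fibers at once.

    ``polylines`` maps fiber_id -> (n, 2) micron polyline.  Returns a tidy
    DataFrame (fiber_id, channel, position_um, spacing_um) where spacing_um
    is NaN for the first peak of each fiber/channel.
    """
    channels = list(channels) if channels is not None else list(image.channels)
    rows = []
    for fid, pl in polylines.items():
        profile = extract_profile(image, pl, width=width, step=step)
        for ch in channels:
            peaks = detect_peaks(profile, ch, min_prominence=min_prominence,
                                 min_separation=min_separation)
            spacings = np.concatenate([[np.nan], np.diff(peaks)]
                                      ) if len(peaks) else np.empty(0)
            for p, s in zip(peaks, spacings):
                rows.append((fid, ch, p, s))
    return pd.DataFrame(rows, columns=["fiber_id", "channel",
                                       "position_um", "spacing_um"])


def plot_spacing_histograms(stats: dict, path=None):
    """Bar plot of the pooled spacing histograms returned by spacing_statistics."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for g, (counts, edges) in stats["histograms"].items():
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.step(centers, counts, where="mid", label=str(g))
    ax.set_xlabel("sarcomeric spacing (um)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
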