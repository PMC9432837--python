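"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the toolkit (sarcomere periodicity, bead-based
strain mapping, phenotype scoring) is validated by parameter recovery from
synthetic data generated here:

* striated-fiber images — stress fibers carrying alternating protein bands
  (e.g. synaptopodin/alpha-actinin 4 vs myosin IIA) at a controlled period
  of 0.5-2 um, rendered as Gaussian bumps along a polyline, blurred by a
  Gaussian PSF and corrupted by additive Gaussian noise;
* bead clouds displaced by a closed-form deformation map whose exact
  deformation gradient is stored per bead;
* cell populations drawn from the four SLS phenotype categories.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile
from scipy import ndimage

from .scoring import PHENOTYPE_CATEGORIES
from .strain_map import BeadField

# FWHM -> Gaussian sigma
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))      # ~2.355


class NyquistError(ValueError):
    """Requested band spacing is not resolvable at the pixel size."""


class BoundsError(ValueError):
    """A polyline or sampling point falls outside the image."""


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

@dataclass
class StriationImage:
    """Multichannel pixel grid with physical pixel size.

    ``data`` has shape (channels, rows, cols), float intensities in [0, 1].
    Coordinates are in microns with the origin at the top-left pixel center,
    x rightward (columns), y downward (rows).
    """

    data: np.ndarray
    channels: tuple
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        self.channels = tuple(self.channels)
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel names must match first axis of data")

    @property
    def shape(self):
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def extent_um(self):
        h, w = self.shape
        return (w - 1) * self.pixel_size, (h - 1) * self.pixel_size

    def to_tiff(self, path) -> None:
        """Write as multichannel 16-bit TIFF with pixel size in metadata."""
        scaled = np.clip(self.data, 0.0, 1.0)
        arr = np.round(scaled * 65535).astype(np.uint16)
        res = 1.0 / self.pixel_size
        tifffile.imwrite(
            path, arr, imagej=True, resolution=(res, res),
            metadata={"unit": "um", "axes": "CYX",
                      "Labels": list(self.channels)})

    @classmethod
    def from_tiff(cls, path, channels=None,
                  pixel_size: float | None = None) -> "StriationImage":
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            if pixel_size is None:
                xres = tf.pages[0].tags.get("XResolution")
                if xres is None:
                    raise ValueError("TIFF lacks resolution metadata; "
                                     "pass pixel_size explicitly")
                num, den = xres.value
                pixel_size = den / num
            if channels is None:
                try:
                    channels = tf.imagej_metadata["Labels"]
                except (TypeError, KeyError):
                    n = arr.shape[0] if arr.ndim == 3 else 1
                    channels = [f"ch{i}" for i in range(n)]
        if arr.ndim == 2:
            arr = arr[None]
        data = arr.astype(float)
        if arr.dtype == np.uint16:
            data = data / 65535.0
        elif arr.dtype == np.uint8:
            data = data / 255.0
        return cls(data=data, channels=tuple(channels),
                   pixel_size=float(pixel_size))


@dataclass
class StriationSpec:
    """Parameters of a synthetic striated fiber.

    ``channel_phase_offsets`` maps channel name to the band phase as a
    fraction of the period; two channels offset by 0.5 alternate perfectly,
    mimicking myosin IIA bands interleaving with synaptopodin/alpha-actinin
    bands.  All lengths are microns.
    """

    spacing: float
    fiber_polyline: np.ndarray
    band_width: float = 0.3
    channel_phase_offsets: dict = field(
        default_factory=lambda: {"synpo": 0.0, "myosin": 0.5})
    psf_sigma: float = 0.15
    noise_sd: float = 0.02
    pixel_size: float = 0.1
    image_shape: tuple = (140, 140)
    fiber_width: float = 0.8           # lateral FWHM of the fiber ridge
    amplitude: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        self.fiber_polyline = np.asarray(self.fiber_polyline, dtype=float)
        if self.spacing <= 0 or self.pixel_size <= 0:
            raise ValueError("spacing and pixel_size must be positive")
        if self.spacing <= 2.0 * self.pixel_size:
            raise NyquistError(
                f"spacing {self.spacing} um is not resolvable at pixel size "
                f"{self.pixel_size} um (need spacing > 2*pixel_size)")
        if self.psf_sigma < 0 or self.noise_sd < 0 or self.band_width <= 0:
            raise ValueError("psf_sigma/noise_sd >= 0, band_width > 0")
        for ch, phase in self.channel_phase_offsets.items():
            if not (0.0 <= phase < 1.0):
                raise ValueError(f"phase offset of {ch!r} must be in [0,1)")
        if self.fiber_polyline.ndim != 2 or self.fiber_polyline.shape[1] != 2:
            raise ValueError("fiber_polyline must be (n, 2) micron points")
        h, w = self.image_shape
        xmax, ymax = (w - 1) * self.pixel_size, (h - 1) * self.pixel_size
        pl = self.fiber_polyline
        if (pl[:, 0].min() < 0 or pl[:, 1].min() < 0
                or pl[:, 0].max() > xmax or pl[:, 1].max() > ymax):
            raise BoundsError("fiber polyline extends outside the image")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["fiber_polyline"] = self.fiber_polyline.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StriationSpec":
        with open(path) as fh:
            d = json.load(fh)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


def _polyline_arclength(polyline: np.ndarray):
    seg = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    return seg_len, np.concatenate([[0.0], np.cumsum(seg_len)])


def polyline_point_at(polyline: np.ndarray, s) -> np.ndarray:
    """Point(s) at arclength ``s`` along a polyline (microns)."""
    seg_len, cum = _polyline_arclength(polyline)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1,
                      0, len(seg_len) - 1)
    t = (s - cum[seg_idx]) / seg_len[seg_idx]
    pts = polyline[seg_idx] + t[:, None] * (polyline[seg_idx + 1]
                                            - polyline[seg_idx])
    return pts


def generate_striation_image(spec: StriationSpec):
    """Render a striated fiber and return (image, ground_truth).

    Bands are Gaussian bumps along the fiber axis at period ``spacing``,
    with lateral Gaussian falloff across the fiber; the ideal image is
    blurred with the PSF and Gaussian noise is added.  ``ground_truth`` maps
    each channel to a dict with the exact band-center arclengths (um along
    the fiber) and xy coordinates, before blur and noise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    px = spec.pixel_size
    pl = spec.fiber_polyline
    seg_len, cum = _polyline_arclength(pl)
    total_len = cum[-1]
    if total_len <= 0:
        raise ValueError("zero-length polyline")

    # per-pixel arclength s and perpendicular distance d to the polyline
    xs = np.arange(w) * px
    ys = np.arange(h) * px
    X, Y = np.meshgrid(xs, ys)
    P = np.stack([X.ravel(), Y.ravel()], axis=1)
    best_d2 = np.full(len(P), np.inf)
    best_s = np.zeros(len(P))
    for i in range(len(seg_len)):
        a, b = pl[i], pl[i + 1]
        ab = b - a
        t = np.clip((P - a) @ ab / (seg_len[i] ** 2), 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.sum((P - proj) ** 2, axis=1)
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_s[closer] = cum[i] + t[closer] * seg_len[i]

    sigma_band = spec.band_width / _FWHM
    sigma_fiber = spec.fiber_width / _FWHM
    lateral = np.exp(-0.5 * best_d2 / sigma_fiber**2)

    data = np.zeros((len(spec.channel_phase_offsets), h, w))
    ground_truth = {}
    for ci, (ch, phase) in enumerate(spec.channel_phase_offsets.items()):
        centers = np.arange(phase * spec.spacing, total_len + 1e-12,
                            spec.spacing)
        along = np.zeros(len(P))
        for c in centers:
            along += np.exp(-0.5 * (best_s - c) ** 2 / sigma_band**2)
        ideal = spec.amplitude * (along * lateral).reshape(h, w)
        if spec.psf_sigma > 0:
            ideal = ndimage.gaussian_filter(ideal, spec.psf_sigma / px)
        if spec.noise_sd > 0:
            ideal = ideal + rng.normal(0.0, spec.noise_sd, size=ideal.shape)
        data[ci] = np.clip(ideal, 0.0, 1.0)
        ground_truth[ch] = {
            "band_arclengths": centers,
            "band_points": polyline_point_at(pl, centers),
        }

    image = StriationImage(data=data,
                           channels=tuple(spec.channel_phase_offsets),
                           pixel_size=px)
    return image, ground_truth


# ---------------------------------------------------------------------------
# bead fields
# ---------------------------------------------------------------------------

_DEFORMATION_KINDS = ("translation", "rotation", "uniform_stretch",
                      "simple_shear", "radial_contraction", "imported_field")


@dataclass
class DeformationSpec:
    """A closed-form 2D deformation map with exact gradient.

    kinds and parameters:

    * ``translation``: ``tx``, ``ty`` (um)
    * ``rotation``: ``angle_deg`` about ``center`` (default domain center)
    * ``uniform_stretch``: ``lambda_x``, ``lambda_y`` about ``center``
    * ``simple_shear``: ``gamma`` (x' = x + gamma * y)
    * ``radial_contraction``: ``fraction`` alpha about ``center``
      (x' = c + (1 - alpha)(x - c); displacement magnitude = alpha * radius)
    * ``imported_field``: callables ``map_fn(points)`` and ``grad_fn(points)``
      defined on the whole domain

    ``domain`` is (xmin, ymin, xmax, ymax) in microns.
    """

    kind: str
    parameters: dict
    domain: tuple = (0.0, 0.0, 50.0, 50.0)

    def __post_init__(self) -> None:
        if self.kind not in _DEFORMATION_KINDS:
            raise ValueError(f"unknown deformation kind {self.kind!r}")
        if self.kind == "uniform_stretch":
            if (self.parameters.get("lambda_x", 1.0) <= 0
                    or self.parameters.get("lambda_y", 1.0) <= 0):
                raise ValueError("stretch factors must be positive")
        if self.kind == "imported_field":
            if not (callable(self.parameters.get("map_fn"))
                    and callable(self.parameters.get("grad_fn"))):
                raise ValueError("imported_field needs map_fn and grad_fn")

    def _center(self) -> np.ndarray:
        c = self.parameters.get("center")
        if c is None:
            xmin, ymin, xmax, ymax = self.domain
            c = (0.5 * (xmin + xmax), 0.5 * (ymin + ymax))
        return np.asarray(c, dtype=float)

    def map(self, points: np.ndarray) -> np.ndarray:
        """Deformed positions of reference ``points`` (n, 2)."""
        X = np.asarray(points, dtype=float)
        p = self.parameters
        if self.kind == "translation":
            return X + np.array([p.get("tx", 0.0), p.get("ty", 0.0)])
        if self.kind == "rotation":
            th = np.deg2rad(p.get("angle_deg", 0.0))
            R = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
            c = self._center()
            return (X - c) @ R.T + c
        if self.kind == "uniform_stretch":
            lam = np.array([p.get("lambda_x", 1.0), p.get("lambda_y", 1.0)])
            c = self._center()
            return c + (X - c) * lam
        if self.kind == "simple_shear":
            g = p.get("gamma", 0.0)
            return X + np.column_stack([g * X[:, 1], np.zeros(len(X))])
        if self.kind == "radial_contraction":
            a = p.get("fraction", 0.05)
            c = self._center()
            return c + (1.0 - a) * (X - c)
        return np.asarray(p["map_fn"](X), dtype=float)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        """Exact deformation gradient F at ``points``; shape (n, 2, 2)."""
        X = np.asarray(points, dtype=float)
        n = len(X)
        p = self.parameters
        if self.kind == "translation":
            F = np.eye(2)
        elif self.kind == "rotation":
            th = np.deg2rad(p.get("angle_deg", 0.0))
            F = np.array([[np.cos(th), -np.sin(th)],
                          [np.sin(th), np.cos(th)]])
        elif self.kind == "uniform_stretch":
            F = np.diag([p.get("lambda_x", 1.0), p.get("lambda_y", 1.0)])
        elif self.kind == "simple_shear":
            F = np.array([[1.0, p.get("gamma", 0.0)], [0.0, 1.0]])
        elif self.kind == "radial_contraction":
            F = (1.0 - p.get("fraction", 0.05)) * np.eye(2)
        else:
            return np.asarray(p["grad_fn"](X), dtype=float)
        return np.broadcast_to(F, (n, 2, 2)).copy()


class InsufficientSamplingError(ValueError):
    """Too few beads to support any strain reconstruction."""


def generate_bead_field(deformation: DeformationSpec,
                        density: float = 0.05,
                        seed: int = 0,
                        n_beads: int | None = None,
                        localization_sd: float = 0.0) -> BeadField:
    """Uniform bead cloud displaced by a known deformation map.

    ``density`` is beads per square micron (the default emulates a dilute
    microbead loading); ``n_beads`` overrides the density-derived count.
    Gaussian localization noise of standard deviation ``localization_sd``
    (um) is added independently to reference and deformed positions; the
    stored ground-truth ``F_true`` is the exact map gradient at the
    noise-free reference positions.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    xmin, ymin, xmax, ymax = deformation.domain
    area = (xmax - xmin) * (ymax - ymin)
    n = int(round(density * area)) if n_beads is None else int(n_beads)
    if n < 4:
        raise InsufficientSamplingError(
            f"expected bead count {n} < 4: increase density or domain")
    rng = np.random.default_rng(seed)
    ref = np.column_stack([rng.uniform(xmin, xmax, n),
                           rng.uniform(ymin, ymax, n)])
    deformed = deformation.map(ref)
    F_true = deformation.gradient(ref)
    if localization_sd > 0:
        ref = ref + rng.normal(0.0, localization_sd, ref.shape)
        deformed = deformed + rng.normal(0.0, localization_sd, deformed.shape)
    return BeadField(ref_positions=ref, def_positions=deformed,
                     match_indices=np.column_stack([np.arange(n)] * 2),
                     localization_sd=localization_sd, F_true=F_true)


# ---------------------------------------------------------------------------
# phenotype populations
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeSpec:
    """Multinomial cell-population draw over the four SLS categories."""

    probabilities: tuple
    n_cells: int
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(p) != len(PHENOTYPE_CATEGORIES):
            raise ValueError(f"need {len(PHENOTYPE_CATEGORIES)} probabilities")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        self.probabilities = tuple(p)


def generate_phenotype_population(spec: PhenotypeSpec) -> list:
    """Reproducible multinomial draw of phenotype category labels.

    The default study condition has most re-seeded podocytes containing
    SLSs (any-SLS fraction above 70%).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_cells == 0:
        return []
    idx = rng.choice(len(PHENOTYPE_CATEGORIES), size=spec.n_cells,
                     p=np.asarray(spec.probabilities))
    return [PHENOTYPE_CATEGORIES[i] for i in idx]
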