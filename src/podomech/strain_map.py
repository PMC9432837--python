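"""Finite-strain mapping from embedded microbead displacements.

Fluorescent microbeads embedded in a hydrogel move with the gel when an
adherent cell contracts or relaxes (drug treatment, lysis).  From matched
bead positions in a reference and a deformed frame this module reconstructs
the in-plane deformation gradient F on a grid by windowed weighted affine
fits, converts it to the Green-Lagrange strain E = 1/2(F^T F - I), and
reports the first principal strain e1 (largest eigenvalue of E) in the
adhesion plane.

The analysis is purely two-dimensional (the adhesion plane); out-of-plane
bead motion is ignored.  Grids are Lagrangian: strain is evaluated at
reference-frame coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class EmptyFieldError(ValueError):
    """No bead pairs could be matched."""


class CoverageError(ValueError):
    """No grid point had enough beads for a deformation-gradient fit."""


class InvertedElementError(ValueError):
    """Deformation gradient with non-positive determinant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BeadField:
    """Matched bead positions before/after deformation (microns).

    ``ref_positions[i]`` and ``def_positions[i]`` are a matched pair; the
    original indices of the pair in the unmatched input clouds are kept in
    ``match_indices`` (shape (n, 2): reference index, deformed index).
    ``F_true`` optionally stores the ground-truth per-bead deformation
    gradient when the field was produced by the synthetic generator.
    """

    ref_positions: np.ndarray
    def_positions: np.ndarray
    match_indices: np.ndarray | None = None
    localization_sd: float = 0.0
    F_true: np.ndarray | None = None
    unmatched_ref: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    unmatched_def: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        self.ref_positions = np.asarray(self.ref_positions, dtype=float)
        self.def_positions = np.asarray(self.def_positions, dtype=float)
        if self.ref_positions.shape != self.def_positions.shape:
            raise ValueError("ref and def positions must have matching shapes")
        if not (np.isfinite(self.ref_positions).all()
                and np.isfinite(self.def_positions).all()):
            raise ValueError("bead positions must be finite")

    @property
    def n_beads(self) -> int:
        return len(self.ref_positions)

    @property
    def displacements(self) -> np.ndarray:
        return self.def_positions - self.ref_positions

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "x_ref": self.ref_positions[:, 0],
            "y_ref": self.ref_positions[:, 1],
            "x_def": self.def_positions[:, 0],
            "y_def": self.def_positions[:, 1],
        })
        if self.F_true is not None:
            for (i, j), name in zip(
                    [(0, 0), (0, 1), (1, 0), (1, 1)],
                    ["F11_true", "F12_true", "F21_true", "F22_true"]):
                df[name] = self.F_true[:, i, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BeadField":
        df = pd.read_csv(path)
        F_true = None
        if "F11_true" in df.columns:
            F_true = np.stack([
                np.stack([df["F11_true"], df["F12_true"]], axis=-1),
                np.stack([df["F21_true"], df["F22_true"]], axis=-1),
            ], axis=1)
        return cls(
            ref_positions=df[["x_ref", "y_ref"]].to_numpy(),
            def_positions=df[["x_def", "y_def"]].to_numpy(),
            F_true=F_true,
        )


@dataclass
class StrainField:
    """Deformation-gradient and Green-Lagrange strain evaluated on a grid.

    Grid points where the local fit was impossible (too few or collinear
    beads) carry NaN in ``F``/``E``/``e1`` and ``defined`` False.
    """

    grid_points: np.ndarray            # (m, 2) reference-frame microns
    F: np.ndarray                      # (m, 2, 2)
    support_count: np.ndarray          # beads used per point
    E: np.ndarray | None = None        # (m, 2, 2)
    e1: np.ndarray | None = None       # (m,)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.F).all(axis=(1, 2))

    def compute_strain(self) -> "StrainField":
        """Fill E and e1 from F (in place); undefined points stay NaN."""
        m = len(self.grid_points)
        self.E = np.full((m, 2, 2), np.nan)
        self.e1 = np.full(m, np.nan)
        ok = self.defined
        if ok.any():
            self.E[ok] = green_lagrange(self.F[ok])
            self.e1[ok] = principal_strain(self.E[ok])[0]
        return self

    def to_dataframe(self) -> pd.DataFrame:
        if self.E is None:
            self.compute_strain()
        return pd.DataFrame({
            "x": self.grid_points[:, 0],
            "y": self.grid_points[:, 1],
            "F11": self.F[:, 0, 0], "F12": self.F[:, 0, 1],
            "F21": self.F[:, 1, 0], "F22": self.F[:, 1, 1],
            "E11": self.E[:, 0, 0], "E12": self.E[:, 0, 1],
            "E22": self.E[:, 1, 1],
            "e1": self.e1,
            "support_count": self.support_count,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bead matching
# ---------------------------------------------------------------------------

def match_beads(ref: np.ndarray, deformed: np.ndarray,
                max_disp: float) -> BeadField:
    """Pair beads between frames by mutual nearest neighbours.

    A reference bead and a deformed bead are paired iff each is the other's
    nearest neighbour and their distance is at most ``max_disp`` (microns).
    Mutuality guarantees no bead appears in two pairs; ambiguous beads are
    simply left unmatched and reported.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    ref = np.asarray(ref, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if len(ref) == 0 or len(deformed) == 0:
        raise EmptyFieldError("empty bead cloud")

    d_rd, nn_rd = cKDTree(deformed).query(ref, distance_upper_bound=max_disp)
    d_dr, nn_dr = cKDTree(ref).query(deformed, distance_upper_bound=max_disp)

    pairs = []
    for i, j in enumerate(nn_rd):
        if j < len(deformed) and nn_dr[j] == i:
            pairs.append((i, j))
    if not pairs:
        raise EmptyFieldError(
            f"no mutual-nearest-neighbour pairs within {max_disp} um")
    idx = np.asarray(pairs, dtype=int)
    matched_ref = set(idx[:, 0].tolist())
    matched_def = set(idx[:, 1].tolist())
    return BeadField(
        ref_positions=ref[idx[:, 0]],
        def_positions=deformed[idx[:, 1]],
        match_indices=idx,
        unmatched_ref=np.array(sorted(set(range(len(ref))) - matched_ref)),
        unmatched_def=np.array(sorted(set(range(len(deformed))) - matched_def)),
    )


# ---------------------------------------------------------------------------
# deformation-gradient fitting
# ---------------------------------------------------------------------------

def make_grid(bounds, spacing: float) -> np.ndarray:
    """Regular reference-frame grid over ``bounds`` = (xmin, ymin, xmax, ymax)."""
    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin, xmax + 0.5 * spacing, spacing)
    ys = np.arange(ymin, ymax + 0.5 * spacing, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def fit_deformation_gradient(bead_field: BeadField, grid: np.ndarray,
                             window_radius: float,
                             min_neighbors: int = 4,
                             weight_sigma: float | None = None,
                             cond_tol: float = 1e-8) -> StrainField:
    """Local affine fits x_def ~ F x_ref + t on a grid of reference points.

    At each grid point the beads within ``window_radius`` are fit by weighted
    least squares with isotropic Gaussian weights (sigma = window_radius / 2
    unless overridden).  The fit is exact on globally affine bead fields.
    Points with fewer than ``min_neighbors`` beads, or whose neighbours are
    (numerically) collinear, are flagged undefined (NaN).
    """
    if window_radius <= 0:
        raise ValueError("window_radius must be positive")
    if weight_sigma is None:
        weight_sigma = window_radius / 2.0
    grid = np.asarray(grid, dtype=float)
    m = len(grid)
    F = np.full((m, 2, 2), np.nan)
    support = np.zeros(m, dtype=int)

    tree = cKDTree(bead_field.ref_positions)
    neighbor_lists = tree.query_ball_point(grid, window_radius)
    X_all = bead_field.ref_positions
    x_all = bead_field.def_positions

    for k, nbrs in enumerate(neighbor_lists):
        support[k] = len(nbrs)
        if len(nbrs) < max(min_neighbors, 3):
            continue
        X = X_all[nbrs]
        x = x_all[nbrs]
        d2 = np.sum((X - grid[k]) ** 2, axis=1)
        w = np.exp(-0.5 * d2 / weight_sigma**2)
        # collinearity: weighted covariance of reference positions must be
        # rank 2, otherwise F is not identifiable
        Xc = X - np.average(X, axis=0, weights=w)
        cov = (w[:, None] * Xc).T @ Xc / w.sum()
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals[0] <= cond_tol * max(eigvals[1], 1e-300):
            continue
        A = np.column_stack([X, np.ones(len(X))])
        Aw = A * w[:, None]
        coef = np.linalg.solve(A.T @ Aw, A.T @ (x * w[:, None]))
        F[k] = coef[:2].T

    if not np.isfinite(F).all(axis=(1, 2)).any():
        raise CoverageError("no grid point had sufficient bead coverage")
    return StrainField(grid_points=grid, F=F, support_count=support)


# ---------------------------------------------------------------------------
# strain kernels
# ---------------------------------------------------------------------------

def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = 1/2 (F^T F - I); batched over leading axes.

    Rigid rotations map to exactly zero strain (objectivity).  A deformation
    gradient with det F <= 0 describes local inversion and is rejected.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (2, 2):
        raise ValueError("F must be (..., 2, 2)")
    det = np.linalg.det(F)
    if np.any(det <= 0):
        raise InvertedElementError("det F <= 0: locally inverted deformation")
    Ft = np.swapaxes(F, -1, -2)
    return 0.5 * (Ft @ F - np.eye(2))


def principal_strain(E: np.ndarray, sym_tol: float = 1e-8):
    """Principal strains of symmetric E: returns (e1, e2, direction of e1).

    e1 >= e2 are the eigenvalues; the direction is the unit eigenvector of
    e1 (sign fixed so the larger-magnitude component is positive).
    Batched over leading axes.
    """
    E = np.asarray(E, dtype=float)
    if E.shape[-2:] != (2, 2):
        raise ValueError("E must be (..., 2, 2)")
    asym = np.abs(E[..., 0, 1] - E[..., 1, 0])
    if np.any(asym > sym_tol):
        raise ValueError(f"E not symmetric within {sym_tol}")
    Es = 0.5 * (E + np.swapaxes(E, -1, -2))
    vals, vecs = np.linalg.eigh(Es)          # ascending
    e1 = vals[..., 1]
    e2 = vals[..., 0]
    direction = vecs[..., :, 1]
    # canonical sign: dominant component nonnegative
    dom = np.where(np.abs(direction[..., 0]) >= np.abs(direction[..., 1]),
                   direction[..., 0], direction[..., 1])
    direction = direction * np.where(dom < 0, -1.0, 1.0)[..., None]
    return e1, e2, direction


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def strain_pipeline(ref: np.ndarray = None, deformed: np.ndarray = None,
                    grid_spacing: float = 2.0,
                    bounds=None,
                    max_disp: float = 2.0,
                    window_radius: float = 5.0,
                    min_neighbors: int = 4,
                    mask=None,
                    bead_field: BeadField | None = None):
    """Match beads, fit F on a Lagrangian grid, and summarise e1.

    Either raw ``ref``/``deformed`` clouds (matched here by mutual nearest
    neighbours within ``max_disp``) or an already-matched ``bead_field``
    (e.g. from the synthetic generator, or from a dedicated tracker when
    displacements are large compared to the bead spacing) may be supplied.
    ``mask`` may be a boolean array over grid points or a callable
    ``mask(points) -> bool array`` selecting e.g. the under-cell region for
    the summary statistics.  Returns ``(StrainField, summary dict)`` where
    the summary reports mean/max/min of the first principal Green-Lagrange
    strain over defined (and masked) grid points.
    """
    if bead_field is not None:
        field = bead_field
    else:
        if ref is None or deformed is None:
            raise ValueError("need ref and deformed clouds, or a bead_field")
        field = match_beads(ref, deformed, max_disp=max_disp)
    if bounds is None:
        lo = field.ref_positions.min(axis=0)
        hi = field.ref_positions.max(axis=0)
        bounds = (lo[0], lo[1], hi[0], hi[1])
    grid = make_grid(bounds, grid_spacing)
    strain = fit_deformation_gradient(field, grid, window_radius,
                                      min_neighbors=min_neighbors)
    strain.compute_strain()

    sel = strain.defined
    if mask is not None:
        mask_arr = mask(grid) if callable(mask) else np.asarray(mask, bool)
        sel = sel & mask_arr
    e1 = strain.e1[sel]
    summary = {
        "n_matched_beads": field.n_beads,
        "n_grid_points": len(grid),
        "n_defined": int(strain.defined.sum()),
        "n_summarised": int(sel.sum()),
        "mean_e1": float(np.mean(e1)) if len(e1) else float("nan"),
        "max_e1": float(np.max(e1)) if len(e1) else float("nan"),
        "min_e1": float(np.min(e1)) if len(e1) else float("nan"),
    }
    return strain, summary
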