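"""Band classification and unwrapping of peptide-mass decimal residuals.

Plotting tryptic peptide masses against their decimal residuals (the fractional
part of the monoisotopic mass) produces parallel diagonal stripes: the residual
grows roughly linearly with mass and wraps past 1 about every 1/b Da, where b is
the half-decimal-place-rule slope (~5.1e-4 for unlabeled peptides). To fit a
single zero-intercept line, each point's residual must be "unwrapped" by adding
the integer number of Daltons its band has already wrapped.

Bands overlap in mass, so a direct mass threshold cannot separate them. Instead
each mass is transformed as

    P_trans = P_M - c * D_R        (c = 1800 Da by default)

which collapses every band into a narrow, near-vertical cluster: points with
small residuals barely move, points with residuals near 1 shift down by ~c. The
clusters are then separated by one-dimensional k-means seeded at preset centers
(0/2000/4000 Da for unlabeled data, 0/1600/3200/4800 Da for fully labeled data
over the 300-6000 Da window), bands are ranked by final center, and the band
index is added to each residual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Preset 1-D k-means centers (Da, transformed scale) for the 300-6000 Da window.
LIGHT_CENTERS: tuple[float, ...] = (0.0, 2000.0, 4000.0)
HEAVY_CENTERS: tuple[float, ...] = (0.0, 1600.0, 3200.0, 4800.0)

DEFAULT_TRANSFORM_CONSTANT = 1800.0


class EmptyClusterError(RuntimeError):
    """A k-means cluster lost all of its points."""


class MassPoint(NamedTuple):
    """One mass with its residual, transformed mass, band and unwrapped residual."""

    P_M: float
    D_R: float
    P_M_trans: float
    band: int
    D_R_unwrapped: float


@dataclass(frozen=True)
class BandConfig:
    """Parameters of the transform + k-means banding step."""

    transform_constant: float = DEFAULT_TRANSFORM_CONSTANT
    centers: tuple[float, ...] = LIGHT_CENTERS
    add_dummy_points: bool = True

    def __post_init__(self) -> None:
        if self.transform_constant <= 0:
            raise ValueError("transform_constant must be positive")
        if len(self.centers) < 1 or np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be a strictly increasing sequence")


def decimal_residual(mass):
    """Fractional part of a (positive) mass: digits behind the decimal point."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("masses must be positive")
    out = mass - np.floor(mass)
    return float(out) if out.ndim == 0 else out


def transform_mass(P_M, D_R, transform_constant: float = DEFAULT_TRANSFORM_CONSTANT):
    """P_trans = P_M - c*D_R; residuals near 0 are fixed points, near 1 shift by ~c."""
    P_M = np.asarray(P_M, dtype=float)
    D_R = np.asarray(D_R, dtype=float)
    if np.any(D_R < 0) or np.any(D_R >= 1):
        raise ValueError("decimal residuals must lie in [0, 1)")
    out = P_M - transform_constant * D_R
    return float(out) if out.ndim == 0 else out


def centers_from_slope(b_guess: float, max_mass: float) -> tuple[float, ...]:
    """Preset centers derived from a slope guess: one per expected band, at k/b.

    Band k holds masses in [k/b, (k+1)/b); on the transformed scale it sits near
    k/b. The number of bands is the number of residual wraps up to max_mass.
    """
    if b_guess <= 0:
        raise ValueError("slope guess must be positive")
    n_bands = math.floor(max_mass * b_guess) + 1
    return tuple(k / b_guess for k in range(n_bands))


def _kmeans_1d(
    values: np.ndarray,
    centers: Sequence[float],
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd k-means on a 1-D array, seeded exactly at ``centers`` (single init).

    Ties in nearest-center assignment break toward the lower-index center.
    Raises EmptyClusterError if any cluster ends up with no points.
    """
    centers = np.asarray(centers, dtype=float)
    labels = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        # argmin returns the first (lowest-index) center on ties
        dist = np.abs(values[:, None] - centers[None, :])
        new_labels = np.argmin(dist, axis=1)
        counts = np.bincount(new_labels, minlength=len(centers))
        if np.any(counts == 0):
            raise EmptyClusterError(
                f"cluster(s) {np.flatnonzero(counts == 0).tolist()} are empty"
            )
        new_centers = np.bincount(new_labels, weights=values, minlength=len(centers)) / counts
        if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
            break
        labels, centers = new_labels, new_centers
    return labels, centers


def classify_bands(masses, config: BandConfig = BandConfig()) -> np.ndarray:
    """Assign a band index to each mass via the transform + preset-center k-means.

    If ``config.add_dummy_points`` is set, one synthetic point is appended at
    each exact center before clustering and removed afterwards, so that small
    datasets cannot leave a cluster empty. Without dummy points an empty
    cluster triggers a warning and a retry with dummy points. Band indices are
    relabeled in increasing order of the final cluster centers, counting from 0.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size < 1:
        raise ValueError("at least one mass is required")
    residuals = decimal_residual(masses)
    transformed = transform_mass(masses, residuals, config.transform_constant)

    values = transformed
    n_real = len(values)
    if config.add_dummy_points:
        values = np.concatenate([values, np.asarray(config.centers, dtype=float)])
    try:
        labels, final_centers = _kmeans_1d(values, config.centers)
    except EmptyClusterError:
        if config.add_dummy_points:
            raise
        logger.warning("empty k-means cluster; retrying with dummy points")
        values = np.concatenate([values, np.asarray(config.centers, dtype=float)])
        labels, final_centers = _kmeans_1d(values, config.centers)
    labels = labels[:n_real]
    # rank clusters by their final center so band index = integer Daltons wrapped
    order = np.argsort(final_centers, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return rank[labels]


def unwrap_residuals(residuals, bands) -> np.ndarray:
    """Add each point's integer band index (in Da) to its decimal residual."""
    residuals = np.asarray(residuals, dtype=float)
    bands = np.asarray(bands)
    if np.any(bands < 0):
        raise ValueError("band indices must be non-negative")
    return residuals + bands


def band_table(masses, config: BandConfig = BandConfig()) -> pd.DataFrame:
    """Tabulate mass, residual, transformed mass, band and unwrapped residual."""
    masses = np.asarray(masses, dtype=float)
    residuals = decimal_residual(masses)
    transformed = transform_mass(masses, residuals, config.transform_constant)
    bands = classify_bands(masses, config)
    return pd.DataFrame(
        {
            "mass": masses,
            "residual": residuals,
            "transformed_mass": transformed,
            "band": bands,
            "unwrapped_residual": unwrap_residuals(residuals, bands),
        }
    )


def mass_points(masses, config: BandConfig = BandConfig()) -> list[MassPoint]:
    tab = band_table(masses, config)
    return [MassPoint(*row) for row in tab.itertuples(index=False)]


class BandUnwrapper(TransformerMixin, BaseEstimator):
    """Transformer mapping masses to (mass, unwrapped decimal residual) pairs.

    Parameters
    ----------
    transform_constant : float, default 1800
        Constant c of the banding transform P_trans = P_M - c*D_R.
    centers : sequence of float or None
        Preset k-means centers on the transformed scale. If None, centers are
        derived from ``slope_guess`` and the data's maximum mass.
    slope_guess : float or None
        Approximate residual-per-Da slope used to derive centers when
        ``centers`` is None. Required in that case.
    add_dummy_points : bool, default True
        Append one synthetic point per center before clustering (small-set
        safeguard); removed before any downstream computation.
    """

    def __init__(
        self,
        transform_constant: float = DEFAULT_TRANSFORM_CONSTANT,
        centers=None,
        slope_guess=None,
        add_dummy_points: bool = True,
    ):
        self.transform_constant = transform_constant
        self.centers = centers
        self.slope_guess = slope_guess
        self.add_dummy_points = add_dummy_points

    def _config(self, masses: np.ndarray) -> BandConfig:
        if self.centers is not None:
            centers = tuple(self.centers)
        elif self.slope_guess is not None:
            centers = centers_from_slope(self.slope_guess, float(masses.max()))
        else:
            raise ValueError("either centers or slope_guess must be given")
        return BandConfig(
            transform_constant=self.transform_constant,
            centers=centers,
            add_dummy_points=self.add_dummy_points,
        )

    @staticmethod
    def _as_masses(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected a 1-D mass array or an (n, 1) column")
        return X

    def fit(self, X, y=None):
        masses = self._as_masses(X)
        config = self._config(masses)
        self.bands_ = classify_bands(masses, config)
        self.residuals_ = decimal_residual(masses)
        self.unwrapped_ = unwrap_residuals(self.residuals_, self.bands_)
        self.centers_ = config.centers
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        masses = self._as_masses(X)
        config = self._config(masses)
        bands = classify_bands(masses, config)
        unwrapped = unwrap_residuals(decimal_residual(masses), bands)
        return np.column_stack([masses, unwrapped])
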