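"""Reference calibration and conversion of fitted slopes to atom % 13C.

Calibration digests a proteome in silico, computes every peptide's mass at
0 and at 100 atom % 13C, bands and unwraps both mass sets, and fits the two
zero-intercept slopes b_12C and b_13C. A user mass list is then banded, fit
robustly, and its slope b_user linearly interpolated between the anchors:

    atom % 13C = (b_user - b_12C) / (b_13C - b_12C) * 100

The standard error of the estimate is the slope standard error scaled by the
same calibration span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator

from . import chem
from .bands import (
    BandConfig,
    HEAVY_CENTERS,
    LIGHT_CENTERS,
    DEFAULT_TRANSFORM_CONSTANT,
    classify_bands,
    decimal_residual,
    unwrap_residuals,
)
from .chem import PeptideRecord, build_reference_peptides
from .fitting import SlopeFit, fit_slope_ols, fit_slope_robust

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """The reference slopes came out unusable (b_13C <= b_12C)."""


@dataclass(frozen=True)
class ReferenceModel:
    """Calibration pair (b_12C, b_13C) with its provenance.

    ``b_12C``/``b_13C`` are the exact least-squares reference slopes (the
    reporting convention). ``b_12C_robust``/``b_13C_robust`` are the same
    anchors fitted with the identical robust (IWLS) procedure applied to user
    data; interpolating a robust user slope between robust anchors keeps the
    calibration estimator-consistent, so the reference's own mass sets map back
    to exactly 0 and 100 atom %. They default to the least-squares slopes when
    not provided. Slopes are stored at full precision; use :meth:`rounded` for
    the 6-digit reporting convention.
    """

    b_12C: float
    b_13C: float
    n_peptides: int
    source: str = "unknown"
    filters: dict = field(default_factory=dict)
    transform_constant: float = DEFAULT_TRANSFORM_CONSTANT
    light_centers: tuple[float, ...] = LIGHT_CENTERS
    heavy_centers: tuple[float, ...] = HEAVY_CENTERS
    b_12C_robust: float | None = None
    b_13C_robust: float | None = None

    def __post_init__(self) -> None:
        if not (self.b_13C > self.b_12C > 0):
            raise CalibrationError(
                f"reference slopes must satisfy b_13C > b_12C > 0, got "
                f"b_12C={self.b_12C!r}, b_13C={self.b_13C!r}"
            )
        if not (self.anchor_13C > self.anchor_12C > 0):
            raise CalibrationError("robust anchors must satisfy b_13C > b_12C > 0")

    @property
    def anchor_12C(self) -> float:
        """0 atom % anchor used by the estimation path."""
        return self.b_12C if self.b_12C_robust is None else self.b_12C_robust

    @property
    def anchor_13C(self) -> float:
        """100 atom % anchor used by the estimation path."""
        return self.b_13C if self.b_13C_robust is None else self.b_13C_robust

    @property
    def span(self) -> float:
        return self.b_13C - self.b_12C

    @property
    def anchor_span(self) -> float:
        return self.anchor_13C - self.anchor_12C

    def rounded(self, digits: int = 6) -> "ReferenceModel":
        return replace(
            self,
            b_12C=float(f"{self.b_12C:.{digits}g}"),
            b_13C=float(f"{self.b_13C:.{digits}g}"),
        )


@dataclass(frozen=True)
class IncorporationEstimate:
    """Atom % 13C estimate for one mass list."""

    atom_percent: float
    se: float
    slope_fit: SlopeFit
    n_masses: int
    out_of_range: bool
    centers_used: tuple[float, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = " (out of calibration range)" if self.out_of_range else ""
        return (
            f"{self.atom_percent:.2f} +/- {self.se:.2f} atom % 13C "
            f"(n={self.n_masses}, b_user={self.slope_fit.b:.6e}){flag}"
        )


def incorporation_from_slope(
    b_user: float, reference: ReferenceModel, se_b: float = 0.0
) -> tuple[float, float]:
    """Linear interpolation of a slope between the least-squares anchors:

    atom % = (b_user - b_12C) / (b_13C - b_12C) * 100.
    """
    atom_percent = (b_user - reference.b_12C) / reference.span * 100.0
    se = se_b / reference.span * 100.0
    return atom_percent, se


def calibrate_from_peptides(
    peptides: list[PeptideRecord],
    transform_constant: float = DEFAULT_TRANSFORM_CONSTANT,
    light_centers: tuple[float, ...] = LIGHT_CENTERS,
    heavy_centers: tuple[float, ...] = HEAVY_CENTERS,
    source: str = "unknown",
    filters: dict | None = None,
    loss: str = "huber",
) -> ReferenceModel:
    """Fit the 0 % and 100 % reference slopes from an already-digested peptide set.

    Both mass sets are banded once; each unwrapped cloud is fit twice — by
    exact least squares (the reported reference slopes) and by the same robust
    IWLS used for user data (the estimation anchors).
    """
    if not peptides:
        raise chem.EmptyReferenceError("no reference peptides")
    slopes = {}
    for tag, masses, centers in (
        ("light", np.array([p.mass_light for p in peptides]), light_centers),
        ("heavy", np.array([p.mass_at(100.0) for p in peptides]), heavy_centers),
    ):
        config = BandConfig(transform_constant, tuple(centers), add_dummy_points=True)
        bands = classify_bands(masses, config)
        unwrapped = unwrap_residuals(decimal_residual(masses), bands)
        slopes[tag] = (
            fit_slope_ols(masses, unwrapped),
            fit_slope_robust(masses, unwrapped, loss=loss),
        )
    logger.info(
        "calibration: b_12C=%.6e, b_13C=%.6e on %d peptide entries",
        slopes["light"][0].b,
        slopes["heavy"][0].b,
        len(peptides),
    )
    return ReferenceModel(
        b_12C=slopes["light"][0].b,
        b_13C=slopes["heavy"][0].b,
        n_peptides=len(peptides),
        source=source,
        filters=dict(filters or {}),
        transform_constant=transform_constant,
        light_centers=tuple(light_centers),
        heavy_centers=tuple(heavy_centers),
        b_12C_robust=slopes["light"][1].b,
        b_13C_robust=slopes["heavy"][1].b,
    )


def calibrate(
    fasta,
    mz_min: float = 300.0,
    mz_max: float = 6000.0,
    len_min: int = 2,
    len_max: int = 40,
    transform_constant: float = DEFAULT_TRANSFORM_CONSTANT,
    light_centers: tuple[float, ...] = LIGHT_CENTERS,
    heavy_centers: tuple[float, ...] = HEAVY_CENTERS,
    source: str | None = None,
) -> ReferenceModel:
    """End-to-end calibration: FASTA -> digest -> filter -> band -> slopes."""
    filters = {"mz_min": mz_min, "mz_max": mz_max, "len_min": len_min, "len_max": len_max}
    peptides = build_reference_peptides(fasta, mz_min, mz_max, len_min, len_max)
    if source is None:
        source = str(fasta) if isinstance(fasta, (str,)) else "in-memory records"
    return calibrate_from_peptides(
        peptides,
        transform_constant=transform_constant,
        light_centers=light_centers,
        heavy_centers=heavy_centers,
        source=source,
        filters=filters,
    )


def estimate_incorporation(
    masses,
    reference: ReferenceModel,
    band_config: BandConfig | None = None,
    loss: str = "huber",
    max_iterations: int = 50,
    convergence_tol: float = 1e-8,
) -> IncorporationEstimate:
    """Estimate atom % 13C for a user mass list against a calibrated reference.

    Bands are classified with dummy points (small-set safeguard). Unless a
    ``band_config`` pins the centers, both reference center sets are tried and
    the unwrap with the lower zero-intercept OLS SSE is kept — partially
    labeled data wraps at an intermediate period, and the trial picks the
    center set that matches it better. The kept unwrap is then fit robustly.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size < 3:
        raise ValueError(
            "at least 3 masses are required for a robust estimate; "
            "collect more peptide masses"
        )
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if np.ptp(masses) == 0:
        raise ValueError("degenerate fit: all masses are identical")
    lo, hi = reference.filters.get("mz_min"), reference.filters.get("mz_max")
    if lo is not None and hi is not None:
        outside = int(np.sum((masses < lo) | (masses > hi)))
        if outside:
            logger.warning(
                "%d of %d masses lie outside the reference window [%g, %g]; kept",
                outside,
                masses.size,
                lo,
                hi,
            )

    if band_config is not None:
        candidates = [band_config]
    else:
        candidates = [
            BandConfig(reference.transform_constant, cs, add_dummy_points=True)
            for cs in (reference.light_centers, reference.heavy_centers)
        ]
    best = None
    for config in candidates:
        bands = classify_bands(masses, config)
        unwrapped = unwrap_residuals(decimal_residual(masses), bands)
        trial = fit_slope_ols(masses, unwrapped)
        if best is None or trial.sse < best[0].sse:
            best = (trial, unwrapped, config)
    trial, unwrapped, config = best

    fit = fit_slope_robust(
        masses,
        unwrapped,
        loss=loss,
        max_iterations=max_iterations,
        convergence_tol=convergence_tol,
    )
    # interpolate the robust user slope between anchors fitted with the same
    # robust procedure, so the calibration is estimator-consistent
    atom_percent = (fit.b - reference.anchor_12C) / reference.anchor_span * 100.0
    se = fit.se_b / reference.anchor_span * 100.0
    out_of_range = not (0.0 <= atom_percent <= 100.0)
    if out_of_range:
        logger.debug(
            "estimate %.2f atom %% lies outside [0, 100]; reported unclipped",
            atom_percent,
        )
    return IncorporationEstimate(
        atom_percent=atom_percent,
        se=se,
        slope_fit=fit,
        n_masses=int(masses.size),
        out_of_range=out_of_range,
        centers_used=config.centers,
    )


class IncorporationEstimator(BaseEstimator):
    """Estimator for 13C atom % incorporation from peptide mass lists.

    ``fit`` calibrates the reference slopes from a proteome (FASTA path,
    (id, sequence) pairs, or pre-digested :class:`PeptideRecord` list);
    ``estimate`` / ``predict`` convert a mass list into atom % 13C.

    Parameters mirror the pipeline stages: the digest filters, the banding
    transform constant and preset centers, and the robust-fit settings.

    Attributes
    ----------
    reference_ : ReferenceModel
    b_12C_, b_13C_ : float — calibration slopes at 0 and 100 atom %.
    n_peptides_ : int — reference entry count.
    """

    def __init__(
        self,
        mz_min: float = 300.0,
        mz_max: float = 6000.0,
        len_min: int = 2,
        len_max: int = 40,
        transform_constant: float = DEFAULT_TRANSFORM_CONSTANT,
        light_centers: tuple[float, ...] = LIGHT_CENTERS,
        heavy_centers: tuple[float, ...] = HEAVY_CENTERS,
        loss: str = "huber",
        max_iterations: int = 50,
        convergence_tol: float = 1e-8,
    ):
        self.mz_min = mz_min
        self.mz_max = mz_max
        self.len_min = len_min
        self.len_max = len_max
        self.transform_constant = transform_constant
        self.light_centers = light_centers
        self.heavy_centers = heavy_centers
        self.loss = loss
        self.max_iterations = max_iterations
        self.convergence_tol = convergence_tol

    def fit(self, X, y=None):
        """Calibrate from a proteome or a pre-digested peptide list."""
        if isinstance(X, ReferenceModel):
            self.reference_ = X
        elif (
            isinstance(X, (list, tuple))
            and X
            and isinstance(X[0], PeptideRecord)
        ):
            self.reference_ = calibrate_from_peptides(
                list(X),
                transform_constant=self.transform_constant,
                light_centers=tuple(self.light_centers),
                heavy_centers=tuple(self.heavy_centers),
                source="peptide records",
                filters={
                    "mz_min": self.mz_min,
                    "mz_max": self.mz_max,
                    "len_min": self.len_min,
                    "len_max": self.len_max,
                },
            )
        else:
            self.reference_ = calibrate(
                X,
                mz_min=self.mz_min,
                mz_max=self.mz_max,
                len_min=self.len_min,
                len_max=self.len_max,
                transform_constant=self.transform_constant,
                light_centers=tuple(self.light_centers),
                heavy_centers=tuple(self.heavy_centers),
            )
        self.b_12C_ = self.reference_.b_12C
        self.b_13C_ = self.reference_.b_13C
        self.n_peptides_ = self.reference_.n_peptides
        return self

    def estimate(self, masses) -> IncorporationEstimate:
        """Full estimate (atom %, standard error, fit diagnostics) for one mass list."""
        if not hasattr(self, "reference_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        return estimate_incorporation(
            masses,
            self.reference_,
            loss=self.loss,
            max_iterations=self.max_iterations,
            convergence_tol=self.convergence_tol,
        )

    def predict(self, X) -> float | list[float]:
        """Atom % 13C for one mass list, or one value per list of lists."""
        X = list(X)
        if X and np.ndim(X[0]) > 0:
            return [self.estimate(m).atom_percent for m in X]
        return self.estimate(np.asarray(X, dtype=float)).atom_percent
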