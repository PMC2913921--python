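"""Synthetic tryptic-peptide generation and the accuracy-vs-sample-size experiment.

The generator emulates a no-missed-cleavage tryptic digest of an average
bacterial proteome: residues are drawn from Swiss-Prot background amino-acid
frequencies, peptide length follows the geometric waiting time to the next K/R
(truncated to 2-40 residues), the C-terminal residue is K or R, and internal
positions exclude K/R (an internal K/R not followed by P would have been
cleaved). Peptides are redrawn until the light monoisotopic mass falls in the
reference window. Labeled masses are exact (no instrument noise) unless a
ppm-scale Gaussian error is requested.

The accuracy experiment repeatedly subsamples peptides at known incorporation
levels, runs the full banding + robust-fit + calibration pipeline on each draw,
and summarizes the replicate estimates per (truth, subsample size) cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandConfig, classify_bands
from .chem import (
    C13_MASS_SHIFT,
    ElementCounts,
    PeptideRecord,
    monoisotopic_mass,
    nominal_mass,
    residue_composition,
)
from .fitting import fit_slope_ols
from .incorporation import ReferenceModel, estimate_incorporation

logger = logging.getLogger(__name__)

#: Amino-acid background frequencies (percent) typical of the GC-rich
#: actinobacterial proteome the reference calibration emulates
#: (Ala/Gly/Val/Arg-rich, Lys/Asn-poor).
MTB_AA_FREQUENCIES = {
    "A": 11.4, "G": 9.1, "V": 8.3, "L": 9.5, "R": 6.2,
    "P": 5.8, "T": 5.5, "D": 5.6, "S": 5.8, "E": 5.2,
    "I": 4.2, "Q": 3.2, "N": 2.4, "F": 3.2, "K": 2.2,
    "Y": 2.4, "H": 2.2, "W": 1.6, "M": 1.9, "C": 0.9,
}

#: Swiss-Prot average amino-acid frequencies (percent), for generic proteomes.
SWISSPROT_AA_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

#: Default background used by the generator.
AA_FREQUENCIES = MTB_AA_FREQUENCIES


def generate_synthetic_peptides(
    n: int,
    seed=None,
    length_range: tuple[int, int] = (2, 40),
    mz_range: tuple[float, float] = (300.0, 6000.0),
    length_distribution: str = "uniform",
    frequencies: dict[str, float] | None = None,
    max_redraws: int = 1000,
) -> list[PeptideRecord]:
    """Generate ``n`` tryptic-like peptides passing the length and mass filters.

    Residues are drawn i.i.d. from the background ``frequencies`` (default: the
    reference-proteome table above) with the C-terminal residue forced to K or
    R at their relative background odds. ``length_distribution`` is ``uniform``
    over the length window (emulating a reference peptide set that represents
    all peptide lengths, as a score-filtered in-silico digest does) or
    ``tryptic`` (geometric waiting time to the next K/R, the raw-digest length
    profile). Deterministic for a fixed ``seed``; raises if the constraints
    are infeasible (nothing accepted within ``max_redraws`` consecutive draws).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    len_min, len_max = length_range
    if not 2 <= len_min <= len_max:
        raise ValueError("length_range must satisfy 2 <= min <= max")
    if length_distribution not in ("uniform", "tryptic"):
        raise ValueError("length_distribution must be 'uniform' or 'tryptic'")
    freqs = dict(frequencies or AA_FREQUENCIES)
    letters = list(freqs)
    probs = np.array([freqs[aa] for aa in letters], dtype=float)
    probs /= probs.sum()
    kr_p = np.array([freqs.get("K", 0.0), freqs.get("R", 0.0)])
    if kr_p.sum() <= 0:
        raise ValueError("background frequencies must include K and/or R")
    kr_p = kr_p / kr_p.sum()
    cleave_p = (freqs.get("K", 0.0) + freqs.get("R", 0.0)) / sum(freqs.values())

    rng = np.random.default_rng(seed)
    records: list[PeptideRecord] = []
    rejects = 0
    while len(records) < n:
        if length_distribution == "uniform":
            length = int(rng.integers(len_min, len_max + 1))
        else:
            length = 1 + int(rng.geometric(cleave_p))
            if not len_min <= length <= len_max:
                rejects += 1
                if rejects > max_redraws:
                    raise ValueError("infeasible generator constraints (length window)")
                continue
        body = rng.choice(letters, size=length - 1, p=probs)
        terminal = rng.choice(["K", "R"], p=kr_p)
        seq = "".join(body) + terminal
        elements = residue_composition(seq)
        mass = monoisotopic_mass(elements, 0.0)
        if not mz_range[0] <= mass <= mz_range[1]:
            rejects += 1
            if rejects > max_redraws:
                raise ValueError("infeasible generator constraints (mass window)")
            continue
        rejects = 0
        records.append(PeptideRecord(seq, elements, mass))
    return records


def labeled_masses(
    peptides: list[PeptideRecord],
    incorporation: float,
    mass_error_ppm: float = 0.0,
    rng=None,
    integer_carbons: bool = True,
) -> np.ndarray:
    """Emulated measured masses at a given atom % 13C.

    A deconvoluted isotopologue peak corresponds to an integer number of
    substituted carbons, so by default each peptide carries
    ``k = round(p/100 * C)`` heavy carbons (exact at 0 and 100 atom %); this
    preserves the decimal-residual band structure at intermediate labeling.
    ``integer_carbons=False`` uses the continuous mean shift instead. Optional
    ppm-scale Gaussian noise emulates instrument mass error.
    """
    if not 0.0 <= incorporation <= 100.0:
        raise ValueError("incorporation must be within [0, 100] atom %")
    if integer_carbons:
        masses = np.array(
            [
                p.mass_light
                + np.round(incorporation / 100.0 * p.elements.C) * C13_MASS_SHIFT
                for p in peptides
            ]
        )
    else:
        masses = np.array([p.mass_at(incorporation) for p in peptides])
    if mass_error_ppm > 0.0:
        rng = np.random.default_rng(rng)
        masses = masses * (1.0 + rng.normal(0.0, mass_error_ppm * 1e-6, masses.size))
    return masses


def true_band_offsets(
    peptides: list[PeptideRecord], incorporation: float
) -> tuple[np.ndarray, np.ndarray]:
    """Masses and ground-truth integer band offsets at an incorporation level.

    The exact unwrapped residual of a peptide is its accumulated mass defect,
    mass minus nominal (integer-isotope) mass — known exactly from the element
    counts. The ground-truth offset of a point is the integer k minimizing
    |D_R + k - b_true * P_M|, with b_true the zero-intercept OLS slope on the
    exactly unwrapped cloud. Only defined at 0 and 100 atom %, where the
    nominal mass is an integer.
    """
    if incorporation not in (0.0, 100.0):
        raise ValueError("exact band offsets are defined at 0 and 100 atom % only")
    masses = labeled_masses(peptides, incorporation)
    defect = masses - np.array(
        [nominal_mass(p.elements, incorporation) for p in peptides]
    )
    b_true = fit_slope_ols(masses, defect).b
    residuals = masses - np.floor(masses)
    offsets = np.round(b_true * masses - residuals).astype(int)
    return masses, offsets


def band_misassignment_rate(
    peptides: list[PeptideRecord],
    incorporation: float,
    config: BandConfig,
) -> float:
    """Fraction of points whose classified band differs from the true offset."""
    masses, truth = true_band_offsets(peptides, incorporation)
    assigned = classify_bands(masses, config)
    return float(np.mean(assigned != truth))


@dataclass(frozen=True)
class AccuracyCell:
    """Replicate estimates for one (truth, subsample size) condition."""

    truth: float
    n_peptides: int
    estimates: tuple[float, ...]
    median: float
    q25: float
    q75: float
    envelope: tuple[float, float]  # 2.5th-97.5th percentile of the estimates

    @property
    def error(self) -> float:
        """Half-width of the 95% replicate envelope around the truth."""
        return max(abs(self.envelope[0] - self.truth), abs(self.envelope[1] - self.truth))

    @property
    def bias(self) -> float:
        return self.median - self.truth


def accuracy_experiment(
    reference_peptides: list[PeptideRecord],
    reference: ReferenceModel,
    truths: tuple[float, ...] = (0.0, 50.0, 100.0),
    sizes: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 200, 300, 500, 1000),
    replicates: int = 100,
    seed=None,
    mass_error_ppm: float = 0.0,
) -> list[AccuracyCell]:
    """Estimation accuracy as a function of peptide count at known truths.

    For each (truth, size) cell: draw ``size`` peptides without replacement
    (independently per replicate), compute their exact labeled masses, run the
    full estimation pipeline against ``reference``, and summarize the replicate
    atom % estimates (median, quartiles, 95% envelope).
    """
    rng = np.random.default_rng(seed)
    n_ref = len(reference_peptides)
    cells: list[AccuracyCell] = []
    for truth in truths:
        all_masses = labeled_masses(reference_peptides, truth)
        for size in sizes:
            if size > n_ref:
                logger.warning(
                    "skipping subsample size %d > reference size %d", size, n_ref
                )
                continue
            estimates = []
            for _ in range(replicates):
                idx = rng.choice(n_ref, size=size, replace=False)
                masses = all_masses[idx]
                if mass_error_ppm > 0.0:
                    masses = masses * (
                        1.0 + rng.normal(0.0, mass_error_ppm * 1e-6, masses.size)
                    )
                est = estimate_incorporation(masses, reference)
                estimates.append(est.atom_percent)
            estimates = np.asarray(estimates)
            lo, q25, med, q75, hi = np.percentile(estimates, [2.5, 25, 50, 75, 97.5])
            cells.append(
                AccuracyCell(
                    truth=float(truth),
                    n_peptides=int(size),
                    estimates=tuple(float(e) for e in estimates),
                    median=float(med),
                    q25=float(q25),
                    q75=float(q75),
                    envelope=(float(lo), float(hi)),
                )
            )
            logger.info(
                "truth %.0f%%, n=%d: median %.2f, envelope [%.2f, %.2f]",
                truth,
                size,
                med,
                lo,
                hi,
            )
    return cells


def accuracy_frame(cells: list[AccuracyCell], long: bool = False) -> pd.DataFrame:
    """Tabulate accuracy cells; ``long=True`` yields one row per replicate."""
    if long:
        rows = [
            {"truth": c.truth, "n_peptides": c.n_peptides, "replicate": i, "estimate": e}
            for c in cells
            for i, e in enumerate(c.estimates)
        ]
        return pd.DataFrame(rows)
    return pd.DataFrame(
        {
            "truth": [c.truth for c in cells],
            "n_peptides": [c.n_peptides for c in cells],
            "median": [c.median for c in cells],
            "q25": [c.q25 for c in cells],
            "q75": [c.q75 for c in cells],
            "envelope_lo": [c.envelope[0] for c in cells],
            "envelope_hi": [c.envelope[1] for c in cells],
            "error": [c.error for c in cells],
            "bias": [c.bias for c in cells],
        }
    )
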