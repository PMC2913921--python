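"""File formats: mass lists, reference models, and tab-separated result tables.

Mass lists are plain ASCII, one singly-charged (z = 1, deconvoluted) mass per
line, no header or row names; both point and comma decimal markers are
accepted. Reference models are small key=value text files with slopes stored at
full precision (round-trip exact).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import PeptideRecord
from .incorporation import IncorporationEstimate, ReferenceModel

logger = logging.getLogger(__name__)


def read_mass_list(path) -> list[float]:
    """Read one positive mass per non-blank line; comma decimals normalized."""
    path = Path(path)
    masses: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                value = float(line.replace(",", "."))
            except ValueError:
                raise ValueError(
                    f"{path.name}: unparseable mass at line {lineno}: {line!r}"
                ) from None
            if value <= 0:
                raise ValueError(
                    f"{path.name}: non-positive mass at line {lineno}: {line!r}"
                )
            masses.append(value)
    if not masses:
        raise ValueError(f"{path.name}: no masses found")
    logger.info("read %d masses from %s", len(masses), path)
    return masses


def write_mass_list(masses, path) -> None:
    with open(path, "w") as fh:
        for m in masses:
            fh.write(f"{float(m)!r}\n")


def write_reference_model(reference: ReferenceModel, path) -> None:
    """Serialize a reference model as key=value text (full float precision)."""
    lines = [
        f"b_12C={reference.b_12C!r}",
        f"b_13C={reference.b_13C!r}",
        f"n_peptides={reference.n_peptides}",
        f"source={reference.source}",
        f"transform_constant={reference.transform_constant!r}",
        "light_centers=" + ",".join(repr(c) for c in reference.light_centers),
        "heavy_centers=" + ",".join(repr(c) for c in reference.heavy_centers),
    ]
    if reference.b_12C_robust is not None:
        lines.append(f"b_12C_robust={reference.b_12C_robust!r}")
    if reference.b_13C_robust is not None:
        lines.append(f"b_13C_robust={reference.b_13C_robust!r}")
    for key, value in reference.filters.items():
        lines.append(f"filter.{key}={value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference_model(path) -> ReferenceModel:
    fields: dict = {"filters": {}}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key in ("b_12C", "b_13C", "transform_constant", "b_12C_robust", "b_13C_robust"):
            fields[key] = float(value)
        elif key == "n_peptides":
            fields[key] = int(value)
        elif key == "source":
            fields[key] = value
        elif key in ("light_centers", "heavy_centers"):
            fields[key] = tuple(float(v) for v in value.split(","))
        elif key.startswith("filter."):
            fields["filters"][key[len("filter.") :]] = float(value)
    return ReferenceModel(**fields)


def write_peptide_table(peptides: list[PeptideRecord], path) -> None:
    """Tab-separated reference peptide table (light and fully labeled masses)."""
    frame = pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptides],
            "length": [p.length for p in peptides],
            "n_carbon": [p.elements.C for p in peptides],
            "mass_light": [p.mass_light for p in peptides],
            "mass_heavy": [p.mass_at(100.0) for p in peptides],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_band_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_estimate_report(
    estimate: IncorporationEstimate, reference: ReferenceModel, path, name: str = ""
) -> None:
    fit = estimate.slope_fit
    lines = [
        f"input={name}",
        f"atom_percent_13C={estimate.atom_percent:.4f}",
        f"standard_error={estimate.se:.4f}",
        f"n_masses={estimate.n_masses}",
        f"b_user={fit.b!r}",
        f"se_b_user={fit.se_b!r}",
        f"fit_method={fit.method}",
        f"converged={fit.converged}",
        f"out_of_range={estimate.out_of_range}",
        f"b_12C={reference.b_12C!r}",
        f"b_13C={reference.b_13C!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
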