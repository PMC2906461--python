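"""Absolute quantification of community members from qPCR data.

Covers the chain: DNA mass -> gene copies, dilution-series standard curves,
Cq -> copies interpolation, extraction-volume scaling, and 16S rRNA operon
copy-number normalization down to cells per ml of culture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeciesAssay",
    "StandardCurve",
    "ExtractionProtocol",
    "DEFAULT_ASSAYS",
    "AVOGADRO",
    "copies_from_dna_mass",
    "fit_standard_curve",
    "copies_per_ml_culture",
    "cells_per_ml",
    "cells_from_copy_density",
    "quantify_plate",
    "community_composition",
    "Composition",
]

AVOGADRO = 6.02214076e23
#: Average molar mass of one double-stranded base pair, g/mol/bp.  650 is the
#: other dialect seen in practice; configurable everywhere it is used.
MASS_PER_BP = 660.0


@dataclass(frozen=True)
class SpeciesAssay:
    """Per-species qPCR assay metadata.

    Genome sizes default to public genome-record values and should be
    overridden from configuration when better numbers are available; outputs
    derived from defaults carry a provenance note.
    """

    species: str
    rrn_copies_per_genome: int
    genome_size_bp: float
    primer_forward: str = ""
    primer_reverse: str = ""
    genome_size_is_default: bool = False

    def __post_init__(self):
        if self.rrn_copies_per_genome < 1:
            raise ValueError("rrn_copies_per_genome must be >= 1")
        if self.genome_size_bp <= 1e5:
            raise ValueError("genome_size_bp implausibly small (<= 1e5 bp)")


DEFAULT_ASSAYS: dict[str, SpeciesAssay] = {
    a.species: a
    for a in [
        SpeciesAssay(
            "C. cellulolyticum", 8, 4_068_724,
            primer_forward="GATGGATACTAGGTGTAG", primer_reverse="TTCCTTTGAGTTTCAACC",
            genome_size_is_default=True,
        ),
        SpeciesAssay(
            "D. vulgaris", 5, 3_570_858,
            primer_forward="GCGTTAAGCATCCCGCCT", primer_reverse="CATCGAATTAAACCACAT",
            genome_size_is_default=True,
        ),
        SpeciesAssay(
            "G. sulfurreducens", 2, 3_814_128,
            primer_forward="AGACTTGAGTACGGGAGA", primer_reverse="TAGCCGCCTTCGCCACCG",
            genome_size_is_default=True,
        ),
    ]
}


@dataclass(frozen=True)
class ExtractionProtocol:
    """Volumes linking one qPCR reaction back to the sampled culture."""

    culture_volume_ml: float = 10.0
    elution_volume_ul: float = 100.0
    template_volume_ul: float = 0.5

    def __post_init__(self):
        if min(self.culture_volume_ml, self.elution_volume_ul, self.template_volume_ul) <= 0:
            raise ValueError("extraction volumes must be positive")

    @property
    def culture_ml_per_reaction(self) -> float:
        """ml of original culture represented by the template in one reaction."""
        return self.culture_volume_ml * self.template_volume_ul / self.elution_volume_ul


def copies_from_dna_mass(
    amount_ng: float, length_bp: float, mass_per_bp: float = MASS_PER_BP
) -> float:
    """Number of molecule copies in ``amount_ng`` of DNA of ``length_bp``.

    copies = ng * 1e-9 * N_A / (length * mass_per_bp).
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if amount_ng < 0:
        raise ValueError("amount_ng must be non-negative")
    return amount_ng * 1e-9 * AVOGADRO / (length_bp * mass_per_bp)


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Cq against log10(copies) from a dilution series."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    copies_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not 0.6 < self.efficiency < 1.2:
            warnings.warn(
                f"amplification efficiency {self.efficiency:.3f} outside (0.6, 1.2)",
                stacklevel=2,
            )

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq_from_copies(self, copies: float) -> float:
        if copies <= 0:
            raise ValueError("copies must be positive")
        return self.intercept + self.slope * np.log10(copies)

    def copies_from_cq(self, cq: float) -> tuple[float, bool]:
        """Interpolate copies from a Cq; second element flags extrapolation."""
        copies = 10.0 ** ((cq - self.intercept) / self.slope)
        lo, hi = self.copies_range
        return copies, not lo <= copies <= hi


def fit_standard_curve(copies, cq) -> StandardCurve:
    """Least-squares Cq-on-log10(copies) line from a dilution series."""
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.shape != cq.shape:
        raise ValueError("copies and cq must have equal length")
    if np.any(copies <= 0):
        raise ValueError("standard copies must be positive")
    log_copies = np.log10(copies)
    if len(np.unique(np.round(log_copies, 12))) < 3:
        raise ValueError("need >= 3 distinct dilution levels with varying copies")
    fit = stats.linregress(log_copies, cq)
    return StandardCurve(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.rvalue**2,
        copies_range=(copies.min(), copies.max()),
    )


def copies_per_ml_culture(
    copies_per_reaction: float, extraction: ExtractionProtocol = ExtractionProtocol()
) -> float:
    """Scale reaction-level copies to copies per ml of original culture."""
    return copies_per_reaction / extraction.culture_ml_per_reaction


def cells_from_copy_density(copies_per_ml: float, assay: SpeciesAssay) -> float:
    """Cells/ml from 16S copies/ml via the per-genome operon count."""
    return copies_per_ml / assay.rrn_copies_per_genome


def cells_per_ml(
    copies_per_reaction: float,
    assay: SpeciesAssay,
    extraction: ExtractionProtocol = ExtractionProtocol(),
) -> float:
    """Cells per ml of culture from copies measured in one reaction."""
    return cells_from_copy_density(copies_per_ml_culture(copies_per_reaction, extraction), assay)


def quantify_plate(
    plate: pd.DataFrame,
    curves: Mapping[str, StandardCurve],
    assays: Mapping[str, SpeciesAssay] = DEFAULT_ASSAYS,
    extraction: ExtractionProtocol = ExtractionProtocol(),
) -> pd.DataFrame:
    """Collapse a qPCR plate export to per-day, per-species cell densities.

    Expects columns ``day, species, cq, bio_rep, tech_rep``.  Technical
    replicates are averaged to one Cq per biological replicate before curve
    interpolation; biological replicates then propagate as mean +/- sd.
    Samples interpolated outside the calibration range are flagged.
    """
    required = {"day", "species", "cq", "bio_rep", "tech_rep"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    unknown = set(plate["species"]) - set(assays)
    if unknown:
        raise KeyError(f"unknown species in plate: {sorted(unknown)}")

    rows = []
    for (day, species), group in plate.groupby(["day", "species"], sort=True):
        curve = curves[species]
        assay = assays[species]
        cells = []
        extrapolated = False
        for _, bio in group.groupby("bio_rep"):
            mean_cq = bio["cq"].mean()
            copies, extra = curve.copies_from_cq(mean_cq)
            extrapolated |= extra
            cells.append(cells_per_ml(copies, assay, extraction))
        cells = np.asarray(cells)
        flags = []
        if extrapolated:
            flags.append("extrapolated")
        if assay.genome_size_is_default:
            flags.append("default_genome_size")
        rows.append(
            {
                "day": day,
                "species": species,
                "cells_per_ml": cells.mean(),
                "cells_per_ml_sd": cells.std(ddof=1) if len(cells) > 1 else 0.0,
                "n_bio_reps": len(cells),
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Composition:
    """Fractional community composition with dominance information."""

    fractions: Mapping[str, float]
    dominant: str
    dominance_ratio: float  # dominant count / largest other count

    def as_dict(self) -> dict[str, float]:
        return dict(self.fractions)


def community_composition(cells: Mapping[str, float]) -> Composition:
    """Normalize per-species cell densities to fractions summing to 1."""
    if not cells:
        raise ValueError("no species counts provided")
    if any(v < 0 for v in cells.values()):
        raise ValueError("cell counts must be non-negative")
    total = float(sum(cells.values()))
    if total <= 0:
        raise ValueError("all cell counts are zero")
    fractions = {sp: v / total for sp, v in cells.items()}
    dominant = max(cells, key=cells.get)
    others = [v for sp, v in cells.items() if sp != dominant]
    ratio = cells[dominant] / max(others) if others and max(others) > 0 else np.inf
    return Composition(fractions=fractions, dominant=dominant, dominance_ratio=ratio)
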