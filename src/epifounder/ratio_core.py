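"""Scalar allelic scores from band-intensity measurements.

Methylation-sensitive restriction digestion followed by hot-stop PCR leaves
one radiolabelled band per allele on the gel; the band intensity is
proportional to the number of DNA molecules of that allele that were
methylated (uncleaved) at the queried CpG.  This module turns the two
per-sample band intensities into the scalar scores used downstream:

* ``allelic_ratio`` — ratio of the less-methylated parental allele's signal
  to the more-methylated one (M/P at the IGF2/H19 DMR, P/M at the IGF2R
  DMR).  0 means strictly monoallelic methylation; 1 means the queried site
  is methylated on equal numbers of both alleles.
* ``xi_score`` — X-inactivation skew at the androgen receptor locus:
  upper-band intensity over total.  0.5 is balanced inactivation.
* ``digestion_efficiency`` — the homozygote control for complete digestion.
* ``predicted_total_methylation`` — the consistency prediction linking an
  allelic ratio to the total percent methylation a bisulfite pyrosequencing
  assay should report at the same site.
* ``classify_loi`` — the 3:1 allelic-expression threshold for calling loss
  of imprinting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import Group, Locus, ScoreKind, Tissue, coerce

__all__ = [
    "AllelicMeasurement",
    "RatioRecord",
    "ControlResult",
    "allelic_ratio",
    "xi_score",
    "digestion_efficiency",
    "predicted_total_methylation",
    "classify_loi",
    "compute_ratios",
]


@dataclass(frozen=True)
class AllelicMeasurement:
    """One assayed sample: two allele band intensities at one locus.

    Intensities are net densitometry signals in arbitrary units (background
    subtraction is assumed to have happened upstream); only their ratio is
    meaningful.
    """

    individual_id: str
    group: Group
    tissue: Tissue
    locus: Locus
    intensity_a: float
    intensity_b: float
    allele_a_label: str = "a"
    allele_b_label: str = "b"

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", coerce(Group, self.group))
        object.__setattr__(self, "tissue", coerce(Tissue, self.tissue))
        object.__setattr__(self, "locus", coerce(Locus, self.locus))
        for name in ("intensity_a", "intensity_b"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class RatioRecord:
    """A scalar allelic score attached to its sample metadata.

    ``parental_origin_assumed`` records that maternal/paternal assignment
    rests on the population-level observation that the less-methylated
    allele is maternal (IGF2/H19) or paternal (IGF2R), not on pedigree.
    """

    individual_id: str
    group: Group
    tissue: Tissue
    locus: Locus
    score_kind: ScoreKind
    value: float
    parental_origin_assumed: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", coerce(Group, self.group))
        object.__setattr__(self, "tissue", coerce(Tissue, self.tissue))
        object.__setattr__(self, "locus", coerce(Locus, self.locus))
        object.__setattr__(self, "score_kind", coerce(ScoreKind, self.score_kind))
        v = float(self.value)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"score value must be finite and >= 0, got {v}")
        if self.score_kind is ScoreKind.XI and v > 1:
            raise ValueError(f"XI score must lie in [0, 1], got {v}")
        object.__setattr__(self, "value", v)


@dataclass(frozen=True)
class ControlResult:
    """Outcome of the homozygote digestion-efficiency control."""

    efficiency: float
    threshold: float
    passed: bool

    def __post_init__(self) -> None:
        if not 0 <= self.efficiency <= 1 or not 0 <= self.threshold <= 1:
            raise ValueError("efficiency and threshold must lie in [0, 1]")
        if self.passed != (self.efficiency >= self.threshold):
            raise ValueError("passed flag inconsistent with efficiency/threshold")


def _check_intensity(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value}")
    return value


def allelic_ratio(numerator_intensity: float, denominator_intensity: float) -> float:
    """Ratio of the two allelic methylation signals.

    The caller designates the presumed less-methylated parental allele as the
    numerator (maternal at IGF2/H19, paternal at IGF2R).  Values above 1 —
    the "reference" allele carrying less signal than expected — are preserved
    rather than clipped.
    """
    num = _check_intensity(numerator_intensity, "numerator_intensity")
    den = _check_intensity(denominator_intensity, "denominator_intensity")
    if den == 0:
        raise ValueError("reference allele signal absent (denominator is zero)")
    return num / den


def xi_score(upper_intensity: float, lower_intensity: float) -> float:
    """X-inactivation skew: upper band over the summed band intensities.

    Returned unfolded (not reflected about 0.5): which allele runs "upper"
    on the gel is arbitrary, so the population distribution is symmetric
    about 0.5 and group means may fall on either side of it.
    """
    upper = _check_intensity(upper_intensity, "upper_intensity")
    lower = _check_intensity(lower_intensity, "lower_intensity")
    total = upper + lower
    if total == 0:
        raise ValueError("both allele intensities are zero")
    return upper / total


def digestion_efficiency(
    uncleaved_intensity: float,
    cleaved_intensity: float,
    threshold: float = 0.99,
) -> ControlResult:
    """Digestion control on a homozygote: fraction of product cleaved.

    Homozygous individuals carry no polymorphic protection from the
    genotyping enzyme, so residual uncleaved signal measures incomplete
    digestion.  The assay is accepted when efficiency reaches ``threshold``
    (default 0.99, i.e. the >99% bar used for hot-stop PCR products).
    """
    unc = _check_intensity(uncleaved_intensity, "uncleaved_intensity")
    clv = _check_intensity(cleaved_intensity, "cleaved_intensity")
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    total = unc + clv
    if total == 0:
        raise ValueError("both control intensities are zero")
    eff = clv / total
    return ControlResult(efficiency=eff, threshold=threshold, passed=eff >= threshold)


def predicted_total_methylation(mp_ratio: float) -> float:
    """Total methylated fraction implied by an M/P ratio.

    Under the model that all paternal alleles are methylated and a fraction
    ``m = M/P`` of maternal alleles has gained methylation, a bisulfite
    assay that does not separate alleles should see ``(1 + m) / 2`` of all
    molecules methylated — always at least 50%.  The model is undefined
    outside ``m`` in [0, 1].
    """
    m = float(mp_ratio)
    if not math.isfinite(m) or not 0 <= m <= 1:
        raise ValueError(f"mp_ratio must lie in [0, 1], got {mp_ratio}")
    return (1 + m) / 2


def classify_loi(
    major_allele_intensity: float, minor_allele_intensity: float
) -> bool:
    """Call loss of imprinting from an allelic expression measurement.

    A transcript is called biallelic (imprinting lost) when the
    more-abundant allele carries strictly less than 3 times the signal of
    the less-abundant one.  Argument order does not matter; a silent minor
    allele is never LOI; exactly 3:1 is not LOI (strict inequality).
    """
    a = _check_intensity(major_allele_intensity, "major_allele_intensity")
    b = _check_intensity(minor_allele_intensity, "minor_allele_intensity")
    major, minor = max(a, b), min(a, b)
    if major == 0:
        raise ValueError("both allele intensities are zero")
    if minor == 0:
        return False
    return major / minor < 3


#: How each locus maps to a score flavor when converting an intensity table.
_LOCUS_SCORE: dict[Locus, ScoreKind] = {
    Locus.IGF2_H19: ScoreKind.MP,
    Locus.IGF2R: ScoreKind.PM,
    Locus.AR: ScoreKind.XI,
}


def compute_ratios(intensities: pd.DataFrame) -> pd.DataFrame:
    """Convert an intensity table into a ratio table.

    For the methylation loci the less-intense allele is taken as the
    numerator (the presumed maternal allele at IGF2/H19, paternal at IGF2R),
    so table-level ratios lie in [0, 1] by construction; callers with
    pedigree information can use :func:`allelic_ratio` directly to preserve
    orientation.  For the androgen receptor locus, ``intensity_a`` is the
    upper band by convention and the score is the X-inactivation skew.

    Parameters
    ----------
    intensities
        Columns ``individual_id, group, tissue, locus, intensity_a,
        intensity_b`` (allele label columns are carried through the
        reader but not needed here).

    Returns
    -------
    DataFrame with columns ``individual_id, group, tissue, locus,
    score_kind, value``.
    """
    required = {"individual_id", "group", "tissue", "locus", "intensity_a", "intensity_b"}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")

    rows = []
    for row in intensities.itertuples(index=False):
        locus = coerce(Locus, row.locus)
        kind = _LOCUS_SCORE[locus]
        a = _check_intensity(row.intensity_a, "intensity_a")
        b = _check_intensity(row.intensity_b, "intensity_b")
        if kind is ScoreKind.XI:
            value = xi_score(a, b)
        else:
            value = allelic_ratio(min(a, b), max(a, b))
        rows.append(
            (
                row.individual_id,
                coerce(Group, row.group).value,
                coerce(Tissue, row.tissue).value,
                locus.value,
                kind.value,
                value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["individual_id", "group", "tissue", "locus", "score_kind", "value"],
    ).astype({"value": np.float64})
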