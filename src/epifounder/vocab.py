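"""Controlled vocabularies shared by all tables.

Every record in the intensity, ratio and Ct tables carries a conception
group, a tissue and a locus or gene drawn from these enumerations; readers
validate against them so a typo ("invitro") fails loudly instead of
silently creating a third group.
"""

from __future__ import annotations

import enum


class Group(str, enum.Enum):
    """Conception group: assisted (in vitro) vs unassisted (in vivo)."""

    IN_VITRO = "in_vitro"
    IN_VIVO = "in_vivo"


class Tissue(str, enum.Enum):
    """Sampled tissues: cord blood, umbilical cord, five placenta sections."""

    CORD_BLOOD = "cord_blood"
    CORD = "cord"
    PLACENTA_1 = "placenta_1"
    PLACENTA_2 = "placenta_2"
    PLACENTA_3 = "placenta_3"
    PLACENTA_4 = "placenta_4"
    PLACENTA_5 = "placenta_5"


#: The five placenta sections, in order; the founder-cell estimators pool these.
PLACENTA_TISSUES: tuple[Tissue, ...] = (
    Tissue.PLACENTA_1,
    Tissue.PLACENTA_2,
    Tissue.PLACENTA_3,
    Tissue.PLACENTA_4,
    Tissue.PLACENTA_5,
)

#: Full tissue layout of one individual.
ALL_TISSUES: tuple[Tissue, ...] = (Tissue.CORD_BLOOD, Tissue.CORD) + PLACENTA_TISSUES


class Locus(str, enum.Enum):
    """Assayed loci.

    IGF2_H19: paternally methylated imprint control region (M/P ratio).
    IGF2R: maternally methylated intronic DMR (P/M ratio).
    AR: androgen receptor CAG repeat used for X-inactivation scoring.
    """

    IGF2_H19 = "IGF2_H19"
    IGF2R = "IGF2R"
    AR = "AR"


class ScoreKind(str, enum.Enum):
    """Flavor of a scalar allelic score."""

    MP = "MP"  # maternal/paternal methylation ratio (IGF2/H19 DMR)
    PM = "PM"  # paternal/maternal methylation ratio (IGF2R DMR)
    XI = "XI"  # X-inactivation skew: upper / (upper + lower)


class Gene(str, enum.Enum):
    """Genes measured by quantitative RT-PCR."""

    IGF2 = "IGF2"
    H19 = "H19"
    IGF2R = "IGF2R"
    GAPDH = "GAPDH"  # housekeeping


def coerce(enum_cls: type[enum.Enum], value: object) -> enum.Enum:
    """Coerce ``value`` to a member of ``enum_cls``.

    Raises ``ValueError`` listing the allowed values, so table readers can
    surface an actionable message with the offending row.
    """
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValueError(
            f"invalid {enum_cls.__name__} value {value!r}; allowed: {{{allowed}}}"
        ) from None
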