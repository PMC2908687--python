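"""Published summary statistics used as worked-example inputs.

Per-sample measurements from the reference cohort of children conceived in
vitro vs in vivo were never deposited; what is public are group-level
summaries.  The subset needed to drive the package's estimators is recorded
here:

* placental X-inactivation score summaries (HUMARA assay; females only),
* placental maternal/paternal IGF2/H19 DMR methylation-ratio summaries,
* allelic-expression minor-allele percentages for IGF2 and H19 transcripts,
* qPCR fold changes of the in vitro group relative to in vivo.

Feeding the variance summaries to :func:`epifounder.founder_estimation.moment_n`
reproduces the cohort's founder stem-cell estimates; the expression
percentages feed :func:`epifounder.ratio_core.classify_loi`.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "XI_PLACENTA_SUMMARY",
    "MP_PLACENTA_SUMMARY",
    "ALLELIC_EXPRESSION_PCT",
    "EXPRESSION_FOLD_CHANGES",
]

#: Placental X-inactivation score summaries per conception group.
#: 50 in vitro and 54 in vivo informative females, five placenta sections
#: each; the dispersion is reported as a standard deviation.
XI_PLACENTA_SUMMARY: dict[str, dict[str, float | int]] = {
    "in_vitro": {"mean": 0.4775, "sd": 0.1637, "n_females": 50, "n_samples": 250},
    "in_vivo": {"mean": 0.4824, "sd": 0.1502, "n_females": 54, "n_samples": 270},
}

#: Placental maternal/paternal IGF2/H19 DMR methylation-ratio summaries.
#: 45 in vitro and 56 in vivo informative individuals, five sections each;
#: the dispersion is reported as a variance.
MP_PLACENTA_SUMMARY: dict[str, dict[str, float | int]] = {
    "in_vitro": {"mean": 0.1017, "variance": 0.0111, "n_individuals": 45,
                 "n_samples": 225},
    "in_vivo": {"mean": 0.0801, "variance": 0.0091, "n_individuals": 56,
                "n_samples": 280},
}

#: Minor-allele share of transcripts (percent) in placental samples with
#: measurable biallelic signal: presumed-maternal IGF2 expression and
#: presumed-paternal H19 expression, by conception group.  None of these
#: reaches the 3:1 threshold for a loss-of-imprinting call.
ALLELIC_EXPRESSION_PCT: pd.DataFrame = pd.DataFrame(
    [
        ("in_vitro", "IGF2", 2.9),
        ("in_vitro", "IGF2", 6.9),
        ("in_vitro", "IGF2", 7.0),
        ("in_vitro", "IGF2", 1.6),
        ("in_vitro", "IGF2", 15.8),
        ("in_vitro", "H19", 2.5),
        ("in_vitro", "H19", 1.9),
        ("in_vitro", "H19", 1.2),
        ("in_vitro", "H19", 1.6),
        ("in_vitro", "H19", 1.0),
        ("in_vitro", "H19", 0.8),
        ("in_vivo", "IGF2", 2.8),
        ("in_vivo", "IGF2", 2.6),
        ("in_vivo", "H19", 3.0),
        ("in_vivo", "H19", 2.1),
        ("in_vivo", "IGF2", 5.5),
        ("in_vivo", "IGF2", 8.8),
    ],
    columns=["group", "gene", "minor_allele_pct"],
)

#: Reported fold changes (in vitro relative to in vivo) by tissue and gene,
#: with group sample sizes; these parameterize the synthetic Ct generator's
#: default effects.
EXPRESSION_FOLD_CHANGES: pd.DataFrame = pd.DataFrame(
    [
        ("cord_blood", "H19", 73, 118, 0.88),
        ("cord_blood", "IGF2", 77, 116, 1.03),
        ("cord_blood", "IGF2R", 75, 121, 0.61),
        ("placenta", "H19", 84, 135, 0.72),
        ("placenta", "IGF2", 98, 160, 0.52),
        ("placenta", "IGF2R", 97, 148, 1.18),
    ],
    columns=["tissue", "gene", "n_in_vitro", "n_in_vivo", "fold_change"],
)
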