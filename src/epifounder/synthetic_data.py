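"""Synthetic cohorts with the clonal-mosaicism structure the analysis assumes.

No per-sample measurements from the motivating study design are publicly
deposited, so every downstream stage is exercised on generated cohorts that
emulate it: two conception groups (in vitro / in vivo), each individual
sampled at cord blood, cord and five placenta sections; per-sample allelic
scores drawn from the founder-cell binomial model (score = k/N with
k ~ Binomial(N, p)); X-inactivation scored in females only; and qPCR Ct
tables in which group fold-change effects on target-gene expression are
injected on the ΔCt scale while the housekeeping gene is unaffected.

All randomness flows from ``CohortConfig.seed`` through one generator, so a
config is a complete, reproducible description of a cohort.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .vocab import ALL_TISSUES, Gene, Group, Locus, PLACENTA_TISSUES, ScoreKind, Tissue

__all__ = ["CtRecord", "CohortConfig", "simulate_founder_scores", "simulate_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR threshold-cycle measurement."""

    individual_id: str
    group: Group
    tissue: Tissue
    gene: Gene
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError(f"ct must be finite, got {self.ct}")


def _default_fold_effects() -> dict[str, dict[str, float]]:
    # Group fold changes (in vitro relative to in vivo) reproduced in the
    # generated expression data; values follow the reference cohort study.
    return {
        Gene.H19.value: {Tissue.CORD_BLOOD.value: 0.88, "placenta": 0.72},
        Gene.IGF2.value: {Tissue.CORD_BLOOD.value: 1.03, "placenta": 0.52},
        Gene.IGF2R.value: {Tissue.CORD_BLOOD.value: 0.61, "placenta": 1.18},
    }


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    Defaults reproduce the study design the package targets: 45 in vitro and
    56 in vivo informative individuals, seven tissue samples each, maternal
    IGF2/H19 DMR methylation probability 0.1, balanced X-inactivation
    (p = 0.5), and founder-cell counts of 8 (in vitro) vs 10 (in vivo).
    """

    n_in_vitro: int = 45
    n_in_vivo: int = 56
    founders_in_vitro: int = 8
    founders_in_vivo: int = 10
    p_dmr: float = 0.1
    p_xi: float = 0.5
    p_igf2r: float | None = None  # set to also emit P/M scores at IGF2R
    tissues: tuple[str, ...] = tuple(t.value for t in ALL_TISSUES)
    noise_sd: float = 0.0  # Gaussian densitometry noise on scores
    fold_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_fold_effects
    )
    ct_sd: float = 0.1  # qPCR technical noise per Ct measurement
    ct_baseline_target: float = 25.0
    ct_baseline_housekeeping: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_in_vitro", "n_in_vivo", "founders_in_vitro", "founders_in_vivo"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p_dmr", "p_xi"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.p_igf2r is not None and not 0 < self.p_igf2r < 1:
            raise ValueError("p_igf2r must lie strictly in (0, 1)")
        if self.noise_sd < 0 or self.ct_sd < 0:
            raise ValueError("noise_sd and ct_sd must be >= 0")
        for t in self.tissues:
            Tissue(t)  # raises on unknown tissue
        for gene, per_tissue in self.fold_effects.items():
            Gene(gene)
            for fold in per_tissue.values():
                if fold <= 0:
                    raise ValueError("fold effects must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["tissues"] = list(data["tissues"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def simulate_founder_scores(
    n_founders: int,
    p: float,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw allelic scores from the founder-cell binomial model.

    Each sample is ``k / n_founders`` with ``k ~ Binomial(n_founders, p)``:
    the fraction of the tissue sample's founder cells carrying the "on"
    epiallele state.  Optional Gaussian measurement noise is added and the
    result truncated to [0, 1] (truncation count logged).
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must lie strictly in (0, 1)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    scores = rng.binomial(n_founders, p, size=n_samples) / n_founders
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=n_samples)
        n_trunc = int(np.sum((scores < 0) | (scores > 1)))
        if n_trunc:
            logger.info("truncated %d noisy score(s) to [0, 1]", n_trunc)
        scores = np.clip(scores, 0.0, 1.0)
    return scores


def _fold_for(config: CohortConfig, gene: str, tissue: str) -> float:
    per_tissue = config.fold_effects.get(gene, {})
    if tissue in per_tissue:
        return per_tissue[tissue]
    if tissue.startswith("placenta") and "placenta" in per_tissue:
        return per_tissue["placenta"]
    return 1.0


#: Tissues at which expression is measured (cord blood plus the placenta
#: section behind the cord insertion, mirroring the single placental
#: expression sample per individual in the emulated design).
_CT_TISSUES: tuple[str, ...] = (Tissue.CORD_BLOOD.value, Tissue.PLACENTA_3.value)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort: a ratio table and a Ct table.

    Ratio table: one maternal/paternal (MP) score at the IGF2/H19 DMR per
    individual per tissue; one X-inactivation (XI) score per *female* per
    tissue (sex assigned Bernoulli(0.5)); optionally one paternal/maternal
    (PM) score at IGF2R when ``p_igf2r`` is set.  Every tissue sample is an
    independent binomial draw with the group's founder count.

    Ct table: per individual, per expression tissue, one Ct per target gene
    plus the housekeeping gene; the in vitro group's target Ct values are
    shifted by −log2(fold) so that the ΔΔCt method recovers the configured
    fold change in expectation.
    """
    rng = np.random.default_rng(config.seed)
    group_specs = (
        (Group.IN_VITRO, config.n_in_vitro, config.founders_in_vitro),
        (Group.IN_VIVO, config.n_in_vivo, config.founders_in_vivo),
    )
    ratio_rows: list[tuple] = []
    ct_rows: list[tuple] = []
    target_genes = tuple(g for g in Gene if g is not Gene.GAPDH)

    for group, n_ind, founders in group_specs:
        for i in range(n_ind):
            ind = f"{'iv' if group is Group.IN_VITRO else 'vv'}-{i + 1:03d}"
            female = bool(rng.random() < 0.5)

            assays: list[tuple[Locus, ScoreKind, float]] = [
                (Locus.IGF2_H19, ScoreKind.MP, config.p_dmr)
            ]
            if config.p_igf2r is not None:
                assays.append((Locus.IGF2R, ScoreKind.PM, config.p_igf2r))
            if female:
                assays.append((Locus.AR, ScoreKind.XI, config.p_xi))
            for locus, kind, p in assays:
                scores = simulate_founder_scores(
                    founders, p, len(config.tissues),
                    noise_sd=config.noise_sd, rng=rng,
                )
                for tissue, value in zip(config.tissues, scores):
                    ratio_rows.append(
                        (ind, group.value, tissue, locus.value, kind.value, float(value))
                    )

            for tissue in _CT_TISSUES:
                if tissue not in config.tissues:
                    continue
                hk_ct = config.ct_baseline_housekeeping + rng.normal(0, config.ct_sd)
                ct_rows.append((ind, group.value, tissue, Gene.GAPDH.value, float(hk_ct)))
                for gene in target_genes:
                    base = config.ct_baseline_target
                    if group is Group.IN_VITRO:
                        # lower expression -> more cycles: ΔΔCt = -log2(fold)
                        base = base - math.log2(_fold_for(config, gene.value, tissue))
                    ct = base + rng.normal(0, config.ct_sd)
                    ct_rows.append((ind, group.value, tissue, gene.value, float(ct)))

    ratios = pd.DataFrame(
        ratio_rows,
        columns=["individual_id", "group", "tissue", "locus", "score_kind", "value"],
    )
    cts = pd.DataFrame(
        ct_rows, columns=["individual_id", "group", "tissue", "gene", "ct"]
    )
    return ratios, cts
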