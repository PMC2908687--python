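"""Between-group comparisons: location, variance equality, and ΔΔCt folds.

The comparisons mirror how clonal-mosaicism cohorts are analyzed: a
Wilcoxon rank-sum test on allelic-score location between conception groups,
a variance-equality test (the quantity the founder-cell model actually
predicts to differ), per-tissue group summary tables, and relative
expression fold changes by the ΔΔCt method with a Welch t-test on per-sample
ΔCt values.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import (
    ALL_TISSUES,
    Gene,
    Group,
    PLACENTA_TISSUES,
    ScoreKind,
    Tissue,
    coerce,
)

__all__ = [
    "GroupSummary",
    "FoldChangeResult",
    "wilcoxon_rank_sum",
    "variance_equality_test",
    "summarize_groups",
    "ddct",
    "fold_change_table",
]

logger = logging.getLogger(__name__)

_EXACT_LIMIT = 20  # full enumeration of C(n, n1) rank assignments up to here


@dataclass(frozen=True)
class GroupSummary:
    """One cell of a tissue × group summary table."""

    tissue: str
    group: Group
    n: int
    mean: float
    variance: float
    p_means: float | None
    p_variances: float | None


@dataclass(frozen=True)
class FoldChangeResult:
    """ΔΔCt fold change of the in vitro group relative to in vivo."""

    gene: Gene
    tissue: str
    n_in_vitro: int
    n_in_vivo: int
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration.

    Pooled values receive midranks; the null distribution of the first
    sample's rank sum is enumerated over all C(n, n1) assignments of ranks
    to groups, and the p-value is the probability of a rank sum at least as
    far from its null mean as observed.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    w_obs = float(ranks[:n1].sum())
    mu = ranks.sum() * n1 / (n1 + n2)
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
    return w_obs, count / total


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    ``mode='exact'`` enumerates all rank assignments (combined n ≤ 20,
    midranks for ties); ``mode='normal_approx'`` uses the tie-corrected,
    continuity-corrected normal approximation; ``mode='auto'`` picks exact
    for combined n ≤ 20.  Returns ``(W, p)`` where ``W`` is the rank sum of
    the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs at least one value")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    n = a.size + b.size
    ranks_w = float(stats.rankdata(np.concatenate([a, b]))[: a.size].sum())
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return ranks_w, 1.0
    if mode == "auto":
        mode = "exact" if n <= _EXACT_LIMIT else "normal_approx"
    if mode == "exact":
        if n > _EXACT_LIMIT:
            raise ValueError(f"exact mode limited to combined n <= {_EXACT_LIMIT}")
        return _rank_sum_exact(a, b)
    if mode == "normal_approx":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        return ranks_w, float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def variance_equality_test(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "levene_median",
) -> tuple[float, float]:
    """Two-sided test of equal variances between two samples.

    ``levene_median`` (Brown–Forsythe, default) is robust to the skewed
    ratio distributions this package deals with; ``f_test`` is the classical
    normal-theory variance-ratio test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("degenerate: no within-group deviation in either group")
    if method == "levene_median":
        stat, p = stats.levene(a, b, center="median")
        return float(stat), float(p)
    if method == "f_test":
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if vb == 0:
            return math.inf, 0.0
        f = va / vb
        cdf = stats.f.cdf(f, a.size - 1, b.size - 1)
        return float(f), float(2 * min(cdf, 1 - cdf))
    raise ValueError(f"unknown method {method!r}")


def _default_tissue_sets() -> list[tuple[str, tuple[Tissue, ...]]]:
    return [
        ("cord_blood", (Tissue.CORD_BLOOD,)),
        ("cord", (Tissue.CORD,)),
        ("placenta", PLACENTA_TISSUES),
        ("total", ALL_TISSUES),
    ]


def summarize_groups(
    ratios: pd.DataFrame,
    score_kind: ScoreKind | str,
    tissue_sets: Sequence[tuple[str, Iterable[Tissue | str]]] | None = None,
    variance_method: str = "levene_median",
    location_mode: str = "normal_approx",
) -> pd.DataFrame:
    """Group mean/variance summary with between-group tests, per tissue set.

    One row per (tissue set, group); the two p-value columns (rank-sum test
    on locations, variance-equality test) are repeated on both group rows of
    a tissue set, and left missing when only one group has data.  Tissue
    sets default to cord blood, cord, pooled placenta sections, and all
    tissues combined ("total").
    """
    kind = coerce(ScoreKind, score_kind)
    sub = ratios[ratios["score_kind"] == kind.value]
    if tissue_sets is None:
        tissue_sets = _default_tissue_sets()
    rows = []
    for label, tissues in tissue_sets:
        tset = {coerce(Tissue, t).value for t in tissues}
        cell = sub[sub["tissue"].isin(tset)]
        samples = {
            g: cell.loc[cell["group"] == g.value, "value"].to_numpy(dtype=float)
            for g in Group
        }
        present = [g for g in Group if samples[g].size > 0]
        if not present:
            logger.warning("no %s records for tissue set %r; row omitted",
                           kind.value, label)
            continue
        p_means = p_vars = None
        if len(present) == 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p_means = wilcoxon_rank_sum(
                    samples[Group.IN_VITRO], samples[Group.IN_VIVO],
                    mode=location_mode,
                )
            try:
                _, p_vars = variance_equality_test(
                    samples[Group.IN_VITRO], samples[Group.IN_VIVO],
                    method=variance_method,
                )
            except ValueError as exc:
                logger.warning("variance test unavailable for %r: %s", label, exc)
        for g in present:
            vals = samples[g]
            rows.append(
                {
                    "tissue": label,
                    "group": g.value,
                    "n": int(vals.size),
                    "mean": float(vals.mean()),
                    "variance": float(np.var(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "p_means": p_means,
                    "p_variances": p_vars,
                }
            )
    return pd.DataFrame(rows)


def ddct(
    ct_records: pd.DataFrame,
    target_gene: Gene | str,
    housekeeping_gene: Gene | str = Gene.GAPDH,
    tissue: Tissue | str | None = None,
    reference_group: Group | str = Group.IN_VIVO,
) -> FoldChangeResult:
    """Relative expression fold change by the ΔΔCt method.

    Per sample, ΔCt = Ct(target) − Ct(housekeeping); ΔΔCt is the difference
    of group mean ΔCt (comparison minus reference); the fold change is
    2^(−ΔΔCt), reported for the comparison (in vitro) group relative to the
    reference (in vivo).  The p-value is a two-sided Welch t-test on the
    per-sample ΔCt values.  Samples missing the housekeeping measurement
    are dropped with a warning.
    """
    target = coerce(Gene, target_gene)
    housekeeping = coerce(Gene, housekeeping_gene)
    reference = coerce(Group, reference_group)
    comparison = Group.IN_VITRO if reference is Group.IN_VIVO else Group.IN_VIVO

    sub = ct_records
    tissue_label = "all"
    if tissue is not None:
        tissue_label = coerce(Tissue, tissue).value
        sub = sub[sub["tissue"] == tissue_label]
    keys = ["individual_id", "group", "tissue"]
    tgt = sub[sub["gene"] == target.value][keys + ["ct"]]
    hk = sub[sub["gene"] == housekeeping.value][keys + ["ct"]]
    merged = tgt.merge(hk, on=keys, how="left", suffixes=("_target", "_hk"))
    n_missing = int(merged["ct_hk"].isna().sum())
    if n_missing:
        logger.warning(
            "dropping %d sample(s) without a %s measurement",
            n_missing, housekeeping.value,
        )
        merged = merged.dropna(subset=["ct_hk"])
    merged = merged.assign(dct=merged["ct_target"] - merged["ct_hk"])
    dct = {
        g: merged.loc[merged["group"] == g.value, "dct"].to_numpy(dtype=float)
        for g in (comparison, reference)
    }
    for g, vals in dct.items():
        if vals.size < 2:
            raise ValueError(
                f"group {g.value} has {vals.size} usable sample(s); need >= 2"
            )
    ddct_value = float(dct[comparison].mean() - dct[reference].mean())
    fold = 2.0 ** (-ddct_value)
    if np.ptp(np.concatenate([dct[comparison], dct[reference]])) == 0:
        p = 1.0
    elif np.ptp(dct[comparison]) == 0 and np.ptp(dct[reference]) == 0:
        p = 0.0  # internally constant groups with different means
    else:
        p = float(stats.ttest_ind(dct[comparison], dct[reference], equal_var=False).pvalue)
    return FoldChangeResult(
        gene=target,
        tissue=tissue_label,
        n_in_vitro=int(dct[Group.IN_VITRO].size),
        n_in_vivo=int(dct[Group.IN_VIVO].size),
        fold_change=fold,
        p_value=p,
    )


def fold_change_table(
    ct_records: pd.DataFrame,
    target_genes: Sequence[Gene | str] = (Gene.H19, Gene.IGF2, Gene.IGF2R),
    housekeeping_gene: Gene | str = Gene.GAPDH,
) -> pd.DataFrame:
    """Fold-change summary, one row per (tissue, target gene) present."""
    rows = []
    for tissue in pd.unique(ct_records["tissue"]):
        for gene in target_genes:
            gene = coerce(Gene, gene)
            if not ((ct_records["tissue"] == tissue)
                    & (ct_records["gene"] == gene.value)).any():
                continue
            res = ddct(ct_records, gene, housekeeping_gene, tissue=tissue)
            rows.append(
                {
                    "tissue": res.tissue,
                    "gene": res.gene.value,
                    "n_in_vitro": res.n_in_vitro,
                    "n_in_vivo": res.n_in_vivo,
                    "fold_change": res.fold_change,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
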