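"""Poisson statistics for droplet digital PCR allelic-balance calls.

In ddPCR the sample is partitioned into ~20,000 droplets and each droplet is
scored positive or negative per fluorescence channel. Copies per droplet are
Poisson distributed, so the mean concentration per partition is

    λ = −ln((N − n_pos) / N)

with a 95% CI obtained by propagating a binomial interval on the positive
fraction through the same transform. For a two-channel assay targeting the
two alleles of a heterozygous SNP, the fractional abundance of the variant
allele is FA = λ_T / (λ_T + λ_K); balanced allelic expression is called when
FA lies within 0.5 ± 0.1 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

#: half-width of the balanced-expression band around 0.5
BALANCE_HALF_WIDTH = 0.1


@dataclass(frozen=True)
class DdpcrWell:
    """Called partition counts for one two-channel well."""

    well_id: str
    n_partitions: int
    n_pos_K: int
    n_pos_T: int

    def __post_init__(self) -> None:
        if self.n_partitions <= 0:
            raise ValueError("n_partitions must be positive")
        for n in (self.n_pos_K, self.n_pos_T):
            if not 0 <= n <= self.n_partitions:
                raise ValueError("positive counts must lie in [0, n_partitions]")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Poisson concentration (copies/partition) with 95% CI."""

    lam: float
    lam_low: float
    lam_high: float
    saturated: bool = False


@dataclass(frozen=True)
class DdpcrEstimate:
    """Fractional abundance of the T allele with 95% CI and balance call."""

    lambda_K: float
    lambda_T: float
    FA: float
    FA_min: float
    FA_max: float
    balanced: bool


def estimate_concentration(
    n_pos: int, n_partitions: int, ci_method: str = "wilson"
) -> ConcentrationEstimate:
    """Maximum-likelihood Poisson concentration from partition counts.

    The MLE is λ̂ = −ln(1 − n_pos/N); the CI comes from a binomial interval
    (Wilson score by default) on the positive fraction, mapped through the
    same monotone transform. Saturation (all partitions positive) leaves λ
    unbounded and is flagged rather than guessed.
    """
    if n_partitions <= 0:
        raise ValueError("n_partitions must be positive")
    if not 0 <= n_pos <= n_partitions:
        raise ValueError("n_pos must lie in [0, n_partitions]")
    if n_pos == n_partitions:
        p_low, _ = proportion_confint(n_pos, n_partitions, alpha=0.05, method=ci_method)
        return ConcentrationEstimate(
            lam=np.inf, lam_low=-np.log1p(-p_low), lam_high=np.inf, saturated=True
        )
    lam = -np.log1p(-n_pos / n_partitions)
    p_low, p_high = proportion_confint(n_pos, n_partitions, alpha=0.05, method=ci_method)
    return ConcentrationEstimate(
        lam=float(lam),
        lam_low=float(-np.log1p(-min(p_low, 1.0 - 1e-15))),
        lam_high=float(-np.log1p(-min(p_high, 1.0 - 1e-15))),
    )


def fractional_abundance(
    est_K: ConcentrationEstimate, est_T: ConcentrationEstimate
) -> DdpcrEstimate:
    """Fractional abundance FA = λ_T / (λ_T + λ_K) with a 95% CI.

    The CI bounds take the extreme combinations of the per-channel CIs
    (λ_T low with λ_K high and vice versa), mirroring the min/max fractional
    abundance reported by droplet-reader software.
    """
    for est in (est_K, est_T):
        if est.saturated or not np.isfinite(est.lam):
            raise ValueError("cannot form fractional abundance from a saturated channel")
    total = est_K.lam + est_T.lam
    if total == 0:
        raise ValueError("both channels empty: fractional abundance undefined")
    fa = est_T.lam / total
    lo_den = est_T.lam_low + est_K.lam_high
    hi_den = est_T.lam_high + est_K.lam_low
    fa_min = est_T.lam_low / lo_den if lo_den > 0 else 0.0
    fa_max = est_T.lam_high / hi_den if hi_den > 0 else 1.0
    return DdpcrEstimate(
        lambda_K=est_K.lam,
        lambda_T=est_T.lam,
        FA=float(fa),
        FA_min=float(min(fa_min, fa)),
        FA_max=float(max(fa_max, fa)),
        balanced=classify_balance(float(fa)) == "balanced",
    )


def classify_balance(fa: float) -> str:
    """Balanced iff FA ∈ [0.5 − 0.1, 0.5 + 0.1], boundaries inclusive."""
    if not np.isfinite(fa):
        raise ValueError("fractional abundance undefined")
    lo, hi = 0.5 - BALANCE_HALF_WIDTH, 0.5 + BALANCE_HALF_WIDTH
    return "balanced" if lo <= fa <= hi else "skewed"


def analyze_well(well: DdpcrWell, ci_method: str = "wilson") -> DdpcrEstimate:
    """Full per-well analysis: channel concentrations → FA → balance call."""
    return fractional_abundance(
        estimate_concentration(well.n_pos_K, well.n_partitions, ci_method),
        estimate_concentration(well.n_pos_T, well.n_partitions, ci_method),
    )


def analyze_wells(wells: Iterable[DdpcrWell], ci_method: str = "wilson") -> pd.DataFrame:
    """Tidy per-well estimate table (one row per well)."""
    rows = []
    for w in wells:
        est = analyze_well(w, ci_method)
        rows.append(
            {
                "well_id": w.well_id,
                "n_partitions": w.n_partitions,
                "n_pos_K": w.n_pos_K,
                "n_pos_T": w.n_pos_T,
                "lambda_K": est.lambda_K,
                "lambda_T": est.lambda_T,
                "fractional_abundance": est.FA,
                "FA_min": est.FA_min,
                "FA_max": est.FA_max,
                "call": "balanced" if est.balanced else "skewed",
            }
        )
    return pd.DataFrame(rows)
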