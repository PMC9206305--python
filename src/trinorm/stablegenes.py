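"""Stable-reference-gene selection and sample-reference normalization factors.

For each normalization mode the screen proceeds as in the emulated workflow:
genes passing a robust-expression filter (count >= 30 in every sample) are
fitted gene-by-gene with a participant random-intercept LMM on log-CPM; any
gene whose study-condition coefficients (time, volume, interactions) reach
|t| >= 1.5 is discarded as showing systematic intervention effects; the
survivors are ranked by decreasing ICC and the top ten become the mode's
stable reference genes.

The sample reference is the housekeeping-style normalization factor: each
selected gene's abundance profile is scaled to max 1 across samples
(x / max(x)) and the scaled profiles are averaged per sample, giving a value
in (0, 1] per sample. Because every stable gene's profile has max exactly 1,
the reference is invariant to rescaling any single gene. Cross-mode ratios
of sample references, modeled over time with a participant random intercept,
quantify how the viewpoints drift apart (the global-amplification signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import StructuralError, logger
from .lmm import (
    LMMFit,
    condition_labels,
    condition_t_max,
    fit_reml,
    screening_design,
    time_design,
)
from .normalize import AbundanceMatrix, check_mode


@dataclass
class StableGeneReport:
    mode: str
    filtered_genes: list[str]
    screened: pd.DataFrame  # per gene: max_abs_t, icc, passed_screen, converged
    ranked: list[str]
    top_k: list[str]


@dataclass
class SampleReference:
    mode: str
    reference: pd.Series  # per sample, in (0, 1]
    contributing_genes: list[str]
    scaled_profiles: pd.DataFrame


@dataclass
class RatioEstimate:
    numerator_mode: str
    denominator_mode: str
    time: str
    fold_change: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        assert self.ci_low <= self.fold_change <= self.ci_high
        assert self.ci_low > 0


def robust_filter(counts: pd.DataFrame, min_count: int = 30) -> list[str]:
    """Genes with count >= min_count in every sample."""
    keep = (counts.to_numpy() >= min_count).all(axis=1)
    genes = counts.index[keep].tolist()
    if not genes:
        logger.warning("robust filter at min_count=%d leaves no genes", min_count)
    return genes


def screen_and_rank(
    logcpm: AbundanceMatrix,
    meta: pd.DataFrame,
    t_threshold: float = 1.5,
    top_k: int = 10,
    include_volume: bool = True,
    include_interactions: bool = True,
) -> StableGeneReport:
    """t-screen then ICC-rank the genes of a log-CPM matrix (one mode)."""
    if not logcpm.log_transformed:
        raise ValueError("screen_and_rank expects log-transformed CPM")
    meta = meta.loc[logcpm.sample_ids]
    X = screening_design(meta, include_volume, include_interactions)
    cond = condition_labels(X)
    groups = meta["participant"].to_numpy()
    values = logcpm.values
    records = []
    for gene in values.index:
        fit = fit_reml(values.loc[gene].to_numpy(), X, groups)
        tmax = condition_t_max(fit, cond)
        records.append(
            {
                "gene_id": gene,
                "max_abs_t": tmax,
                "icc": fit.icc,
                "converged": fit.converged,
                "passed_screen": bool(fit.converged and tmax < t_threshold),
            }
        )
    screened = pd.DataFrame(records).set_index("gene_id")
    n_failed = int((~screened["converged"]).sum())
    if n_failed:
        logger.warning("%d gene fits did not converge and are excluded", n_failed)
    survivors = screened[screened["passed_screen"]]
    if survivors.empty:
        raise ValueError(
            f"no genes pass the |t| < {t_threshold} screen; consider relaxing "
            "the threshold"
        )
    # ICC descending, ties broken deterministically by gene identifier
    ranked = (
        survivors.sort_values(["icc", "gene_id"], ascending=[False, True])
        .index.tolist()
    )
    if len(ranked) < top_k:
        logger.warning(
            "only %d genes survive the screen (requested top %d); using all",
            len(ranked),
            top_k,
        )
    return StableGeneReport(
        mode=logcpm.mode,
        filtered_genes=values.index.tolist(),
        screened=screened,
        ranked=ranked,
        top_k=ranked[:top_k],
    )


def sample_reference(
    abund: AbundanceMatrix | pd.DataFrame, stable_set, mode: str | None = None
) -> SampleReference:
    """Max-scale each stable gene's linear-scale profile and average per sample."""
    if isinstance(abund, AbundanceMatrix):
        if abund.log_transformed:
            raise ValueError("sample_reference needs a linear-scale matrix")
        values = abund.values
        mode = mode or abund.mode
    else:
        values = abund
        if mode is None:
            raise ValueError("mode must be given with a bare DataFrame")
    check_mode(mode)
    stable_set = list(stable_set)
    if not stable_set:
        raise ValueError("stable_set must be non-empty")
    missing = [g for g in stable_set if g not in values.index]
    if missing:
        raise StructuralError(f"stable genes absent from matrix: {missing[:5]}")
    sub = values.loc[stable_set].astype(float)
    maxima = sub.max(axis=1)
    zero = maxima[maxima <= 0].index.tolist()
    if zero:
        logger.warning("stable gene(s) with all-zero profile excluded: %s", zero)
        sub = sub.drop(index=zero)
        maxima = maxima.drop(index=zero)
        if sub.empty:
            raise ValueError("all stable genes have zero profiles")
    scaled = sub.div(maxima, axis=0)
    ref = scaled.mean(axis=0)
    ref.name = "reference"
    return SampleReference(
        mode=mode,
        reference=ref,
        contributing_genes=list(sub.index),
        scaled_profiles=scaled,
    )


def reference_ratio(
    ref_num: SampleReference,
    ref_den: SampleReference,
    meta: pd.DataFrame,
    conf_level: float = 0.95,
) -> list[RatioEstimate]:
    """Cross-mode reference ratios over time with Wald 95% CIs.

    log(ref_num/ref_den) is fitted with time fixed effects (cell-means
    coding, so each coefficient is that time level's estimated mean) and a
    participant random intercept. Returns one estimate per time level
    (exponentiated per-time mean ratio) plus change-from-baseline contrasts
    (``week2_vs_week0`` etc.), all with Wald CIs on the log scale.
    """
    if list(ref_num.reference.index) != list(ref_den.reference.index):
        raise StructuralError("reference sets cover different samples")
    from scipy.stats import norm

    from .io import BASELINE_TIME, TIME_LEVELS
    from .lmm import time_cell_means_design

    zcrit = float(norm.ppf(0.5 + conf_level / 2.0))
    meta = meta.loc[ref_num.reference.index]
    y = np.log(ref_num.reference.to_numpy() / ref_den.reference.to_numpy())
    X = time_cell_means_design(meta)
    fit = fit_reml(y, X, meta["participant"].to_numpy())

    def _estimate(time_label, b, se):
        return RatioEstimate(
            numerator_mode=ref_num.mode,
            denominator_mode=ref_den.mode,
            time=time_label,
            fold_change=float(np.exp(b)),
            ci_low=float(np.exp(b - zcrit * se)),
            ci_high=float(np.exp(b + zcrit * se)),
        )

    out = []
    for t in TIME_LEVELS:
        out.append(_estimate(t, fit.coefficients[t], fit.standard_errors[t]))
    cov = fit.cov_coefficients
    for t in TIME_LEVELS:
        if t == BASELINE_TIME:
            continue
        diff = fit.coefficients[t] - fit.coefficients[BASELINE_TIME]
        var = (
            cov.loc[t, t]
            + cov.loc[BASELINE_TIME, BASELINE_TIME]
            - 2.0 * cov.loc[t, BASELINE_TIME]
        )
        out.append(_estimate(f"{t}_vs_{BASELINE_TIME}", diff, float(np.sqrt(max(var, 0.0)))))
    return out
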