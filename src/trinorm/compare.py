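"""Differential expression under all three normalization modes and their
cross-mode comparison: up/down sets, intersection patterns and direction
conflicts.

The DE universe is fixed before testing (count >= 1 in every sample, minus
the union of the three modes' stable reference genes) and shared across
modes, so Fig-1C-style intersections compare identical genes. Per gene and
mode a negative-binomial GLMM with participant random intercept is fitted to
the raw counts with the mode's log sample-reference as offset; week-2 and
week-12 contrasts against baseline get Wald p-values, Benjamini-Hochberg
adjusted per contrast across genes, and an up/down/ns direction label at the
chosen FDR level. Genes whose fit fails in any mode are labelled ns in every
mode (never silently dropped), keeping the comparison universes identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .io import BASELINE_TIME, TIME_LEVELS, PipelineConfig, StructuralError, logger
from .lmm import condition_labels, time_design
from .nbglmm import bh_adjust, fit_nb_glmm, wald_table
from .normalize import (
    AbundanceMatrix,
    MODES,
    PER_LIBRARY_SIZE,
    PER_SAMPLE_SIZE,
    PER_TOTAL_RNA,
    cpm,
    denominators,
    log_cpm,
    tmm_factors,
)
from .stablegenes import (
    SampleReference,
    StableGeneReport,
    RatioEstimate,
    reference_ratio,
    robust_filter,
    sample_reference,
    screen_and_rank,
)

CONTRASTS = tuple(t for t in TIME_LEVELS if t != BASELINE_TIME)
DIRECTIONS = ("up", "down", "ns")


def de_gene_set(
    counts: pd.DataFrame, min_count: int = 1, exclude=()
) -> list[str]:
    """Genes with count >= min_count in every sample, minus excluded genes."""
    exclude = set(exclude)
    keep = (counts.to_numpy() >= min_count).all(axis=1)
    return [g for g in counts.index[keep] if g not in exclude]


def run_mode_de(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    reference: SampleReference,
    alpha: float = 0.05,
    genes=None,
    include_volume: bool = False,
    n_quadrature: int = 5,
) -> pd.DataFrame:
    """Per-gene NB-GLMM DE for one mode; returns one row per gene x contrast.

    Columns: mode, gene_id, contrast, log_fc, se, z, p, adjusted_p,
    direction, fit_ok.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    samples = list(counts.columns)
    if list(reference.reference.index) != samples:
        raise StructuralError("sample reference does not match count columns")
    meta = meta.loc[samples]
    offset = np.log(reference.reference.to_numpy())
    X = time_design(meta, include_volume=include_volume)
    groups = meta["participant"].to_numpy()
    genes = list(genes) if genes is not None else list(counts.index)

    rows = []
    for gene in genes:
        y = counts.loc[gene].to_numpy()
        try:
            fit = fit_nb_glmm(y, X, groups, offset=offset, n_quadrature=n_quadrature)
            ok = fit.converged and not fit.degenerate
            table = wald_table(fit, list(CONTRASTS)) if ok else None
        except Exception:  # pragma: no cover - defensive, recorded not dropped
            ok, table = False, None
        for c in CONTRASTS:
            if ok and np.isfinite(table.loc[c, "p"]):
                rows.append(
                    {
                        "mode": reference.mode,
                        "gene_id": gene,
                        "contrast": c,
                        "log_fc": table.loc[c, "estimate"],
                        "se": table.loc[c, "se"],
                        "z": table.loc[c, "z"],
                        "p": table.loc[c, "p"],
                        "fit_ok": True,
                    }
                )
            else:
                rows.append(
                    {
                        "mode": reference.mode,
                        "gene_id": gene,
                        "contrast": c,
                        "log_fc": np.nan,
                        "se": np.nan,
                        "z": np.nan,
                        "p": np.nan,
                        "fit_ok": False,
                    }
                )
    res = pd.DataFrame(rows)
    # BH per contrast family across genes
    res["adjusted_p"] = np.nan
    for c in CONTRASTS:
        mask = (res["contrast"] == c) & res["fit_ok"]
        if mask.any():
            res.loc[mask, "adjusted_p"] = bh_adjust(res.loc[mask, "p"].to_numpy())
    sig = res["fit_ok"] & (res["adjusted_p"] < alpha)
    res["direction"] = "ns"
    res.loc[sig & (res["log_fc"] > 0), "direction"] = "up"
    res.loc[sig & (res["log_fc"] < 0), "direction"] = "down"
    n_failed = int((~res["fit_ok"]).sum())
    if n_failed:
        logger.warning(
            "%s: %d gene x contrast fits failed and are labelled ns",
            reference.mode,
            n_failed,
        )
    return res


@dataclass
class ModeComparison:
    membership: pd.DataFrame  # gene x contrast rows with one direction per mode
    pattern_counts: pd.DataFrame  # contrast x (direction triple) counts + pct
    direction_intersections: pd.DataFrame  # Fig-1C style per-direction sets
    conflicts: pd.DataFrame
    de_any_totals: dict


def compare_modes(results: dict[str, pd.DataFrame]) -> ModeComparison:
    """Combine per-mode DE tables into membership patterns and conflicts."""
    if set(results) != set(MODES):
        raise StructuralError(f"need results for all modes {MODES}")
    needed = ["gene_id", "contrast", "direction", "fit_ok"]
    results = {
        m: (
            r
            if all(c in r.columns for c in needed)
            else pd.DataFrame(columns=needed)
            if r.empty
            else r
        )
        for m, r in results.items()
    }
    base = None
    for mode in MODES:
        r = results[mode]
        key = r[["gene_id", "contrast"]].sort_values(["gene_id", "contrast"])
        if base is None:
            base = key.reset_index(drop=True)
        elif not base.equals(key.reset_index(drop=True)):
            raise StructuralError("modes cover different gene/contrast universes")

    wide = None
    for mode in MODES:
        r = results[mode][["gene_id", "contrast", "direction", "fit_ok"]].rename(
            columns={"direction": mode, "fit_ok": f"ok_{mode}"}
        )
        wide = r if wide is None else wide.merge(r, on=["gene_id", "contrast"])
    # joint failure rule: a gene x contrast failing in any mode is ns everywhere
    failed = ~(wide[[f"ok_{m}" for m in MODES]].all(axis=1))
    for m in MODES:
        wide.loc[failed, m] = "ns"
    wide["fit_failed_any"] = failed
    membership = wide[["gene_id", "contrast", *MODES, "fit_failed_any"]]

    de_any = membership[
        (membership[list(MODES)] != "ns").any(axis=1)
    ]
    de_any_totals = {
        c: int((de_any["contrast"] == c).sum()) for c in CONTRASTS
    }

    pat_rows = []
    for c in CONTRASTS:
        sub = de_any[de_any["contrast"] == c]
        total = len(sub)
        counts = (
            sub.groupby(list(MODES), observed=True).size().reset_index(name="count")
        )
        for _, row in counts.iterrows():
            rec = {"contrast": c, "count": int(row["count"])}
            for m in MODES:
                rec[m] = row[m]
            if total > 0:
                rec["pct_of_de_any"] = 100.0 * row["count"] / total
            pat_rows.append(rec)
    pattern_counts = pd.DataFrame(
        pat_rows, columns=["contrast", *MODES, "count", "pct_of_de_any"]
    )

    # Fig-1C style: per contrast and direction, which mode combination called it
    inter_rows = []
    for c in CONTRASTS:
        sub = de_any[de_any["contrast"] == c]
        total = len(sub)
        for d in ("up", "down"):
            flags = sub[list(MODES)].eq(d)
            called = flags.any(axis=1)
            combos = flags[called].apply(
                lambda r: "+".join(m for m in MODES if r[m]), axis=1
            )
            for combo, cnt in combos.value_counts().items():
                inter_rows.append(
                    {
                        "contrast": c,
                        "direction": d,
                        "modes": combo,
                        "count": int(cnt),
                        "pct_of_de_any": 100.0 * cnt / total if total else None,
                    }
                )
    direction_intersections = pd.DataFrame(
        inter_rows, columns=["contrast", "direction", "modes", "count", "pct_of_de_any"]
    )

    tri = membership[list(MODES)]
    conflict_mask = tri.eq("up").any(axis=1) & tri.eq("down").any(axis=1)
    conflicts = membership[conflict_mask].copy()
    return ModeComparison(
        membership=membership,
        pattern_counts=pattern_counts,
        direction_intersections=direction_intersections,
        conflicts=conflicts,
        de_any_totals=de_any_totals,
    )


def summarize_comparison(cmp: ModeComparison) -> dict:
    """Report tables plus upset-style plot data (JSON-serializable)."""
    plot_data = []
    for _, row in cmp.direction_intersections.iterrows():
        plot_data.append(
            {
                "contrast": row["contrast"],
                "direction": row["direction"],
                "set_membership": row["modes"].split("+"),
                "count": row["count"],
                "pct_of_de_any": row["pct_of_de_any"],
            }
        )
    return {
        "pattern_counts": cmp.pattern_counts,
        "direction_intersections": cmp.direction_intersections,
        "de_any_totals": cmp.de_any_totals,
        "n_conflicts": {
            c: int((cmp.conflicts["contrast"] == c).sum()) for c in CONTRASTS
        },
        "upset_data": plot_data,
    }


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineResult:
    config: PipelineConfig
    filtered_genes: list[str]
    stable_reports: dict[str, StableGeneReport]
    references: dict[str, SampleReference]
    ratio_estimates: list[RatioEstimate]
    de_universe: list[str]
    de_results: dict[str, pd.DataFrame]
    comparison: ModeComparison
    summary: dict


def mode_denominators(counts, meta, mode, config: PipelineConfig):
    factors = None
    if mode == PER_LIBRARY_SIZE:
        factors = tmm_factors(
            counts,
            trim_m=config.tmm_trim_m,
            trim_a=config.tmm_trim_a,
            min_count=config.tmm_min_count,
        )
    return denominators(
        counts,
        meta,
        mode,
        factors=factors,
        depth_correction=(
            config.total_rna_depth_correction if mode == PER_TOTAL_RNA else False
        ),
    )


def run_pipeline(
    counts: pd.DataFrame, meta: pd.DataFrame, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full three-viewpoint analysis on a count matrix + metadata."""
    from .io import validate_design

    config = config or PipelineConfig()
    counts, meta = validate_design(counts, meta)

    filtered = robust_filter(counts, config.min_count_stable)
    logger.info("robust filter keeps %d of %d genes", len(filtered), len(counts))

    stable_reports: dict[str, StableGeneReport] = {}
    references: dict[str, SampleReference] = {}
    for mode in MODES:
        denom = mode_denominators(counts, meta, mode, config)
        abund = cpm(counts, denom)
        filtered_abund = AbundanceMatrix(
            values=abund.values.loc[filtered], mode=abund.mode
        )
        logged = log_cpm(filtered_abund, base=config.log_base)
        report = screen_and_rank(
            logged,
            meta,
            t_threshold=config.t_threshold,
            top_k=config.top_k,
            include_volume=config.screen_include_volume,
            include_interactions=config.screen_include_interactions,
        )
        stable_reports[mode] = report
        # references live on the common count scale (per-fixed-RNA-input CPM):
        # stable genes' raw profiles carry each mode's denominator signal, so
        # the log reference is a valid offset on raw counts and cross-mode
        # ratios are meaningful
        references[mode] = sample_reference(
            counts.astype(float), report.top_k, mode=mode
        )
        logger.info(
            "%s: %d screen survivors, top-%d selected",
            mode,
            len(report.ranked),
            len(report.top_k),
        )

    ratio_estimates: list[RatioEstimate] = []
    for num, den in product(MODES, MODES):
        if num == den:
            continue
        ratio_estimates.extend(
            reference_ratio(references[num], references[den], meta)
        )

    exclude = set()
    for report in stable_reports.values():
        exclude.update(report.top_k)
    universe = de_gene_set(counts, config.min_count_de, exclude)
    logger.info("DE universe: %d genes (excluding %d stable)", len(universe),
                len(exclude))

    de_results = {
        mode: run_mode_de(
            counts,
            meta,
            references[mode],
            alpha=config.fdr_alpha,
            genes=universe,
            include_volume=config.de_include_volume,
            n_quadrature=config.n_quadrature,
        )
        for mode in MODES
    }
    comparison = compare_modes(de_results)
    summary = summarize_comparison(comparison)
    return PipelineResult(
        config=config,
        filtered_genes=filtered,
        stable_reports=stable_reports,
        references=references,
        ratio_estimates=ratio_estimates,
        de_universe=universe,
        de_results=de_results,
        comparison=comparison,
        summary=summary,
    )
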