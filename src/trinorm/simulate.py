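"""Synthetic repeated-measures RNA-seq studies with known per-viewpoint truth.

The generator emulates the statistical structure of a resistance-training
transcriptome study: P participants contribute both legs (biological
replicates trained at different volumes) at three time points (weeks 0/2/12),
with participant-specific random intercepts per gene, negative-binomially
dispersed counts, and a *global transcriptome amplification*: total RNA per
mg of tissue rises by the factor A_t (defaults 1.27 at week 2, 1.17 at week
12) and the mRNA pool rises with it.

Generative contract. Per-mg true abundance of gene g in sample s is

    T_gs = exp(alpha_g + u_g,p(s) + delta_g,t(s))

with the per-mg log fold-change delta carrying the amplification: designated
``tissue_stable`` genes keep delta = 0 (constant per mg), designated
``library_stable`` genes track the pool exactly (delta = log A_t, constant
mRNA-pool proportion), background genes track it with a per-gene wobble, and
``de`` genes add a persistent per-gene effect on top of the amplification.
The mRNA pool per mg is M_s = sum_g T_gs; with a fixed total-RNA input the
library reflects composition times depth, so expected counts are

    mu_gs = L_s * T_gs / M_s,        counts ~ NB(mu, phi_g),

with variance mu + phi * mu^2 (mean/dispersion parameterization). RNA yield
per mg Y_s tracks A_t with multiplicative log-normal noise, and sequencing
depth L_s is log-normal scaled by A_t — the observed library-size increase
that accompanies amplification, and the channel through which depth-sensitive
normalization modes can see the global change at all. Tissue mass is drawn
independently of time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    TIME_LEVELS,
    CONDITION_LEVELS,
    validate_metadata,
    write_counts,
    write_metadata,
    write_manifest,
)

GENE_CLASSES = ("tissue_stable", "library_stable", "de", "background")


class ParameterError(ValueError):
    """Invalid simulation parameter; the message names the offending field."""


@dataclass
class SimulationParams:
    """Study dimensions, amplification and noise levels for the generator.

    Defaults mirror the emulated study: 25 participants x 2 legs x 3 time
    points, 1000 ng of total RNA per library, and average total-RNA increases
    of 27% (week 2) and 17% (week 12) per mg of tissue.
    """

    n_participants: int = 25
    n_timepoints: int = 3
    legs_per_participant: int = 2
    n_genes: int = 2000
    amplification_per_time: tuple[float, ...] = (1.0, 1.27, 1.17)
    rna_input_ng: float = 1000.0
    # (meanlog, sdlog) of log-normals
    tissue_mass_distribution: tuple[float, float] = (log(3.0), 0.25)
    depth_distribution: tuple[float, float] = (log(1.5e6), 0.15)
    # (mean, sd) of baseline log abundance alpha_g
    baseline_log_abundance_distribution: tuple[float, float] = (3.0, 1.5)
    # gene-wise random-intercept sd ranges (uniform); designated stable genes
    # draw from the upper range — reference genes are participant-consistent
    participant_sd_range: tuple[float, float] = (0.05, 0.35)
    stable_participant_sd_range: tuple[float, float] = (0.4, 0.6)
    # (meanlog, sdlog) of the log-normal NB dispersion phi_g
    dispersion_distribution: tuple[float, float] = (log(0.05), 0.5)
    fraction_tissue_stable: float = 0.05
    fraction_library_stable: float = 0.05
    fraction_de: float = 0.15
    de_effect_sd: float = 0.5
    # per-gene, per-time wobble of background genes around global amplification
    background_instability_sd: float = 0.3
    rna_yield_noise_sd: float = 0.1
    rna_yield_per_mg_ng: float = 350.0
    # optional systematic moderate-volume effect on de genes (log scale)
    volume_effect_log_fc: float = 0.0
    seed: int = 0

    def validate(self) -> "SimulationParams":
        if self.n_participants < 2:
            raise ParameterError("n_participants must be >= 2")
        if self.n_genes < 2:
            raise ParameterError("n_genes must be >= 2")
        if self.legs_per_participant < 1:
            raise ParameterError("legs_per_participant must be >= 1")
        if self.legs_per_participant > len(CONDITION_LEVELS):
            raise ParameterError(
                f"legs_per_participant must be <= {len(CONDITION_LEVELS)}"
            )
        if self.n_timepoints != len(TIME_LEVELS):
            raise ParameterError(
                f"n_timepoints must be {len(TIME_LEVELS)} (labels {TIME_LEVELS})"
            )
        if len(self.amplification_per_time) != self.n_timepoints:
            raise ParameterError(
                "amplification_per_time must have one factor per time point"
            )
        if any(a <= 0 for a in self.amplification_per_time):
            raise ParameterError("amplification_per_time factors must be > 0")
        if self.amplification_per_time[0] != 1.0:
            raise ParameterError("amplification_per_time at baseline must be 1")
        for name in ("fraction_tissue_stable", "fraction_library_stable", "fraction_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if (
            self.fraction_tissue_stable
            + self.fraction_library_stable
            + self.fraction_de
            > 1.0
        ):
            raise ParameterError("gene-class fractions must sum to <= 1")
        for name in ("rna_input_ng", "rna_yield_per_mg_ng"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in (
            "de_effect_sd",
            "background_instability_sd",
            "rna_yield_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("participant_sd_range", "stable_participant_sd_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ParameterError(f"{name} must be an increasing non-negative range")
        return self


def default_params() -> SimulationParams:
    """Parameter set mirroring the emulated study's dimensions and amplification."""
    return SimulationParams().validate()


@dataclass
class SimulationTruth:
    """Ground truth under each of the three viewpoints.

    ``per_mg_log_fc`` holds delta (the per-tissue truth, exactly 0 at
    baseline); ``per_library_log_fc`` subtracts the log mRNA-pool ratio;
    ``per_total_rna_log_fc`` subtracts log A_t. ``sample_denominator_truth``
    records each sample's realized mRNA pool M_s, RNA yield per mg Y_s,
    sequencing depth L_s and tissue mass.
    """

    gene_class: pd.Series
    per_mg_log_fc: pd.DataFrame
    per_library_log_fc: pd.DataFrame
    per_total_rna_log_fc: pd.DataFrame
    participant_intercepts: pd.DataFrame
    sample_denominator_truth: pd.DataFrame
    baseline_log_abundance: pd.Series
    dispersion: pd.Series


@dataclass
class SimulatedStudy:
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: SimulationTruth
    params_used: SimulationParams


def _per_sample_true_abundance(
    params: SimulationParams, truth: SimulationTruth, metadata: pd.DataFrame
) -> np.ndarray:
    """T_gs = exp(alpha + u + delta [+ volume effect]) for every sample."""
    alpha = truth.baseline_log_abundance.to_numpy()
    u = truth.participant_intercepts
    delta = truth.per_mg_log_fc
    genes = truth.baseline_log_abundance.index
    is_de = (truth.gene_class == "de").to_numpy()
    T = np.empty((len(genes), len(metadata)))
    for j, (_, row) in enumerate(metadata.iterrows()):
        lp = (
            alpha
            + u[row["participant"]].to_numpy()
            + delta[str(row["time"])].to_numpy()
        )
        if (
            params.volume_effect_log_fc != 0.0
            and str(row["condition"]) == CONDITION_LEVELS[1]
            and str(row["time"]) != TIME_LEVELS[0]
        ):
            lp = lp + np.where(is_de, params.volume_effect_log_fc, 0.0)
        T[:, j] = np.exp(lp)
    return T


def expected_counts(
    params: SimulationParams, truth: SimulationTruth, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Analytic expected counts mu_gs = L_s * T_gs / M_s, the sampler's mean."""
    sd = truth.sample_denominator_truth
    if list(sd.index) != list(metadata["sample_id"]):
        raise ValueError("metadata and truth describe different samples")
    T = _per_sample_true_abundance(params, truth, metadata)
    M = T.sum(axis=0)
    L = sd["sequencing_depth"].to_numpy()
    mu = L * T / M
    return pd.DataFrame(
        mu, index=truth.baseline_log_abundance.index, columns=sd.index
    )


def simulate_study(params: SimulationParams, seed: int | None = None) -> SimulatedStudy:
    """Draw one study; identical (params, seed) give bit-identical output."""
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    G, P, T = params.n_genes, params.n_participants, params.n_timepoints
    a = np.log(np.asarray(params.amplification_per_time, dtype=float))

    genes = pd.Index([f"G{i + 1:05d}" for i in range(G)], name="gene_id")
    participants = [f"P{i + 1:02d}" for i in range(P)]

    # gene classes
    n_ts = int(round(params.fraction_tissue_stable * G))
    n_ls = int(round(params.fraction_library_stable * G))
    n_de = int(round(params.fraction_de * G))
    order = rng.permutation(G)
    gene_class = np.full(G, "background", dtype=object)
    gene_class[order[:n_ts]] = "tissue_stable"
    gene_class[order[n_ts : n_ts + n_ls]] = "library_stable"
    gene_class[order[n_ts + n_ls : n_ts + n_ls + n_de]] = "de"

    mean_a, sd_a = params.baseline_log_abundance_distribution
    alpha = rng.normal(mean_a, sd_a, size=G)
    lo, hi = params.participant_sd_range
    sigma_u = rng.uniform(lo, hi, size=G)
    designated = np.isin(gene_class, ("tissue_stable", "library_stable"))
    slo, shi = params.stable_participant_sd_range
    sigma_u[designated] = rng.uniform(slo, shi, size=int(designated.sum()))
    mlog, sdlog = params.dispersion_distribution
    phi = rng.lognormal(mlog, sdlog, size=G)

    # per-mg log fold-changes delta_g,t (baseline exactly 0)
    delta = np.zeros((G, T))
    is_bg = gene_class == "background"
    is_ls = gene_class == "library_stable"
    is_de = gene_class == "de"
    de_effect = rng.normal(0.0, params.de_effect_sd, size=G) * is_de
    for t in range(1, T):
        delta[is_ls, t] = a[t]
        delta[is_bg, t] = a[t] + rng.normal(
            0.0, params.background_instability_sd, size=int(is_bg.sum())
        )
        delta[is_de, t] = a[t] + de_effect[is_de]

    u = rng.normal(0.0, sigma_u[:, None], size=(G, P))

    # sample frame: participant x leg x time
    rows = []
    for pi, part in enumerate(participants):
        leg_conditions = rng.permutation(
            list(CONDITION_LEVELS[: params.legs_per_participant])
        )
        for li, cond in enumerate(leg_conditions):
            for ti, tlab in enumerate(TIME_LEVELS):
                rows.append(
                    {
                        "sample_id": f"{part}_L{li + 1}_{tlab}",
                        "participant": part,
                        "time": tlab,
                        "condition": cond,
                        "p_idx": pi,
                        "t_idx": ti,
                    }
                )
    frame = pd.DataFrame(rows)
    S = len(frame)
    t_idx = frame["t_idx"].to_numpy()

    mg = rng.lognormal(*params.tissue_mass_distribution, size=S)
    yield_noise = rng.lognormal(
        mean=0.0, sigma=params.rna_yield_noise_sd, size=S
    )
    Y = params.rna_yield_per_mg_ng * np.exp(a[t_idx]) * yield_noise
    depth = rng.lognormal(*params.depth_distribution, size=S) * np.exp(a[t_idx])

    metadata = validate_metadata(
        pd.DataFrame(
            {
                "sample_id": frame["sample_id"],
                "participant": frame["participant"],
                "time": frame["time"],
                "condition": frame["condition"],
                "tissue_mass_mg": mg,
                "rna_input_ng": params.rna_input_ng,
            }
        )
    )

    time_cols = list(TIME_LEVELS)
    pool = np.exp(alpha)[:, None] * np.exp(delta)  # population pool per time
    pool_ratio = np.log(pool.sum(axis=0) / pool[:, 0].sum())
    truth = SimulationTruth(
        gene_class=pd.Series(gene_class, index=genes, name="gene_class"),
        per_mg_log_fc=pd.DataFrame(delta, index=genes, columns=time_cols),
        per_library_log_fc=pd.DataFrame(
            delta - pool_ratio[None, :], index=genes, columns=time_cols
        ),
        per_total_rna_log_fc=pd.DataFrame(
            delta - a[None, :], index=genes, columns=time_cols
        ),
        participant_intercepts=pd.DataFrame(u, index=genes, columns=participants),
        sample_denominator_truth=pd.DataFrame(
            {
                "mrna_pool_per_mg": np.nan,  # filled below from realized T
                "rna_yield_per_mg_ng": Y,
                "sequencing_depth": depth,
                "tissue_mass_mg": mg,
                "time": frame["time"].to_numpy(),
            },
            index=pd.Index(frame["sample_id"], name="sample_id"),
        ),
        baseline_log_abundance=pd.Series(alpha, index=genes, name="alpha"),
        dispersion=pd.Series(phi, index=genes, name="dispersion"),
    )

    Tmat = _per_sample_true_abundance(params, truth, metadata)
    M = Tmat.sum(axis=0)
    truth.sample_denominator_truth["mrna_pool_per_mg"] = M
    mu = depth * Tmat / M

    r = 1.0 / phi[:, None]
    counts = rng.negative_binomial(n=r, p=r / (r + mu))
    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=genes, columns=metadata.index
    )
    return SimulatedStudy(
        counts=counts_df, metadata=metadata, truth=truth, params_used=params
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write counts TSV, metadata CSV, truth tables TSV and params JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(study.counts, out / "counts.tsv")
    write_metadata(study.metadata, out / "metadata.csv")
    t = study.truth
    gene_truth = pd.concat(
        [
            t.gene_class,
            t.baseline_log_abundance,
            t.dispersion,
            t.per_mg_log_fc.add_prefix("per_mg_log_fc_"),
            t.per_library_log_fc.add_prefix("per_library_log_fc_"),
            t.per_total_rna_log_fc.add_prefix("per_total_rna_log_fc_"),
        ],
        axis=1,
    )
    gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index_label="gene_id")
    t.sample_denominator_truth.to_csv(out / "truth_samples.tsv", sep="\t")
    t.participant_intercepts.to_csv(
        out / "truth_participant_intercepts.tsv", sep="\t", index_label="gene_id"
    )
    write_manifest(out / "params.json", **asdict(study.params_used))
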