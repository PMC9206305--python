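"""Per-sample denominators for the three normalization viewpoints.

The three modes express a transcript's counts relative to fundamentally
different quantities:

* ``per_library_size`` — counts per TMM-scaled total library count (the
  compositional viewpoint: abundance relative to the overall mRNA pool);
* ``per_total_rna`` — counts per fixed total-RNA input (a constant
  denominator, assuming the same RNA mass entered every library prep);
* ``per_sample_size`` — counts per mg of tissue the RNA was extracted from.

The trimmed-mean-of-M-values (TMM) scaling is implemented from scratch,
following the original algorithm (Robinson & Oshlack 2010): gene-wise log2
ratios of library-size-normalized proportions against a reference sample are
doubly trimmed (30% on M, 5% on A by default) and combined with inverse
binomial-variance weights; factors are anchored to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import StructuralError, logger

PER_LIBRARY_SIZE = "per_library_size"
PER_TOTAL_RNA = "per_total_rna"
PER_SAMPLE_SIZE = "per_sample_size"
MODES = (PER_LIBRARY_SIZE, PER_TOTAL_RNA, PER_SAMPLE_SIZE)


def check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; expected one of {MODES}")
    return mode


@dataclass
class DenominatorSet:
    """Per-sample denominators ``D_s`` for one normalization mode.

    ``components`` records the raw ingredients (library size, TMM factor,
    tissue mass or the constant) for transparency in emitted tables.
    """

    mode: str
    denominator: pd.Series
    components: pd.DataFrame

    def __post_init__(self):
        check_mode(self.mode)
        if (self.denominator <= 0).any() or not np.isfinite(self.denominator).all():
            raise ValueError("denominators must be positive and finite")


@dataclass
class AbundanceMatrix:
    """CPM-scale (or log-CPM) gene x sample abundances for one mode."""

    values: pd.DataFrame
    mode: str
    log_transformed: bool = False
    log_base: float | None = None

    @property
    def gene_ids(self):
        return self.values.index

    @property
    def sample_ids(self):
        return self.values.columns


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Column totals; a sample with zero total counts is degenerate."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad[:5]}")
    return totals.astype(float)


def _upper_quartile_reference(y: np.ndarray, lib: np.ndarray) -> int:
    # reference = sample whose upper-quartile proportion is closest to the
    # mean upper-quartile over samples
    f75 = np.quantile(y, 0.75, axis=0) / lib
    if np.min(f75) == 0:
        logger.warning("one or more samples have zero upper quartile; TMM reference "
                       "selection may be unstable")
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_one(obs, ref, lib_obs, lib_ref, trim_m, trim_a, min_count):
    keep = (obs >= min_count) & (ref >= min_count)
    if not keep.any():
        return None
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * (np.log2(po) + np.log2(pr))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # inverse binomial-variance precision weights (delta method)
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return None
    w = 1.0 / v[keep2]
    return float(2.0 ** (np.sum(m[keep2] * w) / np.sum(w)))


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_count: int = 1,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample against the reference, gene-wise M (log2 ratio of
    library-size-normalized proportions) and A (average log2 abundance) are
    computed over genes with at least ``min_count`` in both samples; the top
    and bottom ``trim_m`` of M and ``trim_a`` of A are discarded and the
    factor is 2**(precision-weighted mean of the surviving M values). Falls
    back to 1 (with a warning) when no genes survive.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    y = counts.to_numpy(dtype=float)
    lib = library_sizes(counts).to_numpy()
    if ref_sample is None:
        ref_idx = _upper_quartile_reference(y, lib)
    else:
        if ref_sample not in counts.columns:
            raise ValueError(f"reference sample {ref_sample!r} not in count matrix")
        ref_idx = counts.columns.get_loc(ref_sample)
    factors = np.ones(counts.shape[1])
    for s in range(counts.shape[1]):
        f = _tmm_one(y[:, s], y[:, ref_idx], lib[s], lib[ref_idx],
                     trim_m, trim_a, min_count)
        if f is None:
            logger.warning(
                "no genes survive TMM trimming for sample %s; factor set to 1",
                counts.columns[s],
            )
            f = 1.0
        factors[s] = f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def denominators(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str,
    factors: pd.Series | None = None,
    depth_correction: bool = False,
) -> DenominatorSet:
    """Build the per-sample denominator ``D_s`` for one mode.

    per_library_size: raw library size x TMM factor (``factors`` required);
    per_total_rna: the constant 1e6 (optionally rescaled by relative depth
    when ``depth_correction`` is on); per_sample_size: tissue mass x 1e6.
    """
    check_mode(mode)
    samples = list(counts.columns)
    comp = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    if mode == PER_LIBRARY_SIZE:
        if factors is None:
            raise ValueError("TMM factors are required for per_library_size")
        factors = factors.reindex(samples)
        if factors.isna().any():
            raise StructuralError("TMM factors do not cover all samples")
        lib = library_sizes(counts)
        denom = lib * factors
        comp["library_size"] = lib
        comp["tmm_factor"] = factors
    elif mode == PER_TOTAL_RNA:
        denom = pd.Series(1e6, index=samples)
        comp["constant"] = 1e6
        if depth_correction:
            lib = library_sizes(counts)
            rel = lib / np.exp(np.mean(np.log(lib)))
            denom = denom * rel
            comp["relative_depth"] = rel
    else:  # per_sample_size
        if "tissue_mass_mg" not in meta.columns:
            raise ValueError("per_sample_size requires tissue_mass_mg in metadata")
        mass = meta["tissue_mass_mg"].reindex(samples)
        if mass.isna().any():
            raise StructuralError("tissue mass missing for some samples")
        denom = mass * 1e6
        comp["tissue_mass_mg"] = mass
    denom.name = "denominator"
    return DenominatorSet(mode=mode, denominator=denom.astype(float), components=comp)


def cpm(
    counts: pd.DataFrame, denom: DenominatorSet, million_scale: bool = True
) -> AbundanceMatrix:
    """counts / D_s (x 1e6 when ``million_scale``), zero pattern preserved.

    The million rescaling is cosmetic: every downstream within-gene statistic
    (t, ICC, DE p-values) is invariant to a common scaling of the denominators.
    """
    missing = [s for s in counts.columns if s not in denom.denominator.index]
    if missing:
        raise StructuralError(f"denominators missing for samples: {missing[:5]}")
    d = denom.denominator.reindex(counts.columns).to_numpy()
    values = counts.to_numpy(dtype=float) / d
    if million_scale:
        values = values * 1e6
    return AbundanceMatrix(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        mode=denom.mode,
    )


def log_cpm(
    abund: AbundanceMatrix, base: float | None = None, pseudocount: float = 0.0
) -> AbundanceMatrix:
    """Elementwise log of a linear abundance matrix.

    With ``pseudocount=0`` every value must be positive; the robust-expression
    filter (minimum count per sample) guarantees this upstream.
    """
    if abund.log_transformed:
        raise ValueError("matrix is already log-transformed")
    v = abund.values.to_numpy() + pseudocount
    if (v <= 0).any():
        raise ValueError(
            "zero or negative values under log transform; apply the robust "
            "expression filter first or set a pseudocount"
        )
    out = np.log(v)
    if base is not None:
        out = out / np.log(base)
    return AbundanceMatrix(
        values=pd.DataFrame(out, index=abund.values.index, columns=abund.values.columns),
        mode=abund.mode,
        log_transformed=True,
        log_base=base if base is not None else float(np.e),
    )
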