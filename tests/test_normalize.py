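import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trinorm as tn
from trinorm.normalize import PER_LIBRARY_SIZE, PER_SAMPLE_SIZE, PER_TOTAL_RNA


def brute_force_tmm(counts, ref_idx, trim_m=0.30, trim_a=0.05, min_count=1):
    """Independent step-by-step TMM oracle (sorting/averaging written from the
    definition rather than via rankdata)."""
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)

    def avg_ranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    factors = []
    for s in range(y.shape[1]):
        obs, ref = y[:, s], y[:, ref_idx]
        keep = (obs >= min_count) & (ref >= min_count)
        o, r = obs[keep], ref[keep]
        po, pr = o / lib[s], r / lib[ref_idx]
        m = np.log2(po) - np.log2(pr)
        a = (np.log2(po) + np.log2(pr)) / 2.0
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        v = (lib[s] - o) / (lib[s] * o) + (lib[ref_idx] - r) / (lib[ref_idx] * r)
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm, ra = avg_ranks(m), avg_ranks(a)
        k2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2.0 ** (np.sum(m[k2] / v[k2]) / np.sum(1.0 / v[k2])))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


def test_library_sizes_basic_and_oracle(toy_counts):
    assert tn.library_sizes(pd.DataFrame({"s": [1, 2, 3]}))["s"] == 6
    doubled = tn.library_sizes(toy_counts * 2)
    assert np.allclose(doubled.to_numpy(), 2 * tn.library_sizes(toy_counts).to_numpy())
    assert np.allclose(
        tn.library_sizes(toy_counts).to_numpy(), toy_counts.to_numpy().sum(axis=0)
    )
    with pytest.raises(ValueError, match="all-zero"):
        tn.library_sizes(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


def test_tmm_identical_and_pure_depth_samples_give_unit_factors():
    base = pd.DataFrame(
        {"a": [10, 20, 30, 5], "b": [10, 20, 30, 5], "c": [30, 60, 90, 15]},
        index=list("wxyz"),
    )
    f = tn.tmm_factors(base)
    assert np.allclose(f.to_numpy(), 1.0)


def test_tmm_matches_frozen_edger_reference():
    # reference factors computed with edgeR 4.0 calcNormFactors(method="TMM")
    rng = np.random.default_rng(42)
    mu = rng.lognormal(4, 1, size=40)
    counts = np.vstack(
        [rng.negative_binomial(10, 10 / (10 + mu * f)) for f in (1.0, 1.4, 0.7, 1.0, 2.2)]
    ).T
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(40)], columns=list("ABCDE"))
    expected = np.array(
        [1.048724845743, 0.955032165646, 1.032099977121, 0.924736306317, 1.046118220935]
    )
    assert np.allclose(tn.tmm_factors(df).to_numpy(), expected, atol=1e-10)


def test_tmm_matches_bruteforce_oracle_on_random_matrices():
    rng = np.random.default_rng(7)
    for _ in range(25):
        g = rng.integers(20, 50)
        s = rng.integers(2, 6)
        counts = pd.DataFrame(
            rng.integers(0, 400, size=(g, s)) + rng.integers(0, 2, size=(g, s)),
            index=[f"g{i}" for i in range(g)],
            columns=[f"s{j}" for j in range(s)],
        )
        counts += 1  # keep libraries non-degenerate
        ref_idx = int(rng.integers(0, s))
        ours = tn.tmm_factors(counts, ref_sample=counts.columns[ref_idx])
        oracle = brute_force_tmm(counts, ref_idx)
        assert np.allclose(ours.to_numpy(), oracle, atol=1e-10)


def test_tmm_properties_geometric_mean_scaling_relabeling(toy_counts):
    counts = toy_counts + 1
    f = tn.tmm_factors(counts)
    assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)
    # common count scaling leaves factors unchanged
    f2 = tn.tmm_factors(counts * 3)
    assert np.allclose(f.to_numpy(), f2.to_numpy(), atol=1e-12)
    # relabeling samples permutes factors with them
    perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
    f3 = tn.tmm_factors(counts[perm])
    assert np.allclose(f3[f.index].to_numpy(), f.to_numpy(), atol=1e-12)


def test_denominators_per_mode(small_study):
    counts, meta = small_study.counts, small_study.metadata
    d_tot = tn.denominators(counts, meta, PER_TOTAL_RNA)
    assert np.allclose(d_tot.denominator.to_numpy(), 1e6)

    d_tis = tn.denominators(counts, meta, PER_SAMPLE_SIZE)
    assert np.allclose(
        d_tis.denominator.to_numpy(), meta["tissue_mass_mg"].to_numpy() * 1e6
    )

    ones = pd.Series(1.0, index=counts.columns)
    d_lib = tn.denominators(counts, meta, PER_LIBRARY_SIZE, factors=ones)
    assert np.allclose(
        d_lib.denominator.to_numpy(), tn.library_sizes(counts).to_numpy()
    )
    with pytest.raises(ValueError, match="TMM factors"):
        tn.denominators(counts, meta, PER_LIBRARY_SIZE)


def test_denominator_example_tissue_mass():
    counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["g1", "g2"])
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "participant": ["P01", "P01"],
            "time": ["week0", "week2"],
            "condition": ["low", "low"],
            "tissue_mass_mg": [2.5, 2.5],
        }
    ).set_index("sample_id", drop=False)
    d = tn.denominators(counts, meta, PER_SAMPLE_SIZE)
    assert np.allclose(d.denominator.to_numpy(), 2.5e6)


def test_cpm_values_and_zero_pattern(toy_counts, small_study):
    denom = tn.denominators(toy_counts, None, PER_TOTAL_RNA)
    ab = tn.cpm(toy_counts, denom)
    assert np.allclose(ab.values.to_numpy(), toy_counts.to_numpy())  # counts/1e6*1e6
    assert ((ab.values.to_numpy() == 0) == (toy_counts.to_numpy() == 0)).all()
    # brute-force elementwise division
    d = tn.denominators(
        small_study.counts, small_study.metadata, PER_SAMPLE_SIZE
    )
    ab2 = tn.cpm(small_study.counts, d)
    manual = (
        small_study.counts.to_numpy()
        / d.denominator.to_numpy()[None, :]
        * 1e6
    )
    assert np.allclose(ab2.values.to_numpy(), manual)


def test_log_cpm_examples_and_zero_error(toy_counts):
    denom = tn.denominators(toy_counts + 1, None, PER_TOTAL_RNA)
    ab = tn.cpm(toy_counts + 1, denom)
    logged = tn.log_cpm(ab)
    assert np.allclose(logged.values.to_numpy(), np.log(ab.values.to_numpy()))
    zero_ab = tn.cpm(toy_counts, tn.denominators(toy_counts, None, PER_TOTAL_RNA))
    if (toy_counts.to_numpy() == 0).any():
        with pytest.raises(ValueError, match="robust"):
            tn.log_cpm(zero_ab)


def test_downstream_invariance_to_log_base_and_denominator_scale(small_study):
    """t-values and ICC are unchanged by log base and common denominator scale."""
    counts = small_study.counts
    keep = tn.robust_filter(counts, 30)[:10]
    meta = small_study.metadata
    from trinorm.lmm import screening_design, condition_labels
    from trinorm.normalize import AbundanceMatrix

    denom = tn.denominators(counts, meta, PER_SAMPLE_SIZE)
    ab = tn.cpm(counts, denom)
    sub = AbundanceMatrix(values=ab.values.loc[keep], mode=ab.mode)
    scaled = AbundanceMatrix(values=ab.values.loc[keep] / 7.3, mode=ab.mode)
    X = screening_design(meta)
    labels = condition_labels(X)
    for gene in keep[:5]:
        f_e = tn.fit_reml(np.log(sub.values.loc[gene]), X, meta["participant"])
        f_2 = tn.fit_reml(np.log2(sub.values.loc[gene]), X, meta["participant"])
        f_s = tn.fit_reml(np.log(scaled.values.loc[gene]), X, meta["participant"])
        assert np.allclose(
            f_e.t_values[labels], f_2.t_values[labels], atol=1e-6
        )
        assert abs(f_e.icc - f_2.icc) < 1e-6
        assert np.allclose(f_e.t_values[labels], f_s.t_values[labels], atol=1e-6)
        assert abs(f_e.icc - f_s.icc) < 1e-6


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_cpm_zero_pattern_property(seed):
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.integers(0, 20, size=(8, 4)),
        index=[f"g{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(4)],
    )
    if (counts.sum(axis=0) == 0).any():
        counts.iloc[0] += 1
    ab = tn.cpm(counts, tn.denominators(counts, None, PER_TOTAL_RNA))
    assert ((ab.values.to_numpy() == 0) == (counts.to_numpy() == 0)).all()
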