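import numpy as np
import pandas as pd
import pytest

import trinorm as tn
from trinorm.simulate import ParameterError


def test_default_params_mirror_study_design():
    p = tn.default_params()
    assert p.n_participants == 25
    assert p.legs_per_participant == 2
    assert p.n_timepoints == 3
    assert p.amplification_per_time == (1.0, 1.27, 1.17)
    assert p.rna_input_ng == 1000


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_participants", 1),
        ("n_genes", 1),
        ("amplification_per_time", (1.0, -0.5, 1.1)),
        ("amplification_per_time", (1.2, 1.27, 1.17)),  # baseline must be 1
        ("fraction_de", 1.2),
        ("fraction_tissue_stable", 0.5),  # fractions sum > 1 with de=0.15+lib 0.5
        ("rna_input_ng", 0.0),
    ],
)
def test_invalid_params_rejected_naming_field(field, value):
    kwargs = {field: value}
    if field == "fraction_tissue_stable":
        kwargs["fraction_library_stable"] = 0.5
    with pytest.raises(ParameterError):
        tn.SimulationParams(**kwargs).validate()


def test_seeded_reproducibility():
    p = tn.SimulationParams(n_participants=4, n_genes=50)
    a = tn.simulate_study(p, seed=7)
    b = tn.simulate_study(p, seed=7)
    assert a.counts.equals(b.counts)
    assert a.truth.per_mg_log_fc.equals(b.truth.per_mg_log_fc)
    assert a.metadata.equals(b.metadata)
    c = tn.simulate_study(p, seed=8)
    assert not a.counts.equals(c.counts)


def test_study_dimensions_and_alignment(small_study):
    p = small_study.params_used
    n_samples = p.n_participants * p.legs_per_participant * p.n_timepoints
    assert small_study.counts.shape == (p.n_genes, n_samples)
    assert list(small_study.metadata.index) == list(small_study.counts.columns)
    assert (small_study.counts.to_numpy() >= 0).all()


def test_no_effect_case_gives_zero_truth_everywhere():
    p = tn.SimulationParams(
        n_participants=4,
        n_genes=40,
        amplification_per_time=(1.0, 1.0, 1.0),
        fraction_de=0.0,
        rna_yield_noise_sd=0.0,
        background_instability_sd=0.0,
    )
    st = tn.simulate_study(p, seed=1)
    assert np.allclose(st.truth.per_mg_log_fc.to_numpy(), 0)
    assert np.allclose(st.truth.per_library_log_fc.to_numpy(), 0)
    assert np.allclose(st.truth.per_total_rna_log_fc.to_numpy(), 0)


def test_truth_invariants(small_study):
    t = small_study.truth
    # baseline per-mg fold change exactly zero
    assert (t.per_mg_log_fc["week0"] == 0).all()
    cls = t.gene_class
    a = np.log(np.asarray(small_study.params_used.amplification_per_time))
    ts = t.per_mg_log_fc.loc[cls == "tissue_stable"]
    assert np.allclose(ts.to_numpy(), 0)
    ls = t.per_mg_log_fc.loc[cls == "library_stable"]
    assert np.allclose(ls.to_numpy(), np.tile(a, (len(ls), 1)))
    # stable-in-one-viewpoint genes drift in the other when the pool grows
    assert (t.per_library_log_fc.loc[cls == "tissue_stable", "week2"] < 0).all()
    assert (t.per_mg_log_fc.loc[cls == "library_stable", "week2"] > 0).all()


def test_expected_counts_conservation_and_trivial_cases(small_study):
    mu = tn.expected_counts(
        small_study.params_used, small_study.truth, small_study.metadata
    )
    depth = small_study.truth.sample_denominator_truth["sequencing_depth"]
    # sum_g mu_gs = L_s
    assert np.allclose(mu.sum(axis=0).to_numpy(), depth.to_numpy(), rtol=1e-12)

    # two genes with equal abundance split the library evenly
    p2 = tn.SimulationParams(
        n_participants=2,
        n_genes=2,
        baseline_log_abundance_distribution=(2.0, 0.0),
        participant_sd_range=(0.0, 0.0),
        stable_participant_sd_range=(0.0, 0.0),
        fraction_tissue_stable=0.0,
        fraction_library_stable=0.0,
        fraction_de=0.0,
        background_instability_sd=0.0,
        amplification_per_time=(1.0, 1.0, 1.0),
    )
    st2 = tn.simulate_study(p2, seed=2)
    mu2 = tn.expected_counts(p2, st2.truth, st2.metadata)
    L = st2.truth.sample_denominator_truth["sequencing_depth"]
    assert np.allclose(mu2.to_numpy(), (L.to_numpy() / 2)[None, :])


def test_expected_counts_matches_bruteforce_formula(small_study):
    st = small_study
    mu = tn.expected_counts(st.params_used, st.truth, st.metadata)
    t = st.truth
    genes = list(st.counts.index[:10])
    for s in list(st.counts.columns[:5]):
        row = st.metadata.loc[s]
        lp = (
            t.baseline_log_abundance
            + t.participant_intercepts[row["participant"]]
            + t.per_mg_log_fc[str(row["time"])]
        )
        T = np.exp(lp.to_numpy())
        L = t.sample_denominator_truth.loc[s, "sequencing_depth"]
        expect = L * T / T.sum()
        got = mu[s].to_numpy()
        assert np.allclose(got[:10], expect[: len(genes)][:10], rtol=1e-12)


def test_sampler_mean_matches_expected_counts():
    p = tn.SimulationParams(n_participants=3, n_genes=25)
    base = tn.simulate_study(p, seed=10)
    mu = tn.expected_counts(p, base.truth, base.metadata)
    g, s = base.counts.index[4], base.counts.columns[2]
    # redraw counts many times at the same latent state via fresh seeds of the
    # NB layer: use the analytic mean and MC error of the NB distribution
    phi = base.truth.dispersion[g]
    m = mu.loc[g, s]
    rng = np.random.default_rng(123)
    r = 1.0 / phi
    draws = rng.negative_binomial(r, r / (r + m), size=200)
    mc_se = np.sqrt((m + phi * m * m) / 200)
    assert abs(draws.mean() - m) < 3 * mc_se


def test_overdispersion_exceeds_poisson():
    p = tn.SimulationParams(
        n_participants=2,
        n_genes=10,
        participant_sd_range=(0.0, 0.0),
        stable_participant_sd_range=(0.0, 0.0),
        background_instability_sd=0.0,
        fraction_de=0.0,
        fraction_tissue_stable=0.0,
        fraction_library_stable=0.0,
        amplification_per_time=(1.0, 1.0, 1.0),
        depth_distribution=(np.log(2e5), 0.0),
        dispersion_distribution=(np.log(0.2), 0.0),
    )
    # with all latent variation off, gene-wise variance across replicate draws
    # must exceed the mean (phi > 0)
    rng = np.random.default_rng(0)
    st = tn.simulate_study(p, seed=3)
    mu = tn.expected_counts(p, st.truth, st.metadata)
    m = mu.iloc[0, 0]
    draws = rng.negative_binomial(1 / 0.2, (1 / 0.2) / (1 / 0.2 + m), size=4000)
    assert draws.var() > 1.5 * draws.mean()


def test_write_study_round_trip(tmp_path, small_study):
    tn.write_study(small_study, tmp_path)
    counts = tn.read_counts(tmp_path / "counts.tsv")
    meta = tn.read_metadata(tmp_path / "metadata.csv")
    assert counts.equals(small_study.counts)
    assert list(meta.index) == list(small_study.metadata.index)
    assert (tmp_path / "params.json").exists()
    assert (tmp_path / "truth_genes.tsv").exists()
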