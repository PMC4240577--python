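import numpy as np
import pandas as pd
import pytest

from _oracles import genorm_m_bruteforce, genorm_normalize_bruteforce
from vlcdprot.design import ITRAQ_CHANNELS, PlexLayout, QC
from vlcdprot.inference import build_incidence, infer_protein_groups
from vlcdprot.itraq import (
    complete_case_filter,
    compute_peptide_ratios,
    genorm_normalize,
    genorm_stability,
    rollup_protein_ratios,
)
from vlcdprot.simulate import (
    EffectConfig,
    make_peptide_map,
    simulate_itraq_intensities,
    simulate_truth,
)


def one_plex(samples=("s1", "s2", "s3", "s4", "s5", "s6")):
    cmap = {113: QC, 117: QC}
    for chan, s in zip((114, 115, 116, 118, 119, 121), samples):
        cmap[chan] = s
    return PlexLayout("plex01", cmap)


def reporter_row(i113, i117, i114, peptide="pep1", spectrum="sp1"):
    row = {"plex_id": "plex01", "peptide_id": peptide, "spectrum_id": spectrum}
    vals = {113: i113, 117: i117, 114: i114}
    for chan in ITRAQ_CHANNELS:
        row[str(chan)] = vals.get(chan, 1000.0)
    return row


class TestPeptideRatios:
    def test_identity_ratio(self):
        rep = pd.DataFrame([reporter_row(1000.0, 1000.0, 1000.0)])
        out = compute_peptide_ratios(rep, [one_plex()])
        got = out[out["sample_id"] == "s1"]["ratio"].iloc[0]
        assert got == pytest.approx(1.0, abs=1e-15)

    def test_mean_of_two_qc_ratios(self):
        rep = pd.DataFrame([reporter_row(400.0, 600.0, 800.0)])
        out = compute_peptide_ratios(rep, [one_plex()])
        got = out[out["sample_id"] == "s1"]["ratio"].iloc[0]
        assert got == pytest.approx(0.5 * (800 / 400 + 800 / 600), rel=1e-12)
        assert got == pytest.approx(1.6667, abs=5e-5)

    def test_spectra_collapse_to_median(self):
        rep = pd.DataFrame([
            reporter_row(1000.0, 1000.0, 1000.0, spectrum="sp1"),
            reporter_row(1000.0, 1000.0, 3000.0, spectrum="sp2"),
        ])
        out = compute_peptide_ratios(rep, [one_plex()])
        got = out[out["sample_id"] == "s1"]
        assert got["ratio"].iloc[0] == pytest.approx(2.0)
        assert got["n_spectra"].iloc[0] == 2

    def test_missing_qc_rows_dropped_and_counted(self):
        rep = pd.DataFrame([
            reporter_row(np.nan, 1000.0, 500.0, spectrum="sp1"),
            reporter_row(0.0, 1000.0, 500.0, spectrum="sp2"),
            reporter_row(1000.0, 1000.0, 500.0, spectrum="sp3"),
        ])
        out = compute_peptide_ratios(rep, [one_plex()])
        assert out.attrs["n_dropped_spectra"] == 2
        assert len(out[out["sample_id"] == "s1"]) == 1

    def test_all_rows_dropped_is_an_error(self):
        rep = pd.DataFrame([reporter_row(0.0, 1000.0, 500.0)])
        with pytest.raises(RuntimeError, match="QC"):
            compute_peptide_ratios(rep, [one_plex()])

    def test_plex_wide_scaling_cancels_exactly(self):
        rng = np.random.default_rng(0)
        rows = [reporter_row(*rng.uniform(100, 2000, 3), peptide=f"pep{i}")
                for i in range(20)]
        rep = pd.DataFrame(rows)
        scaled = rep.copy()
        scaled[[str(c) for c in ITRAQ_CHANNELS]] *= 7.3
        a = compute_peptide_ratios(rep, [one_plex()])
        b = compute_peptide_ratios(scaled, [one_plex()])
        assert np.allclose(a["ratio"], b["ratio"], rtol=1e-14, atol=0)


class TestRollup:
    def _quant(self, ratios_by_peptide):
        rows = [("plex01", pep, "s1", r, 1)
                for pep, rs in ratios_by_peptide.items() for r in rs]
        pr = pd.DataFrame(rows, columns=["plex_id", "peptide_id", "sample_id",
                                         "ratio", "n_spectra"])
        # collapse spectra first, as compute_peptide_ratios would have
        pr = (pr.groupby(["plex_id", "peptide_id", "sample_id"], sort=True)
              ["ratio"].agg(ratio="median", n_spectra="size").reset_index())
        pairs = [(pep, "A") for pep in ratios_by_peptide]
        groups = infer_protein_groups(build_incidence(pairs))
        return rollup_protein_ratios(pr, groups)

    def test_median_of_peptides(self):
        q = self._quant({"pep1": [1.0], "pep2": [1.2], "pep3": [2.0]})
        assert q.abundance.iloc[0, 0] == pytest.approx(1.2)
        assert q.n_peptides.iloc[0, 0] == 3

    def test_single_peptide_identity(self):
        q = self._quant({"pep1": [0.71]})
        assert q.abundance.iloc[0, 0] == pytest.approx(0.71)

    def test_outlier_moves_median_at_most_one_order_statistic(self):
        base = {"pep1": [0.9], "pep2": [1.0], "pep3": [1.1], "pep4": [1.3],
                "pep5": [1.5]}
        ref = self._quant(base).abundance.iloc[0, 0]
        vals = sorted(v[0] for v in base.values())
        max_gap = max(b - a for a, b in zip(vals, vals[1:]))
        poisoned = dict(base, pep5=[1e6])
        got = self._quant(poisoned).abundance.iloc[0, 0]
        assert abs(got - ref) <= max_gap + 1e-12


class TestGenorm:
    def test_proportional_proteins_have_zero_pairwise_variation(self, rng):
        base = rng.uniform(0.5, 2.0, 6)
        m = pd.DataFrame([base, 2 * base, rng.uniform(0.5, 2.0, 6)],
                         index=["a", "b", "c"])
        state = genorm_stability(m)
        assert state.pairwise_v.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_column_multiplier_leaves_stability_unchanged(self, rng):
        m = pd.DataFrame(rng.uniform(0.5, 2.0, (4, 5)))
        state1 = genorm_stability(m)
        m2 = m.copy()
        m2[2] *= 3.7
        state2 = genorm_stability(m2)
        pd.testing.assert_series_equal(state1.m_values, state2.m_values)

    @pytest.mark.parametrize("shape", [(3, 4), (5, 6)])
    def test_matches_bruteforce_oracle(self, rng, shape):
        m = pd.DataFrame(rng.uniform(0.3, 3.0, shape))
        state = genorm_stability(m)
        assert np.allclose(state.m_values.to_numpy(),
                           genorm_m_bruteforce(m.to_numpy()), atol=1e-12)
        normed, _ = genorm_normalize(m, state)
        assert np.allclose(normed.to_numpy(),
                           genorm_normalize_bruteforce(m.to_numpy()), atol=1e-12)

    def test_single_sample_scaling_removed_exactly(self, rng):
        m = pd.DataFrame(rng.uniform(0.3, 3.0, (8, 6)))
        ref, _ = genorm_normalize(m, genorm_stability(m))
        m2 = m.copy()
        m2[3] *= 2.0
        got, _ = genorm_normalize(m2, genorm_stability(m2))
        assert np.allclose(got.to_numpy(), ref.to_numpy(), rtol=1e-12)

    def test_preserve_scale_keeps_constant_matrix_fixed(self):
        cols = list(range(5))
        m = pd.DataFrame({c: [1.4, 0.7, 1.0, 2.0] for c in cols})
        state = genorm_stability(m)
        out, _ = genorm_normalize(m, state, scale="preserve")
        assert np.allclose(out.to_numpy(), m.to_numpy(), rtol=1e-12)

    def test_requires_three_complete_proteins(self):
        m = pd.DataFrame(np.ones((2, 4)))
        with pytest.raises(ValueError, match="3 complete"):
            genorm_stability(m)
        m3 = pd.DataFrame(np.ones((3, 4)))
        m3.iloc[2, 0] = np.nan
        with pytest.raises(ValueError, match="3 complete"):
            genorm_stability(m3)


class TestCompleteCase:
    def test_no_missing_keeps_everything(self, study_design):
        cols = [s.sample_id for s in study_design.samples]
        ab = pd.DataFrame(1.0, index=[f"g{i}" for i in range(5)], columns=cols)
        kept, counts = complete_case_filter(ab, study_design)
        assert counts.n_total == counts.n_complete == counts.n_analyzed == 5

    def test_one_missing_week16_value_drops_protein(self, study_design):
        cols = [s.sample_id for s in study_design.samples]
        ab = pd.DataFrame(1.0, index=["g1", "g2"], columns=cols)
        week16 = [s.sample_id for s in study_design.patient_samples
                  if s.timepoint == "WEEK16"][0]
        ab.loc["g2", week16] = np.nan
        kept, counts = complete_case_filter(ab, study_design)
        assert list(kept.index) == ["g1"]
        assert (counts.n_total, counts.n_complete, counts.n_analyzed) == (2, 1, 1)

    def test_internal_controls_excluded_after_completeness(self, study_design):
        cols = [s.sample_id for s in study_design.patient_samples]
        ab = pd.DataFrame(1.0, index=[f"g{i}" for i in range(234)], columns=cols)
        kept, counts = complete_case_filter(ab, study_design,
                                            internal_controls=["g0", "g1"])
        assert (counts.n_total, counts.n_complete, counts.n_analyzed) == (234, 234, 232)


def test_end_to_end_noise_free_recovery(study_design, study_layouts):
    """With no measurement noise the planted group contrasts come back exactly."""
    cfg = EffectConfig(
        n_proteins=12, diabetes={"PROT0001": 0.23}, diet={"PROT0002": -0.5},
        sigma_b=0.0, sigma_e=0.0, sigma_peptide=0.3, sigma_plex=0.1,
        sigma_channel=0.0, dropout=0.0,
    )
    truth = simulate_truth(study_design, cfg, seed=21)
    pm = make_peptide_map(truth.proteins, seed=22)
    rep = simulate_itraq_intensities(study_layouts, truth, pm, study_design, seed=23)
    pr = compute_peptide_ratios(rep, study_layouts)
    groups = infer_protein_groups(build_incidence(pm))
    quant = rollup_protein_ratios(pr, groups)
    t0 = [s.sample_id for s in study_design.patient_samples
          if s.timepoint == "BASELINE"]
    t16 = [s.sample_id for s in study_design.patient_samples
           if s.timepoint == "WEEK16"]
    gmean = lambda df: 2 ** np.log2(df).mean(axis=1)  # noqa: E731
    # the diabetes effect is shared by every patient sample, so the
    # patient-derived QC pool absorbs it: the protein sits at exactly 1
    diab = gmean(quant.abundance.loc[["PROT0001"], t0])
    assert float(diab.iloc[0]) == pytest.approx(1.0, rel=1e-9)
    # the diet effect is a within-patient contrast and is fully recoverable:
    # pool mean is -0.25, so baseline sits at 2^0.25 and the change is 2^-0.5
    diet_t0 = gmean(quant.abundance.loc[["PROT0002"], t0])
    assert float(diet_t0.iloc[0]) == pytest.approx(2 ** 0.25, rel=1e-9)
    diet_change = (gmean(quant.abundance.loc[["PROT0002"], t16])
                   / gmean(quant.abundance.loc[["PROT0002"], t0]))
    assert float(diet_change.iloc[0]) == pytest.approx(2 ** -0.5, rel=1e-9)
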