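"""Generator contracts: determinism, noise-free exactness, planted structure."""

import numpy as np
import pandas as pd
import pytest

from atroprot import quant
from atroprot.synthetic import (ARCHETYPE_TEMPLATES, ConfigError, GeneratorConfig,
                                generate_annotations, generate_expression_study,
                                generate_pulse_study, generate_site_study)


class TestExpressionStudy:
    def test_same_seed_bit_identical(self, small_cfg):
        t1, d1, g1 = generate_expression_study(small_cfg)
        t2, d2, g2 = generate_expression_study(small_cfg)
        pd.testing.assert_frame_equal(t1.light, t2.light)
        pd.testing.assert_frame_equal(t1.hl_ratio, t2.hl_ratio)
        pd.testing.assert_frame_equal(g1.delta, g2.delta)

    def test_regulated_count_matches_fraction(self):
        cfg = GeneratorConfig(n_proteins=1000, frac_regulated=0.1,
                              n_atrogene_up=10, n_atrogene_down=10, seed=1)
        _, _, truth = generate_expression_study(cfg)
        assert truth.proteins["regulated"].sum() == 100
        assert len(truth.regulated_ids) == 100

    def test_heavy_standard_constant_across_samples(self, small_study):
        table, _, _ = small_study
        assert (table.heavy.nunique(axis=1) == 1).all()

    def test_noise_free_ratio_of_ratios_is_exact_delta(self, noise_free_study):
        table, design, truth = noise_free_study
        norm = quant.normalize_sample_ratios(table)
        prof = quant.build_time_profiles(quant.fold_change_table(norm))
        err = (prof.values - truth.delta).abs().to_numpy()
        assert np.nanmax(err) < 1e-12

    def test_single_regulated_protein_noise_free_doubles_at_peak(self):
        # delta = 1 at the template peak -> den/ctrl ratio-of-ratios exactly 2
        cfg = GeneratorConfig(n_proteins=10, frac_regulated=0.1, effect_log2=1.0,
                              noise_sd_log2=0.0, frac_missing=0.0,
                              n_atrogene_up=0, n_atrogene_down=0,
                              templates={"early_up": ARCHETYPE_TEMPLATES["early_up"]},
                              profile_archetypes=1, seed=3)
        table, design, truth = generate_expression_study(cfg)
        pid = truth.regulated_ids[0]
        norm = quant.normalize_sample_ratios(table)
        fold = quant.fold_change_table(norm)
        day7 = fold[7.0].loc[pid]     # early_up template = 1.0 at day 7
        assert np.allclose(2.0 ** day7.to_numpy(), 2.0, atol=1e-12)

    def test_nonregulated_have_zero_delta(self, small_study):
        _, _, truth = small_study
        null = ~truth.proteins["regulated"]
        assert (truth.delta.loc[null] == 0).all().all()

    def test_null_ratio_of_ratios_marginal_sd(self):
        # two light measurements share no noise: log2 RoR SD = sqrt(2)*sigma
        cfg = GeneratorConfig(n_proteins=2000, frac_regulated=0.0,
                              n_atrogene_up=0, n_atrogene_down=0,
                              noise_sd_log2=0.3, frac_missing=0.0, seed=9)
        table, design, _ = generate_expression_study(cfg)
        fold = quant.fold_change_table(quant.normalize_sample_ratios(table))
        vals = fold.to_numpy().ravel()
        sd = np.nanstd(vals)
        assert abs(sd - np.sqrt(2) * 0.3) < 0.02
        assert abs(np.nanmean(vals)) < 0.01

    def test_too_many_atrogenes_rejected(self):
        with pytest.raises(ConfigError, match="atrogenes"):
            GeneratorConfig(n_proteins=100, frac_regulated=0.1,
                            n_atrogene_up=20, n_atrogene_down=0)

    def test_zero_regulated_with_archetypes_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_proteins=10, frac_regulated=0.01,
                            n_atrogene_up=0, n_atrogene_down=0)


class TestPulseStudy:
    def test_noise_free_matches_one_pool_closed_form(self):
        cfg = GeneratorConfig(n_proteins=50, noise_sd_log2=0.0, frac_missing=0.0,
                              n_atrogene_up=5, n_atrogene_down=5, seed=4)
        table, design, truth = generate_pulse_study(cfg)
        hl = table.hl_ratio
        for _, s in design.frame.iterrows():
            k = truth.proteins["k_den" if s["condition"] == "denervated" else "k_ctrl"]
            f = 1.0 - np.exp(-k * s["time_day"])
            expected = f / (1.0 - f)
            assert np.allclose(hl[s["sample_id"]], expected, rtol=1e-12)

    def test_k_point_example(self):
        # k=0.1/day at t=7: f = 1 - e^-0.7, H/L = f/(1-f) = e^0.7 - 1
        f = 1.0 - np.exp(-0.7)
        assert abs(f - 0.5034147) < 1e-6
        assert abs(f / (1 - f) - (np.exp(0.7) - 1.0)) < 1e-12

    def test_rate_shifted_subset_has_gamma(self):
        cfg = GeneratorConfig(n_proteins=500, frac_rate_shifted=0.1,
                              rate_shift_factor=2.0, seed=5)
        _, _, truth = generate_pulse_study(cfg)
        gamma = truth.proteins["gamma"]
        assert (gamma == 2.0).sum() == 50
        assert ((gamma == 1.0) | (gamma == 2.0)).all()
        shifted = truth.proteins["k_den"] / truth.proteins["k_ctrl"]
        assert np.allclose(shifted, gamma)

    def test_gamma_subset_auc_ordering_noise_free(self):
        from atroprot.incorporation import incorporation_auc
        cfg = GeneratorConfig(n_proteins=100, noise_sd_log2=0.0, frac_missing=0.0,
                              frac_rate_shifted=0.5, rate_shift_factor=2.0,
                              n_atrogene_up=5, n_atrogene_down=5, seed=6)
        _, _, truth = generate_pulse_study(cfg)
        t = np.array(cfg.time_days_pulse)
        for _, row in truth.proteins[truth.proteins["gamma"] > 1].iterrows():
            auc_c = incorporation_auc(t, 1 - np.exp(-row["k_ctrl"] * t))
            auc_d = incorporation_auc(t, 1 - np.exp(-row["k_den"] * t))
            assert auc_d > auc_c


class TestSiteStudy:
    def test_u_zero_sites_track_protein_noise_free(self):
        cfg = GeneratorConfig(n_proteins=100, noise_sd_log2=0.0, frac_missing=0.0,
                              frac_sites_regulated=0.0, frac_proteins_with_sites=0.5,
                              n_atrogene_up=5, n_atrogene_down=5, seed=7)
        table, design, truth = generate_expression_study(cfg)
        st = generate_site_study(cfg, table, truth)
        dsg = st.design.frame.set_index("sample_id")
        for sid in st.log2_ratio.columns:
            t = dsg.loc[sid, "time_day"]
            prot = truth.delta.loc[st.sites["protein_id"], t].to_numpy()
            assert np.allclose(st.log2_ratio[sid].to_numpy(), prot)

    def test_planted_u_offsets_site_from_protein(self):
        cfg = GeneratorConfig(n_proteins=100, noise_sd_log2=0.0, frac_missing=0.0,
                              frac_sites_regulated=1.0, site_effect_log2=1.0,
                              frac_proteins_with_sites=0.5,
                              n_atrogene_up=5, n_atrogene_down=5, seed=8)
        table, design, truth = generate_expression_study(cfg)
        st = generate_site_study(cfg, table, truth)
        sid = st.log2_ratio.columns[0]
        t = st.design.frame.set_index("sample_id").loc[sid, "time_day"]
        prot = truth.delta.loc[st.sites["protein_id"], t].to_numpy()
        resid = st.log2_ratio[sid].to_numpy() - prot
        assert np.allclose(np.abs(resid), 1.0)
        assert (truth.sites["u"] != 0).all()

    def test_total_sites_near_shifted_poisson_expectation(self):
        cfg = GeneratorConfig(n_proteins=1200, sites_per_protein_mean=3.5,
                              frac_proteins_with_sites=0.5, seed=9)
        table, design, truth = generate_expression_study(cfg)
        st = generate_site_study(cfg, table, truth)
        n_prot = 600
        mean = 3.5                       # 1 + Poisson(2.5)
        sd = np.sqrt(n_prot * 2.5)       # variance of the Poisson part
        assert abs(len(st.sites) - n_prot * mean) < 3 * sd


class TestAnnotations:
    def test_planted_down_term_pure(self):
        cfg = GeneratorConfig(n_proteins=500, seed=10)
        _, _, truth = generate_expression_study(cfg)
        ann = generate_annotations(cfg, truth, term_size=30, purity=1.0)
        down_reg = set(truth.proteins.index[(truth.proteins["regulated"])
                                            & (truth.delta.mean(axis=1) < 0)])
        assert ann.terms["DOWN:00"] <= down_reg
        assert len(ann.terms["DOWN:00"]) == 30

    def test_null_term_overlap_near_regulated_fraction(self):
        cfg = GeneratorConfig(n_proteins=2000, frac_regulated=0.2, seed=11)
        _, _, truth = generate_expression_study(cfg)
        ann = generate_annotations(cfg, truth, n_null_terms=50, term_size=40)
        reg = set(truth.regulated_ids)
        overlaps = [len(ann.terms[t] & reg) / len(ann.terms[t])
                    for t in ann.terms if t.startswith("NULL")]
        # binomial mean 0.2, SE of the mean over 50 terms ~ 0.009
        assert abs(np.mean(overlaps) - 0.2) < 0.03

    def test_seed_fixes_membership(self):
        cfg = GeneratorConfig(n_proteins=300, seed=12)
        _, _, truth = generate_expression_study(cfg)
        a1 = generate_annotations(cfg, truth)
        a2 = generate_annotations(cfg, truth)
        assert a1.terms == a2.terms
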