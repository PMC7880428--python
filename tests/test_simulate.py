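"""The synthetic pooled-survey generator: structure, scale and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from geoadditive import (
    GeneratorConfig,
    draw_truth,
    inject_missingness,
    listwise_deletion,
    make_lattice_graph,
    simulate_dataset,
)
from geoadditive.simulate import read_truth, write_truth


def zeroed_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(
        intercept=0.0,
        fixed_effects={k: {l: 0.0 for l in v} for k, v in
                       GeneratorConfig().fixed_effects.items()},
        tau2_str=0.0, tau2_unstr=0.0, tau2_xi=0.0, sd_age=0.0, sd_year=0.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class TestDrawTruth:
    def test_reproducible(self, lattice66):
        a = draw_truth(lattice66, seed=9)
        b = draw_truth(lattice66, seed=9)
        assert np.array_equal(a.f_str, b.f_str)
        assert np.array_equal(a.xi, b.xi)
        assert a.f_year == b.f_year

    def test_all_components_centred(self, lattice66):
        t = draw_truth(lattice66, seed=4)
        assert abs(t.f_str.mean()) < 1e-10
        assert abs(t.f_unstr.mean()) < 1e-10
        assert abs(t.f_age.mean()) < 1e-10
        assert abs(np.mean(list(t.f_year.values()))) < 1e-10
        assert abs(t.xi.mean()) < 1e-10

    def test_zero_variance_gives_zero_component(self, lattice66):
        t = draw_truth(lattice66, zeroed_config(), seed=1)
        assert np.all(t.f_str == 0) and np.all(t.xi == 0)

    def test_negative_variance_rejected(self, lattice66):
        with pytest.raises(ValueError):
            draw_truth(lattice66, zeroed_config(tau2_str=-1.0), seed=0)

    def test_truth_roundtrip(self, lattice66, tmp_path):
        t = draw_truth(lattice66, seed=2)
        write_truth(t, tmp_path / "truth.json")
        t2 = read_truth(tmp_path / "truth.json")
        assert np.allclose(t.f_str, t2.f_str) and t.f_year == t2.f_year


class TestSimulateDataset:
    def test_zero_model_gives_half_prevalence(self, lattice66):
        truth = draw_truth(lattice66, zeroed_config(), seed=1)
        tab = simulate_dataset(truth, lattice66, n_mothers=8000, seed=2)
        n = len(tab)
        assert abs(tab["fgm"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_intercept_sets_national_scale(self, lattice66):
        """logit^-1(-1.1) = 0.2497, the 2016 national prevalence scale."""
        truth = draw_truth(lattice66, zeroed_config(intercept=-1.1), seed=1)
        tab = simulate_dataset(truth, lattice66, n_mothers=12000, seed=3)
        target = float(expit(-1.1))
        assert abs(tab["fgm"].mean() - target) < 3 * np.sqrt(target * (1 - target) / len(tab))

    def test_mother_cut_odds_ratio_recovered(self, lattice66):
        """Empirical 2x2-table odds ratio matches the stated log-odds coefficient."""
        cfg = zeroed_config(intercept=-2.0)
        cfg.fixed_effects["mother_cut"]["Yes"] = np.log(18.0)
        truth = draw_truth(lattice66, cfg, seed=1)
        tab = simulate_dataset(truth, lattice66, n_mothers=40000, seed=4)
        ct = pd.crosstab(tab["mother_cut"], tab["fgm"])
        or_hat = (ct.loc["Yes", 1] * ct.loc["No", 0]) / (ct.loc["Yes", 0] * ct.loc["No", 1])
        assert or_hat == pytest.approx(18.0, rel=0.15)

    def test_girls_share_mother_covariates(self, lattice66):
        truth = draw_truth(lattice66, seed=5)
        tab = simulate_dataset(truth, lattice66, n_mothers=500, seed=6)
        per_mother = tab.groupby("mother_id")[["state", "education", "mother_cut"]].nunique()
        assert (per_mother <= 1).all().all()
        assert len(tab) / tab["mother_id"].nunique() == pytest.approx(1.7, abs=0.15)

    def test_prevalence_monotone_in_intercept(self, lattice66):
        prev = []
        for b0 in (-2.0, -1.0, 0.0, 1.0):
            truth = draw_truth(lattice66, zeroed_config(intercept=b0), seed=1)
            prev.append(simulate_dataset(truth, lattice66, 3000, seed=7)["fgm"].mean())
        assert all(a < b for a, b in zip(prev, prev[1:]))

    def test_survey_design_respected(self, lattice66):
        truth = draw_truth(lattice66, seed=8)
        design = {2008: ("DHS", 0.5), 2016: ("MICS", 0.5)}
        tab = simulate_dataset(truth, lattice66, 2000, survey_design=design, seed=9)
        assert set(tab["year"]) == {2008, 2016}
        assert set(tab.loc[tab.year == 2016, "survey"]) == {"MICS"}

    def test_bad_shares_rejected(self, lattice66):
        truth = draw_truth(lattice66, seed=8)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_dataset(truth, lattice66, 100,
                             survey_design={2008: ("DHS", 0.9)}, seed=0)

    def test_empty_design_rejected(self, lattice66):
        truth = draw_truth(lattice66, seed=8)
        with pytest.raises(ValueError, match="at least one mother"):
            simulate_dataset(truth, lattice66, 0, seed=0)

    def test_weights_positive_mean_one(self, lattice66):
        truth = draw_truth(lattice66, seed=5)
        tab = simulate_dataset(truth, lattice66, 4000, seed=10)
        w = tab.drop_duplicates("mother_id")["weight"]
        assert (w > 0).all() and w.mean() == pytest.approx(1.0, abs=0.05)


class TestMissingness:
    def test_rate_zero_unchanged(self, lattice66):
        truth = draw_truth(lattice66, seed=5)
        tab = simulate_dataset(truth, lattice66, 300, seed=11)
        out = inject_missingness(tab, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, tab)

    def test_rate_within_binomial_error(self, lattice66):
        truth = draw_truth(lattice66, seed=5)
        tab = simulate_dataset(truth, lattice66, 3000, seed=12)
        out = inject_missingness(tab, 0.1, seed=2, columns=("education", "residence"))
        n_cells = 2 * len(out)
        n_missing = int(out[["education", "residence"]].isna().sum().sum())
        assert abs(n_missing - 0.1 * n_cells) < 3 * np.sqrt(n_cells * 0.1 * 0.9)
        assert out["fgm"].notna().all()

    def test_rate_one_rejected(self, lattice66):
        truth = draw_truth(lattice66, seed=5)
        tab = simulate_dataset(truth, lattice66, 10, seed=0)
        with pytest.raises(ValueError):
            inject_missingness(tab, 1.0, seed=0)

    def test_listwise_deletion_matches_row_scan(self, lattice66):
        """Deletion drops exactly the rows a per-row scan flags as incomplete."""
        truth = draw_truth(lattice66, seed=5)
        tab = simulate_dataset(truth, lattice66, 800, seed=13)
        out = inject_missingness(tab, 0.15, seed=3)
        cols = ("education", "residence", "mother_cut", "support", "mother_age")
        kept, n_dropped = listwise_deletion(out, cols)
        flagged = [
            i for i in range(len(out))
            if any(pd.isna(out.iloc[i][c]) for c in cols)
        ]
        assert n_dropped == len(flagged)
        assert kept[list(cols)].notna().all().all()
        assert len(kept) + n_dropped == len(out)
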