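"""Panel generation, causal-SNP selection, risk calibration, stratification."""

import numpy as np
import pytest
from scipy import stats

from hapscan.design import pack_codes, tabulate_haplotypes
from hapscan.simulate import (
    CausalSpec,
    PanelConfig,
    StratConfig,
    balding_nichols_fst,
    calibrate_rr,
    filter_perfect_duplicates,
    pick_causal,
    simulate_case_control,
    simulate_panel,
    simulate_stratified,
)
from hapscan.simulate import _cc_allele_freqs, _power_at_rr


SMALL = dict(n_haplotypes=300, length=80_000.0)


class TestPanel:
    def test_deterministic_under_seed(self):
        a = simulate_panel(PanelConfig(seed=9, **SMALL))
        b = simulate_panel(PanelConfig(seed=9, **SMALL))
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)

    def test_duplicate_filter(self):
        col = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        X = np.column_stack([col, col, 1 - col, 1 - np.roll(col, 2)])
        keep = filter_perfect_duplicates(X)
        assert keep.tolist() == [True, False, False, True]

    def test_common_site_density(self, euro_panel):
        # roughly 955 common (MAF >= 0.05) sites per Mb expected for
        # European-calibrated panels; allow a factor of two either way
        assert 955 / 2 <= euro_panel.n_common <= 955 * 2

    def test_minor_coded(self, euro_panel):
        assert euro_panel.allele_freqs().max() <= 0.5


class TestPickCausal:
    def test_scheme_a_layout(self, euro_panel):
        spec = pick_causal(euro_panel, "typed", 0.25, 5, seed=4)
        assert spec.causal_col not in spec.marker_cols
        assert len(spec.marker_cols) == 6
        assert abs(spec.causal_freq - 0.25) <= 0.05 + 1e-9
        # causal physically between markers 3 and 4
        pos = euro_panel.positions
        assert pos[spec.marker_cols[2]] < pos[spec.causal_col] < pos[spec.marker_cols[3]]

    def test_scheme_b_single_marker_haplotype(self, euro_panel):
        spec = pick_causal(euro_panel, "haplotype", 0.25, 5, seed=4)
        carriers = spec.causal_allele == 1
        codes = pack_codes(euro_panel.alleles[np.ix_(np.flatnonzero(carriers), spec.marker_cols)])
        assert len(np.unique(codes)) == 1  # exactly one marker haplotype
        # frequency equals the closest marker-haplotype frequency
        table = tabulate_haplotypes(euro_panel.alleles[:, spec.marker_cols])
        assert spec.causal_freq == pytest.approx(
            table.freqs[np.argmin(np.abs(table.freqs - 0.25))]
        )

    def test_scheme_a_causal_on_multiple_haplotypes(self, euro_panel):
        spec = pick_causal(euro_panel, "typed", 0.25, 5, seed=4)
        carriers = spec.causal_allele == 1
        codes = pack_codes(euro_panel.alleles[np.ix_(np.flatnonzero(carriers), spec.marker_cols)])
        assert len(np.unique(codes)) >= 1

    def test_no_eligible_site_error(self, euro_panel):
        with pytest.raises(ValueError, match="nearest"):
            pick_causal(euro_panel, "typed", 0.49999, 5, seed=1, rel_tol=1e-6)


class TestCalibrateRR:
    def test_null_power_is_alpha(self):
        assert _power_at_rr(0.25, 1.0, 1500, 1500, 0.05, 0.1, "allelic") == pytest.approx(
            0.05, abs=1e-6
        )

    def test_monotone_in_maf(self):
        rrs = [calibrate_rr(m) for m in (0.005, 0.025, 0.25)]
        assert rrs[0] > rrs[1] > rrs[2] > 1.0

    def test_calibrated_power_round_trip(self, euro_panel, rng):
        # the calibrated RR must reproduce ~80% empirical power for the
        # direct 1-df allelic test of the causal SNP itself
        spec = pick_causal(euro_panel, "typed", 0.25, 5, seed=4)
        rr = calibrate_rr(spec.causal_freq)
        reps = 250
        crit = stats.chi2.ppf(0.95, 1)
        hits = 0
        for _ in range(reps):
            g = np.random.default_rng(int(rng.integers(1, 2**31)))
            risk = np.where(spec.causal_allele == 1, 0.1 * rr, 0.1)
            disease = g.random(len(risk)) < risk
            cases = np.flatnonzero(disease)
            ctrls = np.flatnonzero(~disease)
            case_alleles = spec.causal_allele[g.choice(cases, 1500, replace=False)]
            ctrl_alleles = spec.causal_allele[g.choice(ctrls, 1500, replace=False)]
            tab = np.array(
                [
                    [case_alleles.sum(), 1500 - case_alleles.sum()],
                    [ctrl_alleles.sum(), 1500 - ctrl_alleles.sum()],
                ]
            )
            chi2 = stats.chi2_contingency(tab, correction=False)[0]
            hits += chi2 > crit
        power = hits / reps
        se = np.sqrt(0.8 * 0.2 / reps)
        assert abs(power - 0.8) < 3 * se + 0.02


class TestCaseControl:
    def test_null_rr_no_frequency_difference(self, euro_panel, rng):
        spec = pick_causal(euro_panel, "typed", 0.25, 5, seed=4)
        diffs = []
        for _ in range(40):
            alleles, y = simulate_case_control(
                euro_panel, spec, 1.0, seed=int(rng.integers(1, 2**31))
            )
            diffs.append(alleles[y.y == 1].mean() - alleles[y.y == 0].mean())
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 1e-3

    def test_odds_ratio_approaches_rr_for_rare_disease(self):
        pc, pt = _cc_allele_freqs(0.2, 3.0, 0.01)
        odds_ratio = (pc / (1 - pc)) / (pt / (1 - pt))
        assert odds_ratio == pytest.approx(3.0, rel=0.03)

    def test_extreme_rr_all_carriers_cases(self, euro_panel):
        spec = pick_causal(euro_panel, "typed", 0.25, 5, seed=4)
        pc, _ = _cc_allele_freqs(spec.causal_freq, 99.0, 0.01)
        assert pc > 0.9


class TestStratified:
    def test_frequency_construction(self):
        cfg = StratConfig(delta=0.08, mu=0.08)
        pats = cfg.patterns
        f1, f2 = cfg.freqs(1), cfg.freqs(2)
        assert f1.sum() == pytest.approx(1.0) and f2.sum() == pytest.approx(1.0)
        # SNP 1 differs by exactly delta; SNPs 2 and 3 are identical
        snp_freq = lambda f, j: f @ pats[:, j]
        assert snp_freq(f1, 0) - snp_freq(f2, 0) == pytest.approx(0.08)
        assert snp_freq(f1, 1) == pytest.approx(snp_freq(f2, 1))
        assert snp_freq(f1, 2) == pytest.approx(snp_freq(f2, 2))
        # haplotypes 1 and 2 differ at SNP 1 only
        assert pats[0, 0] != pats[1, 0] and np.array_equal(pats[0, 1:], pats[1, 1:])

    def test_dataset_shape_and_labels(self):
        gm, y, labels = simulate_stratified(StratConfig(), seed=2)
        assert gm.n_individuals == 1000 and gm.n_snps == 3
        assert (labels == 1).sum() == (labels == 2).sum() == 500
        assert set(np.unique(y.y)) <= {0, 1}

    def test_snp1_frequency_difference(self, rng):
        cfg = StratConfig(delta=0.1, mu=0.0)
        diffs = []
        for _ in range(60):
            gm, _, labels = simulate_stratified(cfg, seed=int(rng.integers(1, 2**31)))
            f1 = gm.dosage[labels == 1, 0].mean() / 2
            f2 = gm.dosage[labels == 2, 0].mean() / 2
            diffs.append(f1 - f2)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs) - 0.1) < 3 * se + 1e-3

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            StratConfig(background_freqs=(0.2, 0.05, 0.05, 0.05, 0.05))


class TestFst:
    def test_equal_frequencies_zero(self):
        assert balding_nichols_fst(0.3, 0.3) == 0.0

    def test_known_value(self):
        got = balding_nichols_fst(0.35, 0.30)
        assert got == pytest.approx(0.025**2 / (0.325 * 0.675), rel=1e-9)

    def test_symmetry_and_boundary(self):
        assert balding_nichols_fst(0.2, 0.4) == balding_nichols_fst(0.4, 0.2)
        with pytest.raises(ValueError):
            balding_nichols_fst(0.0, 0.5)
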