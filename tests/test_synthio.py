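import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deaseq import chemistry, synthio
from deaseq.synthio import (
    FORWARD_PRIMER,
    REVERSE_PRIMER,
    SPIKEIN_TEMPLATE,
    SimConfig,
    SimConfigError,
    inject_noise_sites,
    ko_truth,
    make_spikeins,
    plant_modifications,
    simulate_counts,
    simulate_de_calls,
    simulate_expression,
    simulate_reference,
)

COMP = str.maketrans("ACGT", "TGCA")


class TestReference:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(genome_length=100_000, n_chromosomes=1, n_genes=20)
        outputs = []
        for run in range(2):
            genome, genes, intervals = simulate_reference(cfg, seed=7)
            p = tmp_path / f"g{run}.fa"
            genome.to_fasta(p)
            outputs.append(p.read_bytes())
        assert outputs[0] == outputs[1]

    def test_gc_fraction_within_one_percent(self):
        cfg = SimConfig(genome_length=1_000_000, n_chromosomes=1, n_genes=0, gc_fraction=0.64)
        genome, _, _ = simulate_reference(cfg, seed=1)
        assert 0.63 <= genome.gc_fraction() <= 0.65

    def test_zero_genes_degenerate(self):
        cfg = SimConfig(genome_length=50_000, n_chromosomes=1, n_genes=0)
        genome, genes, _ = simulate_reference(cfg, seed=2)
        assert genes == []
        assert genome.lengths == {"chr1": 50_000}

    def test_genes_non_overlapping_and_in_bounds(self):
        cfg = SimConfig(genome_length=200_000, n_chromosomes=2, n_genes=30)
        genome, genes, intervals = simulate_reference(cfg, seed=3)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
            assert 0 <= g.start < g.end <= genome.lengths[g.chrom]
        for spans in by_chrom.values():
            spans.sort()
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))
        for name, ivset in intervals.items():
            for chrom, ivs in ivset.intervals.items():
                assert all(0 <= s < e <= genome.lengths[chrom] for s, e in ivs)

    def test_infeasible_packing_is_config_error(self):
        cfg = SimConfig(genome_length=2_000, n_chromosomes=1, n_genes=10)
        with pytest.raises(SimConfigError, match="pack"):
            simulate_reference(cfg, seed=0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(gc_fraction=1.2)


class TestPlanting:
    def test_gmc_density_matches_configured_ppm(self, small_sim):
        truth, cfg = small_sim["truth"], small_sim["cfg"]
        realized = 1e6 * (truth["state"] == "5gmC").sum() / len(truth)
        assert abs(realized - cfg.gmc_ppm) / cfg.gmc_ppm <= 0.2

    def test_exclusive_fraction_recovered(self, small_sim):
        truth, cfg = small_sim["truth"], small_sim["cfg"]
        gmc = truth[truth["state"] == "5gmC"]
        excl = (gmc["f_mc2"] == 0).mean()
        assert abs(excl - cfg.gmc_exclusive_fraction) <= 0.1

    def test_full_exclusivity_forced(self, small_sim):
        cfg = SimConfig(
            genome_length=100_000, n_chromosomes=1, n_genes=10,
            gmc_ppm=500, gmc_exclusive_fraction=1.0,
        )
        genome, genes, iv = simulate_reference(cfg, seed=21)
        truth = plant_modifications(genome, genes, iv, cfg, seed=22)
        assert (truth.loc[truth["state"] == "5gmC", "f_mc2"] == 0).all()

    def test_all_probabilities_zero_gives_pure_c(self):
        cfg = SimConfig(
            genome_length=50_000, n_chromosomes=1, n_genes=5,
            mc_prob={"CG": 0.0, "CHG": 0.0, "CHH": 0.0}, gmc_ppm=0.0,
        )
        genome, genes, iv = simulate_reference(cfg, seed=23)
        truth = plant_modifications(genome, genes, iv, cfg, seed=24)
        assert (truth["state"] == "C").all()
        assert (truth["f"] == 0).all()

    def test_infeasible_ppm_is_config_error(self, small_sim):
        cfg = SimConfig(
            genome_length=50_000, n_chromosomes=1, n_genes=5,
            gmc_ppm=999_999.0,
            gmc_context_weights={"CG": 0.0, "CHG": 0.0, "CHH": 1.0},
        )
        genome, genes, iv = simulate_reference(cfg, seed=25)
        with pytest.raises(SimConfigError, match="eligible"):
            plant_modifications(genome, genes, iv, cfg, seed=26)

    def test_cpg_methylation_rate_exceeds_chh(self, small_sim):
        truth = small_sim["truth"]
        rate = (
            truth.assign(is_mc=truth["state"] == "5mC")
            .groupby("context", observed=True)["is_mc"]
            .mean()
        )
        assert rate["CG"] > rate["CHH"]

    def test_gmc_prefers_chh_and_introns(self, small_sim):
        truth = small_sim["truth"]
        gmc = truth[truth["state"] == "5gmC"]
        assert (gmc["context"] == "CHH").mean() > 0.5
        assert gmc["in_intron"].mean() > truth["in_intron"].mean()

    def test_state_fraction_invariants(self, small_sim):
        truth = small_sim["truth"]
        assert (truth.loc[truth["state"] == "C", "f"] == 0).all()
        assert (truth.loc[truth["f"] > 0, "state"] != "C").all()
        assert ((truth["f"] + truth["f_mc2"]) <= 1.0 + 1e-12).all()
        assert (truth.loc[truth["state"] != "5gmC", "f_mc2"] == 0).all()

    def test_deterministic_given_seed(self, small_sim):
        cfg, genome, genes, iv = (
            small_sim["cfg"], small_sim["genome"], small_sim["genes"], small_sim["intervals"],
        )
        again = plant_modifications(genome, genes, iv, cfg, seed=12)
        pd.testing.assert_frame_equal(again, small_sim["truth"])


class TestCounts:
    def test_depth_conservation(self, small_records):
        for rec in small_records.values():
            assert (rec["n_unconverted"] + rec["n_converted"] == rec["depth"]).all()

    @pytest.mark.parametrize(
        "state,f,f_mc2,profile,p_expected",
        [
            ("C", 0.0, 0.0, chemistry.dea_profile(0.002), 0.002),
            ("5gmC", 1.0, 0.0, chemistry.dea_profile(0.002), 1.0),
            ("5mC", 1.0, 0.0, chemistry.wgbs_profile(), 1.0),
            ("5mC", 1.0, 0.0, chemistry.tetbs_profile(escape_dispersion=None), 0.03),
            ("5gmC", 0.6, 0.3, chemistry.wgbs_profile(0.002), 0.6 + 0.3 + 0.1 * 0.002),
            ("5mC", 0.5, 0.0, chemistry.dea_profile(0.002), 0.002),
        ],
    )
    def test_unconverted_fraction_matches_chemistry_oracle(self, state, f, f_mc2, profile, p_expected):
        """Empirical unconverted fraction over >= 1e5 draws matches the
        analytic mixture probability within 3 binomial standard errors."""
        truth = pd.DataFrame(
            {
                "chrom": ["chr1"], "pos": [5], "strand": ["+"], "context": ["CG"],
                "trinucleotide": ["CGA"], "state": [state], "f": [f], "f_mc2": [f_mc2],
            }
        )
        rec = simulate_counts(truth, profile, seed=9, depth=200_000)
        phat = rec["ratio"].iloc[0]
        se = np.sqrt(max(p_expected * (1 - p_expected), 1e-12) / 200_000)
        assert abs(phat - p_expected) <= max(3 * se, 1e-6)

    def test_deterministic_given_seed(self, small_sim):
        cfg, truth = small_sim["cfg"], small_sim["truth"]
        a = simulate_counts(truth, chemistry.dea_profile(), cfg, seed=42)
        b = simulate_counts(truth, chemistry.dea_profile(), cfg, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_ko_truth_is_fully_unmodified(self, small_sim):
        ko = ko_truth(small_sim["truth"])
        assert (ko["state"] == "C").all() and (ko["f"] == 0).all()

    def test_noise_injection_creates_callable_sites(self, small_records):
        from deaseq.calling import call_gmc_sites

        noisy = inject_noise_sites(small_records["ko"], 25, seed=3)
        called = call_gmc_sites(noisy)
        assert len(called) >= 20  # most injected sites pass the default filter


class TestSpikeins:
    def test_template_is_the_480bp_fragment(self):
        spikes = make_spikeins()
        assert len(spikes.template) == 480
        assert spikes.template == SPIKEIN_TEMPLATE

    def test_template_flanked_by_pcr_primers(self):
        assert SPIKEIN_TEMPLATE.startswith(FORWARD_PRIMER)
        rev_site = REVERSE_PRIMER.translate(COMP)[::-1]
        assert SPIKEIN_TEMPLATE.endswith(rev_site)

    def test_amplicon_truth_fully_methylated(self):
        spikes = make_spikeins()
        truth = spikes.truth()
        amp = truth[truth["chrom"] == "spikein_mc480"]
        assert (amp["state"] == "5mC").all() and (amp["f"] == 1.0).all()
        lam = truth[truth["chrom"] == "spikein_lambda"]
        assert (lam["state"] == "C").all() and (lam["f"] == 0.0).all()
        # every C of the template on both strands is represented
        assert len(amp) == SPIKEIN_TEMPLATE.count("C") + SPIKEIN_TEMPLATE.count("G")

    def test_control_fragment_is_constant(self):
        a, b = make_spikeins(), make_spikeins()
        assert a.sequences == b.sequences


@pytest.fixture(scope="module")
def assoc():
    cfg = SimConfig.for_association()
    genome, genes, iv = simulate_reference(cfg, seed=31)
    truth = plant_modifications(genome, genes, iv, cfg, seed=32)
    return cfg, genes, truth


class TestExpression:
    def test_null_coefficients_break_the_link(self, assoc):
        cfg, genes, truth = assoc
        from dataclasses import replace

        null_cfg = replace(cfg, expr_gmc_coef=0.0, expr_mc_coef=0.0)
        rhos_gmc, rhos_mc = [], []
        for seed in (33, 34, 35, 36, 37):
            expr = simulate_expression(truth, genes, null_cfg, seed=seed)
            assert len(expr) == len(genes) >= 500
            rhos_gmc.append(stats.spearmanr(expr["gmc_first_third"], expr["fpkm"])[0])
            rhos_mc.append(stats.spearmanr(expr["mc_gene"], expr["fpkm"])[0])
        # each draw is within sampling noise of zero; the average is tighter
        assert np.all(np.abs(rhos_gmc) < 0.15) and abs(np.mean(rhos_gmc)) < 0.05
        assert np.all(np.abs(rhos_mc) < 0.15) and abs(np.mean(rhos_mc)) < 0.05

    def test_positive_gmc_link_recovered(self, assoc):
        cfg, genes, truth = assoc
        expr = simulate_expression(truth, genes, cfg, seed=3)
        rho, p = stats.spearmanr(expr["gmc_first_third"], expr["fpkm"])
        assert rho > 0 and p < 0.05

    def test_negative_mc_link_recovered(self, assoc):
        cfg, genes, truth = assoc
        expr = simulate_expression(truth, genes, cfg, seed=3)
        rho, p = stats.spearmanr(expr["mc_gene"], expr["fpkm"])
        assert rho < 0 and p < 0.05


def test_de_call_rates_recovered():
    ids = [f"g{i}" for i in range(5_000)]
    has_gmc = np.arange(5_000) < 2_500
    de = simulate_de_calls(ids, has_gmc, seed=8)
    frac_with = (de["status"][:2_500] == "down").mean()
    frac_without = (de["status"][2_500:] == "down").mean()
    assert frac_with == pytest.approx(0.20, abs=0.03)
    assert frac_without == pytest.approx(0.14, abs=0.03)
    assert frac_with > frac_without
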