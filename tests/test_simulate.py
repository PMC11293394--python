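import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from nfkbdep.motifs import scan_homodimer
from nfkbdep.simulate import (
    ARCHETYPE_SHAPES,
    GeneratorParams,
    assign_gene_truth,
    generate_genome,
    generate_peaks,
    generate_sequences,
    simulate,
)


class TestParams:
    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorParams(class_proportions=(0.5, 0.1, 0.1, 0.1, 0.1, 0.2))

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            GeneratorParams(n_genes=0)

    def test_empty_chrom_sizes_rejected(self):
        with pytest.raises(ValueError, match="chrom_sizes"):
            GeneratorParams(chrom_sizes={})


class TestGenome:
    def test_deterministic_under_seed(self):
        p = GeneratorParams(n_genes=100, rng_seed=4)
        a = generate_genome(p)
        b = generate_genome(p)
        pd.testing.assert_frame_equal(a, b)

    def test_tss_within_declared_chromosomes(self):
        p = GeneratorParams(n_genes=500, rng_seed=1)
        anno = generate_genome(p)
        for row in anno.itertuples():
            assert 0 <= row.tss < p.chrom_sizes[row.chrom]
        assert (anno["length_kb"] > 0).all()


class TestExpressionGeneration:
    def test_full_simulation_deterministic(self):
        a = simulate(GeneratorParams(n_genes=80, n_peaks=120, rng_seed=9))
        b = simulate(GeneratorParams(n_genes=80, n_peaks=120, rng_seed=9))
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.peaks.signal, b.peaks.signal)

    def test_count_rpkm_consistency(self, small_study):
        libs = small_study.expr_libraries.set_index(
            ["genotype", "stimulus", "timepoint", "replicate"]
        )["library_millions"]
        lengths = small_study.annotation.set_index("gene_id")["length_kb"]
        v = small_study.expression.values
        recomputed = v["count"].to_numpy() / (
            lengths.loc[v["gene_id"]].to_numpy()
            * libs.loc[list(zip(v["genotype"], v["stimulus"], v["timepoint"], v["replicate"]))].to_numpy()
        )
        np.testing.assert_allclose(recomputed, v["rpkm"].to_numpy(), rtol=1e-6)

    def test_null_effect_ratio_gives_unit_ko_wt_ratio(self):
        params = GeneratorParams(n_genes=400, effect_ratio=1.0, rng_seed=3)
        study = simulate(params)
        table = study.expression
        codep = study.truth.gene_class.index[study.truth.gene_class == "codependent"]
        wt = table.rpkm("WT", "lipidA", 6.0)
        ko = table.rpkm("Nfkb1KO", "lipidA", 6.0)
        ratios = (ko.loc[codep] + 0.1) / (wt.loc[codep] + 0.1)
        assert ratios.mean() == pytest.approx(1.0, abs=0.15)

    def test_codependent_genes_collapse_in_both_knockouts(self, default_study):
        # planted effect 0.15 -> realized ratio < 0.33 at >=1 timepoint in
        # >=95% of codependent genes
        table = default_study.expression
        truth = default_study.truth
        codep = truth.gene_class.index[truth.gene_class == "codependent"]
        ok = 0
        for ko_gt in ("Nfkb1KO", "NfkbizKO"):
            below = []
            for t in (1.0, 2.0, 6.0):
                wt = table.rpkm("WT", "lipidA", t).loc[codep]
                ko = table.rpkm(ko_gt, "lipidA", t).loc[codep]
                below.append((ko / wt.clip(lower=0.5)) < 0.33)
            frac = pd.concat(below, axis=1).any(axis=1).mean()
            assert frac >= 0.95

    def test_tnf_tracks_lipid_a_times_planted_factor(self, default_study):
        table = default_study.expression
        truth = default_study.truth
        strong = truth.tnf_factor.index[truth.tnf_factor < 1 / 30]
        lip = table.rpkm("WT", "lipidA", 2.0).loc[strong]
        tnf = table.rpkm("WT", "TNF", 2.0).loc[strong]
        expressed = lip > 10
        realized = (tnf[expressed] + 0.1) / (lip[expressed] + 0.1)
        planted = truth.tnf_factor.loc[strong][expressed]
        # median realized/planted ratio near 1 (counting noise + pseudocount)
        assert np.median(realized / planted) == pytest.approx(1.0, rel=0.5)


class TestPeakGeneration:
    def test_ikbz_archetype_is_late(self, default_study):
        sig = default_study.peaks.signal
        member = default_study.peaks.membership
        ikbz = member.index[member["IkBz"]]
        early = sig.loc[ikbz, [c for c in sig.columns if c.startswith("IkBz:0h") or c.startswith("IkBz:0.5h") or c.startswith("IkBz:1h")]]
        late = sig.loc[ikbz, [c for c in sig.columns if c.startswith("IkBz:2h:") and c.endswith(":WT")]]
        assert early.mean().mean() <= 0.12 * late.mean().mean()

    def test_planted_dependent_peaks_fall_in_strong_band(self, default_study):
        sig = default_study.peaks.signal
        truth = default_study.truth
        dep = truth.peak_dependence.index[truth.peak_dependence == "ikbz_p50_dependent"]
        wt = sig.loc[dep, [c for c in sig.columns if c.startswith("IkBz:2h:") and c.endswith(":WT")]].mean(axis=1)
        ko = sig.loc[dep, [c for c in sig.columns if c.startswith("IkBz:2h:") and c.endswith(":Nfkb1KO")]].mean(axis=1)
        ratios = (ko + 0.1) / (wt + 0.1)
        assert (ratios < 0.33).mean() >= 0.9

    def test_two_seeds_distribution_matched(self):
        params1 = GeneratorParams(n_peaks=2000, n_genes=200, rng_seed=21)
        params2 = GeneratorParams(n_peaks=2000, n_genes=200, rng_seed=22)
        s1 = simulate(params1).peaks.signal
        s2 = simulate(params2).peaks.signal
        col = "RelA:1h:r1:WT"
        a = s1[col][s1[col] > 0]
        b = s2[col][s2[col] > 0]
        assert not np.array_equal(a.to_numpy()[: len(b)], b.to_numpy()[: len(a)])
        assert ks_2samp(a, b).pvalue > 0.01

    def test_peaks_are_disjoint(self, default_study):
        frame = pd.DataFrame(
            [(p.chrom, p.start, p.end) for p in default_study.peaks.peaks],
            columns=["chrom", "start", "end"],
        ).sort_values(["chrom", "start"])
        same_chrom = frame["chrom"].eq(frame["chrom"].shift())
        assert (frame["start"][same_chrom] >= frame["end"].shift()[same_chrom]).all()


class TestSequences:
    def test_window_length_exact(self, small_study):
        assert all(len(s) == small_study.params.motif_window_bp for s in small_study.sequences.values())

    def test_planted_windows_contain_motif(self, small_study):
        truth = small_study.truth
        planted = truth.motif_planted.index[truth.motif_planted]
        for pid in planted:
            assert scan_homodimer(small_study.sequences[pid])

    def test_background_rate_matches_closed_form(self):
        # per-position match probability (1/4)^6, both strands, w-10 positions
        params = GeneratorParams(
            n_genes=10,
            n_peaks=2000,
            motif_p_dependent=0.0,
            motif_p_p50_constitutive=0.0,
            motif_p_background=0.0,
            rng_seed=13,
        )
        study = simulate(params)
        w = params.motif_window_bp
        expected_per_window = 2 * (w - 10) * 0.25**6
        total = sum(len(scan_homodimer(s)) for s in study.sequences.values())
        n = len(study.sequences)
        sd = np.sqrt(n * expected_per_window)  # Poisson-scale error
        assert abs(total - n * expected_per_window) < 5 * sd

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="even|motif"):
            GeneratorParams(motif_window_bp=10)

    def test_assign_gene_truth_proportions(self):
        params = GeneratorParams(n_genes=5000, rng_seed=2)
        truth = assign_gene_truth(params)
        frac = truth.gene_class.value_counts(normalize=True)
        assert frac["weak"] == pytest.approx(0.80, abs=0.03)
        assert frac["codependent"] == pytest.approx(0.02, abs=0.01)
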