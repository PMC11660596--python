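import numpy as np
import pytest

from ailhap.ancestry import (
    AncestryTrack,
    ancestry_accuracy,
    classify_window,
    code_diploid,
    import_rfmix,
    infer_ancestry,
    read_track,
    smooth_track,
    write_track,
)
from ailhap.blocks import build_blocks, spectrum
from ailhap.simulate import ChromosomeSpec, SimConfig, simulate_ail

from conftest import make_genotypes, make_variants


def track_of(posteriors, chrom=None):
    """AncestryTrack from a (n_blocks, n_samples, 2) posterior array."""
    post = np.asarray(posteriors, dtype=float)
    nb = post.shape[0]
    chrom = chrom if chrom is not None else np.array(["chr1"] * nb, dtype=object)
    return AncestryTrack([f"s{i}" for i in range(post.shape[1])], chrom, np.arange(nb), post)


class TestClassifyWindow:
    def test_exclusive_allele_in_zero_pseudocount_limit(self):
        post = classify_window("AA", {}, 10, {"AA": 9}, 10, pseudocount=1e-12)
        assert post == pytest.approx(1.0, abs=1e-9)

    def test_equal_frequency_ties_to_hqla(self):
        post = classify_window("AA", {"AA": 3}, 10, {"AA": 3}, 10)
        assert post == pytest.approx(0.5)
        assert (post >= 0.5) is True  # the >= 0.5 rule assigns HQLA

    def test_smoothed_count_arithmetic(self):
        # freq 0.2 in HQLA (2/10), 0.6 in HB (6/10), pseudocount 1 -> 3/10
        post = classify_window("AA", {"AA": 6}, 10, {"AA": 2}, 10, pseudocount=1)
        assert post == pytest.approx(0.3)

    def test_unseen_allele_everywhere_falls_back_to_half(self):
        assert classify_window("ZZ", {}, 10, {}, 10, pseudocount=1) == pytest.approx(0.5)


class TestSmoothTrack:
    def test_window_one_is_identity(self):
        t = track_of(np.full((4, 2, 2), 0.3))
        out = smooth_track(t, 1)
        np.testing.assert_array_equal(out.posterior, t.posterior)

    def test_running_mean_flips_isolated_block(self):
        post = np.array([1, 1, 0, 1, 1], dtype=float).reshape(5, 1, 1)
        t = track_of(post)
        out = smooth_track(t, 3)
        # middle block: mean(1,0,1) = 2/3 >= 0.5 -> HQLA
        assert out.origin[2, 0, 0] == 1

    def test_all_half_posteriors_called_hqla(self):
        t = track_of(np.full((3, 2, 2), 0.5))
        assert (t.origin == 1).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_track(track_of(np.full((3, 1, 2), 0.5)), 2)

    def test_window_exceeding_chromosome_clips(self):
        post = np.array([0.0, 1.0, 1.0], dtype=float).reshape(3, 1, 1)
        out = smooth_track(track_of(post), 9)
        np.testing.assert_allclose(out.posterior[:, 0, 0], [2 / 3] * 3)


class TestCodeDiploid:
    @pytest.mark.parametrize("origins, expected", [((0, 0), 0), ((0, 1), 1), ((1, 1), 2)])
    def test_copy_counting(self, origins, expected):
        post = np.array(origins, dtype=float).reshape(1, 1, 2)
        assert code_diploid(track_of(post))[0, 0] == expected

    def test_invariant_to_haplotype_swap(self):
        rng = np.random.default_rng(0)
        post = rng.random((6, 4, 2))
        t = track_of(post)
        swapped = track_of(post[:, :, ::-1])
        np.testing.assert_array_equal(code_diploid(t), code_diploid(swapped))


class TestImportRfmix:
    def _fixture(self, tmp_path, posteriors):
        """Windows covering blocks of a tiny 6-SNP, 2-sample dataset."""
        vt = make_variants(6, step=100)
        pg = make_genotypes([[0, 1, 0, 1, 0, 1]] * 4)
        hbs = build_blocks(vt, pg, block_size=2)
        lines = []
        for (s, e), ps in zip([(1000, 1199), (1200, 1399), (1400, 1599)], posteriors):
            cols = []
            for p in ps:  # one P(HQLA) per haplotype
                cols += [f"{1 - p:.3f}", f"{p:.3f}"]
            lines.append(f"chr1 {s} {e} " + " ".join(cols))
        path = tmp_path / "rfmix.txt"
        path.write_text("# chrom spos epos hap posteriors\n" + "\n".join(lines) + "\n")
        return path, hbs

    def test_threshold_rule_on_posteriors(self, tmp_path):
        path, hbs = self._fixture(
            tmp_path, [[0.9, 0.9, 0.9, 0.9], [0.5, 0.5, 0.5, 0.5], [0.1, 0.1, 0.1, 0.1]]
        )
        track = import_rfmix(path, hbs, ["s0", "s1"])
        assert track.origin[0, 0, 0] == 1
        assert track.origin[1, 0, 0] == 1  # 0.5 ties to HQLA
        assert track.origin[2, 0, 0] == 0

    def test_missing_chromosome_listed(self, tmp_path):
        vt = make_variants(4)
        vt2 = make_variants(4, chrom="chr2")
        import numpy as _np
        from ailhap.io import VariantTable

        both = VariantTable(
            _np.concatenate([vt.chrom, vt2.chrom]),
            _np.concatenate([vt.pos, vt2.pos]),
            _np.concatenate([vt.ref, vt2.ref]),
            _np.concatenate([vt.alt, vt2.alt]),
        )
        pg = make_genotypes([[0, 1, 0, 1, 0, 1, 0, 1]] * 4)
        hbs = build_blocks(both, pg, block_size=2)
        path = tmp_path / "rfmix.txt"
        path.write_text("chr1 1000 1400 0.1 0.9 0.1 0.9 0.1 0.9 0.1 0.9\n")
        with pytest.raises(ValueError, match="chr2"):
            import_rfmix(path, hbs, ["s0", "s1"])

    def test_haplotype_count_mismatch(self, tmp_path):
        path, hbs = self._fixture(tmp_path, [[0.9, 0.9]] * 3)  # only 2 haplotypes
        with pytest.raises(ValueError, match="haplotype count mismatch"):
            import_rfmix(path, hbs, ["s0", "s1"])

    def test_midpoint_containment_with_narrow_windows(self, tmp_path):
        vt = make_variants(2, step=100)  # one block, midpoint 1050
        pg = make_genotypes([[0, 1]] * 4)
        hbs = build_blocks(vt, pg, block_size=2)
        path = tmp_path / "rfmix.txt"
        path.write_text(
            "chr1 1000 1040 0.9 0.1 0.9 0.1 0.9 0.1 0.9 0.1\n"
            "chr1 1041 1090 0.1 0.9 0.1 0.9 0.1 0.9 0.1 0.9\n"
        )
        track = import_rfmix(path, hbs, ["s0", "s1"])
        assert (track.origin[0] == 1).all()  # midpoint falls in second window


class TestTrackIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        t = track_of(rng.random((4, 3, 2)))
        write_track(t, tmp_path / "t.tsv")
        t2 = read_track(tmp_path / "t.tsv")
        assert t2.samples == t.samples
        np.testing.assert_allclose(t2.posterior, t.posterior)


class TestAccuracyAndBalance:
    def test_perfect_and_inverted_calls(self):
        truth = np.zeros((3, 2, 2), dtype=np.int8)
        perfect = track_of(np.zeros((3, 2, 2)))
        inverted = track_of(np.ones((3, 2, 2)))
        assert ancestry_accuracy(perfect, truth) == 1.0
        assert ancestry_accuracy(inverted, truth) == 0.0

    def test_fully_diverged_panels_classified_exactly(self):
        """sharing=0 panels: every panel-unique allele is assigned its panel."""
        cfg = SimConfig(
            seed=5,
            chromosomes=[ChromosomeSpec("chr1", 60, 100.0)],
            n_founders=(8, 8),
            pool_size=4,
            sharing=0.0,
            f9_size=60,
            gen_size=60,
            sigma_g2=0.0,
            sigma_e2=1.0,
        )
        res = simulate_ail(cfg)
        hbs = res.combined_blocks()
        hb_spec = spectrum(hbs, res.founders.hb_ids)
        hq_spec = spectrum(hbs, res.founders.hqla_ids)
        track = infer_ancestry(hbs, hb_spec, hq_spec, res.f9.samples, pseudocount=1e-9)
        acc = ancestry_accuracy(track, hbs=hbs, hb_panel=hb_spec, hqla_panel=hq_spec)
        assert acc == 1.0

    def test_mosaic_of_block_diverged_panels_recovered_exactly(self):
        """Panels with disjoint block alleles: every mosaic call matches truth.

        Panel HB is all-ref, panel HQLA all-alt, so block alleles never
        overlap; admixed targets switch origin at block boundaries.
        """
        vt = make_variants(10)
        hb = [[0] * 10, [0] * 10, [0] * 10, [0] * 10]
        hq = [[1] * 10, [1] * 10, [1] * 10, [1] * 10]
        mosaic = [[0] * 5 + [1] * 5, [1] * 5 + [0] * 5]
        pg = make_genotypes(hb + hq + mosaic, samples=["hb0", "hb1", "hq0", "hq1", "t0"])
        hbs = build_blocks(vt, pg, block_size=5)
        track = infer_ancestry(hbs, ["hb0", "hb1"], ["hq0", "hq1"], ["t0"], pseudocount=1e-12)
        truth = np.array([[[0, 1]], [[1, 0]]], dtype=np.int8)  # (blocks, samples, haps)
        assert ancestry_accuracy(track, truth_origin=truth) == 1.0

    def test_simulated_truth_accuracy_beats_shared_allele_floor(self):
        """With partially shared block alleles, accuracy is bounded by the
        shared fraction; the classifier must beat a coin on the rest."""
        cfg = SimConfig(
            seed=5,
            chromosomes=[ChromosomeSpec("chr1", 60, 100.0)],
            n_founders=(8, 8),
            pool_size=4,
            sharing=0.0,
            f9_size=60,
            gen_size=60,
            sigma_g2=0.0,
            sigma_e2=1.0,
        )
        res = simulate_ail(cfg)
        hbs = res.combined_blocks()
        track = infer_ancestry(
            hbs, res.founders.hb_ids, res.founders.hqla_ids, res.f9.samples, pseudocount=1e-9
        )
        acc = ancestry_accuracy(track, truth_origin=res.truth_origin)
        assert acc > 0.75

    def test_genomewide_ancestry_near_half(self, small_sim):
        frac = small_sim.truth_origin.mean()
        # Monte-Carlo SD of the genome-wide HQLA fraction at this design scale
        # is ~0.03 (drift over 8 generations at 80 breeders); allow 3 SD.
        assert abs(frac - 0.5) < 0.1

    def test_no_assignable_blocks_is_an_error(self):
        t = track_of(np.full((2, 2, 2), 0.9))
        with pytest.raises(ValueError):
            ancestry_accuracy(t)
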