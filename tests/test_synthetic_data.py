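"""Simulator: determinism, conservation, junction geometry, pileup model."""

import numpy as np
import pandas as pd
import pytest

from matesv import GenomeMap, chimeric_sv, synthetic_data as sd
from matesv.depth_cnv import WindowScheme, bin_counts

SMALL = (("chr1", 8_000_000), ("chr2", 8_000_000))


def small_cfg(**kw):
    kw.setdefault("genome", SMALL)
    return sd.SimConfig(**kw)


class TestDeterminismAndConservation:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_cfg(events=(sd.SimEvent("del", "chr1", 2_000_000,
                                            2_200_000),),
                        aoh_regions=(("chr2", 1_000_001, 6_200_000),), seed=9)
        a = sd.simulate(cfg)
        b = sd.simulate(cfg)
        da, db = tmp_path / "a", tmp_path / "b"
        pa, pb = a.write(da), b.write(db)
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_different_seed_differs(self):
        a = sd.simulate(small_cfg(seed=1), pairs_only=True)
        b = sd.simulate(small_cfg(seed=2), pairs_only=True)
        assert not a.pairs.pos_a.equals(b.pairs.pos_a)

    def test_fragment_count_conserved_without_events(self):
        cfg = small_cfg(seed=3)
        res = sd.simulate(cfg, pairs_only=True)
        assert len(res.pairs) == cfg.n_fragments()
        assert cfg.n_fragments() == int(np.ceil(
            4.0 * 16_000_000 / (2 * 100)))

    def test_no_events_no_chimeric_pairs(self):
        res = sd.simulate(small_cfg(seed=4), pairs_only=True)
        assert len(chimeric_sv.select_chimeric(res.pairs)) == 0


EXPECTED_KEYS = {
    "del": {("chr1", "chr1", "+", "-")},
    "dup": {("chr1", "chr1", "-", "+")},
    "inv": {("chr1", "chr1", "+", "+"), ("chr1", "chr1", "-", "-")},
    "tra": {("chr1", "chr2", "+", "-"), ("chr1", "chr2", "-", "+")},
}


class TestJunctionGeometry:
    @pytest.mark.parametrize("etype", ["del", "dup", "inv", "tra"])
    def test_truth_keys_match_orientation_grammar(self, etype):
        if etype == "tra":
            ev = sd.SimEvent("tra", "chr1", 3_000_000,
                             partner_chrom="chr2", partner_pos=4_000_000)
        else:
            ev = sd.SimEvent(etype, "chr1", 3_000_000, 3_200_000)
        res = sd.simulate(small_cfg(events=(ev,), seed=5), pileup_only=True)
        assert {tuple(j["key"]) for j in res.truth["junctions"]} == \
            EXPECTED_KEYS[etype]

    @pytest.mark.parametrize("etype", ["del", "dup", "inv"])
    def test_generated_chimeric_pairs_share_truth_keys(self, etype):
        ev = sd.SimEvent(etype, "chr1", 3_000_000, 3_200_000)
        res = sd.simulate(small_cfg(events=(ev,), seed=6), pairs_only=True)
        chim = chimeric_sv.select_chimeric(res.pairs)
        got = set(map(tuple, chim[["chrom_a", "chrom_b",
                                   "strand_a", "strand_b"]].values))
        assert got == EXPECTED_KEYS[etype]

    def test_insertion_forward_vs_inverted_keys(self):
        fwd = sd.SimEvent("ins", "chr1", 3_000_000, 3_200_000,
                          insert_chrom="chr2", insert_at=5_000_000)
        inv = sd.SimEvent("ins", "chr1", 3_000_000, 3_200_000,
                          insert_chrom="chr2", insert_at=5_000_000,
                          orientation="inverted")
        keys = lambda ev: {tuple(j["key"]) for j in sd.simulate(
            small_cfg(events=(ev,), seed=7),
            pileup_only=True).truth["junctions"]}
        assert keys(fwd) == {("chr1", "chr2", "-", "+"),
                             ("chr1", "chr2", "+", "-")}
        assert keys(inv) == {("chr1", "chr2", "+", "+"),
                             ("chr1", "chr2", "-", "-")}

    def test_junction_support_matches_physical_coverage(self):
        """Junction-straddling pair count across 50 seeds tracks the
        closed-form physical coverage N * insert / (2L) per haplotype."""
        counts = []
        for seed in range(50):
            cfg = sd.SimConfig(genome=(("chr1", 5_000_000),),
                               events=(sd.SimEvent("dup", "chr1", 2_000_000,
                                                   2_200_000),),
                               seed=seed)
            res = sd.simulate(cfg, pairs_only=True)
            chim = chimeric_sv.select_chimeric(res.pairs)
            counts.append(len(chim))
        n = sd.SimConfig(genome=(("chr1", 5_000_000),)).n_fragments()
        # het junction: half of fragments on the carrier haplotype; the
        # extra 200 kb copy enlarges that haplotype slightly.
        lam = n * 5_000 / (2 * 5_000_000 + 200_000)
        # fragments whose junction falls within read_len of a read edge
        # are dropped (reads may not cross junctions)
        lam *= (5_000 - 2 * 100) / 5_000
        mean = np.mean(counts)
        sd3 = 3 * np.sqrt(lam / 50)
        assert abs(mean - lam) < sd3 + 1.0


class TestPileupModel:
    def test_aoh_het_density_suppressed(self):
        cfg = small_cfg(aoh_regions=(("chr1", 1_000_001, 7_000_000),), seed=8)
        res = sd.simulate(cfg, pileup_only=True)
        pil = res.pileup
        from matesv.aoh import genotype_sites
        calls = genotype_sites(pil)
        het = calls[calls.genotype == "het"]
        inside = het[(het.chrom == "chr1") & (het.pos > 1_000_000)
                     & (het.pos <= 7_000_000)]
        outside = het[het.chrom == "chr2"]
        dens_in = len(inside) / 6_000_000
        dens_out = len(outside) / 8_000_000
        ratio = dens_in / dens_out
        # binomial check: retention 0.02 of candidates (some ambiguity loss)
        assert ratio < 0.06

    def test_hom_rate_rises_inside_aoh(self):
        cfg = small_cfg(aoh_regions=(("chr1", 1_000_001, 7_000_000),), seed=8)
        res = sd.simulate(cfg, pileup_only=True)
        from matesv.aoh import genotype_sites
        calls = genotype_sites(res.pileup)
        hom = calls[calls.genotype == "hom_alt"]
        dens_in = len(hom[(hom.chrom == "chr1") & (hom.pos > 1_000_000)
                          & (hom.pos <= 7_000_000)]) / 6_000_000
        dens_out = len(hom[hom.chrom == "chr2"]) / 8_000_000
        assert dens_in / dens_out > 1.4

    def test_homozygous_deletion_has_no_sites_or_fragments(self):
        ev = sd.SimEvent("del", "chr1", 2_000_000, 2_500_000, zygosity="hom")
        res = sd.simulate(small_cfg(events=(ev,), seed=9))
        inside_sites = res.pileup[(res.pileup.chrom == "chr1")
                                  & (res.pileup.pos >= 2_000_000)
                                  & (res.pileup.pos <= 2_500_000)]
        assert len(inside_sites) == 0
        inner = res.pairs[(res.pairs.chrom_a == "chr1")
                          & (res.pairs.pos_a > 2_010_000)
                          & (res.pairs.pos_a < 2_490_000)]
        assert len(inner) == 0

    def test_pileup_counts_respect_invariants(self):
        res = sd.simulate(small_cfg(seed=10), pileup_only=True)
        pil = res.pileup
        assert ((pil.ref_count + pil.alt_count) <= pil.depth).all()
        assert (pil[["depth", "ref_count", "alt_count"]] >= 0).all().all()


class TestMaskAndDuplicates:
    def test_lcr_mask_zeroes_mapq(self):
        cfg = small_cfg(lcr_mask=(("chr1", 1_000_000, 1_050_000),), seed=11)
        res = sd.simulate(cfg, pairs_only=True)
        inside = res.pairs[(res.pairs.chrom_a == "chr1")
                           & (res.pairs.pos_a >= 1_000_000)
                           & (res.pairs.pos_a <= 1_050_000)]
        assert (inside.mapq_a == 0).all() and len(inside) > 100

    def test_duplicate_rate_flags_pairs(self):
        res = sd.simulate(small_cfg(duplicate_rate=0.05, seed=12),
                          pairs_only=True)
        frac = res.pairs.duplicate.mean()
        assert 0.03 < frac < 0.07


class TestValidation:
    def test_overlapping_events_rejected(self):
        cfg = small_cfg(events=(
            sd.SimEvent("del", "chr1", 1_000_000, 2_000_000),
            sd.SimEvent("dup", "chr1", 1_500_000, 2_500_000)))
        with pytest.raises(ValueError, match="inconsistent event composition"):
            sd.simulate(cfg)

    def test_out_of_bounds_event_rejected(self):
        cfg = small_cfg(events=(sd.SimEvent("del", "chr1", 1, 9_000_000),))
        with pytest.raises(ValueError, match="out of bounds"):
            sd.simulate(cfg)


class TestPanel:
    def test_needs_ten_replicates(self):
        with pytest.raises(ValueError, match="10"):
            sd.make_panel(small_cfg(), seeds=range(5),
                          scheme=WindowScheme("fixed", 5_000))

    def test_flat_and_robust_to_minority_event(self):
        genome_def = (("chr1", 2_000_000),)
        scheme = WindowScheme("fixed", 5_000)
        genome = GenomeMap(chromosomes=genome_def)
        cfg = sd.SimConfig(genome=genome_def)
        panel = sd.make_panel(cfg, seeds=range(10), scheme=scheme,
                              genome=genome)
        expected = cfg.n_fragments() * 2 * 5_000 / 2_000_000
        # interior windows flat; the outermost windows carry the expected
        # chromosome-end coverage roll-off (no fragment may overhang)
        assert np.allclose(panel.median_count[2:-2], expected, rtol=0.25)
        # an event in 1 of 10 replicates leaves window medians unchanged
        cfg_ev = sd.SimConfig(
            genome=genome_def,
            events=(sd.SimEvent("del", "chr1", 500_001, 700_000,
                                zygosity="hom"),))
        counts_ev = bin_counts(sd.simulate(cfg_ev, pairs_only=True).pairs,
                               scheme, genome)
        stack = [counts_ev["raw_count"].to_numpy()] + [
            bin_counts(sd.simulate(
                sd.SimConfig(genome=genome_def, seed=s),
                pairs_only=True).pairs, scheme, genome)["raw_count"].to_numpy()
            for s in range(1, 10)]
        med = np.median(np.vstack(stack), axis=0)
        view = slice(100, 140)      # windows inside the deleted interval
        assert np.allclose(med[view], panel.median_count.to_numpy()[view],
                           rtol=0.35)
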