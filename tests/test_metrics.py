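"""Individual and pairwise metric computations."""

import itertools

import numpy as np
import pytest

from matechoice.alleles import aa_distance
from matechoice.errors import MissingDataError
from matechoice.metrics import (
    AlleleFrequencyTable,
    MicrosatGenotype,
    build_pair_metrics,
    heterosis_indicator,
    internal_relatedness,
    landry_compatibility,
    mhc_diversity,
    pairwise_relatedness,
    standardized_heterozygosity,
    wetton_sharing,
)


class TestHeterosisAndDiversity:
    def test_homozygote_is_zero(self, toy_db, toy_geno):
        assert heterosis_indicator(toy_geno("i", "TOY", "A1", "A1")) == 0

    def test_heterozygote_is_one_both_levels(self, toy_db, toy_geno):
        g = toy_geno("i", "TOY", "A1", "A2")
        assert heterosis_indicator(g) == 1
        assert heterosis_indicator(g, toy_db, level="protein") == 1

    def test_synonymous_pair_protein_level(self, toy_db, toy_geno):
        g = toy_geno("i", "TOY", "A1", "A3")  # same protein
        assert heterosis_indicator(g, level="allele") == 1
        assert heterosis_indicator(g, toy_db, level="protein") == 0

    def test_missing_genotype_signals(self, toy_db, toy_geno):
        with pytest.raises(MissingDataError):
            heterosis_indicator(toy_geno("i", "TOY", None, None))

    def test_diversity_values(self, toy_db, toy_geno):
        assert mhc_diversity(toy_geno("i", "TOY", "A1", "A1"), toy_db) == 0
        # KLMN vs RLQN differ at positions 1 and 3
        g = toy_geno("i", "TOY", "A1", "A2")
        assert mhc_diversity(g, toy_db) == 2
        assert mhc_diversity(g, toy_db, use_mask=True) == 1  # mask {1}


class TestLandryCompatibility:
    def test_identical_homozygotes(self, toy_db, toy_geno):
        gf = toy_geno("f", "TOY", "A1", "A1")
        gm = toy_geno("m", "TOY", "A1", "A1")
        assert landry_compatibility(gf, gm, toy_db) == 0.0

    def test_hand_value(self, toy_db, toy_geno):
        # female KLMN/KLQN, male KLMN/RLQN -> (0+2+1+1)/4 = 1.0
        gf = toy_geno("f", "TOY", "A1", "A4")
        gm = toy_geno("m", "TOY", "A1", "A2")
        assert landry_compatibility(gf, gm, toy_db) == 1.0

    def test_symmetry_and_mask_bound_random_pairs(self, toy_db, toy_geno):
        names = list(toy_db.alleles)
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.choice(names, 2)
            b = rng.choice(names, 2)
            gf = toy_geno("f", "TOY", a[0], a[1])
            gm = toy_geno("m", "TOY", b[0], b[1])
            full = landry_compatibility(gf, gm, toy_db)
            assert full == landry_compatibility(gm, gf, toy_db)
            assert landry_compatibility(gf, gm, toy_db, use_mask=True) <= full

    def test_equals_exhaustive_cross_enumeration(self, toy_db, toy_geno):
        names = list(toy_db.alleles)
        for fa in itertools.combinations_with_replacement(names, 2):
            for ma in itertools.combinations_with_replacement(names, 2):
                gf = toy_geno("f", "TOY", *fa)
                gm = toy_geno("m", "TOY", *ma)
                expected = np.mean(
                    [
                        aa_distance(
                            toy_db.get(x).aa_seq, toy_db.get(y).aa_seq
                        )
                        for x in fa
                        for y in ma
                    ]
                )
                assert landry_compatibility(gf, gm, toy_db) == expected


class TestWettonSharing:
    @pytest.mark.parametrize(
        "f,m,expected",
        [
            (("A1", "A2"), ("A1", "A2"), 1.0),  # identical class sets
            (("A1", "A4"), ("A2", "A2"), 0.0),  # disjoint
            (("A1", "A2"), ("A2", "A4"), 0.5),  # one shared of 2+2
            (("A1", "A3"), ("A1", "A1"), 1.0),  # synonymous pair = one protein
        ],
    )
    def test_examples(self, toy_db, toy_geno, f, m, expected):
        gf = toy_geno("f", "TOY", *f)
        gm = toy_geno("m", "TOY", *m)
        assert wetton_sharing(gf, gm, toy_db) == expected
        assert wetton_sharing(gm, gf, toy_db) == expected

    def test_one_iff_identical_class_sets(self, toy_db, toy_geno):
        names = list(toy_db.alleles)
        for fa in itertools.combinations_with_replacement(names, 2):
            for ma in itertools.combinations_with_replacement(names, 2):
                gf = toy_geno("f", "TOY", *fa)
                gm = toy_geno("m", "TOY", *ma)
                sets_equal = {toy_db.get(a).protein_class for a in fa} == {
                    toy_db.get(a).protein_class for a in ma
                }
                assert (wetton_sharing(gf, gm, toy_db) == 1.0) == sets_equal


def _freqs(n_loci=1, alleles=(1, 2), probs=None):
    probs = probs or [1 / len(alleles)] * len(alleles)
    return AlleleFrequencyTable(
        {f"ms{i:02d}": dict(zip(alleles, probs)) for i in range(1, n_loci + 1)}
    )


class TestMicrosatMetrics:
    def test_sh_full_homozygote_is_zero(self):
        g = MicrosatGenotype("i", {"ms01": (1, 1), "ms02": (2, 2)})
        assert standardized_heterozygosity(g, _freqs(2)) == 0.0

    def test_sh_all_het_at_half_expected(self):
        # expected heterozygosity 0.5 at every locus -> SH = 1/0.5 = 2
        g = MicrosatGenotype("i", {f"ms{i:02d}": (1, 2) for i in range(1, 5)})
        assert standardized_heterozygosity(g, _freqs(4)) == pytest.approx(2.0)

    def test_ir_single_locus_closed_forms(self):
        f = _freqs(1)
        homo = MicrosatGenotype("i", {"ms01": (1, 1)})
        het = MicrosatGenotype("i", {"ms01": (1, 2)})
        assert internal_relatedness(homo, f) == pytest.approx(1.0)
        assert internal_relatedness(het, f) == pytest.approx(-1.0)

    def test_ir_full_homozygote_is_one(self):
        f = _freqs(5, alleles=(1, 2, 3, 4), probs=[0.4, 0.3, 0.2, 0.1])
        g = MicrosatGenotype("i", {f"ms{i:02d}": (3, 3) for i in range(1, 6)})
        assert internal_relatedness(g, f) == pytest.approx(1.0)

    def test_ir_decreases_with_heterozygosity(self):
        f = _freqs(3, alleles=(1, 2, 3, 4), probs=[0.25] * 4)
        calls = {"ms01": (1, 1), "ms02": (2, 2), "ms03": (3, 3)}
        base = internal_relatedness(MicrosatGenotype("i", calls), f)
        calls2 = dict(calls, ms02=(2, 3))
        less = internal_relatedness(MicrosatGenotype("i", calls2), f)
        assert less < base

    def test_sh_ir_strong_negative_correlation(self):
        # 1,000 HWE individuals at 14 loci: SH and IR are near-mirror
        # measures of multilocus heterozygosity
        rng = np.random.default_rng(11)
        n_loci, n = 14, 1000
        freqs = {}
        genos = []
        for j in range(n_loci):
            k = int(rng.integers(4, 11))
            f = rng.dirichlet(np.ones(k))
            freqs[f"ms{j:02d}"] = dict(zip(range(k), map(float, f)))
        table = AlleleFrequencyTable(freqs)
        for i in range(n):
            calls = {}
            for locus, f in freqs.items():
                a = rng.choice(list(f), size=2, p=list(f.values()))
                calls[locus] = (int(a[0]), int(a[1]))
            genos.append(MicrosatGenotype(str(i), calls))
        sh = [standardized_heterozygosity(g, table) for g in genos]
        ir = [internal_relatedness(g, table) for g in genos]
        assert np.corrcoef(sh, ir)[0, 1] < -0.5


class TestPairwiseRelatedness:
    def test_clone_with_equal_frequency_alleles(self):
        f = _freqs(2, alleles=(1, 2, 3, 4), probs=[0.25] * 4)
        g1 = MicrosatGenotype("a", {"ms01": (1, 2), "ms02": (3, 4)})
        g2 = MicrosatGenotype("b", {"ms01": (1, 2), "ms02": (3, 4)})
        assert pairwise_relatedness(g1, g2, f) == pytest.approx(1.0)

    def test_no_shared_loci_signals(self):
        f = _freqs(2)
        g1 = MicrosatGenotype("a", {"ms01": (1, 2), "ms02": None})
        g2 = MicrosatGenotype("b", {"ms01": None, "ms02": (1, 2)})
        with pytest.raises(MissingDataError):
            pairwise_relatedness(g1, g2, f)

    @staticmethod
    def _hwe_genotype(rng, name, freqs):
        calls = {}
        for locus, f in freqs.items():
            a = rng.choice(list(f), size=2, p=list(f.values()))
            calls[locus] = (int(a[0]), int(a[1]))
        return MicrosatGenotype(name, calls)

    def test_unrelated_mean_near_zero(self):
        rng = np.random.default_rng(5)
        freqs = {
            f"ms{j:02d}": dict(zip(range(6), [1 / 6] * 6)) for j in range(14)
        }
        table = AlleleFrequencyTable(freqs)
        vals = []
        for _ in range(1000):
            a = self._hwe_genotype(rng, "a", freqs)
            b = self._hwe_genotype(rng, "b", freqs)
            vals.append(pairwise_relatedness(a, b, table))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-12

    def test_parent_offspring_mean_near_half(self):
        rng = np.random.default_rng(6)
        freqs = {
            f"ms{j:02d}": dict(zip(range(6), [1 / 6] * 6)) for j in range(14)
        }
        table = AlleleFrequencyTable(freqs)
        vals = []
        for _ in range(1000):
            mother = self._hwe_genotype(rng, "mo", freqs)
            father = self._hwe_genotype(rng, "fa", freqs)
            calls = {
                locus: (
                    mother.calls[locus][rng.integers(2)],
                    father.calls[locus][rng.integers(2)],
                )
                for locus in freqs
            }
            child = MicrosatGenotype("ch", calls)
            vals.append(pairwise_relatedness(mother, child, table))
        se = np.std(vals) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(0.5, abs=3 * se)


class TestBuildPairMetrics:
    def test_row_matches_individual_operations(self, study_scale_sim):
        ds = study_scale_sim.dataset
        loci = list(ds.dbs)
        freqs = ds.allele_frequencies()
        site = ds.sites[0]
        male = site.males[0][0]
        pm = build_pair_metrics(
            site.female, male, loci, ds.dbs, ds.mhc_genotypes,
            ds.microsat_genotypes, freqs,
        )
        for locus in loci:
            gf = ds.mhc_genotypes[(site.female, locus)]
            gm = ds.mhc_genotypes[(male, locus)]
            db = ds.dbs[locus]
            assert pm.compatibility1[locus] == landry_compatibility(gf, gm, db)
            assert pm.abs_compatibility1[locus] == landry_compatibility(
                gf, gm, db, use_mask=True
            )
            assert pm.compatibility2[locus] == wetton_sharing(gf, gm, db)
            assert pm.abs_compatibility1[locus] <= pm.compatibility1[locus]
        assert pm.relatedness == pytest.approx(
            pairwise_relatedness(
                ds.microsat_genotypes[site.female],
                ds.microsat_genotypes[male],
                freqs,
            )
        )

    def test_missing_locus_gives_none_fields(self, toy_db, toy_geno):
        genos = {
            ("f", "TOY"): toy_geno("f", "TOY", None, None),
            ("m", "TOY"): toy_geno("m", "TOY", "A1", "A2"),
        }
        pm = build_pair_metrics("f", "m", ["TOY"], {"TOY": toy_db}, genos)
        assert pm.compatibility1["TOY"] is None
        assert pm.compatibility2["TOY"] is None
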