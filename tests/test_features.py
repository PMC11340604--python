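import math

import numpy as np
import pandas as pd
import pytest

from mirbind.features import families as fam
from mirbind.features.energy import duplex_profile, duplex_energy, paired_mask
from mirbind.features.fold import NussinovFoldBackend
from mirbind.features.registry import FeatureRegistry, RegistryConfig, featurize
from mirbind.features.association import feature_class_association
from mirbind.sequence_io import ResourceBundle
from mirbind.site_scanner import scan_candidate_sites
from mirbind.types import ConservationTrack, MiRNA, TranscriptUTR

from tests.conftest import random_mirna, random_utr


def one_site(mirna, utr, flank=20):
    sites = scan_candidate_sites(mirna, utr, flank=flank)
    assert sites, "fixture UTR must contain a site"
    return sites[0]


class TestSiteTypeFeatures:
    def test_8mer_one_hot(self, mirna, utr_8mer):
        v = fam.site_type_features(one_site(mirna, utr_8mer))
        assert list(v.values()) == [0.0, 0.0, 0.0, 1.0]

    def test_6mer_one_hot(self, mirna):
        utr = TranscriptUTR("t", "GGCAUUCCGG")
        v = fam.site_type_features(one_site(mirna, utr))
        assert list(v.values()) == [1.0, 0.0, 0.0, 0.0]

    def test_indicators_sum_to_one(self, mirna):
        rng = np.random.default_rng(0)
        for _ in range(20):
            utr = random_utr(rng, 300)
            for site in scan_candidate_sites(mirna, utr):
                assert sum(fam.site_type_features(site).values()) == 1.0


class TestDuplexEnergy:
    def test_fully_complementary_negative(self):
        assert duplex_energy("GGGGGGGG", "CCCCCCCC", anchor=7) < 0

    def test_zero_pairs_zero_energy(self):
        prof = duplex_profile("GGGG", "GGGG", anchor=3)
        assert prof.energy == 0.0
        assert prof.paired_count == 0
        assert prof.energy_per_pair == 0.0

    def test_gc_rich_below_au_rich(self):
        # hand sums over the embedded nearest-neighbor table:
        # GGGG/CCCC = 3 stacks of GG = 3 * -3.26; AAAA/UUUU = 3 * -0.93
        gc = duplex_energy("GGGG", "CCCC", anchor=3)
        au = duplex_energy("AAAA", "UUUU", anchor=3)
        assert gc == pytest.approx(3 * -3.26)
        assert au == pytest.approx(3 * -0.93)
        assert gc < au

    def test_adding_pair_never_raises_energy(self):
        rng = np.random.default_rng(1)
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        for _ in range(100):
            m = random_mirna(rng, 12).sequence
            target = list("".join(rng.choice(list("ACGU"), size=12)))
            anchor = 11
            before = duplex_energy(m, "".join(target), anchor=anchor)
            mask = paired_mask(m, "".join(target), anchor)
            unpaired = [k for k, p in enumerate(mask) if not p and 0 <= anchor - k < 12]
            if not unpaired:
                continue
            k = int(rng.choice(unpaired))
            target[anchor - k] = comp[m[k]]
            after = duplex_energy(m, "".join(target), anchor=anchor)
            assert after <= before

    def test_seed_energy_counts_seed_stacks_only(self):
        # pairs only at positions 9-12 leave the seed term at zero
        m = "GGGGGGGGAAAA"
        target = "UUUUGGGGGGGG"  # complement of positions 9-12 only
        prof = duplex_profile(m, target, anchor=11)
        assert prof.seed_energy == 0.0
        assert prof.energy < 0

    def test_unavailable_backend_errors(self):
        with pytest.raises((RuntimeError, ValueError)):
            duplex_energy("ACGU", "ACGU", backend="no-such-backend")


class TestAccessibility:
    def test_site_at_position_zero(self, mirna):
        utr = TranscriptUTR("t", "CAUUCCU" + "G" * 60)
        site = one_site(mirna, utr)
        v = fam.accessibility_features(utr.sequence, site, None)
        assert v["acc_dist5"] == 0.0

    def test_distance_identity_random_sites(self, mirna):
        rng = np.random.default_rng(2)
        count = 0
        while count < 100:
            utr = random_utr(rng, int(rng.integers(60, 400)))
            for site in scan_candidate_sites(mirna, utr):
                v = fam.accessibility_features(utr.sequence, site, None)
                assert v["acc_dist5"] + site.length + v["acc_dist3"] == len(utr)
                count += 1

    def test_au_site_fraction(self, mirna):
        utr = TranscriptUTR("t", "G" * 30 + "ACAUUCCA" + "G" * 30)
        site = one_site(mirna, utr)
        v = fam.accessibility_features(utr.sequence, site, None)
        # site ACAUUCCA holds five A/U bases out of eight
        assert v["acc_au_site"] == pytest.approx(5 / 8)

    def test_flank_au_hand_counted(self, mirna):
        left = "AU" * 15           # 30 nt, AU fraction 1.0
        right = "GC" * 15          # 30 nt, AU fraction 0.0
        utr = TranscriptUTR("t", "G" * 40 + left + "ACAUUCCA" + right + "G" * 40)
        site = [s for s in scan_candidate_sites(mirna, utr) if s.site_type == "8mer"][0]
        v = fam.accessibility_features(utr.sequence, site, None)
        assert v["acc_au_flank5"] == 1.0
        assert v["acc_au_flank3"] == 0.0
        assert v["acc_flank_clipped"] == 0.0

    def test_clipped_flag(self, mirna):
        utr = TranscriptUTR("t", "GACAUUCCAGG" + "G" * 30)
        site = one_site(mirna, utr)
        v = fam.accessibility_features(utr.sequence, site, None)
        assert v["acc_flank_clipped"] == 1.0

    def test_fold_backend_values_bounded(self, mirna, utr_8mer):
        utr = TranscriptUTR("t", "G" * 30 + "ACAUUCCA" + "CAUAUAUAUGG" * 3)
        site = one_site(mirna, utr)
        v = fam.accessibility_features(utr.sequence, site, NussinovFoldBackend())
        assert 0.0 <= v["acc_unpaired_site"] <= 1.0
        assert 0.0 <= v["acc_unpaired_win10"] <= 1.0
        assert v["acc_open_energy"] >= 0.0


class TestSupplementaryPairing:
    def test_perfect_13_16(self, mirna):
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        utr = list("G" * 20 + "GACAUUCCAG" + "G" * 10)
        site = one_site(mirna, TranscriptUTR("t", "".join(utr)))
        anchor = site.anchor
        for k in range(13, 17):
            utr[anchor - (k - 1)] = comp[mirna.sequence[k - 1]]
        utr2 = TranscriptUTR("t", "".join(utr))
        site = [s for s in scan_candidate_sites(mirna, utr2) if s.core_start == site.core_start][0]
        v = fam.supplementary_pairing_features(mirna, utr2.sequence, site)
        assert v["supp_pairs_13_16"] == 4.0
        assert v["supp_ge3_13_16"] == 1.0

    def test_no_complementarity(self, mirna):
        # guide 13-16 = AAGU; opposite bases all G pair with none of them
        utr = TranscriptUTR("t", "G" * 20 + "GACAUUCCAG" + "G" * 10)
        site = one_site(mirna, utr)
        v = fam.supplementary_pairing_features(mirna, utr.sequence, site)
        assert v["supp_pairs_13_16"] == 0.0
        assert v["supp_ge3_13_16"] == 0.0

    def test_pairs_at_13_14_only_run_two(self, mirna):
        # miRNA positions 13,14 are both A; their complements go opposite
        utr = list("G" * 20 + "GACAUUCCAG" + "G" * 10)
        site = one_site(mirna, TranscriptUTR("t", "".join(utr)))
        a = site.anchor
        utr[a - 12] = "U"   # pairs miRNA position 13 (A)
        utr[a - 13] = "U"   # pairs miRNA position 14 (A)
        utr[a - 11] = "C"   # blocks position 12 (G would need C... set non-pair)
        utr[a - 11] = "A"   # position 12 is G; A does not pair, nor wobble
        utr[a - 15] = "C"   # position 16 is U; C does not pair
        utr2 = TranscriptUTR("t", "".join(utr))
        site = [s for s in scan_candidate_sites(mirna, utr2) if s.core_start == site.core_start][0]
        v = fam.supplementary_pairing_features(mirna, utr2.sequence, site)
        assert v["supp_pairs_13_16"] == 2.0
        assert v["supp_run_12_17"] == 2.0

    def test_wobble_counted_separately(self, mirna):
        # position 16 is U; a G opposite it is a wobble, not a WC pair
        utr = list("G" * 20 + "GACAUUCCAG" + "G" * 10)
        site = one_site(mirna, TranscriptUTR("t", "".join(utr)))
        v = fam.supplementary_pairing_features(mirna, "".join(utr), site)
        assert v["supp_wobble_13_16"] >= 1.0


class TestConservationFeatures:
    def test_constant_track(self, mirna, utr_8mer):
        site = one_site(mirna, utr_8mer)
        track = ConservationTrack("t", np.full(len(utr_8mer), 0.8))
        v = fam.conservation_features(track, site)
        for region in ("core", "site", "flank5", "flank3"):
            assert v[f"cons_{region}_mean"] == pytest.approx(0.8)
            assert v[f"cons_{region}_fracthr"] == 1.0

    def test_step_track(self, mirna):
        utr = TranscriptUTR("t", "G" * 40 + "ACAUUCCA" + "G" * 40)
        site = [s for s in scan_candidate_sites(mirna, utr) if s.site_type == "8mer"][0]
        scores = np.zeros(len(utr))
        scores[site.start:site.end] = 1.0
        v = fam.conservation_features(ConservationTrack("t", scores), site)
        assert v["cons_site_mean"] == 1.0
        assert v["cons_flank5_mean"] == 0.0
        assert v["cons_flank3_mean"] == 0.0

    def test_missing_flank_coverage(self, mirna):
        utr = TranscriptUTR("t", "G" * 40 + "ACAUUCCA" + "G" * 40)
        site = [s for s in scan_candidate_sites(mirna, utr) if s.site_type == "8mer"][0]
        scores = np.full(len(utr), np.nan)
        scores[site.start:site.end] = 0.9
        v = fam.conservation_features(ConservationTrack("t", scores), site)
        assert v["cons_site_mean"] == pytest.approx(0.9)
        assert math.isnan(v["cons_flank5_mean"])

    def test_no_track_all_missing(self, mirna, utr_8mer):
        v = fam.conservation_features(None, one_site(mirna, utr_8mer))
        assert all(math.isnan(x) for x in v.values())


class TestSNPFeatures:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["transcript_id", "position", "disease_related"])

    def test_empty_table(self, mirna, utr_8mer):
        site = one_site(mirna, utr_8mer)
        v = fam.snp_features(self.make_table([]), site)
        assert v["snp_count"] == 0.0
        assert v["snp_dis_count"] == 0.0
        assert v["snp_any_p1"] == 0.0

    def test_disease_snp_at_position_3(self, mirna, utr_8mer):
        site = one_site(mirna, utr_8mer)  # 8mer: site positions 1..8 = start..end
        pos = site.end - 8 + 2  # site position 3
        v = fam.snp_features(self.make_table([("ENST00000000001", pos, True)]), site)
        assert v["snp_any_p3"] == 1.0
        assert v["snp_dis_p3"] == 1.0
        assert v["snp_count"] == 1.0
        assert v["snp_dis_count"] == 1.0

    def test_two_benign_snps(self, mirna, utr_8mer):
        site = one_site(mirna, utr_8mer)
        table = self.make_table([
            ("ENST00000000001", site.start, False),
            ("ENST00000000001", site.start + 1, False),
        ])
        v = fam.snp_features(table, site)
        assert v["snp_count"] == 2.0
        assert v["snp_dis_count"] == 0.0

    def test_6mer_missing_positions(self, mirna):
        utr = TranscriptUTR("t", "GGCAUUCCGG")
        site = one_site(mirna, utr)  # 6mer, length 6
        v = fam.snp_features(self.make_table([]), site)
        assert math.isnan(v["snp_any_p1"])
        assert math.isnan(v["snp_any_p2"])
        assert v["snp_any_p3"] == 0.0

    def test_counts_match_naive_recount(self, mirna):
        rng = np.random.default_rng(8)
        done = 0
        while done < 100:
            utr = random_utr(rng, 200)
            sites = scan_candidate_sites(mirna, utr)
            if not sites:
                continue
            positions = rng.choice(200, size=10, replace=False)
            flags = rng.random(10) < 0.5
            table = self.make_table(
                [(utr.transcript_id, int(p), bool(f)) for p, f in zip(positions, flags)]
            )
            for site in sites:
                v = fam.snp_features(table, site)
                naive = sum(1 for p in positions if site.start <= p < site.end)
                naive_d = sum(
                    1 for p, f in zip(positions, flags) if f and site.start <= p < site.end
                )
                assert v["snp_count"] == naive
                assert v["snp_dis_count"] == naive_d
                done += 1


class TestDescriptors:
    def test_homopolymer_composition(self):
        v = fam.descriptor_features("AAAA")
        assert [v["desc_nt_A"], v["desc_nt_C"], v["desc_nt_G"], v["desc_nt_U"]] == [1, 0, 0, 0]

    def test_acgu_dinucleotides(self):
        v = fam.descriptor_features("ACGU")
        for d in ("AC", "CG", "GU"):
            assert v[f"desc_di_{d}"] == pytest.approx(1 / 3)
        assert v["desc_di_AA"] == 0.0

    def test_kmer_families_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            region = "".join(rng.choice(list("ACGU"), size=int(rng.integers(3, 60))))
            v = fam.descriptor_features(region)
            for k, prefix, names in (
                (1, "desc_nt_", fam.NT),
                (2, "desc_di_", fam.DINUCS),
                (3, "desc_tri_", fam.TRINUCS),
            ):
                total = sum(v[f"{prefix}{x}"] for x in names)
                assert total == pytest.approx(1.0)

    def test_short_region_family_missing(self):
        v = fam.descriptor_features("AC")
        assert math.isnan(v["desc_tri_AAA"])
        assert not math.isnan(v["desc_di_AC"])

    def test_longest_run(self):
        assert fam.descriptor_features("ACGGGU")["desc_maxrun"] == 3.0


class TestFeaturize:
    def test_full_registry_154_names(self, mirna, utr_8mer, registry):
        site = one_site(mirna, utr_8mer)
        vec = featurize(site, mirna, utr_8mer, registry)
        assert len(vec) == 154
        assert list(vec) == registry.feature_names

    def test_missing_conservation_gives_16_nans(self, mirna, utr_8mer, registry):
        site = one_site(mirna, utr_8mer)
        vec = featurize(site, mirna, utr_8mer, registry, resources=None)
        cons = [v for k, v in vec.items() if k.startswith("cons_")]
        assert len(cons) == 16
        assert all(math.isnan(v) for v in cons)

    def test_subset_registry(self, mirna, utr_8mer, registry):
        names = registry.feature_names[:22]
        sub = registry.subset(names)
        vec = featurize(one_site(mirna, utr_8mer), mirna, utr_8mer, sub)
        assert list(vec) == names

    def test_unknown_feature_rejected(self, registry):
        with pytest.raises(ValueError):
            registry.subset(["no_such_feature"])

    def test_determinism(self, mirna, utr_8mer, registry, small_corpus):
        res = small_corpus.resources
        site = one_site(mirna, utr_8mer)
        a = featurize(site, mirna, utr_8mer, registry)
        b = featurize(site, mirna, utr_8mer, registry)
        assert a == b

    def test_registry_round_trip(self, registry, tmp_path):
        registry.save(tmp_path / "reg.json")
        back = FeatureRegistry.load(tmp_path / "reg.json")
        assert back.feature_names == registry.feature_names
        assert back.config == registry.config

    def test_family_cardinalities(self, registry):
        from collections import Counter
        counts = Counter(registry.family_of(n) for n in registry.feature_names)
        assert counts == {
            "site_type": 4, "stability": 4, "accessibility": 13,
            "supplementary": 7, "conservation": 16, "snp": 18, "descriptor": 92,
        }


class TestAssociation:
    def test_identical_feature_high_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        df = pd.DataFrame({"f": np.concatenate([x, x])})
        y = np.array([1] * 40 + [0] * 40)
        table = feature_class_association(df, y)
        assert table.loc[0, "pvalue"] > 0.5

    def test_perfect_separation_extreme_statistic(self):
        # all class-1 values rank above class-0: U equals n1*n2
        df = pd.DataFrame({"f": list(range(20, 40)) + list(range(20))})
        y = np.array([1] * 20 + [0] * 20)
        table = feature_class_association(df, y)
        row = table[table["feature"] == "f"].iloc[0]
        assert row["test"] == "mannwhitneyu"
        assert row["statistic"] == pytest.approx(400)

    def test_constant_flagged(self):
        df = pd.DataFrame({"c": [1.0] * 20, "f": list(range(20))})
        y = np.array([0, 1] * 10)
        table = feature_class_association(df, y)
        row = table[table["feature"] == "c"].iloc[0]
        assert not row["informative"]
        assert row["test"] == "constant"

    def test_indicator_uses_chi_square(self):
        df = pd.DataFrame({"b": [1.0] * 15 + [0.0] * 25})
        y = np.array([1] * 20 + [0] * 20)
        table = feature_class_association(df, y)
        assert table.loc[0, "test"] == "chi2"

    def test_single_class_errors(self):
        df = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            feature_class_association(df, np.array([1, 1]))
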