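"""IUCN grouping, rarity filtering, Venn gamma shares, richness tests."""

import numpy as np
import pytest

from mosaicdiv import (
    RegionSpec,
    classify_iucn,
    rarity_filter,
    richness_comparison,
    venn_shares,
)
from mosaicdiv.resampling import StandardizedResult
from mosaicdiv.beta import BetaPartition
from mosaicdiv.summaries import VENN_SUBSETS

from conftest import make_occ


class TestClassifyIucn:
    @pytest.mark.parametrize(
        "code, group",
        [
            ("CR", "Imperiled"),
            ("EN", "Imperiled"),
            ("VU", "Imperiled"),
            ("NT", "Imperiled"),
            ("LC", "NotThreatened"),
            ("DD", "NotAssessed"),
            (None, "NotAssessed"),
        ],
    )
    def test_grouping(self, code, group):
        assert classify_iucn(code) == group

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValueError, match="XX"):
            classify_iucn("XX")


def _region(members, region_id="r1", focal="SPA"):
    return RegionSpec(
        region_id=region_id,
        focal_pa=region_id,
        focal_level=focal,
        buffer_km=50.0,
        members=members,
    )


class TestRarityFilter:
    def _occ(self):
        # sp0 occurs in 3 surveys, sp1 in 2, sp2 in 1, sp3 in 0
        return make_occ(
            [
                [1, 1, 0, 0],
                [1, 1, 0, 0],
                [1, 0, 1, 0],
            ]
        )

    def _region(self):
        return _region({"SPA": ["s0"], "NPA": ["s1", "s2"]})

    def test_species_below_threshold_dropped(self):
        # sp1 (2 occurrences) and sp2 (1) are rare; sp0 (3) stays and the
        # region-absent sp3 is untouched
        out = rarity_filter(self._occ(), self._region(), min_occ=3)
        assert out.species == ["sp0", "sp3"]
        assert out.surveys == ["s0", "s1", "s2"]

    def test_min_occ_one_is_identity(self):
        occ = self._occ()
        out = rarity_filter(occ, self._region(), min_occ=1)
        assert out == occ.submatrix(self._region().member_ids)

    def test_idempotent(self):
        once = rarity_filter(self._occ(), self._region(), min_occ=2)
        twice = rarity_filter(once, self._region(), min_occ=2)
        assert once == twice

    def test_all_common_species_unchanged(self):
        occ = make_occ(np.ones((3, 2), dtype=np.int8))
        out = rarity_filter(occ, self._region(), min_occ=3)
        assert out == occ.submatrix(self._region().member_ids)


class TestVennShares:
    def test_identical_pools_all_in_triple_intersection(self):
        occ = make_occ(np.tile([1, 1, 0], (3, 1)))
        region = _region({"SPA": ["s0"], "RA": ["s1"], "NPA": ["s2"]})
        shares = venn_shares(region, occ, n_iter=5, rng_seed=0)
        assert shares.shares["SPA&RA&NPA"] == pytest.approx(100.0)
        assert shares.gamma == pytest.approx(2.0)

    def test_disjoint_singletons_split_evenly(self):
        occ = make_occ(np.eye(3, dtype=np.int8))
        region = _region({"SPA": ["s0"], "RA": ["s1"], "NPA": ["s2"]})
        shares = venn_shares(region, occ, n_iter=5, rng_seed=0)
        for level in ("SPA", "RA", "NPA"):
            assert shares.shares[level] == pytest.approx(100 / 3)

    def test_toy_region_matches_set_arithmetic_oracle(self):
        # one survey per level -> no subsampling randomness
        occ = make_occ(
            [
                [1, 1, 1, 0, 0, 0, 1],
                [0, 1, 1, 1, 0, 1, 1],
                [0, 0, 1, 0, 1, 1, 1],
            ]
        )
        region = _region({"SPA": ["s0"], "RA": ["s1"], "NPA": ["s2"]})
        shares = venn_shares(region, occ, n_iter=3, rng_seed=0)
        pools = [occ.pooled([s]) for s in ("s0", "s1", "s2")]
        gamma = set.union(*pools)
        expected = {}
        for subset in VENN_SUBSETS:
            inside = subset.split("&")
            members = set.intersection(*(pools["SPA RA NPA".split().index(lv)] for lv in inside))
            for k, pool in enumerate(pools):
                if "SPA RA NPA".split()[k] not in inside:
                    members -= pool
            expected[subset] = 100 * len(members) / len(gamma)
        for subset, value in expected.items():
            assert shares.shares[subset] == pytest.approx(value)
        assert shares.gamma == len(gamma)

    def test_missing_level_skips_region(self, caplog):
        occ = make_occ(np.eye(2, dtype=np.int8))
        region = _region({"SPA": ["s0"], "NPA": ["s1"]})
        with caplog.at_level("WARNING"):
            assert venn_shares(region, occ, n_iter=3, rng_seed=0) is None
        assert "skipped" in caplog.text

    def test_shares_always_sum_to_100(self, small_dataset):
        from mosaicdiv import build_regions

        occ, surveys, species, _ = small_dataset
        for region in build_regions(surveys, 50):
            if region.focal_level != "SPA":
                continue
            for threat in (None, "Imperiled", "NotThreatened"):
                shares = venn_shares(
                    region,
                    occ,
                    n_iter=11,
                    rng_seed=4,
                    threat_filter=threat,
                    species_info=species,
                )
                if shares is not None:
                    assert sum(shares.shares.values()) == pytest.approx(100.0, abs=1e-9)

    def test_balanced_subsampling_requires_threat_metadata(self):
        occ = make_occ(np.eye(3, dtype=np.int8))
        region = _region({"SPA": ["s0"], "RA": ["s1"], "NPA": ["s2"]})
        with pytest.raises(ValueError, match="species_info"):
            venn_shares(region, occ, n_iter=3, rng_seed=0, threat_filter="Imperiled")


def _std(delta_s):
    return StandardizedResult(
        pair=None,
        n_per_side=1,
        beta=BetaPartition(0.5, 0.3, 0.2),
        delta_s=delta_s,
        n_iter=1,
        seed=0,
    )


class TestRichnessComparison:
    def test_all_positive_deltas_minimal_p(self):
        n = 8
        res = richness_comparison([_std(d) for d in range(1, n + 1)])
        # exact signed-rank: smallest two-sided p at n=8 is 2/2^8
        assert res["wilcoxon_p"] == pytest.approx(2 / 2**n)
        assert res["median_delta_s"] == pytest.approx(4.5)

    def test_single_region_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient regions"):
            richness_comparison([_std(1.0)])

    def test_all_zero_deltas_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            res = richness_comparison([_std(0.0)] * 5)
        assert res["wilcoxon_p"] == 1.0

    def test_symmetric_deltas_give_uniform_p(self):
        rng = np.random.default_rng(3)
        ps = [
            richness_comparison([_std(d) for d in rng.normal(size=40)])["wilcoxon_p"]
            for _ in range(300)
        ]
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01
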