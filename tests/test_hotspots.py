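"""Genome binning, hotspot permutation test, consensus intervals."""

import numpy as np
import pytest

from bxdnet.datatypes import ConfigurationError, MarkerMap
from bxdnet.eqtl import EqtlRecord
from bxdnet.hotspots import (HotspotDetector, bin_eqtl, consensus_interval,
                             hotspot_test)
from bxdnet.simulate import make_genotypes


def rec(chrom=1, pos=5.0, interval=None, trait="t", marker="m"):
    return EqtlRecord(trait=trait, dataset="d", peak_marker=marker,
                      chrom=chrom, pos_mb=pos, lod=4.0, genome_p=0.1,
                      tier="suggestive", eqtl_class="trans",
                      interval=interval or (chrom, pos - 10, pos + 10))


class TestBinning:
    def test_boundary_goes_to_upper_bin(self):
        counts = bin_eqtl([rec(pos=30.0)])
        assert counts == {(1, 30.0): 1}

    def test_just_below_boundary_stays_in_lower_bin(self):
        counts = bin_eqtl([rec(pos=29.999)])
        assert counts == {(1, 20.0): 1}

    def test_counts_accumulate_per_bin(self):
        counts = bin_eqtl([rec(pos=1.0), rec(pos=9.0), rec(pos=11.0)])
        assert counts[(1, 0.0)] == 2 and counts[(1, 10.0)] == 1


@pytest.fixture(scope="module")
def wide_panel():
    m = MarkerMap.regular(n_chromosomes=5, markers_per_chr=20,
                          spacing_mb=10.0)
    return make_genotypes(20, m, 0.25, seed=0)


class TestHotspotTest:
    def test_concentrated_eqtl_detected(self, wide_panel):
        records = [rec(chrom=2, pos=40.0 + 0.1 * i, trait=f"t{i}")
                   for i in range(50)]
        hits, thr = hotspot_test(records, wide_panel, n_perm=1000, seed=1)
        assert (2, 40.0) in hits

    def test_single_eqtl_never_significant(self, wide_panel):
        hits, _ = hotspot_test([rec()], wide_panel, n_perm=1000, seed=2)
        assert hits == {}

    def test_uniform_placement_controls_family_wise_error(self, wide_panel):
        rng = np.random.default_rng(3)
        m = wide_panel.map
        false_calls = 0
        n_rep = 60
        for i in range(n_rep):
            picks = rng.integers(0, len(m), size=40)
            records = [rec(chrom=int(m.chromosomes[j]),
                           pos=float(m.positions_mb[j]), trait=f"t{k}")
                       for k, j in enumerate(picks)]
            hits, _ = hotspot_test(records, wide_panel, n_perm=500,
                                   seed=100 + i)
            false_calls += bool(hits)
        assert false_calls / n_rep < 0.15

    def test_empty_records_give_empty_result(self, wide_panel):
        hits, thr = hotspot_test([], wide_panel, n_perm=1000)
        assert hits == {} and np.isnan(thr)


class TestConsensus:
    def _map(self):
        return MarkerMap.regular(n_chromosomes=1, markers_per_chr=20,
                                 spacing_mb=10.0)

    def test_identical_member_intervals_returned_verbatim(self):
        members = [rec(pos=50.0, interval=(1, 40.0, 80.0), trait=f"t{i}")
                   for i in range(5)]
        assert consensus_interval(members, self._map()) == (40.0, 80.0)

    def test_inclusion_fraction_boundary(self):
        # marker at 100 Mb inside 8 of 10 intervals -> included;
        # marker at 110 Mb inside 7 of 10 -> excluded
        members = [rec(pos=90.0, interval=(1, 80.0, 100.0), trait=f"a{i}")
                   for i in range(8)]
        members += [rec(pos=90.0, interval=(1, 80.0, 90.0), trait=f"b{i}")
                    for i in range(2)]
        members[0] = rec(pos=90.0, interval=(1, 80.0, 110.0), trait="wide0")
        lo, hi = consensus_interval(members, self._map(), inclusion=0.8)
        assert hi == 100.0 and lo == 80.0

    def test_disjoint_intervals_yield_empty(self):
        members = [rec(pos=10.0, interval=(1, 0.0, 20.0), trait="a"),
                   rec(pos=150.0, interval=(1, 140.0, 160.0), trait="b"),
                   rec(pos=60.0, interval=(1, 50.0, 70.0), trait="c")]
        with pytest.warns(UserWarning):
            out = consensus_interval(members, self._map())
        assert out is None

    def test_needs_two_members(self):
        with pytest.raises(ConfigurationError):
            consensus_interval([rec()], self._map())


class TestDetector:
    def test_detects_planted_master_locus(self, dataset):
        from bxdnet.eqtl import EqtlScanner
        from bxdnet.sscore import SScoreTransformer
        truth = dataset.truth
        master = next(iter(truth.trans_masters))
        j = dataset.panel.map.marker_ids.index(master)
        mpos = dataset.panel.map.positions_mb[j]
        mchr = int(dataset.panel.map.chromosomes[j])
        S = SScoreTransformer().fit(dataset.probes).transform(dataset.probes)
        targets = list(truth.trans_masters[master])
        background = [g for g in S.index if g not in targets][:120]
        sc = EqtlScanner(n_permutations=200, random_state=4, dataset="sscore")
        sc.fit(S.loc[targets + background], dataset.panel, dataset.annotation)
        suggestive_trans = [r for r in sc.records_
                            if r.tier in ("significant", "suggestive")
                            and r.eqtl_class == "trans"]
        hd = HotspotDetector(n_permutations=2000, random_state=5)
        hd.fit(suggestive_trans, dataset.panel)
        bins = [(b.chromosome, b.bin_start) for b in hd.transbands_]
        expected_bin = (mchr, np.floor(mpos / 10) * 10)
        assert expected_bin in bins
        band = hd.transbands_[bins.index(expected_bin)]
        assert band.consensus is not None
        lo, hi = band.consensus
        assert lo <= mpos <= hi
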