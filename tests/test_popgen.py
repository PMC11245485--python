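import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stresshub as sh
from stresshub.genotypes import GenotypePanel
from stresshub.popgen import (genotype_group_test, precipitation_association,
                              sweep_contrast, windowed_pi, zscore_normalize)


def pairwise_pi_oracle(dosages):
    """Average pairwise difference over explicitly enumerated alleles."""
    total = 0.0
    for row in dosages:
        alleles = []
        for d in row:
            if not np.isnan(d):
                alleles += [1] * int(d) + [0] * (2 - int(d))
        pairs = list(itertools.combinations(range(len(alleles)), 2))
        if pairs:
            total += sum(alleles[i] != alleles[j] for i, j in pairs) / len(pairs)
    return total


def _panel(pos, dosage, n_acc=None, groups=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_acc = dosage.shape[1]
    return GenotypePanel(
        variant_ids=[f"v{i}" for i in range(len(pos))],
        chrom=np.array(["chr1"] * len(pos), dtype=object),
        pos=np.array(pos), ref=["A"] * len(pos), alt=["T"] * len(pos),
        dosage=dosage, accession_ids=[f"a{i}" for i in range(n_acc)],
        groups=None if groups is None else np.array(groups, dtype=object))


class TestWindowedPi:
    def test_monomorphic_window_zero(self):
        p = _panel([10, 50], [[0, 0, 0], [2, 2, 2]])
        prof = windowed_pi(p, region=("chr1", 1, 200), window=200)
        assert prof["pi"].iloc[0] == 0.0 and prof["n_sites"].iloc[0] == 0

    def test_hand_computed_single_site(self):
        # dosages (0, 2): p=0.5, n=4 alleles -> pi_site = (4/3)*0.5 = 0.6667
        p = _panel([10], [[0, 2]])
        prof = windowed_pi(p, region=("chr1", 1, 200), window=200)
        assert prof["pi"].iloc[0] == pytest.approx((4 / 3) * 0.5 / 200)
        assert prof["pi_per_site"].iloc[0] == pytest.approx((4 / 3) * 0.5)

    def test_matches_allele_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_sites = rng.integers(1, 21)
            n_dip = rng.integers(2, 11)
            d = rng.integers(0, 3, size=(n_sites, n_dip)).astype(float)
            d[rng.random(d.shape) < 0.1] = -1
            pos = np.sort(rng.choice(np.arange(1, 200), n_sites, replace=False))
            p = _panel(pos, d.astype(np.int8))
            prof = windowed_pi(p, region=("chr1", 1, 200), window=200)
            oracle = pairwise_pi_oracle(np.where(d < 0, np.nan, d))
            assert prof["pi"].iloc[0] * 200 == pytest.approx(oracle, abs=1e-12)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(10, 8)).astype(np.int8)
        p1 = _panel(np.arange(1, 11), d)
        p2 = _panel(np.arange(1, 11), 2 - d)   # swap ref/alt
        a = windowed_pi(p1, region=("chr1", 1, 200))
        b = windowed_pi(p2, region=("chr1", 1, 200))
        assert np.allclose(a["pi"], b["pi"])

    def test_windows_tile_region(self):
        p = _panel([10, 250, 399], [[0, 1], [1, 1], [0, 2]])
        prof = windowed_pi(p, region=("chr1", 1, 400), window=200)
        assert list(prof["start"]) == [1, 201]
        assert list(prof["end"]) == [200, 400]

    def test_missing_group_errors(self):
        p = _panel([10], [[0, 1]], groups=["x", "x"])
        with pytest.raises(ValueError):
            windowed_pi(p, group="absent", region=("chr1", 1, 200))


class TestSweepContrast:
    def _profiles(self, pi_wild, pi_cult):
        base = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(1, len(pi_wild) * 200, 200),
            "end": np.arange(200, len(pi_wild) * 200 + 1, 200),
        })
        w = base.assign(group="O. ruf", pi=pi_wild)
        c = base.assign(group="japonica", pi=pi_cult)
        return w, c

    def test_identical_groups_not_flagged(self):
        w, c = self._profiles([0.01] * 10, [0.01] * 10)
        call = sweep_contrast(w, c)
        assert call.flag is False and call.ratio == pytest.approx(1.0)

    def test_low_cultivated_diversity_flagged(self):
        w, c = self._profiles([0.01] * 10, [0.001] * 10)
        assert sweep_contrast(w, c).flag is True

    def test_zero_wild_windows_uninformative(self):
        w, c = self._profiles([0.0, 0.01], [0.0, 0.001])
        call = sweep_contrast(w, c)
        assert call.n_informative == 1 and call.flag is True
        w0, c0 = self._profiles([0.0] * 4, [0.0] * 4)
        assert sweep_contrast(w0, c0).flag is None

    def test_monotone_in_cultivated_diversity(self):
        rng = np.random.default_rng(2)
        wild = rng.uniform(0.005, 0.02, 12)
        cult = wild * rng.uniform(0.2, 1.2, 12)
        w, c = self._profiles(wild, cult)
        flag = sweep_contrast(w, c).flag
        w2, c2 = self._profiles(wild, cult * 0.5)
        if flag:
            assert sweep_contrast(w2, c2).flag

    def test_planted_sweep_recovered_null_region_not(self, small_bundle):
        _, panel, _, _, _, truth = small_bundle
        chrom = panel.chrom[0]
        sw = truth.sweep_window
        null_region = (chrom, 5 * 7000 + 1, 5 * 7000 + 6000)
        for region, expected in [((chrom, sw[0], sw[1]), True),
                                 (null_region, False)]:
            w = windowed_pi(panel, group="O. ruf", region=region)
            c = windowed_pi(panel, group="japonica", region=region)
            assert sweep_contrast(w, c).flag is expected


class TestGroupStats:
    def test_separation_limit(self):
        t, p, ma, mb = genotype_group_test([1.0, 1.0001, 0.9999],
                                           [2.0, 2.0001, 1.9999])
        assert p < 1e-6 and ma < mb

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(500):
            a, b = rng.normal(size=(2, 20))
            ps.append(genotype_group_test(a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            genotype_group_test([1.0], [2.0, 3.0])

    def test_zscore_hand_example(self):
        assert np.allclose(zscore_normalize([1, 2, 3]), [-1, 0, 1])
        z = zscore_normalize(np.random.default_rng(4).normal(5, 2, 50))
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)

    def test_zscore_degenerate_errors(self):
        with pytest.raises(ValueError):
            zscore_normalize([3.0])
        with pytest.raises(ValueError):
            zscore_normalize([2.0, 2.0, 2.0])


class TestPrecipitationAssociation:
    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(5)
        flags = 0
        for _ in range(500):
            precip = rng.normal(1200, 300, 120)
            carrier = rng.random(120) < 0.4
            if carrier.sum() < 2 or (~carrier).sum() < 2:
                continue
            flags += precipitation_association(precip, carrier, alpha=0.01).flag
        assert flags / 500 <= 0.03

    def test_planted_cline_recovered_with_sign(self):
        hits = 0
        for seed in range(10):
            cfg = sh.SimConfig(seed=seed, n_accessions=70, n_variants=300)
            panel, truth = sh.simulate_genotypes(cfg)
            geo = sh.simulate_geography(cfg)
            ci = panel.variant_ids.index(truth.cline_variant_id)
            carrier = panel.dosage_float()[ci] > 0
            res = precipitation_association(
                geo["precip_mm"].to_numpy(), carrier, alpha=0.01)
            hits += res.flag and res.r_pointbiserial > 0
        assert hits >= 9

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            precipitation_association(np.ones(10) * 100, np.ones(10, bool))

    def test_mostly_missing_precip_errors(self):
        precip = np.full(20, np.nan)
        precip[:5] = 100.0
        with pytest.raises(ValueError):
            precipitation_association(precip, np.arange(20) % 2 == 0)
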