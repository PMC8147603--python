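import numpy as np
import pytest

from beemito.io_formats import GenotypeTable, MtSequence
from beemito.relatedness import (
    allele_freqs,
    bootstrap_ci,
    dedup_filter,
    qg_relatedness,
)
from beemito.synthetic_data import SimConfig, simulate_pedigree_genotypes


def _table(genos_by_sample, loci=None):
    sample_ids = list(genos_by_sample)
    loci = loci or [f"L{i}" for i in range(len(next(iter(genos_by_sample.values()))))]
    alleles = {
        sid: {loc: g for loc, g in zip(loci, gs)}
        for sid, gs in genos_by_sample.items()
    }
    return GenotypeTable(sample_ids, loci, alleles)


class TestAlleleFreqs:
    def test_simple_counting(self):
        gt = _table({"a": [(1, 1)], "b": [(1, 2)]})
        freqs = allele_freqs(gt)
        assert freqs["L0"] == {1: 0.75, 2: 0.25}

    def test_missing_excluded_and_sum_to_one(self):
        gt = _table({"a": [(1, 2), None], "b": [(2, 3), (5, 5)]})
        freqs = allele_freqs(gt)
        for locus in gt.loci:
            assert sum(freqs[locus].values()) == pytest.approx(1.0)
        assert freqs["L1"] == {5: 1.0}

    def test_all_missing_locus_is_error(self):
        gt = _table({"a": [(1, 1), None], "b": [(1, 2), None]})
        with pytest.raises(ValueError, match="L1"):
            allele_freqs(gt)


class TestQgRelatedness:
    def test_self_pair_is_exactly_one(self, rng):
        genos = {
            f"s{i}": [tuple(sorted(rng.integers(1, 9, 2).tolist())) for _ in range(13)]
            for i in range(20)
        }
        gt = _table(genos)
        freqs = allele_freqs(gt)
        for sid in list(genos)[:5]:
            r, n = qg_relatedness(gt, (sid, sid), freqs)
            assert r == pytest.approx(1.0, abs=1e-12)
            assert n == 13

    def test_symmetry(self, rng):
        genos = {
            f"s{i}": [tuple(sorted(rng.integers(1, 9, 2).tolist())) for _ in range(13)]
            for i in range(10)
        }
        gt = _table(genos)
        freqs = allele_freqs(gt)
        r_xy, _ = qg_relatedness(gt, ("s0", "s1"), freqs)
        r_yx, _ = qg_relatedness(gt, ("s1", "s0"), freqs)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)

    def test_unrelated_mean_near_zero(self, rng):
        # 2000 unrelated diploids, 13 loci x 8 equifrequent alleles
        genos = {
            f"s{i}": [tuple(sorted(rng.integers(1, 9, 2).tolist())) for _ in range(13)]
            for i in range(2000)
        }
        gt = _table(genos)
        freqs = allele_freqs(gt)
        idx = rng.permutation(2000)
        rs = [
            qg_relatedness(gt, (f"s{idx[2 * k]}", f"s{idx[2 * k + 1]}"), freqs)[0]
            for k in range(1000)
        ]
        assert abs(float(np.mean(rs))) < 0.02

    def test_super_sister_mean_three_quarters(self):
        cfg = SimConfig(seed=21, n_loci=13, n_alleles=10)
        ids = [f"s{i}" for i in range(300)]
        pairs = [(f"s{2 * k}", f"s{2 * k + 1}") for k in range(75)]
        gt = simulate_pedigree_genotypes(cfg, ids, pairs)
        freqs = allele_freqs(gt)
        rs = [qg_relatedness(gt, p, freqs)[0] for p in pairs]
        assert float(np.mean(rs)) == pytest.approx(0.75, abs=0.03)

    def test_missing_loci_reduce_n_used(self):
        gt = _table({"a": [(1, 2), None, (3, 4)], "b": [(1, 1), (2, 2), None]})
        freqs = allele_freqs(gt)
        _, n = qg_relatedness(gt, ("a", "b"), freqs)
        assert n == 1


class TestBootstrapCI:
    def test_self_pair_ci_is_unity(self, rng):
        genos = {
            f"s{i}": [tuple(sorted(rng.integers(1, 9, 2).tolist())) for _ in range(13)]
            for i in range(10)
        }
        gt = _table(genos)
        lo, hi = bootstrap_ci(gt, ("s0", "s0"), n_boot=200, seed=3)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_single_usable_locus_undefined(self):
        gt = _table({"a": [(1, 2), None], "b": [(1, 1), (2, 2)], "c": [(1, 2), (2, 2)]})
        assert bootstrap_ci(gt, ("a", "b"), n_boot=100, seed=0) == (None, None)

    def test_n_boot_floor(self):
        gt = _table({"a": [(1, 2)], "b": [(1, 1)]})
        with pytest.raises(ValueError):
            bootstrap_ci(gt, ("a", "b"), n_boot=10, seed=0)

    def test_deterministic_under_seed(self, rng):
        genos = {
            f"s{i}": [tuple(sorted(rng.integers(1, 9, 2).tolist())) for _ in range(13)]
            for i in range(30)
        }
        gt = _table(genos)
        a = bootstrap_ci(gt, ("s0", "s1"), n_boot=150, seed=9)
        b = bootstrap_ci(gt, ("s0", "s1"), n_boot=150, seed=9)
        assert a == b

    def test_super_sister_power(self):
        # >= 80% of super-sister pairs significantly exceed zero at conf 0.95
        cfg = SimConfig(seed=8, n_loci=13, n_alleles=10)
        ids = [f"s{i}" for i in range(200)]
        pairs = [(f"s{2 * k}", f"s{2 * k + 1}") for k in range(50)]
        gt = simulate_pedigree_genotypes(cfg, ids, pairs)
        freqs = None
        hits = 0
        for k, pair in enumerate(pairs):
            lo, _ = bootstrap_ci(gt, pair, n_boot=300, seed=100 + k)
            hits += lo is not None and lo > 0
        assert hits / len(pairs) >= 0.80


class TestDedupFilter:
    def _samples(self, coords):
        return [
            MtSequence(sid, "ACGT", latitude=lat, longitude=lon)
            for sid, (lat, lon) in coords.items()
        ]

    def _clone_gt(self, ids, rng, clones=()):
        # background genotypes keep allele frequencies non-degenerate
        background = [f"bg{i}" for i in range(20)]
        genos = {
            sid: [tuple(sorted(rng.integers(1, 11, 2).tolist())) for _ in range(13)]
            for sid in list(ids) + background
        }
        for a, b in clones:
            genos[b] = list(genos[a])
        return _table(genos)

    def test_close_clones_deduplicated(self, rng):
        samples = self._samples({"a": (50.0, 20.0), "b": (50.005, 20.0)})
        gt = self._clone_gt(["a", "b"], rng, clones=[("a", "b")])
        kept, log = dedup_filter(samples, {"a": "G1", "b": "G1"}, gt, seed=0)
        assert kept == ["a"]  # lexicographically later member dropped
        assert log[0].dropped_id == "b" and log[0].significant

    def test_distance_gate(self, rng):
        samples = self._samples({"a": (50.0, 20.0), "b": (50.1, 20.0)})  # ~11 km
        gt = self._clone_gt(["a", "b"], rng, clones=[("a", "b")])
        kept, log = dedup_filter(samples, {"a": "G1", "b": "G1"}, gt, seed=0)
        assert kept == ["a", "b"] and log == []

    def test_haplotype_gate(self, rng):
        samples = self._samples({"a": (50.0, 20.0), "b": (50.005, 20.0)})
        gt = self._clone_gt(["a", "b"], rng, clones=[("a", "b")])
        kept, log = dedup_filter(samples, {"a": "G1", "b": "G2"}, gt, seed=0)
        assert kept == ["a", "b"]
        assert not log[0].same_haplotype and log[0].dropped_id is None

    def test_kept_plus_dropped_conserves_input(self, rng):
        ids = {f"s{i}": (50.0 + 0.004 * i, 20.0) for i in range(6)}
        samples = self._samples(ids)
        gt = self._clone_gt(list(ids), rng, clones=[("s0", "s1"), ("s3", "s4")])
        hap = {sid: "G1" for sid in ids}
        kept, log = dedup_filter(samples, hap, gt, seed=4)
        dropped = {d.dropped_id for d in log if d.dropped_id}
        assert set(kept) | dropped == set(ids)
        assert len(kept) + len(dropped) == len(ids)

    def test_missing_coordinates_rejected(self, rng):
        gt = self._clone_gt(["a", "b"], rng)
        with pytest.raises(ValueError, match="coordinates"):
            dedup_filter(
                [MtSequence("a", "ACGT"), MtSequence("b", "ACGT", 50.0, 20.0)],
                {"a": "G1", "b": "G1"},
                gt,
            )
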