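"""Mapping, smart shared counting, rarefaction, FPKM, gene-count split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_shared_count, enumerate_downsize, enumerate_richness

from imppipe.gene_quant import (
    GeneCatalog,
    GeneCountTable,
    GeneQuantConfig,
    ReadMapping,
    ReadSet,
    classify_gene_count,
    compute_gene_richness,
    downsize_counts,
    fpkm_normalize,
    map_reads,
    richness_bimodal_threshold,
    smart_shared_count,
)
from imppipe.synthetic_data import generate_gene_catalog


@pytest.fixture(scope="module")
def catalog():
    return generate_gene_catalog(6, (400, 400), seed=3)


class TestMapReads:
    def test_exact_substring_maps_uniquely(self, catalog):
        read = catalog.sequences[2][100:250]
        m = map_reads(ReadSet(["r"], [read]), catalog, GeneQuantConfig())
        assert m.to_dict() == {"r": [(catalog.ids[2], 150, 1.0)]}

    def test_reverse_complement_read_maps(self, catalog):
        from imppipe._seq import revcomp

        read = revcomp(catalog.sequences[1][10:160])
        m = map_reads(ReadSet(["r"], [read]), catalog, GeneQuantConfig())
        assert [g for g, _, _ in m.to_dict()["r"]] == [catalog.ids[1]]

    @pytest.mark.parametrize("n_subs,mapped", [(10, False), (7, True)])
    def test_identity_threshold(self, catalog, n_subs, mapped):
        # 10 substitutions over 150 nt = identity 0.933 < 0.95; 7 = 0.953
        seq = list(catalog.sequences[0][50:200])
        for i in range(n_subs):
            pos = 35 + i  # away from the seed probes at 0, 59, 119
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        m = map_reads(ReadSet(["r"], ["".join(seq)]), catalog, GeneQuantConfig())
        assert ("r" in m.to_dict()) == mapped

    def test_shared_read_hits_both_copies(self):
        base = generate_gene_catalog(1, (400, 400), seed=9).sequences[0]
        cat = GeneCatalog(["g1", "g2"], [base, base])
        read = base[20:170]
        m = map_reads(ReadSet(["r"], [read]), cat, GeneQuantConfig())
        assert sorted(g for g, _, _ in m.to_dict()["r"]) == ["g1", "g2"]

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            map_reads(ReadSet([], []), GeneCatalog([], []), GeneQuantConfig())

    def test_unrelated_read_unmapped(self, catalog):
        m = map_reads(ReadSet(["r"], ["ACGT" * 40]), catalog, GeneQuantConfig())
        assert m.to_dict() == {}


class TestSmartSharedCount:
    def test_hand_worked_split(self):
        rm = ReadMapping.from_hits(
            {"r1": ["g1"], "r2": ["g1"], "r3": ["g2"], "r4": ["g1", "g2"]}, ["g1", "g2"]
        )
        t = smart_shared_count({"s": rm})
        assert t.data.loc["s", "g1"] == pytest.approx(2 + 2 / 3)
        assert t.data.loc["s", "g2"] == pytest.approx(1 + 1 / 3)
        assert t.data.loc["s"].sum() == pytest.approx(t.mapped_totals["s"]) == 4

    def test_all_unique_reads(self):
        rm = ReadMapping.from_hits({"r1": ["g1"], "r2": ["g2"], "r3": ["g2"]}, ["g1", "g2"])
        t = smart_shared_count({"s": rm})
        assert t.data.loc["s"].tolist() == [1.0, 2.0]

    def test_zero_unique_shared_read_splits_equally(self):
        rm = ReadMapping.from_hits({"r1": ["g1", "g2"]}, ["g1", "g2"])
        t = smart_shared_count({"s": rm})
        assert t.data.loc["s"].tolist() == [0.5, 0.5]

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_and_conserves(self, data):
        gene_ids = ["g1", "g2", "g3"]
        n_reads = data.draw(st.integers(1, 8))
        hits = {
            f"r{i}": sorted(
                data.draw(
                    st.sets(st.sampled_from(gene_ids), min_size=1, max_size=3),
                    label=f"read{i}",
                )
            )
            for i in range(n_reads)
        }
        t = smart_shared_count({"s": ReadMapping.from_hits(hits, gene_ids)})
        expected = brute_force_shared_count(hits)
        for g in gene_ids:
            assert t.data.loc["s", g] == pytest.approx(expected.get(g, 0.0), abs=1e-9)
        assert t.data.loc["s"].sum() == pytest.approx(n_reads, abs=1e-6)


class TestRarefaction:
    def _table(self, hits):
        genes = sorted({g for gs in hits.values() for g in gs})
        return smart_shared_count({"s": ReadMapping.from_hits(hits, genes)})

    def test_downsize_identity_at_full_depth(self):
        t = self._table({"r1": ["g1"], "r2": ["g1"], "r3": ["g2"]})
        d = downsize_counts(t, 3, n_reps=5, seed=0)
        assert d.data.loc["s"].tolist() == t.data.loc["s"].tolist()
        assert d.stage == "downsized"

    def test_downsize_matches_enumeration(self):
        reads = {"r1": ["g1"], "r2": ["g1"], "r3": ["g2"]}
        t = self._table(reads)
        n_reps = 3000
        d = downsize_counts(t, 2, n_reps=n_reps, seed=1)
        expected = enumerate_downsize(["g1", "g1", "g2"], 2)
        # per-rep variance of the g1 count is 2/9
        tol = 3 * np.sqrt((2 / 9) / n_reps)
        assert d.data.loc["s", "g1"] == pytest.approx(expected["g1"], abs=tol)
        assert d.data.loc["s", "g2"] == pytest.approx(expected["g2"], abs=tol)

    def test_downsize_excludes_shallow_sample(self):
        t = self._table({"r1": ["g1"]})
        d = downsize_counts(t, 5, n_reps=2, seed=0)
        assert "s" not in d.data.index
        assert "s" in d.excluded

    def test_richness_full_depth_is_detection_count(self):
        t = self._table({"r1": ["g1"], "r2": ["g1"], "r3": ["g1"], "r4": ["g2"]})
        r = compute_gene_richness(t, 4, n_reps=3, seed=0)
        assert r.richness["s"] == 2.0

    def test_richness_matches_enumeration(self):
        t = self._table({"r1": ["g1"], "r2": ["g1"], "r3": ["g2"]})
        n_reps = 3000
        r = compute_gene_richness(t, 2, n_reps=n_reps, seed=2)
        mean, var = enumerate_richness(["g1", "g1", "g2"], 2)
        assert mean == pytest.approx(5 / 3)
        assert r.richness["s"] == pytest.approx(mean, abs=3 * np.sqrt(var / n_reps))

    def test_rarefied_richness_bounded_by_full(self):
        hits = {f"r{i}": [f"g{i % 4}"] for i in range(12)}
        t = self._table(hits)
        full = compute_gene_richness(t, 12, 1, seed=0).richness["s"]
        for depth in (3, 6, 9):
            r = compute_gene_richness(t, depth, n_reps=20, seed=depth)
            assert r.richness["s"] <= full + 1e-9


class TestFpkm:
    def _single(self, count, length, total):
        cat = GeneCatalog(["g"], ["A" * length])
        t = GeneCountTable(
            data=pd.DataFrame({"g": [float(count)]}, index=["s"]),
            stage="downsized",
            mapped_totals=pd.Series({"s": float(total)}),
        )
        return fpkm_normalize(t, cat).data.loc["s", "g"]

    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(10, 1000, 10**6, 10.0), (0, 500, 10**6, 0.0), (5, 500, 2 * 10**6, 5.0)],
    )
    def test_values(self, count, length, total, expected):
        assert self._single(count, length, total) == pytest.approx(expected)

    def test_scale_equivariance(self):
        for c in (2.0, 10.0):
            assert self._single(7 * c, 800, int(3e5 * c)) == pytest.approx(
                self._single(7, 800, int(3e5))
            )

    def test_missing_gene_is_keyed_error(self):
        cat = GeneCatalog(["other"], ["A" * 200])
        t = GeneCountTable(
            data=pd.DataFrame({"g": [1.0]}, index=["s"]),
            stage="downsized",
            mapped_totals=pd.Series({"s": 100.0}),
        )
        with pytest.raises(KeyError, match="g"):
            fpkm_normalize(t, cat)


class TestGeneCountClass:
    def test_boundary_is_strict_less_than(self):
        assert classify_gene_count(606_999, 607_000) == "low"
        assert classify_gene_count(607_000, 607_000) == "high"
        assert classify_gene_count(0, 607_000) == "low"

    def test_negative_richness_rejected(self):
        with pytest.raises(ValueError):
            classify_gene_count(-1, 607_000)

    def test_bimodal_threshold_separates_planted_modes(self, rng):
        low = rng.lognormal(np.log(1500), 0.08, 150)
        high = rng.lognormal(np.log(3200), 0.08, 150)
        thr = richness_bimodal_threshold(np.concatenate([low, high]), seed=0)
        assert 1800 < thr < 2900
        assert (low < thr).all() and (high >= thr).all()
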