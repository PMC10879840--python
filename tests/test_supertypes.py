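"""Descriptor matrices, k selection, DAPC-style supertype assignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from owlmhc import simdata
from owlmhc.genotyper import translate
from owlmhc.supertypes import (
    assign_supertypes,
    build_descriptor_matrix,
    filter_common_supertypes,
    kmeans_bic,
    screen_selected_sites,
    select_k,
    supertype_frequencies,
)


class TestSiteScreen:
    def test_external_list_passthrough(self):
        assert screen_selected_sites({}, "external_list", sites=[7, 9, 24]) == [7, 9, 24]

    def test_empty_external_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty site list"):
            screen_selected_sites({}, "external_list", sites=[])

    def test_monomorphic_alignment_rejected(self):
        aln = {"a": "AAAA", "b": "AAAA"}
        with pytest.raises(ValueError, match="monomorphic"):
            screen_selected_sites(aln, "heuristic")

    def test_heuristic_recovers_injected_variable_sites(self, dab2_pool, dab2_alignment):
        spec, _ = dab2_pool
        found = screen_selected_sites(
            dab2_alignment, "heuristic", n_sites=len(spec.selected_sites)
        )
        # motif variation was built into the selected sites, so most of the
        # top-entropy columns are exactly those sites
        overlap = set(found) & set(spec.selected_sites)
        assert len(overlap) >= len(spec.selected_sites) - 2


class TestDescriptorMatrix:
    def test_shape_is_alleles_by_5_sites(self):
        spec = simdata.DEFAULT_LOCI["DAB1"]
        pool = simdata.generate_allele_pool(spec, seed=1)
        aln = {k: translate(v) for k, v in pool.items()}
        mat = build_descriptor_matrix(aln, list(spec.selected_sites))
        assert mat.shape == (31, 15 * 5)

    def test_identical_residues_at_sites_identical_rows(self):
        aln = {"a": "AYDW", "b": "AYDF", "c": "GYKW"}
        mat = build_descriptor_matrix(aln, [1, 2, 3])  # site 4 ignored
        np.testing.assert_allclose(mat.loc["a"], mat.loc["b"])
        assert not np.allclose(mat.loc["a"], mat.loc["c"])

    def test_columns_standardized(self, dab2_pool, dab2_alignment):
        spec, _ = dab2_pool
        mat = build_descriptor_matrix(dab2_alignment, list(spec.selected_sites))
        assert np.abs(mat.mean(axis=0)).max() < 1e-9
        sds = mat.std(axis=0, ddof=0)
        assert ((np.abs(sds - 1) < 1e-9) | (sds == 0)).all()

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError, match="empty site list"):
            build_descriptor_matrix({"a": "AY"}, [])


def _blobs(k=3, per=8, sep=12.0, seed=0, dim=4):
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, (k, dim))
    rows, labels = [], []
    for i in range(k):
        for j in range(per):
            rows.append(centers[i] + rng.normal(0, 0.5, dim))
            labels.append(f"a{i}{j:02d}")
    return pd.DataFrame(rows, index=labels)


class TestSelectK:
    def test_three_motif_blobs_found_by_both_methods(self):
        # motif-structured data (alleles sharing a binding motif have
        # identical descriptor rows), the substrate this selector is for
        rng = np.random.default_rng(0)
        motifs = rng.normal(0, 5, (3, 6))
        rows = np.vstack([np.repeat(motifs, 4, axis=0)])
        mat = pd.DataFrame(rows, index=[f"a{i:02d}" for i in range(12)])
        for method in ("BIC", "silhouette"):
            k, table = select_k(mat, range(2, 7), method=method, seed=0, n_restarts=20)
            assert k == 3, f"{method} chose {k}"

    def test_bic_matches_direct_recomputation(self):
        mat = _blobs(3)
        _, table = select_k(mat, range(2, 7), method="silhouette", seed=0,
                            n_restarts=20)
        from sklearn.cluster import KMeans

        km = KMeans(3, n_init=20, random_state=0).fit(mat.to_numpy())
        bic = kmeans_bic(mat.to_numpy(), km.labels_, km.cluster_centers_, 3)
        assert table.loc[3, "bic"] == pytest.approx(bic, rel=1e-9)

    def test_matches_exhaustive_silhouette_small_instance(self):
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        mat = _blobs(3, per=4)  # 12 alleles
        k, table = select_k(mat, range(2, 6), method="silhouette", seed=0,
                            n_restarts=20)
        best = None
        for kk in range(2, 6):
            km = KMeans(kk, n_init=20, random_state=0).fit(mat.to_numpy())
            s = silhouette_score(mat.to_numpy(), km.labels_)
            if best is None or s > best[1]:
                best = (kk, s)
        assert k == best[0]

    def test_duplicated_dataset_same_k(self):
        mat = _blobs(3)
        dup = pd.concat([mat, mat.set_axis([f"{i}_copy" for i in mat.index])])
        k1, _ = select_k(mat, range(2, 7), seed=0, n_restarts=20)
        k2, _ = select_k(dup, range(2, 7), seed=0, n_restarts=20)
        assert k1 == k2

    def test_weak_structure_logged(self, caplog):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(30, 4)),
                           index=[f"a{i:02d}" for i in range(30)])
        import logging

        with caplog.at_level(logging.WARNING, logger="owlmhc.supertypes"):
            select_k(mat, range(2, 6), method="silhouette", seed=0, n_restarts=10,
                     silhouette_floor=0.4)
        assert any("weak cluster structure" in r.message for r in caplog.records)


class TestAssignment:
    def test_separated_clusters_stable_under_seed(self):
        mat = _blobs(4, seed=2)
        a1 = assign_supertypes(mat, 4, seed=0, n_restarts=20)
        a2 = assign_supertypes(mat, 4, seed=99, n_restarts=20)
        l1 = [a1.mapping[i] for i in mat.index]
        l2 = [a2.mapping[i] for i in mat.index]
        assert adjusted_rand_score(l1, l2) == pytest.approx(1.0)

    def test_k1_single_supertype(self):
        mat = _blobs(2)
        a = assign_supertypes(mat, 1, seed=0)
        assert set(a.mapping.values()) == {"ST1"}

    def test_ten_motif_pool_recovers_ten_supertypes(self, dab2_pool, dab2_alignment):
        spec, _ = dab2_pool
        mat = build_descriptor_matrix(dab2_alignment, list(spec.selected_sites))
        k, _ = select_k(mat, range(2, 16), method="silhouette", seed=0, n_restarts=20)
        assert k == spec.n_motifs == 10
        a = assign_supertypes(mat, k, seed=0, n_restarts=20)
        assert a.k == 10
        # alleles sharing a motif share all selected-site residues, hence
        # identical descriptor rows -> must share a supertype
        rows = {}
        for lab in mat.index:
            rows.setdefault(tuple(np.round(mat.loc[lab], 9)), set()).add(a.mapping[lab])
        assert all(len(sts) == 1 for sts in rows.values())

    def test_no_allele_dropped_by_clustering(self, dab2_pool, dab2_alignment):
        spec, _ = dab2_pool
        mat = build_descriptor_matrix(dab2_alignment, list(spec.selected_sites))
        a = assign_supertypes(mat, 10, seed=0, n_restarts=20)
        assert set(a.mapping) == set(mat.index)


class TestFrequencies:
    def test_carrier_fraction(self):
        mapping = {"x": "ST1", "y": "ST2"}
        from owlmhc.supertypes import SupertypeAssignment

        assign = SupertypeAssignment("L", mapping, 2, "BIC", 0)
        genos = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(10)],
            "locus": "L",
            "alleles": ["x;y"] * 3 + ["x"] * 3 + ["y"] * 4,
        })
        freqs, presence = supertype_frequencies(assign, genos)
        assert freqs["ST1"] == pytest.approx(0.6)
        assert freqs["ST2"] == pytest.approx(0.7)
        assert presence.shape == (10, 2)

    def test_frequency_floor_is_strict(self):
        freqs = pd.Series({"ST1": 0.10, "ST2": 0.11, "ST3": 0.0})
        assert filter_common_supertypes(freqs) == ["ST2"]

    def test_empty_survivor_set_logged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="owlmhc.supertypes"):
            out = filter_common_supertypes(pd.Series({"ST1": 0.05}))
        assert out == [] and any("skipped" in r.message for r in caplog.records)
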