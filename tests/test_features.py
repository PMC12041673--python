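"""Pair vocabulary, visit-order weights, min-max scaling, BoF and DF."""

import numpy as np
import pytest

from diatraj import (BofVocabulary, FeatureVocabulary, Gender,
                     build_endpoint_dataset, document_frequency, encode_bof,
                     fit_apply_minmax, vectorize_instance)
from diatraj.endpoints import EndpointDataset, LabeledInstance
from diatraj.features import VocabularyError
from diatraj.records import Visit


def _inst(visit_specs, label=1, gender=Gender.MALE, pid=0, endpoint="910"):
    visits = [Visit(a, list(c)) for a, c in visit_specs]
    return LabeledInstance(pid, gender, visits, label, endpoint)


def _dataset(instances, endpoint="910"):
    n_pos = sum(i.label for i in instances)
    return EndpointDataset(endpoint, instances, 0, n_pos,
                           len(instances) - n_pos, len(instances) - n_pos)


class TestVocabulary:
    def test_spec_enumeration(self):
        ds = _dataset([
            _inst([("1050", ["401", "913"])]),
            _inst([("1050", ["401"]), ("1060", ["402"])], pid=1),
        ])
        vocab = FeatureVocabulary.from_dataset(ds)
        assert set(vocab.pairs) == {("1050", "401"), ("1050", "913"),
                                    ("1060", "402")}
        assert vocab.k == 3 and vocab.total_dim == 5

    def test_disjoint_instances_sum(self):
        ds = _dataset([
            _inst([("1050", ["401"])]),
            _inst([("1060", ["913"])], pid=1),
        ])
        assert FeatureVocabulary.from_dataset(ds).k == 2

    def test_matches_brute_force_union(self, clean_records):
        ds, _ = build_endpoint_dataset(clean_records, "910", seed=5)
        vocab = FeatureVocabulary.from_dataset(ds)
        brute = set()
        for inst in ds.instances:
            for v in inst.input_visits:
                brute |= {(v.age_label, c) for c in v.codes}
        assert set(vocab.pairs) == brute
        assert vocab.pairs == sorted(vocab.pairs,
                                     key=lambda p: (int(p[0]), int(p[1])))


class TestVectorization:
    def test_visit_order_weights(self):
        inst = _inst([("1050", ["401"]), ("1060", ["913"])])
        vocab = FeatureVocabulary([("1050", "401"), ("1060", "913")])
        vec = vectorize_instance(inst, vocab)
        assert vec[vocab.index[("1050", "401")]] == 1
        assert vec[vocab.index[("1060", "913")]] == 2
        assert vec[vocab.k] == 1.0 and vec[vocab.k + 1] == 0.0

    def test_single_visit_window_all_weights_one(self):
        inst = _inst([("1050", ["401", "913", "402"])])
        vocab = FeatureVocabulary(
            [("1050", "401"), ("1050", "402"), ("1050", "913")])
        vec = vectorize_instance(inst, vocab)
        assert set(vec[: vocab.k]) == {1.0}

    def test_weights_increase_with_visit_index(self):
        inst = _inst([("1050", ["401"]), ("1060", ["913"]), ("1070", ["402"])])
        vocab = FeatureVocabulary(
            [("1050", "401"), ("1060", "913"), ("1070", "402")])
        vec = vectorize_instance(inst, vocab)
        assert vec[0] < vec[1] < vec[2]

    def test_out_of_vocabulary_pair_errors(self):
        inst = _inst([("1050", ["913"])])
        vocab = FeatureVocabulary([("1050", "401")])
        with pytest.raises(VocabularyError, match="913"):
            vectorize_instance(inst, vocab)

    def test_pair_to_visit_map_recoverable(self):
        """The raw vector is injective up to vocabulary: the pair→visit
        assignment can be read back exactly."""
        inst = _inst([("1050", ["401", "913"]), ("1060", ["402"])])
        vocab = FeatureVocabulary(
            [("1050", "401"), ("1050", "913"), ("1060", "402"), ("1070", "914")])
        vec = vectorize_instance(inst, vocab)
        recovered = {vocab.pairs[i]: int(vec[i])
                     for i in range(vocab.k) if vec[i]}
        assert recovered == {("1050", "401"): 1, ("1050", "913"): 1,
                             ("1060", "402"): 2}


class TestMinMax:
    def test_three_point_column(self):
        X = np.array([[0.0], [1.0], [2.0]])
        fm = fit_apply_minmax(X, np.array([0, 1, 2]))
        assert fm.values[:, 0].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        X = np.full((4, 2), 7.0)
        fm = fit_apply_minmax(X, np.array([0, 1, 2, 3]))
        assert (fm.values == 0).all()

    def test_values_above_fit_max_clipped(self):
        X = np.array([[0.0], [2.0], [5.0]])
        fm = fit_apply_minmax(X, np.array([0, 1]))  # fit sees 0 and 2 only
        assert fm.values[2, 0] == 1.0

    def test_fit_rows_recorded(self):
        X = np.array([[0.0], [1.0], [9.0]])
        fm = fit_apply_minmax(X, np.array([0, 1]))
        assert fm.normalizer.fit_row_ids.tolist() == [0, 1]

    def test_empty_fit_rows_error(self):
        with pytest.raises(ValueError):
            fit_apply_minmax(np.zeros((2, 1)), np.array([], dtype=int))


class TestBagOfFeatures:
    def test_counting_semantics(self):
        inst = _inst([("1050", ["401", "913"]), ("1050", ["402"])])
        vocab = BofVocabulary(["401", "402", "913"], ["1050"])
        vec = encode_bof(inst, vocab)
        names = vocab.column_names()
        values = dict(zip(names, vec))
        assert values["age:1050"] == 2
        assert values["code:401"] == values["code:913"] == values["code:402"] == 1
        assert values["gender:male"] == 1 and values["gender:female"] == 0

    def test_dimension_under_one_hundred(self, clean_records, codebook):
        ds, _ = build_endpoint_dataset(clean_records, "910", seed=5)
        vocab = BofVocabulary.from_dataset(ds)
        assert vocab.total_dim < 100  # ≤ 83 codes + 10 ages + 2 genders

    def test_refines_bof_support(self):
        """Collapsing pair columns over age labels and binarizing reproduces
        the BoF support pattern for codes."""
        inst = _inst([("1050", ["401", "913"]), ("1060", ["402"])])
        vocab = FeatureVocabulary(
            [("1050", "401"), ("1050", "913"), ("1060", "402")])
        vec = vectorize_instance(inst, vocab)
        pair_support = {c for (a, c), i in vocab.index.items() if vec[i] > 0}
        bof_vocab = BofVocabulary(["401", "402", "913"], ["1050", "1060"])
        bof = encode_bof(inst, bof_vocab)
        bof_support = {c for c, v in zip(bof_vocab.codes, bof) if v > 0}
        assert pair_support == bof_support


class TestDocumentFrequency:
    def test_df_percentage(self, codebook):
        pos = [_inst([("1050", ["913"])], pid=i) for i in range(3)]
        pos.append(_inst([("1060", ["402"])], pid=3))
        ds = _dataset(pos)
        table = document_frequency(ds, codebook, top_n=10)
        row = table[(table.age_range == "1050") & (table.code == "913")]
        assert row.df_pct.iloc[0] == pytest.approx(75.0)

    def test_diabetes_pairs_excluded(self, codebook):
        ds = _dataset([_inst([("1050", ["401", "913"])])])
        table = document_frequency(ds, codebook)
        assert "401" not in set(table.code)

    def test_ranking_matches_brute_force(self, clean_records, codebook):
        ds, _ = build_endpoint_dataset(clean_records, "1401", seed=2)
        table = document_frequency(ds, codebook, top_n=5)
        pos = [i for i in ds.instances if i.label == 1]
        counts = {}
        for inst in pos:
            for p in set(inst.pairs()):
                if p[1] != codebook.diabetes_code:
                    counts[p] = counts.get(p, 0) + 1
        brute = sorted(counts.items(),
                       key=lambda kv: (-kv[1], int(kv[0][0]), int(kv[0][1])))[:5]
        got = [((r.age_range, r.code), r.df_pct)
               for r in table.itertuples()]
        for (pair, n), (gpair, gdf) in zip(brute, got):
            assert pair == gpair
            assert gdf == pytest.approx(100 * n / len(pos))

    def test_no_positives_errors(self, codebook):
        ds = _dataset([_inst([("1050", ["913"])], label=0)])
        with pytest.raises(ValueError):
            document_frequency(ds, codebook)
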