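"""Term-level measures, gene-level combiners and the 14-measure matrix."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gosimclust.annotations import AnnotationSet, compute_ic
from gosimclust.ontology import build_dag
from gosimclust.similarity import (MeasureSpec, all_measure_specs, combine,
                                   gene_sim_matrix, read_sim_matrix, term_sim,
                                   vector_sim, write_sim_matrix)

from .conftest import random_annotation_set


class TestTermSim:
    def test_lin_identity(self, five_gene_dag, five_gene_ic):
        assert term_sim("lin", "A", "A", five_gene_ic, five_gene_dag) == 1.0

    def test_root_mica_gives_zero(self, five_gene_dag, five_gene_ic):
        # A and D share only the root, whose IC is 0
        for measure in ("lin", "resnik", "relevance"):
            assert term_sim(measure, "A", "D", five_gene_ic, five_gene_dag) == 0.0

    def test_worked_corpus_values(self, five_gene_dag, five_gene_ic):
        args = (five_gene_ic, five_gene_dag)
        assert term_sim("lin", "A", "B", *args) == pytest.approx(0.2435, abs=1e-4)
        assert term_sim("relevance", "A", "B", *args) == pytest.approx(0.0487, abs=1e-4)
        assert term_sim("resnik", "A", "B", *args) == pytest.approx(0.1386, abs=1e-4)
        assert term_sim("jiang_conrath", "A", "B", *args) == pytest.approx(0.4190, abs=1e-4)

    def test_raw_resnik_option(self, five_gene_dag, five_gene_ic):
        raw = term_sim("resnik", "A", "B", five_gene_ic, five_gene_dag,
                       resnik_normalize=False)
        assert raw == pytest.approx(0.2231, abs=1e-4)

    def test_linear_jc_option(self, five_gene_dag, five_gene_ic):
        s = term_sim("jiang_conrath", "A", "A", five_gene_ic, five_gene_dag,
                     jc_transform="linear")
        assert s == 1.0

    def test_all_measures_in_unit_interval(self, five_gene_dag, five_gene_ic):
        terms = sorted(five_gene_ic.ic)
        for measure in ("resnik", "lin", "jiang_conrath", "relevance"):
            for t1, t2 in itertools.product(terms, terms):
                s = term_sim(measure, t1, t2, five_gene_ic, five_gene_dag)
                assert 0.0 <= s <= 1.0


class TestCombine:
    def test_identical_singletons(self):
        m = np.array([[1.0]])
        assert combine("MAX", m) == combine("BMA", m) == combine("AVG", m) == 1.0

    def test_worked_example(self):
        # X={A}, Y={A,B} with sims 1 and 0.2435
        m = np.array([[1.0, 0.2435]])
        assert combine("MAX", m) == 1.0
        assert combine("AVG", m) == pytest.approx(0.6218, abs=1e-4)
        assert combine("BMA", m) == pytest.approx(0.8109, abs=1e-4)

    def test_avg_dilution_identity_matrix(self):
        # identical sets of 5 mutually dissimilar terms
        m = np.eye(5)
        assert combine("MAX", m) == combine("BMA", m) == 1.0
        assert combine("AVG", m) == pytest.approx(0.2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            combine("MAX", np.zeros((0, 3)))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(1, 10), st.integers(1, 10), st.integers(0, 2**31 - 1))
    def test_matches_brute_force_enumeration(self, m, n, seed):
        ts = np.random.default_rng(seed).random((m, n))
        # independent oracle: explicit loops over all annotation pairs
        best = max(ts[i][j] for i in range(m) for j in range(n))
        mean = sum(ts[i][j] for i in range(m) for j in range(n)) / (m * n)
        row_best = [max(ts[i][j] for j in range(n)) for i in range(m)]
        col_best = [max(ts[i][j] for i in range(m)) for j in range(n)]
        bma = 0.5 * (sum(row_best) / m + sum(col_best) / n)
        assert combine("MAX", ts) == pytest.approx(best)
        assert combine("AVG", ts) == pytest.approx(mean)
        assert combine("BMA", ts) == pytest.approx(bma)


class TestVectorSim:
    def test_identical_sets(self, five_gene_ann, five_gene_ic):
        for measure in ("weighted_cosine", "weighted_jaccard"):
            assert vector_sim(measure, "g1", "g2", five_gene_ann,
                              five_gene_ic) == pytest.approx(1.0)

    def test_root_only_overlap_is_zero(self):
        dag = build_dag([("A", "R", "is_a"), ("B", "R", "is_a")])
        ann = AnnotationSet({"g1": {"A"}, "g2": {"B"}, "g3": {"A"}, "g4": {"B"}}, dag)
        ic = compute_ic(ann)
        for measure in ("weighted_cosine", "weighted_jaccard"):
            assert vector_sim(measure, "g1", "g2", ann, ic) == 0.0

    def test_worked_closure_vectors(self, five_gene_ann, five_gene_ic):
        # closures {A,C,R} vs {B,C,R} with IC weights 0.9163/0.2231/0
        ic_a, ic_c = five_gene_ic.ic["A"], five_gene_ic.ic["C"]
        expected_jac = ic_c / (ic_a + ic_a + ic_c)  # min-sum over max-sum
        cos = ic_c ** 2 / (ic_a ** 2 + ic_c ** 2)
        got_j = vector_sim("weighted_jaccard", "g1", "g3", five_gene_ann, five_gene_ic)
        got_c = vector_sim("weighted_cosine", "g1", "g3", five_gene_ann, five_gene_ic)
        assert got_j == pytest.approx(expected_jac)
        assert got_c == pytest.approx(cos)


class TestGeneSimMatrix:
    def test_identical_genes_offdiag_one(self, five_gene_dag):
        ann = AnnotationSet({"g1": {"A"}, "g2": {"A"}, "g3": {"B"}}, five_gene_dag)
        ic = compute_ic(ann)
        mat = gene_sim_matrix(ann, MeasureSpec(term_measure="lin", combiner="MAX"), ic)
        assert mat.sim("g1", "g2") == 1.0

    def test_all_14_specs_valid_range(self, five_gene_ann, five_gene_ic):
        specs = all_measure_specs()
        assert len(specs) == 14
        seen = set()
        for spec in specs:
            mat = gene_sim_matrix(five_gene_ann, spec, five_gene_ic)
            assert np.all(mat.values >= -1e-12) and np.all(mat.values <= 1 + 1e-12)
            assert np.allclose(np.diag(mat.values), 1.0)
            seen.add(spec.name)
        assert len(seen) == 14

    def test_matrix_matches_scalar_ops(self):
        rng = np.random.default_rng(5)
        ann = random_annotation_set(rng, n_genes=6)
        ic = compute_ic(ann)
        dag = ann.ontology
        spec = MeasureSpec(term_measure="relevance", combiner="BMA")
        mat = gene_sim_matrix(ann, spec, ic)
        for gx, gy in itertools.combinations(mat.genes, 2):
            tx = sorted(t for t in ann.annotations[gx] if t in ic)
            ty = sorted(t for t in ann.annotations[gy] if t in ic)
            block = np.array([[term_sim("relevance", a, b, ic, dag) for b in ty]
                              for a in tx])
            assert mat.sim(gx, gy) == pytest.approx(combine("BMA", block))

    def test_symmetry_all_specs(self):
        rng = np.random.default_rng(9)
        ann = random_annotation_set(rng, n_genes=8)
        ic = compute_ic(ann)
        for spec in all_measure_specs():
            mat = gene_sim_matrix(ann, spec, ic)
            assert np.allclose(mat.values, mat.values.T)

    def test_self_maximality_except_avg(self):
        rng = np.random.default_rng(13)
        ann = random_annotation_set(rng, n_genes=8)
        ic = compute_ic(ann)
        for spec in all_measure_specs():
            if spec.combiner == "AVG":
                continue
            mat = gene_sim_matrix(ann, spec, ic)
            assert np.all(mat.values <= np.diag(mat.values)[:, None] + 1e-9)

    def test_max_monotone_under_annotation_removal(self):
        """Removing an annotation never increases a MAX gene similarity."""
        rng = np.random.default_rng(17)
        spec = MeasureSpec(term_measure="lin", combiner="MAX")
        checked = 0
        while checked < 500:
            ann = random_annotation_set(rng, n_genes=6, max_terms=4)
            ic = compute_ic(ann)
            mat = gene_sim_matrix(ann, spec, ic)
            gene = str(rng.choice(mat.genes))
            if len(ann.annotations[gene]) < 2:
                continue
            drop = str(rng.choice(sorted(ann.annotations[gene])))
            reduced = ann.copy()
            reduced.annotations[gene].discard(drop)
            # IC held fixed: isolate the combiner's response to removal
            mat2 = gene_sim_matrix(reduced, spec, ic)
            for other in mat2.genes:
                if other != gene:
                    assert mat2.sim(gene, other) <= mat.sim(gene, other) + 1e-12
            checked += 1

    def test_tsv_round_trip(self, tmp_path, five_gene_ann, five_gene_ic):
        spec = MeasureSpec(term_measure="lin", combiner="BMA")
        mat = gene_sim_matrix(five_gene_ann, spec, five_gene_ic)
        path = str(tmp_path / "m.tsv")
        write_sim_matrix(mat, path)
        back = read_sim_matrix(path, spec)
        assert back.genes == mat.genes
        assert np.allclose(back.values, mat.values)


class TestMeasureSpec:
    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            MeasureSpec(term_measure="lin", combiner="MAX",
                        vector_measure="weighted_cosine")
        with pytest.raises(ValueError):
            MeasureSpec()

    def test_name_round_trip(self):
        for spec in all_measure_specs():
            assert MeasureSpec.from_name(spec.name) == spec
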