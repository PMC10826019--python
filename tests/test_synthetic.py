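import itertools

import numpy as np
import pytest

from plaquehub import diffexpr, synthetic
from plaquehub.errors import ParameterError


class TestExpressionGenerator:
    def test_shape_and_truth(self):
        expr, truth = synthetic.synth_expression(100, 4, 4, 10, 2.0, 0.5, seed=1)
        assert expr.data.shape == (100, 8)
        assert len(truth.de_genes) == 10
        assert len(expr.case_samples) == 4 and len(expr.control_samples) == 4
        ups = sum(1 for _, e in truth.de_genes if e > 0)
        assert ups == 5  # half up, half down

    def test_determinism(self):
        a, _ = synthetic.synth_expression(50, 4, 4, 5, 1.0, 0.5, seed=9)
        b, _ = synthetic.synth_expression(50, 4, 4, 5, 1.0, 0.5, seed=9)
        assert (a.data.to_numpy() == b.data.to_numpy()).all()

    def test_zero_effect_empty_truth(self):
        _, truth = synthetic.synth_expression(50, 4, 4, 5, 0.0, 0.5, seed=1)
        assert truth.de_genes == []

    def test_too_many_de_genes(self):
        with pytest.raises(ParameterError):
            synthetic.synth_expression(5, 4, 4, 6, 1.0, 0.5, seed=1)

    def test_planted_effect_calibration(self):
        """Mean estimated log2FC of planted genes within 10% of the request."""
        ests = []
        for seed in range(200):
            expr, truth = synthetic.synth_expression(60, 4, 4, 10, 1.5, 0.5, seed)
            table, _ = diffexpr.fit_moderated_t(expr)
            for gene, eff in truth.de_genes:
                ests.append(table.loc[gene, "log2FC"] * np.sign(eff))
        assert abs(np.mean(ests) - 1.5) < 0.15


class TestPpiGenerator:
    def test_all_clique_edges_present(self):
        edges, truth = synthetic.synth_ppi(50, [6, 5, 4], 0.02, seed=7)
        pairs = {
            tuple(sorted((r.gene_a, r.gene_b))) for r in edges.records.itertuples()
        }
        for mod in truth.planted_modules:
            for a, b in itertools.combinations(sorted(mod), 2):
                assert (a, b) in pairs

    def test_single_module_no_background(self):
        edges, truth = synthetic.synth_ppi(10, [4], 0.0, seed=1)
        assert len(edges) == 6  # a lone 4-clique, no hub wires to other modules
        assert truth.hub_gene in truth.planted_modules[0]

    def test_hub_in_largest_module_with_wires(self):
        edges, truth = synthetic.synth_ppi(30, [5, 4, 3], 0.0, seed=1)
        hub = truth.hub_gene
        assert hub in max(truth.planted_modules, key=len)
        deg = {}
        for r in edges.records.itertuples():
            deg[r.gene_a] = deg.get(r.gene_a, 0) + 1
            deg[r.gene_b] = deg.get(r.gene_b, 0) + 1
        assert deg[hub] == 4 + 2  # clique plus one wire per other module

    def test_determinism(self):
        a, _ = synthetic.synth_ppi(40, [5, 4], 0.05, seed=3)
        b, _ = synthetic.synth_ppi(40, [5, 4], 0.05, seed=3)
        assert a.records.equals(b.records)

    def test_small_module_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.synth_ppi(20, [2], 0.0, seed=1)


class TestDrugGenerator:
    def test_counts_and_flags(self):
        edges, _ = synthetic.synth_ppi(40, [6, 4], 0.05, seed=2)
        nodes = set(edges.records.gene_a) | set(edges.records.gene_b)
        disease = set(sorted(nodes)[:6])
        drugs, truth = synthetic.synth_drug_targets(edges, disease, 3, 20, 3, seed=2)
        assert len(drugs) == 23
        assert len(truth.proximal_drugs) == 3
        assert all(len(t) == 3 for t in drugs.values())

    def test_proximal_targets_near_disease(self):
        edges, _ = synthetic.synth_ppi(40, [6, 4], 0.05, seed=2)
        disease = {synthetic.gene_name(i) for i in range(6)}
        neighbors = set()
        for r in edges.records.itertuples():
            if r.gene_a in disease:
                neighbors.add(r.gene_b)
            if r.gene_b in disease:
                neighbors.add(r.gene_a)
        drugs, truth = synthetic.synth_drug_targets(edges, disease, 4, 5, 3, seed=5)
        for did in truth.proximal_drugs:
            assert drugs[did] <= disease | neighbors
            assert drugs[did] & disease  # at least one target on the disease set

    def test_determinism(self):
        edges, _ = synthetic.synth_ppi(40, [6, 4], 0.05, seed=2)
        disease = {synthetic.gene_name(i) for i in range(6)}
        a, _ = synthetic.synth_drug_targets(edges, disease, 3, 10, 3, seed=4)
        b, _ = synthetic.synth_drug_targets(edges, disease, 3, 10, 3, seed=4)
        assert a == b

    def test_pool_too_small(self):
        edges, _ = synthetic.synth_ppi(10, [4], 0.0, seed=1)
        disease = {synthetic.gene_name(0)}
        with pytest.raises(ParameterError):
            synthetic.synth_drug_targets(edges, disease, 1, 1, 50, seed=1)


class TestSignatureGenerator:
    def test_requested_count(self):
        expr, _ = synthetic.synth_expression(200, 4, 4, 0, 0.0, 0.5, seed=1)
        sigs, _ = synthetic.synth_signatures(expr, expr.gene_ids[0], 28, 5, -0.5, seed=1)
        assert len(sigs) == 28

    def test_full_negative_coupling_limit(self):
        """In the noise-free limit (coupling = -1, background genes held
        constant across samples) every signature score is non-increasing in
        the hub and the pooled immune score is perfectly anti-correlated."""
        from plaquehub import immune
        from plaquehub.io_formats import ExpressionMatrix

        expr, _ = synthetic.synth_expression(60, 4, 4, 0, 0.0, 0.5, seed=3)
        hub = expr.gene_ids[0]
        sigs, mutated = synthetic.synth_signatures(expr, hub, 3, 5, -1.0, seed=3)
        members = set().union(*(set(v) for v in sigs.sets.values()))
        data = mutated.data.copy()
        for g in data.index:
            if g != hub and g not in members:
                data.loc[g] = data.loc[g].mean()  # freeze the background
        flat = ExpressionMatrix(data, dict(mutated.groups))
        scores = immune.ssgsea_scores(flat, sigs)
        hub_vec = data.loc[hub].to_numpy()
        order = np.argsort(hub_vec)
        for name in scores.index:
            assert np.all(np.diff(scores.loc[name].to_numpy()[order]) <= 1e-9)
        agg = immune.immune_score(scores)
        res = immune.spearman_exact(hub_vec, agg.to_numpy())
        assert res.coefficient == -1.0

    def test_zero_coupling_uncorrelated_on_average(self):
        """Monte-Carlo: |mean rho| stays small when no coupling is planted."""
        from plaquehub import immune

        rhos = []
        for seed in range(50):
            expr, _ = synthetic.synth_expression(80, 4, 4, 0, 0.0, 0.5, seed)
            hub = expr.gene_ids[0]
            sigs, mutated = synthetic.synth_signatures(expr, hub, 3, 5, 0.0, seed)
            scores = immune.ssgsea_scores(mutated, sigs)
            hub_vec = mutated.data.loc[hub].to_numpy()
            for name in scores.index:
                rhos.append(
                    immune.spearman_exact(hub_vec, scores.loc[name].to_numpy()).coefficient
                )
        assert abs(np.mean(rhos)) < 0.2

    def test_hub_absent_rejected(self):
        expr, _ = synthetic.synth_expression(20, 4, 4, 0, 0.0, 0.5, seed=1)
        with pytest.raises(ParameterError):
            synthetic.synth_signatures(expr, "NOPE", 2, 3, -0.5, seed=1)
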