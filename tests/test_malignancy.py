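"""Chromosome-scale expression, the malignancy score, and WGS copy number."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from scglioma import malignancy as mal
from scglioma import synthetic as syn
from scglioma.io import ExpressionMatrix


def _flat_matrix(n_cells, detect_override=None):
    """One gene per autosome, detected everywhere (plus overrides)."""
    genes = [f"g{c}" for c in mal.AUTOSOMES]
    counts = np.full((22, n_cells), 5, dtype=int)
    if detect_override:
        for gene, n_detected in detect_override.items():
            i = genes.index(gene)
            counts[i] = 0
            counts[i, :n_detected] = 5
    cells = [f"c{i}" for i in range(n_cells)]
    expr = ExpressionMatrix(sp.csr_matrix(counts), pd.Index(genes), pd.Index(cells))
    annot = pd.DataFrame(
        {
            "chromosome": list(mal.AUTOSOMES),
            "is_mito": False,
            "is_hla": False,
        },
        index=pd.Index(genes, name="gene"),
    )
    return expr, annot


class TestChromosomeExpression:
    def test_min_cell_gene_filter_boundary(self):
        """A gene expressed in 99 cells is excluded; 100 is the floor."""
        genes = [f"g{c}" for c in mal.AUTOSOMES] + ["g7_low", "g7_ok"]
        counts = np.full((24, 120), 5, dtype=int)
        counts[22] = 0
        counts[22, :99] = 50
        counts[23] = 0
        counts[23, :100] = 50
        annot = pd.DataFrame(
            {"chromosome": list(mal.AUTOSOMES) + ["7", "7"],
             "is_mito": False, "is_hla": False},
            index=pd.Index(genes, name="gene"),
        )
        expr = ExpressionMatrix(
            sp.csr_matrix(counts), pd.Index(genes),
            pd.Index([f"c{i}" for i in range(120)]),
        )
        chrom = mal.chromosome_expression(expr, annot)
        # cells past 100 see only the ubiquitous chr7 gene; if g7_low had
        # been retained, cell 99 (which expresses it) would differ from
        # cell 100 (which does not) -- they must match instead, and g7_ok
        # (100 cells) must make cell 99 differ from cell 100 on chr7
        assert chrom.loc["c100", "7"] == chrom.loc["c119", "7"]
        assert chrom.loc["c99", "7"] > chrom.loc["c100", "7"]

    def test_hla_genes_excluded(self):
        expr, annot = _flat_matrix(150)
        genes = list(expr.genes) + ["hla1"]
        counts = np.vstack([expr.counts.toarray(),
                            np.full((1, 150), 500, dtype=int)])
        annot2 = pd.concat(
            [annot, pd.DataFrame({"chromosome": ["6"], "is_mito": [False],
                                  "is_hla": [True]}, index=["hla1"])]
        )
        expr2 = ExpressionMatrix(sp.csr_matrix(counts), pd.Index(genes), expr.cells)
        with_hla = mal.chromosome_expression(expr2, annot2)
        without = mal.chromosome_expression(expr, annot)
        # the huge HLA gene must not inflate chromosome 6 (total depth
        # differs, so compare chr6 relative to the other chromosomes)
        rel_with = with_hla["6"] / with_hla.drop(columns="6").mean(axis=1)
        rel_without = without["6"] / without.drop(columns="6").mean(axis=1)
        pd.testing.assert_series_equal(rel_with, rel_without)

    def test_empty_chromosome_is_an_error(self):
        expr, annot = _flat_matrix(150, detect_override={"g13": 5})
        with pytest.raises(ValueError, match="chromosome 13"):
            mal.chromosome_expression(expr, annot)

    def test_zscore_rows_standardized(self, branched):
        expr, truth, _ = branched
        chrom = mal.chromosome_expression(expr, syn.GenomeModel.default().annotation())
        z = mal.zscore_rows(chrom)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_constant_profile_rejected_at_zscore(self):
        chrom = pd.DataFrame(
            np.ones((4, 22)), index=[f"c{i}" for i in range(4)],
            columns=list(mal.AUTOSOMES),
        )
        with pytest.raises(ValueError, match="zero SD"):
            mal.zscore_rows(chrom)


class TestMalignancyScore:
    def test_transformed_clusters_have_higher_medians(self, branched, genome):
        expr, truth, _ = branched
        chrom = mal.chromosome_expression(expr, genome.annotation())
        result = mal.malignancy_score(chrom, truth.population, axis="auto")
        medians = result.cluster_medians
        tr = truth.is_transformed.groupby(truth.population).first()
        assert set(result.transformed_clusters) == set(tr.index[tr])
        assert medians[tr].min() > medians[~tr].max()
        auc = roc_auc_score(truth.is_transformed, result.scores)
        assert auc > 0.99

    def test_all_diploid_makes_no_call(self, tiny_genome):
        on_a, on_b = tiny_genome.genes[:5], tiny_genome.genes[30:35]
        pops = [
            syn.PopulationSpec("a", 0.5, {}, {g: 2.0 for g in on_a}),
            syn.PopulationSpec("b", 0.5, {}, {g: 2.0 for g in on_b}),
        ]
        expr, truth = syn.simulate_expression(tiny_genome, pops, 300, 1500, seed=3)
        chrom = mal.chromosome_expression(expr, tiny_genome.annotation(),
                                          min_cells=50)
        result = mal.malignancy_score(chrom, truth.population, axis="auto")
        assert result.transformed_clusters == ()
        assert not result.is_transformed.any()

    def test_duplicated_cells_score_identically(self, branched, genome):
        expr, truth, _ = branched
        chrom = mal.chromosome_expression(expr, genome.annotation())
        doubled = pd.concat(
            [chrom, chrom.rename(index=lambda c: c + "_dup")]
        )
        clusters = pd.concat(
            [truth.population,
             truth.population.rename(index=lambda c: c + "_dup")]
        )
        result = mal.malignancy_score(doubled, clusters)
        a = result.scores.loc[chrom.index].to_numpy()
        b = result.scores.loc[[c + "_dup" for c in chrom.index]].to_numpy()
        assert np.allclose(a, b)

    def test_single_cluster_rejected(self, branched, genome):
        expr, truth, _ = branched
        chrom = mal.chromosome_expression(expr, genome.annotation())
        ones = pd.Series("all", index=chrom.index)
        with pytest.raises(ValueError, match="clusters"):
            mal.malignancy_score(chrom, ones)


class TestRelativeChromosomeExpression:
    def test_directions_follow_dosage(self, branched, genome):
        expr, truth, _ = branched
        chrom = mal.chromosome_expression(expr, genome.annotation())
        tr = truth.is_transformed
        ratio = mal.relative_chromosome_expression(
            chrom, chrom.index[tr], chrom.index[~tr]
        )
        assert ratio["7"].mean() > 1.02
        assert ratio["10"].mean() < 0.98
        near_diploid = [c for c in mal.AUTOSOMES if c not in ("7", "10")]
        assert ratio[near_diploid].mean().mean() == pytest.approx(1.0, abs=0.05)

    def test_untransformed_cell_rows_are_flat(self, branched, genome):
        expr, truth, _ = branched
        chrom = mal.chromosome_expression(expr, genome.annotation())
        untr = chrom.index[~truth.is_transformed]
        ratio = mal.relative_chromosome_expression(chrom, untr, untr)
        assert np.allclose(ratio.mean(axis=0), 1.0, atol=0.02)


class TestWgsCopyNumber:
    def test_identity_gives_exact_two(self, tiny_genome):
        counts = pd.Series(
            np.arange(1, 23) * 1000, index=pd.Index(list(mal.AUTOSOMES))
        )
        est = mal.wgs_chromosome_copy_number(counts, counts)
        assert (est == 2.0).all()

    def test_recovers_planted_copies(self, genome):
        cn = {"5": 1, "7": 4, "12": 3}
        tumor, germ = syn.simulate_wgs_counts(genome, cn, 10**6, seed=9)
        est = mal.wgs_chromosome_copy_number(tumor, germ)
        for c in mal.AUTOSOMES:
            assert est[c] == pytest.approx(cn.get(c, 2), abs=0.1)

    def test_majority_diploid_pins_diploids_to_two(self, genome):
        """With > half the chromosomes diploid the median ratio is the
        diploid ratio, so diploid chromosomes estimate ~2 by construction."""
        cn = {str(c): 4 for c in range(1, 10)}  # 9 of 22 amplified
        tumor, germ = syn.simulate_wgs_counts(genome, cn, 10**6, seed=10)
        est = mal.wgs_chromosome_copy_number(tumor, germ)
        diploid = [c for c in mal.AUTOSOMES if c not in cn]
        assert np.allclose(est[diploid], 2.0, atol=0.1)

    def test_zero_germline_rejected(self):
        counts = pd.Series(1000, index=pd.Index(list(mal.AUTOSOMES)))
        germ = counts.copy()
        germ["8"] = 0
        with pytest.raises(ValueError, match="germline"):
            mal.wgs_chromosome_copy_number(counts, germ)
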