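"""Molecule-table collapse: the stated examples, oracles, and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from conftest import make_table
from scglioma import _seq
from scglioma import molecules as mol
from scglioma import synthetic as syn


class TestDegenerateFilter:
    @pytest.mark.parametrize(
        "barcode,kept",
        [
            ("ACGTACGTACGN", False),  # contains N
            ("ACGGGGGTACGT", False),  # run of 5 G
            ("ACGGGGTACGTA", True),  # run of exactly 4 G: boundary, kept
            ("ACGTACGTACGT", True),
        ],
    )
    def test_stated_examples(self, barcode, kept):
        table = make_table([(barcode, "AAAAAAAA", "g1", 3)])
        out = mol.filter_degenerate_barcodes(table)
        assert (len(out) == 1) is kept


class TestTruncationCorrection:
    @staticmethod
    def _barcode_with_pairs(barcode, n_pairs, n_terminal_t):
        """n_pairs distinct (umi, gene) pairs, n_terminal_t ending in 'T'."""
        rows = []
        for i in range(n_pairs):
            head = f"{i:03d}".replace("0", "A").replace("1", "C").replace(
                "2", "G"
            ).replace("3", "T").replace("4", "AC")[:3].ljust(3, "A")
            # 7-nt prefix unique per i, last base controls the signature
            prefix = _seq.decode(i, 7)
            tail = "T" if i < n_terminal_t else "G"
            rows.append((barcode, prefix + tail, f"g{i}", 2))
        return make_table(rows)

    def test_corrected_when_thresholds_met(self):
        """25 apparent molecules, 24/25 (96%) terminal 'T': last barcode
        base moves to the UMI head and the trailing 'T' is trimmed."""
        table = self._barcode_with_pairs("ACGTACGTACGG", 25, 24)
        out, n = mol.correct_truncated_barcodes(table)
        assert n == 1
        assert set(out["barcode"]) == {"ACGTACGTACG"}
        orig = table.sort_values("gene").reset_index(drop=True)
        corr = out.sort_values("gene").reset_index(drop=True)
        assert (corr["umi"] == "G" + orig["umi"].str[:-1]).all()

    def test_unchanged_below_t_fraction(self):
        table = self._barcode_with_pairs("ACGTACGTACGG", 25, 12)  # 48%
        out, n = mol.correct_truncated_barcodes(table)
        assert n == 0
        pd.testing.assert_frame_equal(
            out.sort_values("umi").reset_index(drop=True),
            table.sort_values("umi").reset_index(drop=True),
        )

    def test_unchanged_below_molecule_count(self):
        table = self._barcode_with_pairs("ACGTACGTACGG", 15, 15)  # 100% T
        out, n = mol.correct_truncated_barcodes(table)
        assert n == 0

    def test_exactly_90_percent_not_corrected(self):
        # threshold is strictly greater than 90%
        table = self._barcode_with_pairs("ACGTACGTACGG", 20, 18)
        out, n = mol.correct_truncated_barcodes(table)
        assert n == 0


class TestCollapseUmis:
    def test_hamming1_pair_merges_reads(self):
        table = make_table(
            [
                ("ACGTACGTACGT", "AAAAAAAA", "g1", 5),
                ("ACGTACGTACGT", "AAAAAAAT", "g1", 1),
            ]
        )
        out = mol.collapse_umis(table)
        assert len(out) == 1
        assert out.iloc[0]["umi"] == "AAAAAAAA"
        assert out.iloc[0]["reads"] == 6

    def test_scope_is_barcode_and_gene(self):
        table = make_table(
            [
                ("ACGTACGTACGT", "AAAAAAAA", "g1", 5),
                ("ACGTACGTACGT", "AAAAAAAT", "g2", 1),
            ]
        )
        assert len(mol.collapse_umis(table)) == 2

    def test_chain_follows_greedy_order(self):
        """A-B-C chain (A~B, B~C, A!~C), reads 10/2/9: B merges into A,
        C survives -> {A: 12, C: 9}."""
        a, b, c = "AAAAAAAA", "AAAAAAAT", "AAAAAATT"
        assert _oracles.hamming(a, c) == 2
        table = make_table(
            [
                ("ACGTACGTACGT", a, "g1", 10),
                ("ACGTACGTACGT", b, "g1", 2),
                ("ACGTACGTACGT", c, "g1", 9),
            ]
        )
        out = mol.collapse_umis(table).set_index("umi")["reads"]
        assert out.to_dict() == {a: 12, c: 9}

    def test_fixed_point(self):
        rng = np.random.default_rng(0)
        umis = _seq.decode_array(rng.integers(0, 4**8, size=60, dtype=np.uint64), 8)
        table = make_table(
            [("ACGTACGTACGT", u, "g1", int(r)) for u, r in
             zip(umis, rng.integers(1, 20, size=60))]
        )
        once = mol.collapse_umis(table)
        twice = mol.collapse_umis(once)
        pd.testing.assert_frame_equal(
            once.sort_values("umi").reset_index(drop=True),
            twice.sort_values("umi").reset_index(drop=True),
        )

    def test_unequal_umi_lengths_rejected(self):
        table = make_table(
            [
                ("ACGTACGTACGT", "AAAAAAAA", "g1", 1),
                ("ACGTACGTACGT", "AAAAAAA", "g1", 1),
            ]
        )
        with pytest.raises(ValueError, match="length"):
            mol.collapse_umis(table)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, seed):
        """Random groups of <= 30 UMIs drawn from a tight 4-letter space
        (many Hamming-1 pairs) collapse exactly as the oracle says."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        codes = rng.integers(0, 4**3, size=n)  # vary only the last 3 bases
        umis = ["AAAAA" + _seq.decode(int(c), 3) for c in codes]
        reads = rng.integers(1, 30, size=n)
        group = {}
        for u, r in zip(umis, reads):
            group[u] = group.get(u, 0) + int(r)
        table = make_table(
            [("ACGTACGTACGT", u, "g1", r) for u, r in group.items()]
        )
        expected = _oracles.umi_collapse_oracle(list(group.items()))
        got = mol.collapse_umis(table).set_index("umi")["reads"].to_dict()
        assert got == expected


class TestCollapseBarcodes:
    @staticmethod
    def _table_for(barcode, pairs):
        return make_table([(barcode, u, g, 1) for u, g in pairs])

    def _pairs(self, n, start=0):
        return [(_seq.decode(i, 8), f"g{i}") for i in range(start, start + n)]

    def test_merge_when_overlap_sufficient(self):
        """CB2 (30 pairs, 27 shared = 90% of smaller set) merges into CB1."""
        cb1, cb2 = "ACGTACGTACGT", "ACGTACGTACGA"
        big = self._pairs(100)
        small = big[:27] + self._pairs(3, start=200)
        table = pd.concat([self._table_for(cb1, big), self._table_for(cb2, small)])
        out, n = mol.collapse_barcodes(table)
        assert n == 1
        assert set(out["barcode"]) == {cb1}
        assert len(out) == 103  # union of pair sets

    def test_no_merge_below_pair_count(self):
        cb1, cb2 = "ACGTACGTACGT", "ACGTACGTACGA"
        table = pd.concat(
            [self._table_for(cb1, self._pairs(100)),
             self._table_for(cb2, self._pairs(10))]
        )
        out, n = mol.collapse_barcodes(table)
        assert n == 0
        assert set(out["barcode"]) == {cb1, cb2}

    def test_no_merge_below_overlap(self):
        cb1, cb2 = "ACGTACGTACGT", "ACGTACGTACGA"
        big = self._pairs(100)
        small = big[:12] + self._pairs(18, start=200)  # 12/30 = 40%
        table = pd.concat([self._table_for(cb1, big), self._table_for(cb2, small)])
        out, n = mol.collapse_barcodes(table)
        assert n == 0

    def test_matches_bruteforce_oracle(self):
        """Random families of Hamming-1 barcode variants with random
        shared pair sets collapse exactly as the naive oracle says."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            n_true = int(rng.integers(2, 6))
            true_codes = _seq.spaced_codes(rng, n_true, 12, min_dist=3)
            barcodes = {}
            pool = [(_seq.decode(i, 8), f"g{i}") for i in range(120)]
            for code in true_codes:
                bc = _seq.decode(int(code), 12)
                k = int(rng.integers(20, 60))
                mine = [pool[i] for i in rng.choice(120, size=k, replace=False)]
                barcodes[bc] = set(mine)
                if rng.random() < 0.8:  # an error neighbor sharing most pairs
                    nb = _seq.decode(_seq.neighbors1(int(code), 12)[0], 12)
                    share = int(len(mine) * rng.uniform(0.5, 1.0))
                    extra = int(rng.integers(0, 5))
                    nb_pairs = set(mine[:share]) | {
                        pool[i] for i in rng.choice(120, size=extra, replace=False)
                    }
                    if len(nb_pairs) >= 20:
                        barcodes[nb] = nb_pairs
            assert len(barcodes) <= 20
            rows = [
                (bc, u, g, 1) for bc, pairs in barcodes.items() for u, g in pairs
            ]
            out, _ = mol.collapse_barcodes(make_table(rows))
            expected_map = _oracles.barcode_collapse_oracle(barcodes)
            expected_barcodes = {
                expected_map.get(bc, bc) for bc in barcodes
            }
            assert set(out["barcode"]) == expected_barcodes


class TestBuildDge:
    def test_empty_table(self):
        out = mol.build_dge(make_table([]))
        assert out.shape == (0, 0)

    def test_distinct_umis_counted(self):
        table = make_table(
            [
                ("ACGTACGTACGT", "AAAAAAAA", "g1", 4),
                ("ACGTACGTACGT", "CCCCCCCC", "g1", 1),
                ("ACGTACGTACGT", "GGGGGGAA", "g1", 2),
            ]
        )
        out = mol.build_dge(table)
        assert out.dense().loc["g1", "ACGTACGTACGT"] == 3

    def test_roundtrip_equals_truth(self, tiny_genome):
        pops = [syn.PopulationSpec("p", 1.0)]
        expr, truth = syn.simulate_expression(tiny_genome, pops, 25, 300, seed=1)
        table, truth = syn.emit_molecule_table(expr, truth, syn.ErrorModel(), seed=2)
        dge, _ = mol.run_molecule_pipeline(table, call=False)
        rec = dge.dense().rename(
            columns=dict(zip(truth.barcode_of.values, truth.barcode_of.index))
        )
        rec = rec.reindex(index=expr.genes, columns=expr.cells, fill_value=0)
        assert (rec.to_numpy() == expr.counts.toarray()).all()


class TestCallCells:
    def test_bimodal_knee(self):
        """50 high-read barcodes over 500 low ones: the knee calls the
        high block (+-10%)."""
        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            rows.append((_seq.decode(i, 12), "AAAAAAAA", "g1",
                         int(rng.poisson(10_000))))
        for i in range(500):
            rows.append((_seq.decode(1000 + i, 12), "AAAAAAAA", "g1",
                         int(rng.poisson(10)) + 1))
        called = mol.call_cells(make_table(rows))
        assert 45 <= len(called) <= 55
        high = {_seq.decode(i, 12) for i in range(50)}
        assert called <= high or len(called - high) <= 2

    def test_flat_curve_calls_everyone(self):
        rows = [(_seq.decode(i, 12), "AAAAAAAA", "g1", 100) for i in range(30)]
        assert len(mol.call_cells(make_table(rows))) == 30

    def test_dominant_barcode_always_called(self):
        rng = np.random.default_rng(4)
        rows = [("ACGTACGTACGT", "AAAAAAAA", "g1", 50_000)]
        for i in range(40):
            rows.append((_seq.decode(i, 12), "AAAAAAAA", "g1",
                         int(rng.integers(1, 20))))
        assert "ACGTACGTACGT" in mol.call_cells(make_table(rows))

    def test_too_few_barcodes_rejected(self):
        rows = [(_seq.decode(i, 12), "AAAAAAAA", "g1", 10) for i in range(5)]
        with pytest.raises(ValueError, match="barcodes"):
            mol.call_cells(make_table(rows))


class TestPipeline:
    def test_reads_conserved_and_monotone(self, tiny_genome):
        pops = [syn.PopulationSpec("p", 1.0)]
        expr, truth = syn.simulate_expression(tiny_genome, pops, 40, 400, seed=6)
        err = syn.ErrorModel(
            truncation_rate=0.1,
            umi_substitution_rate=0.02,
            barcode_substitution_rate=0.02,
        )
        table, truth = syn.emit_molecule_table(expr, truth, err, seed=7)
        dge, report = mol.run_molecule_pipeline(table, call=False)
        assert report.reads_in - report.degenerate_reads_removed == report.reads_out
        # collapse only merges: recovered molecules never exceed raw records
        assert dge.counts.sum() <= len(table)
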