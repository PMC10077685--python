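"""IDP classification, congruence, haplotypes and SNP region fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitostruct.genome_io import AnnotatedGenome, Feature
from mitostruct.idp_classifier import (
    assign_idp_classes,
    classify_snp_regions,
    collapse_haplotypes,
    idp_clade_congruence,
    select_variable_sites,
)

from conftest import random_seq


def matrix(rows: dict[str, list[str]], genes=None) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    cols = genes or [f"cox1.{i + 1}" for i in range(n)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "strain_id"
    return df


class TestVariableSites:
    def test_identical_rows_give_empty_list(self):
        m = matrix({"a": ["1-1", "0"], "b": ["1-1", "0"]})
        assert select_variable_sites(m) == []

    def test_single_polymorphic_site_selected(self):
        m = matrix({"a": ["5-1", "1-1"], "b": ["0", "1-1"]})
        assert select_variable_sites(m) == ["cox1.1"]

    def test_matches_columnwise_distinct_count_oracle(self, rng):
        states = np.array(["0", "1-1", "1-2", "1-1:B"])
        m = pd.DataFrame(
            states[rng.integers(0, 4, size=(20, 15))],
            index=[f"s{i}" for i in range(20)],
            columns=[f"cox1.{j + 1}" for j in range(15)],
        )
        got = select_variable_sites(m)
        oracle = [c for c in m.columns if len(set(m[c])) >= 2]
        assert got == oracle

    def test_scope_restricts_variation(self):
        m = matrix({"a": ["1-1"], "b": ["0"], "c": ["1-1"]})
        assert select_variable_sites(m, scope=["a", "c"]) == []


class TestIDPClasses:
    def test_uniform_matrix_single_class(self):
        m = matrix({f"s{i}": ["1-1", "0"] for i in range(5)})
        classes = assign_idp_classes(m, select_variable_sites(m))
        assert len(classes) == 1
        assert sorted(classes[0].members) == sorted(m.index)

    def test_planted_vectors_match_unique_row_oracle(self, rng):
        vecs = [["1-1", "0", "2-1"], ["0", "0", "2-1"], ["1-1", "1-1", "0"],
                ["0", "1-1", "0"], ["1-1", "0", "0"]]
        rows = {f"s{i:02d}": vecs[rng.integers(0, 5)] for i in range(20)}
        m = matrix(rows)
        classes = assign_idp_classes(m, select_variable_sites(m))
        got = sorted(sorted(c.members) for c in classes)
        oracle: dict[tuple, list[str]] = {}
        for s, v in rows.items():
            oracle.setdefault(tuple(v), []).append(s)
        assert got == sorted(sorted(v) for v in oracle.values())

    def test_shared_vector_spans_clades(self):
        # two "clades" of strains with one identical planted vector
        m = matrix({"eu1_a": ["1-1"], "eu1_b": ["1-1"], "eu2_a": ["1-1"],
                    "eu2_b": ["0"]})
        classes = assign_idp_classes(m, ["cox1.1"])
        big = next(c for c in classes if len(c.members) == 3)
        assert {"eu1_a", "eu1_b", "eu2_a"} == set(big.members)

    def test_tree_orders_labels(self):
        m = matrix({"a": ["1-1"], "b": ["0"], "c": ["1-1"]})
        nwk = "((b:1,c:1):1,a:1);"
        classes = assign_idp_classes(m, ["cox1.1"], ordering_tree=nwk)
        # b is the first leaf -> its class is IDP1
        assert classes[0].label == "IDP1" and "b" in classes[0].members

    def test_tree_missing_leaf_errors(self):
        m = matrix({"a": ["1-1"], "b": ["0"]})
        with pytest.raises(ValueError, match="missing strains"):
            assign_idp_classes(m, ["cox1.1"], ordering_tree="(a:1,x:1);")

    def test_partition_invariant_to_row_order(self, rng):
        vecs = [["1-1", "0"], ["0", "0"], ["1-1", "1-1"]]
        rows = {f"s{i:02d}": vecs[rng.integers(0, 3)] for i in range(12)}
        m = matrix(rows)
        shuffled = m.loc[rng.permutation(m.index)]
        p1 = sorted(sorted(c.members) for c in
                    assign_idp_classes(m, select_variable_sites(m)))
        p2 = sorted(sorted(c.members) for c in
                    assign_idp_classes(shuffled, select_variable_sites(shuffled)))
        assert p1 == p2

    def test_subsetting_never_increases_classes(self, rng):
        vecs = [["1-1", "0"], ["0", "0"], ["1-1", "1-1"], ["0", "1-1"]]
        rows = {f"s{i:02d}": vecs[rng.integers(0, 4)] for i in range(16)}
        m = matrix(rows)
        full = assign_idp_classes(m, select_variable_sites(m))
        keep = list(m.index[:8])
        sub = m.loc[keep]
        reduced = assign_idp_classes(sub, select_variable_sites(m))
        assert len(reduced) <= len(full)

    def test_simulated_partition_equals_truth(self, sim_dataset):
        import json

        from mitostruct.intron_atlas import (
            build_site_registry,
            map_introns,
            observations_to_matrix,
        )
        from mitostruct.synthetic_data import apply_subtype_declarations

        truth = sim_dataset["truth"]
        genomes = sim_dataset["genomes"]
        reg = build_site_registry(genomes["REF"])
        decl = json.loads((sim_dataset["dir"] / "truth.json").read_text())[
            "subtype_variants"
        ]
        apply_subtype_declarations(reg, decl)
        obs = {s: map_introns(genomes[s], reg)
               for s in sorted(genomes) if s != "REF"}
        m = observations_to_matrix(obs, reg)
        classes = assign_idp_classes(m, select_variable_sites(m))
        got = sorted(sorted(c.members) for c in classes)
        assert got == sorted(sorted(g) for g in truth.partition)


def _ari_oracle(labels_a, labels_b) -> float:
    """Brute-force ARI from the contingency table."""
    from math import comb

    cats_a, cats_b = sorted(set(labels_a)), sorted(set(labels_b))
    n = len(labels_a)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for x, y in zip(labels_a, labels_b):
        table[cats_a.index(x), cats_b.index(y)] += 1
    sum_ij = sum(comb(int(v), 2) for v in table.flat)
    sum_a = sum(comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


class TestCongruence:
    def test_identical_partitions(self):
        idp = {f"s{i}": f"c{i % 3}" for i in range(9)}
        rep = idp_clade_congruence(idp, dict(idp))
        assert rep.adjusted_rand_index == pytest.approx(1.0)
        assert rep.single_clade_class_count == rep.n_classes == 3

    def test_split_class_has_spread_two(self):
        idp = {"a": "IDP1", "b": "IDP1", "c": "IDP2", "d": "IDP2"}
        clades = {"a": "X", "b": "Y", "c": "X", "d": "X"}
        rep = idp_clade_congruence(idp, clades)
        assert rep.per_class_clade_spread["IDP1"] == 2
        assert rep.per_class_clade_spread["IDP2"] == 1
        assert rep.single_clade_class_count == 1

    def test_random_partitions_match_contingency_oracle(self, rng):
        strains = [f"s{i}" for i in range(50)]
        idp = {s: f"I{rng.integers(0, 6)}" for s in strains}
        clades = {s: f"C{rng.integers(0, 4)}" for s in strains}
        rep = idp_clade_congruence(idp, clades)
        oracle = _ari_oracle([idp[s] for s in strains], [clades[s] for s in strains])
        assert rep.adjusted_rand_index == pytest.approx(oracle, abs=1e-9)

    def test_mismatched_strain_sets_error(self):
        with pytest.raises(ValueError, match="different strain sets"):
            idp_clade_congruence({"a": "I1"}, {"b": "C1"})


class TestHaplotypes:
    def test_two_identical_rows_collapse(self):
        aln = pd.DataFrame(
            [list("ACGT"), list("ACGT"), list("ACGA"), list("TCGA")],
            index=["a", "b", "c", "d"],
        )
        classes, n = collapse_haplotypes(aln)
        assert n == 3
        assert ["a", "b"] in classes

    def test_all_distinct_rows(self):
        aln = pd.DataFrame([list("AC"), list("AG"), list("TC")])
        _, n = collapse_haplotypes(aln)
        assert n == 3

    def test_drop_columns_matches_manual_filtering_oracle(self, rng):
        states = np.array(list("ACGTN"))
        data = states[rng.integers(0, 5, size=(12, 30))]
        aln = pd.DataFrame(data, index=[f"s{i}" for i in range(12)])
        classes, n = collapse_haplotypes(aln, missing_policy="drop_columns")
        # oracle: filter columns by hand, then group rows
        keep = [j for j in range(30) if "N" not in set(data[:, j])]
        filtered = ["".join(data[i, keep]) for i in range(12)]
        assert n == len(set(filtered))
        got = sorted(sorted(c) for c in classes)
        oracle: dict[str, list[str]] = {}
        for i, row in enumerate(filtered):
            oracle.setdefault(row, []).append(f"s{i}")
        assert got == sorted(sorted(v) for v in oracle.values())

    def test_strict_policy_keeps_missing_as_state(self):
        aln = pd.DataFrame([list("AN"), list("AA"), list("AN")])
        _, n_strict = collapse_haplotypes(aln, missing_policy="strict")
        assert n_strict == 2
        _, n_drop = collapse_haplotypes(aln, missing_policy="drop_columns")
        assert n_drop == 1

    def test_all_columns_missing_errors(self):
        aln = pd.DataFrame([list("N"), list("A")])
        with pytest.raises(ValueError, match="no columns left"):
            collapse_haplotypes(aln)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_haplotype_count_bounds(self, seed):
        rng = np.random.default_rng(seed)
        states = np.array(list("ACGT"))
        data = states[rng.integers(0, 4, size=(8, 10))]
        _, n = collapse_haplotypes(pd.DataFrame(data))
        assert 1 <= n <= 8


class TestSnpRegions:
    def _annotation(self, rng):
        seq = random_seq(rng, 3000)
        feats = [
            Feature("cox1", "CDS", "+", [(100, 400), (700, 1000)]),
            Feature("cox1-i1", "intron", "+", [(400, 700)], {"host_gene": "cox1"}),
            Feature("trnA", "tRNA", "+", [(1500, 1575)]),
        ]
        return AnnotatedGenome(strain_id="ref", sequence=seq, features=feats)

    def test_exonic_and_intergenic_positions(self, rng):
        g = self._annotation(rng)
        fr = classify_snp_regions([150], g)
        assert fr == {"exon": 1.0, "intron": 0.0, "intergenic": 0.0}
        fr = classify_snp_regions([2500], g)
        assert fr["intergenic"] == 1.0

    def test_fractions_match_interval_scan_oracle(self, rng):
        g = self._annotation(rng)
        positions = sorted(rng.integers(0, 3000, size=100).tolist())
        fr = classify_snp_regions(positions, g)
        exon = [(100, 400), (700, 1000), (1500, 1575)]
        intron = [(400, 700)]
        counts = {"exon": 0, "intron": 0, "intergenic": 0}
        for p in positions:  # independent membership scan
            if any(s <= p < e for s, e in exon):
                counts["exon"] += 1
            elif any(s <= p < e for s, e in intron):
                counts["intron"] += 1
            else:
                counts["intergenic"] += 1
        for k in counts:
            assert fr[k] == pytest.approx(counts[k] / 100)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_out_of_range_position_errors(self, rng):
        g = self._annotation(rng)
        with pytest.raises(ValueError, match="record 1"):
            classify_snp_regions([10, 5000], g)

    def test_vcf_read_positions(self, rng, tmp_path):
        from mitostruct.idp_classifier import read_vcf_positions

        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=3000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "ref\t151\t.\tA\tC\t50\tPASS\t.\n"
            "ref\t2501\t.\tG\tT\t50\tPASS\t.\n"
        )
        pos = read_vcf_positions(str(vcf))
        assert pos == [150, 2500]
        fr = classify_snp_regions(pos, self._annotation(rng))
        assert fr["exon"] == pytest.approx(0.5)
        assert fr["intergenic"] == pytest.approx(0.5)
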