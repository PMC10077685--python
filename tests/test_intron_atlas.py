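"""Intron site registry, mapping, type/subtype calls and anomaly flags."""

import numpy as np
import pytest

from mitostruct.genome_io import (
    AnnotatedGenome,
    Feature,
    GenomeValidationError,
    rotate_genome,
)
from mitostruct.intron_atlas import (
    TypeExemplar,
    build_site_registry,
    classify_intron_type,
    detect_intron_anomalies,
    intron_spliced_position,
    map_introns,
    observation_state,
    observations_to_matrix,
)

from conftest import make_gene_with_introns, random_seq


def reference_genome(rng, intron_counts={"cox1": 19, "cob": 3}, exon_len=120,
                     intron_len=300):
    """Reference with annotated introns; cox1 mirrors a 19-intron reservoir."""
    feats = []
    pos = 50
    intron_seqs = {}
    for gene, k in intron_counts.items():
        seqs = [random_seq(rng, intron_len) for _ in range(k)]
        intron_seqs[gene] = seqs
        gfeats, pos = make_gene_with_introns(gene, pos, exon_len, seqs)
        feats.extend(gfeats)
        pos += 200
    feats.append(Feature("atp6", "CDS", "+", [(pos, pos + 300)]))
    pos += 400
    seq = random_seq(rng, pos + 100)
    g = AnnotatedGenome(strain_id="REF", sequence=seq, features=feats)
    return g, intron_seqs


class TestRegistry:
    def test_cox1_reservoir_sites_strictly_increasing(self, rng):
        ref, _ = reference_genome(rng)
        reg = build_site_registry(ref)
        cox1_sites = reg.sites_for("cox1")
        assert len(cox1_sites) == 19
        pos = [s.spliced_pos for s in cox1_sites]
        assert pos == sorted(pos) and len(set(pos)) == len(pos)
        assert [s.ordinal for s in cox1_sites] == list(range(1, 20))
        # spliced positions are exon-length multiples here
        assert pos == [120 * k for k in range(1, 20)]

    def test_gene_without_introns_has_no_sites(self, rng):
        ref, _ = reference_genome(rng)
        reg = build_site_registry(ref)
        assert reg.sites_for("atp6") == []

    def test_augment_is_idempotent_within_tolerance(self, rng):
        ref, _ = reference_genome(rng)
        reg = build_site_registry(ref)
        n = len(reg)
        site = reg.augment("cox1", 120 * 5 + 3, tol=6)  # near existing site 5
        assert len(reg) == n
        assert site.ordinal == 5
        novel = reg.augment("cox1", 120 * 5 + 60, tol=6)  # genuinely new
        assert len(reg) == n + 1 and novel.novel

    def test_intron_outside_host_gene_rejected(self, rng):
        ref, _ = reference_genome(rng)
        ref.features.append(
            Feature("bad", "intron", "+", [(5, 25)], {"host_gene": "cox1"})
        )
        with pytest.raises(GenomeValidationError, match="outside host gene"):
            build_site_registry(ref)

    def test_registry_json_round_trip(self, rng):
        from mitostruct.intron_atlas import IntronSiteRegistry

        ref, _ = reference_genome(rng)
        reg = build_site_registry(ref)
        reg2 = IntronSiteRegistry.from_json(reg.to_json())
        assert [(s.gene, s.ordinal, s.spliced_pos) for s in reg2.sites] == [
            (s.gene, s.ordinal, s.spliced_pos) for s in reg.sites
        ]


class TestMapping:
    def test_identity_query_reproduces_catalog(self, rng):
        ref, _ = reference_genome(rng)
        reg = build_site_registry(ref)
        obs = map_introns(ref, reg)
        assert len(obs) == len(reg)
        assert all(o.present for o in obs)
        assert all(o.type_label.endswith("-1") for o in obs)

    def test_single_deletion_leaves_others_unchanged(self, rng):
        ref, seqs = reference_genome(rng)
        reg = build_site_registry(ref)
        # rebuild the genome without cox1 intron 5: the flanking exons fuse,
        # so the remaining introns keep their spliced coordinates
        kept = seqs["cox1"][:4] + seqs["cox1"][5:]
        exon_lens = [120] * 4 + [240] + [120] * (len(kept) - 4)
        q_feats, pos = make_gene_with_introns("cox1", 50, exon_lens, kept)
        cob_feats, pos2 = make_gene_with_introns("cob", pos + 200, 120, seqs["cob"])
        q = AnnotatedGenome(
            strain_id="Q", sequence=random_seq(rng, pos2 + 500),
            features=q_feats + cob_feats,
        )
        obs = map_introns(q, reg)
        by_site = {o.site: o for o in obs}
        assert by_site[("cox1", 5)].present is False
        others = [o for o in obs if o.site != ("cox1", 5)]
        assert all(o.present for o in others)

    def test_exon_substitutions_do_not_move_assignments(self, rng):
        # 5% substitutions in exons change sequence but not coordinates:
        # spliced positions stay exact multiples of the exon length
        ref, seqs = reference_genome(rng, intron_counts={"cox1": 4})
        reg = build_site_registry(ref)
        mutated = list(ref.sequence)
        gene = ref.get_gene("cox1")
        for s, e in gene.segments:
            for i in range(s, e):
                if rng.random() < 0.05:
                    mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        q = AnnotatedGenome(strain_id="Q", sequence="".join(mutated),
                            features=[f for f in ref.features])
        obs = map_introns(q, reg, id_threshold=0.5)
        # oracle: hand-computed spliced coordinates from the annotation
        gene_q = q.get_gene("cox1")
        for it in q.introns_of("cox1"):
            pos = intron_spliced_position(gene_q, it)
            site = reg.match("cox1", pos, tol=6)
            assert site is not None
        assert sorted(o.site for o in obs if o.site[0] == "cox1") == [
            ("cox1", k) for k in range(1, 5)
        ]
        assert all(o.present for o in obs if o.site[0] == "cox1")

    def test_two_introns_one_site_is_an_error(self, rng):
        ref, seqs = reference_genome(rng, intron_counts={"cox1": 2})
        reg = build_site_registry(ref)
        # plant a second intron 3 nt into exon 2 -> same site within tol
        gene = ref.get_gene("cox1")
        clash = Feature("cox1-ix", "intron", "+",
                        [(gene.segments[1][0] + 2, gene.segments[1][0] + 40)],
                        {"host_gene": "cox1"})
        q = AnnotatedGenome(strain_id="Q", sequence=ref.sequence,
                            features=ref.features + [clash])
        with pytest.raises(GenomeValidationError, match="both map to site"):
            map_introns(q, reg)

    def test_assignment_invariant_under_rotation(self, rng):
        ref, _ = reference_genome(rng)
        reg = build_site_registry(ref)
        rot = rotate_genome(ref, 1000)
        obs_ref = map_introns(ref, reg)
        obs_rot = map_introns(rot, reg)
        assert [(o.site, o.present) for o in obs_ref] == [
            (o.site, o.present) for o in obs_rot
        ]


class TestTyping:
    def _site(self, rng, n_types=2, length=400, divergence=0.3):
        from mitostruct.intron_atlas import IntronSite

        base = random_seq(rng, length)
        site = IntronSite(gene="cox1", ordinal=23, spliced_pos=1000)
        seqs = {1: base}
        for t in range(2, n_types + 1):
            mutated = list(base)
            hits = np.flatnonzero(rng.random(length) < divergence)
            for i in hits:
                mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
            seqs[t] = "".join(mutated)
        for t, s in seqs.items():
            site.known_types[f"23-{t}"] = TypeExemplar(f"23-{t}", s)
        return site, seqs

    def test_exact_match_returns_type(self, rng):
        site, seqs = self._site(rng)
        label, subtype = classify_intron_type(site, seqs[2])
        assert label == "23-2"
        assert subtype is None

    def test_distant_sequence_registers_new_type(self, rng):
        site, seqs = self._site(rng)
        alien = list(seqs[1])
        hits = np.flatnonzero(rng.random(len(alien)) < 0.40)  # ~70% identity
        for i in hits:
            alien[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[alien[i]]
        alien = "".join(alien)
        import edlib

        # oracle: best alignment identity to every exemplar is below 0.90
        for ex in site.known_types.values():
            d = edlib.align(alien, ex.exemplar_seq, mode="NW", task="distance")
            ident = 1 - d["editDistance"] / max(len(alien), len(ex.exemplar_seq))
            assert ident < 0.90
        label, _ = classify_intron_type(site, alien, id_threshold=0.90)
        assert label == "23-3"
        assert "23-3" in site.known_types

    def test_subtype_snp_plus_indel(self, rng):
        site, seqs = self._site(rng, n_types=1)
        ex = site.known_types["23-1"]
        base = ex.exemplar_seq
        p1, p2 = 100, 250
        ex.subtype_variants = [
            (p1, base[p1], "A" if base[p1] != "A" else "G"),
            (p2, base[p2 : p2 + 2], ""),
        ]
        label_a, sub_a = classify_intron_type(site, base)
        # subtype B: apply the SNP and delete the 2-bp column
        alt = base[:p1] + ex.subtype_variants[0][2] + base[p1 + 1 :]
        alt = alt[:p2] + alt[p2 + 2 :]
        label_b, sub_b = classify_intron_type(site, alt)
        assert (label_a, sub_a) == ("23-1", "A")
        assert (label_b, sub_b) == ("23-1", "B")


class TestAnomalies:
    def test_identity_has_no_anomalies(self, rng):
        ex = TypeExemplar("13-1", random_seq(rng, 600))
        inserts, degenerate = detect_intron_anomalies(ex.exemplar_seq, ex)
        assert inserts == [] and degenerate is False

    def test_planted_1238nt_insert_reported(self, rng):
        ex = TypeExemplar("13-1", random_seq(rng, 600))
        insert = random_seq(rng, 1238)
        obs = ex.exemplar_seq[:300] + insert + ex.exemplar_seq[300:]
        inserts, degenerate = detect_intron_anomalies(obs, ex)
        assert degenerate is False
        assert len(inserts) == 1
        offset, length = inserts[0]
        assert length == pytest.approx(1238, abs=5)
        assert offset == pytest.approx(300, abs=5)

    def test_truncated_copy_flagged_degenerate(self, rng):
        ex = TypeExemplar("3-1", random_seq(rng, 500))
        obs = ex.exemplar_seq[: int(500 * 0.6)]  # 40% of the 3' end missing
        inserts, degenerate = detect_intron_anomalies(obs, ex)
        assert degenerate is True


class TestMatrix:
    def test_states_cover_registry_exactly(self, rng):
        ref, _ = reference_genome(rng)
        reg = build_site_registry(ref)
        obs = {"REF": map_introns(ref, reg)}
        m = observations_to_matrix(obs, reg)
        assert m.shape == (1, len(reg))
        assert (m.loc["REF"] != "0").all()

    def test_absent_state_string(self):
        from mitostruct.intron_atlas import IntronObservation

        ob = IntronObservation(strain_id="s", site=("cox1", 1), present=False)
        assert observation_state(ob) == "0"
        ob2 = IntronObservation(
            strain_id="s", site=("cox1", 1), present=True,
            type_label="1-2", subtype_label="B", inserts=[(10, 1238)],
        )
        assert observation_state(ob2) == "1-2:B+ins1238"

    def test_simulated_matrix_equals_truth_without_gains(self, tmp_path):
        # with gains disabled every present intron keeps the founding type,
        # so the recovered matrix must equal the simulator's truth exactly
        import json

        from mitostruct.synthetic_data import (
            SimParams,
            apply_subtype_declarations,
            emit_genomes,
            simulate_evolution,
        )

        params = SimParams(n_leaves=6, seed=11, gain_rate=0.0)
        truth = simulate_evolution(None, params)
        genomes = emit_genomes(truth, params, tmp_path)
        reg = build_site_registry(genomes["REF"])
        decl = json.loads((tmp_path / "truth.json").read_text())["subtype_variants"]
        apply_subtype_declarations(reg, decl)
        obs = {
            s: map_introns(genomes[s], reg)
            for s in sorted(genomes) if s != "REF"
        }
        m = observations_to_matrix(obs, reg)
        truth_m = truth.state_matrix
        assert m.sort_index().equals(truth_m.sort_index()[m.columns])
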