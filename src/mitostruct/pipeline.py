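"""End-to-end orchestration: configuration, stage sequencing and reports.

The pipeline runs composition stats → inverted-repeat/MIR calls → intron
mapping → dpo profiling → IDP classification → clade congruence → event
inference in order, writing one TSV/JSON per stage plus a combined summary
and a provenance record sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dpo_catalog import build_dpo_catalog, clade_dpo_summary, profile_genome_dpo
from .event_inference import infer_min_events, load_tree
from .genome_io import (
    AnnotatedGenome,
    StrainMeta,
    compute_genome_stats,
    normalize_orientation,
    read_annotated_genome,
    read_metadata_table,
)
from .idp_classifier import (
    assign_idp_classes,
    idp_clade_congruence,
    select_variable_sites,
)
from .intron_atlas import (
    build_site_registry,
    map_introns,
    observations_to_matrix,
    write_state_matrix,
)
from .repeat_structure import call_mir, detect_inverted_repeats
from .synthetic_data import apply_subtype_declarations

log = logging.getLogger("mitostruct")

ALL_STAGES = ("stats", "repeats", "introns", "dpo", "idp", "events")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "mitostruct_out"
    reference: str = "REF"  # strain id of the registry/naming reference
    tree: str | None = None  # newick path for ordering and event inference
    subtype_json: str | None = None  # curated subtype-variant declarations
    anchor_gene: str = "cox1"
    tol: int = 6
    id_threshold: float = 0.90
    merge_id: float = 0.90
    assign_id: float = 0.75
    min_cover: float = 0.60
    min_len: int = 500
    min_identity: float = 0.95
    insert_min: int = 15
    cover_min: float = 0.80
    missing_policy: str = "drop_columns"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def validate(self) -> None:
        if not 0 < self.id_threshold <= 1 or not 0 < self.min_identity <= 1:
            raise ValueError("identity thresholds must be in (0, 1]")
        if self.tol < 0 or self.insert_min < 0 or self.min_len < 50:
            raise ValueError("tol/insert_min must be >= 0 and min_len >= 50")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Plain key=value config file; '#' starts a comment."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            ftype = fields[key].type
            if key == "stages":
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            elif "int" in str(ftype):
                kwargs[key] = int(value)
            elif "float" in str(ftype):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def load_genome_set(
    input_dir: str | Path, anchor_gene: str = "cox1"
) -> tuple[dict[str, AnnotatedGenome], dict[str, StrainMeta]]:
    """Read every genome in a directory (GenBank preferred) plus metadata."""
    input_dir = Path(input_dir)
    paths = sorted(input_dir.glob("*.gbk")) + sorted(input_dir.glob("*.gb"))
    genomes: dict[str, AnnotatedGenome] = {}
    if paths:
        for p in paths:
            g = read_annotated_genome(p, format="genbank")
            genomes[g.strain_id] = g
    else:
        for fa in sorted(input_dir.glob("*.fasta")):
            table = fa.with_suffix("").with_suffix("")  # strip .fasta
            table = fa.parent / (fa.stem + ".features.tsv")
            if table.exists():
                g = read_annotated_genome(fa, format="fasta+table", table=table)
                genomes[g.strain_id] = g
    if not genomes:
        raise FileNotFoundError(f"no genomes found in {input_dir}")
    meta_path = input_dir / "metadata.tsv"
    metas = read_metadata_table(meta_path) if meta_path.exists() else {}
    for sid, g in genomes.items():
        if sid in metas:
            g.metadata = metas[sid]
        genomes[sid] = normalize_orientation(g, anchor_gene)
    return genomes, metas


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the combined summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, metas = load_genome_set(config.input_dir, config.anchor_gene)
    ref_id = config.reference if config.reference in genomes else None
    study = {
        sid: g
        for sid, g in genomes.items()
        if sid != ref_id and g.metadata.clade != "reference"
    }
    log.info("loaded %d genomes (%d study strains)", len(genomes), len(study))
    summary: dict = {"n_strains": len(study), "version": __version__}

    if "stats" in config.stages:
        rows = []
        for sid, g in sorted(genomes.items()):
            st = compute_genome_stats(g)
            rows.append(
                {"strain_id": sid, "length": st.length, "at_content": st.at_content,
                 "gc_skew": st.gc_skew, "n_count": st.n_count}
            )
        pd.DataFrame(rows).to_csv(out / "genome_stats.tsv", sep="\t", index=False)
        summary["mean_at_content"] = float(
            pd.DataFrame(rows)["at_content"].mean()
        )

    orientations: dict[str, str] = {}
    repeats_by_strain = {}
    if "repeats" in config.stages:
        rows = []
        for sid, g in sorted(genomes.items()):
            pairs = detect_inverted_repeats(
                g, min_len=config.min_len, min_identity=config.min_identity
            )
            repeats_by_strain[sid] = pairs
            try:
                rep = call_mir(g, pairs, anchor_gene=config.anchor_gene)
                orient, seg, markers = rep.orientation, rep.segment, rep.markers_found
            except ValueError as exc:
                log.warning("%s: %s", sid, exc)
                orient, seg, markers = "unknown", ("", ""), []
            orientations[sid] = orient
            top = pairs[0] if pairs else None
            rows.append(
                {"strain_id": sid,
                 "irs_a": f"{top.copy_a[0]}-{top.copy_a[1]}" if top else "",
                 "irs_b": f"{top.copy_b[0]}-{top.copy_b[1]}" if top else "",
                 "irs_len": top.length if top else 0,
                 "identity": round(top.identity, 4) if top else 0.0,
                 "mir_start": seg[0], "mir_end": seg[1],
                 "orientation": orient, "markers": ",".join(markers)}
            )
        pd.DataFrame(rows).to_csv(out / "irs_mir.tsv", sep="\t", index=False)
        study_orient = {s: o for s, o in orientations.items() if s in study}
        summary["mir_orientations"] = {
            o: sum(1 for v in study_orient.values() if v == o)
            for o in sorted(set(study_orient.values()))
        }

    matrix = None
    registry = None
    if "introns" in config.stages:
        if ref_id is None:
            raise ValueError(
                f"reference strain {config.reference!r} not among inputs"
            )
        registry = build_site_registry(genomes[ref_id])
        if config.subtype_json:
            payload = json.loads(Path(config.subtype_json).read_text())
            decl = payload.get("subtype_variants", payload)
            apply_subtype_declarations(registry, decl)
        all_obs = {}
        for sid in sorted(study):
            all_obs[sid] = map_introns(
                study[sid], registry, tol=config.tol,
                id_threshold=config.id_threshold,
                insert_min=config.insert_min, cover_min=config.cover_min,
            )
        matrix = observations_to_matrix(all_obs, registry, include_novel=True)
        write_state_matrix(matrix, out / "intron_states.tsv")
        registry.to_json(out / "intron_registry.json")
        summary["n_intron_sites"] = len(registry)

    if "dpo" in config.stages:
        catalog = build_dpo_catalog(
            list(genomes.values()), merge_id=config.merge_id,
            naming_genome=ref_id,
        )
        profiles = []
        rows = []
        for sid in sorted(study):
            prof = profile_genome_dpo(
                study[sid], catalog, assign_id=config.assign_id,
                min_cover=config.min_cover,
                repeats=repeats_by_strain.get(sid),
            ) if catalog else None
            if prof is not None:
                profiles.append(prof)
                for h in prof.hits:
                    rows.append(
                        {"strain_id": sid, "fragment": h.fragment_id,
                         "start": h.segment[0], "end": h.segment[1],
                         "strand": h.strand, "identity": round(h.identity, 4),
                         "in_repeat": h.in_repeat}
                    )
        pd.DataFrame(rows).to_csv(out / "dpo_profiles.tsv", sep="\t", index=False)
        if profiles:
            meta_map = {sid: study[sid].metadata for sid in study}
            fractions, consensus = clade_dpo_summary(profiles, meta_map, catalog)
            fractions.to_csv(out / "dpo_clade_fractions.tsv", sep="\t")
            consensus.to_csv(out / "dpo_clade_consensus.tsv", sep="\t")
        summary["n_dpo_fragments"] = len(catalog)

    classes = None
    if "idp" in config.stages and matrix is not None:
        variable = select_variable_sites(matrix)
        tree = load_tree(config.tree) if config.tree else None
        classes = assign_idp_classes(matrix, variable, ordering_tree=tree)
        rows = []
        for c in classes:
            cl = sorted({study[s].metadata.clade for s in c.members})
            rows.append(
                {"label": c.label, "n_members": len(c.members),
                 "clades": ",".join(cl),
                 "varieties": ",".join(sorted({study[s].metadata.variety for s in c.members})),
                 "origins": ",".join(sorted({study[s].metadata.origin for s in c.members})),
                 "cox1_intron_count": c.cox1_intron_count,
                 "members": ",".join(c.members)}
            )
        pd.DataFrame(rows).to_csv(out / "idp_classes.tsv", sep="\t", index=False)
        summary["n_variable_sites"] = len(variable)
        summary["n_idp_classes"] = len(classes)
        clades = {sid: study[sid].metadata.clade for sid in study}
        if len(set(clades.values())) > 1:
            rep = idp_clade_congruence(classes, clades)
            summary["idp_clade_congruence"] = {
                "single_clade_classes": rep.single_clade_class_count,
                "n_classes": rep.n_classes,
                "adjusted_rand_index": rep.adjusted_rand_index,
            }

    if "events" in config.stages and matrix is not None and config.tree:
        tree = load_tree(config.tree)
        leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        sub = matrix.loc[[s for s in matrix.index if s in leaf_labels]]
        events, count = infer_min_events(tree, sub)
        rows = [
            {"branch": e.branch, "gene": e.gene,
             "sites": ",".join(str(o) for o in sorted(e.site_ordinals)),
             "kind": e.kind}
            for e in events
        ]
        pd.DataFrame(rows).to_csv(out / "events.tsv", sep="\t", index=False)
        summary["n_events"] = count

    provenance = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "version": __version__,
        "seed": config.seed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
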