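"""End-to-end orchestration of the synthetic study pipeline.

``run_pipeline`` executes the toggled stages — simulate, fastq+qc,
refpkg, classify, massmath (KR / squash / islands), edgepca, ecology,
assoc — writing CSV/newick/jplace/JSON artifacts plus a provenance
manifest into an output directory. Re-running with the same config and
seed reproduces identical outputs. Every stage is equally callable as a
library function; the CLI (:mod:`vaginome.cli`) is a thin wrapper.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict

import yaml

from . import __version__, assoc, classify, ecology, edgepca, massmath, read_qc, refpkg, synthetic
from .containers import CountMatrix
from .errors import ConfigurationError

log = logging.getLogger("vaginome")

STAGES = ["simulate", "fastq_qc", "refpkg", "classify", "massmath",
          "edgepca", "ecology", "assoc"]


class DependencyError(ConfigurationError):
    """A toggled stage is missing an upstream artifact."""


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults are the documented analysis constants."""

    out_dir: str = "vaginome_run"
    seed: int = 0
    stages: Dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # synthetic world / cohort
    n_taxa: int = 12
    seqs_per_taxon: int = 4
    seq_length: int = 300
    n_samples: int = 60
    frac_bv: float = 0.45
    race_mix: Dict[str, float] = field(
        default_factory=lambda: {"White": 0.44, "Black": 0.34, "Other": 0.22}
    )
    depth_mean: float = 200.0      # demo-scale; surveys average ~1620/participant
    interaction_strength: float = 1.5
    placement_spread: float = 0.02
    # read QC
    min_len: int = 200
    min_avg_qual: float = 35.0
    clip_window: int = 30
    clip_q_threshold: int = 15
    clip_min_frac: float = 0.9
    frac_bad_barcode: float = 0.03
    frac_short: float = 0.03
    frac_low_quality: float = 0.03
    fastq_samples: int = 6         # subset of samples written to FASTQ
    # refpkg curation
    mislabel_cutoff: float = 0.015
    n_representatives: int = 5
    # classification
    classify_cutoff: float = 0.9
    compound_threshold: float = 0.05
    # massmath
    n_boot: int = 50
    island_cutoff: float = 0.02
    island_min_subjects: int = 2
    island_order: str = "Clostridiales"
    # ecology
    trim_top_frac: float = 0.30
    # assoc
    enet_alpha: float = 0.5
    enet_folds: int = 10
    lrt_min_nonzero: int = 10

    def validate(self) -> "PipelineConfig":
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, False)
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data).validate()


def _need(artifacts: dict, key: str, stage: str):
    if key not in artifacts:
        raise DependencyError(
            f"stage '{stage}' needs artifact '{key}' from an upstream stage "
            "that was not run"
        )
    return artifacts[key]


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the toggled stages; returns the output directory."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    artifacts: dict = {}
    timers: Dict[str, float] = {}

    def stage_on(name: str) -> bool:
        return bool(config.stages.get(name))

    if stage_on("simulate"):
        t0 = time.perf_counter()
        world = synthetic.simulate_reference_world(
            config.n_taxa, config.seqs_per_taxon, config.seq_length,
            seed=config.seed,
        )
        effect = synthetic.EffectConfig.default(
            world.species, interaction_strength=config.interaction_strength
        )
        effect.depth_mean = config.depth_mean
        meta, counts = synthetic.simulate_cohort(
            config.n_samples, config.frac_bv, config.race_mix, effect,
            seed=config.seed + 1,
        )
        placements = synthetic.simulate_placements(
            counts, world, config.placement_spread, seed=config.seed + 2
        )
        artifacts.update(world=world, effect=effect, meta=meta,
                         counts=counts, placements=placements)
        meta.to_csv(os.path.join(out, "sample_meta.csv"), index=False)
        counts.to_csv(os.path.join(out, "true_counts.csv"))
        timers["simulate"] = time.perf_counter() - t0
        log.info("simulate: %d samples, %d taxa (%.2fs)",
                 config.n_samples, config.n_taxa, timers["simulate"])

    if stage_on("fastq_qc"):
        t0 = time.perf_counter()
        world = _need(artifacts, "world", "fastq_qc")
        counts: CountMatrix = _need(artifacts, "counts", "fastq_qc")
        sub_samples = counts.samples[: config.fastq_samples]
        sub = CountMatrix(counts.counts.loc[sub_samples])
        barcodes = synthetic.make_barcodes(sub_samples, seed=config.seed + 3)
        fq = os.path.join(out, "run.fastq")
        logp = os.path.join(out, "injection_log.json")
        synthetic.write_fastq_run(
            sub, world, barcodes, fq, seed=config.seed + 4,
            frac_bad_barcode=config.frac_bad_barcode,
            frac_short=config.frac_short,
            frac_low_quality=config.frac_low_quality,
            log_path=logp,
        )
        per_sample, report = read_qc.run_qc_on_fastq(
            fq, barcodes, synthetic.DEFAULT_PRIMER,
            min_len=config.min_len, min_avg_qual=config.min_avg_qual,
            window=config.clip_window, q_threshold=config.clip_q_threshold,
            min_frac=config.clip_min_frac,
        )
        report.to_json(os.path.join(out, "qc_report.json"))
        artifacts.update(qc_reads=per_sample, qc_report=report)
        timers["fastq_qc"] = time.perf_counter() - t0
        log.info("fastq_qc: %d/%d reads retained (%.2fs)",
                 report.retained, report.input_reads, timers["fastq_qc"])

    if stage_on("refpkg"):
        t0 = time.perf_counter()
        world = _need(artifacts, "world", "refpkg")
        pkg = refpkg.build_reference_package(
            world.sequences, world.leaf_taxids, world.taxonomy,
            tree=world.tree, cutoff=config.mislabel_cutoff,
            n_representatives=max(config.n_representatives, config.seqs_per_taxon),
        )
        pkg.write(os.path.join(out, "refpkg"))
        artifacts["refpkg"] = pkg
        timers["refpkg"] = time.perf_counter() - t0
        log.info("refpkg: %d sequences retained (%.2fs)",
                 len(pkg.sequences), timers["refpkg"])

    if stage_on("classify"):
        t0 = time.perf_counter()
        world = _need(artifacts, "world", "classify")
        placements = _need(artifacts, "placements", "classify")
        labels = classify.label_edges(world.tree, world.taxonomy, world.leaf_taxids)
        classifications = []
        for sample in sorted(placements):
            for read in placements[sample]:
                classifications.append(classify.classify_read(
                    read, labels, world.taxonomy,
                    cutoff=config.classify_cutoff,
                    compound_threshold=config.compound_threshold,
                ))
        table = classify.classification_table(classifications)
        table.to_csv(os.path.join(out, "classifications.csv"), index=False)
        # classified count matrix at species rank
        species = table[table["rank"] == world.taxonomy.species_rank]
        pivot = (
            species.groupby(["sample", "taxid"]).size().unstack(fill_value=0)
        )
        pivot.index.name = "sample_id"
        artifacts["classified_counts"] = pivot
        artifacts["edge_labels"] = labels
        artifacts["classifications"] = classifications
        all_reads = [r for s in sorted(placements) for r in placements[s]]
        classify.write_jplace(all_reads, world.tree,
                              os.path.join(out, "placements.jplace"))
        timers["classify"] = time.perf_counter() - t0
        log.info("classify: %d reads, %.1f%% to species (%.2fs)",
                 len(table), 100.0 * len(species) / max(len(table), 1),
                 timers["classify"])

    if stage_on("massmath"):
        t0 = time.perf_counter()
        world = _need(artifacts, "world", "massmath")
        placements = _need(artifacts, "placements", "massmath")
        maps = [
            massmath.mass_map_from_placements(reads, world.tree, sample_id=s)
            for s, reads in sorted(placements.items())
        ]
        dmat = massmath.kr_distance_matrix(maps, world.tree)
        dmat.to_csv(os.path.join(out, "kr_distances.csv"))
        if config.n_boot > 0:
            ctree = massmath.squash_bootstrap(
                placements, world.tree, n_boot=config.n_boot,
                seed=config.seed + 5,
            )
        else:
            ctree = massmath.squash_cluster(maps, world.tree)
        with open(os.path.join(out, "squash_tree.nwk"), "w") as fh:
            fh.write(ctree.to_newick() + "\n")
        # islands among reads of one order, as for the Clostridiales
        labels = artifacts.get("edge_labels")
        if labels is not None:
            tax = world.taxonomy
            order_taxid = f"o__{config.island_order}"
            island_reads = []
            read_labels = {}
            for c in artifacts.get("classifications", []):
                if c.taxid in tax and order_taxid in tax and tax.is_descendant(
                    c.taxid, order_taxid
                ):
                    read_labels[c.read_id] = tax.name(c.taxid)
            by_id = {r.read_id: r for s in placements for r in placements[s]}
            island_reads = [by_id[rid] for rid in read_labels if rid in by_id]
            island_reads = island_reads[:400]  # desk-scale cap
            islands = massmath.island_cluster(
                island_reads, world.tree, cutoff=config.island_cutoff,
                min_subjects=config.island_min_subjects, labels=read_labels,
            )
            massmath.islands_table(islands).to_csv(
                os.path.join(out, "islands.csv"), index=False
            )
            artifacts["islands"] = islands
        artifacts.update(mass_maps=maps, kr_matrix=dmat, squash_tree=ctree)
        timers["massmath"] = time.perf_counter() - t0
        log.info("massmath: %d samples clustered (%.2fs)", len(maps),
                 timers["massmath"])

    if stage_on("edgepca"):
        t0 = time.perf_counter()
        world = _need(artifacts, "world", "edgepca")
        maps = _need(artifacts, "mass_maps", "edgepca")
        emat = edgepca.edge_mass_matrix(maps, world.tree)
        result = edgepca.edge_pca(emat, n_components=2)
        result.scores.to_csv(os.path.join(out, "edgepca_scores.csv"))
        result.eigenvectors.to_csv(os.path.join(out, "edgepca_loadings.csv"))
        with open(os.path.join(out, "edgepca_pc1_tree.nwk"), "w") as fh:
            fh.write(edgepca.project_component_on_tree(
                result.eigenvectors["PC1"], world.tree) + "\n")
        artifacts["edgepca"] = result
        timers["edgepca"] = time.perf_counter() - t0
        log.info("edgepca: PC1 %.1f%% of variance (%.2fs)",
                 100 * result.variance_fraction[0], timers["edgepca"])

    if stage_on("ecology"):
        t0 = time.perf_counter()
        counts = _need(artifacts, "counts", "ecology")
        meta = _need(artifacts, "meta", "ecology")
        div = ecology.diversity_table(counts)
        div.to_csv(os.path.join(out, "diversity.csv"))
        trimmed, trim_report = ecology.trim_taxa(counts, config.trim_top_frac)
        cooc = ecology.cooccurrence(trimmed)
        cooc.correlations.to_csv(os.path.join(out, "cooccurrence.csv"))
        with open(os.path.join(out, "cooccurrence_dendrogram.nwk"), "w") as fh:
            fh.write(cooc.dendrogram_newick() + "\n")
        summaries = ecology.community_summaries(counts, meta)
        summaries["per_taxon"].to_csv(os.path.join(out, "community_per_taxon.csv"),
                                      index=False)
        summaries["dominance"].to_csv(os.path.join(out, "community_dominance.csv"))
        with open(os.path.join(out, "trim_report.json"), "w") as fh:
            json.dump(trim_report, fh, indent=1)
        artifacts.update(diversity=div, cooccurrence=cooc, summaries=summaries)
        timers["ecology"] = time.perf_counter() - t0
        log.info("ecology: %d taxa trimmed to %d (%.2fs)",
                 trim_report["taxa_before"], trim_report["taxa_after"],
                 timers["ecology"])

    if stage_on("assoc"):
        t0 = time.perf_counter()
        counts = _need(artifacts, "counts", "assoc")
        meta = _need(artifacts, "meta", "assoc")
        lrt = assoc.interaction_lrt(counts, meta,
                                    min_nonzero=config.lrt_min_nonzero)
        lrt.to_csv(os.path.join(out, "race_bv_lrt.csv"), index=False)
        fits, member = assoc.sign_association_table(
            counts, meta, alpha=config.enet_alpha,
            k_folds=config.enet_folds, seed=config.seed + 6,
        )
        member.rename_axis("taxon").to_csv(os.path.join(out, "sign_models.csv"))
        artifacts.update(lrt=lrt, sign_fits=fits, sign_membership=member)
        timers["assoc"] = time.perf_counter() - t0
        log.info("assoc: %d taxa tested (%.2fs)",
                 int((lrt["reason"] == "").sum()), timers["assoc"])

    manifest = {
        "package": "vaginome",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_run": [s for s in STAGES if config.stages.get(s)],
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(os.path.join(out, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return out
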