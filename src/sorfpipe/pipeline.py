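"""End-to-end conserved-sORF discovery over a directory of genome bundles.

Stage order: region partition -> annotation screen -> six-frame scan ->
coding-potential filter -> predictor consensus -> pooling -> homology
screen -> exact dedup -> 70%-identity clustering -> conservation call ->
per-cluster NJ/JTT bootstrap trees.  Every filter logs its in/out counts
and the machine-readable run report mirrors those counts per species.

Default parameters are the study parameters: 80-codon cap, coding
probability threshold 0.5, consensus on exact intervals, homology filter
at 2/3 query coverage and 30% identity, clustering at 70% identity,
conservation at >= 2 species, 1000 bootstrap replicates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio.Seq import Seq

from . import clustering, coding_potential, consensus_screen, genome_io, homology
from . import orf_scanner, phylo

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """In-memory outcome of a pipeline run (the JSON report is also on disk)."""

    report: dict
    pooled: list
    clusters: list


@dataclass
class PipelineConfig:
    max_codons: int = 80
    min_codons: int = 10
    coding_threshold: float = 0.5
    consensus_mode: str = "exact_interval"
    min_coverage: float = 2.0 / 3.0
    min_identity: float = 0.30
    filter_mode: str = homology.AND_RETAIN
    cluster_identity: float = 0.70
    min_species: int = 2
    bootstrap_reps: int = 1000
    seed: int | None = None
    output_dir: str = "sorfpipe_out"
    scan_regions: tuple[str, ...] = ("intergenic", "intronic")

    def __post_init__(self) -> None:
        if not 1 <= self.min_codons <= self.max_codons:
            raise ValueError("require 1 <= min_codons <= max_codons")
        for name in ("coding_threshold", "min_coverage", "min_identity",
                     "cluster_identity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_species < 1 or self.bootstrap_reps < 0:
            raise ValueError("min_species >= 1 and bootstrap_reps >= 0 required")
        if self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("seed required when bootstrap_reps > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "scan_regions" in data:
            data["scan_regions"] = tuple(data["scan_regions"])
        return cls(**data)


def discover_bundles(genome_dir: str | Path) -> list[genome_io.GenomeBundle]:
    """Load every <species>.fasta + <species>.gff pair in the directory.

    A FASTA without its GFF is skipped with an error log entry."""
    genome_dir = Path(genome_dir)
    bundles = []
    fastas = sorted(list(genome_dir.glob("*.fasta")) + list(genome_dir.glob("*.fa")))
    for fasta in fastas:
        species = fasta.stem
        gff = None
        for suffix in (".gff", ".gff3"):
            candidate = fasta.with_name(species + suffix)
            if candidate.exists():
                gff = candidate
                break
        if gff is None:
            logger.error("species %s: FASTA without GFF annotation; skipped", species)
            continue
        bundles.append(genome_io.load_bundle(fasta, gff, species))
    return bundles


def _annotated_proteins(bundle: genome_io.GenomeBundle,
                        ) -> tuple[dict[str, str], dict[str, str], list[str]]:
    """(protein db, function table, coding nt corpus) from the annotation."""
    by_parent: dict[str, list[genome_io.Feature]] = {}
    gene_products: dict[str, str] = {}
    parent_gene: dict[str, str] = {}
    for f in bundle.features:
        if f.ftype == "CDS" and f.parent_id is not None:
            by_parent.setdefault(f.parent_id, []).append(f)
        elif f.ftype == "gene":
            gene_products[f.feature_id] = f.attrs.get("product", "")
        elif f.ftype == "mRNA" and f.parent_id is not None:
            parent_gene[f.feature_id] = f.parent_id

    proteins: dict[str, str] = {}
    functions: dict[str, str] = {}
    coding_nt: list[str] = []
    for parent_id in sorted(by_parent):
        nt, _, _ = consensus_screen._spliced_cds(bundle, by_parent[parent_id])
        if len(nt) % 3 != 0:
            continue
        aa = str(Seq(nt).translate()).rstrip("*")
        if not aa or "*" in aa:
            continue
        subject_id = f"{bundle.species_id}|{parent_id}"
        proteins[subject_id] = aa
        coding_nt.append(nt)
        product = gene_products.get(parent_gene.get(parent_id, ""), "")
        functions[subject_id] = ("hypothetical" if (not product or
                                 "hypothetical" in product.lower())
                                 else "known_function")
    return proteins, functions, coding_nt


def run_pipeline(genome_dir: str | Path, config: PipelineConfig) -> RunResult:
    """Execute the full workflow; returns the report plus in-memory objects."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundles = discover_bundles(genome_dir)
    if not bundles:
        raise ValueError(f"no usable genome bundles in {genome_dir}")

    # output_dir is omitted so reports from different directories compare equal
    report: dict = {"parameters": {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in asdict(config).items()
                                   if k != "output_dir"},
                    "species": {}, "totals": {}}
    annotation_records: list[consensus_screen.SorfRecord] = []
    ab_initio_records: list[consensus_screen.SorfRecord] = []
    protein_db: dict[str, str] = {}
    function_table: dict[str, str] = {}

    for bundle in bundles:
        regions = genome_io.partition_regions(bundle)
        genome_io.write_regions_bed(regions, outdir / f"regions_{bundle.species_id}.bed")
        scan_regions = [r for r in regions if r.label in config.scan_regions]
        extracted = genome_io.extract_region_sequences(bundle, scan_regions)

        ann = consensus_screen.screen_annotated_sorfs(bundle, config.max_codons)
        annotation_records.extend(ann)

        scanner_set = orf_scanner.scan_regions(
            bundle, extracted, config.min_codons, config.max_codons)

        proteins, functions, coding_nt = _annotated_proteins(bundle)
        protein_db.update(proteins)
        function_table.update(functions)

        noncoding_nt = [fwd for region, fwd, _ in extracted
                        if region.label == "intergenic" and len(fwd) >= 6]
        coding_set: list[orf_scanner.OrfCandidate] = []
        probabilities: dict = {}
        if coding_nt and noncoding_nt:
            model = coding_potential.train(coding_nt, noncoding_nt)
            coding_potential.save_model(
                model, outdir / f"hexamer_{bundle.species_id}.tsv")
            coding_set, probabilities = coding_potential.filter_by_probability(
                scanner_set, model, config.coding_threshold, config.max_codons)
        else:
            logger.error("species %s: empty training corpus, coding filter skipped",
                         bundle.species_id)

        cons = consensus_screen.consensus(scanner_set, coding_set,
                                          config.consensus_mode, probabilities)
        ab_initio_records.extend(cons)

        region_counts = {label: sum(1 for r in regions if r.label == label)
                         for label in genome_io.REGION_LABELS}
        report["species"][bundle.species_id] = {
            "intergenic_regions": region_counts["intergenic"],
            "intronic_regions": region_counts["intronic"],
            "exonic_regions": region_counts["exonic"],
            "annotated_orfs": len(proteins),
            "annotated_sorfs": len(ann),
            "scanner_orfs": len(scanner_set),
            "coding_filtered_orfs": len(coding_set),
            "consensus_orfs": len(cons),
        }
        logger.info("species %s: %d scanned -> %d coding -> %d consensus; "
                    "%d annotated sORFs", bundle.species_id, len(scanner_set),
                    len(coding_set), len(cons), len(ann))

    pooled = consensus_screen.pool(annotation_records, ab_initio_records)

    hits = homology.search({r.rid: r.aa_seq for r in pooled}, protein_db)
    retained_hits = homology.filter_hits(hits, config.min_coverage,
                                         config.min_identity, config.filter_mode)
    homology.assign_homology_status(pooled, retained_hits, function_table)

    genomes = {b.species_id: b for b in bundles}
    for rec in pooled:
        genome_seq = genomes[rec.species_id].sequences[rec.seq_id]
        cand = orf_scanner.OrfCandidate(
            species_id=rec.species_id, seq_id=rec.seq_id,
            region_label=rec.region_label, strand=rec.strand, frame=rec.frame,
            start=rec.start, end=rec.end, nt_seq=rec.nt_seq, aa_seq=rec.aa_seq)
        rec.kozak = orf_scanner.kozak_flag(genome_seq, cand)

    unique, n_dup = clustering.dedup_identical(pooled)
    clusters = clustering.greedy_cluster(unique, config.cluster_identity)
    clustering.call_conserved(clusters, config.min_species)
    conserved = [c for c in clusters if c.conserved]
    per_cluster_species, breadth_bins = clustering.conservation_breadth(
        clusters, len(bundles))

    consensus_screen.write_records_tsv(pooled, outdir / "sorfs.tsv")
    consensus_screen.write_pooled_fasta(pooled, outdir / "pooled.faa")
    clustering.write_clusters_tsv(clusters, outdir / "clusters.tsv")
    clustering.write_cluster_fastas(conserved, outdir / "clusters_fasta")

    tree_dir = outdir / "trees"
    tree_dir.mkdir(exist_ok=True)
    n_trees = 0
    for idx, cluster in enumerate(conserved):
        members = cluster.members
        if len(members) < 3:
            continue
        labels = [m.rid for m in members]
        taxa, rows = phylo.stack_alignment(labels, [m.aa_seq for m in members])
        seed = None if config.bootstrap_reps == 0 else (config.seed + idx) % (2 ** 31)
        tree = phylo.bootstrap_support(taxa, rows, n_reps=config.bootstrap_reps,
                                       seed=seed)
        phylo.write_newick(tree, tree_dir / f"{cluster.cluster_id}.nwk")
        n_trees += 1

    report["totals"] = {
        "annotation_sorfs": len(annotation_records),
        "ab_initio_sorfs": len(ab_initio_records),
        "pooled_sorfs": len(pooled),
        "homology_hits_retained": len(retained_hits),
        "known_function": sum(r.homology_status == "known_function" for r in pooled),
        "hypothetical": sum(r.homology_status == "hypothetical" for r in pooled),
        "duplicates_removed": n_dup,
        "unique_sorfs": len(unique),
        "clusters": len(clusters),
        "conserved_clusters": len(conserved),
        "conserved_sorfs": sum(len(c.members) for c in conserved),
        "breadth_histogram": breadth_bins,
        "species_per_conserved_cluster": per_cluster_species,
        "trees_written": n_trees,
    }
    logger.info("pooled %d -> unique %d -> %d clusters (%d conserved)",
                len(pooled), len(unique), len(clusters), len(conserved))

    with open(outdir / "report.json", "w") as out:
        json.dump(report, out, indent=2, sort_keys=True)
        out.write("\n")
    return RunResult(report=report, pooled=pooled, clusters=clusters)
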