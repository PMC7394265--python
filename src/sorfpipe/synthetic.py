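"""Synthetic multi-species genome bundles with planted conserved sORF families.

The generator emulates the pipeline's input structure — per-species genome
FASTA plus gene annotation — with full ground truth, so every stage and the
end-to-end run are testable without downloads:

* i.i.d. background DNA at a configurable GC content;
* annotated ordinary genes (multi-exon, > 80 codons) and a few annotated
  small-ORF genes, with CDS drawn from a biased codon-usage table so a
  hexamer model has signal to learn;
* hidden sORF families: an ancestral peptide per family is reverse-
  translated with the same codon bias, independently mutated per species
  with codon-aware, synonymous-biased (2:1) substitutions, and planted in
  intergenic or intronic space, never overlapping genes or each other.

Each planted copy is a complete ATG..stop ORF of at most 80 codons; the
codon immediately 5' of the start is forced to a stop so the copy's own
start is the most-5' in-frame ATG and a longest-per-stop scanner recovers
the planted interval exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq as _Seq

from .genome_io import Feature, GenomeBundle, revcomp, write_gff
from .orf_scanner import STOP_CODONS, translate_orf

CODON_TABLE: dict[str, list[str]] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _codon = _c1 + _c2 + _c3
            if _codon in STOP_CODONS:
                continue
            CODON_TABLE.setdefault(str(_Seq(_codon).translate()), []).append(_codon)

AA_ALPHABET = "".join(sorted(CODON_TABLE))  # 20 letters, no stop


@dataclass
class PlantSpec:
    """Study conditions for one synthetic multi-species dataset."""

    n_species: int = 3
    genome_length: int = 200_000
    n_ordinary_genes: int = 25
    n_annotated_sorfs: int = 3
    n_sorf_families: int = 10
    family_size_range: tuple[int, int] = (3, 5)  # species carrying a copy
    sorf_length_range: tuple[int, int] = (11, 80)  # codons
    substitution_rate: float = 0.05  # per nucleotide site, per copy
    region_mix: dict[str, float] = field(
        default_factory=lambda: {"intergenic": 0.7, "intronic": 0.3})
    gc_content: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 0.3:
            raise ValueError("substitution rate must lie in [0, 0.3]")
        lo, hi = self.sorf_length_range
        if not 1 <= lo <= hi <= 80:
            raise ValueError("sORF lengths must lie within [1, 80] codons")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise ValueError("region_mix must sum to 1")


TRUTH_COLUMNS = ["family_id", "species_id", "seq_id", "start", "end",
                 "strand", "region_label", "peptide"]


def _biased_codon_usage(rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities, strongly skewed to one preferred
    codon (Dirichlet-free, deterministic given the rng) so hexamer usage in
    coding sequence differs sharply from i.i.d. background."""
    usage = {}
    for aa, codons in CODON_TABLE.items():
        weights = np.full(len(codons), 1.0)
        weights[rng.integers(len(codons))] = 8.0  # preferred codon
        usage[aa] = weights / weights.sum()
    return usage


def _reverse_translate(peptide: str, usage: dict[str, np.ndarray],
                       rng: np.random.Generator) -> str:
    codons = []
    for aa in peptide:
        options = CODON_TABLE[aa]
        codons.append(options[rng.choice(len(options), p=usage[aa])])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _mutate_codons(nt: str, rate: float, usage: dict[str, np.ndarray],
                   rng: np.random.Generator) -> str:
    """Codon-aware substitution: each non-terminal codon mutates with
    probability 1-(1-rate)^3; 2:1 odds of a synonymous change versus a switch
    to a different amino acid.  The initial ATG and the stop are kept, and no
    internal stop can arise."""
    p_codon = 1.0 - (1.0 - rate) ** 3
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    for idx in range(1, len(codons) - 1):  # keep ATG and stop intact
        if rng.random() >= p_codon:
            continue
        aa = translate_orf(codons[idx] + "TAA")
        if rng.random() < 2.0 / 3.0:
            options = [c for c in CODON_TABLE[aa] if c != codons[idx]]
            if not options:
                continue  # e.g. single-codon amino acids (M, W)
            codons[idx] = options[rng.integers(len(options))]
        else:
            new_aa = AA_ALPHABET[rng.integers(20)]
            while new_aa == aa:
                new_aa = AA_ALPHABET[rng.integers(20)]
            options = CODON_TABLE[new_aa]
            codons[idx] = options[rng.choice(len(options), p=usage[new_aa])]
    return "".join(codons)


class _Layout:
    """Non-overlapping placement bookkeeping for one species' chromosome."""

    def __init__(self, length: int, margin: int = 20):
        self.length = length
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, span: int, rng: np.random.Generator,
                within: tuple[int, int] | None = None,
                attempts: int = 200) -> int | None:
        lo, hi = within if within else (self.margin, self.length - self.margin)
        if hi - lo < span:
            return None
        for _ in range(attempts):
            start = int(rng.integers(lo, hi - span + 1))
            stop = start + span
            if all(stop + self.margin <= s or start >= e + self.margin
                   for s, e in self.occupied):
                self.occupied.append((start, stop))
                return start
        return None


def _make_gene(rng: np.random.Generator, usage: dict[str, np.ndarray],
               n_codons: int, n_exons: int) -> tuple[str, list[int]]:
    """A gene's nucleotide parts: returns (cds_nt incl stop, exon cds lengths)."""
    peptide = "M" + "".join(AA_ALPHABET[i] for i in
                            rng.integers(0, 20, size=n_codons - 1))
    cds = _reverse_translate(peptide, usage, rng) + "TAA"
    if n_exons == 1:
        return cds, [len(cds)]
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 3, 3), size=n_exons - 1,
                             replace=False))
    lengths, prev = [], 0
    for cut in list(cuts) + [len(cds)]:
        lengths.append(int(cut) - prev)
        prev = int(cut)
    return cds, lengths


def generate(spec: PlantSpec) -> tuple[list[GenomeBundle], pd.DataFrame]:
    """Build the species bundles and the ground-truth table, deterministically."""
    rng = np.random.default_rng(spec.seed)
    usage = _biased_codon_usage(rng)

    # family ancestors (shared across species)
    lo, hi = spec.sorf_length_range
    size_lo, size_hi = spec.family_size_range
    families = []
    for fam in range(spec.n_sorf_families):
        n_codons = int(rng.integers(lo, hi + 1))
        peptide = "M" + "".join(AA_ALPHABET[i] for i in
                                rng.integers(0, 20, size=n_codons - 1))
        ancestor_nt = "ATG" + _reverse_translate(peptide[1:], usage, rng) + "TAA"
        hi_eff = min(size_hi, spec.n_species)
        lo_eff = min(size_lo, hi_eff)
        size = int(rng.integers(lo_eff, hi_eff + 1))
        carriers = sorted(rng.choice(spec.n_species, size=size, replace=False))
        families.append((f"family_{fam}", ancestor_nt, carriers))

    region_labels = sorted(spec.region_mix)
    region_probs = np.array([spec.region_mix[k] for k in region_labels])

    bundles: list[GenomeBundle] = []
    truth_rows: list[dict] = []
    for sp in range(spec.n_species):
        species_id = f"sp{sp}"
        seq_id = f"{species_id}_chr1"
        genome = list(_random_dna(rng, spec.genome_length, spec.gc_content))
        layout = _Layout(spec.genome_length)
        features: list[Feature] = []
        introns: list[tuple[int, int]] = []  # plantable intron intervals

        def add_gene(gene_idx: int, n_codons: int, n_exons: int,
                     product: str) -> None:
            cds, exon_lengths = _make_gene(rng, usage, n_codons, n_exons)
            intron_lengths = [int(rng.integers(250, 600))
                              for _ in range(n_exons - 1)]
            span = sum(exon_lengths) + sum(intron_lengths)
            start = layout.reserve(span, rng)
            if start is None:
                raise ValueError("infeasible packing: genome too small for "
                                 "the requested gene content")
            strand = "+" if rng.random() < 0.5 else "-"
            placed = cds if strand == "+" else revcomp(cds)
            exon_iv: list[tuple[int, int]] = []
            pos = start
            # exon lengths along the genome follow transcription order on '+',
            # reverse order on '-' (sequence content is revcomp'd as a block)
            glengths = exon_lengths if strand == "+" else exon_lengths[::-1]
            offset = 0
            for i, elen in enumerate(glengths):
                exon_iv.append((pos, pos + elen))
                genome[pos:pos + elen] = list(placed[offset:offset + elen])
                offset += elen
                pos += elen
                if i < len(intron_lengths):
                    introns.append((pos, pos + intron_lengths[i]))
                    pos += intron_lengths[i]
            gid = f"{species_id}_g{gene_idx}"
            mid = f"{species_id}_m{gene_idx}"
            end = exon_iv[-1][1]
            features.append(Feature(seq_id, start, end, strand, "gene", gid,
                                    attrs={"product": product}))
            features.append(Feature(seq_id, start, end, strand, "mRNA", mid,
                                    parent_id=gid))
            for k, (es, ee) in enumerate(exon_iv):
                features.append(Feature(seq_id, es, ee, strand, "exon",
                                        f"{mid}_e{k}", parent_id=mid))
                features.append(Feature(seq_id, es, ee, strand, "CDS",
                                        f"{mid}_c{k}", parent_id=mid))

        gene_idx = 0
        for _ in range(spec.n_ordinary_genes):
            n_codons = int(rng.integers(100, 301))
            n_exons = int(rng.integers(2, 4))
            known = rng.random() < 0.5
            product = (f"kinase-like protein {gene_idx}" if known
                       else "hypothetical protein")
            add_gene(gene_idx, n_codons, n_exons, product)
            gene_idx += 1
        for _ in range(spec.n_annotated_sorfs):
            n_codons = int(rng.integers(lo, hi + 1))
            add_gene(gene_idx, n_codons, 1, "hypothetical protein")
            gene_idx += 1

        # plant this species' family copies
        for family_id, ancestor_nt, carriers in families:
            if sp not in carriers:
                continue
            copy_nt = _mutate_codons(ancestor_nt, spec.substitution_rate,
                                     usage, rng)
            label = region_labels[rng.choice(len(region_labels), p=region_probs)]
            strand = "+" if rng.random() < 0.5 else "-"
            # a stop guard immediately 5' of the start keeps the planted ATG
            # the most-5' in-frame start for its stop
            if strand == "+":
                block = "TAA" + copy_nt
            else:
                block = revcomp(copy_nt) + revcomp("TAA")
            start = None
            if label == "intronic":
                # one planted copy per intron, away from the splice boundaries
                open_introns = [iv for iv in introns
                                if iv[1] - iv[0] >= len(block) + 12]
                if open_introns:
                    idx = int(rng.integers(len(open_introns)))
                    iv = open_introns[idx]
                    introns.remove(iv)
                    start = int(rng.integers(iv[0] + 6,
                                             iv[1] - 6 - len(block) + 1))
            if start is None:
                label = "intergenic"
                start = layout.reserve(len(block), rng)
            if start is None:
                raise ValueError("infeasible packing: no room for planted sORF")
            genome[start:start + len(block)] = list(block)
            orf_start = start + 3 if strand == "+" else start
            orf_end = orf_start + len(copy_nt)
            truth_rows.append({
                "family_id": family_id, "species_id": species_id,
                "seq_id": seq_id, "start": orf_start, "end": orf_end,
                "strand": strand, "region_label": label,
                "peptide": translate_orf(copy_nt)})

        features.sort(key=lambda f: (f.start, f.end, f.ftype))
        bundles.append(GenomeBundle(species_id=species_id,
                                    sequences={seq_id: "".join(genome)},
                                    features=features))

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["family_id", "species_id"]).reset_index(drop=True)
    return bundles, truth


def write_dataset(bundles: Sequence[GenomeBundle], truth: pd.DataFrame,
                  outdir: str | Path) -> None:
    """Emit <species>.fasta + <species>.gff per bundle plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for bundle in bundles:
        with open(outdir / f"{bundle.species_id}.fasta", "w") as out:
            for seq_id, seq in bundle.sequences.items():
                out.write(f">{seq_id}\n")
                for i in range(0, len(seq), 80):
                    out.write(seq[i:i + 80] + "\n")
        write_gff(bundle.features, outdir / f"{bundle.species_id}.gff")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def score_recovery(clusters, truth: pd.DataFrame,
                   ) -> tuple[float, float, int]:
    """(family_recall, copy_recall, false_cluster_count) against ground truth.

    A family counts as recovered iff some conserved cluster contains copies
    of it (matched by exact genomic interval) from >= 2 species and contains
    no copies of any other family.  false_cluster_count is the number of
    conserved clusters holding copies of more than one family.
    """
    interval_to_family = {
        (r.species_id, r.seq_id, r.strand, r.start, r.end): r.family_id
        for r in truth.itertuples()}
    families = sorted(truth["family_id"].unique())
    recovered: set[str] = set()
    matched_copies: set[tuple] = set()
    false_clusters = 0
    for cluster in clusters:
        if not cluster.conserved:
            continue
        fam_hits: dict[str, set[str]] = {}
        for member in cluster.members:
            fam = interval_to_family.get(member.interval_key)
            if fam is not None:
                fam_hits.setdefault(fam, set()).add(member.species_id)
                matched_copies.add(member.interval_key)
        if len(fam_hits) > 1:
            false_clusters += 1
            continue
        for fam, species in fam_hits.items():
            if len(species) >= 2:
                recovered.add(fam)
    family_recall = len(recovered) / len(families) if families else 1.0
    copy_recall = (len(matched_copies) / len(truth) if len(truth) else 1.0)
    return family_recall, copy_recall, false_clusters
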