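"""Genome input and region partitioning.

Reads per-species FASTA + GFF3 bundles and partitions every sequence into
exonic, intronic and intergenic intervals that tile the sequence exactly
(precedence at annotation conflicts: exonic > intronic > intergenic).
Region sequences are extracted on both strands so downstream ORF scanning
sees all six frames of every region.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the I/O boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils.iterators
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

KEPT_FEATURE_TYPES = ("gene", "mRNA", "exon", "CDS")

REGION_LABELS = ("intergenic", "intronic", "exonic")


@dataclass
class Feature:
    """One retained GFF3 feature in 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    ftype: str
    feature_id: str
    parent_id: str | None = None
    attrs: dict = field(default_factory=dict)


@dataclass
class RegionInterval:
    seq_id: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")


@dataclass
class GenomeBundle:
    """One species' sequences plus retained annotation features."""

    species_id: str
    sequences: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def validate(self) -> None:
        for f in self.features:
            if f.seq_id not in self.sequences:
                raise ValueError(f"feature {f.feature_id} on unknown sequence {f.seq_id}")
            if not (0 <= f.start < f.end <= len(self.sequences[f.seq_id])):
                raise ValueError(f"feature {f.feature_id} out of bounds: [{f.start},{f.end})")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into {seq_id: uppercase DNA}.

    The id is the first whitespace-delimited header token; sequences are
    uppercased and U folded to T.  Duplicate ids and empty records are
    hard errors.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
            seq = str(record.seq).upper().replace("U", "T")
            if not seq:
                raise ValueError(f"empty record {record.id!r} in {path}")
            sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return sequences


def read_gff(path: str | Path) -> list[Feature]:
    """Parse GFF3, keeping gene/mRNA/exon/CDS as 0-based half-open Features.

    Records with end < start are rejected with a warning, as are CDS rows
    with strand ".".  The Parent attribute (first value) becomes parent_id.
    """
    features: list[Feature] = []
    seen_ids: dict[str, int] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in KEPT_FEATURE_TYPES:
            continue
        start, end = feat.start - 1, feat.end  # GFF3 1-based inclusive -> half-open
        if end <= start:
            logger.warning("rejecting %s feature with end < start at %s:%s-%s",
                           feat.featuretype, feat.seqid, feat.start, feat.end)
            continue
        if feat.featuretype == "CDS" and feat.strand not in "+-":
            logger.warning("rejecting CDS with undefined strand at %s:%s-%s",
                           feat.seqid, feat.start, feat.end)
            continue
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        fid = attrs.get("ID")
        if fid is None:  # synthesize a stable id for ID-less rows (common for CDS/exon)
            n = seen_ids.get(feat.featuretype, 0)
            seen_ids[feat.featuretype] = n + 1
            fid = f"{feat.featuretype}:{feat.seqid}:{start}-{end}:{n}"
        features.append(Feature(
            seq_id=feat.seqid, start=start, end=end,
            strand=feat.strand if feat.strand in "+-" else ".",
            ftype=feat.featuretype, feature_id=fid,
            parent_id=attrs.get("Parent"), attrs=attrs,
        ))
    return features


def write_gff(features: Iterable[Feature], path: str | Path) -> None:
    """Write Features back to GFF3 (inverse of read_gff for retained types)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attrs)
            attrs["ID"] = f.feature_id
            if f.parent_id is not None:
                attrs["Parent"] = f.parent_id
            col9 = ";".join(f"{k}={v}" for k, v in attrs.items())
            out.write("\t".join([
                f.seq_id, "sorfpipe", f.ftype, str(f.start + 1), str(f.end),
                ".", f.strand, ".", col9,
            ]) + "\n")


def load_bundle(fasta_path: str | Path, gff_path: str | Path, species_id: str) -> GenomeBundle:
    bundle = GenomeBundle(species_id=species_id,
                          sequences=read_fasta(fasta_path),
                          features=read_gff(gff_path))
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted non-overlapping list."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def subtract_intervals(base: list[tuple[int, int]],
                       minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference base \\ minus; both must be merged/sorted."""
    result: list[tuple[int, int]] = []
    j = 0
    for start, end in base:
        pos = start
        while j < len(minus) and minus[j][1] <= pos:
            j += 1
        k = j
        while k < len(minus) and minus[k][0] < end:
            ms, me = minus[k]
            if ms > pos:
                result.append((pos, ms))
            pos = max(pos, me)
            k += 1
        if pos < end:
            result.append((pos, end))
    return result


def complement_intervals(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    return subtract_intervals([(0, length)], merge_intervals(intervals))


def partition_regions(bundle: GenomeBundle) -> list[RegionInterval]:
    """Tile every sequence into exonic / intronic / intergenic intervals.

    exonic   = union of exon intervals (fallback to CDS when no exons);
    intronic = per-transcript gaps between consecutive exons, minus any
               exonic bases of other transcripts;
    intergenic = complement of gene spans (genes, else mRNAs, else CDS).
    Precedence at overlaps is exonic > intronic > intergenic, so the three
    label sets cover each position exactly once.
    """
    regions: list[RegionInterval] = []
    by_seq: dict[str, list[Feature]] = {}
    for f in bundle.features:
        by_seq.setdefault(f.seq_id, []).append(f)

    for seq_id, seq in bundle.sequences.items():
        length = len(seq)
        feats = by_seq.get(seq_id, [])

        exon_like = [f for f in feats if f.ftype == "exon"]
        if not exon_like:
            exon_like = [f for f in feats if f.ftype == "CDS"]
        exonic = merge_intervals([(f.start, f.end) for f in exon_like])

        # introns: gaps between consecutive exons sharing a parent transcript
        by_parent: dict[str, list[Feature]] = {}
        for f in exon_like:
            if f.parent_id is not None:
                by_parent.setdefault(f.parent_id, []).append(f)
        intron_raw: list[tuple[int, int]] = []
        for children in by_parent.values():
            children.sort(key=lambda f: f.start)
            for left, right in zip(children, children[1:]):
                if right.start > left.end:
                    intron_raw.append((left.end, right.start))
        intronic = subtract_intervals(merge_intervals(intron_raw), exonic)

        # gene spans for the intergenic complement
        for span_type in ("gene", "mRNA", "CDS"):
            span_feats = [f for f in feats if f.ftype == span_type]
            if span_feats:
                break
        gene_spans = merge_intervals([(f.start, f.end) for f in span_feats])
        genic = merge_intervals(gene_spans + exonic + intronic)
        intergenic = complement_intervals(genic, length)
        # bases inside gene spans but neither exonic nor intronic (e.g. UTR gaps)
        # fall to intronic so the tiling stays exact
        leftover = subtract_intervals(subtract_intervals(gene_spans, exonic), intronic)
        intronic = merge_intervals(intronic + leftover)

        for start, end in exonic:
            regions.append(RegionInterval(seq_id, start, end, "exonic"))
        for start, end in intronic:
            regions.append(RegionInterval(seq_id, start, end, "intronic"))
        for start, end in intergenic:
            regions.append(RegionInterval(seq_id, start, end, "intergenic"))

    regions.sort(key=lambda r: (r.seq_id, r.start, r.label))
    return regions


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_region_sequences(bundle: GenomeBundle,
                             regions: Iterable[RegionInterval],
                             ) -> list[tuple[RegionInterval, str, str]]:
    """Return (region, forward sequence, reverse-complement sequence) triples."""
    out = []
    for region in regions:
        fwd = bundle.sequences[region.seq_id][region.start:region.end]
        out.append((region, fwd, revcomp(fwd)))
    return out


def write_regions_bed(regions: Iterable[RegionInterval], path: str | Path) -> None:
    """BED6 of region intervals; strand column '.' (regions are strandless)."""
    with open(path, "w") as out:
        for i, r in enumerate(regions):
            out.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.label}_{i}\t0\t.\n")


def write_region_fasta(bundle: GenomeBundle,
                       extracted: Iterable[tuple[RegionInterval, str, str]],
                       path: str | Path) -> None:
    with open(path, "w") as out:
        for region, fwd, rev in extracted:
            stem = f"{bundle.species_id}|{region.seq_id}|{region.label}|{region.start}-{region.end}"
            out.write(f">{stem}|+\n{fwd}\n>{stem}|-\n{rev}\n")
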