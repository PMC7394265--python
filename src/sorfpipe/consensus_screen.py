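"""Annotation-derived sORFs, predictor consensus, and pooling.

Small ORFs enter the pipeline from two sources: (1) transcripts whose
annotated CDS translates to at most 80 residues, and (2) ab-initio
candidates reported by *both* independent predictors (the plain six-frame
scanner and the coding-potential-filtered scanner), intersected either on
identical intervals or on a shared stop codon.  Both sources are pooled,
de-duplicated on the genomic interval with the annotation copy winning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .genome_io import Feature, GenomeBundle, revcomp
from .orf_scanner import MAX_CODONS_DEFAULT, OrfCandidate

logger = logging.getLogger(__name__)

SOURCE_ANNOTATION = "annotation"
SOURCE_AB_INITIO = "ab_initio"

HOMOLOGY_STATUSES = ("known_function", "hypothetical", "none")


@dataclass
class SorfRecord:
    """A small ORF that survived screening, with provenance and flags."""

    species_id: str
    seq_id: str
    region_label: str
    strand: str
    frame: int
    start: int
    end: int
    nt_seq: str
    aa_seq: str
    source: str
    feature_id: str | None = None
    coding_probability: float | None = None
    homology_status: str = "none"
    kozak: str = "undetermined"
    attrs: dict = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return len(self.aa_seq)

    @property
    def interval_key(self) -> tuple[str, str, str, int, int]:
        return (self.species_id, self.seq_id, self.strand, self.start, self.end)

    @property
    def rid(self) -> str:
        """Stable identifier; 'gi' prefix for annotation, 'sf' for ab-initio."""
        if self.source == SOURCE_ANNOTATION:
            return f"{self.species_id}-gi_{self.feature_id}"
        return f"{self.species_id}-sf_{self.seq_id}:{self.start}-{self.end}({self.strand})"


def record_from_candidate(cand: OrfCandidate,
                          coding_probability: float | None = None) -> SorfRecord:
    return SorfRecord(
        species_id=cand.species_id, seq_id=cand.seq_id,
        region_label=cand.region_label, strand=cand.strand, frame=cand.frame,
        start=cand.start, end=cand.end, nt_seq=cand.nt_seq, aa_seq=cand.aa_seq,
        source=SOURCE_AB_INITIO, coding_probability=coding_probability)


def _spliced_cds(bundle: GenomeBundle, cds_parts: list[Feature]) -> tuple[str, int, int]:
    parts = sorted(cds_parts, key=lambda f: f.start)
    seq = "".join(bundle.sequences[f.seq_id][f.start:f.end] for f in parts)
    strand = parts[0].strand
    if strand == "-":
        seq = revcomp(seq)
    return seq, parts[0].start, parts[-1].end


def screen_annotated_sorfs(bundle: GenomeBundle,
                           max_codons: int = MAX_CODONS_DEFAULT) -> list[SorfRecord]:
    """Annotation-derived sORFs: transcripts whose CDS is <= max_codons residues.

    Multi-part CDS lengths are summed over the transcript.  A summed CDS
    length not divisible by 3 gets a frame warning and is skipped.  The
    stop codon, when annotated, does not count toward the residue length.
    """
    by_parent: dict[str, list[Feature]] = {}
    for f in bundle.features:
        if f.ftype == "CDS" and f.parent_id is not None:
            by_parent.setdefault(f.parent_id, []).append(f)

    records: list[SorfRecord] = []
    for parent_id in sorted(by_parent):
        parts = by_parent[parent_id]
        total = sum(f.end - f.start for f in parts)
        if total % 3 != 0:
            logger.warning("transcript %s: CDS length %d not divisible by 3; skipped",
                           parent_id, total)
            continue
        nt, start, end = _spliced_cds(bundle, parts)
        aa = str(Seq(nt).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            logger.warning("transcript %s: internal stop in annotated CDS; skipped", parent_id)
            continue
        if len(aa) > max_codons:
            continue
        first = min(parts, key=lambda f: f.start)
        records.append(SorfRecord(
            species_id=bundle.species_id, seq_id=first.seq_id,
            region_label="exonic", strand=first.strand, frame=0,
            start=start, end=end, nt_seq=nt, aa_seq=aa,
            source=SOURCE_ANNOTATION, feature_id=parent_id,
            attrs=dict(first.attrs)))
    records.sort(key=lambda r: (r.seq_id, r.start, r.end))
    return records


def _stop_key(cand: OrfCandidate) -> tuple[str, str, str, int]:
    # the stop codon's genomic anchor: right edge on '+', left edge on '-'
    anchor = cand.end if cand.strand == "+" else cand.start
    return (cand.species_id, cand.seq_id, cand.strand, anchor)


def consensus(scanner_set: Sequence[OrfCandidate],
              coding_set: Sequence[OrfCandidate],
              match_mode: str = "exact_interval",
              probabilities: dict | None = None) -> list[SorfRecord]:
    """Intersect the two predictors' candidate sets into ab-initio records.

    ``exact_interval`` requires identical (seq_id, strand, start, end) in both
    sets; ``shared_stop`` keys on the stop-codon coordinate and keeps the
    scanner's interval.  Coding probabilities (when supplied) are copied onto
    the surviving records.
    """
    probabilities = probabilities or {}
    if match_mode == "exact_interval":
        coding_keys = {c.interval_key for c in coding_set}
        kept = [c for c in scanner_set if c.interval_key in coding_keys]
    elif match_mode == "shared_stop":
        coding_keys = {_stop_key(c) for c in coding_set}
        kept, seen = [], set()
        for c in scanner_set:
            key = _stop_key(c)
            if key in coding_keys and key not in seen:
                seen.add(key)
                kept.append(c)
    else:
        raise ValueError(f"unknown match_mode {match_mode!r}")
    return [record_from_candidate(c, probabilities.get(c.interval_key)) for c in kept]


def pool(annotation_records: Sequence[SorfRecord],
         ab_initio_records: Sequence[SorfRecord]) -> list[SorfRecord]:
    """Combine both sources, de-duplicated on the genomic interval.

    On a duplicate interval the annotation record wins.  Output order is
    stable: (species, seq_id, start, end, strand).
    """
    chosen: dict = {}
    for rec in ab_initio_records:
        chosen[rec.interval_key] = rec
    for rec in annotation_records:
        chosen[rec.interval_key] = rec  # annotation precedence
    records = list(chosen.values())
    records.sort(key=lambda r: (r.species_id, r.seq_id, r.start, r.end, r.strand))
    return records


def write_records_tsv(records: Iterable[SorfRecord], path: str | Path) -> None:
    cols = ["id", "species", "seq_id", "region_label", "strand", "start", "end",
            "n_codons", "source", "coding_probability", "homology_status", "kozak"]
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for r in records:
            prob = "" if r.coding_probability is None else f"{r.coding_probability:.6f}"
            out.write("\t".join([
                r.rid, r.species_id, r.seq_id, r.region_label, r.strand,
                str(r.start), str(r.end), str(r.n_codons), r.source, prob,
                r.homology_status, r.kozak]) + "\n")


def write_pooled_fasta(records: Iterable[SorfRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in records:
            out.write(f">{r.rid}\n{r.aa_seq}\n")
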