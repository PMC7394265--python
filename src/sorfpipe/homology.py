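"""Protein-level homology screen for candidate sORFs.

Candidates are already translated, so the screen is a local protein-protein
alignment (BLOSUM62, affine gaps 11/1) of each query against a database of
annotated ORF proteins, followed by the coverage/identity hit filter: a hit
must align at least two thirds of the query at >= 30% identity (strict
AND_retain reading; the literal "removed only when both fail" reading is
available as OR_retain).  The best retained hit decides each query's
homology status via a subject function table.

An adapter parses external BLAST tabular output (outfmt 6) into the same
AlignmentHit shape for parity runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .consensus_screen import SorfRecord

MIN_COVERAGE_DEFAULT = 2.0 / 3.0
MIN_IDENTITY_DEFAULT = 0.30

AND_RETAIN = "AND_retain"
OR_RETAIN = "OR_retain"


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    query_aln_start: int  # 0-based half-open, in query residues
    query_aln_end: int
    identity_fraction: float  # identical columns / alignment columns (gaps count)
    score: float  # substitution-matrix units
    coverage: float  # aligned query span / query length
    no_hit: bool = False


def make_aligner(matrix: str = "BLOSUM62", gap_open: int = 11,
                 gap_extend: int = 1) -> PairwiseAligner:
    """Local aligner with BLAST-style affine costs (gap of length k costs open + k*extend)."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def local_align(query_aa: str, subject_aa: str, query_id: str = "query",
                subject_id: str = "subject",
                aligner: PairwiseAligner | None = None) -> AlignmentHit:
    """Optimal local alignment of two peptides as an AlignmentHit.

    Pairs without any positive-scoring window come back with score 0 and
    ``no_hit=True``.  Empty sequences are hard errors.
    """
    if not query_aa or not subject_aa:
        raise ValueError("empty peptide sequence")
    aligner = aligner or _DEFAULT_ALIGNER
    score = aligner.score(query_aa, subject_aa)
    if score <= 0:
        return AlignmentHit(query_id, subject_id, 0, 0, 0.0, 0.0, 0.0, no_hit=True)
    aln = aligner.align(query_aa, subject_aa)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    qstart = int(aln.coordinates[0][0])
    qend = int(aln.coordinates[0][-1])
    coverage = (qend - qstart) / len(query_aa)
    return AlignmentHit(query_id, subject_id, qstart, qend, identity,
                        float(score), coverage)


def filter_hits(hits: Sequence[AlignmentHit],
                min_coverage: float = MIN_COVERAGE_DEFAULT,
                min_identity: float = MIN_IDENTITY_DEFAULT,
                combine: str = AND_RETAIN) -> list[AlignmentHit]:
    """Apply the coverage/identity hit filter (boundaries inclusive).

    AND_retain keeps hits meeting both thresholds; OR_retain removes a hit
    only when it fails both.
    """
    if combine not in (AND_RETAIN, OR_RETAIN):
        raise ValueError(f"unknown combine mode {combine!r}")
    kept = []
    for h in hits:
        if h.no_hit:
            continue
        cov_ok = h.coverage >= min_coverage
        id_ok = h.identity_fraction >= min_identity
        if (cov_ok and id_ok) if combine == AND_RETAIN else (cov_ok or id_ok):
            kept.append(h)
    return kept


def search(queries: Mapping[str, str], subjects: Mapping[str, str],
           aligner: PairwiseAligner | None = None) -> list[AlignmentHit]:
    """All-vs-all local alignment of query peptides against subject peptides."""
    aligner = aligner or _DEFAULT_ALIGNER
    hits: list[AlignmentHit] = []
    for qid, qseq in queries.items():
        for sid, sseq in subjects.items():
            hit = local_align(qseq, sseq, qid, sid, aligner=aligner)
            if not hit.no_hit:
                hits.append(hit)
    return hits


def assign_homology_status(records: Sequence[SorfRecord],
                           hits: Sequence[AlignmentHit],
                           function_table: Mapping[str, str]) -> None:
    """Set each record's homology_status from its best retained hit (in place).

    The highest-scoring retained hit decides; a score tie between labels
    resolves to known_function.  Queries without retained hits stay 'none'.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        label = function_table.get(h.subject_id, "hypothetical")
        prev = best.get(h.query_id)
        if prev is None or h.score > prev.score:
            best[h.query_id] = h
        elif h.score == prev.score:
            prev_label = function_table.get(prev.subject_id, "hypothetical")
            if label == "known_function" and prev_label != "known_function":
                best[h.query_id] = h
    for rec in records:
        hit = best.get(rec.rid)
        if hit is None:
            rec.homology_status = "none"
        else:
            rec.homology_status = function_table.get(hit.subject_id, "hypothetical")


def parse_blast_tabular(path: str | Path,
                        query_lengths: Mapping[str, int]) -> list[AlignmentHit]:
    """Adapter: BLAST outfmt 6 (qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore) -> AlignmentHit list."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            pident, length = float(f[2]), int(f[3])
            qstart, qend = int(f[6]) - 1, int(f[7])  # 1-based inclusive -> half-open
            qlen = query_lengths[qid]
            hits.append(AlignmentHit(
                query_id=qid, subject_id=sid,
                query_aln_start=qstart, query_aln_end=qend,
                identity_fraction=pident / 100.0,
                score=float(f[11]), coverage=(qend - qstart) / qlen))
    return hits
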