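"""Greedy identity clustering and conservation calling.

Mirrors the CD-HIT scheme at desk scale: exact duplicates are removed
first, remaining records are sorted longest-first and each joins the first
existing cluster whose *representative* it matches at >= the identity
threshold (default 0.70, boundary inclusive), otherwise it founds a new
cluster.  Identity is identical columns of an optimal global alignment
divided by the shorter sequence's length (CD-HIT's convention).  A cluster
is called conserved when its members span at least two species.

Identity comes from a substitution-matrix-scored global alignment
(BLOSUM62, affine 11/1): gap placement is paid for, so a short peptide
cannot inflate its identity by scattering matches through a longer one the
way an unpenalised longest-common-subsequence alignment would.  The
residue multiset intersection bounds the identical columns of any
alignment from above and serves as a cheap prefilter in the clustering
loop.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .consensus_screen import SOURCE_ANNOTATION, SorfRecord


@dataclass
class SorfCluster:
    cluster_id: str
    representative: SorfRecord
    members: list[SorfRecord] = field(default_factory=list)
    identities: dict[str, float] = field(default_factory=dict)  # member rid -> id to rep
    conserved: bool = False

    @property
    def species_set(self) -> set[str]:
        return {m.species_id for m in self.members}


def dedup_identical(records: Sequence[SorfRecord]) -> tuple[list[SorfRecord], int]:
    """Collapse exact full-length duplicates (nucleotide sequence when present,
    else peptide).  Annotation-sourced survivors are preferred, then smallest id.
    Returns (unique records, number removed)."""
    groups: dict[str, list[SorfRecord]] = {}
    for rec in records:
        groups.setdefault(rec.nt_seq or rec.aa_seq, []).append(rec)
    unique: list[SorfRecord] = []
    removed = 0
    for seq in groups:
        group = groups[seq]
        group.sort(key=lambda r: (r.source != SOURCE_ANNOTATION, r.rid))
        unique.append(group[0])
        removed += len(group) - 1
    unique.sort(key=lambda r: (r.species_id, r.seq_id, r.start, r.end, r.strand))
    return unique, removed


def _make_global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_GLOBAL_ALIGNER = _make_global_aligner()


def pairwise_identity(a_aa: str, b_aa: str) -> float:
    """Identity = identical columns of the optimal global alignment / length
    of the shorter peptide (the CD-HIT denominator)."""
    if not a_aa or not b_aa:
        raise ValueError("empty peptide sequence")
    aln = _GLOBAL_ALIGNER.align(a_aa, b_aa)[0]
    return aln.counts().identities / min(len(a_aa), len(b_aa))


def _identity_at_least(a_aa: str, b_aa: str, threshold: float) -> float | None:
    """Identity if >= threshold else None, prefiltered by the multiset bound:
    no alignment can have more identical columns than the residue multiset
    intersection."""
    shorter = min(len(a_aa), len(b_aa))
    bound = sum((Counter(a_aa) & Counter(b_aa)).values())
    if bound < threshold * shorter:
        return None
    identity = pairwise_identity(a_aa, b_aa)
    return identity if identity >= threshold else None


_RESIDUE_INDEX = {aa: i for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWYXBZJUO*")}


def _residue_counts(aa_seq: str) -> np.ndarray:
    counts = np.zeros(len(_RESIDUE_INDEX), dtype=np.int32)
    for ch in aa_seq:
        counts[_RESIDUE_INDEX.get(ch, len(_RESIDUE_INDEX) - 1)] += 1
    return counts


def greedy_cluster(records: Sequence[SorfRecord],
                   threshold: float = 0.70) -> list[SorfCluster]:
    """Longest-first, first-fit clustering against cluster representatives.

    The canonical sort (length descending, then id ascending) makes the
    result independent of input order; representatives are the founding,
    i.e. longest, members.  The vectorised multiset bound rules out most
    representatives before any alignment is computed.
    """
    ordered = sorted(records, key=lambda r: (-len(r.aa_seq), r.rid))
    clusters: list[SorfCluster] = []
    rep_counts: list[np.ndarray] = []
    rep_lengths: list[int] = []
    for rec in ordered:
        counts = _residue_counts(rec.aa_seq)
        target = None
        if clusters:
            bounds = np.minimum(np.array(rep_counts), counts).sum(axis=1)
            shorter = np.minimum(np.array(rep_lengths), len(rec.aa_seq))
            for idx in np.nonzero(bounds >= threshold * shorter)[0]:
                identity = pairwise_identity(rec.aa_seq,
                                             clusters[idx].representative.aa_seq)
                if identity >= threshold:
                    target = (int(idx), identity)
                    break
        if target is not None:
            idx, identity = target
            clusters[idx].members.append(rec)
            clusters[idx].identities[rec.rid] = identity
        else:
            cluster = SorfCluster(cluster_id=f"cluster_{len(clusters)}",
                                  representative=rec, members=[rec],
                                  identities={rec.rid: 1.0})
            clusters.append(cluster)
            rep_counts.append(counts)
            rep_lengths.append(len(rec.aa_seq))
    return clusters


def call_conserved(clusters: Sequence[SorfCluster],
                   min_species: int = 2) -> list[SorfCluster]:
    """Flag clusters whose members span >= min_species distinct species.

    Singleton and single-species clusters are never conserved."""
    for cluster in clusters:
        cluster.conserved = len(cluster.species_set) >= min_species
    return list(clusters)


def conservation_breadth(clusters: Sequence[SorfCluster],
                         n_species_total: int) -> tuple[dict[str, int], dict[str, int]]:
    """Per-cluster species counts and a quarter-binned breadth histogram.

    Breadth = species in cluster / total species; histogram bins are
    (0,1/4], (1/4,1/2], (1/2,3/4], (3/4,1] over conserved clusters.
    """
    per_cluster = {c.cluster_id: len(c.species_set) for c in clusters if c.conserved}
    bins = {"<=1/4": 0, "<=1/2": 0, "<=3/4": 0, "<=1": 0}
    for count in per_cluster.values():
        breadth = count / n_species_total
        if breadth <= 0.25:
            bins["<=1/4"] += 1
        elif breadth <= 0.5:
            bins["<=1/2"] += 1
        elif breadth <= 0.75:
            bins["<=3/4"] += 1
        else:
            bins["<=1"] += 1
    return per_cluster, bins


def validate_clusters(clusters: Sequence[SorfCluster], threshold: float = 0.70) -> None:
    """Post-hoc contract check: every member >= threshold identity to its
    representative, and the clusters partition the records."""
    seen: set[str] = set()
    for cluster in clusters:
        for member in cluster.members:
            if member.rid in seen:
                raise AssertionError(f"{member.rid} appears in multiple clusters")
            seen.add(member.rid)
            identity = pairwise_identity(member.aa_seq, cluster.representative.aa_seq)
            if identity < threshold - 1e-12:
                raise AssertionError(
                    f"{member.rid} at identity {identity:.3f} < {threshold} "
                    f"to representative of {cluster.cluster_id}")


def write_clusters_tsv(clusters: Iterable[SorfCluster], path: str | Path) -> None:
    cols = ["cluster_id", "representative", "member", "species",
            "identity_to_rep", "conserved"]
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for c in clusters:
            for m in c.members:
                out.write("\t".join([
                    c.cluster_id, c.representative.rid, m.rid, m.species_id,
                    f"{c.identities[m.rid]:.4f}", str(int(c.conserved))]) + "\n")


def write_cluster_fastas(clusters: Iterable[SorfCluster], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in clusters:
        with open(outdir / f"{c.cluster_id}.faa", "w") as out:
            for m in c.members:
                out.write(f">{m.rid}\n{m.aa_seq}\n")
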