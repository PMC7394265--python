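"""Six-frame small-ORF detection with Kozak-context flagging.

Every reported ORF has both a start (ATG) and a stop codon and encodes at
most ``max_codons`` residues (default 80, i.e. the 240-nt small-ORF cap).
``scan_orfs`` works on a single strand of any sequence; the caller scans
the reverse complement for the other three frames and maps coordinates
back with ``map_to_genome``.

Two emission modes:

``longest_per_stop``
    one ORF per (frame, stop codon): the most-5' ATG whose length falls
    inside the [min_codons, max_codons] window — the one-gene-per-stop
    behaviour of conventional ORF callers.
``all_starts``
    every qualifying ATG, for sensitivity studies.

A codon containing N is neither start nor stop and closes the open frame,
so no ORF ever spans ambiguous sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .genome_io import GenomeBundle, RegionInterval, revcomp

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

MAX_CODONS_DEFAULT = 80


@dataclass
class OrfCandidate:
    """A predicted ORF; coordinates are 0-based half-open and include the stop."""

    species_id: str
    seq_id: str
    region_label: str  # intergenic | intronic | exonic | genome
    strand: str
    frame: int  # 0/1/2 on its own strand
    start: int
    end: int
    nt_seq: str
    aa_seq: str

    @property
    def n_codons(self) -> int:
        return len(self.aa_seq)

    @property
    def interval_key(self) -> tuple[str, str, str, int, int]:
        return (self.species_id, self.seq_id, self.strand, self.start, self.end)


def translate_orf(nt_seq: str) -> str:
    """Translate an ATG..stop nucleotide ORF, dropping the stop symbol."""
    return str(Seq(nt_seq[:-3]).translate())


def scan_orfs(seq: str,
              min_codons: int,
              max_codons: int = MAX_CODONS_DEFAULT,
              mode: str = "longest_per_stop",
              *,
              species_id: str = "",
              seq_id: str = "",
              region_label: str = "genome",
              strand: str = "+") -> list[OrfCandidate]:
    """Scan the three frames of one strand for ATG..stop ORFs.

    Returned coordinates are local to ``seq``.  Sequences shorter than the
    minimal ORF span yield an empty list.
    """
    if mode not in ("longest_per_stop", "all_starts"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (1 <= min_codons <= max_codons):
        raise ValueError("require max_codons >= min_codons >= 1")
    seq = seq.upper()
    n = len(seq)
    out: list[OrfCandidate] = []
    if n < 3 * (min_codons + 1):
        return out

    for frame in range(3):
        open_starts: list[int] = []  # ATG positions since last frame break
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if "N" in codon:  # ambiguous codon: no start, no stop, breaks the frame
                open_starts = []
                continue
            if codon in STOP_CODONS:
                stop_end = pos + 3
                chosen: list[int] = []
                for start in open_starts:  # most-5' first
                    n_codons = (pos - start) // 3
                    if n_codons > max_codons:
                        continue
                    if n_codons < min_codons:
                        break  # later starts are only shorter
                    chosen.append(start)
                    if mode == "longest_per_stop":
                        break
                for start in chosen:
                    nt = seq[start:stop_end]
                    out.append(OrfCandidate(
                        species_id=species_id, seq_id=seq_id,
                        region_label=region_label, strand=strand, frame=frame,
                        start=start, end=stop_end,
                        nt_seq=nt, aa_seq=translate_orf(nt)))
                open_starts = []
            elif codon == START_CODON:
                open_starts.append(pos)
    out.sort(key=lambda c: (c.start, c.end))
    return out


def map_to_genome(candidate: OrfCandidate, region: RegionInterval, strand: str) -> OrfCandidate:
    """Lift an ORF from region-local, strand-local coordinates to genomic ones.

    For '+' the region-local frame reads left to right; for '-' the local
    sequence was the region's reverse complement, so the interval mirrors:
    genomic start = region.end - local end.
    """
    length = region.end - region.start
    if not (0 <= candidate.start < candidate.end <= length):
        raise ValueError("candidate coordinates outside region")
    if strand == "+":
        start = region.start + candidate.start
        end = region.start + candidate.end
    elif strand == "-":
        start = region.end - candidate.end
        end = region.end - candidate.start
    else:
        raise ValueError(f"bad strand {strand!r}")
    return replace(candidate, seq_id=region.seq_id, region_label=region.label,
                   strand=strand, start=start, end=end)


def scan_regions(bundle: GenomeBundle,
                 extracted: Iterable[tuple[RegionInterval, str, str]],
                 min_codons: int,
                 max_codons: int = MAX_CODONS_DEFAULT,
                 mode: str = "longest_per_stop") -> list[OrfCandidate]:
    """Six-frame scan over extracted region sequences, in genomic coordinates."""
    candidates: list[OrfCandidate] = []
    for region, fwd, rev in extracted:
        for strand, local_seq in (("+", fwd), ("-", rev)):
            for cand in scan_orfs(local_seq, min_codons, max_codons, mode,
                                  species_id=bundle.species_id, seq_id=region.seq_id,
                                  region_label=region.label, strand=strand):
                candidates.append(map_to_genome(cand, region, strand))
    candidates.sort(key=lambda c: (c.seq_id, c.start, c.end, c.strand))
    return candidates


def kozak_flag(genome_seq: str, candidate: OrfCandidate) -> str:
    """Kozak-context call for the candidate's ATG: positive, negative, undetermined.

    Positive iff the base at -3 (relative to the A of ATG, strand-aware) is a
    purine and the base at +4 is G; undetermined when the context runs off the
    sequence.  This is a motif check, not a coding-potential-derived integrity
    score, and is labelled as such in all outputs.
    """
    if candidate.strand == "+":
        atg_start = candidate.start
        minus3, plus4 = atg_start - 3, atg_start + 3
        if minus3 < 0 or plus4 >= len(genome_seq):
            return "undetermined"
        up, down = genome_seq[minus3], genome_seq[plus4]
    else:
        # on '-', the ATG occupies [end-3, end); -3 is 3 bases past end, +4 is end-4
        minus3, plus4 = candidate.end + 2, candidate.end - 4
        if minus3 >= len(genome_seq) or plus4 < 0:
            return "undetermined"
        up = revcomp(genome_seq[minus3])
        down = revcomp(genome_seq[plus4])
    if up in "AG" and down == "G":
        return "positive"
    if up in "ACGT" and down in "ACGT":
        return "negative"
    return "undetermined"


def write_orf_fasta(candidates: Iterable[OrfCandidate], path: str | Path,
                    kind: str = "aa") -> None:
    with open(path, "w") as out:
        for c in candidates:
            header = f"{c.species_id}|{c.seq_id}|{c.region_label}|{c.start}-{c.end}|{c.strand}"
            out.write(f">{header}\n{c.aa_seq if kind == 'aa' else c.nt_seq}\n")


def write_orf_tsv(candidates: Iterable[OrfCandidate], path: str | Path,
                  kozak: dict | None = None) -> None:
    with open(path, "w") as out:
        out.write("species\tseq_id\tregion_label\tstrand\tstart\tend\tframe\tn_codons\tkozak\n")
        for c in candidates:
            kz = (kozak or {}).get(c.interval_key, "undetermined")
            out.write(f"{c.species_id}\t{c.seq_id}\t{c.region_label}\t{c.strand}\t"
                      f"{c.start}\t{c.end}\t{c.frame}\t{c.n_codons}\t{kz}\n")
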