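"""Hexamer log-odds coding-potential model.

A trainable discriminator standing in for a dedicated small-ORF coding
classifier: log-odds of each of the 4096 DNA 6-mers between a coding and a
noncoding training corpus, averaged over a sequence's overlapping hexamers
and mapped to a probability through a fitted 1-D logistic calibration.
Candidates are kept when probability >= threshold (default 0.5, boundary
inclusive) and they encode at most 80 residues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .orf_scanner import MAX_CODONS_DEFAULT, OrfCandidate

K = 6
N_KMERS = 4 ** K

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

TOO_SHORT = "too_short"
SCORED = "scored"


@dataclass
class HexamerModel:
    logodds: np.ndarray  # shape (4096,), finite
    pseudocount: float
    calibration: tuple[float, float]  # (a, b) of p = logistic(a * mean_logodds + b)

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        if self.logodds.shape != (N_KMERS,):
            raise ValueError("log-odds table must have 4096 entries")
        if not np.all(np.isfinite(self.logodds)):
            raise ValueError("non-finite log-odds; pseudocount must be > 0")


def _hexamer_codes(seq: str) -> list[int]:
    """Rolling base-4 codes of all overlapping 6-mers; 6-mers with N skipped."""
    seq = seq.upper()
    codes: list[int] = []
    code = 0
    valid = 0  # run length of valid bases ending here
    for ch in seq:
        b = _BASE_CODE.get(ch)
        if b is None:
            valid = 0
            code = 0
            continue
        code = ((code << 2) | b) & (N_KMERS - 1)
        valid += 1
        if valid >= K:
            codes.append(code)
    return codes


def _count_hexamers(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(N_KMERS, dtype=float)
    for seq in seqs:
        codes = _hexamer_codes(seq)
        if codes:
            counts += np.bincount(codes, minlength=N_KMERS)
    return counts


def mean_logodds(model_or_table: "HexamerModel | np.ndarray", nt_seq: str) -> float | None:
    """Mean log-odds over the sequence's hexamers; None when fewer than one."""
    table = model_or_table.logodds if isinstance(model_or_table, HexamerModel) else model_or_table
    codes = _hexamer_codes(nt_seq)
    if not codes:
        return None
    return float(np.mean(table[codes]))


def _fit_calibration(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    # Degenerate corpora (e.g. identical coding/noncoding sets) leave every
    # score equal; a=1, b=0 then maps everything to exactly 0.5.
    if np.ptp(scores) < 1e-12:
        return (1.0, 0.0)
    clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000,
                             class_weight="balanced")
    clf.fit(scores.reshape(-1, 1), labels)
    return (float(clf.coef_[0][0]), float(clf.intercept_[0]))


def _logodds_table(coding_seqs: Iterable[str], noncoding_seqs: Iterable[str],
                   pseudocount: float) -> np.ndarray:
    c_cod = _count_hexamers(coding_seqs)
    c_non = _count_hexamers(noncoding_seqs)
    if c_cod.sum() == 0 or c_non.sum() == 0:
        raise ValueError("each corpus must contain at least one countable hexamer")
    log_p_cod = np.log(c_cod + pseudocount) - math.log(c_cod.sum() + pseudocount * N_KMERS)
    log_p_non = np.log(c_non + pseudocount) - math.log(c_non.sum() + pseudocount * N_KMERS)
    return log_p_cod - log_p_non


CALIBRATION_WINDOW = 240  # nt; the small-ORF length scale


def _calibration_windows(seq: str) -> list[str]:
    chunks = [seq[i:i + CALIBRATION_WINDOW]
              for i in range(0, len(seq), CALIBRATION_WINDOW)]
    return [c for c in chunks if len(c) >= K]


def train(coding_seqs: Sequence[str], noncoding_seqs: Sequence[str],
          pseudocount: float = 1.0) -> HexamerModel:
    """Train hexamer log-odds on two corpora and fit the logistic calibration.

    Frequencies are counted over overlapping 6-mers (step 1); 6-mers containing
    N are skipped.  The calibration is cross-fitted so it reflects held-out
    behaviour: each corpus is split in two, each half is scored under the
    table trained on the opposite halves (in small-ORF-sized windows, so the
    score scale matches the sequences the model will judge), and the 1-D
    logistic fit runs on those out-of-sample scores.  Without held-out
    scoring the sparse 4096-entry table flatters its own training sequences
    and the fitted decision boundary rejects genuinely coding input.
    Empty corpora, or corpora without a countable hexamer, are hard errors.
    """
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both corpora must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logodds = _logodds_table(coding_seqs, noncoding_seqs, pseudocount)

    cod_a, cod_b = coding_seqs[0::2], coding_seqs[1::2]
    non_a, non_b = noncoding_seqs[0::2], noncoding_seqs[1::2]
    scores, labels = [], []
    if cod_a and cod_b and non_a and non_b:
        table_a = _logodds_table(cod_a, non_a, pseudocount)
        table_b = _logodds_table(cod_b, non_b, pseudocount)
        held_out = [(table_a, cod_b, 1), (table_a, non_b, 0),
                    (table_b, cod_a, 1), (table_b, non_a, 0)]
    else:  # corpus too small to split: fall back to in-sample calibration
        held_out = [(logodds, coding_seqs, 1), (logodds, noncoding_seqs, 0)]
    for table, corpus, label in held_out:
        for seq in corpus:
            for window in _calibration_windows(seq):
                s = mean_logodds(table, window)
                if s is not None:
                    scores.append(s)
                    labels.append(label)
    calibration = _fit_calibration(np.array(scores), np.array(labels))
    return HexamerModel(logodds=logodds, pseudocount=float(pseudocount),
                        calibration=calibration)


def score(model: HexamerModel, nt_seq: str) -> float:
    """Coding probability in [0,1]; sequences shorter than 6 score 0.5."""
    p, _ = score_with_flag(model, nt_seq)
    return p


def score_with_flag(model: HexamerModel, nt_seq: str) -> tuple[float, str]:
    s = mean_logodds(model, nt_seq)
    if s is None:
        return 0.5, TOO_SHORT
    a, b = model.calibration
    return 1.0 / (1.0 + math.exp(-(a * s + b))), SCORED


def filter_by_probability(candidates: Sequence[OrfCandidate], model: HexamerModel,
                          threshold: float = 0.5,
                          max_codons: int = MAX_CODONS_DEFAULT,
                          ) -> tuple[list[OrfCandidate], dict]:
    """Keep candidates with probability >= threshold and <= max_codons residues.

    Returns (retained candidates, {interval_key: probability} for all scored).
    """
    retained: list[OrfCandidate] = []
    probabilities: dict = {}
    for cand in candidates:
        p = score(model, cand.nt_seq)
        probabilities[cand.interval_key] = p
        if p >= threshold and cand.n_codons <= max_codons:
            retained.append(cand)
    return retained, probabilities


_KMER_ALPHA = "ACGT"


def _decode(code: int) -> str:
    chars = []
    for shift in range(K - 1, -1, -1):
        chars.append(_KMER_ALPHA[(code >> (2 * shift)) & 3])
    return "".join(chars)


def save_model(model: HexamerModel, path: str | Path) -> None:
    """TSV of (6-mer, log-odds) with a JSON header line for the scalars."""
    header = {"pseudocount": model.pseudocount,
              "calibration_a": model.calibration[0],
              "calibration_b": model.calibration[1]}
    with open(path, "w") as out:
        out.write("#" + json.dumps(header, sort_keys=True) + "\n")
        for code in range(N_KMERS):
            out.write(f"{_decode(code)}\t{model.logodds[code]:.10g}\n")


def load_model(path: str | Path) -> HexamerModel:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("#"))
        logodds = np.zeros(N_KMERS)
        for line in fh:
            kmer, value = line.rstrip("\n").split("\t")
            code = 0
            for ch in kmer:
                code = (code << 2) | _BASE_CODE[ch]
            logodds[code] = float(value)
    return HexamerModel(logodds=logodds, pseudocount=header["pseudocount"],
                        calibration=(header["calibration_a"], header["calibration_b"]))
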