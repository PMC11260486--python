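"""Terminal inverted repeat (TIR) detection on linear chromosomes.

A TIR is a duplicated, mutually reverse-complementary sequence capping both
ends of a linear chromosome.  Detection is framed as a self-alignment: the
chromosome S is locally aligned against its own reverse complement, keeping
only alignments whose query-side start lies within the first ``end_window``
bp of S and whose subject-side end lies within the last ``end_window`` bp of
S (the window absorbs end-polishing artifacts).  The implementation is
seed-and-extend: exact k-mer seeds anchored near both chromosome ends,
extended inward by banded affine-gap dynamic programming.

TIRs in real Streptomyces assemblies span <100 bp to ~3 Mb; the band keeps
the extension linear in repeat length, which full DP (quadratic in
chromosome length) could not afford.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .io import LinearChromosome, reverse_complement

_NEG = -1.0e18


@dataclass
class TIRParams:
    """Scoring and search parameters for TIR detection.

    The gap costs (open 2, extend 1) follow the blastn settings used for this
    kind of end-anchored self-search; match/mismatch default to +1/-2, the
    reward/penalty pair conventionally valid with those gap costs.
    """

    end_window: int = 99
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 2.0  # positive cost
    gap_extend: float = 1.0  # positive cost
    seed_k: int = 15
    min_report: int = 20
    band: int = 200
    xdrop: float = 50.0


@dataclass
class TIRResult:
    chrom_id: str
    detected: bool
    tir_len: int  # query-side alignment span, bp
    fraction: float  # 2 * tir_len / L, both repeat copies counted
    left_start: int
    right_end: int
    identity: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            ops.append((int(n), ch))
            n = ""
    return ops


def _trim_unsupported_tail(ops: list[tuple[int, str]], seed_k: int) -> list[tuple[int, str]]:
    """Trim alignment tails that rest on chance micro-homology.

    A maximum-score endpoint can overshoot a repeat boundary when a short
    spurious match run follows an indel in otherwise unrelated sequence.  Any
    terminal region after the last indel is therefore required to contain at
    least ``seed_k`` matching columns; otherwise it is trimmed away (together
    with trailing mismatch/indel columns, since a repeat cannot end in one).
    Substitution-only alignments are never trimmed.
    """
    ops = list(ops)
    while ops:
        while ops and ops[-1][1] != "=":
            ops.pop()
        if not ops:
            break
        last_indel = max((i for i, (_, op) in enumerate(ops) if op in "ID"), default=None)
        if last_indel is None:
            break
        tail_matches = sum(n for n, op in ops[last_indel + 1 :] if op == "=")
        if tail_matches >= seed_k:
            break
        del ops[last_indel:]
    return ops


def _extend_banded(a: np.ndarray, b: np.ndarray, params: TIRParams) -> tuple[int, int, float]:
    """Affine-gap extension alignment of a against b, anchored at (0, 0).

    Returns (query_span, subject_span, score) of the maximum-score endpoint.
    Three-state Gotoh recurrence over a band of half-width ``params.band``
    around the main diagonal, with X-drop termination.
    """
    band = params.band
    go, ge = params.gap_open, params.gap_extend
    width = 2 * band + 1
    dgrid = np.arange(-band, band + 1)  # diagonal offset d = j - i
    n, m = len(a), len(b)

    M = np.full(width, _NEG)
    Ix = np.full(width, _NEG)  # gap in subject (query base unpaired)
    Iy = np.full(width, _NEG)  # gap in query (subject base unpaired)
    M[band] = 0.0
    lead = dgrid > 0
    Iy[lead] = -(go + ge * dgrid[lead])

    best, best_i, best_j = 0.0, 0, 0
    for i in range(1, n + 1):
        j = i + dgrid
        prev_best = np.maximum(np.maximum(M, Ix), Iy)
        sub = np.full(width, _NEG)
        diag_ok = (j >= 1) & (j <= m)
        jj = j[diag_ok] - 1
        sub[diag_ok] = np.where(b[jj] == a[i - 1], params.match, params.mismatch)
        M_new = prev_best + sub

        M_up = np.concatenate([M[1:], [_NEG]])
        Ix_up = np.concatenate([Ix[1:], [_NEG]])
        Ix_new = np.maximum(M_up - (go + ge), Ix_up - ge)

        # horizontal affine gaps within the row, as a prefix-max scan:
        # Iy[d] = max_{d0 < d} (M[d0] + ge*d0) - go - ge*d
        t = M_new + ge * dgrid
        run = np.maximum.accumulate(np.concatenate([[_NEG], t[:-1]]))
        Iy_new = run - go - ge * dgrid

        exists = (j >= 0) & (j <= m)
        M_new[~diag_ok] = _NEG
        Ix_new[~exists] = _NEG
        Iy_new[~diag_ok] = _NEG
        M, Ix, Iy = M_new, Ix_new, Iy_new

        k = int(np.argmax(M))
        if M[k] > best:
            best, best_i, best_j = float(M[k]), i, int(j[k])
        if max(M.max(), Ix.max(), Iy.max()) < best - params.xdrop:
            break
    return best_i, best_j, best


def find_terminal_inverted_repeat(
    chromosome: LinearChromosome, params: TIRParams | None = None
) -> TIRResult:
    """Detect the terminal inverted repeat of one linear chromosome.

    The longest end-anchored alignment of at least ``min_report`` bp is
    reported (ties broken by higher score, then smaller left start); the
    reported ``tir_len`` is the query-side alignment span and is capped at
    L/2 (a perfect palindrome has fraction 1).
    """
    params = params or TIRParams()
    if chromosome.topology != "linear":
        raise ValueError(f"{chromosome.id}: TIR detection requires a linear chromosome")
    L = chromosome.length
    k = params.seed_k
    if L <= 2 * k:
        raise ValueError(f"{chromosome.id}: chromosome too short ({L} bp) for seed length {k}")

    a = _encode(chromosome.seq)
    b = _encode(reverse_complement(chromosome.seq))
    W = max(params.end_window, 1)

    # seeds: exact k-mers starting within the first W bp of both the query
    # (left chromosome end) and the subject (right chromosome end, rc strand)
    b_kmers: dict[bytes, int] = {}
    for bs in range(min(W, L - k), -1, -1):
        b_kmers[b[bs : bs + k].tobytes()] = bs  # keep smallest start per k-mer
    anchors: dict[int, tuple[int, int]] = {}
    for qs in range(min(W, L - k)):
        bs = b_kmers.get(a[qs : qs + k].tobytes())
        if bs is None:
            continue
        diag = bs - qs
        if diag not in anchors or qs < anchors[diag][0]:
            anchors[diag] = (qs, bs)

    best: tuple[int, float, int] | None = None  # (span, score, -left_start) to maximize
    best_ends: tuple[int, int, int, int] | None = None
    for qs, bs in anchors.values():
        while qs > 0 and bs > 0 and a[qs - 1] == b[bs - 1]:
            qs -= 1
            bs -= 1
        max_q = L // 2 - qs
        if max_q <= 0:
            continue
        span, sspan, score = _extend_banded(a[qs : qs + max_q], b[bs : bs + max_q + params.band], params)
        key = (span, score, -qs)
        if span >= params.min_report and (best is None or key > best):
            best = key
            best_ends = (qs, qs + span, bs, bs + sspan)

    if best_ends is None:
        return TIRResult(chromosome.id, False, 0, 0.0, 0, 0, 0.0)

    # refine the boundary: align the two candidate repeat copies and trim any
    # tail that is not anchored by a seed-length match run after an indel
    qs, qe, bs, be = best_ends
    left = chromosome.seq[qs:qe]
    right_rc = reverse_complement(chromosome.seq)[bs:be]
    ops = _trim_unsupported_tail(
        _cigar_ops(edlib.align(left, right_rc, task="path")["cigar"]), params.seed_k
    )
    qspan = sum(n for n, op in ops if op in "=XI")
    bspan = sum(n for n, op in ops if op in "=XD")
    if qspan < params.min_report:
        return TIRResult(chromosome.id, False, 0, 0.0, 0, 0, 0.0)
    columns = sum(n for n, _ in ops)
    identity = sum(n for n, op in ops if op == "=") / columns
    return TIRResult(
        chrom_id=chromosome.id,
        detected=True,
        tir_len=qspan,
        fraction=2 * qspan / L,
        left_start=qs,
        right_end=L - bs,
        identity=identity,
    )


def tir_summary(results: list[TIRResult]) -> dict:
    """Cohort summary: detection rate and quartile statistics of detected TIRs.

    Quartiles use linear interpolation; the standard deviation uses the n-1
    denominator and is reported as NaN for a single detected TIR.
    """
    if not results:
        raise ValueError("tir_summary requires at least one result")
    detected = [r for r in results if r.detected]
    out: dict = {
        "n": len(results),
        "n_detected": len(detected),
        "detected_fraction": len(detected) / len(results),
    }
    for name, values in (
        ("tir_len", np.array([r.tir_len for r in detected], dtype=float)),
        ("fraction", np.array([r.fraction for r in detected], dtype=float)),
    ):
        if len(values) == 0:
            stats = dict.fromkeys(("median", "q1", "q3", "sd"), math.nan)
        else:
            stats = {
                "median": float(np.median(values)),
                "q1": float(np.quantile(values, 0.25)),
                "q3": float(np.quantile(values, 0.75)),
                "sd": float(np.std(values, ddof=1)) if len(values) > 1 else math.nan,
            }
        for stat, value in stats.items():
            out[f"{name}_{stat}"] = value
    return out


def tir_table(results: list[TIRResult]) -> pd.DataFrame:
    """Per-chromosome TIR results as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "chrom_id": r.chrom_id, "detected": r.detected, "tir_len": r.tir_len,
                "fraction": r.fraction, "identity": r.identity,
                "left_start": r.left_start, "right_end": r.right_end,
            }
            for r in results
        ]
    )
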