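"""PWM motif parsing (HOMER format), log-odds scanning and set enrichment.

A motif file holds blocks of the form::

    >CONSENSUS<TAB>name<TAB>threshold
    p_A p_C p_G p_T      (one row per motif position)

Scores are natural-log odds against a uniform 0.25 background:
score(window) = sum_pos ln(p_base / 0.25). A window containing N is
unscoreable. Hits are emitted on both strands wherever score >= threshold;
reverse-strand hits are reported at the forward-strand offset of the site's
leftmost base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .enrichment import bh_fdr

BACKGROUND = 0.25
PROB_FLOOR = 1e-3
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifParseError(ValueError):
    pass


@dataclass
class MotifPwm:
    name: str
    consensus: str
    probs: np.ndarray  # (L, 4) rows over A,C,G,T
    threshold: float  # natural-log odds detection cutoff

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("PWM must be (L, 4) with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError("PWM rows must sum to 1 (+-1e-3)")
        if (self.probs <= 0).any():
            raise ValueError("PWM probabilities must be positive after flooring")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.probs / BACKGROUND)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class MotifHit:
    motif: str
    sequence_id: str
    offset: int  # forward-strand offset of the leftmost base
    strand: str
    score: float


@dataclass
class MotifEnrichment:
    motif: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p: float
    q: float | None = None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_homer_motifs(text: str) -> list[MotifPwm]:
    """Parse HOMER-format motif text into floored, renormalized PWMs."""
    motifs: list[MotifPwm] = []
    header: tuple[str, str, float] | None = None
    rows: list[list[float]] = []

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        consensus, name, threshold = header
        if not rows:
            raise MotifParseError(f"motif {name!r} has no probability rows (line {lineno})")
        probs = np.asarray(rows, dtype=float)
        probs = np.maximum(probs, PROB_FLOOR)
        probs = probs / probs.sum(axis=1, keepdims=True)
        motifs.append(MotifPwm(name, consensus, probs, threshold))
        header, rows = None, []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            fields = line[1:].split("\t")
            if len(fields) < 3:
                raise MotifParseError(
                    f"line {lineno}: header needs consensus, name and threshold"
                )
            try:
                thr = float(fields[2])
            except ValueError:
                raise MotifParseError(f"line {lineno}: bad threshold {fields[2]!r}") from None
            header = (fields[0], fields[1], thr)
        else:
            if header is None:
                raise MotifParseError(f"line {lineno}: probability row before any header")
            parts = line.split()
            if len(parts) != 4:
                raise MotifParseError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            row = [float(x) for x in parts]
            if not np.isclose(sum(row), 1.0, atol=1e-2):
                raise MotifParseError(f"line {lineno}: row sums to {sum(row):.4f}, not ~1")
            rows.append(row)
    flush(-1)
    return motifs


def format_homer_motifs(pwms: Sequence[MotifPwm]) -> str:
    lines = []
    for pwm in pwms:
        lines.append(f">{pwm.consensus}\t{pwm.name}\t{pwm.threshold:g}")
        for row in pwm.probs:
            lines.append("\t".join(f"{p:.3f}" for p in row))
    return "\n".join(lines) + "\n"


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    idx = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def scan_sequence(pwm: MotifPwm, sequence: str, sequence_id: str = "seq") -> list[MotifHit]:
    """All positions (both strands) scoring >= the motif threshold.

    Returns an empty list when the sequence is shorter than the motif.
    Windows containing N never score.
    """
    L = len(pwm)
    n = len(sequence)
    if n < L:
        return []
    idx = _encode(sequence)
    # column 4 handles N: any window containing N scores -inf
    lod = np.concatenate([pwm.log_odds, np.full((L, 1), -np.inf)], axis=1)  # (L, 5)
    n_windows = n - L + 1
    offsets = np.arange(n_windows)
    fwd = np.zeros(n_windows)
    for k in range(L):
        fwd += lod[k, idx[k : k + n_windows]]
    # reverse strand: score of reverse complement motif on forward sequence
    rc_lod = lod[::-1, [3, 2, 1, 0, 4]]
    rev = np.zeros(n_windows)
    for k in range(L):
        rev += rc_lod[k, idx[k : k + n_windows]]
    hits = []
    for off in offsets[fwd >= pwm.threshold]:
        hits.append(MotifHit(pwm.name, sequence_id, int(off), "+", float(fwd[off])))
    for off in offsets[rev >= pwm.threshold]:
        hits.append(MotifHit(pwm.name, sequence_id, int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_sequences(
    pwms: Sequence[MotifPwm], sequences: dict[str, str]
) -> list[MotifHit]:
    hits = []
    for pwm in pwms:
        for sid, seq in sequences.items():
            hits.extend(scan_sequence(pwm, seq, sid))
    return hits


def known_motif_enrichment(
    foreground: dict[str, str],
    background: dict[str, str],
    pwms: Sequence[MotifPwm],
    q_threshold: float = 0.01,
) -> list[MotifEnrichment]:
    """Hit-count Fisher enrichment of each motif in foreground vs background.

    Per motif, the number of sequences with >=1 hit in each set forms a
    2x2 table tested one-sided (foreground enriched); q-values are BH
    across motifs. All motifs are returned with their statistics; callers
    filter at q < ``q_threshold``.
    """
    if not foreground or not background:
        raise ValueError("foreground and background sets must be non-empty")
    results = []
    for pwm in pwms:
        fg = sum(1 for sid, s in foreground.items() if scan_sequence(pwm, s, sid))
        bg = sum(1 for sid, s in background.items() if scan_sequence(pwm, s, sid))
        table = [[fg, len(foreground) - fg], [bg, len(background) - bg]]
        _, p = stats.fisher_exact(table, alternative="greater")
        results.append(MotifEnrichment(pwm.name, fg, len(foreground), bg, len(background), float(p)))
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
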