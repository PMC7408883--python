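"""Independent brute-force alignment oracle for small instances.

Scores every full-length ungapped placement of a read at every offset of
every contig on both strands (no seeding, no heuristics) using numpy
sliding windows.  Used to check the seed-and-extend aligner and the
two-step extraction; kept free of any package alignment code.
"""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


def _u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _rc(seq: str) -> str:
    return seq.encode("ascii").translate(_RC)[::-1].decode("ascii")


def brute_force_placements(read_seq, contigs, match=1, mismatch=-4):
    """All placements: list of (contig, start, strand, score).

    ``contigs`` maps name -> (sequence, circular).  Circular contigs are
    extended by len(read)-1 bases so origin-spanning placements score.
    """
    m = len(read_seq)
    out = []
    for strand, q in (("+", read_seq), ("-", _rc(read_seq))):
        qarr = _u8(q)
        for name, (seq, circular) in contigs.items():
            ext = seq + seq[: m - 1] if circular else seq
            if len(ext) < m:
                continue
            windows = sliding_window_view(_u8(ext), m)
            n_starts = len(seq) if circular else len(seq) - m + 1
            matches = (windows[:n_starts] == qarr).sum(axis=1)
            scores = match * matches + mismatch * (m - matches)
            for start in range(n_starts):
                out.append((name, start, strand, int(scores[start])))
    return out


def brute_force_best(read_seq, contigs, match=1, mismatch=-4, min_score=20):
    """Best placement, or None below min_score.  Ties resolved like the
    implementation: higher score first, then (contig, start, strand)."""
    placements = brute_force_placements(read_seq, contigs, match, mismatch)
    if not placements:
        return None
    placements.sort(key=lambda c: (-c[3], c[0], c[1], c[2]))
    best = placements[0]
    return best if best[3] >= min_score else None


def brute_force_is_mito(read_seq, contigs, mito_name, match=1, mismatch=-4,
                        min_score=20):
    """Competitive call: True iff the best mito placement strictly beats
    every nuclear placement (ties go to nuclear)."""
    placements = brute_force_placements(read_seq, contigs, match, mismatch)
    mito_best = max(
        (s for c, _, _, s in placements if c == mito_name), default=None
    )
    nuc_best = max(
        (s for c, _, _, s in placements if c != mito_name), default=None
    )
    if mito_best is None or mito_best < min_score:
        return False
    return nuc_best is None or mito_best > nuc_best
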