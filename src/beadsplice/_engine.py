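"""Numba kernels behind the barcode caller.

All sequences arrive as uint8 code arrays (A=0..T=3, other=4).  The local
alignment uses the classic +1 match / -1 mismatch / -1 indel scoring.  Spans
are 0-based half-open.  Tie-breaking is deterministic: among equal-scoring
local alignments the one with the lowest target start wins, then the lowest
query start, then the lowest target end, then the lowest query end.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_align(query, target):  # pragma: no cover - exercised via wrappers
    """Smith-Waterman (+1/-1/-1) with span tracking.

    Returns (score, q_start, q_end, t_start, t_end), half-open.  A score of 0
    means no positive-scoring alignment exists (empty span at 0).
    """
    m = query.shape[0]
    n = target.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    TS = np.zeros((m + 1, n + 1), dtype=np.int32)
    QS = np.zeros((m + 1, n + 1), dtype=np.int32)
    # empty-prefix cells start an alignment at their own coordinates
    for j in range(n + 1):
        TS[0, j] = j
    for i in range(m + 1):
        QS[i, 0] = i
    best = np.int32(0)
    bts = np.int32(0)
    bqs = np.int32(0)
    bte = np.int32(0)
    bqe = np.int32(0)
    for i in range(1, m + 1):
        qc = query[i - 1]
        for j in range(1, n + 1):
            match = 1 if (qc == target[j - 1] and qc <= 3) else -1
            sc = H[i - 1, j - 1] + match
            ts = TS[i - 1, j - 1]
            qs = QS[i - 1, j - 1]
            up = H[i - 1, j] - 1
            if up > sc or (up == sc and (TS[i - 1, j] < ts or (TS[i - 1, j] == ts and QS[i - 1, j] < qs))):
                sc = up
                ts = TS[i - 1, j]
                qs = QS[i - 1, j]
            left = H[i, j - 1] - 1
            if left > sc or (left == sc and (TS[i, j - 1] < ts or (TS[i, j - 1] == ts and QS[i, j - 1] < qs))):
                sc = left
                ts = TS[i, j - 1]
                qs = QS[i, j - 1]
            if sc < 0 or (sc == 0 and (j < ts or (j == ts and i < qs))):
                sc = 0
                ts = j
                qs = i
            H[i, j] = sc
            TS[i, j] = ts
            QS[i, j] = qs
            if sc > best or (
                sc == best
                and (
                    ts < bts
                    or (ts == bts and (qs < bqs or (qs == bqs and (j < bte or (j == bte and i < bqe)))))
                )
            ):
                best = sc
                bts = ts
                bqs = qs
                bte = j
                bqe = i
    return best, bqs, bqe, bts, bte


@njit(cache=True)
def sw_score(query, target):  # pragma: no cover
    """Score-only Smith-Waterman; rolling single row."""
    m = query.shape[0]
    n = target.shape[0]
    prev = np.zeros(n + 1, dtype=np.int32)
    best = 0
    for i in range(m):
        qc = query[i]
        diag = 0  # prev[j-1] before overwrite
        for j in range(1, n + 1):
            match = 1 if (qc == target[j - 1] and qc <= 3) else -1
            sc = diag + match
            if prev[j] - 1 > sc:
                sc = prev[j] - 1
            # prev[j-1] currently holds the value of this row at j-1
            if prev[j - 1] - 1 > sc:
                sc = prev[j - 1] - 1
            if sc < 0:
                sc = 0
            diag = prev[j]
            prev[j] = sc
            if sc > best:
                best = sc
    return best


@njit(cache=True)
def best_barcode(bc_codes, cand, ncand, target):  # pragma: no cover
    """Align every candidate barcode to `target`; returns (idx, score, n_at_top).

    When several candidates reach the top score, the lowest barcode index is
    reported (callers treat n_at_top > 1 as ambiguous anyway).
    """
    best_idx = -1
    best_sc = -1
    n_top = 0
    for c in range(ncand):
        b = cand[c]
        sc = sw_score(bc_codes[b], target)
        if sc > best_sc:
            best_sc = sc
            best_idx = b
            n_top = 1
        elif sc == best_sc:
            n_top += 1
            if b < best_idx:
                best_idx = b
    return best_idx, best_sc, n_top


@njit(cache=True)
def collect_candidates(region, k, offsets, values, lastseen, stamp, out):  # pragma: no cover
    """Barcode ids sharing >=1 exact k-mer with `region`, deduplicated.

    `lastseen`/`stamp` implement an O(1)-reset visited set across calls.
    Returns the number of candidates written to `out`.
    """
    n = region.shape[0]
    cnt = 0
    if n < k:
        return 0
    mask = (1 << (2 * k)) - 1
    km = 0
    valid = 0
    for i in range(n):
        c = region[i]
        if c > 3:
            valid = 0
            km = 0
            continue
        km = ((km << 2) | c) & mask
        valid += 1
        if valid >= k:
            for p in range(offsets[km], offsets[km + 1]):
                b = values[p]
                if lastseen[b] != stamp:
                    lastseen[b] = stamp
                    out[cnt] = b
                    cnt += 1
    return cnt


@njit(cache=True)
def has_shared_kmer(region, k, table):  # pragma: no cover
    """True iff `region` shares an exact k-mer with the sequence behind `table`
    (a 4**k bool array)."""
    n = region.shape[0]
    if n < k:
        return False
    mask = (1 << (2 * k)) - 1
    km = 0
    valid = 0
    for i in range(n):
        c = region[i]
        if c > 3:
            valid = 0
            km = 0
            continue
        km = ((km << 2) | c) & mask
        valid += 1
        if valid >= k and table[km]:
            return True
    return False


@njit(cache=True)
def find_polyt_window(seq, window, min_count, min_t):  # pragma: no cover
    """Leftmost length-`window` window with >= `min_count` T, trimmed to T at
    the edges and extended maximally through adjacent Ts.  Requires >= `min_t`
    T bases in the final interval.  Returns (start, end) half-open or (-1, -1).
    """
    n = seq.shape[0]
    if n < window:
        return -1, -1
    cnt = 0
    for i in range(window):
        if seq[i] == 3:
            cnt += 1
    start = -1
    if cnt >= min_count:
        start = 0
    i = 0
    while start == -1 and i + window < n:
        if seq[i] == 3:
            cnt -= 1
        if seq[i + window] == 3:
            cnt += 1
        i += 1
        if cnt >= min_count:
            start = i
    if start == -1:
        return -1, -1
    end = start + window
    while start < end and seq[start] != 3:
        start += 1
    while end > start and seq[end - 1] != 3:
        end -= 1
    while start > 0 and seq[start - 1] == 3:
        start -= 1
    while end < n and seq[end] == 3:
        end += 1
    tc = 0
    for j in range(start, end):
        if seq[j] == 3:
            tc += 1
    if tc < min_t:
        return -1, -1
    return start, end


@njit(cache=True)
def inject_errors_flat(seq, p_sub, p_ins, p_del, rand, bases, out):  # pragma: no cover
    """Apply i.i.d. per-base substitution/insertion/deletion.

    `rand` supplies 2 uniforms per input base (op choice, insertion), `bases`
    supplies replacement/inserted base codes.  Writes to `out` (size >= 2n+1)
    and returns (length, n_sub, n_ins, n_del).  An insertion is placed after
    the base it is drawn for; substituted bases are guaranteed to differ.
    """
    n = seq.shape[0]
    pos = 0
    ns = 0
    ni = 0
    nd = 0
    for i in range(n):
        u = rand[2 * i]
        c = seq[i]
        if u < p_del:
            nd += 1
        elif u < p_del + p_sub:
            nb = (c + 1 + bases[2 * i] % 3) % 4
            out[pos] = nb
            pos += 1
            ns += 1
        else:
            out[pos] = c
            pos += 1
        if rand[2 * i + 1] < p_ins:
            out[pos] = bases[2 * i + 1]
            pos += 1
            ni += 1
    return pos, ns, ni, nd


def encode_barcodes(barcodes: list[str] | tuple[str, ...]) -> np.ndarray:
    """(n, L) uint8 code matrix for a list of equal-length barcodes."""
    from ._seq import encode

    n = len(barcodes)
    L = len(barcodes[0])
    out = np.empty((n, L), dtype=np.uint8)
    for i, bc in enumerate(barcodes):
        out[i] = encode(bc)
    return out


def build_csr_kmer_index(bc_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """CSR (offsets, values) mapping every k-mer key (2-bit packed) to the
    sorted barcode ids containing it."""
    n, L = bc_codes.shape
    if L < k:
        raise ValueError(f"barcode length {L} < k={k}")
    nk = L - k + 1
    # pack every k-mer of every barcode
    km = np.zeros((n, nk), dtype=np.int64)
    for j in range(k):
        km = (km << 2) | bc_codes[:, j : j + nk].astype(np.int64)
    ids = np.repeat(np.arange(n, dtype=np.int32), nk)
    flat = km.ravel()
    # deduplicate (barcode, kmer) pairs so each barcode appears once per key
    pair = flat << 32 | ids.astype(np.int64)
    pair = np.unique(pair)
    flat = pair >> 32
    ids = (pair & 0xFFFFFFFF).astype(np.int32)
    order = np.argsort(flat, kind="stable")
    flat = flat[order]
    ids = ids[order]
    offsets = np.zeros(4**k + 1, dtype=np.int64)
    np.add.at(offsets, flat + 1, 1)
    offsets = np.cumsum(offsets)
    return offsets, ids


def kmer_presence_table(codes: np.ndarray, k: int) -> np.ndarray:
    """4**k bool array marking the k-mers of one sequence."""
    table = np.zeros(4**k, dtype=np.bool_)
    km = 0
    valid = 0
    mask = (1 << (2 * k)) - 1
    for c in codes:
        if c > 3:
            valid = 0
            km = 0
            continue
        km = ((km << 2) | int(c)) & mask
        valid += 1
        if valid >= k:
            table[km] = True
    return table
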