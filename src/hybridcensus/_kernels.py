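"""Numba kernels for the seed-and-extend local aligner.

The aligner finds shared k-mers between a read and the fragment database
(via the sorted-postings index built by :mod:`hybridcensus.fragdb`), groups
seeds per fragment, and runs a banded affine-gap Smith-Waterman extension
centred on the best-supported diagonal.  A gap of length ``g`` costs
``gap_open + g * gap_extend`` (blastn convention).  Bases coded >= 4 (N)
never match.

These functions are internal; :mod:`hybridcensus.hitcensus` is the public
surface.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1_000_000_000

#: per-read cap on extended candidate fragments (both strands combined)
CAND_CAP = 256
#: per-strand cap on raw seed postings
PAIR_CAP = 16384


@njit(cache=True)
def banded_sw(read, frag, diag, band, match, mismatch, gap_open, gap_extend):
    """Best local alignment score within ``|`` (j-i) - diag ``| <= band``.

    Affine gaps: first gap base costs gap_open + gap_extend, each further
    base gap_extend.  ``mismatch``/``gap_*`` are positive penalties.
    """
    m = read.size
    n = frag.size
    width = 2 * band + 1
    Hp = np.zeros(width, np.int64)
    Fp = np.full(width, NEG, np.int64)
    Hc = np.zeros(width, np.int64)
    Fc = np.full(width, NEG, np.int64)
    best = 0
    for i in range(m):
        ri = read[i]
        e = NEG
        for b in range(width):
            j = i + diag - band + b
            if j < 0 or j >= n:
                Hc[b] = 0  # empty-prefix restart for the j==-1 diagonal source
                Fc[b] = NEG
                continue
            if b + 1 < width:
                f = Fp[b + 1] - gap_extend
                h_up = Hp[b + 1] - gap_open - gap_extend
                if h_up > f:
                    f = h_up
            else:
                f = NEG
            Fc[b] = f
            if b > 0:
                e2 = e - gap_extend
                h_left = Hc[b - 1] - gap_open - gap_extend
                if h_left > e2:
                    e2 = h_left
            else:
                e2 = NEG
            e = e2
            fj = frag[j]
            if ri == fj and ri < 4:
                s = match
            else:
                s = -mismatch
            h = Hp[b] + s
            if e2 > h:
                h = e2
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[b] = h
            if h > best:
                best = h
        Ht = Hp
        Hp = Hc
        Hc = Ht
        Ft = Fp
        Fp = Fc
        Fc = Ft
    return best


@njit(cache=True)
def _revcomp(seq):
    out = np.empty_like(seq)
    n = seq.size
    for i in range(n):
        b = seq[n - 1 - i]
        out[i] = 3 - b if b < 4 else 4
    return out


@njit(cache=True)
def _collect_seeds(read, k, codes, post_frag, post_off, pairs_frag, pairs_diag):
    """Write (fragment, diagonal) seed postings for every valid read k-mer.

    Diagonal convention: diag = fragment_offset - read_offset.  Returns the
    number of postings written (capped at the buffer size).
    """
    m = read.size
    if m < k:
        return 0
    modulus = np.uint64(1)
    for _ in range(k):
        modulus *= np.uint64(4)
    code = np.uint64(0)
    invalid = 0  # count of N bases in the current window
    cnt = 0
    for q in range(m):
        b = read[q]
        if b >= 4:
            invalid = k  # poisons the next k windows
            b = 0
        elif invalid > 0:
            invalid -= 1
        code = (code * np.uint64(4) + np.uint64(b)) % modulus
        if q >= k - 1 and invalid == 0:
            lo = np.searchsorted(codes, code, side="left")
            hi = np.searchsorted(codes, code, side="right")
            for idx in range(lo, hi):
                if cnt >= pairs_frag.size:
                    return cnt
                pairs_frag[cnt] = post_frag[idx]
                pairs_diag[cnt] = post_off[idx] - (q - k + 1)
                cnt += 1
    return cnt


@njit(cache=True)
def _extend(
    read,
    frag_mat,
    pairs_frag,
    pairs_diag,
    n_pairs,
    min_seed,
    band,
    match,
    mismatch,
    gap_open,
    gap_extend,
    cand_frag,
    cand_score,
    cand_strand,
    strand_id,
    n_cand,
):
    """Group seeds per fragment and run the banded extension.

    For each fragment with >= min_seed seed postings, extension is centred
    on the diagonal carrying the most seeds.  Appends (fragment, score)
    into the candidate buffers starting at ``n_cand``; returns the new
    count.  Fragments already present keep the max score.
    """
    if n_pairs == 0:
        return n_cand
    span = np.int64(2 * (read.size + frag_mat.shape[1]))
    keys = np.empty(n_pairs, np.int64)
    for i in range(n_pairs):
        keys[i] = pairs_frag[i] * span + (pairs_diag[i] + span // 2)
    order = np.argsort(keys)
    i = 0
    while i < n_pairs:
        f = pairs_frag[order[i]]
        total = 0
        best_diag = np.int64(0)
        best_run = 0
        j = i
        while j < n_pairs and pairs_frag[order[j]] == f:
            d = pairs_diag[order[j]]
            run = 0
            while j < n_pairs and pairs_frag[order[j]] == f and pairs_diag[order[j]] == d:
                run += 1
                j += 1
            total += run
            if run > best_run:
                best_run = run
                best_diag = d
        i = j
        if total >= min_seed:
            score = banded_sw(
                read, frag_mat[f], best_diag, band, match, mismatch, gap_open, gap_extend
            )
            # dedupe across strands: keep max score per fragment
            found = False
            for c in range(n_cand):
                if cand_frag[c] == f:
                    if score > cand_score[c]:
                        cand_score[c] = score
                        cand_strand[c] = strand_id
                    found = True
                    break
            if not found and n_cand < cand_frag.size:
                cand_frag[n_cand] = f
                cand_score[n_cand] = score
                cand_strand[n_cand] = strand_id
                n_cand += 1
    return n_cand


@njit(cache=True)
def search_all(
    reads_mat,
    read_lens,
    k,
    codes,
    post_frag,
    post_off,
    frag_mat,
    min_seed,
    band,
    match,
    mismatch,
    gap_open,
    gap_extend,
    out_frag,
    out_score,
    out_strand,
    out_count,
):
    """Seed-and-extend every read (both strands) against the database.

    ``reads_mat`` is (n_reads, max_len) uint8 with rows padded by 4s;
    results land in ``out_frag``/``out_score``/``out_strand``
    (n_reads, CAND_CAP) with per-read candidate counts in ``out_count``.
    """
    n_reads = reads_mat.shape[0]
    pairs_frag = np.empty(PAIR_CAP, np.int64)
    pairs_diag = np.empty(PAIR_CAP, np.int64)
    for r in range(n_reads):
        m = read_lens[r]
        fwd = reads_mat[r, :m]
        n_cand = 0
        for strand in range(2):
            seq = fwd if strand == 0 else _revcomp(fwd)
            n_pairs = _collect_seeds(
                seq, k, codes, post_frag, post_off, pairs_frag, pairs_diag
            )
            n_cand = _extend(
                seq,
                frag_mat,
                pairs_frag,
                pairs_diag,
                n_pairs,
                min_seed,
                band,
                match,
                mismatch,
                gap_open,
                gap_extend,
                out_frag[r],
                out_score[r],
                out_strand[r],
                strand,
                n_cand,
            )
        out_count[r] = n_cand
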