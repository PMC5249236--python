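"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def exhaustive_viterbi_split(ll, log_trans, log_init):
    """Best state path by exact enumeration of all k^(n/2) half-paths.

    Every full path is the concatenation of one enumerated prefix and one
    enumerated suffix, so the exact maximum over all k^n paths is the
    maximum over all (prefix, suffix) pairs joined by one transition.
    Scales to lengths where flat enumeration is impractical.
    """
    n, k = ll.shape
    h = n // 2

    def all_paths(length):
        digits = np.indices((k,) * length).reshape(length, -1).T
        return digits

    pre = all_paths(h)
    pre_scores = log_init[pre[:, 0]] + ll[0, pre[:, 0]]
    for t in range(1, h):
        pre_scores += log_trans[pre[:, t - 1], pre[:, t]] + ll[t, pre[:, t]]
    suf = all_paths(n - h)
    suf_scores = ll[h, suf[:, 0]].copy()
    for t in range(1, n - h):
        suf_scores += log_trans[suf[:, t - 1], suf[:, t]] + ll[h + t, suf[:, t]]

    best = (-np.inf, None, None)
    for a in range(k):  # last prefix state
        ia = np.flatnonzero(pre[:, -1] == a)
        pa = ia[np.argmax(pre_scores[ia])]
        for b in range(k):  # first suffix state
            ib = np.flatnonzero(suf[:, 0] == b)
            sb = ib[np.argmax(suf_scores[ib])]
            total = pre_scores[pa] + log_trans[a, b] + suf_scores[sb]
            if total > best[0]:
                best = (float(total), pre[pa], suf[sb])
    return np.concatenate([best[1], best[2]]), best[0]


def exhaustive_viterbi(ll, log_trans, log_init, chunk=2_000_000):
    """Best state path by scoring every one of k^n paths explicitly.

    Paths are enumerated in mixed radix and scored in chunks, entirely
    independent of the dynamic-programming decoder it checks.
    Returns (best_path, best_score).
    """
    n, k = ll.shape
    total = k**n
    best_score = -np.inf
    best_path = None
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        digits = np.empty((idx.size, n), dtype=np.int64)
        rem = idx.copy()
        for t in range(n - 1, -1, -1):
            digits[:, t] = rem % k
            rem //= k
        scores = log_init[digits[:, 0]] + ll[0, digits[:, 0]]
        for t in range(1, n):
            scores += log_trans[digits[:, t - 1], digits[:, t]] + ll[t, digits[:, t]]
        j = int(np.argmax(scores))
        if scores[j] > best_score:
            best_score = float(scores[j])
            best_path = digits[j].copy()
    return best_path, best_score
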