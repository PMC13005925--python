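"""Independent brute-force oracles shared by segmentation tests."""

import numpy as np


def oracle_cbs(v, seed, params):
    """Exhaustive change-point search: same statistic and permutation
    stream as the production CBS (one rng.permutation call per
    permutation), but with explicit Python loops over all arc pairs."""
    rng = np.random.default_rng(seed)
    breaks = set()
    queue = [(0, len(v))]
    while queue:
        lo, hi = queue.pop(0)
        n = hi - lo
        if n < 2 * params.min_width:
            continue
        seg = v[lo:hi]
        if np.ptp(seg) == 0:
            continue
        sd = np.std(seg, ddof=1)
        if sd <= 0:
            continue
        pairs = []
        for i in range(0, n):
            for j in range(i + 1, n + 1):
                if (i, j) == (0, n):
                    continue
                m = j - i
                if m < params.min_width or n - m < params.min_width:
                    continue
                if 0 < i < params.min_width:
                    continue
                if j < n and n - j < params.min_width:
                    continue
                pairs.append((i, j))
        if not pairs:
            continue

        def maxstat(x):
            S = np.concatenate([[0.0], np.cumsum(x)])
            tot = S[n]
            best, bp = -1.0, None
            for (i, j) in pairs:
                m = j - i
                arc = S[j] - S[i]
                z = abs(arc / m - (tot - arc) / (n - m)) / (
                    sd * np.sqrt(1.0 / m + 1.0 / (n - m))
                )
                if z > best:
                    best, bp = z, (i, j)
            return best, bp

        t_obs, pair = maxstat(seg)
        if t_obs <= 0:
            continue
        count = 0
        for _ in range(params.nperm):
            t, _ = maxstat(seg[rng.permutation(n)])
            if t >= t_obs:
                count += 1
        if (count + 1) / (params.nperm + 1) < params.alpha:
            i, j = pair
            cuts = sorted({lo + i, lo + j} - {lo, hi})
            if cuts:
                breaks.update(cuts)
                bounds = [lo] + cuts + [hi]
                queue.extend(zip(bounds[:-1], bounds[1:]))
    return sorted(breaks)
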