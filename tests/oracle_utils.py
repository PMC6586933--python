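"""Independent brute-force oracles used by the test suite.

Deliberately written as plain-Python scans and enumerations, sharing no
code with the package implementation they check.
"""

import itertools
import math


def brute_force_threshold(dff, time, valve_open, prestim_window=15.0, k_sd=3.0,
                          min_samples=5):
    vals = [v for v, t in zip(dff, time)
            if valve_open - prestim_window <= t < valve_open
            and not math.isnan(v)]
    if len(vals) < min_samples:
        return None
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return mean + k_sd * math.sqrt(var)


def brute_force_call(dff, time, valve_open, search_window=60.0,
                     min_duration=5.0, prestim_window=15.0, k_sd=3.0):
    """Explicit scan of every consecutive supra-threshold run.

    Returns (responsive, onset_index, longest_qualifying_span) with the
    same conventions the pipeline documents: strictly above threshold,
    run must *begin* inside [valve, valve + search], span counted as
    (t_last - t_first) + dt.
    """
    threshold = brute_force_threshold(dff, time, valve_open, prestim_window, k_sd)
    if threshold is None:
        return False, None, None
    dt_list = [time[i + 1] - time[i] for i in range(len(time) - 1)]
    dt = sorted(dt_list)[len(dt_list) // 2]

    runs = []
    i = 0
    n = len(dff)
    while i < n:
        if not math.isnan(dff[i]) and dff[i] > threshold:
            j = i
            while j + 1 < n and not math.isnan(dff[j + 1]) and dff[j + 1] > threshold:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    qualifying = []
    for i, j in runs:
        if valve_open <= time[i] <= valve_open + search_window:
            span = time[j] - time[i] + dt
            if span >= min_duration:
                qualifying.append((i, j, span))
    if not qualifying:
        return False, None, None
    onset_idx = qualifying[0][0]
    longest = max(s for _, _, s in qualifying)
    return True, onset_idx, longest


def exact_mwu_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating every assignment of
    the pooled ranks to the first sample (no ties assumed)."""
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rx = sum(ranks[v] for v in x)
    u_obs = rx - nx * (nx + 1) / 2
    u_obs = min(u_obs, nx * ny - u_obs)  # two-sided: distance from either tail
    count = total = 0
    all_ranks = list(range(1, nx + ny + 1))
    for comb in itertools.combinations(all_ranks, nx):
        r = sum(comb)
        u = r - nx * (nx + 1) / 2
        u = min(u, nx * ny - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


def exact_sign_p(n_above, n):
    """Two-sided sign-test p from the binomial pmf, summed directly."""
    def pmf(k):
        return math.comb(n, k) * 0.5**n

    upper = sum(pmf(k) for k in range(n_above, n + 1))
    lower = sum(pmf(k) for k in range(0, n_above + 1))
    return min(1.0, 2.0 * min(upper, lower))
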