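"""Independent loop-based oracles for the feature operators.

Deliberately written as plain-Python definition-level loops (no numpy
reductions) so they share no code path with the implementation.
"""

import math


def mean(x):
    return sum(x) / len(x)


def sample_sd(x):
    m = mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def mean_abs_first_diff(x):
    n = len(x)
    return sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1)


def mean_abs_second_diff(x):
    n = len(x)
    return sum(abs(x[i + 2] - x[i]) for i in range(n - 2)) / (n - 2)


def cumulative_max(x):
    out, cur = [], -math.inf
    for v in x:
        cur = v if v > cur else cur
        out.append(cur)
    return out


def cumulative_min(x):
    out, cur = [], math.inf
    for v in x:
        cur = v if v < cur else cur
        out.append(cur)
    return out


def median(x):
    s = sorted(x)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def moving_median(x, k):
    return [median(x[i:i + k]) for i in range(len(x) - k + 1)]


def channel_stats(x):
    """All amplitude descriptors, definition by definition."""
    n = len(x)
    mav = mean(x)
    sumsq = sum(v * v for v in x)
    rms = math.sqrt(sumsq / n)
    mx, mn = max(x), min(x)
    lpk0 = x.index(mx)
    rival_max, second0 = -math.inf, None
    for i, v in enumerate(x):
        if i != lpk0 and v > rival_max:
            rival_max, second0 = v, i
    m2 = sum((v - mav) ** 2 for v in x) / n
    m4 = sum((v - mav) ** 4 for v in x) / n
    return {
        "mav": mav,
        "med": median(x),
        "min_amp": mn,
        "maxmin": mx - mn,
        "rms": rms,
        "prms": max(abs(v) for v in x) / rms if rms > 0 else float("nan"),
        "rss": math.sqrt(sumsq),
        "std_raw": math.sqrt(sumsq / (n - 1)),
        "var_raw": sumsq / (n - 1),
        "pk": mx,
        "lpk": lpk0 + 1,
        "pp": lpk0 - second0,
        "kurt": m4 / m2**2 if m2 > 0 else float("nan"),
    }


def epoch_stats(x):
    n = len(x)
    m = mean(x)
    m2 = sum((v - m) ** 2 for v in x) / n
    m3 = sum((v - m) ** 3 for v in x) / n
    m4 = sum((v - m) ** 4 for v in x) / n
    mx, mn = max(x), min(x)
    return {
        "mean": m,
        "std": math.sqrt(m2),
        "ptp": mx - mn,
        "var": m2,
        "minim": mn,
        "maxim": mx,
        "argminim": x.index(mn) + 1,
        "argmaxim": x.index(mx) + 1,
        "skewness": m3 / m2**1.5 if m2 > 0 else float("nan"),
        "kurtosis": m4 / m2**2 - 3.0 if m2 > 0 else float("nan"),
    }
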