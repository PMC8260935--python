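"""Independent brute-force oracles used by the tests.

Each function is a literal, loop-based transcription of the defining
formula, deliberately sharing no code with the package implementation.
"""

import math

import numpy as np


def _sgn(u: float) -> int:
    """Counting convention: 1 for positive arguments, else 0."""
    return 1 if u > 0 else 0


def _std(x) -> float:
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))


def brute_force_features(x) -> dict[str, float]:
    x = [float(v) for v in x]
    n = len(x)
    m = sum(x) / n
    d = [v - m for v in x]
    std = _std(x)

    zc = sum(_sgn(-d[i - 1] * d[i]) for i in range(1, n))
    ssc = sum(
        _sgn(-(x[i] - x[i - 1]) * (x[i - 1] - x[i - 2])) for i in range(2, n)
    )
    wl = sum(abs(x[i] - x[i - 1]) for i in range(1, n))
    wa = sum(_sgn(abs(x[i] - x[i - 1]) - std) for i in range(1, n))
    mab = sum(abs(v) for v in x) / n
    msq = sum(v * v for v in x) / n
    rms = math.sqrt(msq)
    mean_cube = sum(v ** 3 for v in x) / n
    v3 = math.copysign(abs(mean_cube) ** (1.0 / 3.0), mean_cube)
    ld = math.exp(sum(math.log(max(abs(v), 1e-12)) for v in x) / n)
    ssd = sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    dabs = math.sqrt(ssd / (n - 1))
    mfl = 0.5 * math.log(ssd) if ssd > 0 else 0.0
    mpr = sum(_sgn(abs(v) - std) for v in x)
    h = n // 2
    mavs = (sum(abs(v) for v in x[:h]) - sum(abs(v) for v in x[h:])) / h
    wma = sum(
        (1.0 if 0.25 * n <= i <= 0.75 * n else 0.5) * abs(x[i - 1])
        for i in range(1, n + 1)
    ) / n

    return {
        "ZC": float(zc), "SSC": float(ssc), "WL": wl, "WA": float(wa),
        "MAB": mab, "MSQ": msq, "RMS": rms, "V3": v3, "LD": ld,
        "DABS": dabs, "MFL": mfl, "MPR": float(mpr), "MAVS": mavs,
        "WMA": wma,
    }


def enumerate_trial_endpoints(n_samples, n_window, n_step):
    """All causal window [start, end) spans by direct enumeration."""
    spans = []
    end = n_window
    while end <= n_samples:
        spans.append((end - n_window, end))
        end += n_step
    return spans


def brute_force_confusion_metrics(tp, tn, fp, fn):
    """Per-definition metric evaluation (degenerate denominators -> 1)."""
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    prec = tp / (tp + fp) if tp + fp else 1.0
    acc = (sens + spec) / 2
    f1 = 2 * sens * prec / (sens + prec) if sens + prec else 0.0
    return sens, spec, prec, acc, f1


def brute_force_mse(y, y_hat):
    return sum((b - a) ** 2 for a, b in zip(y, y_hat)) / len(y)


def brute_force_vaf(y, y_hat):
    ybar = sum(y) / len(y)
    ss_tot = sum((v - ybar) ** 2 for v in y)
    ss_res = sum((b - a) ** 2 for a, b in zip(y, y_hat))
    return 1 - ss_res / ss_tot
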