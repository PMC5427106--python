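"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the timeline oracle
resolves behaviors by brute-force sampling of the raw keystroke list, the
Pearson oracle is the textbook formula, and the p-value oracle goes through
the regularized incomplete beta function rather than scipy.stats.pearsonr.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special

GAP = "gap"


def sample_labels(state_events, duration, step=0.01):
    """Label each 10-ms sample midpoint by the last state keystroke at or
    before it; samples before the first keystroke are labeled ``gap``.

    ``state_events`` is a list of (t, behavior_name) for state keystrokes
    only, sorted by t.
    """
    n = int(round(duration / step))
    mids = (np.arange(n) + 0.5) * step
    labels = np.full(n, GAP, dtype=object)
    if state_events:
        ts = np.array([t for t, _ in state_events])
        names = np.array([n_ for _, n_ in state_events], dtype=object)
        idx = np.searchsorted(ts, mids, side="right") - 1
        ok = idx >= 0
        labels[ok] = names[idx[ok]]
    return labels, step


def oracle_summary(state_events, duration, step=0.01):
    """Per-behavior total time, run count, and latency from the sampled
    label sequence (run-length encoded, so 1000s of logs stay cheap)."""
    labels, step = sample_labels(state_events, duration, step)
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    latency: dict[str, float] = {}
    n = len(labels)
    if n == 0:
        return totals, counts, latency
    change = np.ones(n, dtype=bool)
    change[1:] = labels[1:] != labels[:-1]
    run_starts = np.flatnonzero(change)
    run_lens = np.diff(np.append(run_starts, n))
    for start, length in zip(run_starts, run_lens):
        lab = labels[start]
        if lab == GAP:
            continue
        totals[lab] = totals.get(lab, 0.0) + float(length) * step
        counts[lab] = counts.get(lab, 0) + 1
        if lab not in latency:
            latency[lab] = (float(start) + 0.5) * step
    return totals, counts, latency


def pearson_oracle(a, b):
    """Pearson r from the definition: covariance over product of SDs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))


def pvalue_oracle(r, n):
    """Two-tailed p for Pearson r via the t reference with n-2 df,
    computed through the regularized incomplete beta function."""
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t2 = r * r * df / (1.0 - r * r)
    return float(special.betainc(df / 2.0, 0.5, df / (df + t2)))


def kappa_oracle(la, lb):
    """Cohen's kappa by direct confusion-matrix arithmetic."""
    labels = sorted(set(la) | set(lb))
    idx = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    m = np.zeros((k, k))
    for x, y in zip(la, lb):
        m[idx[x], idx[y]] += 1
    m /= m.sum()
    po = np.trace(m)
    pe = float(m.sum(axis=1) @ m.sum(axis=0))
    if pe >= 1 - 1e-12:
        return 1.0 if po >= 1 - 1e-12 else 0.0
    return float((po - pe) / (1 - pe))


def random_keylog(rng, etho, duration=60.0, n_events=(0, 25), grid=0.05):
    """Random keystroke log on a 50-ms grid (so the 10-ms sampling oracle
    resolves every transition exactly).  Returns a list of KeyEvent plus
    the parallel (t, name) list of state keystrokes for the oracle."""
    from ethoscore import KeyEvent

    n = int(rng.integers(n_events[0], n_events[1] + 1))
    n_slots = int(round(duration / grid))
    ts = np.sort(rng.choice(n_slots, size=min(n, n_slots), replace=False)) * grid
    keys = [b.key for b in etho.behaviors]
    events, state_events = [], []
    for t in ts:
        key = keys[int(rng.integers(len(keys)))]
        events.append(KeyEvent(float(t), key))
        beh = etho.key_map[key]
        if beh.kind == "state":
            state_events.append((float(t), beh.name))
    return events, state_events
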