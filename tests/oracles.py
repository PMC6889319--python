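"""Independent oracles used by the test suite.

The permutation null re-derives the log-rank reference distribution from
first principles: under the null hypothesis of identical survival, the arm
labels are exchangeable, so the statistic's distribution is obtained by
recomputing it over random label shuffles.  The implementation is
vectorised over shuffles with indicator matrices and shares no code with
the implementation under test.
"""

import numpy as np


def logrank_chi2_for_labels(times, events, labels):
    """Log-rank chi-square for a (B, n) matrix of 0/1 arm-A labels.

    Returns a length-B vector.  Pure matrix algebra: at-risk and event
    indicator matrices over the distinct event times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ev_times = np.unique(times[events == 1])
    R = times[:, None] >= ev_times[None, :]            # n x T at-risk
    E = (times[:, None] == ev_times[None, :]) & (events[:, None] == 1)
    d = E.sum(axis=0).astype(float)                    # events per time
    n_at = R.sum(axis=0).astype(float)                 # risk-set sizes
    L = np.atleast_2d(labels).astype(float)            # B x n
    n1 = L @ R                                          # B x T
    d1 = L @ E
    expected = d * n1 / n_at
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(
            n_at > 1,
            d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / (n_at - 1),
            0.0,
        )
    num = (d1.sum(axis=1) - expected.sum(axis=1)) ** 2
    den = var.sum(axis=1)
    return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)


def permutation_logrank_p(times_a, events_a, times_b, events_b,
                          n_perm=100_000, seed=0):
    """Permutation p-value for the log-rank statistic (label shuffles)."""
    times = np.concatenate([times_a, times_b]).astype(float)
    events = np.concatenate([events_a, events_b]).astype(int)
    n_a = len(times_a)
    base = np.zeros(len(times))
    base[:n_a] = 1.0
    observed = logrank_chi2_for_labels(times, events, base[None, :])[0]
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(base, (n_perm, 1)), axis=1)
    null = logrank_chi2_for_labels(times, events, perms)
    return float(np.mean(null >= observed - 1e-12))


def empirical_survival(times):
    """Empirical survival function S(t) = #(T > t)/n (no censoring)."""
    times = np.sort(np.asarray(times, float))
    uniq = np.unique(times)
    surv = [(times > t).mean() for t in uniq]
    return uniq, np.array(surv)
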