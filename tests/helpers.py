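"""Shared test construction utilities."""

from __future__ import annotations

import numpy as np
import pandas as pd

from crpcsurv.features import FeatureMatrix, VariableSpec


def make_fm(X: pd.DataFrame, time, event, skewed=(), imputed=True) -> FeatureMatrix:
    """Wrap a plain matrix + outcome into a FeatureMatrix."""
    specs = [VariableSpec(c, "lab", skewed=c in skewed) for c in X.columns]
    return FeatureMatrix(
        X=X.copy(),
        missing_mask=X.isna(),
        specs=specs,
        time_months=pd.Series(np.asarray(time, dtype=float), index=X.index),
        event=pd.Series(np.asarray(event, dtype=bool), index=X.index),
        imputed=imputed,
    )


def random_survival_instance(rng, n, p=3, beta=None, censor_scale=2.0):
    """Gaussian covariates, exponential survival, independent censoring."""
    X = rng.standard_normal((n, p))
    if beta is None:
        beta = np.zeros(p)
    T = rng.exponential(np.exp(-(X @ beta)))
    C = rng.exponential(censor_scale, n)
    time = np.minimum(T, C)
    event = T <= C
    return X, time, event


def auc_pair_sum_oracle(scores, time, event, t):
    """O(n^2) IPCW cumulative/dynamic AUC by direct double loop (independent
    of the package implementation; the censoring KM is computed by explicit
    product-limit recursion)."""
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    n = len(time)

    def G_left(t0):
        # product-limit estimate of censoring survival just before t0
        g = 1.0
        for u in sorted(set(time)):
            if u >= t0:
                break
            d = np.sum((time == u) & ~event)  # censorings at u
            r = np.sum(time >= u)
            if r > 0:
                g *= 1 - d / r
        return g

    num = 0.0
    wsum = 0.0
    n_ctrl = int(np.sum(time > t))
    if n_ctrl == 0:
        raise ValueError("no controls")
    any_case = False
    for i in range(n):
        if not (event[i] and time[i] <= t):
            continue
        g = G_left(time[i])
        if g <= 0:
            continue
        any_case = True
        w = 1.0 / g
        wsum += w
        for j in range(n):
            if time[j] > t:
                if scores[i] > scores[j]:
                    num += w
                elif scores[i] == scores[j]:
                    num += 0.5 * w
    if not any_case:
        raise ValueError("no cases")
    return num / (wsum * n_ctrl)
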