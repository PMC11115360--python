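"""Signal-detection measures of metacognition from trial tables.

``d'`` measures how well choices discriminate the two stimulus classes.
``meta-d'`` applies the same construction to *confidence-gated* responses:
only responses whose confidence reaches a criterion c count as the "signal"
response when recomputing hit and false-alarm rates. Under a Gaussian
signal-detection observer whose confidence is the true posterior, meta-d'
equals d' at every criterion; a ratio meta-d'/d' below 1 means confidence
carries less information about accuracy than the choice itself did
(metacognitive inefficiency). Confidence built from small discrete sample
counts produces exactly this signature — the binomial evidence distribution
mismatches the Gaussian assumption more and more as the criterion rises.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri


def _clamp_rate(k: int, n: int) -> float:
    """Rate with the 1/(2n) correction so the normal quantile stays finite."""
    if n <= 0:
        raise ValueError("need at least one trial in each stimulus class")
    lo, hi = 0.5 / n, 1.0 - 0.5 / n
    return min(max(k / n, lo), hi)


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Discriminability: Phi^{-1}(hit) - Phi^{-1}(fa). Rates must be in (0,1)."""
    if not (0 < hit_rate < 1) or not (0 < fa_rate < 1):
        raise ValueError("rates must lie strictly inside (0, 1); clamp finite-sample 0/1 rates first")
    return float(ndtri(hit_rate) - ndtri(fa_rate))


def _gated_rates(trials: pd.DataFrame, criterion: float) -> tuple[float, float]:
    stim = trials["stimulus"].to_numpy()
    resp = trials["response"].to_numpy()
    conf = trials["confidence"].to_numpy()
    yes = (resp == 1) & (conf >= criterion)
    n_sig = int(np.count_nonzero(stim == 1))
    n_noise = int(np.count_nonzero(stim == 0))
    if n_sig == 0 or n_noise == 0:
        raise ValueError("both stimulus classes must be present")
    hits = int(np.count_nonzero(yes & (stim == 1)))
    fas = int(np.count_nonzero(yes & (stim == 0)))
    return _clamp_rate(hits, n_sig), _clamp_rate(fas, n_noise)


def meta_dprime(trials: pd.DataFrame, criterion: float) -> float:
    """Confidence-gated d' at a criterion.

    ``trials`` needs columns ``stimulus`` (0/1 class), ``response`` (0/1) and
    ``confidence``. Responses of 1 with confidence >= criterion count as the
    "yes" event; hit and false-alarm rates are recomputed from those and put
    through the normal quantile. At the floor criterion (every confidence
    qualifies) this reduces to the ordinary d' of the raw responses.
    """
    hr, far = _gated_rates(trials, criterion)
    return dprime(hr, far)


def raw_dprime(trials: pd.DataFrame) -> float:
    """Ordinary d' of the raw responses (criterion at the confidence floor)."""
    return meta_dprime(trials, -np.inf)


def efficiency_curve(trials: pd.DataFrame, criteria=None,
                     min_count: int = 50) -> pd.DataFrame:
    """meta-d'/d' across confidence criteria.

    Criteria default to the distinct confidence values achieved in the data
    (the model's confidence scale is discrete); criteria selecting fewer than
    ``min_count`` gated responses are dropped as too noisy to rate.
    """
    d = raw_dprime(trials)
    conf = trials["confidence"].to_numpy()
    resp = trials["response"].to_numpy()
    if criteria is None:
        criteria = np.unique(conf[resp == 1])
    rows = []
    for c in np.asarray(criteria, dtype=float):
        n_gated = int(np.count_nonzero((resp == 1) & (conf >= c)))
        if n_gated < min_count:
            continue
        md = meta_dprime(trials, c)
        rows.append({"criterion": c, "d_prime": d, "meta_d_prime": md,
                     "ratio": md / d, "n_gated": n_gated})
    return pd.DataFrame(rows)
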