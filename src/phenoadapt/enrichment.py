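"""Benefit-conditioned enrollment weights and enriched candidate sampling.

Predicted individualized log HRs are sign-flipped and min-max scaled to a
benefit score x in [0, 1] (1 = strongest predicted responder in the
batch).  The enrollment weight is a squared logistic transform

.. math:: p = \\sigma(k (x - (1 - z)))^2, \\qquad k = 10,

where z is the ratio of predicted responders (log HR < 0) to
non-responders in the population the model was validated on.  The center
1 - z shifts enrollment pressure: when most of the population responds
(large z) even moderate scores enroll with high probability.

Enrollment of a period's candidates is weighted sampling without
replacement of exactly ``ceil(q n)`` ids, so the enrichment level q from
the interim sample-size revision is hit deterministically while relative
weights still govern who is enrolled.  Treatment assignment is never
touched — arms remain randomized 1:1 among enrollees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError

SIGMOID_SCALE = 10.0


def benefit_to_x(predicted_loghr) -> np.ndarray:
    """Sign-flip and min-max scale predictions to [0, 1]; constants map to 0.5."""
    lhr = np.asarray(predicted_loghr, float)
    if len(lhr) < 2:
        raise ValidationError("need >=2 candidates to normalize")
    flipped = -lhr
    lo, hi = flipped.min(), flipped.max()
    if hi == lo:
        return np.full(len(lhr), 0.5)
    return (flipped - lo) / (hi - lo)


def enrollment_probability(x, z: float) -> np.ndarray:
    """Squared-sigmoid enrollment weight; monotone increasing in x."""
    if z <= 0:
        raise ValidationError("responder ratio z must be positive")
    x = np.asarray(x, float)
    sig = 1.0 / (1.0 + np.exp(-SIGMOID_SCALE * (x - (1.0 - z))))
    return sig**2


def responder_ratio(predicted_loghr) -> float:
    """Ratio of predicted responders (log HR < 0) to non-responders.

    With no non-responders the ratio is capped at the responder count.
    """
    lhr = np.asarray(predicted_loghr, float)
    if len(lhr) == 0:
        raise ValidationError("need >=1 prediction")
    resp = int((lhr < 0).sum())
    nonresp = len(lhr) - resp
    if nonresp == 0:
        return float(resp)
    return resp / nonresp


@dataclass(frozen=True)
class EnrollmentLog:
    """Per-candidate record of one enriched period."""

    ids: np.ndarray
    x: np.ndarray
    p: np.ndarray
    enrolled: np.ndarray  # boolean


def sample_period_candidates(candidate_ids, p, q: float, seed: int) -> np.ndarray:
    """Weighted without-replacement enrollment of ceil(q * n) candidates."""
    ids = np.asarray(candidate_ids)
    p = np.asarray(p, float)
    if len(ids) != len(p):
        raise ValidationError("one weight per candidate required")
    if (p <= 0).any():
        raise ValidationError("enrollment weights must be positive")
    m = max(1, int(np.ceil(q * len(ids))))
    m = min(m, len(ids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=m, replace=False, p=p / p.sum())
    return ids[np.sort(chosen)]
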