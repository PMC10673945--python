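"""Computational trial phenomaps: Gower dissimilarity and proximity weights.

Gower's distance for a pair of participants averages per-feature
contributions: for continuous features the absolute difference divided by
the observed range across the analysis population, and for categorical
(including binary) features a 0/1 mismatch indicator.  Distances live in
[0, 1] with 0 for phenotypically identical participants.

A participant's phenotypic neighborhood weight vector applies a cubic
transformation of similarity, :math:`w_j = \\mathrm{ReLU}((1 - d_{ij})^3)`,
so that weight decays sharply with phenotypic distance.  The ReLU guard is
mathematically redundant for distances in [0, 1] and is kept only against
numeric noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CONTINUOUS, ValidationError
from .preprocess import TransformedData


@dataclass
class PhenoMap:
    """Pairwise Gower dissimilarity over an ordered participant subset."""

    ids: np.ndarray
    D: np.ndarray
    feature_kinds: dict
    ranges: dict  # continuous feature -> observed range used for normalization

    def __post_init__(self) -> None:
        if self.D.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape mismatch")

    def index_of(self, participant_id) -> int:
        pos = np.flatnonzero(self.ids == participant_id)
        if len(pos) != 1:
            raise KeyError(f"unknown participant id {participant_id!r}")
        return int(pos[0])


def gower_matrix(td: TransformedData) -> PhenoMap:
    """Gower distance matrix from a preprocessed (imputed) mixed-type frame.

    Zero-range continuous features carry no information about dissimilarity
    and are excluded from the per-pair mean with a warning.
    """
    frame = td.gower_frame
    n = len(frame)
    if n < 2:
        raise ValidationError("need >=2 participants for a phenomap")
    acc = np.zeros((n, n))
    used = 0
    ranges: dict = {}
    for name in frame.columns:
        kind = td.kinds[name]
        if kind == CONTINUOUS:
            x = frame[name].to_numpy(float)
            rng = float(np.max(x) - np.min(x))
            ranges[name] = rng
            if rng == 0.0:
                warnings.warn(f"zero-range continuous feature {name!r} excluded from Gower mean")
                continue
            acc += np.abs(x[:, None] - x[None, :]) / rng
        else:
            x = frame[name].to_numpy()
            acc += (x[:, None] != x[None, :]).astype(float)
        used += 1
    if used == 0:
        raise ValidationError("no usable features for Gower distance")
    D = acc / used
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)  # enforce exact symmetry against float noise
    return PhenoMap(ids=np.asarray(td.ids), D=D, feature_kinds=dict(td.kinds), ranges=ranges)


@dataclass(frozen=True)
class WeightVector:
    index_id: object
    w: np.ndarray


def similarity_weights(pmap: PhenoMap, index_id) -> WeightVector:
    """Cubic proximity weights around one index participant; self-weight 1."""
    i = pmap.index_of(index_id)
    w = np.maximum(0.0, (1.0 - pmap.D[i]) ** 3)
    w[i] = 1.0
    return WeightVector(index_id=index_id, w=w)
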