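"""The per-interim modeling stage shared by the harness and stability loop.

One call runs the full chain on data censored at an interim cut: fit
preprocessing on the training half, build the phenomap, estimate
individualized log HR labels, winsorize them, Boruta-SHAP select
features, tune/fit the boosted benefit regressor, and predict on the
held-out half.  An empty feature selection is not an error — it simply
yields no model, which downstream treats as "no evidence of
heterogeneity" (the negative-control path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benefit import (
    BenefitModel,
    SelectionReport,
    boruta_shap_select,
    fit_benefit_model,
    predict_benefit,
    winsorize_labels,
)
from .core import SplitAssignment, TrialDataset
from .effects import BenefitLabels, individualized_loghr
from .phenomap import gower_matrix
from .preprocess import PipelineError, PreprocessFit, apply_preprocess, fit_preprocess


@dataclass
class InterimModel:
    """Everything fitted at one interim analysis."""

    preprocess: PreprocessFit
    labels: BenefitLabels
    selection: SelectionReport
    model: BenefitModel | None  # None when the selection is empty
    train_ids: np.ndarray
    test_ids: np.ndarray
    test_predictions: np.ndarray | None

    def predict(self, ds: TrialDataset) -> np.ndarray:
        """Predicted log HR for new candidates (pre-randomization data only)."""
        if self.model is None:
            raise PipelineError("no benefit model (empty feature selection)")
        td = apply_preprocess(self.preprocess, ds)
        return predict_benefit(self.model, td.X)


def fit_interim_model(
    cens_ds: TrialDataset,
    split: SplitAssignment,
    seed: int,
    n_grid: int = 25,
    min_weighted_events: float = 5.0,
) -> InterimModel:
    """Fit the full interim chain on an already-censored dataset."""
    train = cens_ds.subset(split.train_ids)
    test = cens_ds.subset(split.test_ids)

    pf = fit_preprocess(train, seed=seed)
    td_train = apply_preprocess(pf, train)
    pmap = gower_matrix(td_train)
    labels = individualized_loghr(train, pmap, min_weighted_events=min_weighted_events)
    labels, bounds = winsorize_labels(labels)

    valid = labels.valid()
    if len(valid) < 50:
        raise PipelineError(f"only {len(valid)} usable labels at this interim")
    X = td_train.X.loc[valid.index]
    selection = boruta_shap_select(X, valid.to_numpy(), seed=seed)

    model = None
    test_pred = None
    if selection.selected:
        model = fit_benefit_model(
            X, valid.to_numpy(), seed=seed, selection=selection,
            label_bounds=bounds, n_grid=n_grid,
        )
        td_test = apply_preprocess(pf, test)
        test_pred = predict_benefit(model, td_test.X)

    return InterimModel(
        preprocess=pf,
        labels=labels,
        selection=selection,
        model=model,
        train_ids=train.ids,
        test_ids=test.ids,
        test_predictions=test_pred,
    )
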