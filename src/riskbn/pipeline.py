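"""End-to-end country analysis: survey → selection → final network → report.

Mirrors the cross-country design: train a country-specific network with
CV10 noise-threshold selection on one sample, freeze its discretization,
and test it both within-sample and on the other country.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess, selection
from .evaluate import EvaluationReport, transfer_report
from .preprocess import FeatureFrame
from .selection import FinalModel, SelectionResult

__all__ = ["CountryAnalysis", "analyze_country", "cross_country_study"]


@dataclass
class CountryAnalysis:
    frame: FeatureFrame          # with noise columns injected
    selection: SelectionResult
    model: FinalModel
    seed: int


def prepare_frame(survey: pd.DataFrame, seed: int) -> FeatureFrame:
    """Derive analysis variables and inject the two shadow noise predictors."""
    frame = preprocess.build_feature_frame(survey)
    m, sd = preprocess.phq9_moments(survey)
    rate = preprocess.male_rate(survey)
    return preprocess.inject_noise_variables(frame, m, sd, rate, seed=seed)


def analyze_country(survey: pd.DataFrame, k: int = 5, alpha: float = 0.01,
                    pseudo_count: float = 1.0, seed: int = 0
                    ) -> CountryAnalysis:
    """Full single-country pipeline on a raw survey table."""
    ss = np.random.SeedSequence(seed)
    noise_seed, cv_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    frame = prepare_frame(survey, seed=noise_seed)
    sel = selection.cv10_select(frame, k=k, alpha=alpha,
                                pseudo_count=pseudo_count, seed=cv_seed)
    model = selection.fit_final_model(frame, sel.retained, k=k, alpha=alpha,
                                      pseudo_count=pseudo_count)
    return CountryAnalysis(frame, sel, model, seed)


def cross_country_study(survey_train: pd.DataFrame, survey_test: pd.DataFrame,
                        k: int = 5, alpha: float = 0.01,
                        pseudo_count: float = 1.0, threshold: float = 0.5,
                        seed: int = 0) -> tuple[CountryAnalysis, EvaluationReport]:
    """Train on one country, evaluate within-sample and on the other country."""
    analysis = analyze_country(survey_train, k=k, alpha=alpha,
                               pseudo_count=pseudo_count, seed=seed)
    test_frame = preprocess.build_feature_frame(survey_test)
    report = transfer_report(analysis.model, analysis.frame, test_frame,
                             threshold=threshold)
    return analysis, report
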