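"""Stage 2 — temporal features from the baseline motor-score sequence.

The two MDS-UPDRS-III scores (Years 0 and 1) are standardized with
mean/SD computed on the *training partition only*, passed as a length-2
sequence through an LSTM, and the final hidden state is linearly projected
to the configured feature width.  Like the Stage-1 extractors, the LSTM is
a deterministic seed-initialized network used as a fixed feature map.
"""

from __future__ import annotations

import numpy as np

from . import _nn
from .cohort import UPDRS3_MAX, PatientRecord
from .imaging import ExtractorSpec, FeatureVector

__all__ = ["updrs_lstm_features", "init_updrs_params", "UpdrsExtractor"]


def init_updrs_params(spec: ExtractorSpec, mean: float = 0.0, sd: float = 1.0) -> dict:
    """LSTM/projection parameters plus the frozen standardization stats."""
    if sd <= 0:
        raise ValueError("standardization sd must be positive")
    rng = np.random.default_rng(spec.seed + 2)
    return {
        "lstm": _nn.init_lstm(rng, 1, spec.lstm_hidden),
        "proj": _nn.init_linear(rng, spec.lstm_hidden, spec.output_width),
        "mean": float(mean),
        "sd": float(sd),
    }


def _validate_scores(scores: np.ndarray) -> None:
    if not np.all(np.isfinite(scores)):
        raise ValueError("motor scores must be finite")
    if np.any(scores < 0) or np.any(scores > UPDRS3_MAX):
        raise ValueError(f"motor scores must lie in [0, {UPDRS3_MAX}]")


def _updrs_batch(scores: np.ndarray, params: dict) -> np.ndarray:
    """scores: (B, 2) raw MDS-UPDRS-III -> (B, output_width)."""
    _validate_scores(scores)
    z = (scores - params["mean"]) / params["sd"]
    h = _nn.lstm_forward(z[:, :, None], params["lstm"])
    return _nn.linear_forward(h, params["proj"])


def updrs_lstm_features(scores, spec: ExtractorSpec, params: dict) -> FeatureVector:
    """Features from the ordered [Y0, Y1] motor-score pair."""
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != (2,):
        raise ValueError("expected exactly two scores")
    return FeatureVector("updrs_lstm", _updrs_batch(s[None], params)[0])


class UpdrsExtractor:
    """Stage-2 extractor: fit the standardizer on the training partition,
    then extract features for any record."""

    def __init__(self, spec: ExtractorSpec):
        self.spec = spec
        self.params = init_updrs_params(spec)
        self._fitted = False

    def fit(self, train_records: list[PatientRecord]) -> "UpdrsExtractor":
        scores = np.array(
            [[r.updrs3["Y0"], r.updrs3["Y1"]] for r in train_records], dtype=np.float64
        )
        _validate_scores(scores)
        mean = float(scores.mean())
        sd = float(scores.std(ddof=1))
        if sd == 0:
            raise ValueError("training scores are constant; cannot standardize")
        self.params["mean"], self.params["sd"] = mean, sd
        self._fitted = True
        return self

    @property
    def standardizer(self) -> tuple[float, float]:
        return self.params["mean"], self.params["sd"]

    def extract_batch(self, records: list[PatientRecord]) -> np.ndarray:
        scores = np.array(
            [[r.updrs3["Y0"], r.updrs3["Y1"]] for r in records], dtype=np.float64
        )
        return _updrs_batch(scores, self.params)

    def extract(self, record: PatientRecord) -> FeatureVector:
        return FeatureVector("updrs_lstm", self.extract_batch([record])[0])
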