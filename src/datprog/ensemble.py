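"""Stage 3 — feature fusion, network training, and ensemble averaging.

Each network concatenates a subset of the Stage-1 imaging features with the
Stage-2 motor features and the clinical covariate block, and feeds them to
a fully connected regression head (linear -> batch-norm -> ReLU -> dropout
-> linear) trained with Adam on a mean-absolute-error loss.  Eleven
networks are trained, one per imaging-feature combination (the seven
non-empty subsets of {ConvLSTM-DaTscan, semi-quantitative, All-ImageNet}
plus the four single backbones); their predictions are averaged, unweighted,
into the final ensemble estimate of the Year-4 MDS-UPDRS-III score.

Concatenation order is fixed: imaging blocks in the order ConvLSTM,
semi-quantitative, vgg16, resnet50, densenet121, inceptionv3; then the
motor-feature block; then the clinical block [age, sex(male=1),
years-since-diagnosis, years-since-symptom-onset], continuous covariates
z-scored on the training partition.  Targets are z-scored on the training
partition inside training and predictions mapped back to raw score units;
logged history is in raw units.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np

from ._nn import FusionHead
from .cohort import PatientRecord
from .imaging import BACKBONE_NAMES, ImagingExtractor
from .motor import UpdrsExtractor

__all__ = [
    "COMBO_TOKENS",
    "FeatureSetCombo",
    "InputAblation",
    "TrainingConfig",
    "TrainedNetwork",
    "EnsembleModel",
    "ConfigurationError",
    "table1_combos",
    "table2_ablations",
    "FULL_ABLATION",
    "FeatureAssembler",
    "assemble_inputs",
    "fusion_forward",
    "train_network",
    "grid_search",
    "build_table1_ensemble",
    "ensemble_predict",
    "desk_scale_config",
]

COMBO_TOKENS = (
    "datscan_convlstm",
    "semiquant",
    "all_imagenet",
    "vgg16",
    "resnet50",
    "densenet121",
    "inceptionv3",
)

# imaging-token -> ordered feature-block names
_TOKEN_BLOCKS = {
    "datscan_convlstm": ("convlstm_datscan",),
    "semiquant": ("semiquant_lstm",),
    "all_imagenet": tuple(f"backbone_{n}" for n in BACKBONE_NAMES),
    **{n: (f"backbone_{n}",) for n in BACKBONE_NAMES},
}
# fixed global concatenation order of imaging blocks
_IMAGING_BLOCK_ORDER = ("convlstm_datscan", "semiquant_lstm") + tuple(
    f"backbone_{n}" for n in BACKBONE_NAMES
)


class ConfigurationError(ValueError):
    """A combo or ablation requested features that were not extracted."""


@dataclass(frozen=True)
class FeatureSetCombo:
    """One row of the eleven imaging-feature combinations."""

    id: int
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("combo must be non-empty")
        unknown = set(self.members) - set(COMBO_TOKENS)
        if unknown:
            raise ValueError(f"unknown combo members {sorted(unknown)}")
        object.__setattr__(self, "members", frozenset(self.members))

    @property
    def blocks(self) -> tuple[str, ...]:
        wanted = {b for m in self.members for b in _TOKEN_BLOCKS[m]}
        return tuple(b for b in _IMAGING_BLOCK_ORDER if b in wanted)


def table1_combos() -> list[FeatureSetCombo]:
    """The eleven imaging-feature combinations: all non-empty subsets of
    {ConvLSTM-DaTscan, semi-quantitative, All-ImageNet} plus the four
    individual backbones."""
    rows = [
        {"datscan_convlstm", "semiquant", "all_imagenet"},
        {"datscan_convlstm", "semiquant"},
        {"datscan_convlstm", "all_imagenet"},
        {"semiquant", "all_imagenet"},
        {"datscan_convlstm"},
        {"semiquant"},
        {"all_imagenet"},
        {"vgg16"},
        {"resnet50"},
        {"densenet121"},
        {"inceptionv3"},
    ]
    return [FeatureSetCombo(i + 1, frozenset(m)) for i, m in enumerate(rows)]


@dataclass(frozen=True)
class InputAblation:
    """One row of the four input-subset ablations."""

    id: int
    use_datscan: bool = True
    use_updrs: bool = True
    use_clinical: bool = True


FULL_ABLATION = InputAblation(1, True, True, True)


def table2_ablations() -> list[InputAblation]:
    """All inputs; no clinical; no DaTscan; no MDS-UPDRS-III."""
    return [
        InputAblation(1, True, True, True),
        InputAblation(2, True, True, False),
        InputAblation(3, False, True, True),
        InputAblation(4, True, False, True),
    ]


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol: MAE loss and the Adam optimizer are fixed."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout_p: float = 0.5
    hidden_width: int = 32
    seed: int = 0
    loss: str = "mae"
    optimizer: str = "adam"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.hidden_width < 1:
            raise ValueError("epochs, batch_size and hidden_width must be positive")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.loss != "mae" or self.optimizer != "adam":
            raise ValueError("loss is fixed to MAE and the optimizer to Adam")


def desk_scale_config(seed: int = 0, epochs: int = 30) -> TrainingConfig:
    """Reduced-epoch configuration for CPU-scale runs.  The learning rate is
    raised to 2e-2 because Adam's per-step update magnitude is bounded by
    the learning rate, and ~120 updates must traverse the unit scale of the
    standardized target."""
    return TrainingConfig(epochs=epochs, learning_rate=2e-2, seed=seed)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ("age_years", "sex01", "years_since_diagnosis", "years_since_symptom_onset")


class FeatureAssembler:
    """Bundles the fitted extractors and turns records into feature blocks
    and assembled input matrices.

    ``fit`` computes every training-partition statistic (motor-score
    standardizer, clinical covariate z-scoring); nothing is ever fitted on
    validation or test records.
    """

    def __init__(self, imaging: ImagingExtractor, updrs: UpdrsExtractor):
        self.imaging = imaging
        self.updrs = updrs
        self.clinical_mean: np.ndarray | None = None
        self.clinical_sd: np.ndarray | None = None

    def fit(self, train_records: list[PatientRecord]) -> "FeatureAssembler":
        self.updrs.fit(train_records)
        raw = self._clinical_raw(train_records)
        mean = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        mean[1], sd[1] = 0.0, 1.0  # sex stays a 0/1 indicator
        self.clinical_mean, self.clinical_sd = mean, sd
        return self

    @staticmethod
    def _clinical_raw(records: list[PatientRecord]) -> np.ndarray:
        return np.array(
            [
                [
                    r.age_years,
                    1.0 if r.sex == "male" else 0.0,
                    r.years_since_diagnosis,
                    r.years_since_symptom_onset,
                ]
                for r in records
            ]
        )

    def blocks(self, records: list[PatientRecord]) -> dict[str, np.ndarray]:
        """All feature blocks for a record list: the six imaging provenances,
        the motor block and the clinical block."""
        if self.clinical_mean is None:
            raise RuntimeError("FeatureAssembler.fit must run on the training partition first")
        out = self.imaging.extract_batch(records)
        out["updrs_lstm"] = self.updrs.extract_batch(records)
        out["clinical"] = (self._clinical_raw(records) - self.clinical_mean) / self.clinical_sd
        return out

    @staticmethod
    def block_layout(
        combo: FeatureSetCombo | None, ablation: InputAblation = FULL_ABLATION
    ) -> tuple[str, ...]:
        """Ordered block names a network with this combo/ablation consumes."""
        names: list[str] = []
        if ablation.use_datscan and combo is not None:
            names.extend(combo.blocks)
        if ablation.use_updrs:
            names.append("updrs_lstm")
        if ablation.use_clinical:
            names.append("clinical")
        if not names:
            raise ConfigurationError("ablation removes every input block")
        return tuple(names)

    def assemble(
        self,
        blocks: dict[str, np.ndarray],
        combo: FeatureSetCombo | None,
        ablation: InputAblation = FULL_ABLATION,
    ) -> np.ndarray:
        """Concatenate the requested blocks (fixed documented order)."""
        names = self.block_layout(combo, ablation)
        missing = [n for n in names if n not in blocks]
        if missing:
            raise ConfigurationError(f"feature blocks not extracted: {missing}")
        return np.concatenate([blocks[n] for n in names], axis=1)


def assemble_inputs(
    record: PatientRecord,
    assembler: FeatureAssembler,
    combo: FeatureSetCombo | None,
    ablation: InputAblation = FULL_ABLATION,
) -> np.ndarray:
    """Assembled input vector for a single record."""
    return assembler.assemble(assembler.blocks([record]), combo, ablation)[0]


# ---------------------------------------------------------------------------
# trained networks and the ensemble
# ---------------------------------------------------------------------------


@dataclass
class TrainedNetwork:
    """One fusion network with its learned head parameters.

    The frozen extractor parameters are not part of this object; only the
    fusion head is learned.  Predictions are in raw MDS-UPDRS-III units.
    """

    combo: FeatureSetCombo | None
    ablation: InputAblation
    head: FusionHead
    block_names: tuple[str, ...]
    feature_widths: dict[str, int]
    training_history: list[tuple[float, float]]
    seed: int
    y_mean: float
    y_sd: float

    def predict_blocks(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        X = np.concatenate([blocks[n] for n in self.block_names], axis=1)
        return self.head.forward(X) * self.y_sd + self.y_mean

    def predict(self, records: list[PatientRecord], assembler: FeatureAssembler) -> np.ndarray:
        return self.predict_blocks(assembler.blocks(records))


@dataclass
class EnsembleModel:
    """Unweighted average of member network predictions."""

    members: list[TrainedNetwork]

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    aggregation: str = "mean"

    def predict_blocks(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        return np.mean([m.predict_blocks(blocks) for m in self.members], axis=0)

    def predict(self, records: list[PatientRecord], assembler: FeatureAssembler) -> np.ndarray:
        return self.predict_blocks(assembler.blocks(records))


def fusion_forward(features: np.ndarray, network: TrainedNetwork | FusionHead) -> np.ndarray:
    """Inference-mode forward pass of the fusion head on assembled features
    (batch-norm uses running statistics, dropout is off), returning scores
    in raw units for a TrainedNetwork or standardized units for a bare head."""
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if isinstance(network, TrainedNetwork):
        return network.head.forward(x) * network.y_sd + network.y_mean
    return network.forward(x)


def _targets(records: list[PatientRecord]) -> np.ndarray:
    missing = [r.patient_id for r in records if r.outcome_y4 is None]
    if missing:
        raise ValueError(f"records lack Year-4 outcomes: {missing[:3]}")
    return np.array([r.outcome_y4 for r in records], dtype=np.float64)


def train_network(
    train: list[PatientRecord],
    validation: list[PatientRecord],
    combo: FeatureSetCombo | None,
    ablation: InputAblation,
    config: TrainingConfig,
    assembler: FeatureAssembler,
    train_blocks: dict[str, np.ndarray] | None = None,
    val_blocks: dict[str, np.ndarray] | None = None,
) -> TrainedNetwork:
    """Train one fusion network on the given partitions.

    Precomputed feature blocks may be passed to avoid re-extracting when
    many networks share one cohort.  Fully reproducible given config.seed.
    """
    if not train or not validation:
        raise ValueError("training and validation partitions must be nonempty")
    if set(r.patient_id for r in train) & set(r.patient_id for r in validation):
        raise ValueError("training and validation partitions overlap")
    tb = train_blocks if train_blocks is not None else assembler.blocks(train)
    vb = val_blocks if val_blocks is not None else assembler.blocks(validation)
    X = assembler.assemble(tb, combo, ablation)
    Xv = assembler.assemble(vb, combo, ablation)
    y = _targets(train)
    yv = _targets(validation)
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    if y_sd == 0:
        y_sd = 1.0
    head = FusionHead(X.shape[1], config.hidden_width, config.dropout_p, seed=config.seed)
    history_z = head.fit(
        X,
        (y - y_mean) / y_sd,
        Xv,
        (yv - y_mean) / y_sd,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    names = FeatureAssembler.block_layout(combo, ablation)
    return TrainedNetwork(
        combo=combo,
        ablation=ablation,
        head=head,
        block_names=names,
        feature_widths={n: tb[n].shape[1] for n in names},
        training_history=[(tr * y_sd, va * y_sd) for tr, va in history_z],
        seed=config.seed,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def grid_search(
    grid: dict[str, list],
    train: list[PatientRecord],
    validation: list[PatientRecord],
    combo: FeatureSetCombo | None,
    ablation: InputAblation,
    config: TrainingConfig,
    assembler: FeatureAssembler,
) -> tuple[TrainingConfig, list[tuple[dict, float]]]:
    """Exhaustive Cartesian grid search over TrainingConfig fields, selecting
    the lowest final validation MAE; ties break to the first candidate in
    lexicographic grid order."""
    if not grid:
        raise ValueError("grid must be nonempty")
    tb = assembler.blocks(train)
    vb = assembler.blocks(validation)
    keys = list(grid)
    results: list[tuple[dict, float]] = []
    best: tuple[float, TrainingConfig] | None = None
    for values in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, values))
        cand = dataclasses.replace(config, **overrides)
        net = train_network(train, validation, combo, ablation, cand, assembler, tb, vb)
        val_mae = net.training_history[-1][1]
        results.append((overrides, val_mae))
        if best is None or val_mae < best[0]:
            best = (val_mae, cand)
    return best[1], results


def build_table1_ensemble(
    train: list[PatientRecord],
    validation: list[PatientRecord],
    config: TrainingConfig,
    assembler: FeatureAssembler,
    train_blocks: dict[str, np.ndarray] | None = None,
    val_blocks: dict[str, np.ndarray] | None = None,
) -> EnsembleModel:
    """Train the eleven member networks (one per imaging-feature combination,
    each also receiving the motor and clinical blocks) and bundle them as
    the ensemble.  Member seeds are config.seed + combo id."""
    tb = train_blocks if train_blocks is not None else assembler.blocks(train)
    vb = val_blocks if val_blocks is not None else assembler.blocks(validation)
    members = []
    for combo in table1_combos():
        member_cfg = dataclasses.replace(config, seed=config.seed + combo.id)
        members.append(
            train_network(train, validation, combo, FULL_ABLATION, member_cfg, assembler, tb, vb)
        )
    return EnsembleModel(members=members)


def ensemble_predict(
    model: EnsembleModel, records: list[PatientRecord], assembler: FeatureAssembler
) -> np.ndarray:
    """Per-record unweighted mean of the member predictions."""
    return model.predict(records, assembler)
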