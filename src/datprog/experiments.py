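"""Experiment orchestration: ensemble evaluation, input ablations, and the
imaging-feature-combination comparison.

All three experiments share, for a given master seed, one cohort, one
train/validation/test split, and one set of frozen extractors; the master
seed also derives every member network's training seed, so an experiment
directory (config + seeds) reproduces its outputs exactly.

In the input-ablation experiment the "DaTscan" block refers to the
convolutional-LSTM imaging features only, and its four networks are trained
fresh; the feature-combination experiment compares the eleven trained
member networks with their own ensemble average.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSpec, PatientRecord, generate_cohort, read_cohort, split_cohort
from .ensemble import (
    EnsembleModel,
    FeatureAssembler,
    FeatureSetCombo,
    TrainedNetwork,
    TrainingConfig,
    build_table1_ensemble,
    table2_ablations,
    train_network,
)
from .evaluation import (
    EvaluationReport,
    PredictionSet,
    diff_squared_errors,
    evaluate_predictions,
    plot_bland_altman,
    plot_scatter_with_bands,
)
from .imaging import BackboneId, ExtractorSpec, ImagingExtractor
from .motor import UpdrsExtractor

__all__ = [
    "ExperimentConfig",
    "PreparedCohort",
    "prepare_cohort",
    "run_ensemble_experiment",
    "run_ablation_table2",
    "run_combos_table1",
    "save_network",
    "table1_label",
]

_TOKEN_LABEL = {
    "datscan_convlstm": "DaTscan",
    "semiquant": "Semi-quantitative",
    "all_imagenet": "All ImageNet",
    "vgg16": "VGG16",
    "resnet50": "ResNet50",
    "densenet121": "DenseNet121",
    "inceptionv3": "InceptionV3",
}
_TOKEN_ORDER = list(_TOKEN_LABEL)


def table1_label(combo: FeatureSetCombo) -> str:
    toks = sorted(combo.members, key=_TOKEN_ORDER.index)
    return " + ".join(_TOKEN_LABEL[t] for t in toks)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    cohort: CohortSpec | str = field(default_factory=CohortSpec)
    master_seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)
    extractor: ExtractorSpec = field(default_factory=ExtractorSpec)
    backbones: tuple[str, ...] = ("vgg16", "resnet50", "densenet121", "inceptionv3")
    experiment: str = "ensemble"
    output_dir: str | None = None
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self):
        if self.experiment not in ("ensemble", "ablation_table2", "combos_table1"):
            raise ValueError(f"unknown experiment {self.experiment!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        d = json.loads(Path(path).read_text())
        if isinstance(d.get("cohort"), dict):
            c = d["cohort"]
            for key in ("volume_shape", "voxel_spacing"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = CohortSpec(**c)
        if isinstance(d.get("training"), dict):
            d["training"] = TrainingConfig(**d["training"])
        if isinstance(d.get("extractor"), dict):
            e = d["extractor"]
            if "conv_kernel" in e:
                e["conv_kernel"] = tuple(e["conv_kernel"])
            d["extractor"] = ExtractorSpec(**e)
        for key in ("backbones", "split_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PreparedCohort:
    """A cohort split into partitions with all feature blocks extracted."""

    records: list[PatientRecord]
    train: list[PatientRecord]
    validation: list[PatientRecord]
    test: list[PatientRecord]
    assembler: FeatureAssembler
    train_blocks: dict[str, np.ndarray]
    val_blocks: dict[str, np.ndarray]
    test_blocks: dict[str, np.ndarray]


def prepare_cohort(config: ExperimentConfig) -> PreparedCohort:
    """Generate (or load) the cohort, split it, fit the training-partition
    statistics, and extract every feature block once.

    The master seed overrides the cohort, extractor and split seeds so a
    single integer reproduces the whole run.
    """
    if isinstance(config.cohort, (str, Path)):
        records = read_cohort(config.cohort)
    else:
        spec = dataclasses.replace(config.cohort, seed=config.master_seed)
        records = generate_cohort(spec)
    train, val, test = split_cohort(records, config.split_fractions, seed=config.master_seed)
    ex_spec = dataclasses.replace(config.extractor, seed=config.master_seed)
    imaging = ImagingExtractor(ex_spec, tuple(BackboneId(name=n) for n in config.backbones))
    assembler = FeatureAssembler(imaging, UpdrsExtractor(ex_spec)).fit(train)
    return PreparedCohort(
        records=records,
        train=train,
        validation=val,
        test=test,
        assembler=assembler,
        train_blocks=assembler.blocks(train),
        val_blocks=assembler.blocks(val),
        test_blocks=assembler.blocks(test),
    )


def _master_training(config: ExperimentConfig) -> TrainingConfig:
    return dataclasses.replace(config.training, seed=config.master_seed)


def _test_prediction_set(
    model, prep: PreparedCohort
) -> PredictionSet:
    pred = model.predict_blocks(prep.test_blocks)
    obs = np.array([r.outcome_y4 for r in prep.test])
    return PredictionSet(obs, pred, [r.patient_id for r in prep.test])


def save_network(net: TrainedNetwork, directory: str | Path) -> None:
    """Checkpoint one trained network: head parameters (npz), run metadata
    (JSON) and the per-epoch training history (CSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "head_params.npz",
        running_mean=net.head.running_mean,
        running_var=net.head.running_var,
        **net.head.params,
    )
    meta = {
        "combo": None if net.combo is None else
            {"id": net.combo.id, "members": sorted(net.combo.members)},
        "ablation": dataclasses.asdict(net.ablation),
        "block_names": list(net.block_names),
        "feature_widths": net.feature_widths,
        "seed": net.seed,
        "y_mean": net.y_mean,
        "y_sd": net.y_sd,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(net.training_history, columns=["train_mae", "val_mae"]).to_csv(
        directory / "history.csv", index_label="epoch"
    )


def _write_common(config: ExperimentConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")


def run_ensemble_experiment(
    config: ExperimentConfig, prep: PreparedCohort | None = None
) -> tuple[EnsembleModel, EvaluationReport]:
    """Train the eleven-member ensemble and evaluate it on the test set."""
    if prep is None:
        prep = prepare_cohort(config)
    model = build_table1_ensemble(
        prep.train, prep.validation, _master_training(config), prep.assembler,
        prep.train_blocks, prep.val_blocks,
    )
    pset = _test_prediction_set(model, prep)
    report = evaluate_predictions(pset)
    if config.output_dir:
        out = Path(config.output_dir)
        _write_common(config, out)
        pset.to_csv(out / "predictions.csv")
        report.to_json(out / "report.json")
        for member in model.members:
            save_network(member, out / f"member_{member.combo.id:02d}")
        plot_scatter_with_bands(pset, report.regression, out / "scatter.png")
        plot_bland_altman(pset, report.bland_altman, out / "bland_altman.png")
    return model, report


def run_ablation_table2(
    config: ExperimentConfig, prep: PreparedCohort | None = None
) -> dict:
    """Train the four input-ablation networks plus the ensemble on identical
    partitions; report per-network evaluations and the difference of squared
    errors of each network against the ensemble."""
    if prep is None:
        prep = prepare_cohort(config)
    base = _master_training(config)
    ensemble = build_table1_ensemble(
        prep.train, prep.validation, base, prep.assembler,
        prep.train_blocks, prep.val_blocks,
    )
    ens_pset = _test_prediction_set(ensemble, prep)
    convlstm_combo = FeatureSetCombo(5, frozenset({"datscan_convlstm"}))
    results = {"ensemble": evaluate_predictions(ens_pset), "ablations": {}}
    obs = ens_pset.observed
    for ablation in table2_ablations():
        cfg = dataclasses.replace(base, seed=base.seed + 100 + ablation.id)
        combo = convlstm_combo if ablation.use_datscan else None
        net = train_network(
            prep.train, prep.validation, combo, ablation, cfg, prep.assembler,
            prep.train_blocks, prep.val_blocks,
        )
        pset = _test_prediction_set(net, prep)
        results["ablations"][ablation.id] = {
            "ablation": ablation,
            "network": net,
            "report": evaluate_predictions(pset),
            "vs_ensemble": diff_squared_errors(pset.predicted, ens_pset.predicted, obs),
        }
    if config.output_dir:
        out = Path(config.output_dir)
        _write_common(config, out)
        ens_pset.to_csv(out / "predictions_ensemble.csv")
        results["ensemble"].to_json(out / "report_ensemble.json")
        for aid, res in results["ablations"].items():
            res["report"].to_json(out / f"report_ablation_{aid}.json")
            save_network(res["network"], out / f"ablation_{aid}")
    return results


def run_combos_table1(
    config: ExperimentConfig, prep: PreparedCohort | None = None
) -> dict:
    """Evaluate each of the eleven member networks and their ensemble; emit a
    summary table with MAPE, MAE, MSE, r and R^2 (with 95% CIs) per row and
    the difference of squared errors of each member against the ensemble."""
    if prep is None:
        prep = prepare_cohort(config)
    model = build_table1_ensemble(
        prep.train, prep.validation, _master_training(config), prep.assembler,
        prep.train_blocks, prep.val_blocks,
    )
    ens_pset = _test_prediction_set(model, prep)
    obs = ens_pset.observed

    rows = []
    reports = {"ensemble": evaluate_predictions(ens_pset)}
    diffs = {}

    def row_from(label: str, rep: EvaluationReport) -> dict:
        return {
            "method": label,
            "MAPE": None if rep.mape is None else rep.mape.estimate,
            "MAPE_ci": None if rep.mape is None else (rep.mape.ci_low, rep.mape.ci_high),
            "MAE": rep.mae.estimate,
            "MAE_ci": (rep.mae.ci_low, rep.mae.ci_high),
            "MSE": rep.mse.estimate,
            "MSE_ci": (rep.mse.ci_low, rep.mse.ci_high),
            "r": rep.pearson_r,
            "R2": rep.regression.r_squared,
        }

    rows.append(row_from("Ensemble approach", reports["ensemble"]))
    for member in model.members:
        pset = _test_prediction_set(member, prep)
        rep = evaluate_predictions(pset)
        label = table1_label(member.combo)
        reports[label] = rep
        diffs[label] = diff_squared_errors(pset.predicted, ens_pset.predicted, obs)
        rows.append(row_from(label, rep))
    summary = pd.DataFrame(rows)

    if config.output_dir:
        out = Path(config.output_dir)
        _write_common(config, out)
        summary.to_csv(out / "summary_table1.csv", index=False)
        ens_pset.to_csv(out / "predictions_ensemble.csv")
        for member in model.members:
            save_network(member, out / f"member_{member.combo.id:02d}")
    return {"model": model, "summary": summary, "reports": reports, "vs_ensemble": diffs}
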