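"""End-to-end study reconstruction.

Stage order: generate (or load) the dataset -> stratified 88/32 split and
PLSDA classification per block -> DUPLEX 60/30/30 split on the autoscaled
fused spectra -> MWPLS interval selection on the calibration set ->
OSWLS-SVM calibration against the monitoring set -> prediction-set
validation (recovery, RMSEP, paired t-test, EJCR) and block ranking.

Every stage draws its seed deterministically from the master seed, so a
run is reproducible from its YAML config alone.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mwpls as mw
from . import split as sp
from .io import fuse_blocks
from .plsda import ClassificationReport, classify, figures_of_merit, fit_plsda, select_n_lv
from .synthetic import GeneratorConfig, TeaDataset, generate_dataset
from .validate import CalibrationReport, ModelRanking, calibration_report, compare_models, rmse
from .wlssvm import PSOConfig, oswls_svm_train

log = logging.getLogger("teaspec")

CLASSIFICATION_BLOCKS = ("mir", "nir")
ALL_BLOCKS = ("mir", "nir", "fused")


@dataclass
class RunConfig:
    """Single-document configuration for a full study run."""

    seed: int = 0
    # generator
    n_classes: int = 12
    n_per_class: int = 10
    separation: float = 1.0
    within_class_cv: float = 0.05
    noise_sd: float = 0.003
    mir_points: int = 1869
    nir_points: int = 1557
    # classification
    train_counts: tuple[int, ...] = sp.STUDY_TRAIN_COUNTS
    classification_blocks: tuple[str, ...] = CLASSIFICATION_BLOCKS
    max_lv: int = 15
    # calibration
    duplex_sizes: tuple[int, int, int] = sp.STUDY_DUPLEX_SIZES
    blocks: tuple[str, ...] = ALL_BLOCKS
    targets: tuple[str, ...] = ("dpph", "abts")
    mwpls_width: int = mw.DEFAULT_WINDOW_WIDTH
    mwpls_max_lv: int = mw.DEFAULT_LV_CAP
    ssr_quantile: float = mw.DEFAULT_SSR_QUANTILE
    pso_cycles: int = 70
    swarm_size: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("train_counts", "classification_blocks", "duplex_sizes", "blocks", "targets"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_classes=self.n_classes,
            n_per_class=self.n_per_class,
            separation=self.separation,
            within_class_cv=self.within_class_cv,
            noise_sd=self.noise_sd,
            mir_points=self.mir_points,
            nir_points=self.nir_points,
            seed=derive_seed(self.seed, "generate"),
        )


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of the stage label mixed with the
    master seed through a SeedSequence, reduced below 2^31."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class BlockClassification:
    block: str
    n_lv: int
    train_report: ClassificationReport
    test_report: ClassificationReport


def _block_matrix(dataset: TeaDataset, block: str):
    """Matrix, wavenumbers and per-column tags for one block choice."""
    if block == "mir":
        return dataset.mir.matrix, dataset.mir.wavenumbers, np.full(
            dataset.mir.n_variables, dataset.mir.tag, dtype=object
        )
    if block == "nir":
        return dataset.nir.matrix, dataset.nir.wavenumbers, np.full(
            dataset.nir.n_variables, dataset.nir.tag, dtype=object
        )
    if block == "fused":
        fused = fuse_blocks([dataset.mir, dataset.nir], scaling="none")
        return fused.matrix, fused.column_wavenumbers, fused.column_tags
    raise ValueError(f"unknown block {block!r}")


def run_classification(
    config: RunConfig, dataset: TeaDataset | None = None
) -> dict[str, BlockClassification]:
    """PLSDA species/grade discrimination per block on the 88/32 split."""
    if dataset is None:
        dataset = generate_dataset(config.generator_config())
    plan = sp.stratified_split(
        dataset.labels, config.train_counts, seed=derive_seed(config.seed, "stratified")
    )
    train, test = plan.indices(sp.TRAIN), plan.indices(sp.TEST)
    n_classes = config.n_classes
    results: dict[str, BlockClassification] = {}
    for block in config.classification_blocks:
        X, _, _ = _block_matrix(dataset, block)
        from .plsda import dummy_code

        coding = dummy_code(dataset.labels[train], n_classes)
        n_lv = select_n_lv(X[train], coding.matrix, config.max_lv, mode="classification")
        model, _ = fit_plsda(X[train], dataset.labels[train], n_lv, n_classes)
        pred_train = classify(model, X[train])
        pred_test = classify(model, X[test])
        results[block] = BlockClassification(
            block=block,
            n_lv=n_lv,
            train_report=figures_of_merit(dataset.labels[train], pred_train, n_classes),
            test_report=figures_of_merit(dataset.labels[test], pred_test, n_classes),
        )
        log.info(
            "classification [%s]: %d LVs, train acc %.3f, test acc %.3f",
            block,
            n_lv,
            results[block].train_report.accuracy,
            results[block].test_report.accuracy,
        )
    return results


@dataclass
class CalibrationResult:
    plan: sp.SplitPlan
    reports: dict[tuple[str, str], CalibrationReport]
    intervals: dict[tuple[str, str], mw.SelectedIntervals]
    rankings: dict[str, ModelRanking]
    models: dict[tuple[str, str], object] = field(default_factory=dict)


def _autoscale_for_geometry(matrix: np.ndarray) -> np.ndarray:
    sd = matrix.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (matrix - matrix.mean(axis=0)) / sd


def run_calibration(
    config: RunConfig, dataset: TeaDataset | None = None
) -> CalibrationResult:
    """MWPLS + OSWLS-SVM calibration of the antioxidant responses.

    One DUPLEX plan (computed on the autoscaled fused spectra, so distances
    are scale-free across blocks) is shared by all blocks and targets.
    Within each branch the block matrix is standardized column-wise using
    calibration-set statistics before MWPLS and the kernel model.
    """
    if dataset is None:
        dataset = generate_dataset(config.generator_config())
    fused = fuse_blocks([dataset.mir, dataset.nir], scaling="none")
    plan = sp.duplex_split(_autoscale_for_geometry(fused.matrix), config.duplex_sizes)
    cal = plan.indices(sp.CALIBRATION)
    val = plan.indices(sp.VALIDATION)
    pred = plan.indices(sp.PREDICTION)

    reports: dict[tuple[str, str], CalibrationReport] = {}
    intervals: dict[tuple[str, str], mw.SelectedIntervals] = {}
    models: dict[tuple[str, str], object] = {}
    for block in config.blocks:
        X, wavenumbers, tags = _block_matrix(dataset, block)
        mu = X[cal].mean(axis=0)
        sd = X[cal].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        for target in config.targets:
            y = dataset.response(target)
            rmap = mw.residue_lines(
                Xs[cal],
                y[cal],
                wavenumbers,
                window_width=config.mwpls_width,
                max_lv=config.mwpls_max_lv,
                column_tags=tags,
            )
            sel = mw.select_intervals(rmap, ssr_quantile=config.ssr_quantile)
            mask = sel.column_mask
            log.info(
                "calibration [%s/%s]: %d intervals, %d variables selected",
                block,
                target,
                len(sel),
                int(mask.sum()),
            )
            Xsel = Xs[:, mask]
            model = oswls_svm_train(
                Xsel[cal],
                y[cal],
                Xsel[val],
                y[val],
                pso=PSOConfig(
                    n_cycles=config.pso_cycles,
                    swarm_size=config.swarm_size,
                    seed=derive_seed(config.seed, f"pso-{block}-{target}"),
                ),
            )
            rmsec = rmse(y[cal], model.predict(Xsel[cal]))
            report = calibration_report(block, target, y[pred], model.predict(Xsel[pred]), rmsec)
            reports[(block, target)] = report
            intervals[(block, target)] = sel
            models[(block, target)] = model
            log.info(
                "calibration [%s/%s]: RMSEC %.4g, RMSEP %.4g, recovery %.1f +/- %.1f %%",
                block,
                target,
                report.rmsec,
                report.rmsep,
                report.mean_recovery,
                report.sd_recovery,
            )
    rankings = {
        target: compare_models({b: reports[(b, target)] for b in config.blocks})
        for target in config.targets
        if len(config.blocks) >= 2
    }
    return CalibrationResult(
        plan=plan, reports=reports, intervals=intervals, rankings=rankings, models=models
    )


def _classification_frame(results: dict[str, BlockClassification]) -> pd.DataFrame:
    rows = []
    for block, res in results.items():
        for k in range(res.test_report.n_classes):
            rows.append(
                {
                    "block": block,
                    "group": f"G{k + 1:02d}",
                    "SEN": res.test_report.sensitivity[k],
                    "SEL": res.test_report.selectivity[k],
                }
            )
    return pd.DataFrame(rows)


def _calibration_frame(result: CalibrationResult, target: str, blocks) -> pd.DataFrame:
    first = result.reports[(blocks[0], target)]
    frame = pd.DataFrame({"sample": np.arange(1, first.actual.size + 1)})
    for block in blocks:
        rep = result.reports[(block, target)]
        frame[f"actual_{block}"] = rep.actual
        frame[f"recovery_{block}"] = rep.recoveries
    return frame


def run_study(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Full reconstruction: classification + calibration (+ artifacts)."""
    dataset = generate_dataset(config.generator_config())
    classification = run_classification(config, dataset)
    calibration = run_calibration(config, dataset)

    summary = {
        "seed": config.seed,
        "n_samples": dataset.n_samples,
        "classification": {
            block: {
                "n_lv": res.n_lv,
                "train_accuracy": res.train_report.accuracy,
                "test_accuracy": res.test_report.accuracy,
                "min_sen": float(np.nanmin(res.test_report.sensitivity)),
                "min_sel": float(np.nanmin(res.test_report.selectivity)),
            }
            for block, res in classification.items()
        },
        "calibration": {
            f"{block}/{target}": {
                "rmsec": rep.rmsec,
                "rmsep": rep.rmsep,
                "mean_recovery": rep.mean_recovery,
                "sd_recovery": rep.sd_recovery,
                "correlation": rep.correlation,
                "slope": rep.slope,
                "intercept": rep.intercept,
                "t": rep.t_statistic,
                "t_critical": rep.t_critical,
                "ejcr_contains_ideal": rep.ejcr.contains_ideal,
                "ejcr_area": rep.ejcr.area,
            }
            for (block, target), rep in calibration.reports.items()
        },
        "ranking": {
            target: {"order": rk.order, "fused_wins": rk.fused_wins}
            for target, rk in calibration.rankings.items()
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        calibration.plan.to_csv(outdir / "duplex_plan.csv", sample_ids=dataset.sample_ids)
        _classification_frame(classification).to_csv(outdir / "classification.csv", index=False)
        for target in config.targets:
            _calibration_frame(calibration, target, config.blocks).to_csv(
                outdir / f"calibration_{target}.csv", index=False
            )
        interval_rows = [
            {"block": block, "target": target, "high_cm1": hi, "low_cm1": lo, "source": tag}
            for (block, target), sel in calibration.intervals.items()
            for hi, lo, tag in sel.intervals
        ]
        pd.DataFrame(interval_rows).to_csv(outdir / "intervals.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
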