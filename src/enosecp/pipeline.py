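"""End-to-end pipeline: simulate -> featurize -> cross-validate -> report.

A :class:`RunConfig` captures every knob of a run; ``run_pipeline`` executes
the stages and writes a deterministic result bundle (feature table,
cross-validated p-values, calibration and efficiency curves, indicator
summaries, accuracy report, PCA projection, and the resolved config).
Every artifact embeds the seed and a hash of the resolved configuration, so
identical configs reproduce identical numeric outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from enosecp.conformal import UnderlyingModelSpec
from enosecp.evaluation import (
    accuracy_forced,
    calibration_curve,
    cross_validate,
    default_epsilon_grid,
    efficiency_curve,
    pca_projection,
    summarize_indicators,
)
from enosecp.features import extract_feature_table
from enosecp.io import write_feature_table
from enosecp.preprocess import baseline_correct
from enosecp.synthetic import TimingConfig, make_signatures, simulate_dataset

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of a simulate->featurize->evaluate run."""

    output_dir: str = "results"
    seed: int = 0
    # synthetic data
    n_classes: int = 10
    per_class: int = 50
    n_sensors: int = 16
    separation: float = 1.0
    sampling_rate: float = 10.0
    baseline_duration: float = 20.0
    reaction_duration: float = 200.0
    cleaning_duration: float = 120.0
    within_class_cv: float = 0.1
    noise_sd: float = 0.01
    drift_slope_sd: float = 1e-4
    # model
    framework: str = "icp"
    model: str = "svm_rbf"
    C: float = 6000.0
    gamma: float = 0.001
    n_trees: int = 500
    standardize: bool | None = None
    # conformal / evaluation
    K: int = 5
    calib_fraction: float = 1 / 3
    n_folds: int = 10
    epsilon_start: float = 0.01
    epsilon_stop: float = 0.99
    epsilon_step: float = 0.01
    make_plots: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (destination and plot flags
        excluded, so relocated reruns stay byte-identical)."""
        payload = self.to_dict()
        payload.pop("output_dir")
        payload.pop("make_plots")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def timing(self) -> TimingConfig:
        return TimingConfig(
            sampling_rate=self.sampling_rate,
            baseline_duration=self.baseline_duration,
            reaction_duration=self.reaction_duration,
            cleaning_duration=self.cleaning_duration,
        )

    def model_spec(self, seed: int) -> UnderlyingModelSpec:
        return UnderlyingModelSpec(
            kind=self.model,
            C=self.C,
            gamma=self.gamma,
            n_trees=self.n_trees,
            standardize=self.standardize,
            seed=seed,
        )

    def epsilon_grid(self) -> np.ndarray:
        grid = np.arange(
            self.epsilon_start, self.epsilon_stop + self.epsilon_step / 2,
            self.epsilon_step,
        )
        return np.round(grid, 10)


def _write_csv(frame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict of the in-memory results (feature table, CV result,
    curves, summaries) alongside the paths written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={config.seed} config={config.config_hash()}"
    for fname, value in config.to_dict().items():
        logger.info("config %s = %r", fname, value)

    master = np.random.default_rng(config.seed)
    sig_seed = int(master.integers(2**31 - 1))
    data_seed = int(master.integers(2**31 - 1))
    model_seed = int(master.integers(2**31 - 1))
    cv_seed = int(master.integers(2**31 - 1))

    signatures = make_signatures(
        config.n_classes,
        config.n_sensors,
        config.separation,
        seed=sig_seed,
        within_class_cv=config.within_class_cv,
        noise_sd=config.noise_sd,
        drift_slope_sd=config.drift_slope_sd,
    )
    recordings = simulate_dataset(
        signatures, config.per_class, config.timing(), seed=data_seed
    )
    logger.info("simulated %d recordings", len(recordings))

    corrected = [baseline_correct(r) for r in recordings]
    table = extract_feature_table(corrected)
    logger.info("extracted %d x %d feature table", table.n_rows, table.n_features)
    write_feature_table(table, out / "features.csv", header_comment=stamp)

    result = cross_validate(
        table,
        config.framework,
        config.model_spec(model_seed),
        n_folds=config.n_folds,
        seed=cv_seed,
        calib_fraction=config.calib_fraction,
        K=config.K,
    )
    _write_csv(result.to_dataframe(), out / "cv_pvalues.csv", stamp)

    grid = config.epsilon_grid()
    calib = calibration_curve(result, grid)
    eff = efficiency_curve(result, grid)
    _write_csv(calib, out / "calibration_curve.csv", stamp)
    _write_csv(eff, out / "efficiency_curve.csv", stamp)

    indicators = summarize_indicators(result)
    _write_csv(indicators, out / "indicators.csv", stamp)

    accuracy = accuracy_forced(result)
    (out / "accuracy.json").write_text(
        json.dumps({"meta": stamp, **accuracy}, indent=1)
    )

    pca = pca_projection(table, n_components=2)
    import pandas as pd

    pca_frame = pd.DataFrame(pca["scores"], columns=["PC1", "PC2"])
    pca_frame["label"] = table.labels
    _write_csv(pca_frame, out / "pca_scores.csv", stamp)
    (out / "pca_variance.json").write_text(
        json.dumps(
            {
                "meta": stamp,
                "variance": pca["variance"].tolist(),
                "variance_fraction": pca["variance_fraction"].tolist(),
            },
            indent=1,
        )
    )

    config.to_yaml(out / "config_resolved.yaml")

    if config.make_plots:
        _write_plots(out, calib, eff, pca_frame)

    return {
        "table": table,
        "cv_result": result,
        "calibration": calib,
        "efficiency": eff,
        "indicators": indicators,
        "accuracy": accuracy,
        "pca": pca,
        "output_dir": out,
    }


def _write_plots(out: Path, calib, eff, pca_frame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(calib["epsilon"], calib["error_rate"], label="error rate")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="diagonal")
    ax.set_xlabel("significance level $\\epsilon$")
    ax.set_ylabel("error rate")
    ax.legend()
    fig.savefig(out / "calibration_plot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot(eff["epsilon"], eff["mean_set_size"])
    ax.set_xlabel("significance level $\\epsilon$")
    ax.set_ylabel("mean prediction-set size")
    fig.savefig(out / "efficiency_plot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for lab in np.unique(pca_frame["label"]):
        sel = pca_frame[pca_frame["label"] == lab]
        ax.scatter(sel["PC1"], sel["PC2"], s=8, label=str(lab))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=6, ncol=2)
    fig.savefig(out / "pca_plot.png", dpi=120)
    plt.close(fig)
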