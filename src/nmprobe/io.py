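"""Experiment configuration, execution, and result persistence.

An :class:`ExperimentConfig` captures everything needed to reproduce a run:
the model setting and overrides, the probing amplitudes, the integration
spec, feature options, analysis options, and the base seed.  It round-trips
losslessly through YAML.  :func:`run_experiment` executes the configured
pipeline and writes a result bundle — tidy CSV tables plus a JSON manifest
recording the config, seeds and package version — which
:func:`load_result` reconstructs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .analysis import run_amplitude_sweep
from .features import compute_features
from .protocol import SETTING_NAMES, StimulusProtocol, build_setting, build_proictal_setting
from .seizure import proictal_experiment
from .simulate import IntegrationSpec, integrate

__all__ = ["ExperimentConfig", "run_experiment", "load_result", "BundleError"]

log = logging.getLogger(__name__)

MANIFEST_VERSION = 1


class BundleError(RuntimeError):
    """A result bundle is missing, truncated, or from an incompatible version."""


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment."""

    setting: str = "II-K"
    mode: str = "sweep"  #: "simulate", "sweep", or "proictal"
    amplitudes: list = field(default_factory=lambda: list(range(0, 201, 20)))
    n_realizations: int = 15
    duration: float = 2000.0
    dt: float = 0.00195
    base_seed: int = 0
    alpha: float = 0.05
    window_s: float = 0.400
    ma_order: int = 20
    mi_bins: int = 16
    ramp_start: float | None = None
    ramp_end: float | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.setting not in SETTING_NAMES:
            raise ValueError(
                f"unknown setting {self.setting!r}; valid: {', '.join(SETTING_NAMES)}")
        if self.mode not in ("simulate", "sweep", "proictal"):
            raise ValueError("mode must be 'simulate', 'sweep' or 'proictal'")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}; valid: {sorted(known)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def build_setting(self):
        if self.mode == "proictal":
            s = build_proictal_setting(self.setting, t_end=self.duration)
            if self.ramp_start is not None or self.ramp_end is not None:
                s = build_setting(self.setting, ramp_start=self.ramp_start or s.ramp.start_value,
                                  ramp_end=self.ramp_end or s.ramp.end_value,
                                  t_end=self.duration)
            return s
        return build_setting(self.setting, ramp_start=self.ramp_start,
                             ramp_end=self.ramp_end, t_end=self.duration)

    @property
    def feature_kwargs(self) -> dict:
        return {"window_s": self.window_s, "ma_order": self.ma_order, "mi_bins": self.mi_bins}


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the configured pipeline and persist a result bundle.

    Returns the bundle directory.  Re-running an identical config produces
    numerically identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setting = config.build_setting()
    t0 = time.perf_counter()
    written: dict[str, str] = {}

    if config.mode == "simulate":
        amp = config.amplitudes[0] if config.amplitudes else 0.0
        stim = StimulusProtocol(amplitude=amp, targets=setting.stim_targets)
        spec = IntegrationSpec(dt=config.dt, duration=config.duration, seed=config.base_seed)
        result = integrate(setting, stim, spec)
        result.save_csv(out / "trace.csv")
        written["trace"] = "trace.csv"
        fs = compute_features(result, **config.feature_kwargs)
        fs.to_frame().to_csv(out / "features.csv", index=False)
        written["features"] = "features.csv"
    elif config.mode == "sweep":
        sweep = run_amplitude_sweep(
            setting, config.amplitudes, config.n_realizations, config.base_seed,
            duration=config.duration, dt=config.dt, alpha=config.alpha,
            feature_kwargs=config.feature_kwargs)
        sweep.correlations.to_csv(out / "sweep.csv", index=False)
        sweep.significance.to_csv(out / "significance.csv", index=False)
        written["sweep"] = "sweep.csv"
        written["significance"] = "significance.csv"
    else:  # proictal
        table, stats_out = proictal_experiment(
            setting, config.amplitudes, config.n_realizations, config.base_seed,
            duration=config.duration, dt=config.dt, alpha=config.alpha)
        table.to_csv(out / "onsets.csv", index=False)
        written["onsets"] = "onsets.csv"
        summary = {
            "anova_F": stats_out["anova_F"], "anova_p": stats_out["anova_p"],
            "n_censored": stats_out["n_censored"],
            "tukey_vs_passive": {str(a): {"significant": bool(s), "p_adj": p}
                                 for a, (s, p) in stats_out["tukey_vs_passive"].items()},
        }
        (out / "proictal_stats.json").write_text(json.dumps(summary, indent=2))
        written["proictal_stats"] = "proictal_stats.json"

    manifest = {
        "manifest_version": MANIFEST_VERSION,
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "outputs": written,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("experiment %s/%s finished in %.1f s -> %s",
             config.setting, config.mode, manifest["elapsed_s"], out)
    return out


def load_result(path):
    """Load a bundle written by :func:`run_experiment`.

    Returns a dict with the manifest under ``"manifest"`` and each output
    table under its manifest key.
    """
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise BundleError(f"no manifest.json in {path}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as err:
        raise BundleError(f"corrupt manifest in {path}: {err}") from err
    if manifest.get("manifest_version") != MANIFEST_VERSION:
        raise BundleError(
            f"bundle version {manifest.get('manifest_version')} != {MANIFEST_VERSION}")
    out = {"manifest": manifest}
    for key, fname in manifest["outputs"].items():
        fpath = path / fname
        if not fpath.exists():
            raise BundleError(f"manifest lists {fname} but it is missing")
        if fname.endswith(".csv"):
            out[key] = pd.read_csv(fpath)
        else:
            try:
                out[key] = json.loads(fpath.read_text())
            except json.JSONDecodeError as err:
                raise BundleError(f"corrupt {fname}: {err}") from err
    return out
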