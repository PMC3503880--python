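"""Pipeline orchestration: config handling, the full assessment chain, and
human/machine-readable reports.

``run_pipeline`` executes simulate (or load) -> preprocess -> average
spectral statistics -> single-trial classification from a single config and
writes every stage output as JSON so the final report is fully traceable and
regenerable without recomputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import Epochs
from .io import read_recording, write_recording
from .preprocess import RejectionReport, preprocess_recording
from .singletrial import (
    BANDS,
    extract_bandpower,
    familywise_permutation_test,
)
from .spectral import (
    ClusterResult,
    cluster_permutation_test,
    compute_tfr,
    contrast_log_ratio,
    welch_spectrum,
)
from .synthetic import (
    EffectSpec,
    NoiseSpec,
    Oscillator,
    SimConfig,
    simulate_recording,
)

__all__ = [
    "ConfigError",
    "load_config",
    "run_pipeline",
    "tabulate_results",
    "format_accuracy",
    "AssessmentReport",
    "render_markdown",
]

COMPARISONS = ("left", "right")


class ConfigError(ValueError):
    """Raised when the pipeline configuration fails validation."""


_DEFAULTS: dict = {
    "seed": 0,
    "input": None,
    "simulate": {
        "n_blocks": 3,
        "sampling_rate": 256.0,
        "artifact_rate": 0.0,
        "noise": {},
        "effects": [],
    },
    "preprocess": {
        "target_sfreq": 100.0,
        "band": [1.0, 40.0],
        "resample_first": True,
        "ptp_threshold": 150.0,
        "var_zmax": 5.0,
        "match_counts": None,
        "reject": True,
    },
    "spectral": {
        "n_perm": 1000,
        "sample_alpha": 0.05,
        "cluster_alpha": 0.0125,
        "fmin": 1.0,
        "fmax": 40.0,
    },
    "classify": {
        "n_perm": 1000,
        "alpha": 0.025,
        "k": 10,
        "bands": None,
    },
    "figures": True,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path_or_dict) -> dict:
    """Load and validate a YAML/JSON pipeline config, applying defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(user) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge(_DEFAULTS, user)
    _validate(cfg)
    return cfg


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _validate(cfg: dict) -> None:
    _require(isinstance(cfg["seed"], int), "seed must be an integer")
    pp = cfg["preprocess"]
    _require(len(pp["band"]) == 2 and 0 < pp["band"][0] < pp["band"][1],
             "preprocess.band must be [lo, hi] with 0 < lo < hi")
    _require(pp["target_sfreq"] > 2 * pp["band"][1],
             "target sampling rate must exceed twice the low-pass cutoff")
    sp = cfg["spectral"]
    for name in ("sample_alpha", "cluster_alpha"):
        _require(0 < sp[name] < 1, f"spectral.{name} must be in (0, 1)")
    _require(sp["n_perm"] >= 1, "spectral.n_perm must be >= 1")
    cl = cfg["classify"]
    _require(0 < cl["alpha"] < 1, "classify.alpha must be in (0, 1)")
    _require(cl["k"] >= 2, "classify.k must be >= 2")
    if cl["bands"] is not None:
        bad = set(cl["bands"]) - set(BANDS)
        _require(not bad, f"unknown bands {sorted(bad)}; choose from {list(BANDS)}")
    sim = cfg["simulate"]
    for eff in sim.get("effects", []):
        _require("condition" in eff and "band" in eff and "depth" in eff,
                 "each effect needs condition, band and depth")


def _sim_config(cfg: dict, seed: int) -> SimConfig:
    sim = cfg["simulate"]
    noise_cfg = dict(sim.get("noise") or {})
    osc_cfg = noise_cfg.pop("oscillators", None)
    noise = NoiseSpec(**noise_cfg)
    if osc_cfg is not None:
        noise.oscillators = [Oscillator(**o) for o in osc_cfg]
    effects = [
        EffectSpec(**{**e, "band": tuple(e["band"])}) for e in sim.get("effects", [])
    ]
    return SimConfig(
        n_blocks=int(sim.get("n_blocks", 3)),
        sampling_rate=float(sim.get("sampling_rate", 256.0)),
        noise=noise,
        effects=effects,
        artifact_rate=float(sim.get("artifact_rate", 0.0)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Report structures
# ---------------------------------------------------------------------------

@dataclass
class AssessmentReport:
    """Machine-readable summary of a full assessment run."""

    config: dict
    seeds: dict[str, int]
    trial_counts: dict[str, int]
    comparisons: dict[str, dict] = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "software_version": self.version,
            "config": self.config,
            "seeds": self.seeds,
            "trial_counts": self.trial_counts,
            "comparisons": self.comparisons,
        }


def format_accuracy(accuracy: float, time_s: float, significant: bool = False) -> str:
    """Render an accuracy/time pair as in the results tables: ``67% (1250 ms)*``."""
    star = "*" if significant else ""
    return f"{round(accuracy * 100):.0f}% ({round(time_s * 1000):.0f} ms){star}"


def tabulate_results(comparisons: dict[str, dict]) -> list[dict]:
    """Flatten per-comparison classification outputs into table rows."""
    rows = []
    for comp, res in comparisons.items():
        cls = res["classification"]
        rows.append(
            {
                "comparison": f"{comp.capitalize()}-Hand vs. Rest",
                "max_smoothed": format_accuracy(
                    cls["max_smoothed_accuracy"],
                    cls["max_smoothed_time_s"],
                    cls["n_significant_timepoints"] > 0,
                ),
                "max_unsmoothed": format_accuracy(
                    cls["max_raw_accuracy"], cls["max_raw_time_s"], False
                ),
            }
        )
    return rows


def render_markdown(report: dict) -> str:
    """Render report.json content as Markdown (pure function of the dict, so
    regeneration is byte-identical)."""
    lines = [
        "# Covert command-following assessment",
        "",
        f"Software version: {report['software_version']}",
        f"Master seed: {report['config']['seed']}",
        "",
        "## Clean trials per condition",
        "",
    ]
    for cond, n in sorted(report["trial_counts"].items()):
        lines.append(f"- {cond}: {n}")
    lines += ["", "## Classification", "",
              "| Comparison | Maximum Smoothed Accuracy (Time) | Maximum Unsmoothed Accuracy (Time) |",
              "|---|---|---|"]
    for row in tabulate_results(report["comparisons"]):
        lines.append(
            f"| {row['comparison']} | {row['max_smoothed']} | {row['max_unsmoothed']} |"
        )
    lines += ["", "Significance (asterisk): familywise-corrected p < "
              f"{report['config']['classify']['alpha']} (one-tailed), "
              "assessed on smoothed accuracies only.", ""]
    lines.append("## Significant spectral clusters")
    lines.append("")
    any_cluster = False
    for comp, res in report["comparisons"].items():
        for cl in res["clusters"]["significant"]:
            any_cluster = True
            lines.append(
                f"- {comp}-hand vs rest, {cl['channel']}, sign {cl['sign']}: "
                f"{cl['freq_range_hz'][0]:.0f}-{cl['freq_range_hz'][1]:.0f} Hz, "
                f"{cl['time_range_s'][0] * 1000:.0f}-{cl['time_range_s'][1] * 1000:.0f} ms, "
                f"p = {cl['p']:.4g}"
            )
    if not any_cluster:
        lines.append("- none")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config, output_dir, write_raw: bool = False) -> AssessmentReport:
    """Execute the full assessment described by ``config``.

    Writes per-stage JSON outputs, the final ``report.json``/``report.md``
    and (optionally) figures under ``output_dir``.  Deterministic given the
    config's master seed, which is split into independent per-stage streams.
    """
    cfg = load_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("simulate", "match", "spectral", "classify"), ss.spawn(4)
        )
    }

    if cfg["input"]:
        raw = read_recording(cfg["input"])
    else:
        sim = simulate_recording(_sim_config(cfg, stage_seeds["simulate"]))
        raw = sim.recording
        if write_raw:
            write_recording(raw, out / "recording.edf", format="edf")

    pp = cfg["preprocess"]
    epochs, report = preprocess_recording(
        raw,
        target_sfreq=pp["target_sfreq"],
        band=tuple(pp["band"]),
        resample_first=pp["resample_first"],
        ptp_threshold=pp["ptp_threshold"],
        var_zmax=pp["var_zmax"],
        target_counts=pp["match_counts"],
        seed=stage_seeds["match"],
        reject=pp["reject"],
    )
    if report is not None:
        _json_dump(report.to_dict(), out / "rejection.json")

    welch = {
        cond: welch_spectrum(epochs, cond).to_dict()
        for cond in sorted(set(epochs.conditions.astype(str)))
    }
    _json_dump(welch, out / "welch.json")

    sp = cfg["spectral"]
    cl = cfg["classify"]
    tfr = compute_tfr(epochs, fmin=sp["fmin"], fmax=sp["fmax"])
    features = extract_bandpower(epochs)
    if cl["bands"]:
        features = features.select_bands(cl["bands"])

    comparisons: dict[str, dict] = {}
    for i, comp in enumerate(COMPARISONS):
        active_idx = np.flatnonzero(epochs.conditions == comp)
        rest_idx = np.flatnonzero(epochs.conditions == "rest")
        if len(active_idx) < 2 or len(rest_idx) < 2:
            continue

        from dataclasses import replace as _replace
        tfr_active = _replace(tfr, power=tfr.power[active_idx])
        tfr_rest = _replace(tfr, power=tfr.power[rest_idx])
        clusters = cluster_permutation_test(
            tfr_active,
            tfr_rest,
            sample_alpha=sp["sample_alpha"],
            n_perm=sp["n_perm"],
            cluster_alpha=sp["cluster_alpha"],
            seed=stage_seeds["spectral"] + i,
        )

        both = np.concatenate([active_idx, rest_idx])
        feats = features.select_trials(np.sort(both))
        perm = familywise_permutation_test(
            feats,
            k=cl["k"],
            n_perm=cl["n_perm"],
            alpha=cl["alpha"],
            seed=stage_seeds["classify"] + i,
        )

        acc, t_acc = perm.observed.max_smoothed
        raw_acc, t_raw = perm.observed.max_raw
        comp_out = {
            "clusters": {
                "all": clusters.to_dict(),
                "significant": [
                    c.to_dict(clusters.freqs, clusters.times)
                    for c in clusters.significant()
                ],
            },
            "classification": {
                "max_smoothed_accuracy": acc,
                "max_smoothed_time_s": t_acc,
                "max_raw_accuracy": raw_acc,
                "max_raw_time_s": t_raw,
                "n_significant_timepoints": int(perm.sig_mask.sum()),
                "significant_times_s": perm.observed.times[perm.sig_mask].tolist(),
                "alpha": cl["alpha"],
            },
        }
        comparisons[comp] = comp_out
        _json_dump(comp_out["clusters"]["all"], out / f"clusters_{comp}.json")
        _json_dump(
            {**perm.to_dict(), "comparison": comp}, out / f"classification_{comp}.json"
        )

        if cfg["figures"]:
            from . import plots

            log_ratio = contrast_log_ratio(tfr_active, tfr_rest)
            plots.plot_tfr_contrast(
                log_ratio, clusters, out / f"tfr_{comp}_vs_rest.png"
            )
            plots.plot_accuracy(perm, out / f"accuracy_{comp}_vs_rest.png")

    if cfg["figures"]:
        from . import plots

        plots.plot_welch(welch, out / "welch.png")

    assessment = AssessmentReport(
        config=cfg,
        seeds=stage_seeds,
        trial_counts=Epochs.condition_counts(epochs),
        comparisons=comparisons,
    )
    _json_dump(assessment.to_dict(), out / "report.json")
    (out / "report.md").write_text(render_markdown(assessment.to_dict()))
    return assessment
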