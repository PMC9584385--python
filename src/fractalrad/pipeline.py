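"""End-to-end orchestration: masks → features → cohort statistics → report.

Three entry points compose the library for batch use. ``run_features`` walks a
directory of NIfTI masks and writes one feature row per subject, continuing
past per-subject failures (a cohort analysis tolerates missing subjects, so
the policy is continue-and-report rather than fail-fast). ``run_analysis``
reproduces the statistical pipeline on a cohort CSV: group comparison table,
univariable screen, backward-eliminated multivariable logistic model with
separation/VIF flags, and ROC of the final model. ``run_simulate`` materialises
synthetic phantoms and cohorts from a YAML spec with a checksum manifest.

Every report echoes the configuration and seeds that produced it, so reruns
are bit-reproducible for deterministic stages and seed-reproducible for
stochastic ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .errors import ConfigError, FractalradError
from .fractal import FractalConfig, extract_features
from .mask import read_mask, resample_isotropic, write_feature_table, write_mask
from .stats import backward_eliminate, comparison_table, roc_analysis

log = logging.getLogger("fractalrad")

#: model candidates in the order they are screened (pathology columns are
#: deliberately absent: they are not part of the imaging prediction model)
DEFAULT_CANDIDATES = (
    "age",
    "female",
    "recurrent",
    "skull_base",
    "heterogeneous_enhancement",
    "capsular_enhancement",
    "necrosis",
    "cystic_change",
    "hyperostosis",
    "skull_invasion",
    "max_diameter_cm",
    "fd",
    "lacunarity",
)
CONTINUOUS_VARS = ("age", "max_diameter_cm", "fd", "lacunarity", "mitosis_count", "ki67")
BINARY_VARS = (
    "female",
    "recurrent",
    "skull_base",
    "heterogeneous_enhancement",
    "capsular_enhancement",
    "necrosis",
    "cystic_change",
    "hyperostosis",
    "skull_invasion",
)


@dataclasses.dataclass
class StatsConfig:
    alpha_normality: float = 0.05
    p_enter: float = 0.05
    p_stay: float = 0.05
    vif_threshold: float = 10.0
    n_boot: int = 2000
    seed: int = 0


@dataclasses.dataclass
class RunConfig:
    """Full-run configuration; exactly one of masks_dir / synthetic spec drives input."""

    masks_dir: str | None = None
    clinical_csv: str | None = None
    cohort_csv: str | None = None
    synthetic_spec: Mapping[str, Any] | None = None
    outcome: str = "group"
    positive_group: str = "mutant"
    fractal: FractalConfig = dataclasses.field(default_factory=FractalConfig)
    stats: StatsConfig = dataclasses.field(default_factory=StatsConfig)
    out_dir: str = "fractalrad_out"


def _prepare_analysis_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    if "sex" in df.columns and "female" not in df.columns:
        df["female"] = (df["sex"] == "female").astype(int)
    return df


def run_features(
    masks_dir: str | Path,
    out_csv: str | Path,
    config: FractalConfig | None = None,
    metadata_csv: str | Path | None = None,
) -> dict[str, Any]:
    """Extract features for every NIfTI mask in a directory.

    Per-subject failures are logged and collected; the run fails only when no
    mask is readable. Returns a summary dict with ``status`` "ok", "partial"
    or "failed".
    """
    config = config or FractalConfig()
    paths = sorted(Path(masks_dir).glob("*.nii")) + sorted(Path(masks_dir).glob("*.nii.gz"))
    features, failures = [], []
    for p in paths:
        try:
            mask = read_mask(p)
            if not mask.is_isotropic:
                mask = resample_isotropic(mask)
            features.append(extract_features(mask, config))
        except (FractalradError, Exception) as exc:  # noqa: BLE001 - continue past any subject
            log.warning("feature extraction failed for %s: %s", p.name, exc)
            failures.append({"path": str(p), "error": str(exc)})
    if not features:
        raise FractalradError(f"no readable masks in {masks_dir} ({len(failures)} failures)")
    metadata = pd.read_csv(metadata_csv) if metadata_csv else None
    write_feature_table(features, out_csv, metadata=metadata)
    status = "partial" if failures else "ok"
    return {
        "status": status,
        "n_ok": len(features),
        "n_failed": len(failures),
        "failures": failures,
        "out_csv": str(out_csv),
        "config": dataclasses.asdict(config),
    }


def run_analysis(
    cohort: pd.DataFrame | str | Path,
    out_dir: str | Path,
    outcome: str = "group",
    positive_group: str = "mutant",
    candidates: Sequence[str] | None = None,
    stats: StatsConfig | None = None,
    plot: bool = True,
) -> dict[str, Any]:
    """Run the statistical pipeline on a cohort table and write a report bundle.

    Outputs under ``out_dir``: ``comparisons.csv`` (per-variable two-group
    tests), ``model.json`` (univariable screen, elimination trace, final
    model with separation/VIF flags, ROC summary), and ``roc.svg``. The
    returned dict mirrors ``model.json``.
    """
    stats = stats or StatsConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = cohort if isinstance(cohort, pd.DataFrame) else pd.read_csv(cohort)
    df = _prepare_analysis_frame(df)
    if outcome == "group":
        y = (df["group"] == positive_group).astype(int)
    else:
        y = df[outcome].astype(int)
    if y.nunique() < 2:
        raise FractalradError(f"outcome {outcome!r} has a single class")
    df = df.assign(_outcome=y)

    cont = [v for v in CONTINUOUS_VARS if v in df.columns]
    binv = [v for v in BINARY_VARS if v in df.columns]
    comparisons = comparison_table(
        df, group_col="group" if "group" in df.columns else "_outcome",
        positive_group=positive_group if "group" in df.columns else 1,
        continuous=cont, binary=binv, alpha_normality=stats.alpha_normality,
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)

    cand = [c for c in (candidates or DEFAULT_CANDIDATES) if c in df.columns]
    model = backward_eliminate(
        df, "_outcome", cand,
        p_enter=stats.p_enter, p_stay=stats.p_stay, vif_threshold=stats.vif_threshold,
    )
    report: dict[str, Any] = {
        "n": int(len(df)),
        "outcome": outcome,
        "positive_group": positive_group,
        "candidates": cand,
        "univariable": {
            t: {
                "or": m.odds_ratios.get(t),
                "or_ci": list(m.or_ci.get(t, (None, None))),
                "p": m.p_values.get(t),
                "separation": m.separation_flags.get(t),
            }
            for t, m in model.univariable.items()
        },
        "elimination_trace": [[t, p] for t, p in model.elimination_trace],
        "vif": model.vif,
        "final_model": {
            "terms": list(model.terms),
            "coefficients": model.coefficients,
            "odds_ratios": model.odds_ratios,
            "or_ci": {k: list(v) for k, v in model.or_ci.items()},
            "p_values": model.p_values,
            "log_likelihood": model.log_likelihood,
        },
        "config": dataclasses.asdict(stats),
    }
    if model.terms:
        scores = model.predict_proba(df)
        roc = roc_analysis(scores, y.to_numpy(), n_boot=stats.n_boot, seed=stats.seed)
        report["roc"] = {
            "auc": roc.auc,
            "auc_ci": list(roc.auc_ci),
            "threshold": roc.threshold,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "accuracy": roc.accuracy,
            "n_boot": roc.n_boot,
        }
        if plot:
            _plot_roc(scores, y.to_numpy(), roc.auc, out / "roc.svg")
    else:
        report["roc"] = None

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    (out / "model.json").write_text(json.dumps(report, indent=2, default=_default, allow_nan=True))
    return report


def _plot_roc(scores: np.ndarray, y: np.ndarray, auc: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(spec: Mapping[str, Any] | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Materialise phantoms and/or a synthetic cohort from a YAML spec.

    Spec schema::

        phantoms:          # optional list
          - kind: cube|slab|line|ball|menger|blob
            ... kind-specific parameters ...
        cohort:            # optional
          n_total: 48
          prevalence: 0.1458
          seed: 7

    Writes NIfTI phantoms, ``cohort.csv`` and ``manifest.json`` (parameters,
    seeds, sha256 checksums) under ``out_dir``.
    """
    if not isinstance(spec, Mapping):
        spec = yaml.safe_load(Path(spec).read_text())
    if not isinstance(spec, Mapping):
        raise ConfigError("spec: expected a mapping at top level")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"outputs": []}
    for i, ph in enumerate(spec.get("phantoms") or []):
        if not isinstance(ph, Mapping) or "kind" not in ph:
            raise ConfigError(f"phantoms[{i}]: each phantom needs a 'kind'")
        params = {k: v for k, v in ph.items() if k not in ("kind", "name")}
        kind = ph["kind"]
        try:
            if kind == "menger":
                mask = synthetic.make_menger_sponge(**params)
            elif kind == "blob":
                mask = synthetic.make_blob(**params)
            elif kind in ("cube", "slab", "line", "ball"):
                mask = synthetic.make_primitive(kind, **params)
            else:
                raise ConfigError(f"phantoms[{i}].kind: unknown kind {kind!r}")
        except TypeError as exc:
            raise ConfigError(f"phantoms[{i}]: bad parameters for {kind!r}: {exc}") from exc
        name = ph.get("name", mask.subject_id)
        path = out / f"{name}.nii.gz"
        write_mask(mask, path)
        manifest["outputs"].append(
            {"path": path.name, "kind": kind, "params": dict(params),
             "n_foreground": mask.n_foreground, "sha256": _sha256(path)}
        )
    if "cohort" in spec and spec["cohort"] is not None:
        cs = spec["cohort"]
        if not isinstance(cs, Mapping):
            raise ConfigError("cohort: expected a mapping of CohortSpec fields")
        try:
            cohort_spec = synthetic.CohortSpec(**cs)
        except TypeError as exc:
            raise ConfigError(f"cohort: {exc}") from exc
        table = synthetic.generate_cohort(cohort_spec)
        path = out / "cohort.csv"
        table.to_csv(path, index=False)
        manifest["outputs"].append(
            {"path": path.name, "kind": "cohort", "params": dict(cs),
             "n_rows": int(len(table)), "sha256": _sha256(path)}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_full(config: RunConfig) -> dict[str, Any]:
    """simulate (optional) → features (optional) → analyze, per the config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict[str, Any] = {}
    cohort_csv = config.cohort_csv
    masks_dir = config.masks_dir
    if config.synthetic_spec is not None:
        sim_dir = out / "synthetic"
        result["simulate"] = run_simulate(config.synthetic_spec, sim_dir)
        if (sim_dir / "cohort.csv").exists():
            cohort_csv = str(sim_dir / "cohort.csv")
        if any(sim_dir.glob("*.nii.gz")) and masks_dir is None:
            masks_dir = str(sim_dir)
    if masks_dir is not None:
        result["features"] = run_features(
            masks_dir, out / "features.csv", config.fractal, config.clinical_csv
        )
        if cohort_csv is None:
            cohort_csv = str(out / "features.csv")
    if cohort_csv is None:
        raise ConfigError("config provides neither a cohort table nor inputs to build one")
    result["analysis"] = run_analysis(
        cohort_csv, out, outcome=config.outcome,
        positive_group=config.positive_group, stats=config.stats,
    )
    return result
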