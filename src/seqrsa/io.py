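"""Formats, configuration and the end-to-end pipeline runner.

Tabular data are TSV (header row, UTF-8, decimal point); volumes and masks
are NIfTI-1 via nibabel; a manifest JSON ties generated files together
with the config and seed.  Result files contain no timestamps so reruns
are byte-reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

try:
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

from . import __version__
from .behavior import BEHAVIOR_COLUMNS, accuracy_metrics, generalization_bias, \
    swap_error_test, timeline_regression
from .design import DESIGN_COLUMNS, ExperimentDesign, build_pair_table
from .exceptions import DesignValidationError
from .mds import model_predicted_distances, nonmetric_mds, stress_permutation_test, \
    embedding_diagnostics
from .pipeline import RoiAnalysisSpec, run_roi_model, sequence_interaction_test
from .rsa import similarity_change_from_datasets
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "RunConfig", "load_design_tsv", "load_behavior_tsv", "write_nifti",
    "read_nifti", "validate_and_load", "run_full_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_design_tsv(path: str | Path) -> ExperimentDesign:
    path = Path(path)
    if not path.exists():
        raise DesignValidationError(f"design file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    unknown = set(df.columns) - set(DESIGN_COLUMNS)
    if unknown:
        raise DesignValidationError(f"{path}: unknown design columns {sorted(unknown)}")
    return ExperimentDesign(df)


def load_behavior_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DesignValidationError(f"behavior file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise DesignValidationError(f"{path}: missing behavior columns {sorted(missing)}")
    return df


def write_nifti(volume: np.ndarray, path: str | Path, voxel_size: float = 1.5) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated end-to-end run configuration."""

    seed: int
    output_dir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    design_path: str | None = None
    behavior_path: str | None = None
    analyses: tuple[str, ...] = ("behavior", "rsa", "interaction", "mds")
    roi_specs: tuple[RoiAnalysisSpec, ...] = ()
    n_perm: int = 1000
    n_flips: int = 1000
    exclude_subjects: tuple[int, ...] = ()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = json.loads(path.read_text())
        if "seed" not in raw:
            raise DesignValidationError(f"{path}: config must set a seed")
        sim = SimulationConfig(**raw.pop("simulation", {}))
        specs = tuple(RoiAnalysisSpec(**s) for s in raw.pop("roi_specs", []))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DesignValidationError(f"{path}: unknown config fields {sorted(unknown)}")
        return cls(simulation=sim, roi_specs=specs, **raw)


def validate_and_load(config_path: str | Path) -> dict:
    """Load and schema-check a config; load referenced inputs with checks."""
    cfg = RunConfig.from_json(config_path)
    bundle: dict = {"config": cfg}
    if cfg.design_path:
        bundle["design"] = load_design_tsv(cfg.design_path)
    if cfg.behavior_path:
        bundle["behavior"] = load_behavior_tsv(cfg.behavior_path)
        n_rows = len(bundle["behavior"])
        if n_rows % 20 != 0:
            raise DesignValidationError(
                f"{cfg.behavior_path}: row count {n_rows} is not a multiple of 20"
            )
    digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]
    bundle["provenance"] = {"config_sha256": digest, "seed": cfg.seed,
                            "version": __version__}
    return bundle


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        d = asdict(obj)
        d.pop("full_fit", None)
        d.pop("subject_results", None)
        return _jsonable(d)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def run_full_pipeline(config: RunConfig) -> dict:
    """Simulate (or load), analyze, and write a machine-readable bundle.

    Executes the configured analyses (behavior, ROI RSA specs, interaction,
    MDS) on simulated data — or on a loaded design/behavior where paths are
    given — and writes one results JSON plus per-analysis TSVs under
    ``output_dir``.  Every stage failure aborts with the stage name; files
    written so far are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": config.seed, "version": __version__}
    if not config.analyses:
        results["warning"] = "empty analysis list; nothing to do"
        (out / "results.json").write_text(json.dumps(results, indent=2))
        return results

    stage = "simulate"
    try:
        with_patterns = any(a in config.analyses for a in ("rsa", "interaction", "mds"))
        design, subjects = simulate_dataset(config.simulation, seed=config.seed,
                                            with_patterns=with_patterns)
        if config.design_path:
            design = load_design_tsv(config.design_path)
        subjects = [s for s in subjects if s.subject_id not in config.exclude_subjects]
        pairs = build_pair_table(design)
        design.to_tsv(out / "design.tsv")
        behavior = pd.concat([s.behavior for s in subjects], ignore_index=True)
        if config.behavior_path:
            behavior = load_behavior_tsv(config.behavior_path)
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)

        if "behavior" in config.analyses:
            stage = "behavior"
            timeline = timeline_regression(behavior, design, n_perm=config.n_perm,
                                           seed=config.seed, n_flips=config.n_flips)
            acc = accuracy_metrics(behavior, design)
            bias = generalization_bias(behavior, design, n_perm=config.n_perm,
                                       seed=config.seed + 1, n_flips=config.n_flips)
            swaps = swap_error_test(behavior, design, n_iter=config.n_perm,
                                    seed=config.seed + 2)
            acc["per_subject"].to_csv(out / "timeline_accuracy.tsv", sep="\t")
            results["behavior"] = {
                "timeline_group": timeline.group,
                "timeline_mean_z": float(timeline.subject_z.mean()),
                "accuracy_group": acc["group"].to_dict(),
                "bias_group": bias.group,
                "bias_mean_slope": float(bias.subject_coef.mean()),
                "swap_errors": {k: v for k, v in swaps.items()},
            }

        changes = None
        if with_patterns and subjects[0].patterns_pre is not None:
            stage = "rsa"
            changes = np.stack([
                similarity_change_from_datasets(s.patterns_pre, s.patterns_post)
                for s in subjects
            ])
        if "rsa" in config.analyses:
            specs = config.roi_specs or (
                RoiAnalysisSpec(subset="same", predictors=("virtual",), focal="virtual",
                                n_perm=config.n_perm, n_flips=config.n_flips,
                                seed=config.seed),
                RoiAnalysisSpec(subset="different", predictors=("virtual",),
                                focal="virtual", n_perm=config.n_perm,
                                n_flips=config.n_flips, seed=config.seed + 1),
            )
            roi_out = []
            rows = []
            for spec in specs:
                res = run_roi_model(changes, pairs, spec)
                roi_out.append({"spec": spec, "group": res.group,
                                "mean_z": float(res.subject_z.mean())})
                for sid, z in enumerate(res.subject_z, start=1):
                    rows.append({"subject": sid, "subset": spec.subset,
                                 "focal": spec.focal, "z": z})
            pd.DataFrame(rows).to_csv(out / "roi_model_z.tsv", sep="\t", index=False)
            results["rsa"] = roi_out

        mixed_fit = None
        if "interaction" in config.analyses:
            stage = "interaction"
            inter = sequence_interaction_test(changes, pairs, n_perm=config.n_perm,
                                              seed=config.seed, n_flips=config.n_flips)
            mixed_fit = inter.mixed
            results["interaction"] = {
                "paired_group": inter.paired_group,
                "mixed_chi2": inter.mixed.chi2,
                "mixed_p": inter.mixed.p,
                "converged": inter.mixed.converged,
            }

        if "mds" in config.analyses:
            stage = "mds"
            if mixed_fit is None:
                inter = sequence_interaction_test(changes, pairs, n_perm=200,
                                                  seed=config.seed,
                                                  n_flips=config.n_flips)
                mixed_fit = inter.mixed
            dist = model_predicted_distances(mixed_fit, pairs)
            emb = nonmetric_mds(dist, n_starts=50, seed=config.seed)
            diag = embedding_diagnostics(emb, dist)
            stress_test = stress_permutation_test(dist, n_iter=min(200, config.n_perm),
                                                  seed=config.seed)
            stress_test.pop("embedding", None)
            pd.DataFrame(emb.configuration, columns=["dim1", "dim2"]).assign(
                event_id=np.arange(1, len(emb.configuration) + 1)
            ).to_csv(out / "mds_embedding.tsv", sep="\t", index=False)
            results["mds"] = {"stress": emb.stress, "diagnostics": diag,
                              "stress_test": stress_test}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "results.json").write_text(json.dumps(_jsonable(results), indent=2))
    return results
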