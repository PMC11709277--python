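"""End-to-end orchestration of the corneal-astigmatism analysis.

``run_pipeline`` drives the full chain on a cohort (read from CSV or
generated synthetically): power-vector decomposition with left-eye
mirroring, reconstruction of corneal power from the pseudophakic
refraction, a 60/20/20 train/validation/test split, fitting of the
constant/REG/NET model families per measurement modality, and a
Table-style evaluation report (centroid, 95% error-ellipse area, MVD, MSE
per modality x model x split) written as CSV and JSON together with model
files, double-angle plot data and a run log.

``apply_published_correction`` is the clinical four-step recipe: decompose
a measured corneal astigmatism, mirror left eyes, apply the published
regression for the modality, and convert back to cylinder/axis notation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, cohort_to_frame, generate_cohort, read_cohort_csv
from .eye import EyeConstants, HaigisConstants, PseudophakicRecord, reconstruct_corneal_power
from .models import (
    MODALITIES,
    NetConfig,
    fit_bivariate_regression,
    fit_constant_model,
    fit_shallow_net,
    published_models,
    save_model,
    split_dataset,
)
from .stats import ellipse_polygon, error_ellipse_95, evaluate_predictions
from .vectors import (
    Laterality,
    PowerVector,
    meridional_to_vector,
    mirror_to_right_eye,
    vector_to_sphero,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "decompose_cohort",
    "apply_published_correction",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_csv`` / ``cohort`` provides the data.  All
    randomness (simulation, splitting, network initialisation) is derived
    from the single master ``seed``.
    """

    seed: int
    outdir: str | Path
    input_csv: str | Path | None = None
    cohort: CohortConfig | None = None
    modalities: tuple[str, ...] = MODALITIES
    model_families: tuple[str, ...] = ("constant", "reg", "net")
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    net: NetConfig = NetConfig()
    haigis: HaigisConstants = HaigisConstants()
    eye: EyeConstants = EyeConstants()

    def __post_init__(self) -> None:
        if not self.modalities or not self.model_families:
            raise ValueError("need at least one modality and one model family")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}; valid: {MODALITIES}")
        unknown = set(self.model_families) - {"constant", "reg", "net"}
        if unknown:
            raise ValueError(f"unknown model families {sorted(unknown)}")


def decompose_cohort(
    records: Sequence[PseudophakicRecord],
    modalities: Sequence[str],
    hc: HaigisConstants = HaigisConstants(),
    ec: EyeConstants = EyeConstants(),
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-modality measured (C0, C45) arrays and the recCP (C0, C45) array,
    all mirrored to the right-eye frame."""
    X = {m: np.empty((len(records), 2)) for m in modalities}
    Y = np.empty((len(records), 2))
    for i, rec in enumerate(records):
        reccp = reconstruct_corneal_power(rec, hc, ec)  # mirrored inside
        Y[i] = (reccp.C0, reccp.C45)
        for m in modalities:
            pv = mirror_to_right_eye(
                meridional_to_vector(rec.modality_readings[m]), rec.laterality
            )
            X[m][i] = (pv.C0, pv.C45)
    return X, Y


def _config_digest(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return repr(o)

    blob = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig):
    """Run the full analysis; returns (report DataFrame, fitted models).

    Writes into ``cfg.outdir``: ``report.csv``/``report.json`` (one row per
    modality x model x split, including the raw recCP-minus-measurement
    rows), ``models/*.json``, ``plot_data/*.csv`` (per-eye error vectors
    plus 95%-ellipse polygon vertices) and ``run_log.json``.  On failure,
    partially written outputs are removed and a stage-tagged
    :class:`PipelineError` is raised.
    """
    outdir = Path(cfg.outdir)
    staging = outdir.parent / (outdir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        report, models = _run_pipeline_inner(cfg, staging)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
    return report, models


def _stage(name: str, exc: Exception) -> PipelineError:
    return PipelineError(f"[{name}] {exc}")


def _run_pipeline_inner(cfg: RunConfig, outdir: Path):
    master = np.random.SeedSequence(cfg.seed)
    sim_seed, split_seed, net_seed_base = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3)
    )

    # (1) read or simulate the cohort
    try:
        if cfg.input_csv is not None:
            records = read_cohort_csv(cfg.input_csv)
        else:
            cohort_cfg = cfg.cohort or CohortConfig()
            cohort_cfg = dataclasses.replace(cohort_cfg, seed=sim_seed)
            records, _ = generate_cohort(cohort_cfg, cfg.haigis, cfg.eye)
    except Exception as exc:
        raise _stage("cohort", exc) from exc

    # (2)+(3) decompose, mirror OS, reconstruct recCP
    try:
        X, Y = decompose_cohort(records, cfg.modalities, cfg.haigis, cfg.eye)
    except Exception as exc:
        raise _stage("reconstruct", exc) from exc

    # (4) split
    try:
        split = split_dataset(len(records), split_seed, cfg.split_fractions)
    except Exception as exc:
        raise _stage("split", exc) from exc

    # (5) fit + (6) evaluate
    class _Identity:
        @staticmethod
        def predict(x):
            return np.asarray(x, dtype=float)

    rows = []
    fitted: dict[tuple[str, str], object] = {}
    models_dir = outdir / "models"
    plot_dir = outdir / "plot_data"
    models_dir.mkdir()
    plot_dir.mkdir()
    try:
        for mi, m in enumerate(cfg.modalities):
            Xtr, Ytr = X[m][split.train], Y[split.train]
            Xval, Yval = X[m][split.validation], Y[split.validation]
            per_family = {"raw": _Identity()}
            if "constant" in cfg.model_families:
                per_family["constant"] = fit_constant_model(Xtr, Ytr)
            if "reg" in cfg.model_families:
                per_family["reg"] = fit_bivariate_regression(Xtr, Ytr)
            if "net" in cfg.model_families:
                net_cfg = dataclasses.replace(cfg.net, seed=net_seed_base + mi)
                per_family["net"] = fit_shallow_net(Xtr, Ytr, Xval, Yval, net_cfg)
            for family, model in per_family.items():
                if family != "raw":
                    fitted[(m, family)] = model
                    save_model(model, models_dir / f"{family}_{m}.json")
                for split_name, idx in (("training", split.train), ("test", split.test)):
                    row = evaluate_predictions(model, X[m][idx], Y[idx])
                    rows.append(
                        {
                            "modality": m,
                            "model": family,
                            "split": split_name,
                            "n": len(idx),
                            "centroid_x_dpt": row.centroid_x,
                            "centroid_y_dpt": row.centroid_y,
                            "ellipse_area_dpt2": row.ellipse_area,
                            "mvd_dpt": row.mvd,
                            "mse_dpt2": row.mse,
                        }
                    )
                    errors = Y[idx] - model.predict(X[m][idx])
                    poly = ellipse_polygon(error_ellipse_95(errors))
                    pd.concat(
                        [
                            pd.DataFrame(
                                {
                                    "kind": "error",
                                    "C0_dpt": errors[:, 0],
                                    "C45_dpt": errors[:, 1],
                                }
                            ),
                            pd.DataFrame(
                                {
                                    "kind": "ellipse",
                                    "C0_dpt": poly[:, 0],
                                    "C45_dpt": poly[:, 1],
                                }
                            ),
                        ],
                        ignore_index=True,
                    ).to_csv(plot_dir / f"{m}_{family}_{split_name}.csv", index=False)
    except Exception as exc:
        raise _stage("fit-evaluate", exc) from exc

    # (7) report + log
    try:
        report = pd.DataFrame(rows)
        report.to_csv(outdir / "report.csv", index=False)
        (outdir / "report.json").write_text(report.to_json(orient="records", indent=1))
        cohort_to_frame(records).to_csv(outdir / "cohort.csv", index=False)
        log = {
            "seed": cfg.seed,
            "sub_seeds": {
                "simulate": sim_seed,
                "split": split_seed,
                "net_base": net_seed_base,
            },
            "config_sha256": _config_digest(cfg),
            "n_records": len(records),
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "reccp": __version__,
            },
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    except Exception as exc:
        raise _stage("report", exc) from exc
    return report, fitted


def apply_published_correction(
    records: Sequence[PseudophakicRecord] | str | Path,
    modality: str,
    output_csv: str | Path | None = None,
    form: str = "minus",
) -> pd.DataFrame:
    """Predict recCP astigmatism from a measured modality, per eye.

    The published four-step recipe: decompose the measured reading into
    (C0, C45), flip C45 for left eyes, apply the published regression for
    the modality, flip back, and convert to cylinder/axis notation (the
    sphere is carried over from the measured equivalent power).
    """
    if modality not in MODALITIES:
        raise ValueError(
            f"unknown modality {modality!r}; valid names: {', '.join(MODALITIES)}"
        )
    if isinstance(records, (str, Path)):
        records = read_cohort_csv(records)
    model = published_models()[modality]
    rows = []
    for i, rec in enumerate(records):
        measured = meridional_to_vector(rec.modality_readings[modality])
        mirrored = mirror_to_right_eye(measured, rec.laterality)
        pred = model.predict(np.array([mirrored.C0, mirrored.C45]))
        pred_eye = mirror_to_right_eye(  # involution: same op flips back
            PowerVector(EQ=measured.EQ, C0=pred[0], C45=pred[1]), rec.laterality
        )
        sc = vector_to_sphero(pred_eye, form=form)
        rows.append(
            {
                "id": i,
                "laterality": rec.laterality.value,
                "modality": modality,
                "measured_EQ_D": measured.EQ,
                "pred_C0_dpt": pred_eye.C0,
                "pred_C45_dpt": pred_eye.C45,
                "pred_sphere_D": sc.sphere,
                "pred_cyl_D": sc.cylinder,
                "pred_axis_deg": sc.axis,
            }
        )
    df = pd.DataFrame(rows)
    if output_csv is not None:
        df.to_csv(output_csv, index=False)
    return df
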