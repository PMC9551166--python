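"""End-to-end orchestration: QC, preprocessing, model fitting, reporting.

``run_identification`` reproduces the identification workflow on a labelled
collection: quality control (for transmission spectra), preprocessing to the
chosen feature representation (FT-IR absorbance, SD-IR, or both
concatenated), a stratified 60/40 split, PCA overview, SIMCA class models
and an OPLS-DA discriminant model with full validation statistics
(R²X/R²Y/Q²Y, RMSEE/RMSECV/RMSEP, permutation intercepts, per-class
sensitivity/specificity/accuracy).  ``run_adulteration_screen`` judges query
spectra against the fitted flower class; ``run_twodcos_report`` produces
synchronous/asynchronous maps with auto- and cross-peak calls for a
perturbation series.  Everything is seed-deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from .errors import DegenerateDataError, ParameterError
from .preprocessing import PreprocessConfig, preprocess
from .spectra_io import (
    MODE_TRANSMITTANCE,
    PerturbationSeries,
    SpectrumCollection,
    qc_accept,
)
from .twod_correlation import (
    TwoDMaps,
    classify_cross_peak,
    dynamic_spectra,
    extract_auto_peaks,
)

FEATURE_SOURCES = ("ftir", "sdir", "both")
DEFAULT_WINDOWS = ((1800.0, 1250.0), (1250.0, 850.0))


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the identification/screening pipeline."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    feature_source: str = "ftir"
    calibration_fraction: float = 0.6
    cv_groups: int = 7
    n_permutations: int = 100
    simca_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_source not in FEATURE_SOURCES:
            raise ParameterError(f"unknown feature source {self.feature_source!r}")
        if not 0 < self.calibration_fraction < 1:
            raise ParameterError("calibration_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        pp = raw.pop("preprocess", {})
        if "baseline" not in pp and "baseline_method" in pp:
            pp["baseline"] = pp.pop("baseline_method")
        return cls(preprocess=PreprocessConfig(**pp), **raw)

    def digest(self) -> str:
        payload = {**asdict(self), "preprocess": asdict(self.preprocess)}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _features(coll: SpectrumCollection, cfg: PipelineConfig) -> chem.DataMatrix:
    """Preprocess every spectrum and assemble the feature matrix."""
    pp = cfg.preprocess
    ftir_cfg = replace(pp, derivative=0)
    sd_cfg = replace(pp, derivative=2)
    rows = []
    for s in coll.spectra:
        if cfg.feature_source == "ftir":
            rows.append(preprocess(s, ftir_cfg).intensities)
        elif cfg.feature_source == "sdir":
            rows.append(preprocess(s, sd_cfg).intensities)
        else:
            rows.append(np.concatenate([
                preprocess(s, ftir_cfg).intensities,
                preprocess(s, sd_cfg).intensities,
            ]))
    X = np.vstack(rows)
    grid = coll.grid if cfg.feature_source != "both" else None
    return chem.DataMatrix(X=X, y=np.asarray(coll.labels, dtype=object),
                           grid=grid, classes=coll.classes)


def _apply_qc(coll: SpectrumCollection) -> tuple[SpectrumCollection, list]:
    """Drop %T spectra failing the transmission rule; absorbance passes through."""
    kept, labels, rejected = [], [], []
    for s, lab in zip(coll.spectra, coll.labels):
        if s.mode == MODE_TRANSMITTANCE and not qc_accept(s):
            rejected.append(s.sample_id)
            continue
        kept.append(s)
        labels.append(lab)
    if not kept:
        raise DegenerateDataError("QC rejected every spectrum")
    out = SpectrumCollection(tuple(kept), tuple(labels))
    for c in coll.classes:
        if c not in out.classes:
            raise DegenerateDataError(f"QC rejected every spectrum of class {c!r}")
    return out, rejected


@dataclass(frozen=True)
class IdentificationResult:
    """Models plus the tabular validation report of one pipeline run."""

    config: PipelineConfig
    simca: chem.SIMCAModel
    oplsda: chem.OPLSDAModel
    pca: chem.PCAModel
    report: dict
    calibration: chem.DataMatrix
    validation: chem.DataMatrix

    def report_json(self) -> str:
        return json.dumps(self.report, indent=2, default=_jsonable)

    def report_frame(self) -> pd.DataFrame:
        """Model-parameter table shaped like a standard chemometrics report."""
        rows = []
        rows.append({"model": "PCA", "part": "-",
                     "R2X": self.report["pca"]["r2x_cumulative"],
                     "Q2": self.report["pca"]["q2_cumulative"]})
        for c, d in self.report["simca"]["per_class"].items():
            rows.append({"model": "PCA-class", "part": c,
                         "R2X": d["r2x"], "Q2": d["q2"]})
        o = self.report["oplsda"]
        rows.append({"model": "OPLS-DA", "part": "-", "R2X": o["r2x"],
                     "R2Y": o["r2y"], "Q2Y": o["q2y"],
                     "R2Y_intercept": o.get("r2y_intercept"),
                     "Q2Y_intercept": o.get("q2y_intercept"),
                     "RMSEE": o["rmsee"], "RMSECV": o["rmsecv"],
                     "RMSEP": o["rmsep"]})
        return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_identification(coll: SpectrumCollection,
                       cfg: PipelineConfig | None = None) -> IdentificationResult:
    """QC -> preprocess -> split -> PCA + SIMCA + OPLS-DA -> validate."""
    cfg = cfg or PipelineConfig()
    coll, rejected = _apply_qc(coll)
    if len(coll.classes) < 2:
        raise DegenerateDataError("identification needs at least two classes")
    data = _features(coll, cfg)
    cal, val = chem.stratified_split(data, cfg.calibration_fraction, cfg.seed)

    n_pca = min(2, cal.n_samples - 1, cal.n_features)
    pca = chem.pca_fit(cal, n_pca)
    pca_q2_vals = chem.pca_q2(cal, n_pca, n_groups=cfg.cv_groups, seed=cfg.seed)

    simca = chem.simca_fit(cal, alpha=cfg.simca_alpha, n_groups=cfg.cv_groups,
                           seed=cfg.seed)
    membership = chem.simca_classify(simca, val)
    simca_per_class = {}
    for c in cal.classes:
        truth = np.asarray([t == c for t in val.y])
        pred = membership[f"member_{c}"].to_numpy()
        cm = np.array([
            [int(np.sum(truth & pred)), int(np.sum(truth & ~pred))],
            [int(np.sum(~truth & pred)), int(np.sum(~truth & ~pred))],
        ])
        # 2x2 layout: rows true in/out of class, cols predicted member/not
        tp, fn, fp, tn = cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1]
        total = cm.sum()
        cmdl = simca.class_models[c]
        simca_per_class[c] = {
            "components": cmdl.n_components,
            "r2x": cmdl.pca.r2x_cumulative,
            "q2": float(cmdl.q2[cmdl.n_components - 1]) if cmdl.q2 is not None else None,
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
            "accuracy": 100.0 * (tp + tn) / total,
        }

    oplsda = chem.oplsda_fit(cal, n_groups=cfg.cv_groups, seed=cfg.seed)
    labels_pred, _ = chem.oplsda_predict(oplsda, val)
    opls_metrics = chem.per_class_metrics(val.y, labels_pred, cal.classes)
    rmse = chem.rmse_metrics(oplsda, cal, val)
    report_opls = {
        "n_predictive": oplsda.n_predictive,
        "n_orthogonal": oplsda.n_orthogonal,
        "r2x": oplsda.r2x, "r2y": oplsda.r2y, "q2y": oplsda.q2y,
        "rmsee": rmse.rmsee, "rmsecv": rmse.rmsecv, "rmsep": rmse.rmsep,
        "per_class": opls_metrics.to_dict(orient="index"),
        "confusion": chem.confusion_matrix(val.y, labels_pred, cal.classes).tolist(),
    }
    if cfg.n_permutations >= 2:
        perm = chem.permutation_test(
            cal, n_permutations=cfg.n_permutations, seed=cfg.seed,
            n_predictive=oplsda.n_predictive, n_orthogonal=oplsda.n_orthogonal,
            n_groups=cfg.cv_groups)
        report_opls["r2y_intercept"] = perm.r2y_intercept
        report_opls["q2y_intercept"] = perm.q2y_intercept
        report_opls["permutation_valid"] = perm.valid

    report = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "qc_rejected": rejected,
        "n_calibration": cal.n_samples,
        "n_validation": val.n_samples,
        "pca": {
            "r2x_per_component": pca.explained_variance_ratio.tolist(),
            "r2x_cumulative": pca.r2x_cumulative,
            "q2_per_component": pca_q2_vals.tolist(),
            "q2_cumulative": float(pca_q2_vals[-1]),
        },
        "simca": {"alpha": cfg.simca_alpha, "per_class": simca_per_class},
        "oplsda": report_opls,
    }
    return IdentificationResult(cfg, simca, oplsda, pca, report, cal, val)


@dataclass(frozen=True)
class ScreenResult:
    """Per-query adulteration verdicts and the 'discriminated k of n' tally."""

    verdicts: pd.DataFrame
    n_queries: int
    n_discriminated_simca: int
    n_discriminated_oplsda: int
    n_discriminated_either: int

    def tally(self, method: str = "either") -> str:
        n = {"simca": self.n_discriminated_simca,
             "oplsda": self.n_discriminated_oplsda,
             "either": self.n_discriminated_either}[method]
        return f"discriminated {n} out of {self.n_queries}"


def run_adulteration_screen(result: IdentificationResult,
                            queries: SpectrumCollection,
                            target_class: str = "flower") -> ScreenResult:
    """Judge query spectra against the fitted target (flower) class.

    A query is discriminated from the target class when the SIMCA model
    rejects its class membership (DModX above the critical limit) or the
    OPLS-DA model predicts a different class.
    """
    if target_class not in result.calibration.classes:
        raise ParameterError(f"no {target_class!r} class in the fitted models")
    qdata = _features(queries, result.config)
    membership = chem.simca_classify(result.simca, qdata)
    dmodx = membership[f"dmodx_{target_class}"].to_numpy()
    simca_out = ~membership[f"member_{target_class}"].to_numpy()
    labels_pred, yhat = chem.oplsda_predict(result.oplsda, qdata)
    opls_out = labels_pred != target_class
    either = simca_out | opls_out
    verdicts = pd.DataFrame({
        "sample_id": [s.sample_id for s in queries.spectra],
        "dmodx_target": dmodx,
        "simca_discriminated": simca_out,
        "oplsda_predicted": labels_pred,
        "oplsda_discriminated": opls_out,
        "discriminated": either,
    })
    return ScreenResult(
        verdicts=verdicts, n_queries=len(queries),
        n_discriminated_simca=int(simca_out.sum()),
        n_discriminated_oplsda=int(opls_out.sum()),
        n_discriminated_either=int(either.sum()),
    )


def run_twodcos_report(series: PerturbationSeries,
                       windows=DEFAULT_WINDOWS,
                       min_prominence: float = 0.02,
                       max_cross_peaks: int = 10) -> dict:
    """Per-window synchronous/asynchronous maps with peak interpretation.

    For each window the report carries the maps, the ranked auto-peaks and
    sign-rule calls for the strongest auto-peak pairs.
    """
    out = {}
    for window in windows:
        d = dynamic_spectra(series, window=window)
        maps = TwoDMaps.compute(d, window=window)
        maps.validate()
        autos = extract_auto_peaks(maps, min_prominence)
        calls = []
        positions = autos.positions[:5]
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                calls.append(classify_cross_peak(maps, positions[i], positions[j]))
                if len(calls) >= max_cross_peaks:
                    break
            if len(calls) >= max_cross_peaks:
                break
        out[window] = {"maps": maps, "auto_peaks": autos, "cross_peaks": calls}
    return out
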