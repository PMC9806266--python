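"""Serialization of fitted pipelines to a single archive file.

A fitted :class:`~neuroconfound.pipeline.PredictionPipeline` (confound
correction, winsor/scale/PCA state, model coefficients and selected C)
round-trips through one ``.npz`` archive holding a JSON header plus the
numeric arrays, so a pipeline can be re-applied bit-identically elsewhere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .confounds import GroupDemeaner, Residualizer
from .models import LinearModelFit
from .pipeline import PredictionPipeline
from .preprocessing import FeatureProcessor, PcaReducer, _ProcessorState

__all__ = ["save_pipeline", "load_pipeline"]


def save_pipeline(pipe: PredictionPipeline, path: str | Path) -> Path:
    """Write a fitted pipeline to one ``.npz`` archive."""
    if pipe.model_ is None:
        raise ValueError("pipeline must be fitted before saving")
    header = {
        "task": pipe.task,
        "correction": pipe.correction,
        "use_pca": pipe.use_pca,
        "cv_folds": pipe.cv_folds,
        "seed": pipe.seed,
        "selected_C": pipe.model_.C,
        "intercept": pipe.model_.intercept,
        "used_pca": pipe.processor_.pca_ is not None,
        "n_train": pipe.processor_.state_.n_train,
    }
    arrays: dict[str, np.ndarray] = {
        "coef": pipe.model_.coef,
        "winsor_lower": pipe.processor_.winsorizer_.lower_,
        "winsor_upper": pipe.processor_.winsorizer_.upper_,
        "scale_mean": pipe.processor_.scaler_.mean_,
        "scale_scale": pipe.processor_.scaler_.scale_,
        "scale_zero_var": pipe.processor_.scaler_.zero_variance_,
    }
    if pipe.processor_.pca_ is not None:
        arrays["pca_components"] = pipe.processor_.pca_.components_
        arrays["pca_mean"] = pipe.processor_.pca_.mean_
        arrays["pca_explained"] = pipe.processor_.pca_.explained_variance_
    if pipe.classes_ is not None:
        arrays["classes"] = np.asarray(pipe.classes_)
    if isinstance(pipe.corrector_, GroupDemeaner):
        arrays["demean_groups"] = np.asarray(pipe.corrector_.groups_)
        for g in pipe.corrector_.groups_:
            arrays[f"demean_X_{g}"] = pipe.corrector_.feature_means_[g]
        if pipe.corrector_.target_means_:
            arrays["demean_y"] = np.array(
                [pipe.corrector_.target_means_[g] for g in pipe.corrector_.groups_]
            )
    elif isinstance(pipe.corrector_, Residualizer):
        arrays["resid_intercept"] = pipe.corrector_.intercept_
        arrays["resid_slope"] = pipe.corrector_.slope_
    path = Path(path)
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_pipeline(path: str | Path) -> PredictionPipeline:
    """Rebuild a fitted pipeline from an archive written by save_pipeline."""
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(bytes(z["header"]).decode())
        pipe = PredictionPipeline(
            task=header["task"],
            correction=header["correction"],
            use_pca=header["use_pca"],
            cv_folds=header["cv_folds"],
            seed=header["seed"],
        )
        proc = FeatureProcessor(use_pca=header["use_pca"])
        proc.winsorizer_.lower_ = z["winsor_lower"]
        proc.winsorizer_.upper_ = z["winsor_upper"]
        proc.scaler_.mean_ = z["scale_mean"]
        proc.scaler_.scale_ = z["scale_scale"]
        proc.scaler_.zero_variance_ = z["scale_zero_var"]
        if header["used_pca"]:
            pca = PcaReducer(z["pca_components"].shape[0])
            pca.components_ = z["pca_components"]
            pca.mean_ = z["pca_mean"]
            pca.explained_variance_ = z["pca_explained"]
            proc.pca_ = pca
        proc.state_ = _ProcessorState(
            used_pca=header["used_pca"], n_train=header["n_train"]
        )
        pipe.processor_ = proc
        pipe.model_ = LinearModelFit(
            coef=z["coef"],
            intercept=header["intercept"],
            C=header["selected_C"],
            task=header["task"],
        )
        pipe.selection_log_ = {"selected_C": header["selected_C"], "loaded": True}
        if "classes" in z:
            pipe.classes_ = z["classes"]
        if header["correction"] == "demean_by_group":
            dm = GroupDemeaner()
            dm.groups_ = z["demean_groups"]
            dm.feature_means_ = {g: z[f"demean_X_{g}"] for g in dm.groups_}
            dm.target_means_ = {}
            if "demean_y" in z:
                dm.target_means_ = dict(zip(dm.groups_, z["demean_y"].tolist()))
            pipe.corrector_ = dm
        elif header["correction"] == "residualize_on_covariate":
            rz = Residualizer()
            rz.intercept_ = z["resid_intercept"]
            rz.slope_ = z["resid_slope"]
            pipe.corrector_ = rz
    return pipe
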