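"""End-to-end experiment orchestration.

Reproduces the study's experimental matrix — three wavelength selectors
crossed with {full spectra, selected wavelengths} and six models — on
simulated or loaded data: simulate/load -> trim -> FD+SNV -> split ->
[select] -> fit -> evaluate. Four machine-readable report tables are
written:

* ``t4_full_classification.csv`` — PLS-DA / SVC / CNNC on full spectra;
* ``t5_selected_classification.csv`` — the same models per selector subset;
* ``t6_selected_regression.csv`` — PLSR / SVR / CNNR per selector subset;
* ``t7_identification.csv`` — regression models scored as classifiers by
  binning their predicted LNC.

plus a ``manifest.json`` reconciling every metric to (model, data variant,
split, n) and recording seeds and package versions. A failing combination
is logged and skipped; the run reports which combinations failed.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classical import PlsConfig, SvmGridConfig, fit_plsda, fit_plsr, fit_svm, predict_model
from .cnn import CnnTrainingProtocol, build_cnnc, build_cnnr, predict_cnn, train_cnn
from .evaluation import (
    NitrogenLevelScheme,
    evaluate_classifier,
    evaluate_regressor,
    identify_from_regression,
)
from .io_datasets import read_spectra_csv, split_dataset, trim_wavelengths
from .preprocess import PreprocessConfig, fd_snv
from .selection import (
    RandomFrogConfig,
    SaliencyConfig,
    WplsConfig,
    random_frog,
    saliency_select,
    subset_dataset,
    wpls_select,
)
from .synthetic import SyntheticConfig, generate_dataset
from .types import SplitSpec

CLASSIFIERS = ("plsda", "svc", "cnnc")
REGRESSORS = ("plsr", "svr", "cnnr")
SELECTORS = ("random_frog", "wpls", "saliency")


@dataclass
class RunConfig:
    """Configuration of one experiment run (YAML-mappable)."""

    input_csv: str | None = None  # load instead of simulating when set
    simulate: dict = field(default_factory=dict)  # SyntheticConfig overrides
    trim: tuple = (430.0, 2500.0)
    preprocess: dict = field(default_factory=dict)  # PreprocessConfig overrides
    split: dict = field(default_factory=dict)  # SplitSpec overrides
    scheme: tuple = (25.01, 35.0)
    selectors: tuple = SELECTORS
    classifiers: tuple = CLASSIFIERS
    regressors: tuple = REGRESSORS
    top_k: int = 40
    frog_iterations: int = 2000
    pls_max_lv: int = 15
    svm_exponent_range: tuple = (-8, 8)
    cnn_epochs: int = 300
    saliency_cnn_epochs: int = 20
    out_dir: str = "leafspec_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _svm_cfg(cfg: RunConfig) -> SvmGridConfig:
    lo, hi = cfg.svm_exponent_range
    exps = tuple(range(int(lo), int(hi) + 1))
    return SvmGridConfig(c_exponents=exps, g_exponents=exps, seed=cfg.seed)


def _fit_predict(model: str, cal, val, cfg: RunConfig):
    """Fit one model on the calibration split; return a predict callable."""
    if model == "plsda":
        h = fit_plsda(cal, PlsConfig(max_latent_variables=cfg.pls_max_lv, seed=cfg.seed))
    elif model == "plsr":
        h = fit_plsr(cal, PlsConfig(max_latent_variables=cfg.pls_max_lv, seed=cfg.seed))
    elif model == "svc":
        h = fit_svm(cal, "classification", _svm_cfg(cfg))
    elif model == "svr":
        h = fit_svm(cal, "regression", _svm_cfg(cfg))
    elif model in ("cnnc", "cnnr"):
        proto = CnnTrainingProtocol(max_epochs=cfg.cnn_epochs, seed=cfg.seed)
        if model == "cnnc":
            n_classes = len(pd.unique(cal.meta["level"].dropna()))
            h = build_cnnc(cal.n_wavelengths, n_classes, seed=cfg.seed)
        else:
            h = build_cnnr(cal.n_wavelengths, seed=cfg.seed)
        h = train_cnn(h, cal, val, proto)
        return h, (lambda ds, h=h: predict_cnn(h, ds))
    else:
        raise ValueError(f"unknown model {model!r}")
    return h, (lambda ds, h=h: predict_model(h, ds))


def _select(selector: str, task: str, cal, full_cal, full_val, cfg: RunConfig):
    if selector == "random_frog":
        res = random_frog(
            cal,
            task,
            RandomFrogConfig(
                n_iterations=cfg.frog_iterations, top_k=cfg.top_k, seed=cfg.seed
            ),
        )
    elif selector == "wpls":
        res = wpls_select(cal, WplsConfig(k=cfg.top_k, seed=cfg.seed), task=task)
    elif selector == "saliency":
        proto = CnnTrainingProtocol(
            max_epochs=cfg.saliency_cnn_epochs, patience=cfg.saliency_cnn_epochs,
            seed=cfg.seed,
        )
        if task == "classification":
            n_classes = len(pd.unique(cal.meta["level"].dropna()))
            h = build_cnnc(cal.n_wavelengths, n_classes, seed=cfg.seed)
        else:
            h = build_cnnr(cal.n_wavelengths, seed=cfg.seed)
        h = train_cnn(h, full_cal, full_val, proto)
        res = saliency_select(
            h, full_cal, SaliencyConfig(final_top_k=cfg.top_k, seed=cfg.seed)
        )
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return res


def run_experiment(cfg: RunConfig) -> dict:
    """Execute the configured matrix; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    if cfg.input_csv:
        ds = read_spectra_csv(cfg.input_csv)
    else:
        ds = generate_dataset(SyntheticConfig(**{"seed": cfg.seed, **cfg.simulate}))
    ds = trim_wavelengths(ds, *cfg.trim)
    ds = fd_snv(ds, PreprocessConfig(**cfg.preprocess))
    ds = split_dataset(ds, SplitSpec(**{"seed": cfg.seed, **cfg.split}))
    cal, val = ds.subset_split("cal"), ds.subset_split("val")
    scheme = NitrogenLevelScheme(*cfg.scheme)
    log(f"dataset: {ds.n_samples} samples x {ds.n_wavelengths} wavelengths")

    failures = []
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "n_samples": ds.n_samples,
        "n_wavelengths": ds.n_wavelengths,
        "tables": {},
        "selections": {},
        "failures": failures,
    }

    def guarded(label, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - abort combination, continue run
            failures.append({"combination": label, "error": repr(exc)})
            log(f"FAILED {label}: {exc}\n{traceback.format_exc()}")
            return None

    # --- T4: full-spectra classification -------------------------------
    t4 = []
    for model in cfg.classifiers:
        def run_t4(model=model):
            _, predict = _fit_predict(model, cal, val, cfg)
            rep = evaluate_classifier(predict, ds)
            for _, r in rep.iterrows():
                t4.append({"model": model, "split": r["split"], "n": r["n"],
                           "accuracy": r["accuracy"]})
        guarded(f"t4/{model}", run_t4)
    if t4:
        pd.DataFrame(t4).to_csv(out / "t4_full_classification.csv", index=False)
        manifest["tables"]["t4"] = "t4_full_classification.csv"

    # --- selections ----------------------------------------------------
    selections = {}
    for task in ("classification", "regression"):
        if not cfg.selectors:
            continue
        if task == "classification" and not cfg.classifiers:
            continue
        if task == "regression" and not cfg.regressors:
            continue
        for selector in cfg.selectors:
            def run_sel(selector=selector, task=task):
                res = _select(selector, task, cal, cal, val, cfg)
                res.to_json(out / f"selection_{selector}_{task}.json")
                selections[(selector, task)] = res
                manifest["selections"][f"{selector}/{task}"] = {
                    "file": f"selection_{selector}_{task}.json",
                    "n_selected": int(len(res.selected_nm)),
                }
            guarded(f"select/{selector}/{task}", run_sel)

    # --- T5: selected-wavelength classification ------------------------
    t5 = []
    for (selector, task), res in selections.items():
        if task != "classification":
            continue
        sub = subset_dataset(ds, res.selected_nm)
        sub_cal, sub_val = sub.subset_split("cal"), sub.subset_split("val")
        for model in cfg.classifiers:
            def run_t5(model=model, selector=selector, sub=sub, sub_cal=sub_cal, sub_val=sub_val):
                _, predict = _fit_predict(model, sub_cal, sub_val, cfg)
                rep = evaluate_classifier(predict, sub)
                for _, r in rep.iterrows():
                    t5.append({"selector": selector, "model": model, "split": r["split"],
                               "n": r["n"], "accuracy": r["accuracy"]})
            guarded(f"t5/{selector}/{model}", run_t5)
    if t5:
        pd.DataFrame(t5).to_csv(out / "t5_selected_classification.csv", index=False)
        manifest["tables"]["t5"] = "t5_selected_classification.csv"

    # --- T6 + T7: regression and identification ------------------------
    t6, t7 = [], []
    variants = [("full", None)] + [
        (sel, res) for (sel, task), res in selections.items() if task == "regression"
    ]
    for name, res in variants:
        sub = ds if res is None else subset_dataset(ds, res.selected_nm)
        sub_cal, sub_val = sub.subset_split("cal"), sub.subset_split("val")
        for model in cfg.regressors:
            def run_reg(model=model, name=name, sub=sub, sub_cal=sub_cal, sub_val=sub_val):
                _, predict = _fit_predict(model, sub_cal, sub_val, cfg)
                if name != "full":
                    rep = evaluate_regressor(predict, sub)
                    for _, r in rep.iterrows():
                        t6.append({"selector": name, "model": model, "split": r["split"],
                                   "n": r["n"], "r2": r["r2"], "rmse": r["rmse"]})
                idrep = identify_from_regression(predict, sub, scheme)
                for _, r in idrep.iterrows():
                    t7.append({"data_type": name, "model": model, "split": r["split"],
                               "n": r["n"], "accuracy": r["accuracy"]})
            guarded(f"t6t7/{name}/{model}", run_reg)
    if t6:
        pd.DataFrame(t6).to_csv(out / "t6_selected_regression.csv", index=False)
        manifest["tables"]["t6"] = "t6_selected_regression.csv"
    if t7:
        pd.DataFrame(t7).to_csv(out / "t7_identification.csv", index=False)
        manifest["tables"]["t7"] = "t7_identification.csv"

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
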