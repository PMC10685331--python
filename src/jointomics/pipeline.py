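"""End-to-end orchestration: simulate -> train -> evaluate -> report.

A run is described by a config mapping (usually loaded from YAML)::

    seed: 7
    dataset:
      preset: gaussian-pair        # or  dir: /path/to/dataset
      n_samples: 500
    flavors: [poe, cgvae]
    network: {latent_dim: 16, hidden_layers: [32], max_epochs: 30}
    evaluation:
      impute: true
      coherence: false
      classify: false
      impute_classify: false
      factors: false
      coherence_draws: 2000

Every artifact (dataset, checkpoints, report TSVs, summary.json, effective
config) lands under the output directory; re-running with an identical
config reproduces identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import yaml

from . import evaluation as ev
from .data import read_dataset, write_dataset
from .linear import GLMImputer, MeanImputer, pca_fit_transform
from .models import NetworkConfig, encoder_input, train
from .synthetic import generate, preset_config

log = logging.getLogger("jointomics")

DEFAULT_EVALUATION = {
    "impute": True,
    "coherence": False,
    "classify": False,
    "impute_classify": False,
    "factors": False,
    "coherence_draws": 2000,
}


def _load_dataset(cfg: dict, seed: int, out_dir: str):
    dcfg = cfg.get("dataset", {})
    if "dir" in dcfg:
        return read_dataset(dcfg["dir"])
    preset = dcfg.get("preset", "gaussian-pair")
    n = int(dcfg.get("n_samples", 1000))
    scfg = preset_config(preset, n_samples=n, seed=seed)
    dataset, _ = generate(scfg)
    if cfg.get("write_dataset", True):
        write_dataset(os.path.join(out_dir, "dataset"), dataset,
                      format=dcfg.get("format", "csv"))
    return dataset


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Execute the requested stages; returns the summary dict (also written
    to ``out_dir/summary.json``)."""
    os.makedirs(out_dir, exist_ok=True)
    if "seed" not in config:
        raise ValueError("config must set an explicit seed")
    seed = int(config["seed"])
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    log.info("stage: dataset")
    dataset = _load_dataset(config, seed, out_dir)
    flavors = list(config.get("flavors", ["poe"]))
    net_kwargs = dict(config.get("network", {}))
    net_kwargs.setdefault("seed", seed)
    evcfg = {**DEFAULT_EVALUATION, **config.get("evaluation", {})}

    results = {}
    for flavor in flavors:
        log.info("stage: train %s", flavor)
        res = train(flavor, dataset, NetworkConfig(**net_kwargs),
                    reference_modality=int(config.get("reference_modality", 0)))
        res.save(os.path.join(out_dir, f"{flavor}.ckpt.npz"))
        res.history.to_csv(os.path.join(out_dir, f"{flavor}_history.csv"), index=False)
        results[flavor] = res

    report = ev.EvaluationReport()
    M = dataset.n_modalities
    names = [s.name for s in dataset.specs]
    if evcfg["impute"] and results:
        log.info("stage: evaluate imputation")
        glm = GLMImputer.fit(dataset)
        meanimp = MeanImputer.fit(dataset)
        for s in range(M):
            for t in range(M):
                if s == t:
                    continue
                task = f"{names[s]}->{names[t]}"
                lls = {}
                for flavor, res in results.items():
                    try:
                        r = ev.imputation_eval(res, dataset, [s], t)
                    except Exception as exc:  # refvae cannot encode non-reference
                        log.info("skip %s %s: %s", flavor, task, exc)
                        continue
                    report.imputation[(flavor, task)] = r
                    lls[flavor] = r.ll
                base = ev.imputation_eval(glm, dataset, [s], t)
                report.imputation[("glm", task)] = base
                report.imputation[("train-mean", task)] = ev.imputation_eval(
                    meanimp, dataset, [s], t)
                if lls:
                    tests = ev.compare_to_baseline(lls, base.ll)
                    tests.insert(0, "task", task)
                    report.tests = tests if report.tests is None else (
                        __import__("pandas").concat([report.tests, tests],
                                                    ignore_index=True))
    classifiers = None
    if evcfg["coherence"] and results:
        log.info("stage: evaluate coherence")
        classifiers = [
            ev.train_modality_classifier(
                X, dataset.labels, dataset.split, spec=spec,
                config=ev.ClassifierConfig(hidden=[64, 64], seed=seed, epochs=50,
                                           learning_rate=1e-3))
            for spec, X in dataset.modalities
        ]
        for flavor, res in results.items():
            report.coherence[flavor] = ev.coherence_eval(
                res, classifiers, n=int(evcfg["coherence_draws"]),
                rng=np.random.default_rng([seed, 11]))
    pca_maps = None
    if evcfg["classify"] or evcfg["impute_classify"]:
        tr = dataset.split_subset("train")
        pca_maps = []
        pcs = []
        k = int(config.get("n_pcs", 32))
        for spec, X in dataset.modalities:
            feats = encoder_input(X, spec)
            kk = min(k, min(tr.n_samples, feats.shape[1]))
            maps, _ = pca_fit_transform(encoder_input(tr.matrix(spec.name), spec), kk)
            pca_maps.append(maps)
            pcs.append(maps.transform(feats))
    if evcfg["classify"] and results:
        log.info("stage: evaluate classification")
        Xcat = np.concatenate(pcs, axis=1)
        report.classification[("pca-concat", "all", "mlp")] = ev.downstream_classify(
            Xcat, dataset.labels, dataset.split, classifier="mlp", seed=seed)
        Xs = [X for _, X in dataset.modalities]
        for flavor, res in results.items():
            try:
                feats = res.encode(Xs).loc
            except Exception as exc:
                log.info("skip classify %s: %s", flavor, exc)
                continue
            report.classification[(flavor, "all", "mlp")] = ev.downstream_classify(
                np.asarray(feats), dataset.labels, dataset.split,
                classifier="mlp", seed=seed)
    if evcfg["impute_classify"] and results and M == 2:
        log.info("stage: evaluate impute-then-classify")
        Xcat = np.concatenate(pcs, axis=1)
        multi = ev.downstream_classify(Xcat, dataset.labels, dataset.split,
                                       classifier="mlp", seed=seed).classifier
        for flavor, res in results.items():
            for measured in range(M):
                try:
                    _, agreement, _ = ev.impute_then_classify(
                        res, dataset, measured, pca_maps, multi)
                except Exception as exc:
                    log.info("skip impute-classify %s: %s", flavor, exc)
                    continue
                report.agreement[(flavor, names[measured])] = agreement
    if evcfg["factors"] and results:
        log.info("stage: classify factors")
        from .joint_signal import classify_factors

        for flavor, res in results.items():
            try:
                fc = classify_factors(res, dataset,
                                      n_permutations=int(evcfg.get("n_permutations", 199)),
                                      seed=seed)
            except Exception as exc:
                log.info("skip factors %s: %s", flavor, exc)
                continue
            report.factor_tables[flavor] = fc.table

    report.write(out_dir)
    summary = report.summary_dict()
    summary["flavors"] = sorted(results)
    summary["best_val_loss"] = {f: results[f].best_val_loss for f in sorted(results)}
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
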