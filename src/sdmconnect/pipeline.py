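"""End-to-end orchestration: configuration, per-stage seeding, and the
full replay of the analysis on a synthetic landscape.

The stage order mirrors the study design: variable preparation and
pruning, occurrence thinning and pseudo-absence construction, the
presence/absence model zoo with an 80/20 split, AUC-weighted ensemble
and max-TSS binarization with protected-area accounting, circuit-theory
connectivity between the focal nodes, and random-forest variable
importance.  Every stochastic stage derives its seed deterministically
from the global seed and the stage name, so any stage can be re-run in
isolation and the whole bundle is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuit, ensemble, evaluation, forest, models, occurrences, synthetic
from .raster import NodeRaster, RasterGrid, RasterStack, write_raster

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All pipeline knobs; round-trips losslessly through YAML."""

    # synthetic landscape
    n_rows: int = 150
    n_cols: int = 150
    n_layers: int = 10
    range_param: float = 8.0
    cell_size: float = 1000.0
    cross_corr_pairs: dict = field(default_factory=lambda: {"bio3|bio11": 0.85})
    truth_beta0: float = -2.0
    truth_betas: dict = field(
        default_factory=lambda: {"bio19": 3.0, "bio7": -2.0, "bio17": 2.0}
    )
    n_presence: int = 80
    n_nodes: int = 6
    node_mean_radius: float = 6.0
    scenarios: dict = field(
        default_factory=lambda: {
            "rcp26": {"deltas": {"bio7": 0.3}, "factors": {"bio19": 0.9}},
            "rcp85": {"deltas": {"bio7": 1.0}, "factors": {"bio19": 0.6, "bio17": 0.7}},
        }
    )
    # occurrence prep
    corr_threshold: float = 0.75
    thin_dist: float = 5000.0
    pa_multiplier: int = 2
    pa_min_dist: float = 5000.0
    # models
    model_list: list = field(default_factory=lambda: ["glm", "maxent", "svm", "ann"])
    split_fraction: float = 0.8
    ocsvm_nu: float = 0.1
    svm_C: float = 1.0
    ann_hidden: int = 8
    ann_epochs: int = 500
    maxent_beta: float = 0.05
    # ensemble / range
    weight_rule: str = "auc"
    po_rule: str = "majority"
    threshold_mode: str = "all"  # "all" (stacked binary) or "test"
    # connectivity
    resistance_transform: str = "inverse"
    resistance_floor: float = 0.01
    neighborhood: int = 8
    pinch_quantile: float = 0.999
    # importance
    n_trees: int = 500
    # global
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def cross_corr_matrix(self, names: list[str]) -> np.ndarray:
        C = np.eye(len(names))
        for pair, r in self.cross_corr_pairs.items():
            a, b = pair.split("|")
            if a in names and b in names:
                i, j = names.index(a), names.index(b)
                C[i, j] = C[j, i] = r
        return C


@dataclass
class PipelineResult:
    """In-memory outputs of a full run."""

    stack: RasterStack
    truth: synthetic.TruthModel
    nodes: NodeRaster
    occ: occurrences.OccurrenceSet
    kept_layers: list
    dropped_layers: list
    thinned: occurrences.OccurrenceSet
    pseudo_absences: occurrences.OccurrenceSet
    training_set: occurrences.OccurrenceSet
    po_models: dict
    pa_models: dict
    split: models.TrainTestSplit
    reports: pd.DataFrame
    ensemble_map: RasterGrid
    threshold: float
    scenario_maps: dict
    scenario_table: pd.DataFrame
    pair_table: pd.DataFrame
    cumulative: RasterGrid
    pinch: RasterGrid
    importance: pd.DataFrame
    test_auc: dict


def _env_at(stack: RasterStack, names: list[str], occ: occurrences.OccurrenceSet) -> np.ndarray:
    sub = stack.subset(names)
    xy = occ.data[["x", "y"]].to_numpy(dtype=float)
    return sub.extract(xy[:, 0], xy[:, 1])


def simulate_inputs(cfg: PipelineConfig):
    """Generate the synthetic input bundle the real study would load."""
    names = synthetic.default_layer_names(cfg.n_layers)
    stack = synthetic.make_environment(
        cfg.n_rows,
        cfg.n_cols,
        cfg.n_layers,
        range_param=cfg.range_param,
        cross_corr=cfg.cross_corr_matrix(names),
        seed=stage_seed(cfg.seed, "environment"),
        cell_size=cfg.cell_size,
        layer_names=names,
    )
    truth = synthetic.TruthModel(cfg.truth_beta0, cfg.truth_betas)
    occ = synthetic.sample_occurrences(
        truth, stack, cfg.n_presence, seed=stage_seed(cfg.seed, "occurrences")
    )
    nodes = synthetic.make_nodes(
        stack.template,
        cfg.n_nodes,
        cfg.node_mean_radius,
        seed=stage_seed(cfg.seed, "nodes"),
    )
    scen = {
        name: synthetic.ScenarioShift(
            name=name, deltas=d.get("deltas", {}), factors=d.get("factors", {})
        )
        for name, d in cfg.scenarios.items()
    }
    return stack, truth, occ, nodes, scen


def run_all(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on the synthetic bundle; optionally write outputs."""
    t0 = time.time()
    log: list[dict] = []

    def _log(stage: str, **kw):
        log.append({"stage": stage, "elapsed_s": round(time.time() - t0, 2), **kw})

    stack, truth, occ, nodes, scenarios = simulate_inputs(cfg)
    _log("simulate", n_presence=len(occ))

    # --- variable pruning and spatial thinning
    kept, dropped, corr = occurrences.prune_correlated(stack, cfg.corr_threshold)
    thinned = occurrences.thin_occurrences(
        occ, cfg.thin_dist, seed=stage_seed(cfg.seed, "thin")
    )
    _log("prep", kept=len(kept), dropped=len(dropped), thinned=len(thinned))

    # --- presence-only models -> pseudo-absence pool
    Xp = _env_at(stack, kept, thinned)
    po_models = {
        "bioclim": models.fit_bioclim(Xp, kept),
        "domain": models.fit_domain(Xp, kept),
        "ocsvm": models.fit_ocsvm(Xp, kept, nu=cfg.ocsvm_nu),
    }
    sub = stack.subset(kept)
    models.calibrate_ocsvm(po_models["ocsvm"], sub.env_matrix())
    po_binaries = []
    for name, m in po_models.items():
        cont = models.predict_raster(m, sub)
        # zero-omission threshold: minimum score over training presences
        th = float(m.predict(Xp).min())
        po_binaries.append(ensemble.binarize(cont, th - 1e-12))
    po_bin = ensemble.ensemble_binary_po(po_binaries, rule=cfg.po_rule)
    pabs = occurrences.generate_pseudo_absences(
        sub,
        thinned,
        po_bin,
        multiplier=cfg.pa_multiplier,
        min_dist=cfg.pa_min_dist,
        seed=stage_seed(cfg.seed, "pseudo_absence"),
    )
    training_set = thinned.merge(pabs)
    _log("pseudo_absence", n=len(pabs))

    # --- presence/absence models on the 80/20 split
    X = _env_at(stack, kept, training_set)
    y = training_set.labels01()
    split = models.stratified_split(
        y, cfg.split_fraction, seed=stage_seed(cfg.seed, "split")
    )
    Xtr, ytr = X[split.train_idx], y[split.train_idx]
    Xte, yte = X[split.test_idx], y[split.test_idx]
    pa_models: dict[str, models.SuitabilityModel] = {}
    for kind in cfg.model_list:
        if kind == "glm":
            pa_models[kind] = models.fit_glm(Xtr, ytr, kept)
        elif kind == "maxent":
            pa_models[kind] = models.fit_maxent(
                Xtr[ytr == 1], sub.env_matrix(), kept, beta=cfg.maxent_beta
            )
        elif kind == "svm":
            pa_models[kind] = models.fit_svm(Xtr, ytr, kept, C=cfg.svm_C)
        elif kind == "ann":
            pa_models[kind] = models.fit_ann(
                Xtr,
                ytr,
                kept,
                hidden=cfg.ann_hidden,
                epochs=cfg.ann_epochs,
                seed=stage_seed(cfg.seed, "ann"),
            )
        else:
            raise ValueError(f"unknown model kind {kind!r}")
    _log("fit", models=list(pa_models))

    # --- evaluation on held-out data; ensemble weights from test AUC
    rows = []
    test_auc = {}
    model_maps = {}
    ens_scores_all = None
    for kind, m in pa_models.items():
        rep = evaluation.evaluate_scores(kind, m.predict(Xte), yte)
        test_auc[kind] = rep.auc
        rows.append(rep.as_row())
        model_maps[kind] = models.predict_raster(m, sub)
    if len(pa_models) >= 2:
        # the ensemble needs at least two members to average
        weights = ensemble.ensemble_weights(test_auc, cfg.weight_rule)
        ens_test = sum(w * pa_models[k].predict(Xte) for k, w in weights.items())
        ens_all = sum(w * pa_models[k].predict(X) for k, w in weights.items())
        rep_ens = evaluation.evaluate_scores("ensemble", ens_test, yte)
        rows.append(rep_ens.as_row())
        ens_map = ensemble.ensemble_continuous(model_maps, test_auc, cfg.weight_rule)
    else:
        only = next(iter(pa_models))
        ens_test = pa_models[only].predict(Xte)
        ens_all = pa_models[only].predict(X)
        rep_ens = evaluation.evaluate_scores(only, ens_test, yte)
        ens_map = model_maps[only]
    reports = pd.DataFrame(rows)
    _log("evaluate", ensemble_auc=rep_ens.auc)

    # --- threshold + scenario range maps
    if cfg.threshold_mode == "all":
        threshold = evaluation.max_tss_threshold(evaluation.tss_curve(ens_all, y))
    else:
        threshold = rep_ens.threshold
    scen_maps = {"current": ensemble.binarize(ens_map, threshold)}
    for name, shift in scenarios.items():
        shifted = synthetic.apply_scenario(sub, shift)
        maps_s = {k: models.predict_raster(m, shifted) for k, m in pa_models.items()}
        cont_s = ensemble.ensemble_continuous(maps_s, test_auc, cfg.weight_rule)
        scen_maps[name] = ensemble.binarize(cont_s, threshold)
    scen_table = ensemble.scenario_report(scen_maps, nodes, valid_mask=sub.mask)
    _log("range", threshold=threshold)

    # --- connectivity
    resist = circuit.resistance_from_suitability(
        ens_map,
        floor=cfg.resistance_floor,
        transform=cfg.resistance_transform,
    )
    network = circuit.build_network(resist, cfg.neighborhood)
    results, pair_table = circuit.solve_all_pairs(network, nodes)
    cumulative = circuit.cumulative_current(results)
    pinch = circuit.pinch_points(cumulative, cfg.pinch_quantile)
    _log("connect", n_pairs=len(results))

    # --- variable importance
    rf = forest.fit_forest(
        X, y, n_trees=cfg.n_trees, seed=stage_seed(cfg.seed, "forest")
    )
    imp = forest.importance_table(
        rf, X, y, kept, seed=stage_seed(cfg.seed, "permute")
    )
    _log("importance", top=imp.iloc[0]["variable"])

    result = PipelineResult(
        stack=stack,
        truth=truth,
        nodes=nodes,
        occ=occ,
        kept_layers=kept,
        dropped_layers=dropped,
        thinned=thinned,
        pseudo_absences=pabs,
        training_set=training_set,
        po_models=po_models,
        pa_models=pa_models,
        split=split,
        reports=reports,
        ensemble_map=ens_map,
        threshold=threshold,
        scenario_maps=scen_maps,
        scenario_table=scen_table,
        pair_table=pair_table,
        cumulative=cumulative,
        pinch=pinch,
        importance=imp,
        test_auc=test_auc,
    )
    if out_dir is not None:
        _write_bundle(result, cfg, corr, log, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_bundle(
    res: PipelineResult,
    cfg: PipelineConfig,
    corr: pd.DataFrame,
    log: list[dict],
    out: Path,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path):
        written.append(path)

    cfg.to_yaml(out / "config.yaml")
    _w(out / "config.yaml")
    corr.to_csv(out / "correlation_matrix.csv")
    _w(out / "correlation_matrix.csv")
    pd.DataFrame(
        {"layer": res.kept_layers + res.dropped_layers,
         "status": ["kept"] * len(res.kept_layers) + ["dropped"] * len(res.dropped_layers)}
    ).to_csv(out / "pruned_variables.csv", index=False)
    _w(out / "pruned_variables.csv")
    res.thinned.to_csv(out / "occurrences_thinned.csv")
    _w(out / "occurrences_thinned.csv")
    res.pseudo_absences.to_csv(out / "pseudo_absences.csv")
    _w(out / "pseudo_absences.csv")
    for kind, m in {**res.po_models, **res.pa_models}.items():
        models.save_model(m, out / f"model_{kind}.json")
        _w(out / f"model_{kind}.json")
    res.reports.to_csv(out / "evaluation.csv", index=False)
    _w(out / "evaluation.csv")
    write_raster(res.ensemble_map, out / "ensemble_continuous.asc")
    _w(out / "ensemble_continuous.asc")
    for name, grid in res.scenario_maps.items():
        write_raster(grid, out / f"binary_{name}.asc")
        _w(out / f"binary_{name}.asc")
    res.scenario_table.to_csv(out / "scenario_report.csv", index=False)
    _w(out / "scenario_report.csv")
    res.pair_table.to_csv(out / "pairwise_connectivity.csv", index=False)
    _w(out / "pairwise_connectivity.csv")
    write_raster(res.cumulative, out / "cumulative_current.asc")
    _w(out / "cumulative_current.asc")
    write_raster(res.pinch, out / "pinch_points.asc")
    _w(out / "pinch_points.asc")
    write_raster(res.nodes.as_grid(), out / "nodes.asc")
    _w(out / "nodes.asc")
    res.importance.to_csv(out / "importance.csv", index=False)
    _w(out / "importance.csv")
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s)
            for s in [
                "environment",
                "occurrences",
                "nodes",
                "thin",
                "pseudo_absence",
                "split",
                "ann",
                "forest",
                "permute",
            ]
        },
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
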