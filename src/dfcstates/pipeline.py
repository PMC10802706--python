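"""End-to-end orchestration: simulate -> preprocess -> DFC -> states ->
nulls -> association -> mediation -> graphs, from one config dict.

One global seed is split deterministically per stage through
``numpy.random.SeedSequence``, so a single integer reproduces a full run.
Each run directory receives a manifest with the canonical config hash;
a failed stage leaves a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import association_screen
from .dfc import DfcSeries, build_taper, windowed_corr
from .graphs import SignedGraphSet, node_strength, state_mean_dfc
from .io import load_parcellation, write_behavior, write_timecourse
from .mediation import bootstrap_mediation
from .nulls import stationarity_test
from .preprocess import PreprocConfig, preprocess
from .states import elbow_select, fit_kmeans, fractional_rates
from .synthetic import CohortSpec, StateSpec, make_state_covariances, simulate_cohort

log = logging.getLogger("dfcstates")

STAGE_ORDER = ("simulate", "preprocess", "dfc", "states", "nulls",
               "assoc", "mediate", "graph")

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "stages": list(STAGE_ORDER),
    "simulate": {"K": 5, "n_subjects": 24, "n_sites": 4,
                 "families_per_site": 6, "T": 380, "tr_seconds": 0.8,
                 "write_scans": False},
    "preprocess": {"detrend_max_order": 3, "bandpass_lo_hz": 0.01,
                   "bandpass_hi_hz": 0.15, "outlier_z": 3.0},
    "dfc": {"width_tr": 40, "sigma_tr": 3.0, "step": 1},
    "states": {"K": 5, "n_init": 10, "run_elbow": False,
               "elbow_k_min": 2, "elbow_k_max": 10},
    "nulls": {"n_scans": 3, "n_surr": 49, "method": "phase"},
    "assoc": {"fdr_q": 0.05, "fdr_scope": "global"},
    "mediate": {"x_state": 0, "m": "cbcl_attention", "y": "nihtbx_fluid",
                "n_boot": 2000},
    "graph": {"state_a": 0, "state_b": -1, "variant": "absolute"},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _merge(base: Dict, override: Optional[Dict]) -> Dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def config_hash(config: Dict) -> str:
    """Stable hash of a config: key order never matters."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: Optional[Dict] = None, out_dir="run") -> Path:
    """Execute the enabled stages in fixed order into ``out_dir``."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    seeds = {s: int(c.generate_state(1)[0] % (2 ** 31))
             for s, c in zip(STAGE_ORDER,
                             np.random.SeedSequence(cfg["seed"]).spawn(
                                 len(STAGE_ORDER)))}
    manifest = {"version": __version__, "config": cfg,
                "config_hash": config_hash(cfg), "stage_seeds": seeds,
                "stages_run": stages, "timestamps": {}}
    ctx: Dict = {"parcellation": load_parcellation()}
    for stage in stages:
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            _STAGES[stage](cfg, seeds[stage], ctx, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
            raise StageError(stage, exc) from exc
        manifest["timestamps"][stage] = round(time.time() - t0, 3)
        log.info("stage %s: done in %.1fs", stage, manifest["timestamps"][stage])
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return out


def _stage_simulate(cfg, seed, ctx, out: Path) -> None:
    sc = cfg["simulate"]
    spec = make_state_covariances(ctx["parcellation"], K=sc["K"], seed=seed)
    cohort = CohortSpec(seed=seed, **{k: v for k, v in sc.items()
                                      if k not in ("K", "write_scans")})
    scans, behavior, truth = simulate_cohort(spec, cohort)
    ctx.update(scans=scans, behavior=behavior, truth=truth, state_spec=spec)
    write_behavior(behavior, out / "behavior.csv")
    truth.to_json(out / "truth.json")
    if sc.get("write_scans"):
        scan_dir = out / "scans"
        scan_dir.mkdir(exist_ok=True)
        for sid, subj_scans in scans.items():
            for tc in subj_scans:
                stem = scan_dir / f"{sid}_{tc.scan_id}"
                write_timecourse(tc, f"{stem}.csv", f"{stem}.json")


def _stage_preprocess(cfg, seed, ctx, out: Path) -> None:
    pc = PreprocConfig(**cfg["preprocess"])
    ctx["scans"] = {sid: [preprocess(tc, pc) for tc in subj]
                    for sid, subj in ctx["scans"].items()}


def _stage_dfc(cfg, seed, ctx, out: Path) -> None:
    dc = cfg["dfc"]
    taper = build_taper(dc["width_tr"], dc["sigma_tr"])
    series: List[DfcSeries] = []
    for subj in ctx["scans"].values():
        for tc in subj:
            series.append(windowed_corr(tc, taper, step=dc["step"]))
    ctx["taper"] = taper
    ctx["dfc_series"] = series


def _stage_states(cfg, seed, ctx, out: Path) -> None:
    sc = cfg["states"]
    series = ctx["dfc_series"]
    K = sc["K"]
    if sc.get("run_elbow"):
        elbow = elbow_select(series,
                             range(sc["elbow_k_min"], sc["elbow_k_max"] + 1),
                             seed=seed, n_init=sc["n_init"])
        K = elbow.k
        with open(out / "elbow.json", "w") as fh:
            json.dump({"k": elbow.k, "weak": elbow.weak,
                       "k_values": elbow.k_values.tolist(),
                       "scores": elbow.scores.tolist()}, fh, indent=1)
    model = fit_kmeans(series, K, seed=seed, n_init=sc["n_init"])
    occ = fractional_rates(model)
    ctx["state_model"] = model
    ctx["occupancy"] = occ
    np.savetxt(out / "centroids.csv", model.centroids, delimiter=",")
    occ.per_scan.to_csv(out / "occupancy_per_scan.csv", index=False)
    occ.per_subject.to_csv(out / "occupancy_per_subject.csv")


def _stage_nulls(cfg, seed, ctx, out: Path) -> None:
    nc = cfg["nulls"]
    scans = [tc for subj in ctx["scans"].values() for tc in subj]
    rng = np.random.default_rng(seed)
    results = []
    for tc in scans[: nc["n_scans"]]:
        res = stationarity_test(tc, ctx.get("taper"), n_surr=nc["n_surr"],
                                method=nc["method"],
                                seed=int(rng.integers(2 ** 31)))
        results.append({"subject_id": tc.subject_id, "scan_id": tc.scan_id,
                        "fraction_significant": res.fraction_significant})
    with open(out / "stationarity.json", "w") as fh:
        json.dump({"method": nc["method"], "n_surr": nc["n_surr"],
                   "scans": results}, fh, indent=1)


def _stage_assoc(cfg, seed, ctx, out: Path) -> None:
    ac = cfg["assoc"]
    table = association_screen(ctx["occupancy"], ctx["behavior"],
                               fdr_q=ac["fdr_q"], fdr_scope=ac["fdr_scope"])
    table.to_csv(out / "associations.csv", index=False)
    ctx["associations"] = table


def _stage_mediate(cfg, seed, ctx, out: Path) -> None:
    mc = cfg["mediate"]
    occ = ctx["occupancy"].per_subject
    beh = ctx["behavior"].table.set_index("subject_id").loc[occ.index]
    x = occ[f"state_{mc['x_state'] % ctx['state_model'].K}"].to_numpy()
    covs = np.column_stack([
        beh["age"].to_numpy(float), (beh["gender"] == "M").to_numpy(float),
        pd.get_dummies(beh["race"], drop_first=True).to_numpy(float),
        beh["height"].to_numpy(float), beh["weight"].to_numpy(float)])
    res = bootstrap_mediation(x, beh[mc["m"]].to_numpy(float),
                              beh[mc["y"]].to_numpy(float), covs,
                              n_boot=mc["n_boot"], seed=seed)
    payload = asdict(res)
    payload["x"] = f"state_{mc['x_state']}"
    payload["m"], payload["y"] = mc["m"], mc["y"]
    with open(out / "mediation.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
    ctx["mediation"] = res


def _stage_graph(cfg, seed, ctx, out: Path) -> None:
    gc = cfg["graph"]
    model = ctx["state_model"]
    series = ctx["dfc_series"]
    state_a = gc["state_a"] % model.K
    state_b = gc["state_b"] % model.K
    subjects = sorted({s.subject_id for s in series})
    rows = []
    for sid in subjects:
        for state in (state_a, state_b):
            fc = state_mean_dfc(series, model, sid, state)
            if fc is None:
                continue
            g = SignedGraphSet.from_fc(fc)
            rows.append({"subject_id": sid, "state": state,
                         **{f"strength_{v}_roi{j}": s
                            for v in ("positive", "negative", "absolute")
                            for j, s in enumerate(node_strength(g, v))}})
    pd.DataFrame(rows).to_csv(out / "graph_strength.csv", index=False)


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "dfc": _stage_dfc,
    "states": _stage_states,
    "nulls": _stage_nulls,
    "assoc": _stage_assoc,
    "mediate": _stage_mediate,
    "graph": _stage_graph,
}
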