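"""End-to-end seeded pipeline runs and the property-check suite.

``run_pipeline`` executes synth -> preprocess -> subspace -> trajectory
geometry -> duration decoding (optionally -> RNN) from a single config
document, fanning one master seed out to named per-stage seeds, and records a
manifest (config hash, seeds, per-stage wall time and row counts, output
paths) plus JSON-lines logs, so stochastic runs are auditable and
byte-reproducible.

``acceptance_suite`` re-runs the package's headline property checks (oracle
equivalences, parameter recovery, geometry contrasts, RNN analogs) and
reports measured value vs bound for each.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import decoder as dec
from . import preprocess as pp
from . import rnn as rnnmod
from . import subspace as sub
from . import synth
from . import trajgeo as tg
from .io import save_condition_tensor, save_subspace

DEFAULT_CONFIG: dict = {
    "seed": 0,
    # balanced condition sampling guarantees the full 8 x 4 grid at compact
    # session sizes; the generator's own default emulates the raw task
    "generator": {"n_trials": 60, "balanced_conditions": True},
    "scheme": "duration",
    "var_threshold": 0.80,
    "region": "full",
    "rnn": {"enabled": False, "n": 200, "n_realizations": 1},
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ["latents", "spikes", "splits", "rnn"]
    return {n: int(c.generate_state(1)[0] % (2**31 - 1))
            for n, c in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run all stages in dependency order; abort naming the failing stage."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    cfg = {**DEFAULT_CONFIG, **config}
    if not isinstance(cfg.get("generator", {}), dict):
        raise ValueError("config schema: 'generator' must be a mapping")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    manifest = {"config_hash": _config_hash(cfg), "seeds": seeds,
                "stages": [], "outputs": []}
    log_path = out / "run_log.jsonl"
    log_f = log_path.open("w")

    def log(stage: str, **kw) -> None:
        log_f.write(json.dumps({"stage": stage, **kw}) + "\n")

    def stage(name: str):
        class _S:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, et, ev, tb):
                if et is not None:
                    log(name, status="failed", error=str(ev))
                    log_f.close()
                    raise RuntimeError(f"stage '{name}' failed: {ev}") from ev
                manifest["stages"].append(
                    {"name": name,
                     "wall_s": round(time.perf_counter() - self_.t0, 3)})
                return False
        return _S()

    with stage("synth"):
        gen_cfg = synth.GeneratorConfig(
            **{**cfg["generator"],
               "latent_seed": cfg["generator"].get("latent_seed",
                                                   seeds["latents"]),
               "spike_seed": cfg["generator"].get("spike_seed",
                                                  seeds["spikes"])})
        session = synth.generate_session(gen_cfg)
        sdir = synth.write_session(session, out / "session")
        manifest["outputs"].append(str(sdir))
        log("synth", n_movements=0 if session.ground_truth is None
            else len(session.ground_truth), seed=seeds["latents"])

    with stage("preprocess"):
        tensor, spec, events = pp.preprocess_session(session,
                                                     scheme=cfg["scheme"])
        tpath = out / "tensor.h5"
        save_condition_tensor(tensor, tpath)
        manifest["outputs"].append(str(tpath))
        log("preprocess", sigma_ms=spec.sigma_ms,
            n_conditions=len(tensor.condition_labels),
            n_units=tensor.n_units)

    with stage("subspace"):
        space = sub.CommonSubspace(cfg["var_threshold"]).fit(tensor)
        spath = out / "subspace.h5"
        save_subspace(space, spath, manifest["config_hash"])
        manifest["outputs"].append(str(spath))
        trajectories = {t.condition: t for t in space.transform(tensor)}
        log("subspace", D=space.D_)

    with stage("trajgeo"):
        results: dict = {}
        if cfg["scheme"] == "duration":
            r2_df = tg.pairwise_scaled_r2(trajectories)
            try:
                ceiling, ceil_df = tg.within_bin_ceiling(
                    tensor.per_movement, space, seed=seeds["splits"])
            except ValueError:   # too few movements per bin to split
                ceiling = None
            lower = tg.lower_limit_r2(trajectories)
            dist_df, dist_sum = tg.distance_contrasts(trajectories,
                                                      "duration")
            r2_df.to_csv(out / "scaled_r2.csv", index=False)
            dist_df.to_csv(out / "hausdorff_duration.csv", index=False)
            results.update(
                scaled_r2_mean=float(r2_df["r2"].mean()),
                within_bin_ceiling=ceiling,
                lower_limit_r2=float(lower["r2"].mean()),
                duration_contrast=dist_sum)
        else:
            dist_df, dist_sum = tg.distance_contrasts(trajectories, "speed")
            dist_df.to_csv(out / "hausdorff_speed.csv", index=False)
            results.update(speed_contrast=dist_sum)
        (out / "trajgeo.json").write_text(json.dumps(results, indent=1))
        manifest["outputs"] += [str(out / "trajgeo.json")]
        log("trajgeo", **{k: v for k, v in results.items()
                          if isinstance(v, float)})

    with stage("decoder"):
        if cfg["scheme"] == "duration":
            bench = dec.decoder_benchmark(trajectories, region=cfg["region"])
            bench.to_csv(out / "decode.csv", index=False)
            manifest["outputs"].append(str(out / "decode.csv"))
            log("decoder", n_samples=len(bench),
                median_rel_error=float(bench["rel_error_movement"].median()))
        else:
            log("decoder", skipped="speed scheme has no duration decode")

    if cfg["rnn"].get("enabled"):
        with stage("rnn"):
            model = rnnmod.build_stabilized_network(
                n=int(cfg["rnn"].get("n", 200)), seed=seeds["rnn"])
            tau_res = rnnmod.timeconstant_experiment(model)
            (out / "rnn.json").write_text(json.dumps(
                {"taus_ms": tau_res["taus_ms"],
                 "durations_ms": tau_res["durations_ms"]}, indent=1))
            manifest["outputs"].append(str(out / "rnn.json"))
            log("rnn", durations=tau_res["durations_ms"])

    log_f.close()
    manifest["outputs"].append(str(log_path))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Property-check suite
# ---------------------------------------------------------------------------

def _brute_hausdorff(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.spatial.distance import cdist
    D = cdist(x, y)
    return max(D.min(axis=1).max(), D.min(axis=0).max())


def acceptance_suite(profile: str = "quick", seed: int = 0) -> list[dict]:
    """Run the package's property checks; failures are report entries."""
    quick = profile == "quick"
    rng = np.random.default_rng(seed)
    report: list[dict] = []

    def entry(name: str, value: float, bound: str, ok: bool) -> None:
        report.append({"check": name, "value": value, "bound": bound,
                       "passed": bool(ok)})

    # Hausdorff oracle equivalence
    worst = 0.0
    for _ in range(50 if quick else 200):
        x = rng.normal(size=(rng.integers(3, 40), 3))
        y = rng.normal(size=(rng.integers(3, 40), 3))
        worst = max(worst, abs(tg.hausdorff(x, y) - _brute_hausdorff(x, y)))
    entry("hausdorff_vs_bruteforce_max_abs_diff", worst, "== 0", worst == 0.0)

    # concatenated R2 formula fidelity
    ok = (tg.scaled_r2([0, 1, 2], [2, 1, 0]) == -3.0
          and tg.scaled_r2([0, 1, 2], [1, 1, 1]) == 0.0
          and tg.scaled_r2([0, 1, 2], [0, 1, 2]) == 1.0)
    entry("scaled_r2_hand_values", float(ok), "exact", ok)

    # rescaling exactness on a linear ramp
    ramp = np.linspace(0.0, 5.0, 37)[:, None] * np.array([[1.0, -2.0]])
    err = float(np.abs(tg.rescale_trajectory(ramp).points
                       - np.linspace(0, 5, 600)[:, None]
                       * np.array([[1.0, -2.0]])).max())
    entry("rescale_linear_max_error", err, "< 1e-12", err < 1e-12)

    # decoder parameter recovery, noise-free
    base = np.stack([np.sin(np.linspace(0, np.pi, 400)),
                     np.sin(2 * np.linspace(0, np.pi, 400))], axis=1)
    ref = sub.NeuralTrajectory(base, 1.0, (0, 1),
                               np.arange(400, dtype=float))
    errs = []
    for v_true in (0.5, 0.75, 1.25, 1.5, 2.0):
        n = int(round(400 * v_true))
        s = tg.rescale_trajectory(base, n).points
        samp = sub.NeuralTrajectory(s, 1.0, (0, 1), np.arange(n, dtype=float))
        res = dec.decode_duration(samp, ref, non_movement_time_ms=0.0)
        errs.append(abs(res.v - v_true) / v_true)
    entry("decoder_v_recovery_max_rel_error", float(max(errs)), "< 0.05",
          max(errs) < 0.05)

    # geometry contrast on an exact-scaling synthetic session
    gcfg = synth.GeneratorConfig(n_trials=150, balanced_conditions=True,
                                 latent_seed=seed + 1, spike_seed=seed + 2)
    session = synth.generate_session(gcfg)
    tensor, _, _ = pp.preprocess_session(session)
    space = sub.CommonSubspace().fit(tensor)
    trajs = {t.condition: t for t in space.transform(tensor)}
    try:
        _, summ = tg.distance_contrasts(trajs, "duration")
        ok = summ["mean_a"] < summ["mean_b"] and summ["p"] < 0.01
        entry("duration_vs_direction_contrast_p", summ["p"], "< 0.01", ok)
    except ValueError as exc:
        entry("duration_vs_direction_contrast_p", np.nan, f"error: {exc}",
              False)

    # decoder on the same session
    bench = dec.decoder_benchmark(trajs, region="full")
    med = float(bench["rel_error_movement"].median())
    entry("decoder_movement_rel_error_median", med, "< 0.15", med < 0.15)

    # RNN: zero input, linear oracle, direction and duration analogs
    model = rnnmod.build_stabilized_network(n=100 if quick else 200,
                                            seed=seed)
    quiet = rnnmod.simulate(model, rnnmod.RampInput(amplitude=0.0))
    z = float(np.abs(quiet["x"]).max())
    entry("rnn_zero_input_max_potential", z, "== 0", z == 0.0)

    n_real = 3 if quick else 20
    mono = []
    for k in range(n_real):
        m = rnnmod.build_stabilized_network(n=100 if quick else 200,
                                            seed=seed + k)
        curve = rnnmod.direction_experiment(m)["distance_curve"]
        mono.append([d for _, d in curve])
    mean_curve = np.mean(mono, axis=0)
    ok = bool(np.all(np.diff(mean_curve) >= 0))
    entry("rnn_distance_vs_angle_nondecreasing", float(ok),
          f"monotone over {n_real} realizations", ok)

    taures = rnnmod.timeconstant_experiment(model)
    d = taures["durations_ms"]
    ok = (not any(np.isnan(d))) and d[0] < d[1] < d[2]
    entry("rnn_duration_monotone_in_tau", float(ok), "strictly increasing",
          ok)
    entry("rnn_scaled_vs_unscaled_r2_gap",
          taures["r2_scaled_extremes"] - taures["r2_unscaled_extremes"],
          "> 0",
          taures["r2_scaled_extremes"] > taures["r2_unscaled_extremes"])
    return report
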