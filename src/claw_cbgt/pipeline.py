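"""End-to-end pipeline: simulate -> binarize -> CLAW -> DDM -> ensembles.

A :class:`PipelineConfig` fixes the scale (number of networks and trials),
one global seed (from which named substreams derive), and per-stage
options.  `run_pipeline` executes the stages in order and returns an
in-memory report bundle; `write_report` serializes it (CSV tables, graph
exports, JSON manifest stamped with the config hash).

Across-network variation comes from jittering the 13 searchable synaptic
weights around the shipped default configuration, mirroring the role of
the genetic search at survey scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binarize as bz
from . import claw as cw
from . import ddm as dm
from . import ensembles as es
from .config import SEARCHABLE_WEIGHTS, NetworkConfig, default_config
from .populations import ALL_POPULATIONS
from .simulate import RateTraceSet, TrialRecord, run_experiment, timeout_fraction

SUBSTREAMS = ("network", "trial", "ga", "ddm")


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    n_networks: int = 30
    n_trials: int = 50
    seed: int = 0
    weight_jitter: float = 0.15   # relative half-width of the weight jitter
    k_near: int = 3               # near-decision window (bins) for thresholds
    transition_mode: str = "per_change"
    pruning_gap: float = 0.25
    fit_z: bool = True
    stages: tuple = ("simulate", "binarize", "claw", "ddm", "ensembles")
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def substream_seed(global_seed: int, name: str, index: int = 0) -> int:
    """Deterministic sub-seed (< 2**31) for a named randomness stream."""
    ss = np.random.SeedSequence([global_seed, SUBSTREAMS.index(name), index])
    return int(ss.generate_state(1)[0]) % (2**31)


def sample_network_configs(pcfg: PipelineConfig, n_screen: int = 16) -> list[NetworkConfig]:
    """Draw network configurations by jittering the searchable weights of
    the default config, keeping only candidates that pass a quick
    feasibility screen (no timeouts in ``n_screen`` screening trials) —
    the survey-scale counterpart of the genetic-search filter."""
    base = default_config()
    rng = np.random.default_rng(substream_seed(pcfg.seed, "network"))
    configs: list[NetworkConfig] = []
    attempts = 0
    max_attempts = 20 * pcfg.n_networks
    while len(configs) < pcfg.n_networks:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {pcfg.n_networks} feasible networks in "
                f"{max_attempts} draws; reduce weight_jitter"
            )
        attempts += 1
        factors = 1.0 + pcfg.weight_jitter * (2 * rng.random(len(SEARCHABLE_WEIGHTS)) - 1)
        values = {
            k: base.weights[k] * f for k, f in zip(SEARCHABLE_WEIGHTS, factors)
        }
        cfg = base.with_searchable(values)
        cfg.seed = len(configs)
        _, screen = run_experiment(cfg, n_screen, substream_seed(pcfg.seed, "ga", attempts))
        if not any(t.timed_out for t in screen):
            configs.append(cfg)
    return configs


def run_pipeline(pcfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns the report bundle."""
    report: dict = {"pipeline_config": dataclasses.asdict(pcfg),
                    "config_hash": pcfg.config_hash()}

    if "simulate" not in pcfg.stages:
        raise ValueError("the simulate stage cannot be disabled")
    configs = sample_network_configs(pcfg)
    traces = RateTraceSet(n_trials_per_network=pcfg.n_trials)
    for i, cfg in enumerate(configs):
        try:
            _, trials = run_experiment(cfg, pcfg.n_trials,
                                       substream_seed(pcfg.seed, "trial", i))
        except Exception as err:
            raise RuntimeError(f"stage simulate failed at network {i}: {err}") from err
        traces.add(cfg, trials)
    all_trials = [t for _, trials in traces for t in trials]
    report["traces"] = traces
    report["timeout_fraction"] = timeout_fraction(all_trials)

    if "binarize" not in pcfg.stages:
        return report
    binary_sets, thresholds = [], []
    for i, (cfg, trials) in enumerate(traces):
        try:
            bset, thr = bz.binarize_network(trials, k_near=pcfg.k_near)
        except Exception as err:
            raise RuntimeError(f"stage binarize failed at network {i}: {err}") from err
        binary_sets.append(bset)
        thresholds.append(thr)
    report["thresholds"] = thresholds
    report["binary_sets"] = binary_sets

    if "claw" not in pcfg.stages:
        return report
    sequences_per_network = [cw.extract_sequences(b) for b in binary_sets]
    pooled = [s for seqs in sequences_per_network for s in seqs]
    if not pooled:
        raise RuntimeError("stage claw failed: no usable state sequences")
    table = cw.estimate_transitions(pooled, mode=pcfg.transition_mode)
    graph = cw.prune_graph(table, gap=pcfg.pruning_gap)
    stats = cw.compute_state_stats(pooled)
    cw.attach_state_stats(graph, stats)
    tertiles = cw.dt_tertiles([s.decision_time for s in pooled])
    partition = cw.partition_zones(graph)
    report.update(sequences=sequences_per_network, transition_table=table,
                  graph=graph, state_stats=stats, tertiles=tertiles,
                  partition=partition)

    if "ddm" not in pcfg.stages:
        return report
    ddm_rows, ddm_meta = [], []
    for i, (cfg, trials) in enumerate(traces):
        sample = dm.sample_from_trials(trials)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = dm.fit_ddm(sample, fit_z=pcfg.fit_z)
        except Exception as err:
            raise RuntimeError(f"stage ddm failed at network {i}: {err}") from err
        p = fit.params
        ddm_rows.append([p.a, p.v, p.t, p.z])
        ddm_meta.append({"network_id": i, "a": p.a, "v": p.v, "t": p.t,
                         "z": p.z, "loglik": fit.loglik,
                         "converged": fit.converged})
    D_all = np.array(ddm_rows)
    report["ddm_table"] = D_all
    report["ddm_fits"] = ddm_meta

    if "ensembles" not in pcfg.stages:
        return report
    try:
        F_all = es.build_feature_matrix(traces)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = es.label_components(es.fit_cca(F_all, D_all))
        drives = es.drive_timeseries(traces, model, tertiles)
        projection = es.zone_projection(traces, sequences_per_network,
                                        partition, model, D_all)
    except Exception as err:
        raise RuntimeError(f"stage ensembles failed: {err}") from err
    report.update(feature_matrix=F_all, ensemble_model=model,
                  drives=drives, zone_projection=projection)
    return report


# --------------------------------------------------------------------- #
# serialization
# --------------------------------------------------------------------- #

def rates_frame(trials: list) -> pd.DataFrame:
    """Long-format rate table: (trial, bin_index, population, rate_hz)."""
    recs = []
    for t in trials:
        for j in range(t.n_bins):
            for i, p in enumerate(ALL_POPULATIONS):
                recs.append((t.trial_id, j, p, t.rates[i, j]))
    return pd.DataFrame(recs, columns=["trial", "bin_index", "population", "rate_hz"])


def behavior_frame(trials: list) -> pd.DataFrame:
    recs = [
        (t.trial_id,
         t.decision_time if not t.timed_out else np.nan,
         t.choice)
        for t in trials
    ]
    return pd.DataFrame(recs, columns=["trial", "decision_time_ms", "choice"])


def write_report(report: dict, out_dir) -> None:
    """Serialize a report bundle to ``out_dir``.

    Refuses to overwrite a directory whose manifest carries a different
    config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") not in (None, report["config_hash"]):
            raise RuntimeError(
                f"{out} holds results for config hash {old['config_hash']}; "
                f"refusing to overwrite with {report['config_hash']}"
            )

    traces = report.get("traces")
    if traces is not None:
        for i, (cfg, trials) in enumerate(traces):
            rates_frame(trials).to_csv(out / f"rates_net{i:03d}.csv", index=False)
            behavior_frame(trials).to_csv(out / f"behavior_net{i:03d}.csv", index=False)

    if "thresholds" in report:
        rows = []
        for i, thr in enumerate(report["thresholds"]):
            for r in thr.to_records():
                rows.append({"network_id": i, **r})
        pd.DataFrame(rows).to_json(out / "thresholds.json", orient="records", indent=1)

    if "graph" in report:
        cw.export_graph(report["graph"], out / "graph.json", "json")
        cw.export_graph(report["graph"], out / "graph.graphml", "graphml")
        cw.export_graph(report["graph"], out / "graph.dot", "dot")
        stats = report["state_stats"]
        pd.DataFrame([
            {"state": s, "mean_dt_ms": st.mean_dt, "n_left": st.n_left,
             "n_right": st.n_right, "kl_nats": st.kl_divergence,
             "p_stn_l": st.aux_activation["STN-L"],
             "p_stn_r": st.aux_activation["STN-R"],
             "p_gpea_l": st.aux_activation["GPeA-L"],
             "p_gpea_r": st.aux_activation["GPeA-R"]}
            for s, st in sorted(stats.items())
        ]).to_csv(out / "state_stats.csv", index=False)
        part = report["partition"]
        pd.DataFrame(
            [{"state": s, "zone": z} for s, z in sorted(part.state_to_zone.items())]
        ).to_csv(out / "zones.csv", index=False)

    if "ddm_fits" in report:
        pd.DataFrame(report["ddm_fits"]).to_csv(out / "ddm_params.csv", index=False)

    if "ensemble_model" in report:
        model = report["ensemble_model"]
        rows = []
        inv = {v: k for k, v in model.labels.items()}
        for j in range(model.U.shape[1]):
            comp = inv.get(j, f"component_{j}")
            for name, u in zip(es.FEATURE_NAMES, model.U[:, j]):
                rows.append({"side": "activity", "name": name,
                             "component": comp, "loading": u})
            for name, v in zip(es.DDM_COLUMNS, model.V[:, j]):
                rows.append({"side": "ddm", "name": name,
                             "component": comp, "loading": v})
        pd.DataFrame(rows).to_csv(out / "loadings.csv", index=False)
        drives = report["drives"]
        drows = []
        for g, d in drives.groups.items():
            for b, bin_idx in enumerate(d["aligned_bins"]):
                for label, j in drives.component_labels.items():
                    drows.append({"group": g, "aligned_bin": int(bin_idx),
                                  "ensemble": label,
                                  "mean": d["mean"][b, j], "sd": d["sd"][b, j]})
        pd.DataFrame(drows).to_csv(out / "drives.csv", index=False)
        pd.DataFrame(report["zone_projection"].to_records()).to_csv(
            out / "zone_projection.csv", index=False)

    manifest = {
        "config_hash": report["config_hash"],
        "pipeline_config": report["pipeline_config"],
        "timeout_fraction": report.get("timeout_fraction"),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))


# --------------------------------------------------------------------- #
# external tables
# --------------------------------------------------------------------- #

def read_external_tables(rate_csv, behavior_csv, bin_ms: float = 10.0,
                         stim_onset_bin: int = 0) -> tuple[NetworkConfig, list]:
    """Read user-supplied binned rate and behavior tables as one network.

    The rate CSV needs columns (trial, bin_index, population, rate_hz) and
    the behavior CSV (trial, decision_time_ms, choice).  Finer uniform
    binning that divides 10 ms is rebinned by block means with a warning.
    """
    rates = pd.read_csv(rate_csv)
    behavior = pd.read_csv(behavior_csv)
    for col in ("trial", "bin_index", "population", "rate_hz"):
        if col not in rates.columns:
            raise ValueError(f"rate table missing column {col!r}")
    for col in ("trial", "decision_time_ms", "choice"):
        if col not in behavior.columns:
            raise ValueError(f"behavior table missing column {col!r}")
    if (rates["rate_hz"] < 0).any():
        raise ValueError("negative rates in the rate table")
    unknown = set(rates["population"]) - set(ALL_POPULATIONS)
    if unknown:
        raise ValueError(f"unknown populations: {sorted(unknown)}")

    beh = behavior.set_index("trial")
    trials = []
    factor = 1
    if bin_ms != 10.0:
        if not np.isclose((10.0 / bin_ms) % 1, 0):
            raise ValueError("bin width must divide 10 ms")
        factor = int(round(10.0 / bin_ms))
        warnings.warn(f"rebinning {bin_ms} ms bins to 10 ms by block means")
    for trial_id, g in rates.groupby("trial"):
        if trial_id not in beh.index:
            raise ValueError(f"behavior row missing for trial {trial_id}")
        mat = g.pivot_table(index="population", columns="bin_index",
                            values="rate_hz")
        mat = mat.reindex(ALL_POPULATIONS)
        if mat.isna().any().any():
            raise ValueError(f"trial {trial_id}: missing population/bin entries")
        arr = mat.to_numpy()
        if factor > 1:
            nb = arr.shape[1] // factor
            arr = arr[:, : nb * factor].reshape(arr.shape[0], nb, factor).mean(axis=2)
        row = beh.loc[trial_id]
        dt = row["decision_time_ms"]
        timed_out = pd.isna(dt)
        n_bins = arr.shape[1]
        dec_end = n_bins - 1 if timed_out else min(
            stim_onset_bin + int(round(dt / 10.0)) - 1, n_bins - 1)
        trials.append(TrialRecord(
            rates=arr,
            decision_time=float("inf") if timed_out else float(dt),
            choice=str(row["choice"]) if not timed_out else "none",
            phase_marks={"stim_onset": stim_onset_bin,
                         "decision_end": max(dec_end, stim_onset_bin),
                         "consolidation_end": n_bins - 1},
            bin_ms=10.0,
            trial_id=int(trial_id),
        ))
    return default_config(), trials
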