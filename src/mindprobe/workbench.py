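"""Run orchestration: simulate -> preprocess -> features -> label ->
cluster-test -> lmm -> similarity -> classify -> report.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be re-run independently; the resolved
configuration and a manifest (stage seeds, timings, exclusions) are
written next to the artifacts. All randomness derives from one root
seed through stage-name-keyed substreams.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import decode, labels as lb, lmm as lmm_mod, spectral
from .containers import DIMENSIONS, REST_DIMENSIONS, ProbeReport
from .edf import read_edf, write_edf
from .layout import make_layout
from .nn import ScnnConfig
from .preprocess import Epoch, preprocess_recording
from .synth import (Cohort, EffectSpec, Oscillator, SynthConfig,
                    simulate_cohort)

STAGES = ("simulate", "preprocess", "features", "label", "cluster-test",
          "lmm", "similarity", "classify", "report")


@dataclass
class RunConfig:
    """Resolved parameters for a full pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    window_s: float = 12.0
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    significance_alpha: float = 0.05
    adjacency_threshold: float = cl.DEFAULT_ADJACENCY_THRESHOLD
    scnn: ScnnConfig = field(default_factory=ScnnConfig)
    n_iterations: int = 25
    n_permutation_runs: int = 25
    min_trials_per_class: int = 50
    run_loso: bool = True
    run_permutations: bool = True
    dimensions: tuple[str, ...] = DIMENSIONS
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Stage-name-keyed substream of the root seed (stable, < 2^31)."""
        return int(np.random.SeedSequence(
            self.seed, spawn_key=(zlib.crc32(stage.encode()),)
        ).generate_state(1)[0] % (2 ** 31))


# --------------------------------------------------------------------------
# config (de)serialization

def _encode(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _encode(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_to_json(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(_encode(config), indent=2))


def config_from_json(path) -> RunConfig:
    raw = json.loads(Path(path).read_text())
    synth_raw = raw.pop("synth", {})
    scnn_raw = raw.pop("scnn", {})
    synth_raw["oscillators"] = tuple(
        Oscillator(**{**o, "topo_center": tuple(o["topo_center"])})
        for o in synth_raw.get("oscillators", []))
    synth_raw["effects"] = tuple(
        EffectSpec(**{**e, "electrodes": tuple(e["electrodes"]),
                      "band": tuple(e["band"])})
        for e in synth_raw.get("effects", []))
    synth_raw["correlation"] = np.asarray(synth_raw["correlation"])
    synth_raw["probe_gap"] = tuple(synth_raw["probe_gap"])
    synth_raw["aperiodic_offset"] = tuple(synth_raw["aperiodic_offset"])
    synth_raw["aperiodic_exponent"] = tuple(synth_raw["aperiodic_exponent"])
    raw["dimensions"] = tuple(raw.get("dimensions", DIMENSIONS))
    return RunConfig(synth=SynthConfig(**synth_raw), scnn=ScnnConfig(**scnn_raw),
                     **raw)


def demo_config(seed: int = 0) -> RunConfig:
    """A desk-scale configuration exercising every stage in minutes."""
    synth = SynthConfig(
        n_participants=3, n_sessions=2, task_duration=400.0, n_probes=12,
        probe_gap=(25.0, 35.0), rest_duration=120.0, window_s=12.0,
        seed=seed,
    )
    return RunConfig(
        synth=synth, n_permutations=500, n_iterations=3,
        n_permutation_runs=10, min_trials_per_class=20,
        scnn=ScnnConfig(learning_rate=1e-3, max_epochs=30), seed=seed,
    )


# --------------------------------------------------------------------------
# manifest helpers

class Manifest:
    def __init__(self, run_dir: Path):
        self.path = Path(run_dir) / "manifest.json"
        self.data = json.loads(self.path.read_text()) if self.path.exists() \
            else {"stages": {}, "exclusions": []}

    def record(self, stage: str, seed: int, elapsed: float, **extra):
        self.data["stages"][stage] = {"seed": seed,
                                      "elapsed_s": round(elapsed, 3), **extra}
        self.save()

    def exclude(self, unit: str, rule: str):
        self.data["exclusions"].append({"unit": unit, "rule": rule})
        self.save()

    def save(self):
        self.path.write_text(json.dumps(self.data, indent=2))


def _require(path: Path, what: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing required artifact for this stage: {path} ({what}); "
            "run the upstream stage first")


# --------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, run_dir) -> Cohort:
    run_dir = Path(run_dir)
    (run_dir / "recordings").mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    synth = config.synth.with_(seed=config.stage_seed("simulate"))
    cohort = simulate_cohort(synth)
    for rec in cohort.task_recordings:
        write_edf(rec, run_dir / "recordings" /
                  f"task_p{rec.participant_id}_s{rec.session_id}.edf")
    for rec in cohort.rest_recordings:
        write_edf(rec, run_dir / "recordings" /
                  f"rest_p{rec.participant_id}_s{rec.session_id}"
                  f"_b{rec.block}.edf")
    rows = []
    for rep in cohort.task_reports + cohort.rest_reports:
        rows.append({"participant": rep.participant_id,
                     "session": rep.session_id,
                     "condition": "task" if rep.scope == "momentary" else "rest",
                     "block": rep.block, "probe_id": rep.probe_id,
                     "probe_time_s": rep.probe_time, "activity": rep.activity,
                     **{d: rep.ratings.get(d, "") for d in DIMENSIONS}})
    pd.DataFrame(rows).to_csv(run_dir / "reports.csv", index=False)
    truth = {
        f"p{p}_s{s}": {
            "latents": gt.latents.tolist(),
            "window_starts": gt.window_starts.tolist(),
            "window_ends": gt.window_ends.tolist(),
            "effect_masks": {d: m.tolist() for d, m in gt.effect_masks.items()},
        } for (p, s), gt in cohort.ground_truth.items()
    }
    (run_dir / "ground_truth.json").write_text(json.dumps(truth))
    config_to_json(config, run_dir / "config.json")
    Manifest(run_dir).record("simulate", synth.seed, time.time() - t0,
                             n_task=len(cohort.task_recordings),
                             n_rest=len(cohort.rest_recordings))
    return cohort


def _load_reports(run_dir: Path) -> pd.DataFrame:
    _require(run_dir / "reports.csv", "probe reports")
    return pd.read_csv(run_dir / "reports.csv")


def stage_preprocess(config: RunConfig, run_dir) -> None:
    """Condition each EDF recording and store epochs per session."""
    run_dir = Path(run_dir)
    rec_dir = run_dir / "recordings"
    _require(rec_dir, "EDF recordings")
    out = run_dir / "epochs"
    out.mkdir(exist_ok=True)
    t0 = time.time()
    n = 0
    for path in sorted(rec_dir.glob("*.edf")):
        parts = path.stem.split("_")
        condition = parts[0]
        p, s = int(parts[1][1:]), int(parts[2][1:])
        b = int(parts[3][1:]) if condition == "rest" else 0
        rec = read_edf(path, condition=condition, participant_id=p,
                       session_id=s, block=b)
        epochs = preprocess_recording(rec)
        np.savez_compressed(
            out / f"{path.stem}.npz",
            data=np.stack([e.data for e in epochs]),
            t_start=np.array([e.t_start for e in epochs]),
            meta=np.array([p, s, b, rec.sample_rate]))
        n += len(epochs)
    Manifest(run_dir).record("preprocess", config.stage_seed("preprocess"),
                             time.time() - t0, n_epochs=n)


def stage_features(config: RunConfig, run_dir) -> None:
    """Welch + aperiodic subtraction: one feature table per session."""
    run_dir = Path(run_dir)
    ep_dir = run_dir / "epochs"
    _require(ep_dir, "preprocessed epochs")
    out = run_dir / "features"
    out.mkdir(exist_ok=True)
    t0 = time.time()
    layout = make_layout()
    cols = [f"{ch}_{int(f)}Hz" for ch in layout.labels for f in spectral.FREQS]
    for path in sorted(ep_dir.glob("*.npz")):
        z = np.load(path)
        data, t_start, meta = z["data"], z["t_start"], z["meta"]
        rows = []
        for k in range(len(t_start)):
            ep = Epoch(data[k], float(t_start[k]), float(meta[3]),
                       int(meta[0]), int(meta[1]),
                       "rest" if "rest" in path.stem else "task", int(meta[2]))
            rows.append(spectral.epoch_spectral_matrix(ep).periodic.ravel())
        df = pd.DataFrame(rows, columns=cols)
        df.insert(0, "t_start", t_start)
        df.to_csv(out / f"{path.stem}.csv", index=False)
    Manifest(run_dir).record("features", config.stage_seed("features"),
                             time.time() - t0)


def _feature_matrices(df: pd.DataFrame) -> list[spectral.SpectralMatrix]:
    feats = df.drop(columns=["t_start"]).to_numpy()
    return [spectral.SpectralMatrix(row.reshape(32, len(spectral.FREQS)))
            for row in feats]


def _session_trials(run_dir: Path, config: RunConfig,
                    reports_df: pd.DataFrame, stem: str
                    ) -> list[lb.LabeledTrial]:
    """Reconstruct labeled trials for one stored session table."""
    df = pd.read_csv(run_dir / "features" / f"{stem}.csv")
    matrices = _feature_matrices(df)
    parts = stem.split("_")
    condition = parts[0]
    p, s = int(parts[1][1:]), int(parts[2][1:])
    b = int(parts[3][1:]) if condition == "rest" else 0
    dummy = np.zeros((1, 1))
    epochs = [Epoch(dummy, float(t), config.synth.sample_rate, p, s,
                    condition, b) for t in df["t_start"]]
    pairs = list(zip(epochs, matrices))
    sel = reports_df[(reports_df.participant == p)
                     & (reports_df.session == s)
                     & (reports_df.condition == condition)
                     & (reports_df.block == b)]
    out = []
    for _, row in sel.iterrows():
        dims = DIMENSIONS if condition == "task" else REST_DIMENSIONS
        ratings = {d: int(row[d]) for d in dims if not pd.isna(row[d])}
        rep = ProbeReport(
            float(row.probe_time_s), row.activity if condition == "task" else None,
            ratings, "momentary" if condition == "task" else "retrospective",
            p, s, block=b, probe_id=int(row.probe_id))
        if condition == "task":
            out.extend(lb.assemble_trials(pairs, [rep], config.window_s))
        else:
            out.extend(lb.label_rest(pairs, rep))
    return out


def _all_trials(run_dir: Path, config: RunConfig, condition: str
                ) -> list[lb.LabeledTrial]:
    feat_dir = run_dir / "features"
    _require(feat_dir, "feature tables")
    reports = _load_reports(run_dir)
    trials = []
    for path in sorted(feat_dir.glob(f"{condition}_*.csv")):
        trials.extend(_session_trials(run_dir, config, reports, path.stem))
    return trials


def stage_label(config: RunConfig, run_dir) -> None:
    """Labels table: one row per trial, one class column per dimension."""
    run_dir = Path(run_dir)
    t0 = time.time()
    rows = []
    for condition in ("task", "rest"):
        for t in _all_trials(run_dir, config, condition):
            rows.append({"trial_id": t.trial_id, "participant": t.participant_id,
                         "session": t.session_id, "condition": t.condition,
                         "block": t.block, "probe_id": t.probe_id,
                         **{d: t.labels.get(d, "") for d in DIMENSIONS}})
    pd.DataFrame(rows).to_csv(run_dir / "labels.csv", index=False)
    Manifest(run_dir).record("label", config.stage_seed("label"),
                             time.time() - t0, n_trials=len(rows))


def _session_pairs(trials, dimension, manifest=None):
    by_session = {}
    for t in trials:
        by_session.setdefault((t.participant_id, t.session_id), []).append(t)
    pairs = []
    for key in sorted(by_session):
        pair = lb.session_condition_pairs(by_session[key], dimension)
        if pair is None:
            if manifest is not None:
                manifest.exclude(
                    f"participant {key[0]} session {key[1]} ({dimension})",
                    "no trials on one end of the dimension")
            continue
        pairs.append(pair)
    return pairs


def stage_cluster_test(config: RunConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    t0 = time.time()
    manifest = Manifest(run_dir)
    trials = _all_trials(run_dir, config, "task")
    layout = make_layout()
    adjacency = cl.electrode_adjacency(layout, config.adjacency_threshold)
    out_dir = run_dir / "cluster"
    out_dir.mkdir(exist_ok=True)
    results = {}
    seed = config.stage_seed("cluster-test")
    for dim in config.dimensions:
        pairs = _session_pairs(trials, dim, manifest)
        if len(pairs) < 2:
            manifest.exclude(f"dimension {dim}", "fewer than 2 session pairs")
            continue
        upper = [u.matrix for u, _ in pairs]
        lower = [l.matrix for _, l in pairs]
        res = cl.ClusterPermutationTest(upper, lower, adjacency,
                                        config.cluster_alpha).fit(
            config.n_permutations, seed)
        (out_dir / f"{dim}.json").write_text(
            json.dumps(res.to_dict(layout), indent=2))
        pd.DataFrame(res.t_map, index=layout.labels,
                     columns=[f"{int(f)}Hz" for f in spectral.FREQS]
                     ).to_csv(out_dir / f"{dim}_tmap.csv")
        mask = np.zeros_like(res.t_map, dtype=int)
        for c in res.significant(config.significance_alpha):
            mask |= c.mask(res.t_map.shape).astype(int) * c.sign
        pd.DataFrame(mask, index=layout.labels,
                     columns=[f"{int(f)}Hz" for f in spectral.FREQS]
                     ).to_csv(out_dir / f"{dim}_mask.csv")
        results[dim] = res
    manifest.record("cluster-test", seed, time.time() - t0,
                    dimensions=list(results))
    return results


def stage_lmm(config: RunConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    cluster_dir = run_dir / "cluster"
    _require(cluster_dir, "cluster-test results")
    t0 = time.time()
    trials = _all_trials(run_dir, config, "task")
    reports = _reports_as_objects(_load_reports(run_dir))
    out_dir = run_dir / "lmm"
    out_dir.mkdir(exist_ok=True)
    results = {}
    for dim in config.dimensions:
        mask_path = cluster_dir / f"{dim}_mask.csv"
        if not mask_path.exists():
            continue
        mask = pd.read_csv(mask_path, index_col=0).to_numpy() != 0
        if not mask.any():
            continue
        pairs = _session_pairs(trials, dim)
        table = lmm_mod.cluster_response_table(pairs, mask)
        res = lmm_mod.fit_lmm_end(table)
        top = lb.top_correlated_dimensions(reports, dim)
        cov_table = _covariate_table(table, reports, top, dim)
        cov_res = lmm_mod.fit_lmm_covariates(
            cov_table, [c for c in cov_table.columns if c.startswith("cov_")])
        results[dim] = {"end_model": res, "covariate_model": cov_res}
        (out_dir / f"{dim}.json").write_text(json.dumps({
            "end_effect": res.end_effect, "end_ci": res.end_ci,
            "p_value": res.p_value, "singular": res.singular,
            "covariate_p_value": cov_res.p_value,
            "covariates_used": {str(k): v for k, v in top.items()},
        }, indent=2))
    Manifest(run_dir).record("lmm", config.stage_seed("lmm"),
                             time.time() - t0, dimensions=list(results))
    return results


def _reports_as_objects(df: pd.DataFrame) -> list[ProbeReport]:
    out = []
    for _, row in df[df.condition == "task"].iterrows():
        ratings = {d: int(row[d]) for d in DIMENSIONS if not pd.isna(row[d])}
        out.append(ProbeReport(float(row.probe_time_s), row.activity, ratings,
                               "momentary", int(row.participant),
                               int(row.session), block=int(row.block),
                               probe_id=int(row.probe_id)))
    return out


def _covariate_table(table, reports, top_by_participant, dim):
    """Attach session x end mean ratings of the top-correlated dimensions."""
    df = table.copy()
    by_ps = {}
    for rep in reports:
        by_ps.setdefault((rep.participant_id, rep.session_id), []).append(rep)
    for j in range(3):
        vals = []
        for _, row in df.iterrows():
            p = int(row["participant"])
            covs = top_by_participant.get(p, [])
            if j >= len(covs):
                vals.append(np.nan)
                continue
            cov_dim = covs[j]
            reps = by_ps.get((p, int(row["session"])), [])
            member = [r.ratings[cov_dim] for r in reps
                      if cov_dim in r.ratings
                      and lb.dichotomize(r.ratings.get(dim, 4)) == row["end"]]
            vals.append(np.mean(member) if member else 4.0)
        df[f"cov_{j}"] = np.nan_to_num(np.asarray(vals, float), nan=4.0)
    return df


def stage_similarity(config: RunConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    t0 = time.time()
    manifest = Manifest(run_dir)
    task_trials = _all_trials(run_dir, config, "task")
    rest_trials = _all_trials(run_dir, config, "rest")
    reports = _load_reports(run_dir)
    rest_reports = []
    for _, row in reports[reports.condition == "rest"].iterrows():
        ratings = {d: int(row[d]) for d in REST_DIMENSIONS if not pd.isna(row[d])}
        rest_reports.append(ProbeReport(
            float(row.probe_time_s), None, ratings, "retrospective",
            int(row.participant), int(row.session), block=int(row.block)))
    excluded = lb.cohort_rest_exclusions(rest_reports)
    for dim in sorted(excluded):
        manifest.exclude(f"dimension {dim} (rest)",
                         "a participant lacks one end across all rest sessions")
    results = {}
    for dim in config.dimensions:
        if dim == "off_task" or dim in excluded:
            continue
        task_pairs = _session_pairs(task_trials, dim)
        rest_pairs = _session_pairs(rest_trials, dim)
        if not task_pairs or not rest_pairs:
            continue
        task_mean = cl.grand_difference_matrix(task_pairs)
        rest_mean = cl.grand_difference_matrix(rest_pairs)
        sim = cl.task_rest_similarity(task_mean, rest_mean)
        results[dim] = {"r": sim.r, "p": sim.p}
    (run_dir / "similarity.json").write_text(json.dumps(
        {"excluded_dimensions": sorted(excluded), "similarity": results},
        indent=2))
    manifest.record("similarity", config.stage_seed("similarity"),
                    time.time() - t0)
    return results


def stage_classify(config: RunConfig, run_dir) -> dict:
    run_dir = Path(run_dir)
    t0 = time.time()
    manifest = Manifest(run_dir)
    trials = _all_trials(run_dir, config, "task")
    out_dir = run_dir / "performance"
    out_dir.mkdir(exist_ok=True)
    seed = config.stage_seed("classify")
    results = {}
    rows = []
    for dim in config.dimensions:
        try:
            tensor = decode.trial_tensor(trials, dim)
            summary = decode.within_participant_cv(
                tensor, config.scnn, n_iterations=config.n_iterations,
                min_trials_per_class=config.min_trials_per_class, seed=seed)
        except ValueError as exc:
            manifest.exclude(f"dimension {dim} (classification)", str(exc))
            continue
        for p in summary.excluded_participants:
            manifest.exclude(f"participant {p} ({dim}, classification)",
                             f"fewer than {config.min_trials_per_class} "
                             "trials in a class")
        entry = {"within": summary}
        if config.run_permutations:
            def runner(t, s, _dim=dim):
                return decode.within_participant_cv(
                    t, config.scnn, n_iterations=1,
                    min_trials_per_class=config.min_trials_per_class,
                    seed=s).mean("mcc")

            perm = decode.permutation_significance(
                runner, tensor, summary.iteration_values["mcc"],
                n_runs=config.n_permutation_runs, seed=seed + 1)
            entry["permutation"] = perm
        if config.run_loso and summary.n_participants >= 2:
            entry["loso"] = decode.loso_transfer_cv(
                tensor, config.scnn, n_iterations=config.n_iterations,
                min_trials_per_class=config.min_trials_per_class,
                seed=seed + 2)
        results[dim] = entry
        row = {"dimension": dim}
        for m in decode.METRICS:
            row[f"within_{m}_mean"] = entry["within"].mean(m)
            row[f"within_{m}_sd"] = entry["within"].sd(m)
            if "loso" in entry:
                row[f"loso_{m}_mean"] = entry["loso"].mean(m)
                row[f"loso_{m}_sd"] = entry["loso"].sd(m)
        if "permutation" in entry:
            row["permutation_p"] = entry["permutation"].p_permutation
            row["wilcoxon_p"] = entry["permutation"].p_wilcoxon
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "performance.csv", index=False)
    manifest.record("classify", seed, time.time() - t0,
                    dimensions=list(results))
    return results


def stage_report(config: RunConfig, run_dir) -> Path:
    """Render a markdown summary from the run's artifacts (idempotent)."""
    run_dir = Path(run_dir)
    lines = ["# Run report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += ["## Stages completed", ""]
        for stage, info in manifest["stages"].items():
            lines.append(f"- {stage}: seed {info['seed']}, "
                         f"{info['elapsed_s']} s")
        if manifest["exclusions"]:
            lines += ["", "## Exclusions", ""]
            for e in manifest["exclusions"]:
                lines.append(f"- {e['unit']}: {e['rule']}")
    cluster_dir = run_dir / "cluster"
    if cluster_dir.exists():
        lines += ["", "## Cluster-based permutation tests", ""]
        truth_path = run_dir / "ground_truth.json"
        truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
        for path in sorted(cluster_dir.glob("*.json")):
            dim = path.stem
            res = json.loads(path.read_text())
            sig = [c for c in res["clusters"] if c["p"] < config.significance_alpha]
            lines.append(f"- {dim}: {len(res['clusters'])} clusters, "
                         f"{len(sig)} significant")
            if sig and truth:
                any_gt = next(iter(truth.values()))
                mask = np.asarray(any_gt["effect_masks"].get(dim, []))
                if mask.size:
                    layout = make_layout()
                    planted = {(layout.labels[i], 4 + j)
                               for i, j in zip(*np.nonzero(mask))}
                    detected = {(m["electrode"], int(m["freq_hz"]))
                                for c in sig for m in c["members"]}
                    overlap = len(planted & detected)
                    lines.append(f"  - planted-region overlap: {overlap}/"
                                 f"{len(planted)} planted cells detected")
    else:
        lines += ["", "## Cluster-based permutation tests", "",
                  "- MISSING (stage not run)"]
    sim_path = run_dir / "similarity.json"
    if sim_path.exists():
        sim = json.loads(sim_path.read_text())
        lines += ["", "## Task-rest similarity", ""]
        for dim, v in sim["similarity"].items():
            lines.append(f"- {dim}: r = {v['r']:.3f} (p = {v['p']:.2e})")
        if sim["excluded_dimensions"]:
            lines.append(f"- excluded at rest: "
                         f"{', '.join(sim['excluded_dimensions'])}")
    perf_path = run_dir / "performance" / "performance.csv"
    if perf_path.exists():
        df = pd.read_csv(perf_path)
        lines += ["", "## Decoding performance", "",
                  df.to_markdown(index=False)]
    else:
        lines += ["", "## Decoding performance", "",
                  "- MISSING (classify stage not run)"]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out


def run_all(config: RunConfig, run_dir) -> None:
    stage_simulate(config, run_dir)
    stage_preprocess(config, run_dir)
    stage_features(config, run_dir)
    stage_label(config, run_dir)
    stage_cluster_test(config, run_dir)
    stage_lmm(config, run_dir)
    stage_similarity(config, run_dir)
    stage_classify(config, run_dir)
    stage_report(config, run_dir)
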