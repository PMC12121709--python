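"""Experiment orchestration: simulate -> preprocess -> decode -> bias -> stats.

`run_experiment` reproduces the full synthetic experiment from a single
seeded configuration and writes a report bundle (per-participant trial
matrices, accuracy results per ROI x condition, bias reports, group
statistics, and a JSON summary stamped with the config hash and seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import decode as decode_mod
from . import preprocess as pre
from . import stats as stats_mod
from . import synth

logger = logging.getLogger(__name__)

SCHEMA_PATH = Path(__file__).parent / "schema" / "summary_schema.json"


@dataclass
class ExperimentConfig:
    """Seeded, serializable description of one synthetic experiment.

    Defaults mirror the printed design: 80 dots, 8/0.25 deg aperture,
    1 s trials + 8 s offsets, 8 motion types x 5 repeats x 10 runs,
    360 TRs at TR = 1 s, 1/40 Hz high-pass, TR 6-9 window, 10:90
    balanced splits x 5000 bootstraps, 500 vertex-equating resamples,
    +-30 deg HM wedge, 4 deg eccentricity bound, 0.2-8 deg & VE > 5%
    vertex filter.
    """

    n_participants: int = 10
    n_stereo_pros: int = 5
    lapse: float = 0.02
    rois: tuple[str, ...] = ("V1", "MT", "MST", "FST")
    n_vertices: dict = dfield(default_factory=dict)   # per-ROI overrides
    n_runs: int = 10
    n_repeats: int = 5
    run_length: int = 360
    tr: float = 1.0
    noise: dict = dfield(default_factory=dict)        # NoiseParams overrides
    n_boot: int = 5000
    n_resample: int = 500
    test_fraction: float = 0.10
    include_rotated: bool = True
    run_decoding: bool = True
    run_bias: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_runs, self.n_repeats, self.n_boot) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.n_stereo_pros <= self.n_participants:
            raise ValueError("n_stereo_pros must be in [0, n_participants]")
        bad = [r for r in self.rois if r not in synth.ROI_PRESETS]
        if bad:
            raise ValueError(f"unknown ROI presets: {bad}")

    def noise_params(self) -> synth.NoiseParams:
        return dataclasses.replace(synth.NoiseParams(), **self.noise)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rois"] = list(self.rois)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "rois" in d:
            d["rois"] = tuple(d["rois"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31))


def make_observers(config: ExperimentConfig, rng: np.random.Generator) -> list[synth.Observer]:
    obs = []
    for i in range(config.n_participants):
        group = "stereo_pro" if i < config.n_stereo_pros else "stereo_struggler"
        obs.append(synth.Observer(id=f"sub-{i:02d}", group=group, lapse=config.lapse))
    return obs


def simulate_participant(
    config: ExperimentConfig,
    observer: synth.Observer,
    seed: int,
    rotated: bool = False,
):
    """One session: population, schedule, simulated runs, z-score and percent matrices."""
    rng = np.random.default_rng(seed)
    pops = []
    for roi in config.rois:
        spec = synth.ROI_PRESETS[roi]
        n = config.n_vertices.get(roi, spec.n_vertices)
        pops.append(synth.sample_vertices(spec, n, rng=rng))
    population = synth.concat_populations(pops)
    schedule = synth.make_schedule(
        n_runs=config.n_runs, n_repeats=config.n_repeats, seed=_spawn_seed(rng),
        rotated=rotated, tr=config.tr, run_length=config.run_length,
    )
    noise = config.noise_params()
    z_runs, pct_runs, reports = [], [], []
    for run_id, _ in schedule.runs():
        run = synth.simulate_run(population, schedule, observer, noise,
                                 seed=_spawn_seed(rng), run=run_id)
        z_runs.append(pre.single_trial_matrix(run, mode="zscore"))
        pct_runs.append(pre.single_trial_matrix(run, mode="percent"))
        rep_rng = np.random.default_rng(_spawn_seed(rng))
        for row, percept in zip(run.trials.itertuples(), run.percepts):
            report = synth.simulate_behavioral_report(
                observer, row.condition, row.direction, bool(row.rotated),
                rng=rep_rng, percept=percept,
            )
            reports.append({
                "participant": observer.id, "run": row.run, "condition": row.condition,
                "direction": row.direction, "rotated": bool(row.rotated),
                "report": report, "correct": report == row.direction,
            })
    return {
        "population": population,
        "schedule": schedule,
        "zscore": pre.assemble_session(z_runs),
        "percent": pre.assemble_session(pct_runs),
        "behavior": pd.DataFrame(reports),
    }


def roi_vertex_ids(population: synth.VertexPopulation, roi: str) -> np.ndarray:
    return np.flatnonzero((population.table["roi"] == roi).to_numpy())


def decode_session(
    matrix: pre.TrialMatrix,
    population: synth.VertexPopulation,
    rois,
    n_boot: int,
    rng: np.random.Generator,
    test_fraction: float = 0.10,
) -> dict:
    """Per ROI: stereoscopic, combined, and averaged perspective decoding."""
    out = {}
    for roi in rois:
        ids = roi_vertex_ids(population, roi)
        sub = matrix.vertex_subset(ids)
        res = {}
        for cond in ("stereoscopic", "combined", "perspectiveL", "perspectiveR"):
            res[cond] = decode_mod.decode_direction(
                sub, condition=cond, n_boot=n_boot, seed=_spawn_seed(rng),
                test_fraction=test_fraction,
            )
        res["perspective"] = decode_mod.perspective_average(
            res.pop("perspectiveL"), res.pop("perspectiveR"))
        out[roi] = res
    return out


def classify_observers(
    behavior: pd.DataFrame,
    alpha_z: float = 1.96,
) -> pd.DataFrame:
    """Label participants stereo-pro / stereo-struggler from behaviour.

    A participant is a stereo-struggler when their unrotated
    stereoscopic-cue accuracy does not exceed the upper edge of the
    binomial 95% interval around chance for their trial count.
    Participants with no stereoscopic responses are excluded (logged).
    """
    rows = []
    stereo = behavior[(behavior["condition"] == "stereoscopic")
                      & (~behavior["rotated"].astype(bool))]
    for pid, sub in behavior.groupby("participant"):
        psub = stereo[stereo["participant"] == pid]
        resp = psub["report"].notna() if "report" in psub else pd.Series([], dtype=bool)
        n = int(resp.sum())
        if n == 0:
            logger.warning("participant %s has no stereoscopic responses; excluded", pid)
            continue
        acc = float(psub.loc[resp, "correct"].mean())
        cut = 0.5 + alpha_z * np.sqrt(0.25 / n)
        rows.append({"participant": pid, "stereo_accuracy": acc, "n_trials": n,
                     "group": "stereo_struggler" if acc <= cut else "stereo_pro"})
    return pd.DataFrame(rows)


def dissociation_study(
    n_participants: int = 7,
    rois: tuple[str, ...] = ("MT", "FST"),
    n_runs: int = 10,
    n_boot: int = 150,
    seed: int = 0,
    *,
    n_vertices: dict | None = None,
    noise: dict | None = None,
    lapse: float = 0.02,
) -> pd.DataFrame:
    """Main-vs-rotated decoding for a stereo-pro cohort (headline dissociation).

    Returns one row per participant x ROI x cue condition x session with
    the mean bootstrap decoding accuracy.  Percept-tuned FST loses its
    stereoscopic signal under the 90-deg rotation while retinal-tuned MT
    does not; perspective decoding is unaffected in both.
    """
    config = ExperimentConfig(
        n_participants=n_participants, n_stereo_pros=n_participants, lapse=lapse,
        rois=rois, n_runs=n_runs, n_boot=n_boot, seed=seed,
        n_vertices=n_vertices or {}, noise=noise or {},
    )
    rng = np.random.default_rng(seed)
    rows = []
    for observer in make_observers(config, rng):
        for session, rotated in (("main", False), ("rotated", True)):
            sim = simulate_participant(config, observer, _spawn_seed(rng), rotated)
            res = decode_session(sim["zscore"], sim["population"], rois,
                                 n_boot, rng, config.test_fraction)
            for roi, conds in res.items():
                for cond in ("stereoscopic", "perspective"):
                    rows.append({
                        "participant": observer.id, "roi": roi, "condition": cond,
                        "session": session,
                        "accuracy": conds[cond].mean_accuracy,
                    })
    return pd.DataFrame(rows)


def dissociation_tests(accuracies: pd.DataFrame) -> dict:
    """Rank-sum tests of the main-vs-rotated accuracy change per ROI x condition."""
    out = {}
    for (roi, cond), sub in accuracies.groupby(["roi", "condition"]):
        main = sub[sub["session"] == "main"].sort_values("participant")["accuracy"]
        rot = sub[sub["session"] == "rotated"].sort_values("participant")["accuracy"]
        res = stats_mod.mann_whitney_u(main.to_numpy(), rot.to_numpy())
        out[f"{roi}_{cond}"] = {
            "drop": float(main.mean() - rot.mean()),
            "U": res.statistic, "p": res.p_value,
        }
    return out


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic experiment and write the report bundle.

    Stages are independent: decoding and bias diagnostics can each be
    disabled; the summary always includes the design counts, behaviour
    and observer classification.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    observers = make_observers(config, rng)
    summary: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "participants": [],
        "group_stats": {},
    }
    config.to_yaml(out_dir / "config.yaml")

    behavior_all, decode_rows, bias_rows = [], [], []
    for observer in observers:
        pdir = out_dir / observer.id
        pdir.mkdir(exist_ok=True)
        sessions = [("main", False)] + ([("rotated", True)] if config.include_rotated else [])
        entry = {"id": observer.id, "group": observer.group, "sessions": {}}
        for session, rotated in sessions:
            sim = simulate_participant(config, observer, _spawn_seed(rng), rotated)
            sim["population"].to_tsv(pdir / f"{session}_vertices.tsv")
            sim["schedule"].to_tsv(pdir / f"{session}_schedule.tsv")
            sim["zscore"].save_tsv(pdir / f"{session}_trial_matrix.tsv")
            behavior_all.append(sim["behavior"])
            sess_entry = {"n_trials": sim["zscore"].n_trials,
                          "n_vertices": sim["zscore"].n_vertices}
            if config.run_decoding:
                res = decode_session(sim["zscore"], sim["population"], config.rois,
                                     config.n_boot, rng, config.test_fraction)
                sess_entry["decoding"] = {
                    roi: {c: r.summary() for c, r in conds.items()}
                    for roi, conds in res.items()
                }
                for roi, conds in res.items():
                    for cond, r in conds.items():
                        decode_rows.append({
                            "participant": observer.id, "group": observer.group,
                            "session": session, "roi": roi, "condition": cond,
                            "accuracy": r.mean_accuracy,
                        })
            if config.run_bias and not rotated:
                sess_entry["bias"] = _participant_bias(config, sim, rng, observer,
                                                       bias_rows)
            entry["sessions"][session] = sess_entry
        summary["participants"].append(entry)

    behavior = pd.concat(behavior_all, ignore_index=True)
    behavior.to_csv(out_dir / "behavior.tsv", sep="\t", index=False)
    classification = classify_observers(behavior)
    classification.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
    summary["classification"] = classification.to_dict(orient="records")

    if decode_rows:
        dec = pd.DataFrame(decode_rows)
        dec.to_csv(out_dir / "decoding.tsv", sep="\t", index=False)
        summary["group_stats"].update(_group_decoding_stats(dec))
    if bias_rows:
        pd.DataFrame(bias_rows).to_csv(out_dir / "bias.tsv", sep="\t", index=False)
        summary["group_stats"].update(_group_bias_stats(pd.DataFrame(bias_rows)))

    validate_summary(summary)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _participant_bias(config, sim, rng, observer, bias_rows) -> dict:
    out = {}
    for roi in config.rois:
        ids = roi_vertex_ids(sim["population"], roi)
        pop = sim["population"]
        kept = np.intersect1d(ids, bias_mod.filter_vertices(pop))
        polar = bias_mod.split_polar(kept, pop)
        bold = bias_mod.bold_group_means(sim["percent"], polar,
                                         condition="stereoscopic")
        ecc_split = bias_mod.split_eccentricity(kept, pop)
        out[roi] = {
            "hm_nhm_bold": bold.difference,
            "n_hm": int(polar.group_a.size), "n_nhm": int(polar.group_b.size),
            "ecc_groups": [int(ecc_split.group_a.size), int(ecc_split.group_b.size)],
        }
        bias_rows.append({"participant": observer.id, "roi": roi,
                          "hm_nhm_bold": bold.difference})
    return out


def _group_decoding_stats(dec: pd.DataFrame) -> dict:
    out = {}
    main = dec[dec["session"] == "main"]
    cells = main[main["roi"].isin(["MT", "FST"])
                 & main["condition"].isin(["perspective", "stereoscopic"])]
    if cells["participant"].nunique() >= 2 and not cells.empty:
        try:
            res = stats_mod.mixed_model_contrast(
                cells.rename(columns={"condition": "cue"}), value="accuracy")
            out["cue_x_roi_interaction"] = {"t": res.statistic, "p": res.p_value}
        except Exception as err:  # noqa: BLE001
            logger.warning("mixed-model contrast failed: %s", err)
    if "rotated" in dec["session"].unique():
        out["main_vs_rotated"] = dissociation_tests(
            dec[dec["condition"].isin(["stereoscopic", "perspective"])])
    return out


def _group_bias_stats(bias_df: pd.DataFrame) -> dict:
    out = {}
    for roi, sub in bias_df.groupby("roi"):
        vals = sub["hm_nhm_bold"].dropna().to_numpy()
        if vals.size >= 2 and np.any(vals != 0):
            res = stats_mod.wilcoxon_signed_rank(vals)
            out[f"hm_nhm_bold_{roi}"] = {
                "mean": float(vals.mean()), "W": res.statistic, "p": res.p_value,
            }
    return out


def validate_summary(summary: dict, schema_path: Path = SCHEMA_PATH) -> None:
    """Structural validation of the report summary against the shipped schema.

    Checks required keys and value types (a minimal JSON-schema subset).
    """
    schema = json.loads(Path(schema_path).read_text())
    _validate_node(summary, schema, "summary")


_TYPES = {"object": dict, "array": list, "string": str, "number": (int, float),
          "integer": int, "boolean": bool}


def _validate_node(node, schema: dict, where: str) -> None:
    expected = schema.get("type")
    if expected and not isinstance(node, _TYPES[expected]):
        raise ValueError(f"{where}: expected {expected}, got {type(node).__name__}")
    for key in schema.get("required", []):
        if key not in node:
            raise ValueError(f"{where}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if isinstance(node, dict) and key in node:
            _validate_node(node[key], sub, f"{where}.{key}")
    if expected == "array" and "items" in schema:
        for i, item in enumerate(node):
            _validate_node(item, schema["items"], f"{where}[{i}]")
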