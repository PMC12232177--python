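"""Configuration, COLVAR-style tables, and the staged analysis pipeline.

The pipeline strings together the whole desk-scale study: generate the
surrogate fixture, filter the candidate contacts, train the 1-D
discriminant CV, run OPES on it, label the visited states, train the 2-D
multitask CV, run OPES on that, and estimate the free-energy surface with
path barriers.  A single strict config file (YAML) controls every stage;
re-running with the same config and seed reproduces the report.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts, deeplda, fes, multitask, opes, states, surrogate
from .errors import ConfigurationError, SchemaError

__all__ = [
    "PipelineConfig",
    "DEFAULT_CONFIG",
    "load_config",
    "write_colvar",
    "read_colvar",
    "run_pipeline",
]

logger = logging.getLogger("translocv")

ALL_STAGES = (
    "generate",
    "filter",
    "train-lda",
    "sample-opes-1d",
    "label-states",
    "train-multitask",
    "sample-opes-2d",
    "fes",
    "report",
)

# Pipeline defaults are deliberately desk-scale (minutes on one CPU); the
# per-module defaults carry the full study-condition values.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "translocv_out",
    "stages": list(ALL_STAGES),
    "surrogate": {
        "kT": 0.616,
        "friction": 1.0,
        "timestep": 5.0e-4,
        "diagonal_penalty": 10.0,
        "saddle_heights": {
            "PRE-INT1": 7.5,
            "INT1-POST": 15.0,
            "PRE-INT2": 17.0,
            "INT2-POST": 10.0,
        },
        "basin_depths": {"PRE": 0.0, "INT1": 3.0, "INT2": 5.0, "POST": 0.0},
    },
    "fixture": {"n_frames_per_state": 2000, "n_reactive": 4000},
    "filter": {"presence_cutoff": 6.0, "presence_fraction": 0.5, "sd_mode": "max"},
    "deeplda": {
        "epochs": 500,
        "learning_rate": 5.0e-4,
        "l2_regularization": 1.0e-4,
        "sw_regularization": 0.05,
        "lorentzian_scale": 40.0,
    },
    "multitask": {
        "epochs": 500,
        "learning_rate": 1.0e-3,
        "target_sigma": 0.2,
        "labeled_batch_per_state": 500,
        "unlabeled_batch": 2000,
    },
    "opes_1d": {
        "BARRIER": 20.0,
        "STRIDE": 500,
        "SIGMA": [0.05],
        "variant": "explore",
        "n_steps": 150000,
        "wall_limits": [-1.5, 1.5],
        "wall_force_constant": 40000.0,
        "record_stride": 5,
    },
    "opes_2d": {
        "BARRIER": 20.0,
        "STRIDE": 20,
        "SIGMA": [0.1, 0.1],
        "variant": "explore",
        "sigma_mode": "jump",
        "sigma_cap": 3.0,
        "build_steps": 400000,
        "tail_steps": 250000,
        "tail_discard_fraction": 0.2,
        "wall_limits": [-7.5, 7.5],
        "wall_force_constant": 40000.0,
        "record_stride": 10,
    },
    "states": {"radius": 0.25, "settle": 10},
    "fes": {
        "bins": 60,
        "cv_range": [-7.5, 7.5],
        "n_blocks": 4,
        "smooth_sigma": 0.4,
        "basin_radius": 1.5,
        "corridor_tol": 1.0,
    },
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved configuration (defaults merged with the user file)."""

    values: dict

    def __getitem__(self, key):
        return self.values[key]

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    @property
    def stages(self) -> list[str]:
        return list(self.values["stages"])


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown configuration key {where!r}")
        ref = defaults[key]
        if isinstance(ref, dict):
            if not isinstance(val, dict):
                raise ConfigurationError(f"{where!r} must be a mapping")
            out[key] = _merge_strict(ref, val, where)
        else:
            if isinstance(ref, bool) and not isinstance(val, bool):
                raise ConfigurationError(f"{where!r} must be a boolean")
            if isinstance(ref, (int, float)) and not isinstance(ref, bool):
                if not isinstance(val, (int, float)) or isinstance(val, bool):
                    raise ConfigurationError(f"{where!r} must be a number")
            if isinstance(ref, str) and not isinstance(val, str):
                raise ConfigurationError(f"{where!r} must be a string")
            if isinstance(ref, list) and not isinstance(val, list):
                raise ConfigurationError(f"{where!r} must be a list")
            out[key] = val
    return out


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected, omissions take defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    user = yaml.safe_load(path.read_text())
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigurationError("config root must be a mapping")
    resolved = _merge_strict(DEFAULT_CONFIG, user)
    unknown = [s for s in resolved["stages"] if s not in ALL_STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages {unknown}")
    logger.info("resolved configuration: %s", json.dumps(resolved, sort_keys=True))
    return PipelineConfig(values=resolved)


# ---------------------------------------------------------------------------
# COLVAR-style whitespace tables

def write_colvar(df: pd.DataFrame, path) -> None:
    """Write a whitespace table with a '#! FIELDS ...' header.

    Values are written with ``repr`` so a read-back reproduces them exactly.
    """
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_colvar(path) -> pd.DataFrame:
    """Read a COLVAR-style table; column-count mismatches name the line."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#! FIELDS "):
            raise SchemaError(f"{path}: missing '#! FIELDS' header")
        fields = header[len("#! FIELDS "):].split()
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(fields):
                raise SchemaError(
                    f"{path}:{lineno}: expected {len(fields)} columns, found {len(parts)}"
                )
            rows.append([float(p) for p in parts])
    return pd.DataFrame(rows, columns=fields)


def trajectory_to_colvar(traj: surrogate.Trajectory) -> pd.DataFrame:
    cols = {"time": traj.times}
    if traj.cv is not None:
        cv = np.atleast_2d(traj.cv)
        if cv.shape[0] != len(traj):
            cv = cv.T
        for k in range(cv.shape[1]):
            cols[f"cv{k + 1}"] = cv[:, k]
    if traj.bias is not None:
        cols["opes.bias"] = traj.bias
    if traj.wall_bias is not None:
        cols["wall.bias"] = traj.wall_bias
    if traj.weights is not None:
        cols["weight"] = traj.weights
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# staged execution

def _stage_seed(base_seed: int, stage: str) -> int:
    # stable per-stage substream, kept below 2**31
    return (base_seed * 1000003 + sum(ord(c) for c in stage)) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute the configured stages in order and return the report dict.

    Artifacts (filter report, models, COLVAR tables, FES grid, report) are
    persisted under the output directory; a stage failure propagates after
    the partial artifacts are on disk.
    """
    cfg = config.values
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    art: dict = {}
    report: dict = {"seed": config.seed, "stages_run": []}

    for stage in config.stages:
        logger.info("stage %s", stage)
        _STAGE_FUNCS[stage](cfg, art, report, outdir)
        report["stages_run"].append(stage)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _stage_generate(cfg, art, report, outdir):
    sc = cfg["surrogate"]
    sys_cfg = surrogate.SurrogateConfig(
        saddle_heights=dict(sc["saddle_heights"]),
        basin_depths=dict(sc["basin_depths"]),
        diagonal_penalty=sc["diagonal_penalty"],
        kT=sc["kT"],
        friction=sc["friction"],
        timestep=sc["timestep"],
        seed=cfg["seed"],
    )
    art["system"] = surrogate.build_surrogate(sys_cfg)
    art["specs"] = surrogate.default_descriptor_specs(seed=cfg["seed"])
    n = cfg["fixture"]["n_frames_per_state"]
    pre, post, _ = surrogate.make_fixture(seed=cfg["seed"], n_frames_per_state=n)
    art["fixture_pre"], art["fixture_post"] = pre, post
    labeled, reactive = surrogate.make_multistate_fixture(
        seed=cfg["seed"],
        n_labeled_per_state=n,
        n_reactive=cfg["fixture"]["n_reactive"],
    )
    art["labeled4"], art["reactive"] = labeled, reactive
    report["fixture"] = {
        "n_candidates": len(pre.descriptor_ids),
        "n_frames_per_state": n,
    }


def _stage_filter(cfg, art, report, outdir):
    fc = cfg["filter"]
    retained, rep = contacts.filter_descriptors(
        art["fixture_pre"],
        art["fixture_post"],
        presence_cutoff=fc["presence_cutoff"],
        presence_fraction=fc["presence_fraction"],
        sd_mode=fc["sd_mode"],
    )
    art["retained"] = retained
    rep.to_csv(outdir / "filter_report.csv")
    counts = rep.records.removing_rule.value_counts().to_dict()
    report["filter"] = {"n_retained": len(retained), "removed_by_rule": counts}


def _stage_train_lda(cfg, art, report, outdir):
    dc = cfg["deeplda"]
    pre = art["fixture_pre"].select(art["retained"])
    post = art["fixture_post"].select(art["retained"])
    table = _concat_tables(pre, post)
    config = deeplda.DeepLDAConfig(
        layer_widths=(len(art["retained"]), 30, 20, 15, 10, 5),
        epochs=dc["epochs"],
        learning_rate=dc["learning_rate"],
        l2_regularization=dc["l2_regularization"],
        sw_regularization=dc["sw_regularization"],
        lorentzian_scale=dc["lorentzian_scale"],
        seed=_stage_seed(cfg["seed"], "train-lda"),
    )
    model = deeplda.train_deep_lda(table, config)
    art["lda"] = model
    model.save(outdir / "deeplda_cv.json")
    means = {
        s: float(model.evaluate(table.frames_for(s).values()).mean())
        for s in (model.positive_state, model.negative_state)
    }
    report["deeplda"] = {"state_cv_means": means}


def _stage_sample_1d(cfg, art, report, outdir):
    oc = cfg["opes_1d"]
    dmap = surrogate.DescriptorMap(art["specs"]).subset(art["retained"])
    opes_cfg = opes.OPESConfig(
        barrier=oc["BARRIER"], stride=oc["STRIDE"], sigma=tuple(oc["SIGMA"]),
        variant=oc["variant"],
    )
    wall = [opes.WallSpec(oc["wall_limits"][0], oc["wall_limits"][1], oc["wall_force_constant"])]
    traj, bias = opes.run_opes(
        art["system"], art["lda"], opes_cfg, wall, oc["n_steps"],
        seed=_stage_seed(cfg["seed"], "sample-opes-1d"),
        descriptor_map=dmap, record_stride=oc["record_stride"],
    )
    art["traj_1d"], art["bias_1d"] = traj, bias
    write_colvar(trajectory_to_colvar(traj), outdir / "colvar_opes_1d.dat")
    report["opes_1d"] = {"n_kernels": bias.kernel_count, "n_frames": len(traj)}


def _stage_label_states(cfg, art, report, outdir):
    ref = states.StateReference(radius=cfg["states"]["radius"])
    labels = states.assign_states(art["traj_1d"], ref)
    recs = states.count_transitions(labels, settle=cfg["states"]["settle"])
    art["labels_1d"], art["transitions_1d"] = labels, recs
    pd.DataFrame([dataclasses.asdict(r) for r in recs]).to_csv(
        outdir / "transitions_1d.csv", index=False
    )
    report["states_1d"] = {
        "n_transitions": len(recs),
        "by_pathway": {
            "via_INT1": sum(1 for r in recs if r.pathway == 1),
            "via_INT2": sum(1 for r in recs if r.pathway == 2),
        },
    }


def _stage_train_multitask(cfg, art, report, outdir):
    mc = cfg["multitask"]
    labeled = art["labeled4"].select(art["retained"])
    reactive = art["reactive"].select(art["retained"])
    config = multitask.MultiTaskConfig(
        encoder_widths=(len(art["retained"]), 50, 30, 15, 5, 2),
        decoder_widths=(2, 5, 15, 30, 50, len(art["retained"])),
        epochs=mc["epochs"],
        learning_rate=mc["learning_rate"],
        target_sigma=mc["target_sigma"],
        labeled_batch_per_state=mc["labeled_batch_per_state"],
        unlabeled_batch=mc["unlabeled_batch"],
        seed=_stage_seed(cfg["seed"], "train-multitask"),
    )
    model = multitask.train_multitask(labeled, reactive, config)
    art["mt"] = model
    model.save(outdir / "multitask_cv.json")
    cents = {}
    for s in surrogate.STATE_NAMES:
        z = model.evaluate(labeled.frames_for(s).values())
        cents[s] = [float(v) for v in z.mean(axis=0)]
    report["multitask"] = {"state_centroids": cents}


def _stage_sample_2d(cfg, art, report, outdir):
    """Build a flat bias once, then sample frozen-bias tails from each basin."""
    oc = cfg["opes_2d"]
    dmap = surrogate.DescriptorMap(art["specs"]).subset(art["retained"])
    opes_cfg = opes.OPESConfig(
        barrier=oc["BARRIER"], stride=oc["STRIDE"], sigma=tuple(oc["SIGMA"]),
        variant=oc["variant"], sigma_mode=oc["sigma_mode"], sigma_cap=oc["sigma_cap"],
    )
    lims = oc["wall_limits"]
    wall = [opes.WallSpec(lims[0], lims[1], oc["wall_force_constant"])] * 2
    base_seed = _stage_seed(cfg["seed"], "sample-opes-2d")
    _, bias = opes.run_opes(
        art["system"], art["mt"], opes_cfg, wall, oc["build_steps"],
        seed=base_seed, descriptor_map=dmap, record_stride=100,
    )
    tails = []
    recs = []
    for k, state in enumerate(surrogate.STATE_NAMES):
        traj, _ = opes.run_opes(
            art["system"], art["mt"], opes_cfg, wall, oc["tail_steps"],
            seed=(base_seed + 1 + k) % 2**31, descriptor_map=dmap,
            record_stride=oc["record_stride"], record_noise=True,
            freeze_after=0, bias_init=bias,
            x0=surrogate.BASIN_CENTERS[state],
        )
        labels = states.assign_states(
            traj, states.StateReference(radius=cfg["states"]["radius"])
        )
        recs += states.count_transitions(labels, settle=cfg["states"]["settle"])
        n_equil = int(oc["tail_discard_fraction"] * len(traj))
        tails.append((traj, n_equil))
        write_colvar(trajectory_to_colvar(traj), outdir / f"colvar_opes_2d_{state}.dat")
    art["tails_2d"], art["bias_2d"] = tails, bias
    art["transitions_2d"] = recs
    tally = {
        "via_INT1": sum(1 for r in recs if r.pathway == 1),
        "via_INT2": sum(1 for r in recs if r.pathway == 2),
    }
    report["opes_2d"] = {
        "n_kernels": bias.kernel_count,
        "n_transitions": len(recs),
        "by_pathway": tally,
    }
    pre_origin = [r for r in recs if r.start_state == "PRE" and r.pathway is not None]
    if pre_origin:
        frac, ci = states.pathway_preference(recs)
        report["opes_2d"]["pre_origin_fraction_via_INT1"] = frac
        report["opes_2d"]["fraction_ci"] = list(ci)


def _stage_fes(cfg, art, report, outdir):
    fc = cfg["fes"]
    bias = art["bias_2d"]
    # pooled frozen-bias tails; umbrella weights w ∝ exp(beta*V) are exact
    # for the static bias each tail sampled
    s = np.concatenate([t.cv[n0:] for t, n0 in art["tails_2d"]])
    logw = bias.beta * np.concatenate([t.bias[n0:] for t, n0 in art["tails_2d"]])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    grid = fes.GridSpec(tuple(fc["cv_range"]), tuple(fc["cv_range"]), fc["bins"])
    grid_fes = fes.estimate_fes(s, w, grid, bias.beta, smooth_sigma=fc["smooth_sigma"])
    grid_fes.write_text(outdir / "fes.dat")
    centers = art["mt"].state_centers
    barriers = fes.edge_barriers(
        grid_fes, centers, basin_radius=fc["basin_radius"], corridor_tol=fc["corridor_tol"]
    )
    errs, skipped = fes.edge_barrier_errors(
        s, w, grid, bias.beta, centers,
        n_blocks=fc["n_blocks"], smooth_sigma=fc["smooth_sigma"],
        basin_radius=fc["basin_radius"], corridor_tol=fc["corridor_tol"],
    )
    report["fes"] = {
        "barriers_kcal_mol": {k: float(v) for k, v in barriers.items()},
        "barrier_errors": errs,
        "blocks_skipped": skipped,
    }
    art["fes"] = grid_fes


def _stage_report(cfg, art, report, outdir):
    # summary stage: nothing to compute, report is assembled incrementally
    return


def _concat_tables(a, b):
    from .tables import DescriptorTable

    df = pd.concat([a.data, b.data], ignore_index=True)
    labels = np.concatenate([a.labels, b.labels])
    return DescriptorTable(df, a.metadata, labels)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "filter": _stage_filter,
    "train-lda": _stage_train_lda,
    "sample-opes-1d": _stage_sample_1d,
    "label-states": _stage_label_states,
    "train-multitask": _stage_train_multitask,
    "sample-opes-2d": _stage_sample_2d,
    "fes": _stage_fes,
    "report": _stage_report,
}
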