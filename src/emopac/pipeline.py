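"""Orchestrated end-to-end runs: simulate -> preprocess -> tf -> permtest
-> pac -> behavior -> correlate -> report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML), writes
every stage's output into a run directory as HDF5 result containers and
CSV tables, and is bit-reproducible under a fixed global seed: per-stage
sub-seeds are derived by stable hashing of stage names, and container
checksums (over array contents) are written to ``checksums.json`` so two
runs can be compared.

Stages may be run individually; a stage whose inputs are neither in memory
nor on disk raises :class:`DependencyError` naming the missing stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, groupstats, pac as pacmod, permstats, preprocess as prep
from .io import (EpochedDataset, ResultArray, ResultContainer, config_hash,
                 container_checksum, read_container, write_container)
from .montage import CLUSTERS
from .synth import CONDITIONS, SimulationConfig, simulate_behavior, simulate_study
from .timefreq import DEFAULT_FREQS, TFMap, aggregate_tf, cluster_tf_map

logger = logging.getLogger("emopac")

STAGE_ORDER = ("simulate", "preprocess", "tf", "permtest", "pac",
               "behavior", "correlate", "report")
DEPENDENCIES = {
    "simulate": (),
    "preprocess": ("simulate",),
    "tf": ("preprocess",),
    "permtest": ("tf",),
    "pac": ("preprocess",),
    "behavior": ("simulate",),
    "correlate": ("pac", "behavior"),
    "report": (),
}


class DependencyError(RuntimeError):
    """A requested stage is missing an upstream artifact."""


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    stages: list[str] = dataclasses.field(
        default_factory=lambda: [s for s in STAGE_ORDER])
    simulate: dict = dataclasses.field(default_factory=dict)
    preprocess: dict = dataclasses.field(default_factory=dict)
    tf: dict = dataclasses.field(default_factory=dict)
    permutation: dict = dataclasses.field(default_factory=dict)
    pac: dict = dataclasses.field(default_factory=dict)
    report: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; expected from {STAGE_ORDER}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seed(self, stage: str, extra: str = "") -> int:
        """Deterministic sub-seed: global seed combined with a stable hash
        of the stage name (and an optional qualifier)."""
        tag = zlib.crc32(f"{stage}/{extra}".encode())
        ss = np.random.SeedSequence([int(self.seed), tag])
        return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# dataset <-> container round trip
# ---------------------------------------------------------------------------

def _datasets_to_container(datasets: list[EpochedDataset], cfg_hash: str,
                           seed: int) -> ResultContainer:
    container = ResultContainer(provenance={
        "config_hash": cfg_hash, "seed": seed, "version": __version__,
        "kind": "epoched_eeg",
    })
    for ds in datasets:
        container.add(ds.participant_id, ResultArray(
            # float32 on disk: EEG epochs dominate run-directory size and
            # micro-volt data carry nowhere near 7 significant digits
            values=ds.data.astype(np.float32),
            dims=("trial", "channel", "time"),
            coords={
                "trial": np.array(ds.condition_labels),
                "channel": np.array(ds.channel_names),
                "time": ds.times,
            },
            attrs={"sampling_rate": ds.sampling_rate,
                   "epoch_t0": ds.epoch_window[0],
                   "epoch_t1": ds.epoch_window[1],
                   "participant": ds.participant_id},
        ))
    return container


def _datasets_from_container(container: ResultContainer) -> list[EpochedDataset]:
    datasets = []
    for name in sorted(container.arrays):
        arr = container.arrays[name]
        datasets.append(EpochedDataset(
            data=arr.values,
            sampling_rate=float(arr.attrs["sampling_rate"]),
            channel_names=[str(c) for c in arr.coords["channel"]],
            condition_labels=[str(c) for c in arr.coords["trial"]],
            epoch_window=(float(arr.attrs["epoch_t0"]), float(arr.attrs["epoch_t1"])),
            participant_id=str(arr.attrs["participant"]),
        ))
    return datasets


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, out: Path) -> None:
    params = dict(config.simulate)
    use_defaults = params.pop("study_defaults", True)
    params.setdefault("seed", config.stage_seed("simulate"))
    sim = (SimulationConfig.study_default(**params) if use_defaults
           else SimulationConfig(**params))
    logger.info("simulate: %d participants, %d trials/condition, %.0f Hz",
                sim.n_participants, sim.n_trials_per_condition, sim.sampling_rate)
    state["sim_config"] = sim
    state["datasets_raw"] = simulate_study(sim)
    state["behavior"] = simulate_behavior(sim)
    state["behavior"].to_csv(out / "behavior.csv", index=False)
    container = _datasets_to_container(state["datasets_raw"], state["cfg_hash"],
                                       config.seed)
    write_container(container, out / "eeg_raw.h5")


def _stage_preprocess(config: RunConfig, state: dict, out: Path) -> None:
    params = dict(config.preprocess)
    spec = prep.FilterSpec(**params.pop("filter", {}))
    target_rate = params.pop("target_rate", 256.0)
    bad_channels = params.pop("bad_channels", [])
    order = params.pop("order", prep.DEFAULT_ORDER)
    datasets = state["datasets_raw"]
    logger.info("preprocess: %d datasets -> %.0f Hz, order %s",
                len(datasets), target_rate, list(order))
    state["datasets"] = [
        prep.preprocess_dataset(ds, filter_spec=spec, target_rate=target_rate,
                                bad_channels=bad_channels, order=order)
        for ds in datasets
    ]
    container = _datasets_to_container(state["datasets"], state["cfg_hash"],
                                       config.seed)
    container.provenance["kind"] = "epoched_eeg_preprocessed"
    write_container(container, out / "eeg_preprocessed.h5")


def _tf_windows(config: RunConfig) -> tuple[tuple[float, float], tuple[float, float]]:
    params = config.tf
    return (tuple(params.get("activation_window", (0.0, 10.0))),
            tuple(params.get("reference_window", (-6.0, -1.0))))


def _stage_tf(config: RunConfig, state: dict, out: Path) -> None:
    params = dict(config.tf)
    decim = params.get("decim", 8)
    fmax = params.get("fmax", 70.0)
    freq_step = params.get("freq_step", 1.0)
    freqs = np.arange(1.0, fmax + 1e-9, freq_step)
    act_win, ref_win = _tf_windows(config)
    datasets = state["datasets"]
    container = ResultContainer(provenance={
        "config_hash": state["cfg_hash"], "seed": config.seed,
        "version": __version__, "kind": "tf_maps",
    })
    state["tf"] = {}
    for cluster in CLUSTERS:
        for condition in CONDITIONS:
            maps = [cluster_tf_map(ds, cluster, condition, freqs=freqs,
                                   decim=decim) for ds in datasets]
            acts = np.stack([m.crop(act_win).values for m in maps])
            refs = np.stack([m.crop(ref_win).values for m in maps])
            grand = aggregate_tf(maps)
            key = f"{cluster}_{condition}"
            state["tf"][key] = {"activation": acts, "reference": refs,
                                "grand": grand}
            act_times = maps[0].crop(act_win).times
            ref_times = maps[0].crop(ref_win).times
            participants = np.array([m.participant_id for m in maps])
            container.add(f"{key}__activation", ResultArray(
                acts, ("participant", "freq", "time"),
                {"participant": participants, "freq": freqs, "time": act_times},
                attrs={"cluster": cluster, "condition": condition}))
            container.add(f"{key}__reference", ResultArray(
                refs, ("participant", "freq", "time"),
                {"participant": participants, "freq": freqs, "time": ref_times},
                attrs={"cluster": cluster, "condition": condition}))
            container.add(f"{key}__grand", ResultArray(
                grand.values, ("freq", "time"),
                {"freq": freqs, "time": grand.times},
                attrs={"cluster": cluster, "condition": condition,
                       "level": "grand_average"}))
            logger.info("tf: %s/%s grand map %s", cluster, condition,
                        grand.values.shape)
    write_container(container, out / "tf.h5")


def _load_tf(state: dict, out: Path) -> None:
    container = read_container(out / "tf.h5")
    state["tf"] = {}
    for cluster in CLUSTERS:
        for condition in CONDITIONS:
            key = f"{cluster}_{condition}"
            grand_arr = container.arrays[f"{key}__grand"]
            grand = TFMap(values=grand_arr.values,
                          freqs=np.asarray(grand_arr.coords["freq"], dtype=float),
                          times=np.asarray(grand_arr.coords["time"], dtype=float),
                          cluster=cluster, condition=condition,
                          level="grand_average")
            state["tf"][key] = {
                "activation": container.arrays[f"{key}__activation"].values,
                "reference": container.arrays[f"{key}__reference"].values,
                "grand": grand,
            }


def _stage_permtest(config: RunConfig, state: dict, out: Path) -> None:
    params = dict(config.permutation)
    params.setdefault("cluster_k", 100)
    container = ResultContainer(provenance={
        "config_hash": state["cfg_hash"], "seed": config.seed,
        "version": __version__, "kind": "tf_significance",
    })
    state["permtest"] = {}
    for key, maps in state["tf"].items():
        cfg = permstats.PermutationConfig(
            seed=config.stage_seed("permtest", key), **params)
        result = permstats.run_permutation_test(maps["activation"],
                                                maps["reference"], cfg)
        state["permtest"][key] = result
        grand = maps["grand"]
        coords = {"freq": grand.freqs,
                  "time": np.arange(result.mask.shape[1], dtype=float)}
        for field in ("mask", "direction", "p_values", "z_values", "observed"):
            container.add(f"{key}__{field}", ResultArray(
                np.asarray(getattr(result, field)), ("freq", "time"), coords,
                attrs={"n_permutations": cfg.n_permutations,
                       "alpha": cfg.alpha, "cluster_k": cfg.cluster_k}))
        logger.info("permtest: %s -> %d significant elements in clusters",
                    key, int(result.mask.sum()))
    write_container(container, out / "permtest.h5")


def _stage_pac(config: RunConfig, state: dict, out: Path) -> None:
    params = dict(config.pac)
    n_surrogates = params.get("n_surrogates", 200)
    smooth_halfwidth = params.get("smooth_halfwidth", 2)
    perm_params = dict(params.get("permutation", {}))
    perm_params.setdefault("cluster_k", 12)
    act_win, ref_win = _tf_windows(config)
    grid = pacmod.BandGrid()
    datasets = state["datasets"]
    container = ResultContainer(provenance={
        "config_hash": state["cfg_hash"], "seed": config.seed,
        "version": __version__, "kind": "pac",
    })
    state["pac"] = {}
    for path in pacmod.PATHS:
        for condition in CONDITIONS:
            key = f"{path}_{condition}"
            acts, refs = [], []
            for ds in datasets:
                seed = config.stage_seed("pac", f"{ds.participant_id}/{key}")
                act = pacmod.comodulogram(ds, path, condition, grid, act_win,
                                          n_surrogates, seed,
                                          window_label="activation")
                ref = pacmod.comodulogram(ds, path, condition, grid, ref_win,
                                          n_surrogates, seed + 1,
                                          window_label="reference")
                acts.append(act)
                refs.append(ref)
            act_stack = np.stack([m.values for m in acts])
            ref_stack = np.stack([m.values for m in refs])
            contrast = [dataclasses.replace(a, values=a.values - r.values,
                                            window="contrast")
                        for a, r in zip(acts, refs)]
            grand = pacmod.grand_average_pac(contrast,
                                             smooth_halfwidth=smooth_halfwidth)
            sig = pacmod.pac_significance(
                act_stack, ref_stack,
                permstats.PermutationConfig(
                    seed=config.stage_seed("pacsig", key), **perm_params))
            state["pac"][key] = {"participant_contrast": contrast,
                                 "grand": grand, "significance": sig}
            participants = np.array([m.participant_id for m in acts])
            coords3 = {"participant": participants,
                       "phase_freq": grid.phase_centers,
                       "amp_freq": grid.amp_centers}
            coords2 = {"phase_freq": grid.phase_centers,
                       "amp_freq": grid.amp_centers}
            attrs = {"path": path, "condition": condition}
            container.add(f"{key}__activation", ResultArray(
                act_stack, ("participant", "phase_freq", "amp_freq"), coords3,
                attrs=attrs))
            container.add(f"{key}__reference", ResultArray(
                ref_stack, ("participant", "phase_freq", "amp_freq"), coords3,
                attrs=attrs))
            container.add(f"{key}__grand_contrast", ResultArray(
                grand.values, ("phase_freq", "amp_freq"), coords2, attrs=attrs))
            container.add(f"{key}__mask", ResultArray(
                sig.mask, ("phase_freq", "amp_freq"), coords2, attrs=attrs))
            container.add(f"{key}__z", ResultArray(
                sig.z_values, ("phase_freq", "amp_freq"), coords2, attrs=attrs))
            logger.info("pac: %s -> %d significant bins", key,
                        int(sig.mask.sum()))
    write_container(container, out / "pac.h5")


def _load_pac(state: dict, out: Path) -> None:
    container = read_container(out / "pac.h5")
    grid = pacmod.BandGrid()
    state["pac"] = {}
    for path in pacmod.PATHS:
        for condition in CONDITIONS:
            key = f"{path}_{condition}"
            act = container.arrays[f"{key}__activation"]
            ref = container.arrays[f"{key}__reference"]
            contrast = []
            for i, pid in enumerate(act.coords["participant"]):
                contrast.append(pacmod.PACMatrix(
                    values=act.values[i] - ref.values[i],
                    phase_freqs=grid.phase_centers, amp_freqs=grid.amp_centers,
                    path=path, condition=condition, window="contrast",
                    participant_id=str(pid)))
            grand = pacmod.PACMatrix(
                values=container.arrays[f"{key}__grand_contrast"].values,
                phase_freqs=grid.phase_centers, amp_freqs=grid.amp_centers,
                path=path, condition=condition, level="grand_average",
                window="contrast")
            state["pac"][key] = {"participant_contrast": contrast,
                                 "grand": grand, "significance": None}


def _stage_behavior(config: RunConfig, state: dict, out: Path) -> None:
    table = state["behavior"]
    rows = []
    for dv in ("arousal", "pleasure", "originality"):
        result = groupstats.oneway_anova(table, dv, mode="within")
        rows.append({"dv": dv, "F": result.F, "df1": result.df[0],
                     "df2": result.df[1], "p": result.p,
                     "eta_squared_partial": result.eta_squared_partial})
        for cmp in result.posthoc:
            rows.append({"dv": dv, "pair": " vs ".join(cmp.pair),
                         "t": cmp.t, "p_tukey": cmp.p_adjusted,
                         "mean_difference": cmp.mean_difference})
        logger.info("behavior: %s F(%d,%d)=%.2f p=%.2g", dv, result.df[0],
                    result.df[1], result.F, result.p)
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "behavior_anova.csv", index=False)
    state["behavior_anova"] = frame


def _stage_correlate(config: RunConfig, state: dict, out: Path) -> None:
    genders = {}
    for _, row in state["behavior"].iterrows():
        genders[row["participant"]] = row["gender"]
    matrices = {}
    for key, payload in state["pac"].items():
        path, condition = key.rsplit("_", 1)
        for m in payload["participant_contrast"]:
            matrices[(m.participant_id, condition, path)] = m
    features = groupstats.pac_feature_table(matrices, genders)
    features.to_csv(out / "pac_features.csv", index=False)
    frames = [groupstats.correlations_frame(
        groupstats.pac_correlations(features, group="all"))]
    for gender in ("male", "female"):
        count = features[features["gender"] == gender]["participant"].nunique()
        if count >= 4:
            frames.append(groupstats.correlations_frame(
                groupstats.pac_correlations(features, group=gender)))
        else:
            logger.info("correlate: skipping %s subgroup (n=%d < 4)", gender, count)
    corr = pd.concat(frames, ignore_index=True)
    corr.to_csv(out / "correlations.csv", index=False)
    state["correlations"] = corr
    logger.info("correlate: %d feature pairs", len(corr))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def render_report(run_dir: str | Path, heatmaps: bool = True) -> Path:
    """Summary document for a (possibly partial) run directory.

    Writes ``report.md`` plus, when requested, heatmap panels of the grand
    TF maps (cluster x condition) and PAC comodulograms (path x
    condition). Missing stages become placeholder sections. Regeneration
    is idempotent.
    """
    run_dir = Path(run_dir)
    lines = ["# Pipeline run summary", ""]

    behavior_path = run_dir / "behavior_anova.csv"
    lines.append("## Behavioral ANOVA")
    if behavior_path.exists():
        table = pd.read_csv(behavior_path)
        lines.append("")
        lines.append(table.to_markdown(index=False))
    else:
        lines.append("_behavior stage not run_")
    lines.append("")

    fig_dir = run_dir / "figures"

    lines.append("## Time-frequency maps")
    if (run_dir / "tf.h5").exists():
        container = read_container(run_dir / "tf.h5")
        grand_keys = sorted(k for k in container.arrays if k.endswith("__grand"))
        lines.append(f"{len(grand_keys)} grand-average cluster x condition panels.")
        if heatmaps:
            fig_dir.mkdir(exist_ok=True)
            _tf_figure(container, grand_keys, fig_dir / "tf_grand.png")
            lines.append("![TF grand averages](figures/tf_grand.png)")
    else:
        lines.append("_tf stage not run_")
    lines.append("")

    lines.append("## Significant TF regions")
    if (run_dir / "permtest.h5").exists():
        container = read_container(run_dir / "permtest.h5")
        for key in sorted(container.arrays):
            if key.endswith("__mask"):
                mask = container.arrays[key].values
                lines.append(f"- {key.replace('__mask', '')}: "
                             f"{int(mask.sum())} significant elements")
    else:
        lines.append("_permtest stage not run_")
    lines.append("")

    lines.append("## Phase-amplitude coupling")
    if (run_dir / "pac.h5").exists():
        container = read_container(run_dir / "pac.h5")
        grand_keys = sorted(k for k in container.arrays
                            if k.endswith("__grand_contrast"))
        lines.append(f"{len(grand_keys)} grand-average path x condition comodulograms.")
        for key in sorted(container.arrays):
            if key.endswith("__mask"):
                mask = container.arrays[key].values
                lines.append(f"- {key.replace('__mask', '')}: "
                             f"{int(mask.sum())} significant bins")
        if heatmaps:
            fig_dir.mkdir(exist_ok=True)
            _pac_figure(container, grand_keys, fig_dir / "pac_grand.png")
            lines.append("![PAC comodulograms](figures/pac_grand.png)")
    else:
        lines.append("_pac stage not run_")
    lines.append("")

    lines.append("## PAC correlations")
    corr_path = run_dir / "correlations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        starred = corr[corr["stars"].notna() & (corr["stars"] != "")]
        lines.append(f"{len(corr)} feature pairs tested; "
                     f"{len(starred)} starred at p < .05.")
        if len(starred):
            lines.append("")
            cols = ["group", "path", "feature_a", "feature_b", "r", "p", "stars"]
            lines.append(starred[cols].to_markdown(index=False))
    else:
        lines.append("_correlate stage not run_")
    lines.append("")

    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report


def _tf_figure(container: ResultContainer, keys: list[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = sorted({container.arrays[k].attrs["cluster"] for k in keys})
    conditions = [c for c in CONDITIONS]
    fig, axes = plt.subplots(len(clusters), len(conditions),
                             figsize=(4 * len(conditions), 2.5 * len(clusters)),
                             squeeze=False)
    for i, cluster in enumerate(clusters):
        for j, condition in enumerate(conditions):
            key = f"{cluster}_{condition}__grand"
            arr = container.arrays[key]
            ax = axes[i][j]
            vmax = max(np.abs(arr.values).max(), 1e-6)
            ax.pcolormesh(arr.coords["time"], arr.coords["freq"], arr.values,
                          cmap="RdBu_r", vmin=-vmax, vmax=vmax, shading="auto")
            ax.set_title(f"{cluster} / {condition}", fontsize=8)
            if i == len(clusters) - 1:
                ax.set_xlabel("time (s)")
            if j == 0:
                ax.set_ylabel("freq (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _pac_figure(container: ResultContainer, keys: list[str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = [p for p in pacmod.PATHS]
    conditions = [c for c in CONDITIONS]
    fig, axes = plt.subplots(len(paths), len(conditions),
                             figsize=(3.2 * len(conditions), 2.4 * len(paths)),
                             squeeze=False)
    for i, p in enumerate(paths):
        for j, condition in enumerate(conditions):
            arr = container.arrays[f"{p}_{condition}__grand_contrast"]
            ax = axes[i][j]
            vmax = max(np.abs(arr.values).max(), 1e-6)
            ax.pcolormesh(arr.coords["phase_freq"], arr.coords["amp_freq"],
                          arr.values.T, cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                          shading="auto")
            ax.set_title(f"{p} / {condition}", fontsize=8)
            if i == len(paths) - 1:
                ax.set_xlabel("phase freq (Hz)")
            if j == 0:
                ax.set_ylabel("amp freq (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_LOADERS = {
    "simulate": lambda state, out: (
        state.update(datasets_raw=_datasets_from_container(
            read_container(out / "eeg_raw.h5")),
            behavior=pd.read_csv(out / "behavior.csv"))
        if (out / "eeg_raw.h5").exists() and (out / "behavior.csv").exists()
        else None),
    "preprocess": lambda state, out: (
        state.update(datasets=_datasets_from_container(
            read_container(out / "eeg_preprocessed.h5")))
        if (out / "eeg_preprocessed.h5").exists() else None),
    "tf": lambda state, out: (_load_tf(state, out)
                              if (out / "tf.h5").exists() else None),
    "pac": lambda state, out: (_load_pac(state, out)
                               if (out / "pac.h5").exists() else None),
    "behavior": lambda state, out: (
        state.update(behavior_anova=pd.read_csv(out / "behavior_anova.csv"))
        if (out / "behavior_anova.csv").exists() else None),
}

_STATE_KEYS = {
    "simulate": ("datasets_raw", "behavior"),
    "preprocess": ("datasets",),
    "tf": ("tf",),
    "permtest": ("permtest",),
    "pac": ("pac",),
    "behavior": ("behavior_anova",),
    "correlate": ("correlations",),
    "report": (),
}

_RUNNERS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "tf": _stage_tf,
    "permtest": _stage_permtest,
    "pac": _stage_pac,
    "behavior": _stage_behavior,
    "correlate": _stage_correlate,
}


def _satisfied(stage: str, state: dict) -> bool:
    return all(key in state for key in _STATE_KEYS[stage])


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in dependency order.

    Returns the run directory; writes ``checksums.json`` with a checksum
    per result container so reruns can be compared bit-for-bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {"cfg_hash": config_hash(config.to_dict())}
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    for stage in config.stages:
        for dep in DEPENDENCIES[stage]:
            if _satisfied(dep, state):
                continue
            loader = _LOADERS.get(dep)
            if loader is not None:
                loader(state, out)
            if not _satisfied(dep, state):
                raise DependencyError(
                    f"stage {stage!r} needs output of stage {dep!r}, which was "
                    "neither requested nor found in the run directory"
                )
        if stage == "report":
            render_report(out, heatmaps=config.report.get("heatmaps", True))
        else:
            logger.info("running stage %s", stage)
            _RUNNERS[stage](config, state, out)

    checksums = {}
    for name in ("eeg_raw", "eeg_preprocessed", "tf", "permtest", "pac"):
        path = out / f"{name}.h5"
        if path.exists():
            checksums[name] = container_checksum(read_container(path))
    (out / "checksums.json").write_text(json.dumps(checksums, indent=2, sort_keys=True))
    return out


def demo_config(out_dir: str = "runs/demo", seed: int = 0) -> RunConfig:
    """Small end-to-end demonstration configuration (4 participants,
    10 trials per condition, coarse TF time grid)."""
    return RunConfig(
        seed=seed,
        out_dir=out_dir,
        simulate={"n_participants": 4, "n_trials_per_condition": 10},
        tf={"decim": 16, "freq_step": 2.0},
        permutation={"n_permutations": 500},
        pac={"n_surrogates": 100},
    )
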