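"""Pipeline orchestration: simulate -> extract -> power / bias / vibration /
spatio-temporal clustering from a single config.

Each stage writes its tables under a stage-named subdirectory of the output
directory; machine-readable metrics accumulate in ``metrics.json``
(validated against the schema shipped in ``spncat/schemas``), and
``manifest.json`` records the package version, a hash of the resolved
config, the seed, and per-stage completion status.  Reruns with an
identical config reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .bias import cumulative_distribution, egger_test, group_compare, random_effects_mean
from .catalogue import Catalogue, load_catalogue, save_catalogue
from .clusters import (
    cluster_permutation_test,
    cluster_window_spn,
    electrode_occurrence,
    most_significant_negative_cluster,
)
from .extraction import spn_summary
from .power import (
    PowerQuery,
    amplitude_regression,
    binomial_critical_count,
    fit_effect_model,
    power_table,
)
from .simulate import SynthConfig, generate_catalogue
from .vibration import DEFAULT_CLUSTERS, chi_square_independence, recompute_clusters

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES", "metrics_schema"]

log = logging.getLogger("spncat.pipeline")

STAGES = ("simulate", "extract", "power", "bias", "vibration", "stcluster")
_TSV_FLOAT = "%.10g"


class PipelineError(RuntimeError):
    pass


# --- metrics schema (pydantic models double as the published JSON schema) --


class PowerMetrics(BaseModel):
    effect_model: dict[str, float]
    amplitude_regression: dict[str, float]
    binomial_critical_24: Optional[int]
    binomial_critical_48: Optional[int]


class BiasMetrics(BaseModel):
    group_comparison: dict[str, float]
    meta: dict[str, dict[str, float]]
    egger: dict[str, float]
    n_significant: int


class VibrationMetrics(BaseModel):
    significance_counts: dict[str, int]
    chi_square: Optional[dict[str, float]]
    correlation_range: tuple[float, float]


class StClusterMetrics(BaseModel):
    n_experiments: int
    n_with_cluster: int
    apriori_datadriven_r: Optional[float]


class Metrics(BaseModel):
    power: Optional[PowerMetrics] = None
    bias: Optional[BiasMetrics] = None
    vibration: Optional[VibrationMetrics] = None
    stcluster: Optional[StClusterMetrics] = None


def metrics_schema() -> dict:
    """The JSON schema the pipeline's ``metrics.json`` validates against."""
    return Metrics.model_json_schema()


# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative pipeline run: input, stages, output, seed, overrides."""

    stages: tuple[str, ...]
    out: Path
    catalogue: Path | None = None
    synth: Mapping[str, Any] | None = None
    seed: int | None = None
    overrides: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.out = Path(self.out)
        if self.catalogue is not None:
            self.catalogue = Path(self.catalogue)
        if not self.stages:
            raise PipelineError("config enables no stages")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
        if self.catalogue is not None and self.out.resolve() == self.catalogue.resolve():
            raise PipelineError("output directory must differ from the input catalogue")
        stochastic = {"simulate", "stcluster"} & set(self.stages)
        if stochastic and self.seed is None:
            raise PipelineError(f"stages {sorted(stochastic)} need a seed")
        # dependency check, before any work
        have_catalogue = self.catalogue is not None or "simulate" in self.stages
        have_summaries = "extract" in self.stages
        for stage in self.stages:
            if stage in ("extract", "vibration", "stcluster") and not have_catalogue:
                raise PipelineError(f"stage {stage!r} needs a catalogue (input or simulate)")
            if stage in ("power", "bias") and not have_summaries:
                raise PipelineError(f"stage {stage!r} needs extract summaries")

    @classmethod
    def from_mapping(cls, obj: Mapping[str, Any], out: Path | None = None) -> "RunConfig":
        obj = dict(obj)
        if out is not None:
            obj["out"] = out
        return cls(
            stages=tuple(obj.get("stages", ())),
            out=Path(obj["out"]),
            catalogue=Path(obj["catalogue"]) if obj.get("catalogue") else None,
            synth=obj.get("synth"),
            seed=obj.get("seed"),
            overrides=obj.get("overrides", {}),
            log_level=obj.get("log_level", "INFO"),
        )

    def canonical(self) -> dict:
        # the output path is deliberately excluded: two runs of the same
        # analysis into different directories share a config hash
        return {
            "stages": list(self.stages),
            "catalogue": str(self.catalogue) if self.catalogue else None,
            "synth": dict(self.synth) if self.synth else None,
            "seed": self.seed,
            "overrides": {k: dict(v) for k, v in self.overrides.items()},
        }


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.canonical(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=_TSV_FLOAT)


def summaries_frame(catalogue: Catalogue, cluster=None, window=None) -> pd.DataFrame:
    """One row per experiment: SPN summary at its original (or a fixed)
    cluster/window plus the metadata the downstream stages need."""
    rows = []
    for exp in catalogue.experiments:
        cl = tuple(cluster) if cluster else exp.original_cluster
        win = tuple(window) if window else exp.original_window
        s = spn_summary(exp, cl, win, catalogue.montage)
        rows.append(
            dict(
                experiment_id=exp.id, cluster=",".join(cl),
                window_start_ms=win[0], window_end_ms=win[1],
                n=s.n, mean=s.mean, sd=s.sd, se=s.se, d_z=s.d_z, t=s.t, df=s.df,
                p_two_tailed=s.p_two_tailed, prop_directional=s.prop_directional,
                w_load=exp.w_load, task_relevant=exp.task_relevant,
                published=int(exp.published),
            )
        )
    return pd.DataFrame(rows)


def _summary_objects(frame: pd.DataFrame):
    from .extraction import SpnSummary

    out = []
    for _, row in frame.iterrows():
        n = int(row["n"])
        out.append(
            SpnSummary(
                experiment_id=str(row["experiment_id"]),
                cluster=tuple(str(row["cluster"]).split(",")),
                window=(float(row["window_start_ms"]), float(row["window_end_ms"])),
                n=n, diffs=(),
                mean=float(row["mean"]), sd=float(row["sd"]), se=float(row["se"]),
                d_z=float(row["d_z"]), t=float(row["t"]), df=n - 1,
                p_two_tailed=float(row["p_two_tailed"]),
                prop_directional=float(row["prop_directional"]),
            )
        )
    return out


def _maybe_figure(fn, path: Path) -> None:
    # figures are best-effort; the TSVs are the tested contract
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig = fn(plt)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=100)
        plt.close(fig)
    except Exception as err:  # pragma: no cover
        log.warning("figure %s skipped: %s", path.name, err)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Stage order is fixed (simulate, extract, power, bias, vibration,
    stcluster); a failing stage leaves earlier outputs intact, is marked
    ``failed`` in the manifest, and aborts the run with
    :class:`PipelineError`.
    """
    logging.basicConfig(level=config.log_level)
    out = config.out
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "spncat",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    metrics = Metrics()
    catalogue: Catalogue | None = None
    summaries: pd.DataFrame | None = None

    def _ov(stage: str) -> dict:
        return dict(config.overrides.get(stage, {}))

    ordered = [s for s in STAGES if s in config.stages]
    try:
        for stage in ordered:
            log.info("stage %s", stage)
            if stage == "simulate":
                synth = dict(config.synth or {})
                synth.setdefault("seed", config.seed)
                cfg = SynthConfig(**synth)
                catalogue = generate_catalogue(cfg)
                save_catalogue(catalogue, out / "simulate" / "catalogue")
            elif stage == "extract":
                if catalogue is None:
                    catalogue = load_catalogue(config.catalogue)
                ov = _ov("extract")
                summaries = summaries_frame(
                    catalogue, cluster=ov.get("cluster"), window=ov.get("window")
                )
                _write_tsv(summaries, out / "extract" / "summaries.tsv")
            elif stage == "power":
                assert summaries is not None
                ov = _ov("power")
                model = fit_effect_model(
                    list(zip(summaries["mean"], summaries["d_z"]))
                )
                reg = amplitude_regression(summaries)
                grid = ov.get("amplitudes") or list(np.arange(-3.5, -0.2499, 0.25))
                q = PowerQuery(
                    d=1.0, alpha=ov.get("alpha", 0.05),
                    target_power=ov.get("target_power", 0.8),
                )
                table = power_table(grid, model, q)
                _write_tsv(table, out / "power" / "required_n.tsv")
                metrics.power = PowerMetrics(
                    effect_model={
                        "a": model.a, "b": model.b, "c": model.c,
                        "r_squared": model.r_squared,
                    },
                    amplitude_regression={
                        "intercept": reg.intercept, "coef_w": reg.coef_w,
                        "coef_task": reg.coef_task, "r_squared": reg.r_squared,
                    },
                    binomial_critical_24=binomial_critical_count(24),
                    binomial_critical_48=binomial_critical_count(48),
                )
            elif stage == "bias":
                assert summaries is not None
                pub = summaries[summaries["published"] == 1]
                unpub = summaries[summaries["published"] == 0]
                objs = _summary_objects(summaries)
                cum = cumulative_distribution(objs)
                _write_tsv(cum, out / "bias" / "cumulative.tsv")
                funnel = summaries[["experiment_id", "mean", "se", "published"]]
                _write_tsv(funnel, out / "bias" / "funnel.tsv")
                meta = {
                    "all": random_effects_mean(list(zip(summaries["mean"], summaries["se"]))),
                }
                if len(pub) >= 1:
                    meta["published"] = random_effects_mean(list(zip(pub["mean"], pub["se"])))
                if len(unpub) >= 1:
                    meta["unpublished"] = random_effects_mean(list(zip(unpub["mean"], unpub["se"])))
                gc = None
                if len(pub) >= 2 and len(unpub) >= 2:
                    gc = group_compare(unpub["mean"], pub["mean"])
                eg = egger_test(list(zip(summaries["mean"], summaries["se"])))
                metrics.bias = BiasMetrics(
                    group_comparison=(
                        {"welch_t": gc.welch_t, "df": gc.satterthwaite_df, "p": gc.p,
                         "mean_difference": gc.mean_difference, "p_mann_whitney": gc.p_mw}
                        if gc else {}
                    ),
                    meta={
                        name: {"k": m.k, "weighted_mean": m.weighted_mean,
                               "ci_low": m.ci_low, "ci_high": m.ci_high,
                               "tau_squared": m.tau_squared, "i_squared": m.i_squared}
                        for name, m in meta.items()
                    },
                    egger={"intercept": eg.intercept, "t": eg.t, "p": eg.p},
                    n_significant=int(cum["significant"].sum()),
                )
                _maybe_figure(
                    lambda plt: _cumulative_figure(plt, cum), out / "bias" / "cumulative.png"
                )
                _maybe_figure(
                    lambda plt: _funnel_figure(plt, summaries), out / "bias" / "funnel.png"
                )
            elif stage == "vibration":
                if catalogue is None:
                    catalogue = load_catalogue(config.catalogue)
                ov = _ov("vibration")
                report = recompute_clusters(
                    catalogue,
                    clusters=ov.get("clusters", DEFAULT_CLUSTERS),
                    window=tuple(ov.get("window", (300.0, 1000.0))),
                )
                amp = report.amplitudes().reset_index(names="experiment_id")
                _write_tsv(amp, out / "vibration" / "amplitudes.tsv")
                counts = report.significance_counts
                n_exp = len(report.experiment_ids)
                counts_frame = pd.DataFrame(
                    [(k, v, n_exp - v) for k, v in counts.items()],
                    columns=["cluster", "significant", "non_significant"],
                )
                _write_tsv(counts_frame, out / "vibration" / "significance_counts.tsv")
                corr = report.correlation_matrix
                _write_tsv(
                    corr.reset_index(names="cluster"), out / "vibration" / "correlations.tsv"
                )
                chi = None
                table = counts_frame[["significant", "non_significant"]].to_numpy()
                try:
                    res = chi_square_independence(table)
                    chi = {"statistic": res.statistic, "df": float(res.df), "p": res.p}
                except ValueError:
                    log.info("chi-square skipped: degenerate counts table")
                off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
                metrics.vibration = VibrationMetrics(
                    significance_counts=counts,
                    chi_square=chi,
                    correlation_range=(float(off_diag.min()), float(off_diag.max())),
                )
            elif stage == "stcluster":
                if catalogue is None:
                    catalogue = load_catalogue(config.catalogue)
                ov = _ov("stcluster")
                n_perm = int(ov.get("n_permutations", 200))
                alpha = float(ov.get("cluster_alpha", 0.05))
                rows, best = [], []
                ss = np.random.SeedSequence(config.seed).spawn(len(catalogue.experiments))
                for exp, child in zip(catalogue.experiments, ss):
                    regular, random_ = exp.contrast
                    diffs = []
                    for pid in exp.participants:
                        r = exp.participants[pid][regular]
                        d = r.data - exp.participants[pid][random_].data
                        diffs.append(
                            type(r)(pid, "diff", d, r.sampling_rate, r.epoch_start)
                        )
                    res = cluster_permutation_test(
                        diffs, catalogue.montage, cluster_alpha=alpha,
                        n_permutations=n_perm,
                        seed=int(child.generate_state(1)[0] % (2**31)),
                    )
                    top = most_significant_negative_cluster(res)
                    best.append(top)
                    if top is not None:
                        step = 1000.0 / exp.sampling_rate
                        for lab, samp in sorted(top.members):
                            rows.append(
                                dict(experiment_id=exp.id, electrode=lab, sample=samp,
                                     time_ms=exp.epoch_start + samp * step,
                                     mass=top.mass, p=top.p)
                            )
                _write_tsv(
                    pd.DataFrame(rows, columns=[
                        "experiment_id", "electrode", "sample", "time_ms", "mass", "p",
                    ]),
                    out / "stcluster" / "clusters.tsv",
                )
                present = [c for c in best if c is not None]
                if present:
                    occ = electrode_occurrence(best, catalogue.montage)
                    _write_tsv(
                        pd.DataFrame(sorted(occ.items()), columns=["electrode", "proportion"]),
                        out / "stcluster" / "electrode_occurrence.tsv",
                    )
                r_val = None
                if len(present) >= 3:
                    apriori, datadriven = [], []
                    for exp, top in zip(catalogue.experiments, best):
                        if top is None:
                            continue
                        s_ap = spn_summary(
                            exp, exp.original_cluster, exp.original_window, catalogue.montage
                        )
                        s_dd = cluster_window_spn(exp, top, catalogue.montage)
                        apriori.append(s_ap.mean)
                        datadriven.append(s_dd.mean)
                    if np.std(apriori) > 0 and np.std(datadriven) > 0:
                        r_val = float(np.corrcoef(apriori, datadriven)[0, 1])
                metrics.stcluster = StClusterMetrics(
                    n_experiments=len(catalogue.experiments),
                    n_with_cluster=len(present),
                    apriori_datadriven_r=r_val,
                )
            manifest["stages"][stage] = "completed"
    except Exception as err:
        manifest["stages"][stage] = f"failed: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    (out / "metrics.json").write_text(
        json.dumps(metrics.model_dump(), indent=1, sort_keys=True)
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _cumulative_figure(plt, cum: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(cum))
    ax.plot(x, cum["mean"], color="tab:blue", label="mean")
    ax.fill_between(x, cum["ci_low"], cum["ci_high"], alpha=0.3)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("experiments (sorted by amplitude)")
    ax.set_ylabel("SPN amplitude (µV)")
    ax.legend()
    return fig


def _funnel_figure(plt, summaries: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(summaries["published"] == 1, "tab:green", "tab:red")
    ax.scatter(summaries["mean"], summaries["se"], c=colors, s=18)
    ax.invert_yaxis()
    ax.set_xlabel("mean amplitude (µV)")
    ax.set_ylabel("standard error (µV)")
    return fig
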